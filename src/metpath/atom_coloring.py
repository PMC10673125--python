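"""Canonical atom colors and count-feature matrices.

An *atom color* is a canonical string encoding one atom together with its
bonded neighborhood out to ``k`` bonds (the *bond inclusivity*).  At k=0 a
color is just the atom's element plus its chirality code, so the k=0 color
counts of a compound are its (non-hydrogen, by default plus explicit-H)
chemical formula.  At k>=1 the neighborhood is expanded bond by bond,
excluding hydrogen atoms, and each neighbor contributes a parenthesized
sub-string carrying its own recursive color and the connecting bond's
order/stereo descriptor.  Counting how often each color appears in each
compound, and concatenating the k=0..3 count vectors, yields the feature
matrix used by the downstream pathway classifiers.

Canonicalization contract: two rooted k-neighborhoods receive the same
string exactly when they are isomorphic as rooted labeled trees of simple
paths (same elements, chirality codes, bond orders and bond stereo), which
is achieved by sorting sibling sub-strings lexicographically at every level
and collapsing ``n`` identical siblings into a single ``n_``-prefixed
sub-string.  The serialization grammar is this package's own; it is designed
for uniqueness, not human readability.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .chem_graph import MolecularGraph

__all__ = [
    "AtomColor",
    "AtomColorVector",
    "FeatureMatrix",
    "color_atom",
    "compute_color_counts",
    "full_color_vector",
    "featurize",
    "drop_duplicate_columns",
    "find_duplicate_feature_vectors",
]

K_MAX_SUPPORTED = 3


class AtomColor(NamedTuple):
    """A canonical neighborhood string at a given bond inclusivity."""

    canonical: str
    inclusivity: int

    @property
    def label(self) -> str:
        """Column label used in feature matrices: ``k<k>|<canonical>``."""
        return f"k{self.inclusivity}|{self.canonical}"


@dataclass
class AtomColorVector:
    """Counts of each atom color present in one compound (absent = omitted)."""

    compound_id: str
    counts: dict[AtomColor, int]


def _check_k(k: int) -> None:
    if not 0 <= k <= K_MAX_SUPPORTED:
        raise ValueError(f"bond inclusivity must be in 0..{K_MAX_SUPPORTED}, got {k}")


def _collapse_siblings(pieces: list[str]) -> str:
    """Sort sibling sub-strings and collapse runs of n identical ones to n_(...)."""
    pieces.sort()
    out: list[str] = []
    i = 0
    while i < len(pieces):
        j = i
        while j < len(pieces) and pieces[j] == pieces[i]:
            j += 1
        n = j - i
        out.append(pieces[i] if n == 1 else f"{n}_{pieces[i]}")
        i = j
    return "".join(out)


def color_atom(
    g: MolecularGraph,
    atom_index: int,
    k: int,
    include_stereo: bool = True,
    _adj: list[list] | None = None,
) -> AtomColor:
    """Canonical color of one atom at bond inclusivity ``k``.

    The neighborhood is breadth-limited by bond count from the root; cycles
    are traversed without revisiting atoms already on the current path, so
    the expansion is a tree of simple paths.  Hydrogen atoms never appear in
    k>=1 neighborhoods.  ``include_stereo=False`` drops both the chirality
    suffix on atoms and the stereo digit on bonds (ablation switch).
    """
    _check_k(k)
    if not 0 <= atom_index < len(g.atoms):
        raise KeyError(f"atom index {atom_index} not in graph {g.source_id!r}")
    adj = _adj if _adj is not None else g.adjacency()
    atoms = g.atoms

    def node_code(i: int) -> str:
        a = atoms[i]
        return f"{a.element}{a.chirality}" if include_stereo else a.element

    def recurse(i: int, depth: int, path: frozenset[int]) -> str:
        root = node_code(i)
        if depth == 0:
            return root
        pieces: list[str] = []
        for j, bond in adj[i]:
            if j in path or atoms[j].element == "H":
                continue
            sub = recurse(j, depth - 1, path | {j})
            bd = f"{bond.order}{bond.stereo}" if include_stereo else f"{bond.order}"
            pieces.append(f"({sub}.{bd})")
        return root + _collapse_siblings(pieces)

    return AtomColor(recurse(atom_index, k, frozenset((atom_index,))), k)


def compute_color_counts(
    g: MolecularGraph,
    k: int,
    include_h_at_k0: bool = True,
    include_stereo: bool = True,
) -> AtomColorVector:
    """Color every eligible atom at level ``k`` and tally identical strings.

    Eligible atoms: all atoms at k=0 (explicit hydrogens included by default,
    yielding an ``H0`` color; set ``include_h_at_k0=False`` for a strictly
    non-hydrogen formula); non-hydrogen atoms only at k>=1.
    """
    _check_k(k)
    if len(g.atoms) == 0:
        raise ValueError(f"graph {g.source_id!r} has no atoms")
    adj = g.adjacency()
    counts: Counter[AtomColor] = Counter()
    for a in g.atoms:
        if a.element == "H" and not (k == 0 and include_h_at_k0):
            continue
        counts[color_atom(g, a.index, k, include_stereo=include_stereo, _adj=adj)] += 1
    return AtomColorVector(g.source_id, dict(counts))


def full_color_vector(
    g: MolecularGraph,
    k_max: int = K_MAX_SUPPORTED,
    include_h_at_k0: bool = True,
    include_stereo: bool = True,
) -> AtomColorVector:
    """Concatenated color counts for k = 0..k_max (used as merge/dedup key)."""
    counts: dict[AtomColor, int] = {}
    for k in range(k_max + 1):
        counts.update(compute_color_counts(g, k, include_h_at_k0, include_stereo).counts)
    return AtomColorVector(g.source_id, counts)


@dataclass
class FeatureMatrix:
    """Compound × atom-color count matrix.

    ``df`` has compound IDs as index and color labels (``k<k>|<canonical>``,
    ordered by inclusivity then lexicographically) as columns; values are
    non-negative integer counts.  ``dropped_columns`` maps each dropped
    duplicate column to the retained column it was value-identical with.
    """

    df: pd.DataFrame
    dropped_columns: dict[str, str] = field(default_factory=dict)

    @property
    def row_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def subset_rows(self, ids: Sequence[str]) -> "FeatureMatrix":
        return FeatureMatrix(self.df.loc[list(ids)], dict(self.dropped_columns))

    def values(self) -> np.ndarray:
        return self.df.to_numpy()

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index_label="compound_id")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        return cls(pd.read_csv(path, sep="\t", index_col="compound_id"))

    def to_triplets(self, path, dictionary_path=None) -> None:
        """Write nonzero cells as (compound_id, column_index, count) TSV,
        with the color-string ↔ column-index dictionary as JSON."""
        import json as _json

        rows, cols = np.nonzero(self.df.to_numpy())
        trip = pd.DataFrame(
            {
                "compound_id": self.df.index.to_numpy()[rows],
                "column_index": cols,
                "count": self.df.to_numpy()[rows, cols],
            }
        )
        trip.to_csv(path, sep="\t", index=False)
        if dictionary_path is not None:
            Path(dictionary_path).write_text(
                _json.dumps({c: i for i, c in enumerate(self.df.columns)}, indent=1)
            )

    @classmethod
    def from_triplets(cls, path, dictionary_path) -> "FeatureMatrix":
        import json as _json

        colmap = _json.loads(Path(dictionary_path).read_text())
        columns = [c for c, _ in sorted(colmap.items(), key=lambda kv: kv[1])]
        trip = pd.read_csv(path, sep="\t")
        ids = list(dict.fromkeys(trip["compound_id"]))
        df = pd.DataFrame(0, index=ids, columns=columns, dtype=np.int64)
        for cid, ci, n in zip(trip["compound_id"], trip["column_index"], trip["count"]):
            df.loc[cid, columns[int(ci)]] = int(n)
        return cls(df)


def _column_sort_key(label: str) -> tuple[int, str]:
    k_part, canonical = label.split("|", 1)
    return int(k_part[1:]), canonical


def featurize(
    graphs: Iterable[MolecularGraph],
    k_max: int = K_MAX_SUPPORTED,
    include_h_at_k0: bool = True,
    include_stereo: bool = True,
) -> FeatureMatrix:
    """Build the compound × color count matrix for k = 0..k_max.

    Columns are the union of colors observed at each inclusivity level,
    concatenated in k order then lexicographic; a cell is the count of that
    color in that compound (0 if absent), so every column has at least one
    nonzero value by construction.  Ambiguous-atom substitution is expected
    to have been applied to the inputs already.
    """
    _check_k(k_max)
    rows: list[dict[str, int]] = []
    ids: list[str] = []
    for g in graphs:
        vec = full_color_vector(g, k_max, include_h_at_k0, include_stereo)
        rows.append({c.label: n for c, n in vec.counts.items()})
        ids.append(g.source_id)
    if not rows:
        raise ValueError("featurize requires at least one graph")
    df = pd.DataFrame(rows, index=ids).fillna(0).astype(np.int64)
    df = df[sorted(df.columns, key=_column_sort_key)]
    return FeatureMatrix(df)


def drop_duplicate_columns(m: FeatureMatrix) -> FeatureMatrix:
    """Drop value-identical columns, keeping the first in column order.

    Duplicate columns carry no additional information and only slow model
    training; after rows are removed (curation), re-running this may drop
    further columns.  The dropped→kept mapping is recorded on the result
    (merged with any mapping already present).
    """
    df = m.df
    first_by_key: dict[bytes, str] = {}
    keep: list[str] = []
    mapping: dict[str, str] = dict(m.dropped_columns)
    for col in df.columns:
        key = df[col].to_numpy().tobytes()
        kept = first_by_key.get(key)
        if kept is None:
            first_by_key[key] = col
            keep.append(col)
        else:
            mapping[col] = kept
    return FeatureMatrix(df[keep].copy(), mapping)


def find_duplicate_feature_vectors(m: FeatureMatrix) -> list[list[str]]:
    """Groups (>= 2 members) of rows with identical feature vectors.

    Groups and their members are ordered by first appearance, so output is
    deterministic for a given row order.
    """
    by_key: dict[bytes, list[str]] = {}
    arr = m.df.to_numpy()
    for rid, row in zip(m.df.index, arr):
        by_key.setdefault(row.tobytes(), []).append(rid)
    return [grp for grp in by_key.values() if len(grp) >= 2]
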