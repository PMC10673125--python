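"""Synthetic molecular benchmarks with planted, size-dependent pathway signal.

The generator emulates the *structure* of a KEGG-derived metabolite dataset
without any download: small connected heavy-atom graphs over a realistic
element alphabet (optional chirality, bond orders and stereo, R-group and
repeat-unit markers), multi-label assignment over 12 broad pathway
categories with unbalanced positive proportions, and category-specific
planted substructure motifs.  Compounds below a configurable size threshold
receive labels drawn independently of their structure (pure noise), which
is what makes the information-content filtering analysis recoverable;
compounds at or above the threshold carry label *c* exactly when category
*c*'s motif was planted into them (optionally XOR-ed with label noise).

Motifs are tiny subgraphs built from elements deliberately absent from the
background alphabet, so motif presence is a clean, learnable signal.  No
valence model is enforced — the downstream pipeline consumes graphs, not
chemistry — but degrees are bounded so the graphs look molecule-like.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .chem_graph import Atom, Bond, MolecularGraph, write_molfile
from .dataset_pipeline import DEFAULT_CATEGORIES

__all__ = [
    "DEFAULT_CATEGORIES",
    "GeneratorConfig",
    "GroundTruth",
    "SyntheticBenchmark",
    "build_motif_library",
    "generate_molecule",
    "plant_motif",
    "generate_benchmark",
    "write_fixtures",
]

#: Rare elements reserved for motifs; never sampled into the background.
_MOTIF_ELEMENTS = ("F", "Cl", "Br", "I", "Si", "Se", "B", "As", "Ge", "Sn", "Sb", "Te")

_DEGREE_CAP = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 4}


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic benchmark.

    Defaults mirror the real dataset's shape at desk scale: 1200 compounds,
    12 unbalanced categories with positive proportions between 0.03 and
    0.25, an ambiguous (R-group / repeat-marker) fraction near 0.06, and a
    size spectrum concentrated on small metabolites.
    """

    n_compounds: int = 1200
    atom_count_range: tuple[int, int] = (6, 40)
    atom_count_log_mean: float = 2.5
    atom_count_log_sd: float = 0.45
    element_weights: dict[str, float] = field(
        default_factory=lambda: {"C": 0.58, "O": 0.20, "N": 0.13, "S": 0.05, "P": 0.04}
    )
    bond_order_probs: dict[int, float] = field(
        default_factory=lambda: {1: 0.78, 2: 0.18, 3: 0.04}
    )
    p_chiral: float = 0.10
    p_stereo_bond: float = 0.08
    ring_edge_rate: float = 0.6
    p_r_group: float = 0.04
    p_repeat_marker: float = 0.02
    n_categories: int = 12
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    positive_proportions: tuple[float, ...] = (
        0.25, 0.20, 0.17, 0.15, 0.13, 0.11, 0.09, 0.08, 0.06, 0.05, 0.04, 0.03,
    )
    signal_size_threshold: int = 8
    label_noise_rate: float = 0.0
    motif_scaffold_len: int = 2
    n_duplicate_molfiles: int = 2
    n_permuted_duplicates: int = 2
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.atom_count_range
        if lo < 1 or hi < lo:
            raise ValueError(f"infeasible atom count range {self.atom_count_range}")
        if self.n_categories < 2:
            raise ValueError("need at least 2 categories")
        if self.n_categories > len(_MOTIF_ELEMENTS):
            raise ValueError(
                f"at most {len(_MOTIF_ELEMENTS)} categories supported by the motif library"
            )
        if len(self.positive_proportions) < self.n_categories:
            raise ValueError("one positive proportion target per category required")
        for p in (
            self.p_chiral, self.p_stereo_bond, self.p_r_group,
            self.p_repeat_marker, self.label_noise_rate, *self.positive_proportions,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")


@dataclass
class GroundTruth:
    labels: pd.DataFrame  # bool, index compound_id, columns categories
    motifs: dict[str, str]  # category -> motif description
    duplicate_molfile_pairs: list[tuple[str, str]]
    duplicate_vector_pairs: list[tuple[str, str]]
    signal_size_threshold: int


@dataclass
class SyntheticBenchmark:
    graphs: dict[str, MolecularGraph]
    molfiles: dict[str, str]
    links: pd.DataFrame  # columns: compound_id, leaf
    hierarchy: pd.DataFrame  # columns: leaf, category
    metadata: pd.DataFrame  # columns: compound_id, NAME, COMMENT
    truth: GroundTruth
    categories: list[str]


def build_motif_library(
    n_categories: int = 12, scaffold_len: int = 2
) -> list[MolecularGraph]:
    """One small planted-signal motif per category.

    Each motif is a rare-element atom (never sampled into the background,
    so presence is unambiguous) carried on a short category-specific
    scaffold of common elements with a distinctive bond-order pattern.
    The scaffold emulates how informative substructures appear in real
    metabolites — embedded in a recurring chemical context rather than as
    a bare atom — so a planted motif contributes a correlated block of
    atom-color columns, not a single isolated one.
    """
    if n_categories > len(_MOTIF_ELEMENTS):
        raise ValueError("not enough motif elements")
    scaffold_elements = ("C", "C", "O", "N")
    motifs: list[MolecularGraph] = []
    for i in range(n_categories):
        el = _MOTIF_ELEMENTS[i]
        # rare atom -> chain of scaffold atoms, patterned per category
        atoms = [Atom(0, el)]
        bonds = []
        for j in range(scaffold_len):
            atoms.append(Atom(j + 1, scaffold_elements[(i + j) % len(scaffold_elements)]))
            order = 1 + ((i + j) % 2)
            bonds.append(Bond(j, j + 1, order=order))
        motifs.append(MolecularGraph(atoms, bonds, source_id=f"motif:{el}:{i}"))
    return motifs


def _sample_size(cfg: GeneratorConfig, rng: np.random.Generator) -> int:
    lo, hi = cfg.atom_count_range
    if lo == hi:
        return lo
    x = int(round(float(rng.lognormal(cfg.atom_count_log_mean, cfg.atom_count_log_sd))))
    return int(min(max(x, lo), hi))


def _sample_from(probs: dict, rng: np.random.Generator):
    keys = list(probs)
    w = np.asarray([probs[k] for k in keys], dtype=float)
    return keys[int(rng.choice(len(keys), p=w / w.sum()))]


def generate_molecule(
    cfg: GeneratorConfig, rng: np.random.Generator, size: int | None = None
) -> MolecularGraph:
    """Random connected heavy-atom graph within the configured size range.

    A random spanning tree (attachment respecting loose per-element degree
    caps) plus a few extra ring-closing edges; bond orders, bond stereo and
    atom chirality sampled per the configured probabilities; at most one
    ambiguity marker (R-group or repeat-unit atom) per molecule, sampled
    with probabilities ``p_r_group`` / ``p_repeat_marker``.  ``size``
    overrides the sampled atom count (used when motif planting must land
    the finished molecule on a target size).
    """
    cfg.validate()
    n = size if size is not None else _sample_size(cfg, rng)
    if n < 1:
        raise ValueError(f"molecule size must be >= 1, got {n}")
    elements = [_sample_from(cfg.element_weights, rng) for _ in range(n)]
    chirality = [
        (int(rng.integers(1, 3)) if rng.random() < cfg.p_chiral else 0) for _ in range(n)
    ]
    degree = np.zeros(n, dtype=int)
    bonds: list[Bond] = []
    bonded: set[tuple[int, int]] = set()

    def cap(i: int) -> int:
        return _DEGREE_CAP.get(elements[i], 4)

    def bond_attrs() -> tuple[int, int]:
        order = _sample_from(cfg.bond_order_probs, rng)
        stereo = int(rng.choice([1, 6])) if rng.random() < cfg.p_stereo_bond else 0
        return int(order), stereo

    for i in range(1, n):
        open_slots = [j for j in range(i) if degree[j] < cap(j)]
        parent = int(rng.choice(open_slots)) if open_slots else int(rng.integers(0, i))
        order, stereo = bond_attrs()
        bonds.append(Bond(parent, i, order=order, stereo=stereo))
        bonded.add((min(parent, i), max(parent, i)))
        degree[parent] += 1
        degree[i] += 1

    if n >= 4:
        for _ in range(int(rng.poisson(cfg.ring_edge_rate))):
            i, j = (int(v) for v in rng.choice(n, size=2, replace=False))
            lo, hi = min(i, j), max(i, j)
            if (lo, hi) in bonded or degree[i] >= cap(i) or degree[j] >= cap(j):
                continue
            bonds.append(Bond(lo, hi, order=1, stereo=0))
            bonded.add((lo, hi))
            degree[i] += 1
            degree[j] += 1

    atoms = [Atom(i, elements[i], chirality=chirality[i]) for i in range(n)]
    u = rng.random()
    marker_target = int(rng.integers(0, n))
    if u < cfg.p_r_group:
        atoms[marker_target] = Atom(marker_target, "R", is_r_group=True)
    elif u < cfg.p_r_group + cfg.p_repeat_marker:
        atoms[marker_target] = Atom(marker_target, "*", is_repeat_marker=True)
    return MolecularGraph(atoms, bonds)


def plant_motif(
    g: MolecularGraph, motif: MolecularGraph, rng: np.random.Generator
) -> MolecularGraph:
    """Attach a copy of ``motif`` to ``g`` by one new single bond.

    The returned graph contains the motif as a subgraph, so the motif's
    atom colors (at sufficient inclusivity) are guaranteed present; the
    result stays connected whenever ``g`` was.
    """
    if len(motif) >= len(g):
        raise ValueError(
            f"motif ({len(motif)} atoms) must be smaller than the host ({len(g)} atoms)"
        )
    off = len(g.atoms)
    atoms = list(g.atoms) + [
        Atom(off + a.index, a.element, a.chirality, a.is_r_group, a.is_repeat_marker)
        for a in motif.atoms
    ]
    bonds = list(g.bonds) + [
        Bond(off + b.a, off + b.b, order=b.order, stereo=b.stereo) for b in motif.bonds
    ]
    hosts = [a.index for a in g.atoms if a.element != "H"]
    host = int(rng.choice(hosts))
    bonds.append(Bond(host, off, order=1, stereo=0))
    return MolecularGraph(atoms, bonds, source_id=g.source_id)


_KEYWORD_COMMENTS = (
    "Acyl-enzyme reaction intermediate",
    "Peptide carrier conjugate",
    "Bound to a transfer RNA species",
)


def generate_benchmark(cfg: GeneratorConfig | None = None) -> SyntheticBenchmark:
    """Generate the full fixture set a pipeline run consumes.

    Emits molecular graphs and V2000 molfile texts, a compound→pathway-leaf
    link table, a leaf→category hierarchy (including an overview leaf
    outside the 12 categories, linked by unlabeled compounds so the label
    linker's exclusion path is exercised), entry metadata with a few
    keyword-flagged rows for the curation workflow, deliberately duplicated
    molfiles (byte-identical and atom-permuted), and the ground truth.
    """
    cfg = cfg or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    cats = list(cfg.categories[: cfg.n_categories])
    props = np.asarray(cfg.positive_proportions[: cfg.n_categories], dtype=float)
    motifs = build_motif_library(cfg.n_categories, cfg.motif_scaffold_len)

    graphs: dict[str, MolecularGraph] = {}
    labels_rows: list[np.ndarray] = []
    ids: list[str] = []
    for i in range(cfg.n_compounds):
        cid = f"S{i:05d}"
        target = _sample_size(cfg, rng)
        eligible = target >= cfg.signal_size_threshold
        lab = rng.random(cfg.n_categories) < props
        if eligible and lab.any():
            # pre-shrink the base graph so the finished molecule lands on
            # the sampled size despite the planted motif atoms
            planted_atoms = int(sum(len(motifs[ci]) for ci in np.flatnonzero(lab)))
            min_base = max(len(m) for m in motifs) + 1
            base = max(min_base, target - planted_atoms)
            g = generate_molecule(cfg, rng, size=base)
            for ci in np.flatnonzero(lab):
                g = plant_motif(g, motifs[ci], rng)
        else:
            g = generate_molecule(cfg, rng, size=target)
        if cfg.label_noise_rate > 0:
            lab ^= rng.random(cfg.n_categories) < cfg.label_noise_rate
        g.source_id = cid
        graphs[cid] = g
        ids.append(cid)
        labels_rows.append(lab)

    labels = pd.DataFrame(np.vstack(labels_rows), index=ids, columns=cats)

    # Deliberate duplicates: byte-identical clones and atom-permuted clones
    # (identical color vectors, different bytes).  Clones get one extra
    # label so merging must union labels.
    dup_pairs: list[tuple[str, str]] = []
    vec_pairs: list[tuple[str, str]] = []
    labeled_ids = [cid for cid in ids if labels.loc[cid].any()]
    next_i = cfg.n_compounds
    for j in range(min(cfg.n_duplicate_molfiles, len(labeled_ids))):
        src = labeled_ids[j]
        cid = f"S{next_i:05d}"
        next_i += 1
        graphs[cid] = MolecularGraph(
            list(graphs[src].atoms), list(graphs[src].bonds), source_id=cid
        )
        lab = labels.loc[src].to_numpy().copy()
        lab[int(rng.integers(0, cfg.n_categories))] = True
        labels.loc[cid] = lab
        dup_pairs.append((src, cid))
    for j in range(min(cfg.n_permuted_duplicates, len(labeled_ids) - cfg.n_duplicate_molfiles)):
        src = labeled_ids[cfg.n_duplicate_molfiles + j]
        cid = f"S{next_i:05d}"
        next_i += 1
        g = graphs[src]
        perm = rng.permutation(len(g.atoms))
        inv = np.empty_like(perm)
        inv[perm] = np.arange(len(perm))
        atoms = [None] * len(g.atoms)
        for a in g.atoms:
            atoms[inv[a.index]] = Atom(
                int(inv[a.index]), a.element, a.chirality, a.is_r_group, a.is_repeat_marker
            )
        bonds = [
            Bond(int(inv[b.a]), int(inv[b.b]), order=b.order, stereo=b.stereo)
            for b in g.bonds
        ]
        graphs[cid] = MolecularGraph(atoms, bonds, source_id=cid)
        labels.loc[cid] = labels.loc[src].to_numpy()
        vec_pairs.append((src, cid))

    molfiles = {cid: write_molfile(g, name="") for cid, g in graphs.items()}

    # Hierarchy: two leaves per category, plus an overview leaf outside the
    # 12 categories that unlabeled compounds link to.
    hier_rows = []
    for ci, cat in enumerate(cats):
        hier_rows.append((f"L{ci:02d}A", cat))
        hier_rows.append((f"L{ci:02d}B", cat))
    hier_rows.append(("L_OVERVIEW", "Global and overview maps"))
    hierarchy = pd.DataFrame(hier_rows, columns=["leaf", "category"])

    link_rows = []
    for cid in graphs:
        row = labels.loc[cid]
        if row.any():
            for ci in np.flatnonzero(row.to_numpy()):
                leaf = f"L{ci:02d}{'A' if rng.random() < 0.7 else 'B'}"
                link_rows.append((cid, leaf))
        else:
            link_rows.append((cid, "L_OVERVIEW"))
    links = pd.DataFrame(link_rows, columns=["compound_id", "leaf"])

    meta_rows = []
    kw_i = 0
    for cid in graphs:
        has_r = any(a.is_r_group for a in graphs[cid].atoms)
        comment = ""
        if has_r and kw_i % 2 == 0:
            comment = _KEYWORD_COMMENTS[(kw_i // 2) % len(_KEYWORD_COMMENTS)]
        if has_r:
            kw_i += 1
        meta_rows.append((cid, f"Synthetic metabolite {cid}", comment))
    metadata = pd.DataFrame(meta_rows, columns=["compound_id", "NAME", "COMMENT"])

    truth = GroundTruth(
        labels=labels.astype(bool),
        motifs={cats[i]: motifs[i].source_id for i in range(cfg.n_categories)},
        duplicate_molfile_pairs=dup_pairs,
        duplicate_vector_pairs=vec_pairs,
        signal_size_threshold=cfg.signal_size_threshold,
    )
    return SyntheticBenchmark(graphs, molfiles, links, hierarchy, metadata, truth, cats)


def write_fixtures(bench: SyntheticBenchmark, out_dir: str | Path) -> Path:
    """Write the fixture bundle (molfiles + TSVs + ground-truth JSON) to disk.

    Deterministic: the same config seed yields byte-identical files.
    """
    out = Path(out_dir)
    (out / "molfiles").mkdir(parents=True, exist_ok=True)
    for cid, text in sorted(bench.molfiles.items()):
        (out / "molfiles" / f"{cid}.mol").write_text(text)
    bench.links.to_csv(out / "links.tsv", sep="\t", index=False)
    bench.hierarchy.to_csv(out / "hierarchy.tsv", sep="\t", index=False)
    bench.metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
    truth = {
        "labels": {
            cid: [bool(v) for v in row]
            for cid, row in zip(bench.truth.labels.index, bench.truth.labels.to_numpy())
        },
        "categories": bench.categories,
        "motifs": bench.truth.motifs,
        "duplicate_molfile_pairs": bench.truth.duplicate_molfile_pairs,
        "duplicate_vector_pairs": bench.truth.duplicate_vector_pairs,
        "signal_size_threshold": bench.truth.signal_size_threshold,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    return out
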