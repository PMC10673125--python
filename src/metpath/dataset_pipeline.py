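"""Benchmark dataset assembly: labels, dedup/merging, curation, filtering.

The pipeline mirrors the cascade used to build a KEGG-style metabolite
benchmark: link each compound to the broad pathway categories sitting one
level above its leaf pathways, drop compounds without metabolic links,
merge entries whose molfiles are identical (or whose full atom-color
vectors coincide), featurize, filter out compounds with too few
non-hydrogen atoms, apply semi-manual curation instructions, and drop
value-duplicate feature columns.  Every step appends a provenance row
(step name, entries before, entries after) so counts reconcile end to end.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .atom_coloring import (
    FeatureMatrix,
    drop_duplicate_columns,
    featurize,
    find_duplicate_feature_vectors,
    full_color_vector,
)
from .chem_graph import (
    MolecularGraph,
    count_non_hydrogen_atoms,
    detect_ambiguity,
    read_molfile_dir,
    substitute_ambiguous,
    write_molfile,
)

__all__ = [
    "CURATION_KEYWORDS",
    "DatasetEntry",
    "CurationAction",
    "BenchmarkDataset",
    "CompoundSource",
    "DirectoryCompoundSource",
    "link_pathway_labels",
    "merge_duplicate_molfiles",
    "find_keyword_hits",
    "generate_curation_template",
    "apply_curation",
    "filter_by_atom_count",
    "split_ambiguous",
    "build_dataset",
    "write_bundle",
    "read_bundle",
    "read_curation_tsv",
    "write_curation_tsv",
]

#: Keywords whose presence in an entry's NAME or COMMENT flags it as a
#: potential macromolecule (protein / nucleic acid) during curation.
CURATION_KEYWORDS = ("protein", "enzyme", "peptide", "rna", "dna")

#: The 12 broad KEGG 'Metabolism' branches, excluding the catchall
#: 'Global and overview maps'; the default binary classification targets.
DEFAULT_CATEGORIES = (
    "Amino acid metabolism",
    "Biosynthesis of other secondary metabolites",
    "Carbohydrate metabolism",
    "Chemical structure transformation maps",
    "Energy metabolism",
    "Glycan biosynthesis and metabolism",
    "Lipid metabolism",
    "Metabolism of cofactors and vitamins",
    "Metabolism of other amino acids",
    "Metabolism of terpenoids and polyketides",
    "Nucleotide metabolism",
    "Xenobiotics biodegradation and metabolism",
)


@dataclass
class DatasetEntry:
    compound_id: str
    labels: np.ndarray  # bool vector aligned with the dataset's categories
    merged_ids: set[str] = field(default_factory=set)
    graph: MolecularGraph | None = None
    ambiguous: bool = False
    non_h_count: int = 0


@dataclass(frozen=True)
class CurationAction:
    compound_ids: tuple[str, ...]
    action: str  # merge | remove | keep
    reason: str = ""

    def __post_init__(self) -> None:
        if self.action not in ("merge", "remove", "keep"):
            raise ValueError(f"unknown curation action {self.action!r}")
        need = 2 if self.action == "merge" else 1
        if len(self.compound_ids) < need:
            raise ValueError(
                f"action {self.action!r} requires >= {need} compound IDs, "
                f"got {len(self.compound_ids)}"
            )


@dataclass
class BenchmarkDataset:
    """Entries + aligned feature matrix + step-by-step provenance."""

    entries: list[DatasetEntry]
    features: FeatureMatrix
    categories: list[str]
    provenance: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.features.row_ids != [e.compound_id for e in self.entries]:
            raise ValueError("feature rows are not aligned with entries")

    @property
    def ids(self) -> list[str]:
        return [e.compound_id for e in self.entries]

    def labels_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            np.vstack([e.labels for e in self.entries]) if self.entries
            else np.zeros((0, len(self.categories)), bool),
            index=self.ids,
            columns=self.categories,
        ).astype(bool)

    def ambiguous_mask(self) -> np.ndarray:
        return np.asarray([e.ambiguous for e in self.entries], dtype=bool)

    def record(self, step: str, before: int, after: int) -> None:
        self.provenance.append((step, before, after))

    def _subset(self, keep_ids: list[str], step: str) -> "BenchmarkDataset":
        before = len(self.entries)
        keep = set(keep_ids)
        entries = [e for e in self.entries if e.compound_id in keep]
        ds = BenchmarkDataset(
            entries=entries,
            features=self.features.subset_rows([e.compound_id for e in entries]),
            categories=list(self.categories),
            provenance=list(self.provenance),
        )
        ds.record(step, before, len(entries))
        return ds


class CompoundSource:
    """Adapter interface for obtaining compound molecular graphs.

    A live-database fetcher (with its own pagination and rate limiting)
    would implement the same two methods; the bundled implementation reads
    a directory of molfiles keyed by filename stem.  Whether label linking
    should use leaf pathway IDs or names upstream is a property of the
    source and is left to the adapter.
    """

    def compound_ids(self) -> list[str]:
        raise NotImplementedError

    def graphs(self) -> dict[str, MolecularGraph]:
        raise NotImplementedError


class DirectoryCompoundSource(CompoundSource):
    def __init__(self, molfile_dir: str | Path):
        self.molfile_dir = Path(molfile_dir)

    def compound_ids(self) -> list[str]:
        return sorted(p.stem for p in self.molfile_dir.glob("*.mol"))

    def graphs(self) -> dict[str, MolecularGraph]:
        return read_molfile_dir(self.molfile_dir)


def link_pathway_labels(
    compound_to_leaf: pd.DataFrame,
    leaf_to_category: pd.DataFrame,
    categories: list[str] | None = None,
) -> tuple[dict[str, np.ndarray], list[str]]:
    """Map each compound to a boolean vector over the broad categories.

    A label is true iff the compound links to at least one leaf under that
    category; compounds whose links all fall outside the category list
    (e.g. overview maps) are excluded from the output.  Leaves absent from
    the hierarchy are warned about and returned, never silently dropped.
    """
    leaf_map = dict(zip(leaf_to_category["leaf"], leaf_to_category["category"]))
    if categories is None:
        categories = sorted(set(leaf_map.values()))
    cat_index = {c: i for i, c in enumerate(categories)}
    unknown: list[str] = []
    out: dict[str, np.ndarray] = {}
    for cid, leaf in zip(compound_to_leaf["compound_id"], compound_to_leaf["leaf"]):
        cat = leaf_map.get(leaf)
        if cat is None:
            unknown.append(leaf)
            continue
        ci = cat_index.get(cat)
        if ci is None:
            continue  # linked, but outside the requested category set
        vec = out.setdefault(cid, np.zeros(len(categories), dtype=bool))
        vec[ci] = True
    if unknown:
        uniq = sorted(set(unknown))
        warnings.warn(
            f"{len(uniq)} leaf ID(s) missing from the hierarchy, affected links "
            f"excluded: {uniq[:5]}{'...' if len(uniq) > 5 else ''}",
            stacklevel=2,
        )
    return out, sorted(set(unknown))


def _merge_key(entry: DatasetEntry, mode: str) -> object:
    if mode == "bytes":
        return write_molfile(entry.graph, name="")
    if mode == "color-vector":
        vec = full_color_vector(substitute_ambiguous(entry.graph))
        return tuple(sorted((c.label, n) for c, n in vec.counts.items()))
    raise ValueError(f"unknown merge equivalence mode {mode!r}")


def merge_duplicate_molfiles(
    entries: list[DatasetEntry], equivalence: str = "bytes"
) -> list[DatasetEntry]:
    """Merge entries with equivalent molfiles into one representative each.

    Equivalence is either byte-identity of the (normalized) molfile or
    identity of the full k=0..3 atom-color vector.  Within each class the
    lexicographically smallest compound ID is kept, its pathway labels
    become the union over the class, and absorbed IDs are recorded in
    ``merged_ids``.  Output preserves the order of the kept entries.
    """
    groups: dict[object, list[DatasetEntry]] = {}
    for e in entries:
        groups.setdefault(_merge_key(e, equivalence), []).append(e)
    merged: dict[str, DatasetEntry] = {}
    for grp in groups.values():
        keeper = min(grp, key=lambda e: e.compound_id)
        labels = keeper.labels.copy()
        merged_ids = set(keeper.merged_ids)
        for e in grp:
            labels |= e.labels
            if e.compound_id != keeper.compound_id:
                merged_ids.add(e.compound_id)
                merged_ids |= e.merged_ids
        merged[keeper.compound_id] = replace(
            keeper, labels=labels, merged_ids=merged_ids
        )
    return [merged[e.compound_id] for e in entries if e.compound_id in merged]


def find_keyword_hits(
    metadata: pd.DataFrame, keywords: tuple[str, ...] = CURATION_KEYWORDS
) -> dict[str, list[str]]:
    """Case-insensitive substring search over the NAME and COMMENT fields."""
    hits: dict[str, list[str]] = {}
    for _, row in metadata.iterrows():
        text = f"{row.get('NAME', '')} {row.get('COMMENT', '')}".lower()
        matched = [k for k in keywords if k in text]
        if matched:
            hits[str(row["compound_id"])] = matched
    return hits


def generate_curation_template(
    dup_groups: list[list[str]], keyword_hits: dict[str, list[str]]
) -> pd.DataFrame:
    """One empty-action template row per duplicate-vector group and per
    keyword-flagged compound, for a curator to fill in."""
    rows = []
    for grp in dup_groups:
        rows.append((";".join(grp), "duplicate_feature_vector", "", ""))
    for cid in sorted(keyword_hits):
        rows.append((cid, "keyword:" + ",".join(keyword_hits[cid]), "", ""))
    return pd.DataFrame(rows, columns=["compound_ids", "flagged_for", "action", "reason"])


def write_curation_tsv(template: pd.DataFrame, path: str | Path) -> None:
    template.to_csv(path, sep="\t", index=False)


def read_curation_tsv(path: str | Path) -> list[CurationAction]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    actions = []
    for _, row in df.iterrows():
        action = str(row.get("action", "")).strip()
        if not action:
            continue
        actions.append(
            CurationAction(
                compound_ids=tuple(str(row["compound_ids"]).split(";")),
                action=action,
                reason=str(row.get("reason", "")),
            )
        )
    return actions


def apply_curation(
    dataset: BenchmarkDataset, actions: list[CurationAction]
) -> BenchmarkDataset:
    """Apply curator instructions (merge / remove / keep), all-or-nothing.

    Validation happens before any mutation: every referenced ID must exist
    and no ID may appear in more than one action.  Merges union labels and
    keep the lexicographically smallest ID; removals delete the entry;
    keeps are recorded no-ops.  Duplicate feature columns are re-dropped
    afterwards, since removing rows can create new value-identical columns.
    """
    known = set(dataset.ids)
    seen: set[str] = set()
    for act in actions:
        for cid in act.compound_ids:
            if cid not in known:
                raise ValueError(f"curation references unknown compound ID {cid!r}")
            if cid in seen:
                raise ValueError(f"compound ID {cid!r} appears in more than one action")
            seen.add(cid)

    before = len(dataset.entries)
    by_id = {e.compound_id: e for e in dataset.entries}
    removed: set[str] = set()
    for act in actions:
        if act.action == "remove":
            removed.update(act.compound_ids)
        elif act.action == "merge":
            keeper_id = min(act.compound_ids)
            keeper = by_id[keeper_id]
            labels = keeper.labels.copy()
            merged_ids = set(keeper.merged_ids)
            for cid in act.compound_ids:
                labels |= by_id[cid].labels
                if cid != keeper_id:
                    merged_ids.add(cid)
                    merged_ids |= by_id[cid].merged_ids
                    removed.add(cid)
            by_id[keeper_id] = replace(keeper, labels=labels, merged_ids=merged_ids)

    entries = [by_id[e.compound_id] for e in dataset.entries if e.compound_id not in removed]
    feats = dataset.features.subset_rows([e.compound_id for e in entries])
    feats = drop_duplicate_columns(feats)
    ds = BenchmarkDataset(
        entries=entries,
        features=feats,
        categories=list(dataset.categories),
        provenance=list(dataset.provenance),
    )
    ds.record("curation", before, len(entries))
    return ds


def filter_by_atom_count(dataset: BenchmarkDataset, threshold: int) -> BenchmarkDataset:
    """Retain entries with at least ``threshold`` non-hydrogen atoms."""
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    keep = [e.compound_id for e in dataset.entries if e.non_h_count >= threshold]
    if not keep:
        warnings.warn(
            f"atom-count threshold {threshold} removed every entry", stacklevel=2
        )
    return dataset._subset(keep, f"atom_count_filter(>={threshold})")


def split_ambiguous(
    dataset: BenchmarkDataset,
) -> tuple[BenchmarkDataset, BenchmarkDataset]:
    """Partition into (ambiguous, non-ambiguous) subsets.

    The subsets are mutually exclusive, their sizes sum to the full size,
    and all three datasets share the identical feature column set.
    """
    amb_ids = [e.compound_id for e in dataset.entries if e.ambiguous]
    non_ids = [e.compound_id for e in dataset.entries if not e.ambiguous]
    return dataset._subset(amb_ids, "split:ambiguous"), dataset._subset(
        non_ids, "split:non_ambiguous"
    )


def build_dataset(
    molfiles: dict[str, MolecularGraph] | str | Path,
    links: pd.DataFrame,
    hierarchy: pd.DataFrame,
    categories: list[str] | None = None,
    metadata: pd.DataFrame | None = None,
    curation: list[CurationAction] | None = None,
    min_atoms: int = 0,
    merge_equivalence: str = "bytes",
    k_max: int = 3,
) -> BenchmarkDataset:
    """Run the full assembly cascade and return the benchmark dataset.

    R-group / repeat-marker substitution is applied before featurization;
    the original ambiguity flags are retained on the entries.
    """
    if isinstance(molfiles, dict):
        graphs = molfiles
    elif isinstance(molfiles, CompoundSource):
        graphs = molfiles.graphs()
    else:
        graphs = read_molfile_dir(molfiles)
    if categories is None:
        present = {c for c in hierarchy["category"]}
        categories = [c for c in DEFAULT_CATEGORIES if c in present] or sorted(present)
    label_map, _unknown = link_pathway_labels(links, hierarchy, categories)
    n_source = len(graphs)

    entries: list[DatasetEntry] = []
    for cid in sorted(graphs):
        if cid not in label_map:
            continue
        g = graphs[cid]
        has_r, has_rep = detect_ambiguity(g)
        entries.append(
            DatasetEntry(
                compound_id=cid,
                labels=label_map[cid],
                graph=g,
                ambiguous=has_r or has_rep,
                non_h_count=count_non_hydrogen_atoms(g),
            )
        )
    n_labeled = len(entries)
    entries = merge_duplicate_molfiles(entries, equivalence=merge_equivalence)
    n_merged = len(entries)

    feats = featurize(
        [substitute_ambiguous(e.graph) for e in entries], k_max=k_max
    )
    feats = drop_duplicate_columns(feats)
    ds = BenchmarkDataset(entries=entries, features=feats, categories=list(categories))
    ds.record("loaded", n_source, n_source)
    ds.record("pathway_label_link", n_source, n_labeled)
    ds.record(f"merge_duplicate_molfiles({merge_equivalence})", n_labeled, n_merged)
    # re-sync the earlier records into provenance order before later filters
    if min_atoms > 0:
        ds = filter_by_atom_count(ds, min_atoms)
    if curation:
        ds = apply_curation(ds, curation)
    return ds


def write_bundle(dataset: BenchmarkDataset, out_dir: str | Path) -> Path:
    """Persist features, labels, flags and provenance as TSV/JSON files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset.features.to_tsv(out / "features.tsv")
    dataset.labels_frame().astype(int).to_csv(
        out / "labels.tsv", sep="\t", index_label="compound_id"
    )
    flags = pd.DataFrame(
        {
            "compound_id": dataset.ids,
            "ambiguous": [int(e.ambiguous) for e in dataset.entries],
            "non_h_count": [e.non_h_count for e in dataset.entries],
            "merged_ids": [";".join(sorted(e.merged_ids)) for e in dataset.entries],
        }
    )
    flags.to_csv(out / "flags.tsv", sep="\t", index=False)
    (out / "provenance.json").write_text(
        json.dumps(
            {
                "categories": dataset.categories,
                "steps": [
                    {"step": s, "before": b, "after": a}
                    for s, b, a in dataset.provenance
                ],
            },
            indent=1,
        )
    )
    return out


def read_bundle(bundle_dir: str | Path) -> BenchmarkDataset:
    """Load a bundle written by :func:`write_bundle` (graphs are not kept)."""
    d = Path(bundle_dir)
    feats = FeatureMatrix.from_tsv(d / "features.tsv")
    labels = pd.read_csv(d / "labels.tsv", sep="\t", index_col="compound_id").astype(bool)
    flags = pd.read_csv(
        d / "flags.tsv", sep="\t", index_col="compound_id", keep_default_na=False
    )
    meta = json.loads((d / "provenance.json").read_text())
    entries = []
    for cid in feats.row_ids:
        merged = flags.loc[cid, "merged_ids"]
        entries.append(
            DatasetEntry(
                compound_id=str(cid),
                labels=labels.loc[cid].to_numpy(),
                merged_ids=set(str(merged).split(";")) if str(merged) else set(),
                ambiguous=bool(flags.loc[cid, "ambiguous"]),
                non_h_count=int(flags.loc[cid, "non_h_count"]),
            )
        )
    return BenchmarkDataset(
        entries=entries,
        features=feats,
        categories=list(meta["categories"]),
        provenance=[(s["step"], s["before"], s["after"]) for s in meta["steps"]],
    )
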