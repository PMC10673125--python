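import numpy as np
import pandas as pd
import pytest

from metpath.chem_graph import Atom, Bond, MolecularGraph
from metpath.dataset_pipeline import (
    BenchmarkDataset,
    CurationAction,
    DatasetEntry,
    apply_curation,
    build_dataset,
    filter_by_atom_count,
    find_keyword_hits,
    generate_curation_template,
    link_pathway_labels,
    merge_duplicate_molfiles,
    read_bundle,
    split_ambiguous,
    write_bundle,
)


def _links(rows):
    return pd.DataFrame(rows, columns=["compound_id", "leaf"])


def _hier(rows):
    return pd.DataFrame(rows, columns=["leaf", "category"])


HIER = _hier([("L1", "CatA"), ("L2", "CatA"), ("L3", "CatB"), ("L4", "CatC"),
              ("L9", "Overview")])


class TestLinkPathwayLabels:
    def test_two_leaves_one_category(self):
        labels, unknown = link_pathway_labels(
            _links([("c1", "L1"), ("c1", "L2")]), HIER, ["CatA", "CatB", "CatC"]
        )
        assert labels["c1"].tolist() == [True, False, False]
        assert unknown == []

    def test_three_categories(self):
        labels, _ = link_pathway_labels(
            _links([("c1", "L1"), ("c1", "L3"), ("c1", "L4")]),
            HIER, ["CatA", "CatB", "CatC"],
        )
        assert labels["c1"].sum() == 3

    def test_non_metabolic_only_excluded(self):
        labels, _ = link_pathway_labels(
            _links([("c1", "L9")]), HIER, ["CatA", "CatB", "CatC"]
        )
        assert "c1" not in labels

    def test_unknown_leaf_warned_and_reported(self):
        with pytest.warns(UserWarning, match="missing from the hierarchy"):
            labels, unknown = link_pathway_labels(
                _links([("c1", "L1"), ("c2", "LX")]), HIER, ["CatA"]
            )
        assert unknown == ["LX"] and "c2" not in labels


def _entry(cid, labels, element="C", n_atoms=3, chir=0):
    atoms = [Atom(i, element, chirality=chir if i == 0 else 0) for i in range(n_atoms)]
    bonds = [Bond(i, i + 1) for i in range(n_atoms - 1)]
    g = MolecularGraph(atoms, bonds, source_id=cid)
    return DatasetEntry(
        compound_id=cid, labels=np.asarray(labels, bool), graph=g,
        non_h_count=n_atoms,
    )


class TestMergeDuplicates:
    def test_identical_molfiles_union_labels(self):
        a = _entry("c2", [True, False])
        b = _entry("c1", [False, True])
        merged = merge_duplicate_molfiles([a, b], equivalence="bytes")
        assert len(merged) == 1
        assert merged[0].compound_id == "c1"  # lexicographically smallest kept
        assert merged[0].labels.tolist() == [True, True]
        assert merged[0].merged_ids == {"c2"}

    def test_distinct_entries_unchanged(self):
        a = _entry("c1", [True, False], n_atoms=3)
        b = _entry("c2", [False, True], n_atoms=4)
        merged = merge_duplicate_molfiles([a, b])
        assert [e.compound_id for e in merged] == ["c1", "c2"]

    def test_three_way_duplicate(self):
        entries = [_entry(c, [True, False]) for c in ("c3", "c1", "c2")]
        merged = merge_duplicate_molfiles(entries)
        assert len(merged) == 1
        assert merged[0].merged_ids == {"c2", "c3"}

    def test_color_vector_mode_merges_permuted_atoms(self):
        a = _entry("c1", [True, False], n_atoms=3)
        g = MolecularGraph(
            [Atom(0, "C"), Atom(1, "C"), Atom(2, "C")], [Bond(0, 2), Bond(1, 2)], "c2"
        )  # same chain, different atom order -> different bytes
        b = DatasetEntry("c2", np.array([False, True]), graph=g, non_h_count=3)
        assert len(merge_duplicate_molfiles([a, b], "bytes")) == 2
        assert len(merge_duplicate_molfiles([a, b], "color-vector")) == 1


class TestCurationWorkflow:
    def test_keyword_matching_case_insensitive(self):
        meta = pd.DataFrame(
            {"compound_id": ["c1", "c2", "c3"],
             "NAME": ["An Enzyme intermediate", "glucose", "tRNA adduct"],
             "COMMENT": ["", "", ""]}
        )
        hits = find_keyword_hits(meta)
        assert hits == {"c1": ["enzyme"], "c3": ["rna"]}

    def test_template_rows(self):
        t = generate_curation_template([["c1", "c2"]], {"c3": ["dna"]})
        assert len(t) == 2
        assert t.loc[0, "compound_ids"] == "c1;c2"
        assert (t["action"] == "").all()

    def test_empty_template_has_header(self):
        t = generate_curation_template([], {})
        assert len(t) == 0
        assert list(t.columns) == ["compound_ids", "flagged_for", "action", "reason"]

    def test_action_validation(self):
        with pytest.raises(ValueError, match=">= 2"):
            CurationAction(("c1",), "merge")
        with pytest.raises(ValueError, match="unknown curation action"):
            CurationAction(("c1",), "zap")


def _mini_dataset(n=10, n_cat=2):
    from metpath.atom_coloring import featurize

    entries = []
    for i in range(n):
        labels = [i % 2 == 0, i % 3 == 0]
        entries.append(_entry(f"c{i}", labels, n_atoms=3 + i % 5, chir=i % 3))
    fm = featurize([e.graph for e in entries])
    for i, e in enumerate(entries):
        e.ambiguous = i < 2
    return BenchmarkDataset(entries, fm, ["CatA", "CatB"])


class TestApplyCuration:
    def test_remove_one_of_ten(self):
        ds = apply_curation(_mini_dataset(), [CurationAction(("c3",), "remove")])
        assert len(ds.entries) == 9 and "c3" not in ds.ids
        assert ds.provenance[-1] == ("curation", 10, 9)

    def test_merge_unions_labels(self):
        ds = _mini_dataset()
        la = {e.compound_id: e.labels.copy() for e in ds.entries}
        out = apply_curation(ds, [CurationAction(("c1", "c2"), "merge")])
        kept = next(e for e in out.entries if e.compound_id == "c1")
        assert (kept.labels == (la["c1"] | la["c2"])).all()
        assert "c2" not in out.ids

    def test_keep_is_noop(self):
        out = apply_curation(_mini_dataset(), [CurationAction(("c0",), "keep")])
        assert len(out.entries) == 10

    def test_unknown_id_rejected_atomically(self):
        ds = _mini_dataset()
        with pytest.raises(ValueError, match="unknown compound ID"):
            apply_curation(ds, [
                CurationAction(("c1",), "remove"),
                CurationAction(("nope",), "remove"),
            ])
        assert len(ds.entries) == 10  # untouched

    def test_conflicting_actions_rejected(self):
        with pytest.raises(ValueError, match="more than one action"):
            apply_curation(_mini_dataset(), [
                CurationAction(("c1",), "remove"),
                CurationAction(("c1", "c2"), "merge"),
            ])


class TestFilterByAtomCount:
    def test_threshold_zero_is_identity(self):
        ds = _mini_dataset()
        assert len(filter_by_atom_count(ds, 0).entries) == len(ds.entries)

    def test_boundary_inclusive(self):
        entries = [_entry("a", [True, False], n_atoms=3),
                   _entry("b", [True, False], n_atoms=7),
                   _entry("c", [False, True], n_atoms=20)]
        from metpath.atom_coloring import featurize

        ds = BenchmarkDataset(entries, featurize([e.graph for e in entries]),
                              ["CatA", "CatB"])
        out = filter_by_atom_count(ds, 7)
        assert out.ids == ["b", "c"]

    def test_overlarge_threshold_warns_empty(self):
        ds = _mini_dataset()
        with pytest.warns(UserWarning, match="removed every entry"):
            out = filter_by_atom_count(ds, 1000)
        assert len(out.entries) == 0


class TestSplitAmbiguous:
    def test_partition_sizes_and_disjointness(self):
        ds = _mini_dataset()
        amb, non = split_ambiguous(ds)
        assert len(amb.entries) == 2 and len(non.entries) == 8
        assert set(amb.ids).isdisjoint(non.ids)
        assert sorted(amb.ids + non.ids) == sorted(ds.ids)

    def test_feature_columns_identical_across_subsets(self):
        ds = _mini_dataset()
        amb, non = split_ambiguous(ds)
        assert amb.features.columns == non.features.columns == ds.features.columns

    def test_no_ambiguous(self):
        ds = _mini_dataset()
        for e in ds.entries:
            e.ambiguous = False
        amb, non = split_ambiguous(ds)
        assert len(amb.entries) == 0 and len(non.entries) == 10


class TestEndToEndAssembly:
    def test_provenance_reconciles(self, small_dataset):
        for step, before, after in small_dataset.provenance:
            assert after <= before
        # seeded byte-duplicates are merged away
        merge_steps = [p for p in small_dataset.provenance if p[0].startswith("merge")]
        assert merge_steps and merge_steps[0][1] - merge_steps[0][2] == 2

    def test_merge_conserves_label_union(self, small_benchmark, small_dataset):
        truth = small_benchmark.truth.labels
        for src, clone in small_benchmark.truth.duplicate_molfile_pairs:
            kept = min(src, clone)
            entry = next(e for e in small_dataset.entries if e.compound_id == kept)
            expected = truth.loc[src].to_numpy() | truth.loc[clone].to_numpy()
            assert (entry.labels == expected).all()

    def test_every_entry_has_a_label(self, small_dataset):
        assert small_dataset.labels_frame().any(axis=1).all()

    def test_ambiguous_flags_match_graphs(self, small_benchmark, small_dataset):
        from metpath.chem_graph import detect_ambiguity

        for e in small_dataset.entries[:50]:
            has_r, has_rep = detect_ambiguity(small_benchmark.graphs[e.compound_id])
            assert e.ambiguous == (has_r or has_rep)

    def test_bundle_round_trip(self, small_dataset, tmp_path):
        write_bundle(small_dataset, tmp_path / "bundle")
        back = read_bundle(tmp_path / "bundle")
        assert back.ids == small_dataset.ids
        assert back.categories == small_dataset.categories
        pd.testing.assert_frame_equal(
            back.features.df, small_dataset.features.df, check_names=False
        )
        assert (back.labels_frame() == small_dataset.labels_frame()).all().all()
        assert back.ambiguous_mask().tolist() == small_dataset.ambiguous_mask().tolist()


class TestCompoundSource:
    def test_directory_source_feeds_build(self, tmp_path, small_benchmark):
        from metpath.dataset_pipeline import DirectoryCompoundSource

        sub = dict(list(small_benchmark.molfiles.items())[:20])
        for cid, text in sub.items():
            (tmp_path / f"{cid}.mol").write_text(text)
        src = DirectoryCompoundSource(tmp_path)
        assert src.compound_ids() == sorted(sub)
        ds = build_dataset(src, small_benchmark.links, small_benchmark.hierarchy,
                           categories=small_benchmark.categories, k_max=1)
        assert set(ds.ids) <= set(sub)
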