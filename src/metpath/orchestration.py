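"""Pipeline orchestration: fixtures → build → filter → benchmark → report.

A run manifest names the stages to execute (any prefix of the fixed DAG),
a global seed and an output root.  Every stage writes its outputs plus a
``provenance.json`` recording the SHA-256 checksums of its inputs and
outputs, the seed and the package version; with ``resume`` enabled a stage
whose recorded input checksums still match is skipped, and an intermediate
file whose checksum no longer matches its producer's record fails loudly,
naming the file.  A failing stage leaves its partial outputs quarantined
under ``<stage>.failed`` instead of half-written results.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .dataset_pipeline import (
    apply_curation,
    build_dataset,
    filter_by_atom_count,
    find_keyword_hits,
    generate_curation_template,
    read_bundle,
    read_curation_tsv,
    write_bundle,
)
from .atom_coloring import find_duplicate_feature_vectors
from .evaluation import odds_table, relative_importance, report_tables
from .info_filter import (
    per_compound_misclassification,
    select_threshold,
    sliding_window_rates,
)
from .modeling import run_benchmark
from .synthetic_data import GeneratorConfig, generate_benchmark, write_fixtures

log = logging.getLogger("metpath")

STAGES = ("fixtures", "build", "filter", "benchmark", "report")

__all__ = ["RunManifest", "run_pipeline", "STAGES"]


@dataclass
class RunManifest:
    out_root: str
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    resume: bool = False
    # stage configuration (desk-scale defaults)
    generator: dict = field(default_factory=dict)
    min_atoms: int | None = None  # None: select via the info filter
    merge_equivalence: str = "bytes"
    k_max: int = 3
    curation_file: str | None = None
    info_reps: int = 10
    window_size: int = 5
    families: list[str] = field(default_factory=lambda: ["random_forest", "gradient_boosted_trees"])
    training_datasets: list[str] = field(default_factory=lambda: ["full", "non_ambiguous"])
    n_folds: int = 25
    n_estimators: int = 60
    tune_budget: int = 0

    def __post_init__(self) -> None:
        order = {s: i for i, s in enumerate(STAGES)}
        unknown = [s for s in self.stages if s not in order]
        if unknown:
            raise ValueError(f"unknown stages {unknown}; valid: {list(STAGES)}")
        idxs = sorted(order[s] for s in self.stages)
        if idxs != list(range(idxs[0], idxs[0] + len(idxs))) or (idxs and idxs[0] != 0 and False):
            raise ValueError("stages must form a contiguous prefix-respecting chain")
        self.stages = [STAGES[i] for i in idxs]

    @classmethod
    def from_file(cls, path: str | Path) -> "RunManifest":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _tree_checksums(root: Path) -> dict[str, str]:
    return {
        str(p.relative_to(root)): _sha256(p)
        for p in sorted(root.rglob("*"))
        if p.is_file()
    }


def _verify_outputs(stage_dir: Path) -> None:
    """Check a finished stage's files against its recorded checksums."""
    prov_file = stage_dir / "stage_provenance.json"
    prov = json.loads(prov_file.read_text())
    for rel, sha in prov["outputs"].items():
        f = stage_dir / rel
        if not f.exists() or _sha256(f) != sha:
            raise RuntimeError(
                f"checksum mismatch for intermediate file {f}; the stage "
                f"output was modified or corrupted — re-run without resume"
            )


def _finish_stage(stage: str, stage_dir: Path, inputs: dict[str, str], seed: int) -> None:
    outputs = {
        rel: sha
        for rel, sha in _tree_checksums(stage_dir).items()
        if rel != "stage_provenance.json"
    }
    (stage_dir / "stage_provenance.json").write_text(
        json.dumps(
            {"stage": stage, "seed": seed, "version": __version__,
             "inputs": inputs, "outputs": outputs},
            indent=1, sort_keys=True,
        )
    )


def _stage_current(stage_dir: Path, inputs: dict[str, str]) -> bool:
    prov_file = stage_dir / "stage_provenance.json"
    if not prov_file.exists():
        return False
    prov = json.loads(prov_file.read_text())
    if prov.get("inputs") != inputs:
        return False
    _verify_outputs(stage_dir)
    return True


def run_pipeline(manifest: RunManifest) -> dict:
    """Execute the requested stages in order; returns the provenance summary."""
    root = Path(manifest.out_root)
    root.mkdir(parents=True, exist_ok=True)
    summary: dict[str, dict] = {}

    def run_stage(stage: str, inputs: dict[str, str], fn) -> Path:
        stage_dir = root / stage
        if manifest.resume and stage_dir.exists() and _stage_current(stage_dir, inputs):
            log.info("stage=%s status=skipped (resume, inputs unchanged)", stage)
            summary[stage] = {"status": "skipped"}
            return stage_dir
        tmp = root / f".{stage}.tmp"
        if tmp.exists():
            shutil.rmtree(tmp)
        tmp.mkdir(parents=True)
        try:
            fn(tmp)
        except Exception:
            failed = root / f"{stage}.failed"
            if failed.exists():
                shutil.rmtree(failed)
            tmp.rename(failed)
            log.error("stage=%s status=failed outputs quarantined under %s", stage, failed)
            raise
        _finish_stage(stage, tmp, inputs, manifest.seed)
        if stage_dir.exists():
            shutil.rmtree(stage_dir)
        tmp.rename(stage_dir)
        summary[stage] = {"status": "completed"}
        log.info("stage=%s status=completed", stage)
        return stage_dir

    fixtures_dir = root / "fixtures"
    if "fixtures" in manifest.stages:
        cfg = GeneratorConfig(**{"seed": manifest.seed, **manifest.generator})

        def _fixtures(tmp: Path) -> None:
            bench = generate_benchmark(cfg)
            write_fixtures(bench, tmp)
            log.info("stage=fixtures compounds=%d", len(bench.graphs))

        fixtures_dir = run_stage("fixtures", {"config": json.dumps(vars(cfg), default=str, sort_keys=True)}, _fixtures)

    bundle_dir = root / "build"
    if "build" in manifest.stages:
        fx_inputs = _tree_checksums(fixtures_dir)

        def _build(tmp: Path) -> None:
            links = pd.read_csv(fixtures_dir / "links.tsv", sep="\t")
            hierarchy = pd.read_csv(fixtures_dir / "hierarchy.tsv", sep="\t")
            metadata = pd.read_csv(
                fixtures_dir / "metadata.tsv", sep="\t", keep_default_na=False
            )
            curation = (
                read_curation_tsv(manifest.curation_file)
                if manifest.curation_file
                else None
            )
            ds = build_dataset(
                fixtures_dir / "molfiles",
                links,
                hierarchy,
                metadata=metadata,
                curation=curation,
                merge_equivalence=manifest.merge_equivalence,
                k_max=manifest.k_max,
            )
            write_bundle(ds, tmp)
            template = generate_curation_template(
                find_duplicate_feature_vectors(ds.features),
                find_keyword_hits(metadata),
            )
            template.to_csv(tmp / "curation_template.tsv", sep="\t", index=False)
            for step, before, after in ds.provenance:
                log.info("stage=build step=%s before=%d after=%d", step, before, after)

        bundle_dir = run_stage("build", fx_inputs, _build)

    filtered_dir = root / "filter"
    if "filter" in manifest.stages:
        build_inputs = _tree_checksums(bundle_dir)

        def _filter(tmp: Path) -> None:
            ds = read_bundle(bundle_dir)
            records = per_compound_misclassification(
                ds, n_reps=manifest.info_reps, seed=manifest.seed
            )
            records.to_csv(tmp / "misclassification.tsv", sep="\t")
            series = sliding_window_rates(records, manifest.window_size)
            series.to_csv(tmp / "window_series.tsv", sep="\t", index=False)
            threshold = (
                manifest.min_atoms
                if manifest.min_atoms is not None
                else select_threshold(series)
            )
            (tmp / "threshold.json").write_text(json.dumps({"threshold": int(threshold)}))
            filtered = filter_by_atom_count(ds, int(threshold))
            write_bundle(filtered, tmp / "bundle")
            log.info(
                "stage=filter threshold=%d before=%d after=%d",
                threshold, len(ds.entries), len(filtered.entries),
            )

        filtered_dir = run_stage("filter", build_inputs, _filter)

    bench_dir = root / "benchmark"
    if "benchmark" in manifest.stages:
        filt_inputs = _tree_checksums(filtered_dir)

        def _benchmark(tmp: Path) -> None:
            ds = read_bundle(filtered_dir / "bundle")
            results, importances = run_benchmark(
                ds,
                families=manifest.families,
                training_datasets=manifest.training_datasets,
                n_folds=manifest.n_folds,
                seed=manifest.seed,
                n_estimators=manifest.n_estimators,
                tune_budget=manifest.tune_budget,
            )
            results.to_csv(tmp / "results.tsv", sep="\t", index=False)
            imp_frames = []
            for task, arr in importances.items():
                df = relative_importance(arr, ds.features.columns)
                df.insert(0, "category", task.category)
                df.insert(0, "training_dataset", task.training_dataset)
                df.insert(0, "family", task.family)
                imp_frames.append(df)
            if imp_frames:
                pd.concat(imp_frames, ignore_index=True).to_csv(
                    tmp / "importance.tsv", sep="\t", index=False
                )
            log.info("stage=benchmark rows=%d tasks=%d", len(results), len(importances))

        bench_dir = run_stage("benchmark", filt_inputs, _benchmark)

    if "report" in manifest.stages:
        bench_inputs = _tree_checksums(bench_dir)

        def _report(tmp: Path) -> None:
            ds = read_bundle(filtered_dir / "bundle")
            results = pd.read_csv(bench_dir / "results.tsv", sep="\t")
            labels = ds.labels_frame()
            weights = {c: float(labels[c].mean()) for c in labels.columns}
            pd.DataFrame(
                sorted(weights.items()), columns=["category", "proportion"]
            ).to_csv(tmp / "proportions.tsv", sep="\t", index=False)
            # odds for the globally most prevalent features, per two-class category
            feats = ds.features.df
            top = (feats >= 1).sum().sort_values(ascending=False).index[:25]
            two_class = [c for c in labels.columns
                         if labels[c].any() and not labels[c].all()]
            odds = odds_table(feats, labels[two_class], feature_subset=list(top))
            report_tables(results, weights, tmp, odds_frame=odds)
            log.info("stage=report tables written to %s", tmp)

        run_stage("report", bench_inputs, _report)

    (root / "run_summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
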