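"""Binary metrics, weighted aggregation, feature importance and odds ratios.

Metric conventions follow the benchmark protocol: accuracy and the
Matthews correlation coefficient (MCC) are always valid; precision, recall
and F1 are flagged invalid whenever their denominator is zero, and invalid
fold scores are excluded from every aggregate rather than propagated as
NaN.  MCC uses the zero-factor convention (value 0, still valid) so every
CV fold contributes an MCC.  The unit-normalized MCC rescales [-1, 1] to
[0, 1] via (MCC + 1) / 2.

Aggregation weights each (category, fold) score by the proportion of the
dataset its category occupies, so small categories do not dominate the
overall number.  Feature importances are made comparable across folds by
dividing each fold's scores by that fold's maximum, then taking the
per-feature median across folds.  Feature/label association is summarized
by presence odds: among positive entries the odds of containing a feature
at least once, likewise among negatives, and their ratio (∞ when the
negative odds are zero).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfusionCounts",
    "AggregateReport",
    "OddsRecord",
    "confusion_from_predictions",
    "binary_metrics",
    "normalized_mcc",
    "relative_improvement",
    "weighted_aggregate",
    "relative_importance",
    "odds",
    "odds_ratio",
    "feature_odds",
    "odds_table",
    "write_results",
    "read_results",
    "report_tables",
]

METRICS = ("accuracy", "precision", "recall", "f1", "mcc", "normalized_mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def confusion_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=bool)
    y_pred = np.asarray(y_pred, dtype=bool)
    return ConfusionCounts(
        tp=int(np.sum(y_true & y_pred)),
        tn=int(np.sum(~y_true & ~y_pred)),
        fp=int(np.sum(~y_true & y_pred)),
        fn=int(np.sum(y_true & ~y_pred)),
    )


def binary_metrics(c: ConfusionCounts) -> dict[str, tuple[float, bool]]:
    """Metric name → (value, valid) for one test partition.

    Zero-denominator precision/recall/F1 are (0.0, False); MCC with a zero
    factor under the square root is (0.0, True).
    """
    if c.n == 0:
        raise ValueError("confusion counts sum to zero")
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    out: dict[str, tuple[float, bool]] = {}
    out["accuracy"] = ((tp + tn) / c.n, True)
    out["precision"] = (tp / (tp + fp), True) if tp + fp > 0 else (0.0, False)
    out["recall"] = (tp / (tp + fn), True) if tp + fn > 0 else (0.0, False)
    if 2 * tp + fp + fn > 0:
        out["f1"] = (2 * tp / (2 * tp + fp + fn), True)
    else:
        out["f1"] = (0.0, False)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    out["mcc"] = (mcc, True)
    out["normalized_mcc"] = (normalized_mcc(mcc), True)
    return out


def normalized_mcc(mcc: float) -> float:
    """Rescale an MCC from [-1, 1] to the unit interval: (MCC + 1) / 2."""
    if not -1.0 <= mcc <= 1.0:
        raise ValueError(f"MCC {mcc} outside [-1, 1]")
    return (mcc + 1.0) / 2.0


def relative_improvement(new: float, old: float) -> float:
    """Percent improvement of ``new`` over ``old``: (new - old) / old × 100."""
    return (new - old) / old * 100.0


@dataclass
class AggregateReport:
    weighted_mean: float
    weighted_sd: float
    unweighted_mean: float
    unweighted_sd: float
    median: float
    maximum: float
    n_valid: dict[str, int]
    excluded_categories: list[str]


def weighted_aggregate(
    values: pd.DataFrame, weights: dict[str, float]
) -> AggregateReport:
    """Aggregate per-(category, fold) scores with category-proportion weights.

    ``values`` needs columns ``category``, ``value`` and (optionally)
    ``valid``; invalid scores are excluded before aggregation, and each
    surviving score carries its category's weight.  The weighted SD is the
    frequency-weighted population form sqrt(Σwᵢ(xᵢ-x̄w)²/Σwᵢ).  Categories
    with zero valid scores are reported and excluded.
    """
    df = values.copy()
    if "valid" in df.columns:
        df = df[df["valid"].astype(bool)]
    w_arr = np.asarray([weights.get(c, np.nan) for c in df["category"]], dtype=float)
    if np.isnan(w_arr).any():
        missing = sorted(set(df["category"]) - set(weights))
        raise ValueError(f"missing weights for categories: {missing}")
    if (w_arr < 0).any() or (len(w_arr) and w_arr.sum() == 0):
        raise ValueError("weights must be non-negative and not all zero")
    x = df["value"].to_numpy(dtype=float)
    if len(x) == 0:
        raise ValueError("no valid scores to aggregate")
    wm = float(np.sum(w_arr * x) / np.sum(w_arr))
    wsd = float(math.sqrt(np.sum(w_arr * (x - wm) ** 2) / np.sum(w_arr)))
    n_valid = df.groupby("category")["value"].size().astype(int).to_dict()
    excluded = sorted(set(values["category"]) - set(n_valid))
    return AggregateReport(
        weighted_mean=wm,
        weighted_sd=wsd,
        unweighted_mean=float(x.mean()),
        unweighted_sd=float(x.std()),
        median=float(np.median(x)),
        maximum=float(x.max()),
        n_valid={str(k): int(v) for k, v in n_valid.items()},
        excluded_categories=excluded,
    )


def relative_importance(
    per_fold_raw: np.ndarray, feature_names: list[str]
) -> pd.DataFrame:
    """Median across folds of per-fold max-normalized importance scores.

    ``per_fold_raw`` is (folds × features); each fold's scores are divided
    by that fold's maximum so the most important feature scores 1.0 per
    fold, then each feature's median across folds is reported (features a
    fold's model never used score 0 there).  Sorted descending, ties by
    feature name.
    """
    raw = np.asarray(per_fold_raw, dtype=float)
    if raw.ndim != 2:
        raise ValueError("expected a (folds, features) array")
    maxima = raw.max(axis=1)
    if (maxima <= 0).any():
        bad = int(np.flatnonzero(maxima <= 0)[0])
        raise ValueError(f"fold {bad} has all-zero importances (untrained model?)")
    rel = raw / maxima[:, None]
    med = np.median(rel, axis=0)
    df = pd.DataFrame(
        {"feature": feature_names, "median_relative_importance": med}
    )
    return df.sort_values(
        ["median_relative_importance", "feature"], ascending=[False, True]
    ).reset_index(drop=True)


@dataclass(frozen=True)
class OddsRecord:
    category: str
    feature: str
    positive_odds: float
    negative_odds: float
    odds_ratio: float  # may be math.inf; NaN when 0/0


def odds(n_with: int, n_without: int) -> float:
    """Odds of having a feature: with/without (∞ if nothing lacks it)."""
    if n_without == 0:
        return math.inf if n_with > 0 else math.nan
    return n_with / n_without


def odds_ratio(positive_odds: float, negative_odds: float) -> float:
    """positive odds / negative odds; ∞ when the negative odds are zero."""
    if math.isnan(positive_odds) or math.isnan(negative_odds):
        return math.nan
    if negative_odds == 0.0:
        return math.inf if positive_odds > 0 else math.nan
    if math.isinf(positive_odds):
        return math.inf
    return positive_odds / negative_odds


def feature_odds(
    presence: np.ndarray,
    labels: np.ndarray,
    feature: str = "",
    category: str = "",
) -> OddsRecord:
    """Presence odds of one feature among positive and negative entries.

    Presence means the atom color appears at least once in the compound.
    Requires at least one positive and one negative entry.
    """
    p = np.asarray(presence, dtype=bool)
    y = np.asarray(labels, dtype=bool)
    if not y.any() or y.all():
        raise ValueError(
            f"category {category or '<unnamed>'} needs both positive and negative entries"
        )
    pos = odds(int(np.sum(p & y)), int(np.sum(~p & y)))
    neg = odds(int(np.sum(p & ~y)), int(np.sum(~p & ~y)))
    return OddsRecord(category, feature, pos, neg, odds_ratio(pos, neg))


def odds_table(
    features: pd.DataFrame, labels: pd.DataFrame, feature_subset: list[str] | None = None
) -> pd.DataFrame:
    """Odds records for every (category, feature) pair requested."""
    cols = feature_subset if feature_subset is not None else list(features.columns)
    rows = []
    for cat in labels.columns:
        y = labels[cat].to_numpy(dtype=bool)
        for f in cols:
            rec = feature_odds(features[f].to_numpy() >= 1, y, feature=f, category=cat)
            rows.append(
                (cat, f, rec.positive_odds, rec.negative_odds, rec.odds_ratio)
            )
    return pd.DataFrame(
        rows, columns=["category", "feature", "positive_odds", "negative_odds", "odds_ratio"]
    )


def write_results(frame: pd.DataFrame, path: str | Path) -> None:
    """Persist a long metric frame as TSV (infinities as the literal 'inf')."""
    frame.to_csv(path, sep="\t", index=False)


def read_results(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])


def report_tables(
    results: pd.DataFrame,
    weights: dict[str, float],
    out_dir: str | Path,
    importance_frames: dict[str, pd.DataFrame] | None = None,
    odds_frame: pd.DataFrame | None = None,
) -> Path:
    """Emit the aggregate/metric/importance/odds report TSVs.

    Deterministic: identical inputs produce byte-identical files.  Rows for
    missing (task, partition) combinations are simply absent.
    """
    if len(results) == 0:
        raise ValueError("results store is empty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    results = results.sort_values(
        ["family", "training_dataset", "category", "partition", "metric", "fold"]
    ).reset_index(drop=True)
    write_results(results, out / "metrics.tsv")

    rows = []
    group_cols = ["family", "training_dataset", "partition", "metric"]
    for keys, grp in results.groupby(group_cols, sort=True):
        if "valid" in grp.columns and not grp["valid"].astype(bool).any():
            continue  # a metric with no valid fold anywhere: row absent
        rep = weighted_aggregate(grp[["category", "value", "valid"]], weights)
        rows.append(
            (*keys, rep.weighted_mean, rep.weighted_sd, rep.unweighted_mean,
             rep.unweighted_sd, rep.median, rep.maximum,
             int(sum(rep.n_valid.values())))
        )
    agg = pd.DataFrame(
        rows,
        columns=group_cols
        + ["weighted_mean", "weighted_sd", "unweighted_mean", "unweighted_sd",
           "median", "maximum", "n_valid"],
    )
    agg.to_csv(out / "aggregates.tsv", sep="\t", index=False)

    if importance_frames:
        frames = []
        for task_name, df in sorted(importance_frames.items()):
            df = df.copy()
            df.insert(0, "task", task_name)
            frames.append(df)
        pd.concat(frames, ignore_index=True).to_csv(
            out / "importance.tsv", sep="\t", index=False
        )
    if odds_frame is not None:
        odds_frame.to_csv(out / "odds.tsv", sep="\t", index=False)
    return out
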