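"""Benchmarking of scoring functions against true model quality.

Three performance measures over tables of (target, model, score,
true_quality), where true quality is a structural similarity in [0, 1]
(TM-score, GDT_TS, or the toy quality of the synthetic fixtures) and
lower scores mean more native-like:

* category-stratified pairwise ranking accuracy — the percentage of
  model pairs, differing in quality by at least ``min_diff`` (0.1), for
  which the better-scoring model is the higher-quality one; 50% is a
  random ranking;
* average predicted rank — where the models of a quality category land
  in each target's score-sorted order (rank 1 = best predicted);
* mean per-target Pearson correlation between score and quality
  (negative for a good scorer).

Method differences are tested with the two-sided Wilcoxon signed-rank
test on paired per-target accuracies.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CategoryScheme:
    """Quality categories: near-native [0.8, 1.0], good [0.6, 0.8), medium
    [0.4, 0.6), poor [0, 0.4); pairs must differ in quality by min_diff."""

    thresholds: tuple[float, float, float] = (0.8, 0.6, 0.4)
    names: tuple[str, str, str, str] = ("near-native", "good", "medium", "poor")
    min_diff: float = 0.1

    def __post_init__(self) -> None:
        t = self.thresholds
        if not (1.0 > t[0] > t[1] > t[2] > 0.0):
            raise ValueError("thresholds must be strictly decreasing within (0, 1)")


DEFAULT_SCHEME = CategoryScheme()


def categorize(quality, scheme: CategoryScheme = DEFAULT_SCHEME):
    """Map qualities in [0, 1] to category names (vectorized)."""
    q = np.asarray(quality, dtype=float)
    if np.any(q < 0) or np.any(q > 1):
        raise ValueError("quality outside [0, 1]")
    t = scheme.thresholds
    out = np.select([q >= t[0], q >= t[1], q >= t[2]], scheme.names[:3], scheme.names[3])
    return str(out[()]) if out.ndim == 0 else out


REQUIRED_COLUMNS = ("target", "model", "score", "quality")


def _check_records(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records table lacks columns {missing}")


@dataclass
class PairwiseResult:
    accuracy: float  # percent, NaN when no qualifying pairs
    n_pairs: int
    per_target: pd.DataFrame  # columns target, correct, total


def pairwise_accuracy(
    records: pd.DataFrame,
    scheme: CategoryScheme = DEFAULT_SCHEME,
    category: str | None = None,
    pair_category: str = "higher",
) -> PairwiseResult:
    """Pairwise ranking accuracy, pooled over targets.

    Within each target every unordered model pair with quality difference
    >= ``min_diff`` is examined; a pair is correct when the lower (better)
    score belongs to the higher-quality model (score ties count as
    incorrect).  ``category`` restricts to pairs assigned to one quality
    category; assignment follows ``pair_category``: the category of the
    ``higher``-quality member (default), of the ``lower``, or require
    ``both`` members in the category.  ``category=None`` pools everything.
    """
    _check_records(records)
    if pair_category not in ("higher", "lower", "both"):
        raise ValueError(f"unknown pair_category {pair_category!r}")
    rows = []
    for target, grp in records.groupby("target", sort=True):
        q = grp["quality"].to_numpy(float)
        s = grp["score"].to_numpy(float)
        n = q.size
        if n < 2:
            continue
        i, j = np.triu_indices(n, k=1)
        keep = np.abs(q[i] - q[j]) >= scheme.min_diff
        i, j = i[keep], j[keep]
        hi_is_i = q[i] > q[j]
        q_hi = np.where(hi_is_i, q[i], q[j])
        q_lo = np.where(hi_is_i, q[j], q[i])
        s_hi = np.where(hi_is_i, s[i], s[j])
        s_lo = np.where(hi_is_i, s[j], s[i])
        if category is not None:
            if pair_category == "higher":
                keep = categorize(q_hi, scheme) == category
            elif pair_category == "lower":
                keep = categorize(q_lo, scheme) == category
            else:
                keep = (categorize(q_hi, scheme) == category) & (
                    categorize(q_lo, scheme) == category)
            s_hi, s_lo = s_hi[keep], s_lo[keep]
        correct = int(np.count_nonzero(s_hi < s_lo))
        rows.append((target, correct, int(s_hi.size)))
    per_target = pd.DataFrame(rows, columns=["target", "correct", "total"])
    total = int(per_target["total"].sum()) if len(per_target) else 0
    if total == 0:
        return PairwiseResult(float("nan"), 0, per_target)
    acc = 100.0 * per_target["correct"].sum() / total
    return PairwiseResult(float(acc), total, per_target)


def average_predicted_rank(
    records: pd.DataFrame,
    scheme: CategoryScheme = DEFAULT_SCHEME,
    category: str | None = None,
) -> float:
    """Mean predicted rank of a category's models, per target then over targets.

    Models are ranked ascending by score within each target (rank 1 = best
    predicted; ties get averaged ranks).  Returns NaN when the category
    occurs in no target.
    """
    _check_records(records)
    means = []
    for _, grp in records.groupby("target", sort=True):
        s = grp["score"].to_numpy(float)
        q = grp["quality"].to_numpy(float)
        ranks = sps.rankdata(s, method="average")
        mask = np.ones(q.size, bool) if category is None else categorize(q, scheme) == category
        if mask.any():
            means.append(float(ranks[mask].mean()))
    return float(np.mean(means)) if means else float("nan")


def mean_pearson(records: pd.DataFrame, min_models: int = 3) -> float:
    """Unweighted mean over targets of Pearson r between score and quality.

    Targets with fewer than ``min_models`` models or zero score/quality
    variance are skipped with a warning.  Good scorers give negative r.
    """
    _check_records(records)
    rs = []
    for target, grp in records.groupby("target", sort=True):
        s = grp["score"].to_numpy(float)
        q = grp["quality"].to_numpy(float)
        if s.size < min_models or s.std() == 0 or q.std() == 0:
            log.warning("target %s skipped in correlation (too few models or zero variance)",
                        target)
            continue
        rs.append(float(sps.pearsonr(s, q).statistic))
    return float(np.mean(rs)) if rs else float("nan")


@dataclass
class MethodComparison:
    p_value: float
    significant: bool
    direction: str | None  # "A" | "B": which method has the higher mean, None if identical


def compare_methods(
    accuracy_a: np.ndarray | list[float],
    accuracy_b: np.ndarray | list[float],
    alpha: float = 0.05,
) -> MethodComparison:
    """Two-sided Wilcoxon signed-rank test on paired per-target accuracies.

    Zero-difference pairs are dropped; if every pair is zero the methods are
    indistinguishable (p = 1, not significant).
    """
    a = np.asarray(accuracy_a, float)
    b = np.asarray(accuracy_b, float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    nz = d[d != 0]
    if nz.size == 0:
        return MethodComparison(1.0, False, None)
    res = sps.wilcoxon(nz, alternative="two-sided")
    direction = "A" if float(np.mean(d)) > 0 else "B"
    return MethodComparison(float(res.pvalue), bool(res.pvalue < alpha), direction)


# ---------------------------------------------------------------------------
# Table I/O and the combined report


def read_quality_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV with columns target, model, metric, value (quality in [0, 1])."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("target", "model", "metric", "value") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: quality table lacks columns {missing}")
    return df


def read_score_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("model", "formalism", "total_score") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: score table lacks columns {missing}")
    return df


def join_scores(scores: pd.DataFrame, quality: pd.DataFrame, metric: str | None = None) -> pd.DataFrame:
    """Join a score table with a quality table on model id.

    Returns one records frame per formalism stacked, with columns
    target, model, formalism, score, quality.  Raises on orphan model ids.
    """
    qual = quality if metric is None else quality[quality["metric"] == metric]
    if qual.empty:
        raise ValueError(f"no quality rows for metric {metric!r}")
    merged = scores.merge(qual.rename(columns={"value": "quality"}), on="model", how="left")
    orphans = merged[merged["quality"].isna()]["model"].unique()
    if orphans.size:
        shown = ", ".join(map(str, orphans[:10]))
        raise ValueError(f"{orphans.size} model id(s) lack quality entries: {shown}")
    merged = merged.rename(columns={"total_score": "score"})
    return merged[["target", "model", "formalism", "score", "quality"]]


def benchmark_report(
    records: pd.DataFrame,
    scheme: CategoryScheme = DEFAULT_SCHEME,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Long-format report over all formalisms present in ``records``.

    Sections: ``accuracy`` (per category, %), ``rank`` (average predicted
    rank per category), ``correlation`` (mean per-target Pearson r), and a
    ``wilcoxon`` block with pairwise method comparisons on per-target
    all-category accuracies.
    """
    _check_records(records)
    formalisms = list(dict.fromkeys(records["formalism"]))
    rows: list[tuple] = []
    per_target_acc: dict[str, pd.DataFrame] = {}
    for fm in formalisms:
        sub = records[records["formalism"] == fm]
        for cat in scheme.names:
            res = pairwise_accuracy(sub, scheme, cat)
            rows.append(("accuracy", cat, fm, res.accuracy, res.n_pairs))
            rows.append(("rank", cat, fm, average_predicted_rank(sub, scheme, cat),
                         int(sub.groupby("target").size().shape[0])))
        pooled = pairwise_accuracy(sub, scheme, None)
        rows.append(("accuracy", "all", fm, pooled.accuracy, pooled.n_pairs))
        rows.append(("correlation", "all", fm, mean_pearson(sub),
                     int(sub["target"].nunique())))
        pt = pooled.per_target.set_index("target")
        per_target_acc[fm] = 100.0 * pt["correct"] / pt["total"].replace(0, np.nan)
    for fa, fb in itertools.combinations(formalisms, 2):
        joined = pd.concat([per_target_acc[fa].rename("a"),
                            per_target_acc[fb].rename("b")], axis=1).dropna()
        cmp = compare_methods(joined["a"].to_numpy(), joined["b"].to_numpy(), alpha)
        winner = {"A": fa, "B": fb, None: ""}[cmp.direction if cmp.significant else None]
        rows.append(("wilcoxon", f"{fa}_vs_{fb}", winner, cmp.p_value, len(joined)))
    return pd.DataFrame(rows, columns=["section", "category", "formalism", "value", "n"])
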