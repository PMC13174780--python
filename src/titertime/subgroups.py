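"""Cross-sectional age x time-of-day subgroup discovery and comparison.

A small, deterministic CART regression tree (response: ln titer; predictors:
age and rounded sampling hour) finds the age bands and sampling-hour cuts
that maximize the between-subgroup difference in mean ln titer. Each
time-of-day split is then compared formally: two-group ANOVA on ln titers,
mean difference and fold change exp(diff), detection rates with exact
(Clopper-Pearson) intervals, and a Pearson chi-square test of the detection
proportions.

Split thresholds lie at midpoints between adjacent observed predictor
values, so on integer hours a threshold of 8.5 partitions {<= 8} from
{>= 9}. Tree growth is deterministic: on exact tie, the lower threshold
wins and age is preferred over hour.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CohortTable
from .errors import DataError

AGE_COL = "age_years"
TOD_COL = "tod_hour"
PREDICTOR_ORDER = (AGE_COL, TOD_COL)

_TIE_TOL = 1e-9


# ---------------------------------------------------------------------------
# CART
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CartParams:
    max_depth: int = 3
    min_split: int = 20
    min_bucket: int = 7
    cp: float = 0.01


@dataclass
class CartNode:
    n: int
    mean: float
    sse: float
    depth: int
    predictor: str | None = None  # None for a leaf
    threshold: float | None = None
    improvement: float | None = None  # SSE reduction achieved by the split
    left: "CartNode | None" = None  # predictor <= threshold
    right: "CartNode | None" = None  # predictor > threshold

    @property
    def is_leaf(self) -> bool:
        return self.predictor is None

    def leaves(self) -> list["CartNode"]:
        if self.is_leaf:
            return [self]
        assert self.left is not None and self.right is not None
        return self.left.leaves() + self.right.leaves()

    def to_dict(self) -> dict[str, Any]:
        d: dict[str, Any] = {"n": self.n, "mean": self.mean, "sse": self.sse}
        if not self.is_leaf:
            d.update(
                predictor=self.predictor,
                threshold=self.threshold,
                improvement=self.improvement,
                left=self.left.to_dict(),
                right=self.right.to_dict(),
            )
        return d


def best_split(
    x: np.ndarray, y: np.ndarray, min_bucket: int = 1
) -> tuple[float, float] | None:
    """SSE-optimal binary split of ``y`` by ``x <= threshold``.

    Thresholds are midpoints between adjacent sorted unique values of ``x``.
    Returns (sse_reduction, threshold), or None if no admissible split
    exists. On ties the smallest threshold wins.
    """
    order = np.argsort(x, kind="mergesort")
    xs, ys = x[order], y[order]
    n = xs.size
    if n < 2 * min_bucket:
        return None
    # candidate boundaries: positions where x changes value
    change = np.nonzero(np.diff(xs) > 0)[0] + 1  # left group size at each boundary
    if change.size == 0:
        return None
    csum = np.cumsum(ys)
    total = csum[-1]
    nl = change.astype(float)
    nr = n - nl
    sum_l = csum[change - 1]
    # SSE reduction of a mean split: n_l*n_r/n * (mean_l - mean_r)^2
    mean_l = sum_l / nl
    mean_r = (total - sum_l) / nr
    red = nl * nr / n * (mean_l - mean_r) ** 2
    ok = (nl >= min_bucket) & (nr >= min_bucket)
    if not ok.any():
        return None
    red = np.where(ok, red, -np.inf)
    best = int(np.argmax(red))  # argmax keeps the first (lowest threshold) on ties
    thr = float((xs[change[best] - 1] + xs[change[best]]) / 2.0)
    return float(red[best]), thr


def _grow(
    df: pd.DataFrame,
    y: np.ndarray,
    depth: int,
    params: CartParams,
    root_sse: float,
) -> CartNode:
    n = y.size
    mean = float(y.mean())
    sse = float(((y - mean) ** 2).sum())
    node = CartNode(n=n, mean=mean, sse=sse, depth=depth)
    if depth >= params.max_depth or n < params.min_split:
        return node
    best: tuple[float, str, float] | None = None
    for pred in PREDICTOR_ORDER:
        x = df[pred].to_numpy(dtype=float)
        found = best_split(x, y, params.min_bucket)
        if found is None:
            continue
        red, thr = found
        if best is None or red > best[0] + _TIE_TOL:
            best = (red, pred, thr)
    if best is None:
        return node
    red, pred, thr = best
    # absolute floor guards against float-epsilon splits of a constant response
    if red < max(params.cp * root_sse, 1e-12 * n * (1.0 + mean * mean)):
        return node
    mask = df[pred].to_numpy(dtype=float) <= thr
    node.predictor = pred
    node.threshold = thr
    node.improvement = red
    node.left = _grow(df[mask], y[mask], depth + 1, params, root_sse)
    node.right = _grow(df[~mask], y[~mask], depth + 1, params, root_sse)
    return node


def fit_cart(
    cohort: CohortTable | pd.DataFrame,
    analyte: str | None = None,
    params: CartParams = CartParams(),
) -> CartNode:
    """Grow the depth-limited regression tree on ln titers.

    A constant response or constant predictors simply yield a root-only
    tree. Deterministic given the data.
    """
    df = cohort.for_analyte(analyte) if isinstance(cohort, CohortTable) else cohort
    if len(df) < 1:
        raise DataError("empty cohort")
    y = np.log(df["titer"].to_numpy(dtype=float))
    root_sse = float(((y - y.mean()) ** 2).sum())
    return _grow(df.reset_index(drop=True), y, 0, params, root_sse)


# ---------------------------------------------------------------------------
# subgroup comparison
# ---------------------------------------------------------------------------


def fold_change(diff_ln: float) -> float:
    """Ratio of geometric-mean titers implied by a mean ln difference."""
    if not math.isfinite(diff_ln):
        raise DataError("fold change of a non-finite ln difference")
    return math.exp(diff_ln)


def detection_rate_ci(
    k: int, n: int, level: float = 0.95
) -> tuple[float, float, float]:
    """Exact (Clopper-Pearson) binomial interval: (rate, lower, upper)."""
    if n < 1:
        raise DataError("detection rate needs n >= 1")
    if not 0 <= k <= n:
        raise DataError(f"k={k} outside [0, {n}]")
    alpha = 1.0 - level
    lower = float(stats.beta.ppf(alpha / 2.0, k, n - k + 1)) if k > 0 else 0.0
    upper = float(stats.beta.ppf(1.0 - alpha / 2.0, k + 1, n - k)) if k < n else 1.0
    return k / n, lower, upper


def chi_square_detection(
    k1: int, n1: int, k2: int, n2: int, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square (1 df) on the 2x2 detected/undetected table."""
    if n1 < 1 or n2 < 1:
        raise DataError("chi-square needs n >= 1 per group")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise DataError("chi-square undefined: a margin of the 2x2 table is zero")
    res = stats.chi2_contingency(table, correction=yates)
    return float(res.statistic), float(res.pvalue)


def spearman_check(x: Any, y: Any) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties) with its p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError("spearman needs equal-length inputs of size >= 3")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DataError("spearman undefined for constant input")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def _two_group_anova(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """One-way two-group ANOVA F and p, with the degenerate zero-variance
    convention F=0, p=1 when both groups are constant at equal means."""
    if a.size < 2 or b.size < 2:
        raise DataError("ANOVA needs >= 2 records per group")
    ssw = float(((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum())
    if ssw == 0:
        if np.isclose(a.mean(), b.mean()):
            return 0.0, 1.0
        return float("inf"), 0.0
    f, p = stats.f_oneway(a, b)
    return float(f), float(p)


@dataclass(frozen=True)
class DetectionSummary:
    k: int
    n: int
    rate: float
    ci_lower: float
    ci_upper: float


@dataclass(frozen=True)
class SubgroupComparison:
    analyte: str
    age_lo: float
    age_hi: float
    tod_cut: int
    n_early: int
    n_late: int
    mean_ln_early: float
    mean_ln_late: float
    diff: float  # early - late
    fold_change: float
    anova_f: float
    anova_p: float
    detect_early: DetectionSummary
    detect_late: DetectionSummary
    chisq_stat: float
    chisq_p: float


def subgroup_compare(
    cohort: CohortTable | pd.DataFrame,
    analyte: str,
    age_range: tuple[float, float],
    tod_cut: int,
    level: float = 0.95,
) -> SubgroupComparison:
    """Compare early (tod <= cut) vs late samplers inside an age band."""
    df = cohort.for_analyte(analyte) if isinstance(cohort, CohortTable) else cohort
    age_lo, age_hi = age_range
    band = df[(df[AGE_COL] >= age_lo) & (df[AGE_COL] <= age_hi)]
    early = band[band[TOD_COL] <= tod_cut]
    late = band[band[TOD_COL] > tod_cut]
    if early.empty or late.empty:
        raise DataError("both sides of the TOD cut must be nonempty")
    ln_e = np.log(early["titer"].to_numpy(dtype=float))
    ln_l = np.log(late["titer"].to_numpy(dtype=float))
    f, p = _two_group_anova(ln_e, ln_l)
    diff = float(ln_e.mean() - ln_l.mean())
    k_e, n_e = int(early["detected"].sum()), len(early)
    k_l, n_l = int(late["detected"].sum()), len(late)
    rate_e, lo_e, hi_e = detection_rate_ci(k_e, n_e, level)
    rate_l, lo_l, hi_l = detection_rate_ci(k_l, n_l, level)
    try:
        chi, chi_p = chi_square_detection(k_e, n_e, k_l, n_l)
    except DataError:  # all-detected or none-detected margin
        chi, chi_p = float("nan"), float("nan")
    return SubgroupComparison(
        analyte=analyte,
        age_lo=float(age_lo),
        age_hi=float(age_hi),
        tod_cut=int(tod_cut),
        n_early=n_e,
        n_late=n_l,
        mean_ln_early=float(ln_e.mean()),
        mean_ln_late=float(ln_l.mean()),
        diff=diff,
        fold_change=fold_change(diff),
        anova_f=f,
        anova_p=p,
        detect_early=DetectionSummary(k_e, n_e, rate_e, lo_e, hi_e),
        detect_late=DetectionSummary(k_l, n_l, rate_l, lo_l, hi_l),
        chisq_stat=chi,
        chisq_p=chi_p,
    )


def duration_balance_check(
    cohort: CohortTable | pd.DataFrame,
    analyte: str,
    subgroups: list[tuple[tuple[float, float], int]],
) -> dict[str, Any]:
    """Mean disease duration per age x TOD subgroup, with a one-way ANOVA p.

    ``subgroups`` is a list of ((age_lo, age_hi), tod_cut); each contributes
    an early and a late group. Raises when fewer than two groups result.
    """
    df = cohort.for_analyte(analyte) if isinstance(cohort, CohortTable) else cohort
    if "duration_years" not in df.columns:
        raise DataError("cohort has no duration_years column")
    groups: list[np.ndarray] = []
    rows: list[dict[str, Any]] = []
    for (age_lo, age_hi), cut in subgroups:
        band = df[(df[AGE_COL] >= age_lo) & (df[AGE_COL] <= age_hi)]
        for label, part in (
            ("early", band[band[TOD_COL] <= cut]),
            ("late", band[band[TOD_COL] > cut]),
        ):
            if part.empty:
                continue
            d = part["duration_years"].to_numpy(dtype=float)
            groups.append(d)
            rows.append(
                {
                    "age_lo": age_lo,
                    "age_hi": age_hi,
                    "tod_cut": cut,
                    "side": label,
                    "n": d.size,
                    "mean_duration": float(d.mean()),
                }
            )
    if len(groups) < 2:
        raise DataError("duration balance check needs >= 2 subgroups")
    if all(g.size > 0 for g in groups) and sum(
        float(((g - g.mean()) ** 2).sum()) for g in groups
    ) == 0:
        means = [g.mean() for g in groups]
        f, p = (0.0, 1.0) if np.allclose(means, means[0]) else (float("inf"), 0.0)
    else:
        f, p = stats.f_oneway(*groups)
    return {"groups": rows, "anova_f": float(f), "anova_p": float(p)}


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------


def _tod_split_nodes(
    node: CartNode, constraints: dict[str, tuple[float, float]]
) -> list[tuple[CartNode, dict[str, tuple[float, float]]]]:
    """All internal nodes splitting on the hour, with their path constraints."""
    if node.is_leaf:
        return []
    assert node.predictor is not None and node.threshold is not None
    out = []
    if node.predictor == TOD_COL:
        out.append((node, dict(constraints)))
    for child, side in ((node.left, "le"), (node.right, "gt")):
        c = {k: v for k, v in constraints.items()}
        lo, hi = c.get(node.predictor, (-math.inf, math.inf))
        if side == "le":
            c[node.predictor] = (lo, min(hi, node.threshold))
        else:
            c[node.predictor] = (max(lo, node.threshold), hi)
        out.extend(_tod_split_nodes(child, c))
    return out


def subgroup_report(
    cohort: CohortTable | pd.DataFrame,
    analyte: str,
    params: CartParams = CartParams(),
) -> dict[str, Any]:
    """Full pipeline for one analyte: tree + a comparison per TOD split.

    Each comparison restricts the cohort to the node's path constraints
    (age band, and any upstream hour constraints) and compares the two
    sides of the node's hour threshold.
    """
    df = cohort.for_analyte(analyte) if isinstance(cohort, CohortTable) else cohort
    tree = fit_cart(df, params=params)
    comparisons = []
    for node, constraints in _tod_split_nodes(tree, {}):
        # path constraints are half-open intervals (lo, hi]: left branches
        # impose <= threshold, right branches impose > threshold
        sub = df
        age_lo, age_hi = constraints.get(AGE_COL, (-math.inf, math.inf))
        tod_lo, tod_hi = constraints.get(TOD_COL, (-math.inf, math.inf))
        mask = (
            (sub[AGE_COL] > age_lo)
            & (sub[AGE_COL] <= age_hi)
            & (sub[TOD_COL] > tod_lo)
            & (sub[TOD_COL] <= tod_hi)
        )
        sub = sub[mask]
        assert node.threshold is not None
        cut = int(math.floor(node.threshold))
        try:
            cmp_ = subgroup_compare(
                sub.reset_index(drop=True), analyte, (-math.inf, math.inf), cut
            )
        except DataError:
            continue
        comparisons.append(
            {
                "age_lo": None if not math.isfinite(age_lo) else age_lo,
                "age_hi": None if not math.isfinite(age_hi) else age_hi,
                "tod_threshold": node.threshold,
                "improvement": node.improvement,
                "comparison": cmp_,
            }
        )
    return {"analyte": analyte, "tree": tree.to_dict(), "comparisons": comparisons}
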