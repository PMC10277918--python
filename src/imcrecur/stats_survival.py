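"""Statistical layer: rank tests, contingency tests, survival analysis,
dichotomization rules, the immunohistochemistry staining index, and
purity-based sample selection.

Conventions used throughout: all tests are two-sided, significance is
declared at p < 0.05, and recurrence-free survival is measured from
primary treatment with non-recurrence deaths censored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import scipy.stats as sps
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "mann_whitney_u",
    "spearman",
    "fisher_exact",
    "km_logrank",
    "dichotomize",
    "staining_index",
    "select_high_purity",
    "SurvivalComparison",
    "PuritySelection",
]

EXACT_MAX_N = 12  # exact Mann-Whitney enumeration up to this combined size


@lru_cache(maxsize=None)
def _u_distribution(n: int, m: int) -> tuple[int, ...]:
    """Counts of rank arrangements giving each U value in 0..n*m.

    Classic recurrence: c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u),
    where U counts (x > y) pairs for the n-sample.
    """
    if n == 0 or m == 0:
        return (1,)
    a = _u_distribution(n - 1, m)
    b = _u_distribution(n, m - 1)
    out = [0] * (n * m + 1)
    for u, c in enumerate(a):
        out[u + m] += c
    for u, c in enumerate(b):
        out[u] += c
    return tuple(out)


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test; returns (U for x, p).

    Exact null enumeration when len(x)+len(y) <= 12 with no ties,
    otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    u_x = float(np.sum(x[:, None] > y[None, :]) + 0.5 * np.sum(x[:, None] == y[None, :]))
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if n + m <= EXACT_MAX_N and not has_ties:
        dist = np.array(_u_distribution(n, m), dtype=float)
        dist /= dist.sum()
        u = int(round(u_x))
        p_le = dist[: u + 1].sum()
        p_ge = dist[u:].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return u_x, float(p)
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return u_x, float(res.pvalue)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("Spearman correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def fisher_exact(table) -> float:
    """Two-sided Fisher's exact p for a 2x2 count table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if np.any(t < 0) or not np.issubdtype(t.dtype, np.integer) and np.any(t != np.floor(t)):
        raise ValueError("counts must be non-negative integers")
    _, p = sps.fisher_exact(t.astype(int), alternative="two-sided")
    return float(p)


@dataclass
class SurvivalComparison:
    """Kaplan-Meier curves per group plus the Mantel-Cox log-rank test."""

    curves: dict  # group -> DataFrame(time, at_risk, survival)
    chi2: float
    p_value: float
    group_sizes: dict  # group -> (n patients, n events)
    summary: pd.DataFrame = field(default=None, repr=False)

    def legend_counts(self) -> dict:
        """'patients/events' style labels, e.g. {'low': '18 (9)'}."""
        return {g: f"{n} ({e})" for g, (n, e) in self.group_sizes.items()}


def km_logrank(time, event, group) -> SurvivalComparison:
    """Kaplan-Meier recurrence-free survival per group and the Mantel-Cox
    log-rank comparison (chi-square with k-1 df for k groups).

    Parameters are aligned per-patient vectors: follow-up time (months),
    event indicator (1 = recurrence, 0 = censored), and group label.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    if np.any(time <= 0):
        raise ValueError("times must be positive")
    if not set(np.unique(event)) <= {0, 1}:
        raise ValueError("event must be 0/1")
    labels = pd.unique(group)
    if labels.size < 2:
        raise ValueError("need at least two groups")
    if event.sum() < 1:
        raise ValueError("need at least one event")
    curves, sizes = {}, {}
    for g in labels:
        sel = group == g
        if sel.sum() == 0:
            raise ValueError(f"group {g!r} has no patients")
        kmf = KaplanMeierFitter()
        kmf.fit(time[sel], event[sel])
        tbl = kmf.event_table
        curves[g] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "at_risk": tbl["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
                "survival": kmf.survival_function_.iloc[:, 0].to_numpy(),
            }
        )
        sizes[g] = (int(sel.sum()), int(event[sel].sum()))
    res = multivariate_logrank_test(time, group, event)
    summary = pd.DataFrame(
        {
            "group": list(sizes),
            "patients": [sizes[g][0] for g in sizes],
            "events": [sizes[g][1] for g in sizes],
        }
    )
    return SurvivalComparison(
        curves=curves,
        chi2=float(res.test_statistic),
        p_value=float(res.p_value),
        group_sizes=sizes,
        summary=summary,
    )


def dichotomize(values: pd.Series, rule: str = "median") -> pd.Series:
    """Split per-patient values into two groups.

    rules: ``median`` (<= median -> 'low'), ``lowest_quartile``
    (<= 25th percentile -> 'low'), ``zero_vs_positive`` (0 -> 'loss').
    The median itself goes to the low group.
    """
    values = pd.Series(values, dtype=float)
    if values.nunique() == 1:
        raise ValueError("all values equal: dichotomization is degenerate")
    if rule == "median":
        cut = values.median()
        labels = np.where(values <= cut, "low", "high")
    elif rule == "lowest_quartile":
        if values.size < 4:
            raise ValueError("quartile rule needs >= 4 patients")
        cut = np.percentile(values.to_numpy(), 25)
        labels = np.where(values <= cut, "low", "high")
    elif rule == "zero_vs_positive":
        labels = np.where(values == 0, "loss", "positive")
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return pd.Series(labels, index=values.index, name="group")


INTENSITY_SCORES = (0, 1, 2, 3)  # loss, weak, moderate, strong
AREA_SCORES = (1, 2, 3)  # <10%, 10-50%, >50% positive tumor area


def staining_index(intensity_score: int, area_score: int) -> int:
    """IHC staining index: intensity category (0-3) x positive-area
    category (1-3); attainable values {0,1,2,3,4,6,9}."""
    if intensity_score not in INTENSITY_SCORES:
        raise ValueError(f"intensity score must be one of {INTENSITY_SCORES}")
    if area_score not in AREA_SCORES:
        raise ValueError(f"area score must be one of {AREA_SCORES}")
    return intensity_score * area_score


@dataclass
class PuritySelection:
    """Samples selected for high tumor purity (lowest infiltration scores)."""

    selected: list
    fraction: float
    n_total: int


def select_high_purity(scores: pd.Series, fraction: float = 0.33) -> PuritySelection:
    """Select the floor(fraction * n) samples with the lowest
    stromal/immune-infiltration score (lower score = purer tumor).

    Ties broken deterministically by sample id.
    """
    scores = pd.Series(scores)
    n = scores.size
    if n < 3:
        raise ValueError("need at least 3 samples")
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    k = math.floor(fraction * n)
    if k == 0:
        raise ValueError("fraction selects zero samples")
    order = scores.reset_index()
    order.columns = ["sample_id", "score"]
    order = order.sort_values(["score", "sample_id"], kind="mergesort")
    return PuritySelection(
        selected=order["sample_id"].head(k).tolist(), fraction=fraction, n_total=n
    )
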