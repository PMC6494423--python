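"""Per-condition aggregation and Kolmogorov–Smirnov group comparisons.

Amplitude values are summarized per condition as mean ± SEM with the axon
count, and conditions are compared pairwise with the two-sided two-sample
Kolmogorov–Smirnov test (exact D over the pooled order statistics, asymptotic
p-value — appropriate at the cohort sizes used here, ~20 or more axons per
condition).  Raw p-values are reported per contrast, without multiplicity
correction, and mapped to the usual significance stars.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError
from .periodicity import AnalysisConfig

__all__ = [
    "GroupSummary",
    "KSComparison",
    "ks2",
    "significance_stars",
    "summarize",
    "lag_min_midpoint",
]


@dataclass
class GroupSummary:
    """Amplitude collection of one condition with mean, SEM and n."""

    label: str
    values: np.ndarray
    mean: float
    sem: float
    n: int


@dataclass
class KSComparison:
    """Two-sided two-sample KS comparison between two conditions."""

    label_a: str
    label_b: str
    D: float
    p: float
    stars: str = ""


def ks2(a: Sequence[float], b: Sequence[float],
        label_a: str = "a", label_b: str = "b") -> KSComparison:
    """Two-sided two-sample Kolmogorov–Smirnov test.

    D is the exact supremum distance between the two empirical distribution
    functions over the pooled sample; the p-value uses the asymptotic
    Kolmogorov distribution with the standard effective-n scaling.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("KS test requires at least 2 values per sample")
    res = stats.ks_2samp(a, b, alternative="two-sided", method="asymp")
    p = float(min(res.pvalue, 1.0))
    p = max(p, np.finfo(float).tiny)  # keep p in (0, 1]
    return KSComparison(label_a=label_a, label_b=label_b, D=float(res.statistic),
                        p=p, stars=significance_stars(p))


def significance_stars(p: float) -> str:
    """Map a p-value to the figure-legend convention (* ≤0.05, ** ≤0.01, *** ≤0.001)."""
    if p <= 0.001:
        return "***"
    if p <= 0.01:
        return "**"
    if p <= 0.05:
        return "*"
    return "n.s."


def summarize(
    groups: Mapping[str, Sequence[float]],
    contrasts: Optional[Sequence[tuple]] = None,
):
    """Summarize labeled amplitude collections and compare conditions.

    Returns ``(summaries, comparisons)``: one :class:`GroupSummary` per group
    (mean, SEM with the n−1 sample standard deviation, n) and a DataFrame of
    pairwise KS comparisons.  ``contrasts`` defaults to all pairs in label
    order; a single group yields an empty comparison table.
    """
    summaries = []
    arrays = {}
    for label, values in groups.items():
        v = np.asarray(list(values), dtype=float)
        if v.size == 0:
            raise ParameterError(f"group {label!r} is empty")
        arrays[label] = v
        sem = float(v.std(ddof=1) / np.sqrt(v.size)) if v.size > 1 else 0.0
        summaries.append(
            GroupSummary(label=label, values=v, mean=float(v.mean()), sem=sem, n=v.size)
        )
    labels = list(arrays)
    if contrasts is None:
        contrasts = [(labels[i], labels[j])
                     for i in range(len(labels)) for j in range(i + 1, len(labels))]
    rows = []
    for la, lb in contrasts:
        if la not in arrays or lb not in arrays:
            raise ParameterError(f"contrast ({la}, {lb}) names an unknown group")
        comp = ks2(arrays[la], arrays[lb], la, lb)
        rows.append({"label_a": la, "label_b": lb, "D": comp.D, "p": comp.p,
                     "stars": comp.stars})
    comparisons = pd.DataFrame(rows, columns=["label_a", "label_b", "D", "p", "stars"])
    return summaries, comparisons


def lag_min_midpoint(
    acf_mean: np.ndarray,
    cfg: Optional[AnalysisConfig] = None,
    tie_tol: float = 1e-6,
) -> float:
    """Half-period location by the midpoint-of-bracketing-lags convention.

    On a lag grid of ``bin_nm`` multiples the half-period of a 190 nm lattice
    (95 nm) falls between two lags; for a periodic signal the (circular)
    autocorrelation is symmetric about the half-period, so the two adjacent
    lags with the lowest values bracket it and their midpoint recovers it.

    The bracketing pair is the adjacent pair with the smallest value sum.
    For a sharply peaked lattice the trough is a plateau whose members are
    tied to within numerical noise, so pairs whose sums are within
    ``tie_tol`` (per value, i.e. ``2 * tie_tol`` on the sum) of the best are
    treated as tied and resolved toward the pair whose midpoint is nearest
    the window center, then toward the smaller lag — the same convention the
    amplitude extremum uses.
    """
    cfg = cfg if cfg is not None else AnalysisConfig()
    acf_mean = np.asarray(acf_mean, dtype=float)
    lags = np.arange(len(acf_mean)) * cfg.bin_nm
    lo, hi = cfg.min_window_nm
    idx = np.flatnonzero((lags >= lo) & (lags <= hi))
    if idx.size < 2:
        raise ParameterError("minimum window holds fewer than two lags")
    vals = acf_mean[idx]
    wlags = lags[idx]
    sums = vals[:-1] + vals[1:]
    mids = (wlags[:-1] + wlags[1:]) / 2.0
    tied = np.flatnonzero(sums <= sums.min() + 2.0 * tie_tol)
    center = (lo + hi) / 2.0
    best = min(tied, key=lambda i: (abs(mids[i] - center), mids[i]))
    return float(mids[best])
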