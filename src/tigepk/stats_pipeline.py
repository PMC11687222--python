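"""Normality-gated univariate statistics and the per-site 6:2:2 split.

Every comparison and correlation is gated by a one-sample
Kolmogorov-Smirnov test against a normal with the sample's own mean/SD
(p >= 0.05 => treated as normal): normal data get the t test / Pearson
correlation / mean +- SD summaries, non-normal data get the
Mann-Whitney U test / Spearman correlation / median (Q1, Q3) summaries.
Raw p-values are reported without multiple-testing correction — the
tables deliberately mirror a raw-p screening analysis, so familywise
error is NOT controlled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pk_core import SAMPLING_TIMES_H

__all__ = [
    "StatResult",
    "SplitAssignment",
    "normality_gate",
    "compare_groups",
    "correlate",
    "describe",
    "split_dataset",
    "concentration_day_correlation",
]

ALPHA = 0.05


@dataclass(frozen=True)
class StatResult:
    variable: str
    test: str                 # one of KS, t, MWU, Pearson, Spearman
    statistic: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or math.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


@dataclass(frozen=True)
class SplitAssignment:
    """Per-site disjoint (train, validation, test) index sets over 0..n_total-1."""

    per_site: tuple[tuple[np.ndarray, np.ndarray, np.ndarray], ...]

    def _concat(self, part: int) -> np.ndarray:
        return np.concatenate([site[part] for site in self.per_site])

    @property
    def train(self) -> np.ndarray:
        return self._concat(0)

    @property
    def validation(self) -> np.ndarray:
        return self._concat(1)

    @property
    def test(self) -> np.ndarray:
        return self._concat(2)

    def counts(self) -> list[tuple[int, int, int]]:
        return [(len(a), len(b), len(c)) for a, b, c in self.per_site]


def normality_gate(x, alpha: float = ALPHA) -> bool:
    """True iff a KS test against N(mean, sd) does not reject at ``alpha``.

    Uses the estimated-parameter KS variant (no Lilliefors correction).
    A constant sample is reported non-normal (degenerate SD).
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("normality test requires n >= 3")
    sd = x.std(ddof=1)
    if sd == 0:
        return False
    _, p = stats.kstest(x, "norm", args=(x.mean(), sd))
    return bool(p >= alpha)


def compare_groups(x, group_labels, variable: str = "x") -> StatResult:
    """Two-group location comparison, test chosen by per-group normality.

    Both groups normal -> independent t test; otherwise Mann-Whitney U.
    More than two labels are rejected; callers run pairwise comparisons.
    """
    x = np.asarray(x, dtype=float)
    labels = np.asarray(group_labels)
    uniq = np.unique(labels)
    if uniq.size != 2:
        raise ValueError(f"exactly 2 groups required, got {uniq.size}")
    a, b = x[labels == uniq[0]], x[labels == uniq[1]]
    if min(a.size, b.size) < 3:
        raise ValueError("each group needs n >= 3")
    if normality_gate(a) and normality_gate(b):
        stat, p = stats.ttest_ind(a, b)
        test = "t"
    else:
        stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
        test = "MWU"
    return StatResult(variable, test, float(stat), float(p), int(x.size))


def correlate(x, y, variable: str = "x~y") -> StatResult:
    """Pearson when both margins pass the normality gate, else Spearman."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must align")
    if x.size < 3:
        raise ValueError("correlation requires n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance input")
    if normality_gate(x) and normality_gate(y):
        r, p = stats.pearsonr(x, y)
        test = "Pearson"
    else:
        r, p = stats.spearmanr(x, y)
        test = "Spearman"
    return StatResult(variable, test, float(r), float(p), int(x.size))


def describe(x) -> dict:
    """Mean +- SD for normal samples, median (Q1, Q3) otherwise."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    normal = normality_gate(x) if x.size >= 3 else False
    if normal:
        return {"kind": "mean_sd", "mean": float(x.mean()), "sd": float(x.std(ddof=1)), "n": int(x.size)}
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return {"kind": "median_iqr", "median": float(med), "q1": float(q1), "q3": float(q3), "n": int(x.size)}


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_dataset(site_sizes, ratios=(0.6, 0.2, 0.2), seed: int = 0) -> SplitAssignment:
    """Randomized per-site 6:2:2 partition with deterministic sizes.

    Within each site of size n: n_train = round(r1*n) and
    n_val = round(r2*n) (half-away-from-zero rounding), remainder to test —
    e.g. sites of 200 and 63 give (120, 40, 40) and (38, 13, 12).
    Membership is shuffled by ``seed``; indices are global (site blocks are
    laid out consecutively).
    """
    if abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must sum to 1")
    rng = np.random.default_rng(seed)
    per_site, offset = [], 0
    for n in site_sizes:
        if n < 5:
            raise ValueError(f"site size {n} too small to split")
        n_train = _round_half_away(ratios[0] * n)
        n_val = _round_half_away(ratios[1] * n)
        n_test = n - n_train - n_val
        if n_test < 0:
            raise ValueError("rounding produced a negative test-set size")
        idx = offset + rng.permutation(n)
        per_site.append((np.sort(idx[:n_train]), np.sort(idx[n_train:n_train + n_val]), np.sort(idx[n_train + n_val:])))
        offset += n
    return SplitAssignment(tuple(per_site))


def concentration_day_correlation(conc: pd.DataFrame, days, times=SAMPLING_TIMES_H) -> pd.DataFrame:
    """Correlate hospitalization days with concentration at each grid time.

    ``conc`` holds one column per grid time (named ``conc_{t:g}h``) and one
    row per patient. Missing time points are skipped with a warning column
    rather than an error. Returns one row per time in grid order.
    """
    days = np.asarray(days, dtype=float)
    rows = []
    for t in times:
        col = f"conc_{t:g}h"
        if col not in conc.columns:
            rows.append({"time_h": t, "test": "missing", "statistic": float("nan"),
                         "p_value": float("nan"), "n": 0, "significant": False})
            continue
        res = correlate(conc[col].to_numpy(), days, variable=col)
        rows.append({"time_h": t, "test": res.test, "statistic": res.statistic,
                     "p_value": res.p_value, "n": res.n, "significant": res.significant})
    return pd.DataFrame(rows)
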