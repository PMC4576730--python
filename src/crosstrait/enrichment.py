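"""Tail-stratified cross-trait enrichment tests.

Given pruned, paired p-values for a discovery and a lookup trait, the SNPs
in the discovery tail (P < t1) are tested for an excess of nominal lookup
associations (P < t2) against the remaining SNPs, with a Yates-corrected
chi-square on the 2x2 table.  Also here: the exact binomial lookup test used
at genome-wide significant loci, threshold sensitivity grids, Q-Q/genomic
inflation summaries and Wilson proportion intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


class ZeroMarginError(ValueError):
    """A 2x2 margin is empty, so the chi-square test is undefined."""


@dataclass
class ContingencyTable:
    """2x2 counts of pruned SNPs stratified by discovery/lookup thresholds.

    ``a``: disc<t1 & lookup<t2, ``b``: disc<t1 & lookup>=t2,
    ``c``: disc>=t1 & lookup<t2, ``d``: disc>=t1 & lookup>=t2.
    """

    a: int
    b: int
    c: int
    d: int
    disc_thresh: float = np.nan
    lookup_thresh: float = np.nan

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell count")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class EnrichmentResult:
    """One enrichment test: the table, the chi-square, and per-stratum proportions."""

    table: ContingencyTable
    chi2_stat: float
    chi2_p: float
    prop_tail: float          # lookup-significant fraction in the discovery tail
    prop_rest: float
    ci_tail: tuple[float, float]
    ci_rest: tuple[float, float]
    valid: bool = True        # False when a zero margin made the test undefined


def stratify_counts(
    disc_p,
    lookup_p,
    disc_thresh: float = 1e-3,
    lookup_thresh: float = 0.05,
) -> ContingencyTable:
    """Count pruned SNPs into the 2x2 of (disc < t1) x (lookup < t2).

    Threshold semantics are strict "<" on both axes (a SNP at exactly the
    threshold falls in the ">=" stratum).
    """
    disc_p = np.asarray(disc_p, dtype=float)
    lookup_p = np.asarray(lookup_p, dtype=float)
    if disc_p.shape != lookup_p.shape:
        raise ValueError("discovery and lookup p-value arrays differ in length")
    in_tail = disc_p < disc_thresh
    in_look = lookup_p < lookup_thresh
    return ContingencyTable(
        a=int(np.sum(in_tail & in_look)),
        b=int(np.sum(in_tail & ~in_look)),
        c=int(np.sum(~in_tail & in_look)),
        d=int(np.sum(~in_tail & ~in_look)),
        disc_thresh=disc_thresh,
        lookup_thresh=lookup_thresh,
    )


def chisq_yates(table: ContingencyTable) -> tuple[float, float]:
    """Pearson chi-square with Yates' continuity correction on a 2x2 table.

    ``stat = sum(max(0, |O-E|-0.5)^2 / E)`` over the four cells, with
    expectations from the margins; p is the upper tail of chi-square(1 df).
    The correction term is clamped at zero so a perfectly proportional table
    scores exactly 0 rather than being over-corrected.  Raises
    :class:`ZeroMarginError` when a row or column margin is empty.
    """
    obs = table.as_array()
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if np.any(row == 0) or np.any(col == 0):
        raise ZeroMarginError("zero margin: chi-square test undefined")
    exp = row @ col / n
    stat = float(np.sum(np.maximum(0.0, np.abs(obs - exp) - 0.5) ** 2 / exp))
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p


def proportion_ci(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """95% Wilson score interval for a binomial proportion k/n."""
    if n <= 0:
        raise ValueError("n must be > 0")
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    # the Wilson bound is exactly 0 at k=0 and 1 at k=n; clamp the roundoff
    return (0.0 if k == 0 else float(lo)), (1.0 if k == n else float(hi))


def enrich(
    disc_p,
    lookup_p,
    disc_thresh: float = 1e-3,
    lookup_thresh: float = 0.05,
) -> EnrichmentResult:
    """Stratify + chi-square + per-stratum proportions, in one call."""
    t = stratify_counts(disc_p, lookup_p, disc_thresh, lookup_thresh)
    tail_n, rest_n = t.a + t.b, t.c + t.d
    prop_tail = t.a / tail_n if tail_n else np.nan
    prop_rest = t.c / rest_n if rest_n else np.nan
    ci_tail = proportion_ci(t.a, tail_n) if tail_n else (np.nan, np.nan)
    ci_rest = proportion_ci(t.c, rest_n) if rest_n else (np.nan, np.nan)
    try:
        stat, p = chisq_yates(t)
        valid = True
    except ZeroMarginError:
        stat, p, valid = np.nan, np.nan, False
    return EnrichmentResult(t, stat, p, prop_tail, prop_rest, ci_tail, ci_rest, valid)


def binomial_lookup(k: int, n: int, p0: float) -> float:
    """Exact upper-tail binomial probability P(X >= k) with X ~ Bin(n, p0).

    The lookup test at genome-wide significant loci: each of ``n``
    independent loci has probability ``p0`` of showing a lookup p-value
    below the chosen cutoff by chance; observing ``k`` or more such loci is
    the one-sided evidence of enrichment.
    """
    if not 0 <= k <= n:
        raise ValueError("need 0 <= k <= n")
    if not 0 < p0 < 1:
        raise ValueError("need p0 in (0,1)")
    return float(stats.binom.sf(k - 1, n, p0))


def sensitivity_grid(
    disc_p,
    lookup_p,
    disc_threshs,
    lookup_threshs,
) -> pd.DataFrame:
    """One enrichment test per (discovery, lookup) threshold pair, tidy.

    Columns: thresholds, four cell counts, per-stratum proportions,
    chi-square stat/p and a ``valid`` flag (False where a zero margin made
    the test undefined; such cells are flagged, not fatal).
    """
    if not len(disc_threshs) or not len(lookup_threshs):
        raise ValueError("threshold lists must be non-empty")
    rows = []
    for t1 in disc_threshs:
        for t2 in lookup_threshs:
            r = enrich(disc_p, lookup_p, t1, t2)
            rows.append(
                {
                    "disc_thresh": t1,
                    "lookup_thresh": t2,
                    "a": r.table.a,
                    "b": r.table.b,
                    "c": r.table.c,
                    "d": r.table.d,
                    "prop_tail": r.prop_tail,
                    "prop_rest": r.prop_rest,
                    "chi2_stat": r.chi2_stat,
                    "chi2_p": r.chi2_p,
                    "valid": r.valid,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class QQResult:
    """Expected/observed -log10 p quantiles plus the genomic inflation factor."""

    points: pd.DataFrame   # columns: expected, observed (-log10 scale)
    lambda_gc: float


def qq_points(pvalues) -> QQResult:
    """Q-Q coordinates and genomic inflation lambda for a set of p-values.

    Rank i of N (smallest p first) has expected quantile i/(N+1); lambda is
    the median observed 1-df chi-square (from p) over the median of the
    chi-square(1) distribution.  Used to choose the discovery threshold as
    the point where observed quantiles leave the null diagonal.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value array")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0,1]")
    p_sorted = np.sort(p)
    n = p.size
    expected = np.arange(1, n + 1) / (n + 1.0)
    points = pd.DataFrame(
        {"expected": -np.log10(expected), "observed": -np.log10(p_sorted)}
    )
    chi_obs = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi_obs) / stats.chi2.ppf(0.5, df=1))
    return QQResult(points, lam)
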