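"""Direction-of-effect analyses between two traits' shared top variants.

Whether the shared signals push the two phenotypes the same way is tested
two ways: a two-sided sign test of concordant effect directions against
P=0.5, and an ordinary least-squares regression of one trait's betas on the
other's.  Discordant directions at shared loci (risk allele for one trait
lowering the other) are the signature of biological rather than mediated
pleiotropy.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
import statsmodels.api as sm

log = logging.getLogger(__name__)


@dataclass
class DirectionSummary:
    """Sign-test and regression summaries over a set of shared loci."""

    n: int
    n_concordant: int
    binom_p: float
    slope: float = np.nan
    intercept: float = np.nan
    r2: float = np.nan
    slope_p: float = np.nan
    n_zero_dropped: int = 0


def _two_sided_binom(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided binomial p by tail doubling, capped at 1."""
    lower = stats.binom.cdf(k, n, p0)
    upper = stats.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def sign_concordance(effects_a, effects_b) -> DirectionSummary:
    """Two-sided sign test of effect-direction concordance against P=0.5.

    A locus is concordant when sign(beta_A) == sign(beta_B) on the shared
    allele frame.  Loci with an exactly-zero effect on either trait carry no
    direction and are dropped with a logged count.
    """
    a = np.asarray(effects_a, dtype=float)
    b = np.asarray(effects_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("effect vectors differ in length")
    nonzero = (a != 0) & (b != 0)
    n_zero = int((~nonzero).sum())
    if n_zero:
        log.warning("dropping %d locus/loci with a zero effect from the sign test", n_zero)
    a, b = a[nonzero], b[nonzero]
    n = a.size
    if n == 0:
        raise ValueError("no loci with non-zero effects on both traits")
    k = int(np.sum(np.sign(a) == np.sign(b)))
    return DirectionSummary(n=n, n_concordant=k, binom_p=_two_sided_binom(k, n), n_zero_dropped=n_zero)


def effect_regression(effects_a, effects_b) -> tuple[float, float, float, float]:
    """OLS of trait-A betas (outcome) on trait-B betas (predictor).

    Returns (slope, intercept, R², slope p) with the slope p from the t
    distribution on n-2 df.  R² equals the squared Pearson correlation of
    the two effect vectors.
    """
    y = np.asarray(effects_a, dtype=float)
    x = np.asarray(effects_b, dtype=float)
    if x.shape != y.shape:
        raise ValueError("effect vectors differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 loci for the regression")
    if np.var(x) == 0:
        raise ValueError("zero variance in the predictor effects")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return (
        float(fit.params[1]),
        float(fit.params[0]),
        float(fit.rsquared),
        float(fit.pvalues[1]),
    )


def direction_summary(effects_a, effects_b) -> DirectionSummary:
    """Sign test plus effect regression in one summary (regression needs n>=3)."""
    out = sign_concordance(effects_a, effects_b)
    a = np.asarray(effects_a, dtype=float)
    b = np.asarray(effects_b, dtype=float)
    nz = (a != 0) & (b != 0)
    if nz.sum() >= 3 and np.var(b[nz]) > 0:
        slope, intercept, r2, slope_p = effect_regression(a[nz], b[nz])
        out.slope, out.intercept, out.r2, out.slope_p = slope, intercept, r2, slope_p
    return out
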