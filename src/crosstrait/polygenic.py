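"""Threshold-based weighted polygenic profile scoring and case-control tests.

Score SNPs are selected from the pruned discovery trait at increasingly
liberal p-value cutoffs; each individual's profile score is the sum of their
score-allele dosages weighted by the discovery beta.  Association of scores
with case-control status is assessed by a Welch mean comparison and a
logistic regression on the standardized score, with Nagelkerke pseudo-R² as
the variance-explained summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

log = logging.getLogger(__name__)

#: discovery p-value cutoffs defining the nested score-SNP sets
DEFAULT_THRESHOLDS = (0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.75)


@dataclass
class ScoreDefinition:
    """Score alleles and weights for one discovery p-value threshold.

    ``entries`` columns: ``SNP`` (id), ``EA`` (score allele = discovery
    effect allele), ``WEIGHT`` (signed discovery beta).
    """

    threshold: float
    entries: pd.DataFrame

    def __len__(self) -> int:
        return len(self.entries)


@dataclass
class ProfileScores:
    """Per-individual aggregate score for one threshold."""

    scores: pd.Series          # indexed by individual id
    threshold: float
    n_snps: int                # SNPs that contributed
    n_dropped: int = 0         # score SNPs absent from the dosage matrix
    status: pd.Series | None = None


@dataclass
class ScoreAssociation:
    """Association of a profile score with case-control status."""

    welch_t: float
    welch_p: float
    slope: float               # logistic log-OR per SD of score
    slope_se: float
    wald_p: float
    nagelkerke_r2: float
    n_cases: int
    n_controls: int
    separated: bool = False    # complete separation: slope unreliable/infinite


def select_score_snps(
    discovery: pd.DataFrame,
    thresholds=DEFAULT_THRESHOLDS,
) -> list[ScoreDefinition]:
    """One nested ScoreDefinition per threshold from a pruned discovery table.

    ``discovery`` needs columns ``SNP EA BETA P`` (e.g. the pruned rows of
    the discovery trait).  Selection is strict ``P < threshold``; an empty
    selection yields an empty definition with a warning.
    """
    need = {"SNP", "EA", "BETA", "P"}
    if not need.issubset(discovery.columns):
        raise KeyError(f"discovery table needs columns {sorted(need)}")
    out = []
    for t in thresholds:
        sel = discovery.loc[discovery["P"] < t, ["SNP", "EA", "BETA"]]
        sel = sel.rename(columns={"BETA": "WEIGHT"}).reset_index(drop=True)
        if sel.empty:
            log.warning("no SNPs selected at threshold P < %g", t)
        out.append(ScoreDefinition(threshold=t, entries=sel))
    return out


def compute_profile(
    dosages: pd.DataFrame,
    sdef: ScoreDefinition,
    coded_allele: pd.Series | None = None,
    status: pd.Series | None = None,
) -> ProfileScores:
    """Weighted score-allele counts per individual.

    ``dosages`` is individual-major: rows indexed by individual id, columns
    by snp_id, values in [0,2] counting copies of the coded allele.
    ``coded_allele`` maps snp_id -> the allele the matrix counts; columns
    coded on the other allele are flipped (d -> 2-d) onto the score allele.
    Missing dosages are imputed with the score-allele frequency estimate
    2*f (the column mean of observed dosages); score SNPs absent from the
    matrix are dropped with a warning and counted.
    """
    entries = sdef.entries
    present = entries["SNP"].isin(dosages.columns)
    n_dropped = int((~present).sum())
    if n_dropped:
        log.warning("%d score SNP(s) absent from the dosage matrix", n_dropped)
    entries = entries.loc[present]
    if entries.empty:
        scores = pd.Series(0.0, index=dosages.index)
        return ProfileScores(scores, sdef.threshold, 0, n_dropped, status)

    mat = dosages[entries["SNP"]].to_numpy(dtype=float)
    if coded_allele is not None:
        coded = coded_allele.reindex(entries["SNP"]).to_numpy()
        flip = coded != entries["EA"].to_numpy()
        mat[:, flip] = 2.0 - mat[:, flip]
    if np.isnan(mat).any():
        col_mean = np.nanmean(mat, axis=0)   # = 2 * estimated allele frequency
        nan_r, nan_c = np.nonzero(np.isnan(mat))
        mat[nan_r, nan_c] = col_mean[nan_c]
    scores = pd.Series(mat @ entries["WEIGHT"].to_numpy(), index=dosages.index)
    return ProfileScores(scores, sdef.threshold, len(entries), n_dropped, status)


def score_association(
    scores: ProfileScores | pd.Series,
    status: pd.Series | None = None,
) -> ScoreAssociation:
    """Test whether cases carry higher profile scores than controls.

    Welch two-sample comparison of means, plus a logistic regression of
    status on the standardized score fitted by IRLS to tolerance 1e-8; the
    slope is the log-OR per SD of score.  Complete separation is flagged
    rather than fatal.
    """
    if isinstance(scores, ProfileScores):
        s = scores.scores
        status = scores.status if status is None else status
    else:
        s = scores
    if status is None:
        raise ValueError("case/control status required")
    status = status.reindex(s.index) if isinstance(status, pd.Series) else pd.Series(status, index=s.index)
    y = status.to_numpy(dtype=float)
    x = s.to_numpy(dtype=float)
    cases, controls = x[y == 1], x[y == 0]
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both cases and controls must be non-empty")

    welch_t, welch_p = stats.ttest_ind(cases, controls, equal_var=False)

    sd = x.std(ddof=1)
    z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
    X = sm.add_constant(z)
    separated = False
    try:
        import warnings
        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            fit = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-8, maxiter=200)
        separated = any(issubclass(w.category, PerfectSeparationWarning) for w in caught)
        slope = float(fit.params[1])
        slope_se = float(fit.bse[1])
        wald_p = float(fit.pvalues[1])
        ll1 = float(fit.llf)
        if not np.isfinite(slope_se) or abs(slope) > 30:
            separated = True
    except Exception:   # PerfectSeparationError and friends
        separated = True
        slope, slope_se, wald_p, ll1 = np.inf, np.inf, np.nan, np.nan
    if separated:
        log.warning("complete separation: logistic slope unreliable")

    n = len(y)
    p1 = y.mean()
    ll0 = n * (p1 * np.log(p1) + (1 - p1) * np.log(1 - p1))
    if np.isfinite(ll1):
        r2_cs = 1.0 - np.exp(2.0 * (ll0 - ll1) / n)
        nagelkerke = float(r2_cs / (1.0 - np.exp(2.0 * ll0 / n)))
    else:
        nagelkerke = np.nan
    return ScoreAssociation(
        welch_t=float(welch_t),
        welch_p=float(welch_p),
        slope=slope,
        slope_se=slope_se,
        wald_p=wald_p,
        nagelkerke_r2=nagelkerke,
        n_cases=int((y == 1).sum()),
        n_controls=int((y == 0).sum()),
        separated=separated,
    )
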