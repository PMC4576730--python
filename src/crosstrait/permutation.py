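"""Empirical enrichment significance by matched-size random SNP draws.

Instead of trusting the chi-square asymptotics, draw the same number of
independent SNPs as sit in the discovery tail, at random and without
replacement, from the pruned lookup-trait pool; count how many clear the
lookup threshold; repeat; and report the fraction of draws whose count
meets or exceeds the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class EmpiricalResult:
    """Observed tail overlap versus its permutation null."""

    observed_count: int
    draws: int
    exceed_count: int
    empirical_p: float
    seed: int | None = None

    @property
    def p_text(self) -> str:
        """Human-readable p; '< 1/draws' when no draw reached the observation."""
        if self.exceed_count == 0:
            return f"< {1.0 / self.draws:g}"
        return f"{self.empirical_p:g}"


def empirical_p(exceed_count: int, draws: int) -> float:
    """Exact fraction exceed_count/draws (no pseudo-count added)."""
    if draws <= 0:
        raise ValueError("draws must be > 0")
    if not 0 <= exceed_count <= draws:
        raise ValueError("need 0 <= exceed_count <= draws")
    return exceed_count / draws


def permute_enrichment(
    pruned_lookup_pvalues,
    n_draw: int,
    observed_count: int,
    lookup_thresh: float = 0.05,
    draws: int = 10_000,
    seed: int | None = None,
    exclude=None,
) -> EmpiricalResult:
    """Empirical p for the observed discovery-tail lookup overlap.

    Each draw samples ``n_draw`` SNPs without replacement from the pruned
    lookup-trait pool and counts those with lookup p < ``lookup_thresh``;
    ``exceed_count`` counts draws with count >= ``observed_count``.  The
    pool defaults to all pruned SNPs (discovery-tail members included); pass
    a boolean mask in ``exclude`` to remove e.g. the tail SNPs themselves.
    Bit-identical output for a given seed.
    """
    p = np.asarray(pruned_lookup_pvalues, dtype=float)
    if exclude is not None:
        p = p[~np.asarray(exclude, dtype=bool)]
    if n_draw > p.size:
        raise ValueError(f"n_draw={n_draw} exceeds pool of {p.size} SNPs")
    if observed_count > n_draw:
        raise ValueError("observed_count cannot exceed n_draw")
    passes = (p < lookup_thresh).astype(np.int64)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(draws):
        idx = rng.choice(p.size, size=n_draw, replace=False)
        if int(passes[idx].sum()) >= observed_count:
            exceed += 1
    return EmpiricalResult(
        observed_count=observed_count,
        draws=draws,
        exceed_count=exceed,
        empirical_p=empirical_p(exceed, draws),
        seed=seed,
    )
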