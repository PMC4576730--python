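"""Greedy r²-based LD pruning of paired summary statistics.

The pruner repeatedly takes the most significantly associated SNP still in
play, retains it, and eliminates every SNP correlated with it at r² above the
threshold, producing an approximately independent set.  LD can come from a
precomputed pairwise r² table or be derived from dosages within a window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


class LDSource:
    """Sparse symmetric pairwise r² lookup.

    Built from an iterable/DataFrame of ``(snp_a, snp_b, r2)``.  Pairs not
    stored are treated as r²=0 (the convention of a sparse precomputed
    table); r²(x,x)=1 by definition.
    """

    def __init__(self, pairs=None):
        self._adj: dict[str, dict[str, float]] = {}
        if pairs is None:
            return
        if isinstance(pairs, pd.DataFrame):
            it = zip(pairs.iloc[:, 0], pairs.iloc[:, 1], pairs.iloc[:, 2])
        else:
            it = iter(pairs)
        for a, b, r2 in it:
            self.add(str(a), str(b), float(r2))

    def add(self, a: str, b: str, r2: float) -> None:
        if not 0.0 <= r2 <= 1.0 + 1e-12:
            raise ValueError(f"r2 out of [0,1] for pair ({a},{b}): {r2}")
        if a == b:
            return
        self._adj.setdefault(a, {})[b] = r2
        self._adj.setdefault(b, {})[a] = r2

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0
        return self._adj.get(a, {}).get(b, 0.0)

    def neighbors(self, snp: str):
        """(partner, r2) pairs stored for ``snp``."""
        return self._adj.get(snp, {}).items()

    def n_pairs(self) -> int:
        return sum(len(v) for v in self._adj.values()) // 2

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (a, b, r2)
            for a, nb in self._adj.items()
            for b, r2 in nb.items()
            if a < b
        ]
        return pd.DataFrame(rows, columns=["SNP_A", "SNP_B", "R2"])

    @classmethod
    def read_pairs(cls, path) -> "LDSource":
        """Read a 3-column tab-delimited ``SNP_A SNP_B R2`` file."""
        df = pd.read_csv(path, sep="\t", dtype={0: str, 1: str})
        return cls(df)

    def write_pairs(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def r2_from_dosages(
    dosages: pd.DataFrame,
    positions: pd.DataFrame | None = None,
    window_bp: int = 1_000_000,
) -> LDSource:
    """Compute pairwise r² (squared Pearson correlation) from a dosage matrix.

    ``dosages`` is SNP-major: rows indexed by snp_id, columns individuals,
    values in [0,2].  ``positions`` is an optional sidecar with columns
    ``SNP CHR BP``; when given, only pairs on the same chromosome within
    ``window_bp`` are emitted (everything beyond is treated as r²=0).
    Monomorphic SNPs have undefined correlation and are omitted with a
    warning.
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    if dosages.shape[1] < 2:
        raise ValueError("need at least 2 individuals to estimate r2")
    var = dosages.var(axis=1, ddof=1)
    mono = var <= 0
    if mono.any():
        log.warning("omitting %d monomorphic SNP(s) from r2 computation", int(mono.sum()))
    d = dosages.loc[~mono]
    snps = list(d.index.astype(str))

    if positions is not None:
        pos = positions.set_index(positions["SNP"].astype(str))
        chrom = pos["CHR"].astype(str).reindex(snps)
        bp = pos["BP"].astype(np.int64).reindex(snps)
    ld = LDSource()
    if len(snps) < 2:
        return ld
    corr = np.corrcoef(d.to_numpy(dtype=float))
    for i in range(len(snps)):
        for j in range(i + 1, len(snps)):
            if positions is not None:
                if chrom.iloc[i] != chrom.iloc[j] or abs(int(bp.iloc[i]) - int(bp.iloc[j])) > window_bp:
                    continue
            ld.add(snps[i], snps[j], float(corr[i, j] ** 2))
    return ld


@dataclass
class PrunedSet:
    """Result of a greedy pruning pass.

    ``retained`` lists surviving SNP ids in retention (significance) order;
    ``eliminated_by`` maps each removed SNP to the retained SNP that removed
    it — an audit trail from which the full partition can be reconstructed.
    """

    retained: list[str]
    eliminated_by: dict[str, str] = field(default_factory=dict)
    rank_by: str = "a"
    r2_max: float = 0.2

    def __len__(self) -> int:
        return len(self.retained)

    @property
    def retained_set(self) -> set[str]:
        return set(self.retained)


def greedy_prune(paired, ld: LDSource, r2_max: float = 0.2, rank_by: str = "a") -> PrunedSet:
    """Prune to approximately independent SNPs by the greedy tail-first rule.

    Iteratively retains the SNP with the smallest ``rank_by`` p-value among
    those not yet eliminated, then eliminates all SNPs with r² > ``r2_max``
    against it.  Ties on p break to the lexicographically smallest SNP id so
    the output is independent of input row order.

    ``paired`` is a :class:`~crosstrait.sumstats.PairedSumStats` or any
    DataFrame-bearing object/frame with ``SNP`` and ``P_A``/``P_B`` (or
    ``P``) columns; ``rank_by`` selects ``"a"`` or ``"b"`` as the discovery
    trait ordering the pass.
    """
    df = getattr(paired, "df", paired)
    pcol = {"a": "P_A", "b": "P_B"}.get(rank_by, rank_by)
    if pcol not in df.columns:
        if "P" in df.columns:
            pcol = "P"
        else:
            raise KeyError(f"no p-value column for rank_by={rank_by!r}")
    order = df[["SNP", pcol]].sort_values([pcol, "SNP"], kind="mergesort")["SNP"]

    in_input = set(df["SNP"])
    retained: list[str] = []
    eliminated_by: dict[str, str] = {}
    for snp in order:
        if snp in eliminated_by:
            continue
        retained.append(snp)
        for other, r2 in ld.neighbors(snp):
            if (
                r2 > r2_max
                and other in in_input
                and other not in eliminated_by
                and other != snp
            ):
                eliminated_by[other] = snp
    # a SNP retained earlier can never be eliminated later: elimination only
    # touches SNPs not yet processed or not yet retained — assert the partition
    assert len(retained) + len(eliminated_by) == len(in_input)
    return PrunedSet(retained, eliminated_by, rank_by=rank_by, r2_max=r2_max)


def pruned_frame(paired, pruned: PrunedSet) -> pd.DataFrame:
    """Rows of the paired table restricted to the retained SNPs."""
    df = getattr(paired, "df", paired)
    return df[df["SNP"].isin(pruned.retained_set)].reset_index(drop=True)
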