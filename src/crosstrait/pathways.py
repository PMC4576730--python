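"""Nearest-gene mapping and pathway overrepresentation testing.

Shared-signal SNPs are mapped to the closest gene within a window (1 Mb by
default; intergenic SNPs with no gene that close are excluded), the mapped
genes are deduplicated into a set, and each pathway in a catalog is tested
for overrepresentation of that set with a one-sided Fisher exact test under
Bonferroni control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

GENE_COLUMNS = ("CHR", "START", "END", "GENE")   # 1-based inclusive internally


@dataclass
class PathwayCatalog:
    """Pathway name -> member gene symbols, over a defined gene universe."""

    pathways: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __post_init__(self):
        if not self.universe:
            self.universe = set().union(*self.pathways.values()) if self.pathways else set()
        for name, members in self.pathways.items():
            if not members:
                raise ValueError(f"empty pathway: {name}")
            if not members <= self.universe:
                raise ValueError(f"pathway {name} has members outside the universe")

    def __len__(self) -> int:
        return len(self.pathways)


def read_genes_bed(path, zero_based: bool = True) -> pd.DataFrame:
    """Read a 4-column BED-like gene annotation (chrom, start, end, symbol).

    With ``zero_based`` (standard BED half-open intervals) coordinates are
    converted to the 1-based inclusive convention used internally.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["CHR", "START", "END", "GENE"],
                     dtype={"CHR": str, "GENE": str}, comment="#")
    if zero_based:
        df["START"] = df["START"] + 1
    bad = df["START"] > df["END"]
    if bad.any():
        raise ValueError(f"{int(bad.sum())} gene record(s) with start > end")
    if df["GENE"].duplicated().any():
        raise ValueError("duplicate gene symbols in annotation")
    return df


def read_gmt(path) -> PathwayCatalog:
    """Read a GMT file (name, description, member genes per line)."""
    pathways: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            pathways[parts[0]] = set(g for g in parts[2:] if g)
    return PathwayCatalog(pathways)


def map_nearest_gene(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    window: int = 1_000_000,
) -> tuple[pd.DataFrame, int]:
    """Map each SNP to the closest gene within ``window`` bp.

    ``snps`` needs columns ``SNP CHR BP``; ``genes`` the internal 1-based
    inclusive ``CHR START END GENE``.  Distance is 0 for a SNP inside the
    gene body, otherwise the gap to the nearer end.  Equidistant genes break
    to the lexicographically smallest symbol (both are logged).  Returns the
    mapping (columns ``SNP GENE DISTANCE``) and the count of SNPs with no
    gene within the window.
    """
    rows = []
    n_unmapped = 0
    by_chrom = {c: g.sort_values("START") for c, g in genes.groupby("CHR")}
    for snp, chrom, bp in zip(snps["SNP"], snps["CHR"].astype(str), snps["BP"]):
        g = by_chrom.get(chrom)
        if g is None:
            n_unmapped += 1
            continue
        start = g["START"].to_numpy()
        end = g["END"].to_numpy()
        dist = np.where(
            (bp >= start) & (bp <= end),
            0,
            np.minimum(np.abs(bp - start), np.abs(bp - end)),
        )
        ok = dist <= window
        if not ok.any():
            n_unmapped += 1
            continue
        dmin = dist[ok].min()
        candidates = sorted(g["GENE"].to_numpy()[ok & (dist == dmin)])
        if len(candidates) > 1:
            log.info("SNP %s equidistant from genes %s; keeping %s",
                     snp, candidates, candidates[0])
        rows.append({"SNP": snp, "GENE": candidates[0], "DISTANCE": int(dmin)})
    if n_unmapped:
        log.info("%d SNP(s) had no gene within %d bp", n_unmapped, window)
    return pd.DataFrame(rows, columns=["SNP", "GENE", "DISTANCE"]), n_unmapped


@dataclass
class OverrepResult:
    """One pathway's overrepresentation test."""

    pathway: str
    observed: int
    expected: float
    pathway_size: int
    fisher_p: float
    significant: bool


def overrep_test(
    gene_set,
    catalog: PathwayCatalog,
    alpha: float = 0.05,
    n_tests: int | None = None,
) -> tuple[list[OverrepResult], int]:
    """One-sided Fisher exact enrichment test of ``gene_set`` per pathway.

    Genes outside the catalog universe are dropped with a count (returned).
    For each pathway the 2x2 of (in set) x (in pathway) over the universe is
    tested one-sided for enrichment; expected = |set|*|pathway|/|universe|.
    ``significant`` flags p below the Bonferroni threshold alpha/n_tests
    (``n_tests`` defaults to the number of pathways in the catalog, but the
    denominator is caller-controllable).
    """
    genes = set(gene_set)
    in_universe = genes & catalog.universe
    n_dropped = len(genes) - len(in_universe)
    if n_dropped:
        log.info("%d of %d gene(s) absent from the catalog universe", n_dropped, len(genes))
    if not in_universe:
        raise ValueError("no genes from the set are present in the catalog universe")
    n_tests = n_tests if n_tests is not None else len(catalog)
    thresh = bonferroni_threshold(alpha, n_tests)

    N = len(catalog.universe)
    n_set = len(in_universe)
    out = []
    for name, members in catalog.pathways.items():
        K = len(members)
        obs = len(in_universe & members)
        table = [[obs, n_set - obs], [K - obs, N - K - (n_set - obs)]]
        _, p = stats.fisher_exact(table, alternative="greater")
        out.append(
            OverrepResult(
                pathway=name,
                observed=obs,
                expected=n_set * K / N,
                pathway_size=K,
                fisher_p=float(p),
                significant=bool(p < thresh),
            )
        )
    out.sort(key=lambda r: r.fisher_p)
    return out, n_dropped


def overrep_frame(results: list[OverrepResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def bonferroni_threshold(alpha: float = 0.05, n_tests: int = 1) -> float:
    """Per-test significance threshold alpha/n controlling family-wise error."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return alpha / n_tests
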