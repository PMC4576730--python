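"""Synthetic paired GWAS data with known truth, for testing every stage.

The generator emulates the structure the enrichment analyses assume: SNPs
arranged in LD blocks with geometrically decaying within-block correlation,
a small fraction of blocks causal for both traits with a tunable cross-trait
effect correlation (including the discordant directions seen at real shared
loci), trait-specific causal blocks, and a null background with uniform
p-values.  Summary statistics are generated directly at the z-score level:
within a block the marginal z-scores are multivariate normal with
correlation matrix rho_LD^|i-j| and mean equal to the tag SNP's
noncentrality sqrt(2 f (1-f) n) * beta propagated through the LD, which is
what an individual-level GWAS would produce in expectation, at a fraction of
the cost.  Individual-level genotypes are generated only for the polygenic
profile-scoring stage, via a liability-threshold case-control model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ldprune import LDSource
from .pathways import PathwayCatalog
from .sumstats import SumStatTable

#: ordered non-complementary allele pairs (survive strand-ambiguity filtering)
_SAFE_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
               ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]
_AMBIG_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]


@dataclass
class GeneratorConfig:
    """Study conditions for the paired-summary-statistics generator.

    Defaults mirror a desk-scale version of a case-control GWAS of ~10k
    subjects (trait A) looked up against a large quantitative-trait
    meta-GWAS of ~77k subjects (trait B): effects on the standardized
    genotype scale, with a negative cross-trait correlation among shared
    causal effects by default.
    """

    n_blocks: int = 400
    block_size: int = 25
    rho_ld: float = 0.8             # within-block LD decay: corr = rho^|i-j|
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_a: int = 10_254               # trait A GWAS sample size
    n_b: int = 77_167               # trait B GWAS sample size
    pi_shared: float = 0.03         # fraction of blocks causal for both traits
    pi_a: float = 0.05              # trait-A-only causal fraction
    pi_b: float = 0.05
    effect_sd_a: float = 0.02       # SD of standardized causal effects, trait A
    effect_sd_b: float = 0.01
    rho_effect: float = -0.5        # cross-trait correlation of shared effects
    frac_ambiguous: float = 0.0     # fraction of SNPs given A/T or C/G alleles
    ld_r2_floor: float = 0.05       # pairs below this r2 are not emitted
    seed: int | None = None

    @property
    def n_snps(self) -> int:
        return self.n_blocks * self.block_size

    def validate(self) -> None:
        if self.n_blocks < 1 or self.block_size < 1:
            raise ValueError("invariant violated: n_blocks >= 1 and block_size >= 1")
        if not 0.0 <= self.rho_ld < 1.0:
            raise ValueError("invariant violated: rho_ld in [0,1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("invariant violated: 0 < maf_lo <= maf_hi <= 0.5")
        if min(self.pi_shared, self.pi_a, self.pi_b) < 0 or self.pi_shared + self.pi_a + self.pi_b > 1:
            raise ValueError("invariant violated: pi_shared + pi_a + pi_b <= 1 with all >= 0")
        if not -1.0 <= self.rho_effect <= 1.0:
            raise ValueError("invariant violated: rho_effect in [-1,1]")
        if min(self.n_a, self.n_b) < 2:
            raise ValueError("invariant violated: sample sizes >= 2")
        if not 0.0 <= self.frac_ambiguous <= 1.0:
            raise ValueError("invariant violated: frac_ambiguous in [0,1]")


@dataclass
class SimulatedPair:
    """Paired tables, the LD that relates their SNPs, and the ground truth."""

    table_a: SumStatTable
    table_b: SumStatTable
    ld: LDSource
    truth: pd.DataFrame          # SNP BLOCK TAG CAUSAL_A CAUSAL_B BETA_A_TRUE BETA_B_TRUE
    config: GeneratorConfig
    child_seeds: dict[str, int] = field(default_factory=dict)


def _child_rngs(seed, names):
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(names))
    rngs = {n: np.random.default_rng(c) for n, c in zip(names, children)}
    seeds = {n: int(c.generate_state(1)[0]) for n, c in zip(names, children)}
    return rngs, seeds


def generate_paired_sumstats(cfg: GeneratorConfig) -> SimulatedPair:
    """Generate a pair of summary-statistic tables with planted shared loci.

    Per block, at most the tag SNP carries a causal effect.  Shared blocks
    draw (beta_A, beta_B) from a bivariate normal with correlation
    ``rho_effect``; trait-specific blocks draw a single effect.  Effects are
    on the standardized-genotype scale and converted to allelic betas via
    1/sqrt(2 f (1-f)).  Deterministic for a given seed.
    """
    cfg.validate()
    rngs, child_seeds = _child_rngs(
        cfg.seed, ["layout", "effects", "zscores", "alleles"]
    )
    nb, bs = cfg.n_blocks, cfg.block_size
    n = cfg.n_snps

    # block roles and tag positions
    rl = rngs["layout"]
    n_sh = int(round(cfg.pi_shared * nb))
    n_ao = int(round(cfg.pi_a * nb))
    n_bo = int(round(cfg.pi_b * nb))
    perm = rl.permutation(nb)
    shared = perm[:n_sh]
    a_only = perm[n_sh:n_sh + n_ao]
    b_only = perm[n_sh + n_ao:n_sh + n_ao + n_bo]
    tags = rl.integers(0, bs, size=nb)

    # standardized causal effects at the tags
    re_ = rngs["effects"]
    beta_a = np.zeros(nb)
    beta_b = np.zeros(nb)
    if n_sh:
        cov = np.array(
            [
                [cfg.effect_sd_a**2, cfg.rho_effect * cfg.effect_sd_a * cfg.effect_sd_b],
                [cfg.rho_effect * cfg.effect_sd_a * cfg.effect_sd_b, cfg.effect_sd_b**2],
            ]
        )
        # eigh handles the singular cov at rho_effect = +/-1
        both = re_.multivariate_normal([0.0, 0.0], cov, size=n_sh, method="eigh")
        beta_a[shared] = both[:, 0]
        beta_b[shared] = both[:, 1]
    beta_a[a_only] = re_.normal(0.0, cfg.effect_sd_a, size=n_ao)
    beta_b[b_only] = re_.normal(0.0, cfg.effect_sd_b, size=n_bo)

    # within-block correlation and its Cholesky factor (shared by all blocks)
    idx = np.arange(bs)
    sigma = cfg.rho_ld ** np.abs(idx[:, None] - idx[None, :])
    L = np.linalg.cholesky(sigma)

    # noncentrality propagated through LD: corr-with-tag * sqrt(n) * beta_std
    tag_corr = sigma[:, tags].T                     # (nb, bs): rho^|i-tag_b|
    z = np.empty((2, nb, bs))
    rz = rngs["zscores"]
    for t, (beta, n_tr) in enumerate([(beta_a, cfg.n_a), (beta_b, cfg.n_b)]):
        ncp = tag_corr * (np.sqrt(n_tr) * beta)[:, None]
        eps = rz.standard_normal((nb, bs))
        z[t] = ncp + eps @ L.T

    # frequencies, alleles, coordinates
    ra = rngs["alleles"]
    maf = ra.uniform(cfg.maf_range[0], cfg.maf_range[1], size=n)
    flip_freq = ra.random(n) < 0.5
    eaf = np.where(flip_freq, 1.0 - maf, maf)
    ambig = ra.random(n) < cfg.frac_ambiguous
    safe_idx = ra.integers(0, len(_SAFE_PAIRS), size=n)
    amb_idx = ra.integers(0, len(_AMBIG_PAIRS), size=n)
    ea = np.where(ambig, np.array([p[0] for p in _AMBIG_PAIRS])[amb_idx],
                  np.array([p[0] for p in _SAFE_PAIRS])[safe_idx])
    oa = np.where(ambig, np.array([p[1] for p in _AMBIG_PAIRS])[amb_idx],
                  np.array([p[1] for p in _SAFE_PAIRS])[safe_idx])

    block_of = np.repeat(np.arange(nb), bs)
    within = np.tile(np.arange(bs), nb)
    n_chrom = min(22, nb)
    chrom_of_block = np.arange(nb) % n_chrom + 1
    block_rank = np.arange(nb) // n_chrom      # position of the block on its chromosome
    pos = 1 + block_rank[block_of] * 500_000 + within * 5_000
    snp_ids = np.array([f"rs{i + 1}" for i in range(n)])

    def table(trait_idx, trait, n_tr):
        zz = z[trait_idx].reshape(n)
        se = 1.0 / np.sqrt(2.0 * eaf * (1.0 - eaf) * n_tr)
        p = np.clip(2.0 * stats.norm.sf(np.abs(zz)), 1e-300, 1.0)
        df = pd.DataFrame(
            {
                "SNP": snp_ids,
                "CHR": chrom_of_block[block_of].astype(str),
                "BP": pos.astype(np.int64),
                "EA": ea,
                "OA": oa,
                "EAF": eaf,
                "BETA": zz * se,
                "SE": se,
                "P": p,
                "N": float(n_tr),
            }
        )
        return SumStatTable(df, trait=trait, provenance="synthetic")

    table_a = table(0, "trait_A", cfg.n_a)
    table_b = table(1, "trait_B", cfg.n_b)

    # emit within-block LD pairs with r2 = rho^(2|i-j|) above the floor
    ld = LDSource()
    if cfg.rho_ld > 0:
        max_d = bs - 1
        if cfg.ld_r2_floor > 0:
            max_d = min(max_d, int(np.floor(np.log(cfg.ld_r2_floor) / (2.0 * np.log(cfg.rho_ld)))))
        for d in range(1, max_d + 1):
            r2 = cfg.rho_ld ** (2 * d)
            for b in range(nb):
                base = b * bs
                for i in range(bs - d):
                    ld.add(snp_ids[base + i], snp_ids[base + i + d], r2)

    is_tag = within == tags[block_of]
    truth = pd.DataFrame(
        {
            "SNP": snp_ids,
            "BLOCK": block_of,
            "TAG": is_tag,
            "CAUSAL_A": is_tag & (beta_a[block_of] != 0.0),
            "CAUSAL_B": is_tag & (beta_b[block_of] != 0.0),
            "BETA_A_TRUE": np.where(is_tag, beta_a[block_of], 0.0),
            "BETA_B_TRUE": np.where(is_tag, beta_b[block_of], 0.0),
        }
    )
    return SimulatedPair(table_a, table_b, ld, truth, cfg, child_seeds)


def generate_casecontrol(
    effects: pd.DataFrame,
    n_case: int,
    n_control: int,
    prevalence: float = 0.1,
    seed: int | None = None,
    batch_size: int = 2_000,
    max_batches: int = 500,
) -> tuple[pd.DataFrame, pd.Series]:
    """Case-control genotypes under a liability-threshold model.

    ``effects`` needs columns ``SNP EAF BETA_TRUE`` (standardized-scale
    liability effects; zero rows are fine).  Genotypes are Binomial(2, f)
    per SNP; liability is the standardized-genotype weighted sum plus normal
    noise scaled so total liability variance is 1; individuals above the
    upper ``prevalence`` quantile are cases.  Batches are drawn until both
    quotas are met (error after ``max_batches``).

    Returns an individual-major dosage DataFrame (columns = SNP ids,
    counting effect-allele copies) and a 0/1 status Series.
    """
    if not 0.0 < prevalence < 1.0:
        raise ValueError("prevalence must be in (0,1)")
    f = effects["EAF"].to_numpy(dtype=float)
    beta = effects["BETA_TRUE"].to_numpy(dtype=float)
    var_g = float(np.sum(beta**2))
    if var_g >= 1.0:
        raise ValueError("genetic liability variance must be < 1")
    sd_e = np.sqrt(1.0 - var_g)
    thr = stats.norm.isf(prevalence)

    rng = np.random.default_rng(seed)
    denom = np.sqrt(2.0 * f * (1.0 - f))
    cases, controls = [], []
    for _ in range(max_batches):
        g = rng.binomial(2, f, size=(batch_size, f.size)).astype(float)
        x = (g - 2.0 * f) / denom
        liab = x @ beta + rng.normal(0.0, sd_e, size=batch_size)
        is_case = liab > thr
        if len(cases) < n_case:
            cases.extend(g[is_case][: n_case - len(cases)])
        if len(controls) < n_control:
            controls.extend(g[~is_case][: n_control - len(controls)])
        if len(cases) >= n_case and len(controls) >= n_control:
            break
    else:
        raise RuntimeError(
            f"case/control quota not reached after {max_batches} batches "
            f"(prevalence {prevalence} too extreme for the batch budget)"
        )
    geno = np.vstack([np.asarray(cases), np.asarray(controls)])
    status = np.concatenate([np.ones(n_case, dtype=int), np.zeros(n_control, dtype=int)])
    ids = [f"ind_{i + 1}" for i in range(len(status))]
    dosages = pd.DataFrame(geno, index=ids, columns=effects["SNP"].to_numpy())
    return dosages, pd.Series(status, index=ids, name="STATUS")


def generate_pathway_fixture(
    n_genes: int = 100,
    n_pathways: int = 10,
    planted_pathway_size: int = 10,
    planted_overlap: int = 5,
    gene_set_size: int = 10,
    seed: int | None = None,
) -> tuple[pd.DataFrame, PathwayCatalog, list[str]]:
    """A gene annotation, a pathway catalog and a gene set with one planted signal.

    The first pathway ("planted_pathway") contributes ``planted_overlap`` of
    its members to the emitted gene set; the rest of the set is drawn from
    outside that pathway, so its Fisher enrichment is controllable by
    construction.  Gene coordinates are random on synthetic chromosomes.
    """
    if planted_overlap > min(planted_pathway_size, gene_set_size):
        raise ValueError("planted_overlap cannot exceed pathway or set size")
    if planted_pathway_size > n_genes or gene_set_size > n_genes:
        raise ValueError("pathway/set sizes cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    symbols = np.array([f"GENE{i + 1:04d}" for i in range(n_genes)])
    chrom = rng.integers(1, 6, size=n_genes).astype(str)
    start = rng.integers(1, 50_000_000, size=n_genes)
    length = rng.integers(5_000, 200_000, size=n_genes)
    genes = pd.DataFrame(
        {"CHR": chrom, "START": start, "END": start + length, "GENE": symbols}
    ).sort_values(["CHR", "START"]).reset_index(drop=True)

    planted = rng.choice(symbols, size=planted_pathway_size, replace=False)
    pathways = {"planted_pathway": set(planted)}
    for k in range(1, n_pathways):
        members = rng.choice(symbols, size=planted_pathway_size, replace=False)
        pathways[f"pathway_{k}"] = set(members)
    catalog = PathwayCatalog(pathways, universe=set(symbols))

    others = np.setdiff1d(symbols, planted)
    gene_set = list(rng.choice(planted, size=planted_overlap, replace=False)) + list(
        rng.choice(others, size=gene_set_size - planted_overlap, replace=False)
    )
    return genes, catalog, gene_set


def null_config(n_snps: int = 10_000, seed: int | None = None, **kw) -> GeneratorConfig:
    """A pure-null configuration (no causal blocks) at the given scale."""
    block_size = kw.pop("block_size", 25)
    return GeneratorConfig(
        n_blocks=n_snps // block_size,
        block_size=block_size,
        pi_shared=0.0,
        pi_a=0.0,
        pi_b=0.0,
        seed=seed,
        **kw,
    )
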