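"""End-to-end orchestration: harmonize -> prune -> enrich -> permute ->
score -> direction -> pathways, from a single config, with a manifest.

Two entry points: :func:`analyze_pair` is the in-memory composition used by
tests and simulations; :func:`run_pipeline` is the file-driven runner behind
the command line, which validates its inputs up front, logs every stage's
dropped-record counts, and writes a report bundle plus a manifest recording
the seed and a hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .sumstats import SumStatTable, PairedSumStats, read_sumstats, harmonize
from .ldprune import LDSource, PrunedSet, greedy_prune, pruned_frame
from .enrichment import EnrichmentResult, enrich, sensitivity_grid, qq_points
from .permutation import EmpiricalResult, permute_enrichment
from .polygenic import DEFAULT_THRESHOLDS, select_score_snps, compute_profile, score_association
from .concordance import direction_summary
from .pathways import read_genes_bed, read_gmt, map_nearest_gene, overrep_test, overrep_frame

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid or incomplete run configuration (raised before any compute)."""


@dataclass
class RunConfig:
    """File paths, thresholds and seeds for a full pipeline run."""

    sumstats_a: str | None = None
    sumstats_b: str | None = None
    ld_pairs: str | None = None
    dosages: str | None = None        # individual-major TSV, header = SNP ids
    status: str | None = None         # two-column TSV: individual id, 0/1
    genes_bed: str | None = None
    pathways_gmt: str | None = None
    disc_thresh: float = 1e-3
    lookup_thresh: float = 0.05
    grid_disc: tuple[float, ...] = ()
    grid_lookup: tuple[float, ...] = ()
    r2_max: float = 0.2
    maf_min: float = 0.01
    draws: int = 10_000
    perm_max_p: float = 0.10          # permute only when the chi-square p is below this
    score_thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    alpha: float = 0.05
    n_tests: int | None = None        # Bonferroni denominator; default = catalog size
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        for name in ("sumstats_a", "sumstats_b", "ld_pairs", "dosages",
                     "status", "genes_bed", "pathways_gmt"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise ConfigError(f"configured path for {name} does not exist: {p}")
        for t in (self.disc_thresh, self.lookup_thresh, *self.grid_disc,
                  *self.grid_lookup, *self.score_thresholds):
            if not 0.0 < t <= 1.0:
                raise ConfigError(f"threshold out of (0,1]: {t}")
        if self.sumstats_a is None or self.sumstats_b is None:
            raise ConfigError("both sumstats_a and sumstats_b are required")
        if (self.dosages is None) != (self.status is None):
            raise ConfigError("dosages and status must be given together")
        if (self.genes_bed is None) != (self.pathways_gmt is None):
            raise ConfigError("genes_bed and pathways_gmt must be given together")


def config_hash(cfg: RunConfig) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PairAnalysis:
    """In-memory result of harmonize -> prune -> enrich for one direction."""

    paired: PairedSumStats
    pruned: PrunedSet
    frame: pd.DataFrame            # paired rows restricted to pruned SNPs
    result: EnrichmentResult
    empirical: EmpiricalResult | None = None


def analyze_pair(
    table_a: SumStatTable,
    table_b: SumStatTable,
    ld: LDSource,
    disc: str = "a",
    disc_thresh: float = 1e-3,
    lookup_thresh: float = 0.05,
    r2_max: float = 0.2,
    maf_min: float = 0.01,
    paired: PairedSumStats | None = None,
) -> PairAnalysis:
    """Harmonize, prune on the discovery trait, and run the enrichment test.

    ``disc`` selects which trait ("a" or "b") is the discovery side whose
    tail is interrogated; the other trait provides the lookup p-values.
    Pass a precomputed ``paired`` to skip re-harmonization.
    """
    if paired is None:
        paired = harmonize(table_a, table_b, maf_min=maf_min)
    pruned = greedy_prune(paired, ld, r2_max=r2_max, rank_by=disc)
    frame = pruned_frame(paired, pruned)
    disc_p = frame["P_A" if disc == "a" else "P_B"].to_numpy()
    look_p = frame["P_B" if disc == "a" else "P_A"].to_numpy()
    result = enrich(disc_p, look_p, disc_thresh, lookup_thresh)
    return PairAnalysis(paired, pruned, frame, result)


def permute_pair(analysis: PairAnalysis, disc: str = "a",
                 draws: int = 10_000, seed: int | None = None) -> EmpiricalResult:
    """Permutation empirical p for an analyzed pair's enrichment table."""
    look_p = analysis.frame["P_B" if disc == "a" else "P_A"].to_numpy()
    t = analysis.result.table
    emp = permute_enrichment(
        look_p,
        n_draw=t.a + t.b,
        observed_count=t.a,
        lookup_thresh=t.lookup_thresh,
        draws=draws,
        seed=seed,
    )
    analysis.empirical = emp
    return emp


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every configured stage and return (and optionally write) the report.

    Deterministic given ``cfg.seed``.  Stages without inputs (no dosages, no
    pathway files) are skipped; downstream stages that do not depend on them
    still run.  Any stage failure aborts with the stage name and cause.
    """
    cfg.validate()
    report: dict = {
        "manifest": {
            "version": __version__,
            "seed": cfg.seed,
            "config_hash": config_hash(cfg),
            "config": asdict(cfg),
        },
        "stages": {},
    }

    def stage(name, fn):
        try:
            out = fn()
        except Exception as e:
            raise RuntimeError(f"stage '{name}' failed: {e}") from e
        report["stages"][name] = out
        return out

    table_a = read_sumstats(cfg.sumstats_a, trait="trait_A")
    table_b = read_sumstats(cfg.sumstats_b, trait="trait_B")
    ld = LDSource.read_pairs(cfg.ld_pairs) if cfg.ld_pairs else LDSource()

    paired = stage("harmonize", lambda: harmonize(table_a, table_b, maf_min=cfg.maf_min))
    report["stages"]["harmonize"] = paired.counts

    analyses: dict[str, PairAnalysis] = {}
    for disc in ("a", "b"):
        an = analyze_pair(
            table_a, table_b, ld,
            disc=disc,
            disc_thresh=cfg.disc_thresh,
            lookup_thresh=cfg.lookup_thresh,
            r2_max=cfg.r2_max,
            paired=paired,
        )
        analyses[disc] = an
        t, r = an.result.table, an.result
        entry = {
            "n_pruned": len(an.pruned),
            "counts": {"a": t.a, "b": t.b, "c": t.c, "d": t.d},
            "chi2_stat": r.chi2_stat,
            "chi2_p": r.chi2_p,
            "prop_tail": r.prop_tail,
            "prop_rest": r.prop_rest,
            "valid": r.valid,
        }
        if r.valid and r.chi2_p < cfg.perm_max_p:
            emp = permute_pair(an, disc=disc, draws=cfg.draws, seed=cfg.seed)
            entry["empirical_p"] = emp.empirical_p
            entry["empirical_p_text"] = emp.p_text
            entry["exceed_count"] = emp.exceed_count
        report["stages"][f"enrichment_disc_{disc}"] = entry

    if cfg.grid_disc and cfg.grid_lookup:
        frame = analyses["a"].frame
        grid = sensitivity_grid(
            frame["P_A"].to_numpy(), frame["P_B"].to_numpy(),
            cfg.grid_disc, cfg.grid_lookup,
        )
        report["stages"]["sensitivity_grid"] = grid.to_dict(orient="records")

    # Q-Q and lambda on the full harmonized set: pruning keeps the most
    # significant SNP per LD clump and would bias the quantiles downward
    frame_a = analyses["a"].frame
    qq = qq_points(paired.df["P_A"].to_numpy())
    report["stages"]["qq"] = {"lambda_gc": qq.lambda_gc}

    # direction of effect at the shared-signal loci
    shared = frame_a[
        (frame_a["P_A"] < cfg.disc_thresh) & (frame_a["P_B"] < cfg.lookup_thresh)
    ]
    if len(shared) > 0:
        ds = direction_summary(shared["BETA_A"].to_numpy(), shared["BETA_B"].to_numpy())
        report["stages"]["direction"] = {
            "n": ds.n, "n_concordant": ds.n_concordant, "binom_p": ds.binom_p,
            "slope": ds.slope, "r2": ds.r2, "slope_p": ds.slope_p,
        }

    if cfg.dosages is not None:
        def polygenic_stage():
            dosages = pd.read_csv(cfg.dosages, sep="\t", index_col=0)
            status = pd.read_csv(cfg.status, sep="\t", index_col=0).iloc[:, 0]
            frame_b = analyses["b"].frame
            disc_table = frame_b.rename(columns={"BETA_B": "BETA", "P_B": "P"})[
                ["SNP", "EA", "BETA", "P"]
            ]
            sdefs = select_score_snps(disc_table, cfg.score_thresholds)
            out = []
            for sdef in sdefs:
                prof = compute_profile(dosages, sdef, status=status)
                if prof.n_snps == 0:
                    out.append({"threshold": sdef.threshold, "n_snps": 0})
                    continue
                assoc = score_association(prof)
                out.append(
                    {
                        "threshold": sdef.threshold,
                        "n_snps": prof.n_snps,
                        "welch_p": assoc.welch_p,
                        "slope_per_sd": assoc.slope,
                        "wald_p": assoc.wald_p,
                        "nagelkerke_r2": assoc.nagelkerke_r2,
                        "separated": assoc.separated,
                    }
                )
            return out

        stage("polygenic", polygenic_stage)

    if cfg.genes_bed is not None:
        def pathway_stage():
            genes = read_genes_bed(cfg.genes_bed)
            catalog = read_gmt(cfg.pathways_gmt)
            mapped, n_unmapped = map_nearest_gene(
                shared[["SNP", "CHR", "BP"]], genes
            )
            if mapped.empty:
                return {"n_unmapped": n_unmapped, "results": []}
            results, n_dropped = overrep_test(
                set(mapped["GENE"]), catalog, alpha=cfg.alpha, n_tests=cfg.n_tests
            )
            return {
                "n_unmapped": n_unmapped,
                "n_outside_universe": n_dropped,
                "results": overrep_frame(results).to_dict(orient="records"),
            }

        stage("pathways", pathway_stage)

    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_jsonable)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(report["manifest"], fh, indent=2, default=_jsonable)
        qq.points.to_csv(outdir / "qq_points.tsv", sep="\t", index=False)
        log.info("report written to %s", outdir)
    return report


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if isinstance(obj, (np.ndarray, tuple, set)):
        return list(obj)
    return str(obj)
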