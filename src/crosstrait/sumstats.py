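"""Reading, validation and cross-trait harmonization of GWAS summary statistics.

The canonical in-memory container is a :class:`pandas.DataFrame` with the
columns ``SNP CHR BP EA OA EAF BETA SE P N`` (tab-delimited on disk, one row
per variant).  Effects are always stored as betas on the additive scale; odds
ratios from case-control scans are converted by natural log at read time so
that every downstream computation works on a single scale.

Harmonization joins two traits' tables by rsID onto the first trait's
effect-allele frame.  Strand is never observed directly, so the only safe way
to align alleles is by matching them — which is also why strand-ambiguous
A/T and C/G variants must be discarded: their two strand readings are
indistinguishable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical column order for summary-statistic tables
CANONICAL_COLUMNS = ("SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P", "N")

#: columns that must be present (BETA may arrive as OR and is converted)
MANDATORY_COLUMNS = ("SNP", "CHR", "BP", "EA", "OA", "EAF", "SE", "P")

VALID_ALLELES = frozenset("ACGT")
COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: strand-ambiguous (palindromic) allele pairs
AMBIGUOUS_PAIRS = (frozenset("AT"), frozenset("CG"))


class SumStatsError(ValueError):
    """Fatal problem with a summary-statistics input (bad config or content)."""


@dataclass
class SumStatTable:
    """One trait's per-SNP association summaries.

    ``df`` holds the canonical columns; ``rejected`` counts rows dropped at
    validation, keyed by the violated rule.
    """

    df: pd.DataFrame
    trait: str = ""
    provenance: str = ""
    rejected: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)


@dataclass
class PairedSumStats:
    """Per-SNP join of two traits on a shared effect-allele frame.

    ``df`` columns: ``SNP CHR BP EA OA EAF_A BETA_A SE_A P_A EAF_B BETA_B
    SE_B P_B FLIPPED``.  ``counts`` records the join size and how many SNPs
    each filter removed (``joined``, ``incompatible_removed``,
    ``ambiguous_removed``, ``maf_removed``, ``retained``).
    """

    df: pd.DataFrame
    trait_a: str = ""
    trait_b: str = ""
    counts: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.df)

    def tables(self) -> tuple[SumStatTable, SumStatTable]:
        """Split back into two single-trait tables, both on the shared frame."""
        base = self.df[["SNP", "CHR", "BP", "EA", "OA"]]
        a = base.assign(
            EAF=self.df["EAF_A"].to_numpy(),
            BETA=self.df["BETA_A"].to_numpy(),
            SE=self.df["SE_A"].to_numpy(),
            P=self.df["P_A"].to_numpy(),
            N=np.nan,
        )
        b = base.assign(
            EAF=self.df["EAF_B"].to_numpy(),
            BETA=self.df["BETA_B"].to_numpy(),
            SE=self.df["SE_B"].to_numpy(),
            P=self.df["P_B"].to_numpy(),
            N=np.nan,
        )
        return (
            SumStatTable(a.reset_index(drop=True), trait=self.trait_a),
            SumStatTable(b.reset_index(drop=True), trait=self.trait_b),
        )


def _coerce_canonical(df: pd.DataFrame, column_map: dict[str, str] | None) -> pd.DataFrame:
    if column_map:
        df = df.rename(columns=column_map)
    if "OR" in df.columns and "BETA" not in df.columns:
        with np.errstate(invalid="ignore", divide="ignore"):
            df["BETA"] = np.log(pd.to_numeric(df["OR"], errors="coerce"))
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if "BETA" not in df.columns:
        missing.append("BETA (or OR)")
    if missing:
        raise SumStatsError(f"missing mandatory column(s): {', '.join(missing)}")
    if "N" not in df.columns:
        df["N"] = np.nan
    return df


def validate_records(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Apply the per-record invariants; return (valid rows, rejection counts).

    Invariants: alleles single bases in {A,C,G,T} and distinct; EAF in [0,1];
    SE > 0; P in (0,1]; BP parseable as an integer.
    """
    df = df.copy()
    for col in ("BP", "EAF", "BETA", "SE", "P", "N"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("EA", "OA"):
        df[col] = df[col].astype(str).str.upper()

    checks = {
        "unparseable": df[["BP", "EAF", "BETA", "SE", "P"]].isna().any(axis=1),
        "bad_allele": ~(df["EA"].isin(VALID_ALLELES) & df["OA"].isin(VALID_ALLELES))
        | (df["EA"] == df["OA"]),
        "bad_eaf": ~df["EAF"].between(0.0, 1.0),
        "bad_se": ~(df["SE"] > 0),
        "bad_p": ~((df["P"] > 0) & (df["P"] <= 1)),
    }
    rejected: dict[str, int] = {}
    bad = pd.Series(False, index=df.index)
    for rule, mask in checks.items():
        mask = mask.fillna(True) & ~bad  # attribute each row to the first rule hit
        n = int(mask.sum())
        if n:
            rejected[rule] = n
            log.warning("rejected %d row(s): %s", n, rule)
        bad |= mask
    out = df.loc[~bad].reset_index(drop=True)
    out["BP"] = out["BP"].astype(np.int64)
    return out, rejected


def read_sumstats(
    path,
    column_map: dict[str, str] | None = None,
    trait: str = "",
    sep: str = "\t",
) -> SumStatTable:
    """Read a tab-delimited summary-statistics file into a validated table.

    ``column_map`` maps file headers onto the canonical names (map a header
    to ``"OR"`` to have it log-converted into ``BETA``).  Rows violating the
    record invariants are skipped with a logged count; a duplicated SNP id is
    a fatal error, because the rsID is the join key for everything downstream.
    """
    raw = pd.read_csv(path, sep=sep, dtype={0: str})
    df = _coerce_canonical(raw, column_map)
    df["SNP"] = df["SNP"].astype(str)
    df["CHR"] = df["CHR"].astype(str)
    df, rejected = validate_records(df)
    dup = df["SNP"][df["SNP"].duplicated()]
    if len(dup):
        raise SumStatsError(f"duplicated SNP id(s): {', '.join(sorted(set(dup))[:5])}")
    df = df[list(CANONICAL_COLUMNS)]
    return SumStatTable(df, trait=trait, provenance=str(path), rejected=rejected)


def write_sumstats(table: SumStatTable, path) -> None:
    """Write a table back to the canonical tab-delimited dialect."""
    table.df.to_csv(path, sep="\t", index=False)


def is_ambiguous(ea: pd.Series, oa: pd.Series) -> pd.Series:
    """True for strand-ambiguous (A/T or C/G) allele pairs."""
    pair_at = (ea == "A") & (oa == "T") | (ea == "T") & (oa == "A")
    pair_cg = (ea == "C") & (oa == "G") | (ea == "G") & (oa == "C")
    return pair_at | pair_cg


def harmonize(
    a: SumStatTable,
    b: SumStatTable,
    maf_min: float = 0.01,
    drop_ambiguous: bool = True,
) -> PairedSumStats:
    """Join two traits' tables by SNP id onto trait A's effect-allele frame.

    Where B's effect allele equals A's other allele, B's beta sign is flipped
    and its frequency replaced by 1-EAF.  Allele pairs that neither match nor
    swap are dropped (counted as ``incompatible_removed``).  With
    ``drop_ambiguous``, A/T and C/G SNPs are removed; SNPs with
    ``min(EAF, 1-EAF) <= maf_min`` on either trait are removed (strict "<="
    exclusion, i.e. a MAF of exactly ``maf_min`` is excluded).
    """
    m = a.df.merge(b.df, on="SNP", suffixes=("_A", "_B"), how="inner")
    counts = {"joined": len(m)}

    same = (m["EA_B"] == m["EA_A"]) & (m["OA_B"] == m["OA_A"])
    swap = (m["EA_B"] == m["OA_A"]) & (m["OA_B"] == m["EA_A"])
    incompatible = ~(same | swap)
    counts["incompatible_removed"] = int(incompatible.sum())
    m = m.loc[~incompatible].copy()
    flipped = (m["EA_B"] == m["OA_A"]).to_numpy()
    m["BETA_B"] = np.where(flipped, -m["BETA_B"], m["BETA_B"])
    m["EAF_B"] = np.where(flipped, 1.0 - m["EAF_B"], m["EAF_B"])
    m["FLIPPED"] = flipped

    if drop_ambiguous:
        amb = is_ambiguous(m["EA_A"], m["OA_A"])
        counts["ambiguous_removed"] = int(amb.sum())
        m = m.loc[~amb]
    else:
        counts["ambiguous_removed"] = 0

    maf = np.minimum.reduce(
        [m["EAF_A"], 1.0 - m["EAF_A"], m["EAF_B"], 1.0 - m["EAF_B"]]
    )
    low = maf <= maf_min
    counts["maf_removed"] = int(low.sum())
    m = m.loc[~low]

    out = pd.DataFrame(
        {
            "SNP": m["SNP"],
            "CHR": m["CHR_A"],
            "BP": m["BP_A"],
            "EA": m["EA_A"],
            "OA": m["OA_A"],
            "EAF_A": m["EAF_A"],
            "BETA_A": m["BETA_A"],
            "SE_A": m["SE_A"],
            "P_A": m["P_A"],
            "EAF_B": m["EAF_B"],
            "BETA_B": m["BETA_B"],
            "SE_B": m["SE_B"],
            "P_B": m["P_B"],
            "FLIPPED": m["FLIPPED"],
        }
    ).reset_index(drop=True)
    counts["retained"] = len(out)
    log.info(
        "harmonized %s vs %s: joined=%d incompatible=%d ambiguous=%d maf=%d retained=%d",
        a.trait or "A", b.trait or "B",
        counts["joined"], counts["incompatible_removed"],
        counts["ambiguous_removed"], counts["maf_removed"], counts["retained"],
    )
    return PairedSumStats(out, trait_a=a.trait, trait_b=b.trait, counts=counts)
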