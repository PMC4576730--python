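import numpy as np
import pandas as pd
import pytest

from crosstrait.sumstats import SumStatTable


def make_table(rows, trait="T"):
    """Build a SumStatTable from (snp, chr, bp, ea, oa, eaf, beta, se, p) tuples."""
    df = pd.DataFrame(
        rows, columns=["SNP", "CHR", "BP", "EA", "OA", "EAF", "BETA", "SE", "P"]
    )
    df["CHR"] = df["CHR"].astype(str)
    df["N"] = np.nan
    return SumStatTable(df, trait=trait)


@pytest.fixture
def toy_pair():
    """Ten SNPs in both traits: 2 below the MAF cutoff, 1 ambiguous, 1 allele-swapped."""
    a_rows = []
    b_rows = []
    for i in range(10):
        snp = f"rs{i}"
        eaf = 0.005 if i in (0, 1) else 0.3
        ea, oa = ("A", "T") if i == 2 else ("A", "G")
        a_rows.append((snp, "1", 1000 + i, ea, oa, eaf, 0.1, 0.05, 0.5))
        if i == 3:  # swapped allele frame in B
            b_rows.append((snp, "1", 1000 + i, oa, ea, 1 - eaf, -0.2, 0.05, 0.5))
        else:
            b_rows.append((snp, "1", 1000 + i, ea, oa, eaf, 0.2, 0.05, 0.5))
    return make_table(a_rows, "A"), make_table(b_rows, "B")
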