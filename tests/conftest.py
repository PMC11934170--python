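import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from mitomr.gwas_io import SummaryStatsTable

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_table(trait_id, role, rows, category=None):
    """Build a SummaryStatsTable from (rsid, ea, oa, eaf, beta, se, pval, n)
    tuples; chrom/pos are synthesized."""
    df = pd.DataFrame(
        rows,
        columns=["rsid", "effect_allele", "other_allele", "eaf", "beta",
                 "se", "pval", "n"],
    )
    df["chrom"] = "1"
    df["pos"] = 1_000_000 + 1_000 * np.arange(len(df))
    return SummaryStatsTable(trait_id, role, df, category)


def p_of(beta, se):
    from scipy import stats

    return float(2 * stats.norm.sf(abs(beta / se)))


@pytest.fixture
def exposure_pair():
    """A matched exposure/outcome table pair over three SNPs."""
    exp = make_table(
        "PROT", "exposure",
        [("rs1", "A", "G", 0.3, 0.10, 0.01, p_of(0.10, 0.01), 50_000),
         ("rs2", "T", "C", 0.2, 0.08, 0.01, p_of(0.08, 0.01), 50_000),
         ("rs3", "C", "A", 0.4, -0.12, 0.01, p_of(-0.12, 0.01), 50_000)],
    )
    out = make_table(
        "OUT", "outcome",
        [("rs1", "A", "G", 0.3, 0.02, 0.005, p_of(0.02, 0.005), 200_000),
         ("rs2", "T", "C", 0.2, 0.016, 0.005, p_of(0.016, 0.005), 200_000),
         ("rs3", "C", "A", 0.4, -0.024, 0.005, p_of(-0.024, 0.005), 200_000)],
        category="creatinine",
    )
    return exp, out
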