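import numpy as np
import pandas as pd
import pytest

from mrscan.sumstats import SummaryStatsTable


@pytest.fixture
def rng():
    return np.random.default_rng(20260928)


def pairs_frame(bx, sx, by, sy, rsids=None):
    """Build an estimator-ready harmonized-pairs frame from raw arrays."""
    bx = np.asarray(bx, dtype=float)
    k = bx.size
    return pd.DataFrame(
        {
            "rsid": rsids if rsids is not None else [f"rs{i}" for i in range(k)],
            "beta_exposure": bx,
            "se_exposure": np.asarray(sx, dtype=float),
            "beta_outcome": np.asarray(by, dtype=float),
            "se_outcome": np.asarray(sy, dtype=float),
        }
    )


def merge_two_sample(exposure: SummaryStatsTable, outcome: SummaryStatsTable):
    """Row-align clean (identically coded) exposure/outcome tables into a
    pairs frame, bypassing allele harmonization.  Only valid when both tables
    use the same effect allele per SNP, as the simulator guarantees before
    corruption."""
    ex = exposure.df.set_index("rsid")
    out = outcome.df.set_index("rsid")
    common = ex.index.intersection(out.index)
    return pd.DataFrame(
        {
            "rsid": common,
            "beta_exposure": ex.loc[common, "beta"].to_numpy(),
            "se_exposure": ex.loc[common, "se"].to_numpy(),
            "beta_outcome": out.loc[common, "beta"].to_numpy(),
            "se_outcome": out.loc[common, "se"].to_numpy(),
        }
    ).reset_index(drop=True)
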