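import numpy as np
import pandas as pd
import pytest

from compmr import OutcomeSpec, SimConfig, simulate_cohort
from compmr.sumstats import COLUMNS, SumStats


def make_sumstats(
    n=20,
    seed=0,
    chrom="1",
    spacing=1_000_000,
    trait="trait",
    sex_group="combined",
    scale="standardized",
    beta=None,
    se=None,
    maf=None,
    pos=None,
):
    """Small synthetic summary-statistics table with self-consistent p-values."""
    rng = np.random.default_rng(seed)
    beta = rng.normal(0, 0.05, n) if beta is None else np.asarray(beta, float)
    n = len(beta)
    se = np.full(n, 0.02) if se is None else np.asarray(se, float)
    maf = rng.uniform(0.05, 0.5, n) if maf is None else np.asarray(maf, float)
    pos = np.arange(1, n + 1) * spacing if pos is None else np.asarray(pos)
    from scipy import stats

    pval = 2 * stats.norm.sf(np.abs(beta / se))
    table = pd.DataFrame(
        {
            "variant": [f"rs{i + 1}" for i in range(n)],
            "chrom": chrom,
            "pos": pos,
            "ref": "A",
            "alt": "G",
            "minor_AF": maf,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": 1000,
        }
    )[COLUMNS]
    return SumStats(table, trait=trait, sex_group=sex_group, scale=scale)


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 4-factor cohort with a binary disease, reused across tests."""
    cfg = SimConfig(
        n_individuals=1500,
        n_snps=80,
        seed=11,
        outcome_specs=[
            OutcomeSpec("disease", "binary", [0.0, 0.4, 0.0, 0.0], prevalence=0.2),
            OutcomeSpec("marker", "continuous", [0.3, 0.0, 0.0, 0.0]),
        ],
    )
    return simulate_cohort(cfg)
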