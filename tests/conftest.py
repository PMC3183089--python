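import numpy as np
import pandas as pd
import pytest

from twinmeth.discovery import MVPCallSet
from twinmeth.synthetic import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def effect_cohort():
    """Small cohort with 3–6% effects at 40 truth probes, all cohorts present."""
    cfg = SimConfig(
        n_probes=1500,
        n_true_mvps=40,
        effect_range=(0.03, 0.06),
        missing_rate=0.002,
        seed=20_211,
    )
    return cfg, *simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """Complete-null cohort (no injected effects), no missingness."""
    cfg = SimConfig(
        n_probes=1500,
        n_true_mvps=0,
        missing_rate=0.0,
        frac_sex_probes=0.0,
        seed=977,
    )
    return cfg, *simulate_cohort(cfg)


def make_call_set(probe_ids, directions, alpha=0.01):
    """Assemble a minimal valid MVPCallSet for downstream-stage tests."""
    directions = np.asarray(directions)
    return MVPCallSet(
        calls=pd.DataFrame(
            {
                "probe_id": probe_ids,
                "p_value": np.full(len(probe_ids), alpha / 10),
                "direction": directions,
                "mean_diff": np.where(directions == "hyper", 0.03, -0.03),
            }
        ),
        alpha=alpha,
        n_pairs=15,
        n_probes_tested=len(probe_ids),
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
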