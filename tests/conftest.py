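import numpy as np
import pytest

from allrisk import SimConfig, SurvivalOutcome, simulate_cohort
from allrisk.cohort import derive_endpoints
from allrisk.transforms import COVARIATE_NAMES, encode_cohort


def make_outcomes(times, events, endpoint="RFS"):
    return [SurvivalOutcome(float(t), int(e), endpoint) for t, e in zip(times, events)]


@pytest.fixture(scope="session")
def sim_cohort():
    """A moderate synthetic cohort shared across test modules."""
    return simulate_cohort(SimConfig(n=3000, seed=42))


@pytest.fixture(scope="session")
def sim_design(sim_cohort):
    """(records, design matrix, RFS outcomes) for the full covariate set."""
    recs = [p.record for p in sim_cohort]
    kept, outcomes, _ = derive_endpoints(recs, "RFS")
    kept2, X, _ = encode_cohort(kept, required=COVARIATE_NAMES)
    assert len(kept2) == len(kept)  # no missingness by default
    return kept2, X, outcomes


def survival_data(rng, n, beta, censor_scale=2.5, X=None):
    """Simple PH data generator for unit tests (continuous times, no ties)."""
    beta = np.asarray(beta, dtype=float)
    if X is None:
        X = rng.normal(size=(n, len(beta)))
    t = rng.exponential(np.exp(-(X @ beta)))
    c = rng.exponential(censor_scale, size=n)
    obs = np.minimum(t, c)
    ev = (t <= c).astype(int)
    return X, make_outcomes(obs, ev)
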