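import warnings

import numpy as np
import pandas as pd
import pytest

from cshazard.cohort import Cohort
from cshazard.simulate import GeneratorSpec, simulate_current_status

warnings.filterwarnings("ignore", category=FutureWarning, module="arviz")


@pytest.fixture(scope="session")
def exp_cohort():
    """n=2000 cohort from a constant hazard 0.02, ages uniform on [18, 85]."""
    from cshazard.hazards import ParametricHazard
    spec = GeneratorSpec(n=2000, seed=42,
                         baseline=ParametricHazard("exponential", {"rate": 0.02}))
    return simulate_current_status(spec)


@pytest.fixture(scope="session")
def default_cohort():
    """n=2000 cohort from the default log-normal onset-age baseline."""
    return simulate_current_status(GeneratorSpec(n=2000, seed=7))


def make_cohort(ages, events, **covs):
    """Tiny cohort straight from arrays (helper for oracle tests)."""
    df = pd.DataFrame({"observation_age": np.asarray(ages, dtype=float),
                       "event": np.asarray(events, dtype=bool)})
    for name, vals in covs.items():
        df[name] = np.asarray(vals, dtype=float)
    return Cohort(df, list(covs))
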