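"""Shared fixtures: the default acquisition schedule and a noiseless
synthetic electroporation experiment with known ground truth.

The noiseless dataset (and its fitted results) is session-scoped because
several test modules check different facets of the same study conditions:
saturated wall coefficient 0.008 um^2/s, onset delay 60 s, ramp 300 s,
tissue coefficient 30 um^2/s.
"""

import numpy as np
import pytest

from epperm.fitting import FitContext, GAConfig
from epperm.model import MicrovascularPermeabilityModel
from epperm.pk import PKParams, fit_pk
from epperm.schedule import make_schedule
from epperm.synthetic import default_truth, simulate_trace
from epperm.trace import normalize_trace, subtract_background

# ground truth of the shared synthetic experiment
TRUE_D_SAT = 0.008
TRUE_DELAY = 60.0
TRUE_RAMP = 300.0
TRUE_D_TISS = 30.0

#: Reduced GA budget used throughout the suite: enough, together with the
#: Nelder-Mead polish, to localize the optimum on these traces.
FAST_GA = dict(population=12, max_generations=8, polish_maxiter=200)


@pytest.fixture(scope="session")
def schedule():
    return make_schedule()


@pytest.fixture(scope="session")
def noiseless_ds(schedule):
    truth = default_truth(
        schedule, d_sat=TRUE_D_SAT, delay=TRUE_DELAY, ramp=TRUE_RAMP, d_tiss=TRUE_D_TISS, noise_cv=0.0
    )
    return simulate_trace(schedule, truth)


@pytest.fixture(scope="session")
def norm_trace(noiseless_ds):
    return normalize_trace(subtract_background(noiseless_ds.trace))


@pytest.fixture(scope="session")
def fitted_pk(norm_trace, schedule):
    t2, y2 = norm_trace.phase("II")
    params, _ = fit_pk(t2, y2, schedule.t_fd)
    return params


@pytest.fixture(scope="session")
def true_context(schedule):
    """Fit context carrying the generator's exact pharmacokinetics."""
    return FitContext(pk=PKParams(), t_fd=schedule.t_fd, t_ep=schedule.t_ep, d_tiss=TRUE_D_TISS)


@pytest.fixture(scope="session")
def noiseless_results(noiseless_ds):
    """Full two-stage fit of the noiseless trace (shared; ~15 s)."""
    model = MicrovascularPermeabilityModel(noiseless_ds.trace, d_tiss=TRUE_D_TISS)
    return model.fit(GAConfig(seed=3, **FAST_GA))
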