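import numpy as np
import pytest

from stratddm.ddm import DiffusionSpec, simulate_ddm_paths

#: the anchor diffusion spec used throughout (group-mean threshold, start
#: bias and retrieval drift of the default generator)
ANCHOR_SPEC = DiffusionSpec(v=1.49, a=3.91, w=0.54)

EM_DT = 2e-4
EM_N = 30000
EM_MAX_T = 6.0


@pytest.fixture(scope="session")
def em_reference():
    """Brute-force Euler-Maruyama reference sample for the anchor spec
    (shared across DDM unit tests and the numerics acceptance test)."""
    codes, times = simulate_ddm_paths(ANCHOR_SPEC, EM_DT, EM_MAX_T, EM_N, seed=20)
    return {"spec": ANCHOR_SPEC, "dt": EM_DT, "max_time": EM_MAX_T,
            "n": EM_N, "codes": codes, "times": times}


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort reused by IO / measures tests."""
    from stratddm.simulate import simulate_cohort

    return simulate_cohort(n_persons=6, n_sessions=2, trials_per_session=30,
                           seed=123)
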