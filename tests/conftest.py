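import numpy as np
import pytest

import ternthresh as tt


@pytest.fixture
def exp1_grid():
    return np.linspace(-200.0, 200.0, 25)


@pytest.fixture
def small_design():
    """Exp-1 geometry scaled down: 25 d values, 40 trials per d per
    condition, 2 sessions of 10 alternating blocks."""
    return tt.DesignSpec(
        d_values=tuple(np.linspace(-200.0, 200.0, 25)),
        trials_per_d=40,
        conditions=("intermodal", "intramodal"),
        sessions=2,
        blocks_per_session=10,
        condition_layout="alternating",
    )


@pytest.fixture
def single_cond_design():
    """One-condition Exp-1 grid with 400 trials per d."""
    return tt.DesignSpec(
        d_values=tuple(np.linspace(-200.0, 200.0, 25)),
        trials_per_d=400,
        conditions=("only",),
        sessions=20,
        blocks_per_session=20,
    )


def counts_from_probs(d_values, p_xy, p_si, p_yx, n, rng):
    """Multinomial counts cell by cell — trial-free generation used when a
    test only needs the count marginals of the observer model."""
    draws = np.array([rng.multinomial(n, p) for p in np.stack([p_xy, p_si, p_yx], 1)])
    return tt.ConditionCounts(
        condition="sim",
        d_values=d_values,
        n_xy=draws[:, 0],
        n_si=draws[:, 1],
        n_yx=draws[:, 2],
    )
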