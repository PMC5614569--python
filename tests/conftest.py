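import logging

import numpy as np
import pytest

from dsaflow import build_time_grid, compute_amtt, default_schedule
from dsaflow.phantom import generate_phantom, standard_phantom

logging.getLogger("dsaflow").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_grid():
    return build_time_grid(default_schedule())


@pytest.fixture(scope="session")
def easy_phantom():
    """Noiseless disjoint-compartment phantom with capillary FWHM 5.0 s."""
    series, truth = generate_phantom(standard_phantom("easy", seed=11))
    return series, truth


@pytest.fixture(scope="session")
def noisy_mc():
    """100 seeded 5%-noise realizations of the easy phantom, run through the
    decomposition pipeline once and shared by the recovery/accuracy tests.

    Returns a list of (truth, AMTTResult) pairs. Registration is skipped:
    these phantoms are motionless, and motion correction has its own
    dedicated phantom and tests.
    """
    out = []
    for seed in range(100):
        series, truth = generate_phantom(
            standard_phantom("easy", seed=seed, noise_sigma=0.05))
        res = compute_amtt(series, seed=seed, register=False)
        out.append((truth, res))
    return out


def matched_abs_corr(courses, truth_courses):
    """For each true compartment course, the best |Pearson r| over the
    recovered component time courses."""
    best = {}
    for phase, tc in truth_courses.items():
        best[phase] = max(
            abs(np.corrcoef(courses[k], tc)[0, 1]) for k in range(courses.shape[0]))
    return best
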