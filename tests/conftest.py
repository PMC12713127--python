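"""Shared fixtures: synthetic ground-truth scenarios reused across tests.

Heavy Monte-Carlo fixtures are session-scoped so the planted-recovery run
and the 20-seed attenuation experiment are computed exactly once.
"""

import pytest

from spatiodyn import QPPConfig, default_atlas, detect_qpp, generate_background, \
    plant_qpp, zscore
from spatiodyn.experiments import (attenuation_experiment, random_template,
                                   score_recovery)

ATTENUATION_SEEDS = tuple(range(20))


@pytest.fixture(scope="session")
def atlas():
    return default_atlas()


@pytest.fixture(scope="session")
def planted_recovery():
    """Detection on the standard planted scenario: 105 ICNs, T=800, W=8,
    ~30 occurrences, background noise SD 0.2, amplitude 1."""
    template = random_template(105, 8, seed=11)
    bg = generate_background(105, 800, 3.0, global_signal_weight=0.0,
                             noise_sd=0.2, seed=1)
    ts, truth = plant_qpp(bg, template, mean_interval_tr=26, jitter_tr=3,
                          amplitude_map=1.0, seed=2)
    ts = zscore(ts)
    detected = detect_qpp(ts, QPPConfig(seed=3))
    return {"truth": truth, "detected": detected, "series": ts,
            "score": score_recovery(truth, detected)}


@pytest.fixture(scope="session")
def attenuation_runs():
    """The 50%-attenuation experiment over 20 fixed seeds."""
    return [attenuation_experiment(s) for s in ATTENUATION_SEEDS]
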