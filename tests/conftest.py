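from dataclasses import replace

import numpy as np
import pytest

from pamffr.cohort import DEFAULT_EFFECTS, GazeCondition, reference_profile, sample_cohort
from pamffr.stimgen import StimSpec


@pytest.fixture(scope="session")
def quiet_structure():
    """Generator defaults with every nuisance source switched off:
    no sweep noise, no between-block muscle state — fully deterministic."""
    return replace(DEFAULT_EFFECTS, noise_sd=0.0, pam_state_sd=0.0, pam_shape_sd=0.0)


@pytest.fixture()
def ref_profile():
    return reference_profile(noise_sd=0.0)


@pytest.fixture()
def gaze5():
    return GazeCondition(5)


@pytest.fixture()
def stim100():
    return StimSpec(f0=100.0)


@pytest.fixture(scope="session")
def seed_summary():
    """Pipeline statistics on the 25-seed default-cohort protocol.

    Shared by the acceptance tests; computed once per session.
    """
    from pamffr.pipeline import analyze_cohort

    keys = ("mean_pam_p2p_g5", "r_pam_ffr_g5", "model_mean_r", "model_mean_r2",
            "ratio_mastoid", "ratio_c7", "r_music_ffr", "partial_pam_ffr",
            "partial_music_ffr", "sobel_z", "max_vif", "quad_p_mastoid",
            "quad_p_c7", "lin_p_c7")
    acc = {k: [] for k in keys}
    for seed in range(1, 26):
        res = analyze_cohort(seed, n_boot=200)
        for k in keys:
            acc[k].append(res[k])
    return {k: np.asarray(v) for k, v in acc.items()}
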