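import numpy as np
import pytest

import physioaffect as pa


@pytest.fixture(scope="session")
def default_design():
    return pa.StudyDesign(seed=42)


@pytest.fixture(scope="session")
def default_timeline(default_design):
    return pa.generate_timeline(default_design)


@pytest.fixture(scope="session")
def small_cohort():
    """Scaled 12-subject cohort with extracted raw and reduced features."""
    design = pa.scaled_design(n_subjects=12, seed=2024)
    profiles, timeline, recordings = pa.simulate_cohort(design)
    matrix = pa.build_feature_matrix(recordings, timeline)
    reducer = pa.CorrelationThresholdReducer().fit(matrix)
    return {
        "design": design,
        "profiles": profiles,
        "timeline": timeline,
        "recordings": recordings,
        "matrix": matrix,
        "reducer": reducer,
        "reduced": reducer.transform(matrix),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(7)


def quiet_params(**overrides):
    """EffectParams with every noise source silenced (degenerate diagnostics)."""
    defaults = dict(
        tonic_between_subject_sd=0.0,
        scr_amplitude_cv=0.0,
        subject_reactivity_sd=0.0,
        block_reactivity_sd=0.0,
        scl_drift_amplitude=0.0,
        noise_sd={"scl": 0.0, "bvp": 0.0},
        powerline_amplitude=0.0,
        emg_resting_jitter_sd=0.0,
        nsscr_rate_per_min=0.0,
        heart_period_drift_sd_ms=0.0,
    )
    defaults.update(overrides)
    return pa.EffectParams(**defaults)
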