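"""Shared fixtures: small synthetic sessions and segmented contact sets.

Everything is generated programmatically at fixed seeds; session-scoped
fixtures are reused across test modules to keep the suite fast.
"""

from __future__ import annotations

import numpy as np
import pytest

from grfest import features, pipeline, synth


@pytest.fixture(scope="session")
def profile() -> synth.ParticipantProfile:
    return synth.ParticipantProfile(
        participant_id="P_demo",
        mass=70.0,
        easy_speed=11.0,
        insole_length=270.0,
        footstrike=0.2,
        stride_cv=0.03,
        rng_seed=123,
    )


@pytest.fixture(scope="session")
def geometry() -> synth.InsoleGeometry:
    return synth.default_geometry(270.0)


@pytest.fixture(scope="session")
def condition() -> synth.Condition:
    return synth.Condition(speed=11.0, gradient=1.0, duration=30.0)


@pytest.fixture(scope="session")
def session(profile, condition) -> synth.SensorSession:
    return synth.generate_session(profile, condition, seed=11)


@pytest.fixture(scope="session")
def clean_config() -> synth.SessionConfig:
    """Noise-free generator settings (flight noise kept so detection is exercised)."""
    return synth.SessionConfig(
        grf_noise_sd_bw=0.0, fsr_noise_sd=0.0, accel_noise_sd_g=0.0, accel_wobble_g=0.0
    )


@pytest.fixture(scope="session")
def clean_session(profile, condition, clean_config) -> synth.SensorSession:
    return synth.generate_session(profile, condition, seed=17, config=clean_config)


@pytest.fixture(scope="session")
def contacts(session):
    segged, result = pipeline.session_to_contacts(session)
    assert result.synchronized
    return segged


@pytest.fixture(scope="session")
def small_dataset():
    """3 participants x 1 flat condition x 12 contacts: enough for structural
    LOSO and small training runs."""
    cohort = synth.generate_cohort(3, seed=5)
    out = []
    for p in cohort:
        cond = synth.Condition(p.easy_speed, 1.0, 30.0)
        sess = synth.generate_session(p, cond, seed=p.rng_seed, n_contacts=26)
        segged, _ = pipeline.session_to_contacts(sess)
        out.extend(segged[:12])
    return out


@pytest.fixture(scope="session")
def small_features(small_dataset):
    fm = features.build_features(small_dataset)
    targets = features.targets_from_contacts(small_dataset, "grf_v")
    return fm, targets


@pytest.fixture(scope="session")
def overfit_contacts(profile, clean_config):
    """20 noise-free contacts from one runner, for capacity/overfit checks."""
    cond = synth.Condition(11.0, 1.0, 30.0)
    sess = synth.generate_session(profile, cond, seed=29, config=clean_config, n_contacts=34)
    segged, _ = pipeline.session_to_contacts(sess)
    assert len(segged) >= 20
    return segged[:20]
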