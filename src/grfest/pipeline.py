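"""End-to-end glue: raw session -> synchronized, segmented contacts.

These helpers chain the per-module operations in the documented order
(filter -> detect -> synchronize -> segment) and are what the CLI, the test
suite and the acceptance analyses drive.
"""

from __future__ import annotations

import logging

from grfest import preprocess, sync, synth
from grfest.preprocess import FootContact

logger = logging.getLogger(__name__)


def session_to_contacts(
    session: synth.SensorSession,
    threshold: float = preprocess.DEFAULT_THRESHOLD_N,
    force_cutoff: float = preprocess.DEFAULT_FORCE_CUTOFF_HZ,
    imu_cutoff: float = preprocess.DEFAULT_IMU_CUTOFF_HZ,
) -> tuple[list[FootContact], sync.SyncResult]:
    """Detect, synchronize and segment one session's contacts."""
    f_events = preprocess.force_events(session, threshold=threshold, cutoff=force_cutoff)
    p_bursts = preprocess.pressure_bursts(session)
    p_events = preprocess.pressure_events(session)
    i_events = preprocess.imu_events(session, cutoff=imu_cutoff)
    result = sync.synchronize_session(f_events, p_events, i_events)
    if not result.synchronized:
        logger.warning(
            "session %s/%s unsynchronizable (r_pressure=%.3f, r_imu=%.3f)",
            session.profile.participant_id, session.condition.condition_id,
            result.pressure_alignment.r, result.imu_alignment.r,
        )
        return [], result
    contacts = preprocess.segment_contacts(
        session, result.triples, f_events, p_bursts, i_events,
        force_cutoff=force_cutoff, imu_cutoff=imu_cutoff,
    )
    return contacts, result


def build_synthetic_dataset(
    n_participants: int = 10,
    contacts_per_condition: int = 8,
    seed: int = 42,
    session_config: synth.SessionConfig | None = None,
) -> list[FootContact]:
    """A compact multi-condition study: each participant runs a flat (+1%),
    uphill (+6%, 10% slower) and downhill (-4%, 10% faster) stage.

    Sessions are generated with a few spare contacts so that device-window
    clipping still leaves ``contacts_per_condition`` usable contacts each.
    """
    cohort = synth.generate_cohort(n_participants, seed=seed)
    contacts: list[FootContact] = []
    for profile in cohort:
        conditions = [
            synth.Condition(profile.easy_speed, 1.0, 30.0),
            synth.Condition(0.9 * profile.easy_speed, 6.0, 30.0),
            synth.Condition(1.1 * profile.easy_speed, -4.0, 30.0),
        ]
        for j, cond in enumerate(conditions):
            session = synth.generate_session(
                profile, cond, seed=profile.rng_seed + j,
                config=session_config, n_contacts=contacts_per_condition + 14,
            )
            segged, _ = session_to_contacts(session)
            contacts.extend(segged[:contacts_per_condition])
    return contacts
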