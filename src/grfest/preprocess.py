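"""Filtering, contact detection, upsampling, CoP computation and segmentation.

The raw-to-contact pipeline is: low-pass the continuous treadmill force
(4th-order zero-phase Butterworth, 15 Hz), detect stance with a 40 N
threshold, upsample the stance-only 50 Hz pressure log back to 1,000 Hz with
a quadratic interpolator, compute the centre of pressure from the 16 FSR
channels and the insole geometry, and time-normalize every per-contact
signal to 400 samples.  Per-contact force traces are filtered at 15 Hz and
accelerometer traces at 10 Hz; the interpolated pressure traces are left
unfiltered (the 20 ms averaging windows already band-limit them).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, signal

from grfest.synth import (
    FORCE_FS,
    InsoleGeometry,
    SensorSession,
)

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLD_N = 40.0
DEFAULT_FORCE_CUTOFF_HZ = 15.0
DEFAULT_IMU_CUTOFF_HZ = 10.0
DEFAULT_MIN_CONTACT_S = 0.08
NORMALIZED_LENGTH = 400


@dataclass(frozen=True)
class ContactEvents:
    """Ordered (initial_contact, toe_off) sample-index pairs on one stream's
    clock; intervals are half-open [ic, to)."""

    events: tuple[tuple[int, int], ...]
    fs: float

    def __post_init__(self) -> None:
        prev_end = -1
        for ic, to in self.events:
            if not ic < to:
                raise ValueError("each event needs ic < to")
            if ic < prev_end:
                raise ValueError("events must be strictly ordered and non-overlapping")
            prev_end = to

    def __len__(self) -> int:
        return len(self.events)

    @property
    def ic_times(self) -> np.ndarray:
        """Initial-contact times in seconds."""
        return np.asarray([ic for ic, _ in self.events], dtype=float) / self.fs


@dataclass
class FootContact:
    """One stance phase with all channels time-normalized to 400 samples."""

    force_v: np.ndarray  # (400,) N
    force_ap: np.ndarray  # (400,) N
    pressure: np.ndarray  # (400, 16) raw FSR units
    cop_x: np.ndarray  # (400,) mm
    cop_y: np.ndarray  # (400,) mm
    accel: np.ndarray  # (400, 3) g
    gct: float  # s, measured before normalization
    mass: float  # kg
    speed: float  # km/h
    gradient: float  # %
    insole_length: float  # mm
    participant_id: str
    condition_id: str

    def __post_init__(self) -> None:
        for name in ("force_v", "force_ap", "cop_x", "cop_y"):
            if len(getattr(self, name)) != NORMALIZED_LENGTH:
                raise ValueError(f"{name} must have {NORMALIZED_LENGTH} samples")
        if self.pressure.shape != (NORMALIZED_LENGTH, 16):
            raise ValueError("pressure must be (400, 16)")
        if self.accel.shape != (NORMALIZED_LENGTH, 3):
            raise ValueError("accel must be (400, 3)")
        if not 0.0 < self.gct <= 0.4:
            raise ValueError("gct must lie in (0, 0.4] s")


def butterworth_lowpass(
    x: np.ndarray, fs: float, cutoff: float, order: int = 4, axis: int = 0
) -> np.ndarray:
    """Zero-phase (forward-backward) low-pass Butterworth filter.

    The forward-backward pass squares the magnitude response, so a
    sinusoid at the cutoff frequency comes out at half amplitude.
    """
    x = np.asarray(x, dtype=float)
    if not 0.0 < cutoff < fs / 2.0:
        raise ValueError(f"cutoff must lie in (0, fs/2), got {cutoff} at fs={fs}")
    sos = signal.butter(order, cutoff, btype="low", fs=fs, output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.shape[axis] <= padlen:
        raise ValueError(f"signal too short for filtering (need > {padlen} samples)")
    return signal.sosfiltfilt(sos, x, axis=axis)


def detect_contacts(
    force_v: np.ndarray,
    fs: float,
    threshold: float = DEFAULT_THRESHOLD_N,
    min_duration_s: float = DEFAULT_MIN_CONTACT_S,
) -> ContactEvents:
    """Threshold-based stance detection on a (filtered) vertical force trace.

    A contact is a maximal run of samples strictly above ``threshold``;
    ic is the first sample of the run and to the index one past the last
    (half-open).  Runs shorter than ``min_duration_s`` are discarded as noise.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    force_v = np.asarray(force_v, dtype=float)
    above = force_v > threshold
    if not above.any():
        return ContactEvents(events=(), fs=fs)
    padded = np.diff(np.concatenate([[0], above.astype(np.int8), [0]]))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)
    min_len = int(round(min_duration_s * fs))
    events = tuple(
        (int(s), int(e)) for s, e in zip(starts, ends) if e - s >= min_len
    )
    return ContactEvents(events=events, fs=fs)


def upsample_quadratic(
    times: np.ndarray, values: np.ndarray, target_fs: float = FORCE_FS
) -> tuple[np.ndarray, np.ndarray]:
    """Reconstruct a 1,000 Hz trace from sparse (50 Hz) logged samples with a
    piecewise-quadratic interpolant through the knots.

    The output grid spans the knot range at 1/target_fs spacing.  With fewer
    than 3 knots a quadratic is underdetermined; falls back to linear with a
    logged warning.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 2:
        raise ValueError("need at least 2 samples to interpolate")
    if len(times) < 3:
        logger.warning("fewer than 3 samples: falling back to linear interpolation")
        kind = "linear"
    else:
        kind = "quadratic"
    f = interpolate.interp1d(times, values, kind=kind, axis=0)
    n_out = int(np.floor((times[-1] - times[0]) * target_fs)) + 1
    t_out = times[0] + np.arange(n_out) / target_fs
    return t_out, f(t_out)


def time_normalize(trace: np.ndarray, length: int = NORMALIZED_LENGTH) -> np.ndarray:
    """Linearly interpolate a trace onto ``length`` points uniformly spanning
    its full extent; the first and last samples are preserved exactly.

    Works on (n,) or (n, channels) arrays along axis 0.
    """
    trace = np.asarray(trace, dtype=float)
    n = trace.shape[0]
    if n < 2:
        raise ValueError("need at least 2 samples to time-normalize")
    src = np.arange(n, dtype=float)
    dst = np.linspace(0.0, n - 1.0, length)
    if trace.ndim == 1:
        return np.interp(dst, src, trace)
    return np.column_stack([np.interp(dst, src, trace[:, k]) for k in range(trace.shape[1])])


def compute_cop(
    pressure_sample: np.ndarray,
    geometry: InsoleGeometry,
    previous: tuple[float, float] | None = None,
) -> tuple[float, float]:
    """Weighted-average centre of pressure for one 16-channel sample.

    cop = sum_i w_i * coord_i / sum_i w_i with w_i the raw channel value.
    With zero total pressure, returns the previous valid CoP within the
    contact if given, else the geometric centroid of the sensor grid.
    """
    w = np.asarray(pressure_sample, dtype=float)
    if w.shape != (geometry.n_sensors,):
        raise ValueError(f"expected {geometry.n_sensors} channel values")
    if np.any(w < 0):
        raise ValueError("pressure values must be non-negative")
    total = w.sum()
    if total == 0.0:
        if previous is not None:
            return previous
        cx, cy = geometry.centroid
        return float(cx), float(cy)
    cop = w @ geometry.sensor_coords / total
    return float(cop[0]), float(cop[1])


def compute_cop_trace(pressure: np.ndarray, geometry: InsoleGeometry) -> np.ndarray:
    """Per-sample CoP over a contact, carrying the last valid CoP forward
    through zero-pressure samples."""
    pressure = np.asarray(pressure, dtype=float)
    out = np.empty((pressure.shape[0], 2))
    prev: tuple[float, float] | None = None
    for i in range(pressure.shape[0]):
        prev = compute_cop(pressure[i], geometry, previous=prev)
        out[i] = prev
    return out


# --------------------------------------------------------------------------
# per-device event derivation
# --------------------------------------------------------------------------


def force_events(
    session: SensorSession,
    threshold: float = DEFAULT_THRESHOLD_N,
    cutoff: float = DEFAULT_FORCE_CUTOFF_HZ,
) -> ContactEvents:
    """Contacts on the treadmill stream: 15 Hz zero-phase filter, 40 N threshold."""
    filtered = butterworth_lowpass(session.force.vertical, session.force.fs, cutoff)
    return detect_contacts(filtered, session.force.fs, threshold)


def pressure_bursts(
    session: SensorSession, gap_s: float = 0.03
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group the stance-only pressure log into per-contact bursts: the device
    only logs during stance, so any timestamp gap larger than ``gap_s``
    separates two contacts.  Returns [(times, values), ...]."""
    t = session.pressure.times
    if len(t) == 0:
        return []
    breaks = np.flatnonzero(np.diff(t) > gap_s) + 1
    groups = np.split(np.arange(len(t)), breaks)
    return [(t[g], session.pressure.values[g]) for g in groups]


def pressure_events(session: SensorSession, gap_s: float = 0.03) -> ContactEvents:
    """Contact events on the pressure device clock, one per logged burst.

    Indices are expressed on a virtual 1,000 Hz reconstruction clock (the
    rate the device samples at internally before 50 Hz logging).
    """
    bursts = pressure_bursts(session, gap_s)
    events = []
    for times, _ in bursts:
        ic = int(round(times[0] * FORCE_FS))
        to = int(round(times[-1] * FORCE_FS)) + 1
        events.append((ic, to))
    return ContactEvents(events=tuple(events), fs=FORCE_FS)


def imu_events(
    session: SensorSession,
    cutoff: float = DEFAULT_IMU_CUTOFF_HZ,
    accel_threshold_g: float = -0.5,
    min_duration_s: float = DEFAULT_MIN_CONTACT_S,
) -> ContactEvents:
    """Accelerometer-based step detection: stance is a run where the low-pass
    filtered vertical axis rises above ``accel_threshold_g`` (between
    contacts the foot is in free fall at -1 g)."""
    az = butterworth_lowpass(session.imu.accel[:, 2], session.imu.fs, cutoff)
    shifted = az - accel_threshold_g
    return detect_contacts(shifted, session.imu.fs, threshold=1e-12, min_duration_s=min_duration_s)


# --------------------------------------------------------------------------
# segmentation
# --------------------------------------------------------------------------


def segment_contacts(
    session: SensorSession,
    triples: list[tuple[int, int, int]],
    f_events: ContactEvents,
    p_bursts: list[tuple[np.ndarray, np.ndarray]],
    i_events: ContactEvents,
    force_cutoff: float = DEFAULT_FORCE_CUTOFF_HZ,
    imu_cutoff: float = DEFAULT_IMU_CUTOFF_HZ,
) -> list[FootContact]:
    """Build 400-sample FootContacts from synchronized per-device indices.

    ``triples`` holds (force_idx, pressure_idx, imu_idx) for each physical
    contact (see :mod:`grfest.sync`).  Per contact: the force slice is
    filtered at 15 Hz, the accelerometer slice at 10 Hz, the 50 Hz pressure
    burst is quadratically upsampled to 1,000 Hz (no further filtering) and
    the CoP computed per sample; everything is then time-normalized to 400
    points.  Contacts whose pressure burst is too short to interpolate are
    dropped with a logged reason.
    """
    contacts: list[FootContact] = []
    fs_force = session.force.fs
    for fi, pi, ii in triples:
        ic, to = f_events.events[fi]
        fv = session.force.vertical[ic:to]
        fap = session.force.anteroposterior[ic:to]
        try:
            fv_f = butterworth_lowpass(fv, fs_force, force_cutoff)
            fap_f = butterworth_lowpass(fap, fs_force, force_cutoff)
        except ValueError as err:
            logger.warning("dropping contact %d: force slice unfilterable (%s)", fi, err)
            continue

        times_p, values_p = p_bursts[pi]
        if len(times_p) < 2:
            logger.warning("dropping contact %d: pressure burst too short", fi)
            continue
        _, pressure_up = upsample_quadratic(times_p, values_p)
        pressure_up = np.clip(pressure_up, 0.0, None)  # interpolation can undershoot 0
        cop = compute_cop_trace(pressure_up, session.geometry)

        iic, ito = i_events.events[ii]
        acc = session.imu.accel[iic:ito]
        try:
            acc_f = butterworth_lowpass(acc, session.imu.fs, imu_cutoff, axis=0)
        except ValueError as err:
            logger.warning("dropping contact %d: IMU slice unfilterable (%s)", fi, err)
            continue

        contacts.append(
            FootContact(
                force_v=time_normalize(fv_f),
                force_ap=time_normalize(fap_f),
                pressure=time_normalize(pressure_up),
                cop_x=time_normalize(cop[:, 0]),
                cop_y=time_normalize(cop[:, 1]),
                accel=time_normalize(acc_f),
                gct=(to - ic) / fs_force,
                mass=session.profile.mass,
                speed=session.condition.speed,
                gradient=session.condition.gradient,
                insole_length=session.profile.insole_length,
                participant_id=session.profile.participant_id,
                condition_id=session.condition.condition_id,
            )
        )
    return contacts
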