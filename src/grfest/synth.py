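"""Synthetic cohort, GRF forward model and raw three-device sensor streams.

Real deployments record three independently clocked devices: an instrumented
treadmill (vertical + anteroposterior force, 1,000 Hz), a 16-FSR pressure
insole (sampled at 1,000 Hz but logged at 50 Hz as 20 ms moving averages,
stance only), and a shoe-mounted IMU (~1,138 Hz accelerometer).  This module
generates sessions with that exact structure — clock offsets, stride-time
jitter, stance-only logging, logarithmic FSR response — together with the
clean ground truth, so every downstream stage can be tested without access
to a human dataset.

Units: forces in N, accelerations in g, lengths in mm, times in s,
speeds in km/h, gradients in % incline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

G = 9.81  # m/s^2, used for all bodyweight conversions

FORCE_FS = 1000.0
IMU_FS = 1138.0
PRESSURE_LOG_FS = 50.0
PRESSURE_WINDOW_S = 0.020  # 20 ms moving-average logging window


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class ParticipantProfile:
    """One synthetic runner.

    ``footstrike`` is a latent scalar in [0, 1]: 0 = extreme rearfoot,
    1 = extreme forefoot.  ``stride_cv`` is the coefficient of variation of
    stride time (unitless).
    """

    participant_id: str
    mass: float  # kg
    easy_speed: float  # km/h
    insole_length: float  # mm
    footstrike: float
    stride_cv: float
    rng_seed: int

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"mass must be positive, got {self.mass}")
        if not 0.0 <= self.footstrike <= 1.0:
            raise ValueError("footstrike latent must lie in [0, 1]")
        if not 0.0 < self.stride_cv <= 0.1:
            raise ValueError("stride_cv must lie in (0, 0.1]")


@dataclass(frozen=True)
class Condition:
    """One treadmill stage: constant speed and gradient for ``duration`` s."""

    speed: float  # km/h
    gradient: float  # % incline, signed
    duration: float  # s

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if not -10.0 <= self.gradient <= 10.0:
            raise ValueError("gradient must lie in [-10, +10] %")

    @property
    def condition_id(self) -> str:
        return f"s{self.speed:.1f}_g{self.gradient:+.0f}"


@dataclass(frozen=True)
class InsoleGeometry:
    """Sensor coordinates in the insole-local frame.

    y runs anteroposterior, 0 at the heel, increasing toward the toe;
    x runs mediolateral with 0 at the midline.  Units mm.
    """

    sensor_coords: np.ndarray  # (16, 2) [x, y]
    insole_length: float  # mm

    def __post_init__(self) -> None:
        coords = np.asarray(self.sensor_coords, dtype=float)
        object.__setattr__(self, "sensor_coords", coords)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("sensor_coords must be (n, 2)")
        if coords.shape[0] < 2:
            raise ValueError("insole geometry needs at least 2 sensors")
        y = coords[:, 1]
        if np.any(y < 0) or np.any(y > self.insole_length):
            raise ValueError("sensor y coordinates must lie in [0, insole_length]")
        if len({tuple(c) for c in coords.tolist()}) != coords.shape[0]:
            raise ValueError("sensor coordinates must be pairwise distinct")

    @property
    def n_sensors(self) -> int:
        return int(self.sensor_coords.shape[0])

    @property
    def centroid(self) -> np.ndarray:
        return self.sensor_coords.mean(axis=0)


def default_geometry(insole_length: float = 270.0) -> InsoleGeometry:
    """4x4 sensor grid spanning [0.05, 0.95] * length in y and +/-25 mm in x."""
    ys = np.linspace(0.05, 0.95, 4) * insole_length
    xs = np.linspace(-25.0, 25.0, 4)
    grid = np.array([(x, y) for y in ys for x in xs])
    return InsoleGeometry(sensor_coords=grid, insole_length=insole_length)


@dataclass(frozen=True)
class CohortConfig:
    """Distribution parameters for the synthetic cohort.

    Defaults target a mixed-sex recreational-runner pool: mass and easy
    running speed are truncated normals pooled across the two sexes, and the
    footstrike latent is drawn so its terciles reproduce the configured
    rearfoot/midfoot/forefoot proportions.
    """

    mass_mean: float = 65.9
    mass_sd: float = 10.4
    mass_bounds: tuple[float, float] = (45.0, 100.0)
    speed_mean: float = 11.0
    speed_sd: float = 1.5
    speed_bounds: tuple[float, float] = (7.0, 16.0)
    insole_length_mean: float = 270.0
    insole_length_sd: float = 15.0
    insole_length_bounds: tuple[float, float] = (230.0, 310.0)
    # rear/mid/fore proportions of the footstrike latent terciles
    footstrike_props: tuple[float, float, float] = (0.54, 0.30, 0.16)
    stride_cv_bounds: tuple[float, float] = (0.015, 0.05)

    def __post_init__(self) -> None:
        for sd in (self.mass_sd, self.speed_sd, self.insole_length_sd):
            if sd <= 0:
                raise ValueError("distribution SDs must be positive")
        if abs(sum(self.footstrike_props) - 1.0) > 1e-9:
            raise ValueError("footstrike proportions must sum to 1")
        if any(p < 0 for p in self.footstrike_props):
            raise ValueError("footstrike proportions must be non-negative")


@dataclass(frozen=True)
class SessionConfig:
    """Noise levels and device parameters for raw-stream generation."""

    grf_noise_sd_bw: float = 0.05  # additive noise on both GRF components, BW
    flight_force_noise_sd: float = 2.0  # N, force-plate noise outside stance
    fsr_a: float = 1.0  # raw = a * ln(1 + b * F)
    fsr_b: float = 0.01  # 1/N
    fsr_noise_sd: float = 0.01  # raw units
    kernel_width_mm: float = 25.0  # Gaussian spread of load over sensors
    accel_noise_sd_g: float = 0.03
    accel_wobble_g: float = 0.1  # smooth segment-dynamics perturbation
    device_offset_range_s: float = 2.0  # clock starts drawn base +/- range
    lead_in_s: float = 2.5  # master-clock margin before the device windows


@dataclass
class SessionTruth:
    """Clean ground truth retained alongside the raw streams (master clock)."""

    contact_intervals: np.ndarray  # (n_contacts, 2) [start, end) in s
    grf_v: list[np.ndarray]  # per-contact clean traces, N, 1,000 Hz
    grf_ap: list[np.ndarray]
    centroids: list[np.ndarray]  # per-contact (n, 2) true CoP path, mm
    stride_times: np.ndarray  # (n_contacts - 1,) s

    def __post_init__(self) -> None:
        iv = np.asarray(self.contact_intervals, dtype=float)
        if len(iv) and (np.any(np.diff(iv[:, 0]) <= 0) or np.any(iv[:, 1] <= iv[:, 0])):
            raise ValueError("contact intervals must be sorted and non-overlapping")
        if len(iv) > 1 and np.any(iv[1:, 0] < iv[:-1, 1]):
            raise ValueError("contact intervals must not overlap")


@dataclass
class ForceStream:
    fs: float
    vertical: np.ndarray  # N
    anteroposterior: np.ndarray  # N


@dataclass
class PressureStream:
    """Stance-only 50 Hz log: explicit timestamps (device clock) + 16 channels."""

    times: np.ndarray  # (m,) s
    values: np.ndarray  # (m, 16) raw FSR units


@dataclass
class ImuStream:
    fs: float
    accel: np.ndarray  # (n, 3) g; axes [mediolateral, anteroposterior, vertical]
    gyro: np.ndarray | None = None  # (n, 3) deg/s; generated, unused downstream


@dataclass
class SensorSession:
    """Three unsynchronized device streams + metadata for one participant x condition."""

    force: ForceStream
    pressure: PressureStream
    imu: ImuStream
    device_offsets: dict[str, float]  # master-clock start time of each device
    profile: ParticipantProfile
    condition: Condition
    geometry: InsoleGeometry
    truth: SessionTruth


# --------------------------------------------------------------------------
# cohort
# --------------------------------------------------------------------------


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float], size: int
) -> np.ndarray:
    a, b = (bounds[0] - mean) / sd, (bounds[1] - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(
    n_participants: int, seed: int, config: CohortConfig | None = None
) -> list[ParticipantProfile]:
    """Draw a reproducible cohort of synthetic runners.

    Mass, easy speed and insole length come from truncated normals; the
    footstrike latent is a tercile mixture matching the configured
    rear/mid/fore proportions; stride-time CV is uniform in its band.
    """
    if n_participants < 1:
        raise ValueError("n_participants must be >= 1")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(seed)
    masses = _truncated_normal(rng, cfg.mass_mean, cfg.mass_sd, cfg.mass_bounds, n_participants)
    speeds = _truncated_normal(rng, cfg.speed_mean, cfg.speed_sd, cfg.speed_bounds, n_participants)
    lengths = _truncated_normal(
        rng, cfg.insole_length_mean, cfg.insole_length_sd, cfg.insole_length_bounds, n_participants
    )
    tercile = rng.choice(3, size=n_participants, p=cfg.footstrike_props)
    footstrike = (tercile + rng.uniform(0.0, 1.0, n_participants)) / 3.0
    stride_cv = rng.uniform(*cfg.stride_cv_bounds, n_participants)
    seeds = rng.integers(0, 2**31 - 1, n_participants)
    return [
        ParticipantProfile(
            participant_id=f"P{i:03d}",
            mass=float(masses[i]),
            easy_speed=float(speeds[i]),
            insole_length=float(lengths[i]),
            footstrike=float(footstrike[i]),
            stride_cv=float(stride_cv[i]),
            rng_seed=int(seeds[i]),
        )
        for i in range(n_participants)
    ]


def generate_protocol(profile: ParticipantProfile, quick: bool = True) -> list[Condition]:
    """The treadmill protocol: flat (+1%), uphill (+6%) and downhill (-4%)
    stages at speeds centred on the participant's easy pace (+/-10%) plus a
    fixed 12 km/h flat stage.

    ``quick`` scales every stage to 30 s (full protocol: 2-5 min stages);
    speed ratios and gradients are preserved.
    """
    v = profile.easy_speed
    full = [
        Condition(v, 1.0, 300.0),
        Condition(0.9 * v, 1.0, 120.0),
        Condition(1.1 * v, 1.0, 120.0),
        Condition(12.0, 1.0, 180.0),
        Condition(v, 6.0, 120.0),
        Condition(0.9 * v, 6.0, 120.0),
        Condition(v, -4.0, 120.0),
        Condition(1.1 * v, -4.0, 120.0),
        Condition(0.9 * v, -4.0, 120.0),
    ]
    if not quick:
        return full
    return [replace(c, duration=30.0) for c in full]


# --------------------------------------------------------------------------
# GRF forward model
# --------------------------------------------------------------------------


def _endpoint_taper(t: np.ndarray, width: float = 0.02) -> np.ndarray:
    # linear ramp over the first/last `width` of stance so traces are exactly
    # zero at touchdown and toe-off
    return np.clip(np.minimum(t, 1.0 - t) / width, 0.0, 1.0)


def generate_grf(
    profile: ParticipantProfile,
    condition: Condition,
    contact_duration: float,
    rng: np.random.Generator,
    noise_sd_bw: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Clean two-component GRF traces for one stance phase, in N at 1,000 Hz.

    The vertical component is an active half-sine peaking near 45% stance
    (about 2.5 BW at easy pace, rising with speed) plus an impact transient
    near 15% stance whose amplitude shrinks linearly with the footstrike
    latent (pure forefoot -> no transient).  The anteroposterior component is
    braking-then-propulsion; gradient shifts the balance (uphill -> more
    propulsion, downhill -> more braking).  Both are exactly zero at the
    endpoints; optional white noise is added on top.
    """
    if contact_duration <= 0:
        raise ValueError("contact_duration must be positive")
    if not 0.1 <= contact_duration <= 0.4:
        raise ValueError("contact_duration must lie in [0.1, 0.4] s")
    n = int(round(contact_duration * FORCE_FS))
    t = np.linspace(0.0, 1.0, n)

    # active peak: half sine, time-warped so the maximum sits at 45% stance
    tau = np.where(t <= 0.45, t / 0.45 * 0.5, 0.5 + (t - 0.45) / 0.55 * 0.5)
    amp_v = 2.5 * (condition.speed / profile.easy_speed) ** 0.4
    active = amp_v * np.sin(np.pi * tau)

    # impact transient: rearfoot strikers only
    impact_amp = 0.8 * (1.0 - profile.footstrike)
    impact = impact_amp * np.exp(-0.5 * ((t - 0.15) / 0.04) ** 2)

    taper = _endpoint_taper(t)
    grf_v_bw = (active + impact) * taper

    amp_ap = 0.35 * (condition.speed / profile.easy_speed) ** 0.5
    brake_propel = -amp_ap * np.sin(2.0 * np.pi * t)
    grad_shift = 0.012 * condition.gradient * np.sin(np.pi * t)
    grf_ap_bw = (brake_propel + grad_shift) * taper

    if noise_sd_bw > 0:
        grf_v_bw = grf_v_bw + rng.normal(0.0, noise_sd_bw, n)
        grf_ap_bw = grf_ap_bw + rng.normal(0.0, noise_sd_bw, n)
    grf_v_bw = np.clip(grf_v_bw, 0.0, None)

    bw = profile.mass * G
    return grf_v_bw * bw, grf_ap_bw * bw


def true_centroid_path(
    n: int, profile: ParticipantProfile, geometry: InsoleGeometry
) -> np.ndarray:
    """True CoP trajectory (mm) through one stance: touchdown position set by
    the footstrike latent (rearfoot -> heel, forefoot -> anterior), rolling
    smoothly toward the forefoot."""
    u = np.linspace(0.0, 1.0, n)
    y0 = geometry.insole_length * (0.15 + 0.55 * profile.footstrike)
    y1 = geometry.insole_length * 0.80
    smooth = u * u * (3.0 - 2.0 * u)  # smoothstep
    y = y0 + (y1 - y0) * smooth
    x = -5.0 + 10.0 * u
    return np.column_stack([x, y])


def generate_pressures(
    grf_v: np.ndarray,
    profile: ParticipantProfile,
    geometry: InsoleGeometry,
    rng: np.random.Generator,
    config: SessionConfig | None = None,
    centroid: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Distribute vertical force over the insole sensors and apply the FSR
    response.

    Per sample, force is split across sensors with Gaussian weights centred
    on the travelling pressure centroid (weights normalised, so the inverse
    transform conserves total force exactly when noise is off).  Each
    sensor's raw output is ``a * ln(1 + b * F_sensor)`` plus noise.

    Returns ``(raw, centroid)``: raw FSR trace (n, 16) and the true centroid
    path (n, 2) used, which is retained in session truth for testing.
    """
    grf_v = np.asarray(grf_v, dtype=float)
    if np.any(grf_v < 0):
        raise ValueError("grf_v must be non-negative")
    if geometry.n_sensors < 2:
        raise ValueError("insole geometry needs at least 2 sensors")
    cfg = config or SessionConfig()
    n = len(grf_v)
    if centroid is None:
        centroid = true_centroid_path(n, profile, geometry)

    d2 = ((centroid[:, None, :] - geometry.sensor_coords[None, :, :]) ** 2).sum(axis=2)
    if cfg.kernel_width_mm <= 0.0:
        weights = np.zeros_like(d2)
        weights[np.arange(n), np.argmin(d2, axis=1)] = 1.0
    else:
        weights = np.exp(-0.5 * d2 / cfg.kernel_width_mm**2)
        weights /= weights.sum(axis=1, keepdims=True)
    sensor_force = weights * grf_v[:, None]
    raw = cfg.fsr_a * np.log1p(cfg.fsr_b * sensor_force)
    if cfg.fsr_noise_sd > 0:
        raw = raw + rng.normal(0.0, cfg.fsr_noise_sd, raw.shape)
        raw = np.clip(raw, 0.0, None)
    return raw, centroid


def invert_fsr(raw: np.ndarray, a: float = 1.0, b: float = 0.01) -> np.ndarray:
    """Inverse FSR transform: F = (exp(raw / a) - 1) / b."""
    return np.expm1(np.asarray(raw, dtype=float) / a) / b


def generate_imu(
    grf_v: np.ndarray,
    grf_ap: np.ndarray,
    profile: ParticipantProfile,
    rng: np.random.Generator,
    config: SessionConfig | None = None,
    fs_in: float = FORCE_FS,
    fs_out: float = IMU_FS,
) -> np.ndarray:
    """Shoe-mounted accelerometer trace (n_out, 3) in g, axes [ML, AP, V].

    The vertical axis follows ``grf_v / (m g) - 1`` (free fall = -1 g when no
    force is applied) and the AP axis ``grf_ap / (m g)``, each with a smooth
    low-frequency segment-dynamics wobble and white noise; resampled to the
    IMU rate and clipped to the device's +/-30 g range.
    """
    cfg = config or SessionConfig()
    grf_v = np.asarray(grf_v, dtype=float)
    grf_ap = np.asarray(grf_ap, dtype=float)
    n = len(grf_v)
    bw = profile.mass * G
    t = np.arange(n) / fs_in

    def wobble() -> np.ndarray:
        f = rng.uniform(2.0, 5.0)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        return cfg.accel_wobble_g * np.sin(2.0 * np.pi * f * t + phase)

    az = grf_v / bw - 1.0 + wobble()
    ay = grf_ap / bw + wobble()
    ax = 0.5 * wobble()
    accel = np.column_stack([ax, ay, az])
    if cfg.accel_noise_sd_g > 0:
        accel = accel + rng.normal(0.0, cfg.accel_noise_sd_g, accel.shape)

    n_out = int(np.floor((n - 1) / fs_in * fs_out)) + 1
    t_out = np.arange(n_out) / fs_out
    out = np.column_stack([np.interp(t_out, t, accel[:, k]) for k in range(3)])
    return np.clip(out, -30.0, 30.0)


# --------------------------------------------------------------------------
# stance-only 50 Hz logging
# --------------------------------------------------------------------------


def emulate_pressure_logging(
    values: np.ndarray,
    intervals: list[tuple[float, float]] | np.ndarray,
    fs: float = FORCE_FS,
    window_s: float = PRESSURE_WINDOW_S,
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce a 1,000 Hz pressure trace to the device's stance-only 50 Hz log.

    Within each contact interval, consecutive non-overlapping 20 ms windows
    are averaged to one sample stamped at the centre of the averaged span; a
    trailing (or sub-window) remainder yields one partial-window sample.
    No samples exist outside the intervals.

    ``values`` may be (n,) or (n, channels); intervals are [start, end) in
    seconds on the trace's clock, sorted and non-overlapping.
    """
    values = np.asarray(values, dtype=float)
    one_d = values.ndim == 1
    if one_d:
        values = values[:, None]
    iv = np.asarray(intervals, dtype=float).reshape(-1, 2)
    if len(iv) > 1 and (np.any(np.diff(iv[:, 0]) <= 0) or np.any(iv[1:, 0] < iv[:-1, 1])):
        raise ValueError("intervals must be sorted and non-overlapping")
    win = max(1, int(round(window_s * fs)))
    times, out = [], []
    n = values.shape[0]
    for start_s, end_s in iv:
        i0 = max(0, int(np.ceil(start_s * fs)))
        i1 = min(n, int(np.ceil(end_s * fs)))
        pos = i0
        while pos < i1:
            stop = min(pos + win, i1)
            out.append(values[pos:stop].mean(axis=0))
            times.append((pos + stop - 1) / 2.0 / fs)
            pos = stop
    times_arr = np.asarray(times, dtype=float)
    out_arr = np.asarray(out, dtype=float) if out else np.empty((0, values.shape[1]))
    if one_d:
        out_arr = out_arr[:, 0] if len(out_arr) else np.empty(0)
    return times_arr, out_arr


# --------------------------------------------------------------------------
# full session
# --------------------------------------------------------------------------


def _stride_time_mean(speed: float) -> float:
    # same-foot stride time shortens mildly with speed; clamped to a
    # physiological band
    return float(np.clip(0.75 - 0.008 * (speed - 11.0), 0.60, 0.90))


def _contact_time_mean(speed: float) -> float:
    return float(np.clip(0.40 - 0.012 * speed, 0.12, 0.35))


def generate_stride_schedule(
    profile: ParticipantProfile,
    condition: Condition,
    rng: np.random.Generator,
    n_contacts: int | None = None,
) -> np.ndarray:
    """Contact intervals (n, 2) in s for one stage, with stride times jittered
    at the participant's stride_cv.  Starts after a short lead-in; if
    ``n_contacts`` is None the schedule fills the stage duration."""
    st_mean = _stride_time_mean(condition.speed)
    ct_mean = _contact_time_mean(condition.speed)
    onsets, t = [], 0.5
    k = 0
    while True:
        if n_contacts is not None and k >= n_contacts:
            break
        if n_contacts is None and t + ct_mean > condition.duration - 0.2:
            break
        onsets.append(t)
        t += st_mean * (1.0 + profile.stride_cv * rng.standard_normal())
        k += 1
    onsets_a = np.asarray(onsets)
    cts = ct_mean * (1.0 + 0.02 * rng.standard_normal(len(onsets_a)))
    cts = np.clip(cts, 0.1, 0.4)
    # guard against (pathological) overlap at extreme jitter
    if len(onsets_a) > 1:
        cts[:-1] = np.minimum(cts[:-1], np.diff(onsets_a) - 0.05)
    return np.column_stack([onsets_a, onsets_a + cts])


def generate_session(
    profile: ParticipantProfile,
    condition: Condition,
    seed: int,
    config: SessionConfig | None = None,
    geometry: InsoleGeometry | None = None,
    n_contacts: int | None = None,
    offset_shifts: dict[str, float] | None = None,
) -> SensorSession:
    """Generate one full three-device recording.

    Contacts and flight phases are laid out on a master clock.  The force
    device (the reference clock) records every contact; the pressure and IMU
    devices start at independent clock offsets drawn within
    +/- ``device_offset_range_s`` of the force start (overridable via
    ``offset_shifts``), so a later-starting device misses leading contacts
    and an earlier-starting one misses trailing contacts.  All clean ground
    truth is retained on the master clock.
    """
    cfg = config or SessionConfig()
    geom = geometry or default_geometry(profile.insole_length)
    rng = np.random.default_rng(seed)

    # force device start on the master clock, placed so that any shifted
    # device window still starts at positive master time
    off_f = cfg.lead_in_s + cfg.device_offset_range_s
    shifts = offset_shifts or {
        dev: float(rng.uniform(-cfg.device_offset_range_s, cfg.device_offset_range_s))
        for dev in ("pressure", "imu")
    }
    offsets = {
        "force": off_f,
        "pressure": off_f + shifts.get("pressure", 0.0),
        "imu": off_f + shifts.get("imu", 0.0),
    }

    intervals = generate_stride_schedule(profile, condition, rng, n_contacts)
    intervals = intervals + off_f  # first contact ~0.5 s into the force window
    duration = (
        condition.duration
        if n_contacts is None
        else float(intervals[-1, 1] - off_f + 0.7)
    )
    t_master_end = max(offsets.values()) + duration + 0.5
    n_master = int(round(t_master_end * FORCE_FS))

    # clean per-contact traces
    grf_v_list, grf_ap_list, centroid_list = [], [], []
    force_v = rng.normal(0.0, cfg.flight_force_noise_sd, n_master)
    force_ap = rng.normal(0.0, cfg.flight_force_noise_sd, n_master)
    pressure_full = np.zeros((n_master, geom.n_sensors))
    accel_master = np.zeros((n_master, 3))
    accel_master[:, 2] = -1.0  # free fall between contacts
    stride_sched = []

    for start, end in intervals:
        dur = end - start
        gv, gap = generate_grf(profile, condition, dur, rng, noise_sd_bw=0.0)
        raw, cen = generate_pressures(gv, profile, geom, rng, cfg)
        i0 = int(round(start * FORCE_FS))
        i1 = i0 + len(gv)
        noisy_v = np.clip(gv + rng.normal(0.0, cfg.grf_noise_sd_bw * profile.mass * G, len(gv)), 0.0, None)
        noisy_ap = gap + rng.normal(0.0, cfg.grf_noise_sd_bw * profile.mass * G, len(gap))
        force_v[i0:i1] = noisy_v
        force_ap[i0:i1] = noisy_ap
        pressure_full[i0:i1] = raw
        bw = profile.mass * G
        accel_master[i0:i1, 2] = gv / bw - 1.0
        accel_master[i0:i1, 1] = gap / bw
        grf_v_list.append(gv)
        grf_ap_list.append(gap)
        centroid_list.append(cen)
        stride_sched.append(start)

    truth = SessionTruth(
        contact_intervals=intervals,
        grf_v=grf_v_list,
        grf_ap=grf_ap_list,
        centroids=centroid_list,
        stride_times=np.diff(np.asarray(stride_sched)),
    )

    # ---- force device window
    f0 = int(round(offsets["force"] * FORCE_FS))
    f1 = min(n_master, f0 + int(round(duration * FORCE_FS)))
    force = ForceStream(fs=FORCE_FS, vertical=force_v[f0:f1].copy(), anteroposterior=force_ap[f0:f1].copy())

    # ---- pressure device: keep contacts fully inside its window, log at 50 Hz
    p_start, p_end = offsets["pressure"], offsets["pressure"] + duration
    keep = [(s, e) for s, e in intervals if s >= p_start and e <= p_end]
    log_t, log_v = emulate_pressure_logging(pressure_full, keep, fs=FORCE_FS)
    pressure = PressureStream(times=log_t - p_start, values=log_v)

    # ---- IMU device window, with wobble + noise, resampled to 1,138 Hz
    i0 = int(round(offsets["imu"] * FORCE_FS))
    i1 = min(n_master, i0 + int(round(duration * FORCE_FS)))
    seg = accel_master[i0:i1]
    t_seg = np.arange(len(seg)) / FORCE_FS
    wob_f = rng.uniform(0.6, 1.5)
    wob_ph = rng.uniform(0.0, 2.0 * np.pi, 3)
    wob = cfg.accel_wobble_g * np.sin(2.0 * np.pi * wob_f * t_seg[:, None] + wob_ph[None, :])
    seg = seg + wob + rng.normal(0.0, cfg.accel_noise_sd_g, seg.shape)
    n_out = int(np.floor((len(seg) - 1) / FORCE_FS * IMU_FS)) + 1
    t_out = np.arange(n_out) / IMU_FS
    accel = np.column_stack([np.interp(t_out, t_seg, seg[:, k]) for k in range(3)])
    accel = np.clip(accel, -30.0, 30.0)
    gyro = np.clip(
        200.0 * rng.standard_normal((n_out, 3)), -4000.0, 4000.0
    )  # generated for schema realism; unused downstream
    imu = ImuStream(fs=IMU_FS, accel=accel, gyro=gyro)

    return SensorSession(
        force=force,
        pressure=pressure,
        imu=imu,
        device_offsets=offsets,
        profile=profile,
        condition=condition,
        geometry=geom,
        truth=truth,
    )
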