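"""Stride-time correlation alignment of independently clocked devices.

Each device detects foot contacts on its own clock, so contact #k on one
device is generally not contact #k on another.  Stride times (initial
contact to next initial contact of the same foot) form a jittered sequence
that is common to all devices up to an index shift; Pearson-correlating the
two stride-time vectors at every candidate integer lag and taking the
maximum recovers that shift.  An alignment is accepted when the correlation
at the best lag exceeds 0.85.

Both pairwise alignments (pressure vs force, IMU vs force) are anchored on
the treadmill force stream, which serves as the reference clock.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from grfest.preprocess import ContactEvents

ACCEPTANCE_THRESHOLD = 0.85
DEFAULT_MAX_LAG = 20
DEFAULT_MIN_OVERLAP = 10


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of one pairwise stride-time alignment.

    ``offset`` is the signed contact-index shift of stream B relative to
    stream A: element ``a[i]`` corresponds to ``b[i - offset]``.  ``r`` is
    the Pearson correlation at that offset (NaN when undefined).
    """

    offset: int
    r: float
    n_overlap: int
    accepted: bool


@dataclass(frozen=True)
class SyncResult:
    """Per-session synchronization outcome: the two pairwise alignments and,
    when both are accepted, the per-contact (force, pressure, imu) index
    triples for every contact visible on all three devices."""

    pressure_alignment: AlignmentResult
    imu_alignment: AlignmentResult
    triples: list[tuple[int, int, int]]

    @property
    def synchronized(self) -> bool:
        return self.pressure_alignment.accepted and self.imu_alignment.accepted


def stride_times(events: ContactEvents) -> np.ndarray:
    """Stride durations in seconds: consecutive initial-contact differences."""
    if len(events) < 2:
        raise ValueError("need at least 2 contacts to compute stride times")
    return np.diff(events.ic_times)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    sx, sy = x.std(), y.std()
    if sx == 0.0 or sy == 0.0:
        return np.nan
    return float(np.corrcoef(x, y)[0, 1])


def align_streams(
    strides_a: np.ndarray,
    strides_b: np.ndarray,
    max_lag: int = DEFAULT_MAX_LAG,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    threshold: float = ACCEPTANCE_THRESHOLD,
) -> AlignmentResult:
    """Exhaustive integer-lag scan for the stride-time alignment of B onto A.

    Evaluates Pearson r at every lag in [-max_lag, +max_lag] whose overlap
    has at least ``min_overlap`` stride pairs and returns the lag with the
    maximal r; ties break toward the smaller |lag| (then the negative lag).
    If every candidate window has zero variance the correlation is undefined
    and an explicit non-accepted result (r = NaN) is returned.
    """
    a = np.asarray(strides_a, dtype=float)
    b = np.asarray(strides_b, dtype=float)
    if len(a) < min_overlap or len(b) < min_overlap:
        raise ValueError(f"both stride vectors need >= min_overlap={min_overlap} elements")
    best: tuple[float, int, int] | None = None  # (r, lag, n_overlap)
    for lag in sorted(range(-max_lag, max_lag + 1), key=lambda k: (abs(k), k)):
        lo = max(0, lag)
        hi = min(len(a), len(b) + lag)
        n = hi - lo
        if n < min_overlap:
            continue
        r = _pearson(a[lo:hi], b[lo - lag : hi - lag])
        if np.isnan(r):
            continue
        if best is None or r > best[0]:
            best = (r, lag, n)
    if best is None:
        return AlignmentResult(offset=0, r=float("nan"), n_overlap=0, accepted=False)
    r, lag, n = best
    return AlignmentResult(offset=lag, r=r, n_overlap=n, accepted=bool(r > threshold))


def synchronize_session(
    force_events: ContactEvents,
    pressure_events: ContactEvents,
    imu_events: ContactEvents,
    max_lag: int = DEFAULT_MAX_LAG,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    threshold: float = ACCEPTANCE_THRESHOLD,
) -> SyncResult:
    """Synchronize all three devices against the force stream.

    Aligns force-vs-pressure and force-vs-IMU stride-time vectors, then maps
    every force contact to its pressure and IMU indices, dropping contacts
    not present on all three devices.  If either alignment is rejected the
    session is flagged unsynchronizable (empty triples).
    """
    for ev in (force_events, pressure_events, imu_events):
        if len(ev) < min_overlap + 1:
            raise ValueError("each device needs at least min_overlap + 1 contacts")
    sf = stride_times(force_events)
    ap = align_streams(sf, stride_times(pressure_events), max_lag, min_overlap, threshold)
    ai = align_streams(sf, stride_times(imu_events), max_lag, min_overlap, threshold)
    triples: list[tuple[int, int, int]] = []
    if ap.accepted and ai.accepted:
        for fi in range(len(force_events)):
            pi = fi - ap.offset
            ii = fi - ai.offset
            if 0 <= pi < len(pressure_events) and 0 <= ii < len(imu_events):
                triples.append((fi, pi, ii))
    return SyncResult(pressure_alignment=ap, imu_alignment=ai, triples=triples)
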