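"""The per-contact [N x 400 x 26] model input matrix and leak-free z-scoring.

Channel order is fixed and documented (``CHANNEL_NAMES``): the 16 FSR
pressure channels, the two CoP coordinates, the three accelerometer axes,
then five discrete descriptors (ground contact time, participant mass,
running speed, gradient, insole length) broadcast along the 400-sample time
axis.  Standardization statistics are always fitted on the training split
only and applied unchanged to validation data, so no information leaks from
held-out contacts into the transform.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np

from grfest.preprocess import NORMALIZED_LENGTH, FootContact

logger = logging.getLogger(__name__)

CHANNEL_NAMES: tuple[str, ...] = tuple(
    [f"fsr_{i + 1:02d}" for i in range(16)]
    + ["cop_x", "cop_y", "accel_x", "accel_y", "accel_z", "gct", "mass", "speed", "gradient", "insole_length"]
)
N_CHANNELS = len(CHANNEL_NAMES)  # 26
DISCRETE_CHANNELS = ("gct", "mass", "speed", "gradient", "insole_length")


@dataclass
class FeatureMatrix:
    """[n_contacts x 400 x 26] array plus channel labels and row provenance."""

    values: np.ndarray
    channel_names: tuple[str, ...] = CHANNEL_NAMES
    contact_index: list[tuple[str, str, int]] = field(default_factory=list)
    standardized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != (NORMALIZED_LENGTH, len(self.channel_names)):
            raise ValueError(
                f"values must be [n x {NORMALIZED_LENGTH} x {len(self.channel_names)}], got {self.values.shape}"
            )
        if self.contact_index and len(self.contact_index) != self.values.shape[0]:
            raise ValueError("contact_index length must match n_contacts")

    @property
    def n_contacts(self) -> int:
        return int(self.values.shape[0])

    @property
    def participant_ids(self) -> np.ndarray:
        return np.asarray([pid for pid, _, _ in self.contact_index])

    def channel(self, name: str) -> int:
        return self.channel_names.index(name)


def build_features(contacts: list[FootContact]) -> FeatureMatrix:
    """Assemble the input matrix from segmented contacts, in input order."""
    if not contacts:
        raise ValueError("contacts must be non-empty")
    rows = np.empty((len(contacts), NORMALIZED_LENGTH, N_CHANNELS))
    index = []
    for i, c in enumerate(contacts):
        rows[i, :, 0:16] = c.pressure
        rows[i, :, 16] = c.cop_x
        rows[i, :, 17] = c.cop_y
        rows[i, :, 18:21] = c.accel
        rows[i, :, 21] = c.gct
        rows[i, :, 22] = c.mass
        rows[i, :, 23] = c.speed
        rows[i, :, 24] = c.gradient
        rows[i, :, 25] = c.insole_length
        index.append((c.participant_id, c.condition_id, i))
    return FeatureMatrix(values=rows, contact_index=index, standardized=False)


def targets_from_contacts(contacts: list[FootContact], component: str = "grf_v") -> np.ndarray:
    """Per-contact 400-sample force targets in bodyweight units."""
    if component not in ("grf_v", "grf_ap"):
        raise ValueError("component must be 'grf_v' or 'grf_ap'")
    out = np.empty((len(contacts), NORMALIZED_LENGTH))
    for i, c in enumerate(contacts):
        trace = c.force_v if component == "grf_v" else c.force_ap
        out[i] = trace / (c.mass * 9.81)
    return out


@dataclass(frozen=True)
class Standardizer:
    """Per-channel mean/std fitted on a training FeatureMatrix."""

    mean: np.ndarray  # (26,)
    std: np.ndarray  # (26,), strictly positive
    fitted_on: str = ""  # dataset fingerprint

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean", np.asarray(self.mean, dtype=float))
        object.__setattr__(self, "std", np.asarray(self.std, dtype=float))
        if np.any(self.std <= 0):
            raise ValueError("standardizer std must be strictly positive")

    @property
    def fingerprint(self) -> str:
        h = hashlib.sha256()
        h.update(self.mean.tobytes())
        h.update(self.std.tobytes())
        return h.hexdigest()[:16]


def _dataset_fingerprint(values: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.asarray(values.shape, dtype=np.int64).tobytes())
    h.update(np.ascontiguousarray(values).tobytes())
    return h.hexdigest()[:16]


def fit_standardizer(train: FeatureMatrix) -> Standardizer:
    """Per-channel statistics pooled over contacts x 400 time samples.

    A zero-variance channel (e.g. a single-gradient dataset) gets std
    replaced by 1 with a logged warning, so it maps to all-zeros.
    """
    if train.standardized:
        raise ValueError("refusing to fit a standardizer on already-standardized data")
    if train.n_contacts < 2:
        raise ValueError("need at least 2 contacts to fit a standardizer")
    flat = train.values.reshape(-1, len(train.channel_names))
    mean = flat.mean(axis=0)
    std = flat.std(axis=0)
    zero = std == 0.0
    if zero.any():
        names = [train.channel_names[i] for i in np.flatnonzero(zero)]
        logger.warning("zero-variance channels %s: std set to 1", names)
        std = np.where(zero, 1.0, std)
    return Standardizer(mean=mean, std=std, fitted_on=_dataset_fingerprint(train.values))


def apply_standardizer(s: Standardizer, data: FeatureMatrix) -> FeatureMatrix:
    """z-score ``data`` using the training statistics in ``s`` only.

    Rejects already-standardized input (applying twice double-standardizes).
    """
    if data.standardized:
        raise ValueError("feature matrix is already standardized")
    if len(data.channel_names) != len(s.mean):
        raise ValueError("channel count mismatch between standardizer and data")
    values = (data.values - s.mean) / s.std
    return FeatureMatrix(
        values=values,
        channel_names=data.channel_names,
        contact_index=list(data.contact_index),
        standardized=True,
    )


def inverse_standardizer(s: Standardizer, data: FeatureMatrix) -> FeatureMatrix:
    """Exact algebraic inverse of :func:`apply_standardizer`."""
    if not data.standardized:
        raise ValueError("feature matrix is not standardized")
    values = data.values * s.std + s.mean
    return FeatureMatrix(
        values=values,
        channel_names=data.channel_names,
        contact_index=list(data.contact_index),
        standardized=False,
    )
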