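"""LOSO evaluation and the reported agreement statistics.

Per-contact metrics: RMSE in bodyweight (BW), relative RMSE (RMSE as a
percentage of the measured waveform's range), Pearson correlation, vertical
peak and impulse percentage differences, and the anteroposterior peak
braking / propulsive force differences (in BW and N).  Aggregation follows
leave-one-subject-out (LOSO) validation: one fold per participant, the
standardizer and model refitted on everyone else.

Model-sensitivity tools: Bland-Altman agreement (bias, 1.96-SD limits of
agreement, and the slope of difference vs measured magnitude), permutation
feature importance (PFI: RMSE ratio after replacing one input channel with
random values), and the binned profile of peak error against the
anteroposterior centre-of-pressure position at touchdown.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, stats

from grfest.features import (
    CHANNEL_NAMES,
    FeatureMatrix,
    apply_standardizer,
)
from grfest.model import ModelConfig, TrainedEstimator, fit_fold, predict
from grfest.preprocess import FootContact
from grfest.synth import G

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContactMetrics:
    rmse_bw: float
    rrmse: float  # %
    pearson_r: float
    peak_diff_pct: float | None  # vertical only
    impulse_diff_pct: float | None  # vertical only
    peak_braking_diff_bw: float | None  # anteroposterior only
    peak_braking_diff_n: float | None
    peak_propulsive_diff_bw: float | None
    peak_propulsive_diff_n: float | None


def contact_metrics(
    measured: np.ndarray, estimated: np.ndarray, mass: float, component: str = "grf_v"
) -> ContactMetrics:
    """All per-contact agreement metrics; traces in BW.

    rRMSE = 100 * RMSE / (max(measured) - min(measured)).  Differences are
    signed estimated - measured (negative = underestimation).  Vertical
    contacts report peak and (trapezoidal) impulse percentage differences;
    anteroposterior contacts report the braking (most negative) and
    propulsive (most positive) peak differences in BW and N.
    """
    measured = np.asarray(measured, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if measured.shape != estimated.shape:
        raise ValueError("measured and estimated traces must have equal length")
    if mass <= 0:
        raise ValueError("mass must be positive")
    rng_m = measured.max() - measured.min()
    if rng_m == 0.0:
        raise ValueError("flat measured trace: rRMSE undefined")
    rmse = float(np.sqrt(np.mean((estimated - measured) ** 2)))
    rrmse = 100.0 * rmse / rng_m
    r = float(stats.pearsonr(measured, estimated).statistic)
    bw_to_n = mass * G

    peak_diff_pct = impulse_diff_pct = None
    brake_bw = brake_n = prop_bw = prop_n = None
    if component == "grf_v":
        peak_m, peak_e = measured.max(), estimated.max()
        peak_diff_pct = 100.0 * (peak_e - peak_m) / peak_m
        imp_m = float(integrate.trapezoid(measured))
        imp_e = float(integrate.trapezoid(estimated))
        impulse_diff_pct = 100.0 * (imp_e - imp_m) / imp_m
    elif component == "grf_ap":
        brake_bw = float(estimated.min() - measured.min())
        prop_bw = float(estimated.max() - measured.max())
        brake_n = brake_bw * bw_to_n
        prop_n = prop_bw * bw_to_n
    else:
        raise ValueError("component must be 'grf_v' or 'grf_ap'")
    return ContactMetrics(
        rmse_bw=rmse,
        rrmse=rrmse,
        pearson_r=r,
        peak_diff_pct=peak_diff_pct,
        impulse_diff_pct=impulse_diff_pct,
        peak_braking_diff_bw=brake_bw,
        peak_braking_diff_n=brake_n,
        peak_propulsive_diff_bw=prop_bw,
        peak_propulsive_diff_n=prop_n,
    )


@dataclass
class EvaluationReport:
    """LOSO outcome: tidy per-contact table, per-participant means, grand means."""

    per_contact: pd.DataFrame
    per_participant: pd.DataFrame
    grand: dict[str, float]
    failed_folds: list[tuple[str, str]] = field(default_factory=list)


def run_loso(
    features: FeatureMatrix,
    targets: np.ndarray,
    config: ModelConfig,
    participants: list[str] | None = None,
    dtype: str = "float64",
) -> EvaluationReport:
    """Leave-one-subject-out evaluation.

    ``features`` must be UNstandardized; each fold refits the standardizer
    and model on the remaining participants (no leakage).  A failing fold is
    recorded and the remaining folds continue.
    """
    if features.standardized:
        raise ValueError("run_loso() needs unstandardized features (per-fold z-scoring)")
    pids = features.participant_ids
    if participants is None:
        participants = list(dict.fromkeys(pids.tolist()))
    if len(set(participants)) != len(participants):
        raise ValueError("duplicated participant id in dataset")
    if len(participants) < 3:
        raise ValueError("LOSO needs at least 3 participants")
    component = config.target
    rows = []
    failed: list[tuple[str, str]] = []
    for pid in participants:
        held = pids == pid
        if not held.any():
            failed.append((pid, "no contacts for participant"))
            continue
        try:
            tr = FeatureMatrix(
                values=features.values[~held],
                channel_names=features.channel_names,
                contact_index=[ci for ci, h in zip(features.contact_index, held) if not h],
                standardized=False,
            )
            va = FeatureMatrix(
                values=features.values[held],
                channel_names=features.channel_names,
                contact_index=[ci for ci, h in zip(features.contact_index, held) if h],
                standardized=False,
            )
            assert not set(va.participant_ids) & set(tr.participant_ids)
            est, std = fit_fold(tr, targets[~held], config, dtype=dtype)
            pred = predict(est, apply_standardizer(std, va))
        except Exception as err:  # noqa: BLE001 - fold failures are reported, not fatal
            logger.warning("LOSO fold %s failed: %s", pid, err)
            failed.append((pid, str(err)))
            continue
        masses = features.values[held][:, 0, features.channel("mass")]
        for k in range(pred.shape[0]):
            m = contact_metrics(targets[held][k], pred[k], mass=float(masses[k]), component=component)
            rows.append(
                {
                    "participant_id": pid,
                    "contact": k,
                    "rmse_bw": m.rmse_bw,
                    "rrmse": m.rrmse,
                    "pearson_r": m.pearson_r,
                    "peak_diff_pct": m.peak_diff_pct,
                    "impulse_diff_pct": m.impulse_diff_pct,
                    "peak_braking_diff_bw": m.peak_braking_diff_bw,
                    "peak_propulsive_diff_bw": m.peak_propulsive_diff_bw,
                }
            )
    per_contact = pd.DataFrame(rows)
    numeric = [c for c in per_contact.columns if c not in ("participant_id", "contact")]
    per_participant = per_contact.groupby("participant_id")[numeric].agg(["mean", "std"])
    grand = {c: float(per_participant[(c, "mean")].mean()) for c in numeric if per_participant[(c, "mean")].notna().any()}
    return EvaluationReport(
        per_contact=per_contact, per_participant=per_participant, grand=grand, failed_folds=failed
    )


# --------------------------------------------------------------------------
# Bland-Altman
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BlandAltmanSummary:
    bias: float
    loa_low: float
    loa_high: float
    slope: float
    n: int


def bland_altman(measured: np.ndarray, estimated: np.ndarray) -> BlandAltmanSummary:
    """Agreement summary on paired values (e.g. per-contact peak forces).

    d = estimated - measured; bias = mean(d); limits of agreement
    bias -/+ 1.96 * SD(d); slope = least-squares gradient of d against the
    measured magnitude (positive slope = underestimation growing with
    magnitude when d is negative at the top of the range).
    """
    measured = np.asarray(measured, dtype=float)
    estimated = np.asarray(estimated, dtype=float)
    if measured.shape != estimated.shape:
        raise ValueError("paired vectors must have equal length")
    if len(measured) < 3:
        raise ValueError("Bland-Altman needs at least 3 pairs")
    d = estimated - measured
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if np.ptp(measured) == 0.0:
        slope = 0.0 if np.allclose(d, d[0]) else float("nan")
    else:
        slope = float(stats.linregress(measured, d).slope)
    return BlandAltmanSummary(
        bias=bias, loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd, slope=slope, n=len(d)
    )


# --------------------------------------------------------------------------
# permutation feature importance
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PFIResult:
    channel: str
    pfi: float  # mean over reps of permuted RMSE / original RMSE
    pfi_median: float
    n_reps: int
    per_rep: np.ndarray


def pfi(
    estimator: TrainedEstimator,
    features: FeatureMatrix,
    targets: np.ndarray,
    channel: str | int,
    n_reps: int = 100,
    seed: int = 0,
) -> PFIResult:
    """Permutation feature importance of one input channel.

    Per repetition the channel's values across all contacts and timesteps
    are replaced by i.i.d. standard-normal draws (the inputs are z-scored,
    so this matches the nominal channel distribution) and the RMSE is
    recomputed; the PFI is the ratio of permuted to original RMSE.  A
    channel the model ignores yields exactly 1.0.
    """
    if isinstance(channel, str):
        if channel not in features.channel_names:
            raise ValueError(f"unknown channel {channel!r}")
        ch = features.channel_names.index(channel)
    else:
        ch = int(channel)
        if not 0 <= ch < len(features.channel_names):
            raise ValueError(f"channel index {ch} out of range")
    if not features.standardized:
        raise ValueError("pfi() requires standardized features")
    rng = np.random.default_rng(seed)
    base_pred = predict(estimator, features)
    base_rmse = float(np.sqrt(np.mean((base_pred - targets) ** 2)))
    ratios = np.empty(n_reps)
    x = features.values
    for rep in range(n_reps):
        xp = x.copy()
        xp[:, :, ch] = rng.standard_normal(x.shape[:2])
        perturbed = FeatureMatrix(
            values=xp, channel_names=features.channel_names, standardized=True
        )
        pred = predict(estimator, perturbed)
        ratios[rep] = float(np.sqrt(np.mean((pred - targets) ** 2))) / base_rmse
    return PFIResult(
        channel=features.channel_names[ch],
        pfi=float(ratios.mean()),
        pfi_median=float(np.median(ratios)),
        n_reps=n_reps,
        per_rep=ratios,
    )


def pfi_table(
    estimator: TrainedEstimator,
    features: FeatureMatrix,
    targets: np.ndarray,
    n_reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """PFI for every input channel, as a tidy table."""
    rows = []
    for name in features.channel_names:
        res = pfi(estimator, features, targets, name, n_reps=n_reps, seed=seed)
        rows.append({"channel": name, "pfi_mean": res.pfi, "pfi_median": res.pfi_median})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# CoP-position error profile
# --------------------------------------------------------------------------


def touchdown_cop_y(contact: FootContact) -> float:
    """Normalized anteroposterior CoP at touchdown: cop_y at the first sample
    with nonzero total pressure, divided by insole length."""
    total = contact.pressure.sum(axis=1)
    nz = np.flatnonzero(total > 0)
    idx = int(nz[0]) if len(nz) else 0
    return float(contact.cop_y[idx] / contact.insole_length)


def cop_error_profile(
    contacts: list[FootContact], peak_errors: np.ndarray, n_bins: int = 10
) -> pd.DataFrame:
    """Mean +/- SD of per-contact peak error binned by touchdown CoP position.

    Bins cover normalized cop_y in [0, 1]; empty bins are absent from the
    output (columns: bin, bin_center, n, mean, sd).
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    peak_errors = np.asarray(peak_errors, dtype=float)
    if len(contacts) != len(peak_errors):
        raise ValueError("contacts and peak_errors must align")
    pos = np.asarray([touchdown_cop_y(c) for c in contacts])
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    which = np.clip(np.digitize(pos, edges) - 1, 0, n_bins - 1)
    df = pd.DataFrame({"bin": which, "error": peak_errors})
    agg = df.groupby("bin")["error"].agg(n="count", mean="mean", sd="std").reset_index()
    agg.insert(1, "bin_center", (edges[agg["bin"]] + edges[agg["bin"] + 1]) / 2.0)
    return agg
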