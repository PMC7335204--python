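"""Temporal preprocessing of ROI time series.

Motion scrubbing (framewise displacement + run-limit censoring), the
minimum-clean-interval inclusion rule, combined detrending/nuisance
regression, and zero-phase band-pass filtering with interpolation across
censored frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .core import (
    REASON_FD,
    REASON_RUN_ROTATION,
    REASON_RUN_TRANSLATION,
    CensorMask,
    MotionTrace,
    RoiTimeSeries,
)

__all__ = [
    "PreprocessParams",
    "framewise_displacement",
    "censor_volumes",
    "check_inclusion",
    "InclusionReport",
    "regress_and_detrend",
    "bandpass_censored",
    "preprocess_subject",
]

# Assumed head radius (mm) converting rotation differences to a displacement:
# a rotation of theta radians moves a point on a 50 mm sphere by ~50*theta mm.
HEAD_RADIUS_MM = 50.0


@dataclass(frozen=True)
class PreprocessParams:
    """Thresholds and band for temporal preprocessing.

    run_translation_limit : mm, per-axis absolute excursion from the
        reference (first) volume above which a volume is censored.
    run_rotation_limit : degrees, same rule for each rotation axis.
    fd_limit : mm, scan-to-scan framewise displacement threshold.
    min_interval : seconds, minimum contiguous window a subject must have.
    max_censored_fraction : largest tolerated censored fraction in that window.
    band : Hz, (low, high) pass band.
    """

    run_translation_limit: float = 1.0
    run_rotation_limit: float = 1.0
    fd_limit: float = 1.0
    min_interval: float = 300.0
    max_censored_fraction: float = 0.10
    band: tuple[float, float] = (0.009, 0.1)

    def __post_init__(self) -> None:
        for name in ("run_translation_limit", "run_rotation_limit", "fd_limit", "min_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.max_censored_fraction < 1:
            raise ValueError("max_censored_fraction must lie in (0, 1)")
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("band must satisfy 0 < low < high")


def framewise_displacement(motion: MotionTrace) -> np.ndarray:
    """Scan-to-scan framewise displacement in mm.

    FD[t] = sum_i |dx_i[t]| + 50 * sum_i |dtheta_i[t]| with backward
    differences; translations in mm, rotations in radians.  FD[0] = 0 by
    convention (no predecessor volume).
    """
    dt = np.abs(np.diff(motion.translations, axis=0)).sum(axis=1)
    dr = np.abs(np.diff(motion.rotations, axis=0)).sum(axis=1)
    fd = np.zeros(motion.n_volumes)
    fd[1:] = dt + HEAD_RADIUS_MM * dr
    return fd


def censor_volumes(motion: MotionTrace, params: PreprocessParams | None = None) -> CensorMask:
    """Flag volumes violating run-excursion or framewise-displacement limits.

    A volume is censored if any translation axis departs more than
    ``run_translation_limit`` mm from the first (reference) volume, any
    rotation axis departs more than ``run_rotation_limit`` degrees, or its
    FD exceeds ``fd_limit`` mm.  Reason codes record every rule a volume
    violated.
    """
    params = params or PreprocessParams()
    rot_limit_rad = np.deg2rad(params.run_rotation_limit)

    rel_trans = motion.translations - motion.translations[0]
    rel_rot = motion.rotations - motion.rotations[0]
    hit_trans = (np.abs(rel_trans) > params.run_translation_limit).any(axis=1)
    hit_rot = (np.abs(rel_rot) > rot_limit_rad).any(axis=1)
    hit_fd = framewise_displacement(motion) > params.fd_limit

    censored = hit_trans | hit_rot | hit_fd
    reasons: list[tuple[str, ...]] = []
    for t in range(motion.n_volumes):
        r = []
        if hit_trans[t]:
            r.append(REASON_RUN_TRANSLATION)
        if hit_rot[t]:
            r.append(REASON_RUN_ROTATION)
        if hit_fd[t]:
            r.append(REASON_FD)
        reasons.append(tuple(r))
    return CensorMask(censored, reasons)


@dataclass(frozen=True)
class InclusionReport:
    included: bool
    reason: str
    best_window: tuple[int, int] | None = None  # [start, stop) volume indices
    best_fraction: float = field(default=float("nan"))


def check_inclusion(
    mask: CensorMask, tr: float, params: PreprocessParams | None = None
) -> InclusionReport:
    """Subject inclusion rule: a contiguous window of at least
    ``min_interval`` seconds in which at most ``max_censored_fraction`` of
    the volumes are censored.

    All windows of every admissible length are scanned; the reported best
    window is the one with the lowest censored fraction (ties broken toward
    longer, then earlier, windows).
    """
    params = params or PreprocessParams()
    t_total = mask.n_volumes
    w = int(np.ceil(params.min_interval / tr))
    if t_total < w:
        return InclusionReport(
            False, f"run of {t_total} volumes shorter than minimum interval ({w} volumes)"
        )
    csum = np.concatenate([[0], np.cumsum(mask.censored.astype(int))])
    best_frac = np.inf
    best: tuple[int, int] | None = None
    for length in range(w, t_total + 1):
        counts = csum[length:] - csum[:-length]
        start = int(np.argmin(counts))
        frac = counts[start] / length
        if frac < best_frac or (frac == best_frac and best is not None):
            # same fraction at a longer length wins (loop ascends in length)
            best_frac = frac
            best = (start, start + length)
    included = bool(best_frac <= params.max_censored_fraction)
    reason = "ok" if included else (
        f"best admissible window has censored fraction "
        f"{best_frac:.3f} > {params.max_censored_fraction}"
    )
    return InclusionReport(included, reason, best, float(best_frac))


def _design_matrix(
    motion: MotionTrace, nuisance: np.ndarray, n_volumes: int
) -> tuple[np.ndarray, list[str]]:
    t = np.arange(n_volumes, dtype=float)
    trend = (t - t.mean()) / max(t.std(), 1.0)
    cols = [np.ones(n_volumes), trend]
    names = ["intercept", "linear_trend"]
    for j, nm in enumerate(["wm", "csf", "global"]):
        cols.append(nuisance[:, j])
        names.append(nm)
    pars = motion.parameters
    for j in range(6):
        cols.append(pars[:, j])
        names.append(f"motion{j + 1}")
    return np.column_stack(cols), names


def regress_and_detrend(
    ts: RoiTimeSeries,
    motion: MotionTrace,
    nuisance: np.ndarray,
    mask: CensorMask | None = None,
) -> RoiTimeSeries:
    """OLS removal of linear trend, WM/CSF/global and 6 motion regressors.

    The model is fitted on uncensored volumes only; residuals at censored
    positions are filled in from the fitted model (and stay flagged), so
    interpolation in the subsequent filtering step has sensible values to
    bridge.
    """
    nuisance = np.asarray(nuisance, dtype=float)
    if nuisance.shape != (ts.n_volumes, 3):
        raise ValueError("nuisance must be (T, 3): WM, CSF, global")
    if motion.n_volumes != ts.n_volumes:
        raise ValueError("motion trace length must match time series")
    mask = mask if mask is not None else (ts.mask or CensorMask.clean(ts.n_volumes))

    x, names = _design_matrix(motion, nuisance, ts.n_volumes)
    keep = ~mask.censored
    xk = x[keep]
    rank = np.linalg.matrix_rank(xk)
    if rank < x.shape[1]:
        # name columns whose removal restores full column rank
        collinear = [
            names[j]
            for j in range(x.shape[1])
            if np.linalg.matrix_rank(np.delete(xk, j, axis=1)) == rank
        ]
        raise ValueError(f"design matrix rank-deficient; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(xk, ts.data[keep], rcond=None)
    resid = ts.data - x @ beta
    return RoiTimeSeries(resid, ts.tr, mask=mask, node_labels=ts.node_labels)


def _interpolate_censored(data: np.ndarray, censored: np.ndarray) -> np.ndarray:
    """Linear interpolation across censored frames; edges held constant."""
    if not censored.any():
        return data
    if censored.all():
        raise ValueError("cannot interpolate: every volume is censored")
    t = np.arange(data.shape[0])
    good = ~censored
    out = data.copy()
    for j in range(data.shape[1]):
        out[censored, j] = np.interp(t[censored], t[good], data[good, j])
    return out


def bandpass_censored(
    ts: RoiTimeSeries,
    mask: CensorMask | None = None,
    band: tuple[float, float] = (0.009, 0.1),
    tr: float | None = None,
    order: int = 4,
) -> RoiTimeSeries:
    """Zero-phase Butterworth band-pass with censored-frame interpolation.

    Censored points are linearly interpolated before filtering so the
    filter does not ring across gaps, then re-flagged afterwards: they are
    never used downstream.  Forward-backward 4th-order Butterworth.
    """
    tr = tr if tr is not None else ts.tr
    mask = mask if mask is not None else (ts.mask or CensorMask.clean(ts.n_volumes))
    nyquist = 0.5 / tr
    low, high = band
    if high >= nyquist:
        raise ValueError(f"band high {high} Hz >= Nyquist {nyquist:.4f} Hz for TR {tr}")
    filled = _interpolate_censored(ts.data, mask.censored)
    sos = signal.butter(order, [low, high], btype="bandpass", fs=1.0 / tr, output="sos")
    filtered = signal.sosfiltfilt(sos, filled, axis=0)
    return RoiTimeSeries(filtered, tr, mask=mask, node_labels=ts.node_labels)


def preprocess_subject(
    ts: RoiTimeSeries,
    motion: MotionTrace,
    nuisance: np.ndarray,
    params: PreprocessParams | None = None,
) -> tuple[RoiTimeSeries, CensorMask, InclusionReport]:
    """Full temporal preprocessing for one subject.

    Censors by motion, checks the inclusion rule, regresses nuisance
    signals and band-pass filters.  The returned series carries the censor
    mask; the inclusion report says whether the subject qualifies.
    """
    params = params or PreprocessParams()
    mask = censor_volumes(motion, params)
    report = check_inclusion(mask, ts.tr, params)
    cleaned = regress_and_detrend(ts, motion, nuisance, mask)
    filtered = bandpass_censored(cleaned, mask, params.band, ts.tr)
    return filtered, mask, report
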