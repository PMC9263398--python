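"""Deterministic conditioning of ROI time series.

The chain mirrors standard resting-state preparation at ROI grain:
initial-volume deletion -> linear detrend -> nuisance regression ->
temporal band-pass.  Motion screening operates on the six rigid-body
realignment parameters and flags subjects for exclusion; despiking and
slice-timing act on raw volumes and are recorded as "not applied" at this
grain.  Every operation is linear and leaves the sampling interval and unit
count untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .cohort import RoiTimeSeries

#: Head radius (mm) used to convert rotations to arc displacement for FD.
FD_ROTATION_RADIUS_MM = 50.0

#: Default motion-exclusion limits.
MOTION_LIMITS = {"translation_mm": 2.0, "rotation_deg": 2.0, "mean_fd_mm": 0.5}

#: Reflect-padding length (samples) used by the zero-phase band-pass.
BANDPASS_PAD = 50


@dataclass
class MotionSummary:
    subject_id: str
    max_translation: float   # mm
    max_rotation: float      # degrees
    mean_fd: float           # mm
    excluded: bool


@dataclass
class ConditioningReport:
    n_volumes_deleted: int
    filter_band: tuple[float, float]
    nuisance_columns: list[str] = field(default_factory=list)
    motion: list[MotionSummary] = field(default_factory=list)
    not_applied: tuple[str, ...] = ("despiking", "slice-timing")


def delete_initial_volumes(series: RoiTimeSeries, n: int) -> RoiTimeSeries:
    """Drop the first ``n`` volumes (steady-state settling period)."""
    if n < 0:
        raise ValueError("n must be non-negative")
    if n >= series.n_timepoints:
        raise ValueError(
            f"{series.subject_id}: cannot delete {n} of {series.n_timepoints} volumes")
    return RoiTimeSeries(series.subject_id, series.data[:, n:], series.tr,
                         series.unit_roi_ids)


def frame_displacement(motion: np.ndarray,
                       radius_mm: float = FD_ROTATION_RADIUS_MM) -> np.ndarray:
    """Power-style framewise displacement from 6 realignment parameters.

    ``motion`` has one row per volume: three translations (mm) then three
    rotations (degrees).  Rotations are converted to arc length on a sphere of
    ``radius_mm``.  FD_t = sum of absolute backward differences of the six
    converted traces; returned for volumes 1..T-1.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6:
        raise ValueError("motion table must be volumes x 6 (3 translations mm, 3 rotations deg)")
    if motion.shape[0] < 2:
        raise ValueError("frame displacement undefined for fewer than 2 volumes")
    conv = motion.copy()
    conv[:, 3:] = np.deg2rad(conv[:, 3:]) * radius_mm
    return np.abs(np.diff(conv, axis=0)).sum(axis=1)


def flag_motion_exclusion(motion: np.ndarray, subject_id: str = "",
                          limits: dict | None = None) -> MotionSummary:
    """Apply the exclusion rule: translation > 2 mm, rotation > 2 deg, or
    mean FD > 0.5 mm (any one suffices)."""
    lim = dict(MOTION_LIMITS)
    if limits:
        lim.update(limits)
    motion = np.asarray(motion, dtype=float)
    fd = frame_displacement(motion)
    max_t = float(np.abs(motion[:, :3]).max())
    max_r = float(np.abs(motion[:, 3:]).max())
    mean_fd = float(fd.mean())
    excluded = (max_t > lim["translation_mm"] or max_r > lim["rotation_deg"]
                or mean_fd > lim["mean_fd_mm"])
    return MotionSummary(subject_id, max_t, max_r, mean_fd, excluded)


def linear_detrend(data: np.ndarray) -> np.ndarray:
    """Remove the per-unit least-squares line along the last axis."""
    data = np.asarray(data, dtype=float)
    if data.shape[-1] < 3:
        raise ValueError("detrending needs at least 3 timepoints")
    return signal.detrend(data, axis=-1, type="linear")


def regress_nuisance(data: np.ndarray, confounds: np.ndarray | None,
                     names: list[str] | None = None) -> np.ndarray:
    """Project out confound columns (plus an intercept) from each unit.

    With no confounds this mean-centres each unit.  A rank-deficient design
    raises, naming the collinear columns.
    """
    data = np.asarray(data, dtype=float)
    T = data.shape[-1]
    if confounds is None or (hasattr(confounds, "shape") and np.size(confounds) == 0):
        X = np.ones((T, 1))
        names = ["intercept"]
    else:
        confounds = np.asarray(confounds, dtype=float)
        if confounds.ndim == 1:
            confounds = confounds[:, None]
        if confounds.shape[0] != T:
            raise ValueError("confound rows must match timepoints")
        X = np.column_stack([np.ones(T), confounds])
        names = ["intercept"] + (names or [f"confound_{i}" for i in range(confounds.shape[1])])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify columns whose removal restores full rank
        collinear = [names[j] for j in range(X.shape[1])
                     if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank]
        raise ValueError(f"confound matrix is rank deficient; collinear columns: {collinear}")
    beta, *_ = np.linalg.lstsq(X, data.T, rcond=None)
    return data - (X @ beta).T


def bandpass_filter(data: np.ndarray, low: float, high: float, tr: float,
                    design: str = "fft", order: int = 4) -> np.ndarray:
    """Zero-phase temporal band-pass along the last axis.

    The default realization is an ideal (rectangular-response) FFT filter
    with reflect padding of :data:`BANDPASS_PAD` samples, the convention of
    the standard ALFF tool chain: it is exactly zero-phase, preserves
    in-band amplitudes, and is idempotent up to padding edge effects —
    important because short resting-state series are filtered once in
    conditioning and again implicitly by the ALFF band.  ``design="butter"``
    selects a forward-backward Butterworth (order ``order`` per pass)
    instead.
    """
    data = np.asarray(data, dtype=float)
    nyq = 0.5 / tr
    if not (0 < low < high):
        raise ValueError("need 0 < low < high")
    if high >= nyq:
        raise ValueError(f"high cut {high} Hz must be below Nyquist {nyq} Hz")
    T = data.shape[-1]
    pad = min(BANDPASS_PAD, T - 1)
    if design == "butter":
        sos = signal.butter(order, [low, high], btype="bandpass",
                            fs=1.0 / tr, output="sos")
        return signal.sosfiltfilt(sos, data, axis=-1, padtype="even", padlen=pad)
    if design != "fft":
        raise ValueError(f"unknown filter design {design!r}")
    ext = np.concatenate(
        [data[..., pad:0:-1], data, data[..., -2:-2 - pad:-1]], axis=-1)
    spec = np.fft.rfft(ext, axis=-1)
    freqs = np.fft.rfftfreq(ext.shape[-1], d=tr)
    spec[..., (freqs < low) | (freqs > high)] = 0.0
    out = np.fft.irfft(spec, n=ext.shape[-1], axis=-1)
    return out[..., pad:pad + T]


def condition_series(series: RoiTimeSeries, trim_volumes: int = 10,
                     band: tuple[float, float] = (0.01, 0.1),
                     confounds: np.ndarray | None = None,
                     confound_names: list[str] | None = None) -> RoiTimeSeries:
    """Full conditioning chain: trim -> detrend -> nuisance -> band-pass.

    ``confounds`` rows must match the post-trim timepoint count.
    """
    out = delete_initial_volumes(series, trim_volumes)
    data = linear_detrend(out.data)
    data = regress_nuisance(data, confounds, confound_names)
    data = bandpass_filter(data, band[0], band[1], series.tr)
    return RoiTimeSeries(series.subject_id, data, series.tr, series.unit_roi_ids)
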