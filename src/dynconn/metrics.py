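"""Dynamic amplitude (mdALFF) and seed dynamic connectivity (dFC) metrics.

ALFF (amplitude of low-frequency fluctuation) is the mean square-root power of
a signal over a low-frequency band, here computed from an untapered DFT of the
full segment with a one-sided amplitude-calibrated spectrum: a pure in-band
sinusoid of amplitude A contributes exactly A at its bin.  mALFF divides ALFF
by the global mean over included units, so its mask-average is exactly 1 and
any fixed spectral scaling cancels.

Dynamic metrics slide a fixed-length window over the conditioned series.  Per
window the ROI-wise mALFF map is formed (window-wise global-mean
normalisation); the across-window mean and sample variance are mdALFF_mean and
mdALFF_var.  Seed dFC correlates the seed ROI with every target within each
window, Fisher-Z transforms the correlations (clipped at |r| = 1 - 1e-7), and
summarises them as dFC_mean and dFC_var on the Z scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import ParcellationAtlas
from .cohort import CohortDataset, RoiTimeSeries

#: Fisher-Z clip: |r| is bounded at 1 - FISHER_CLIP before atanh.
FISHER_CLIP = 1e-7

DEFAULT_ALFF_BAND = (0.01, 0.08)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in TR units.

    Window ``w`` covers the half-open sample range
    ``[w*step, w*step + length)``; a trailing partial window is discarded, so
    ``n_windows(T) = floor((T - length)/step) + 1``.
    """

    length: int = 50
    step: int = 10

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("window length must be >= 2 samples")
        if self.step < 1:
            raise ValueError("window step must be >= 1 sample")

    def n_windows(self, T: int) -> int:
        if self.length > T:
            raise ValueError(f"window length {self.length} exceeds {T} timepoints")
        return (T - self.length) // self.step + 1

    def windows(self, T: int) -> list[tuple[int, int]]:
        """Half-open (start, stop) sample ranges of every full window."""
        return [(w * self.step, w * self.step + self.length)
                for w in range(self.n_windows(T))]


def make_windows(T: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """List the half-open index ranges of ``spec`` applied to ``T`` samples."""
    return spec.windows(T)


def _sqrt_power_spectrum(x: np.ndarray, tr: float) -> tuple[np.ndarray, np.ndarray]:
    """One-sided amplitude-calibrated sqrt power spectrum along the last axis.

    Returns (freqs, sqrtP) where sqrtP[k] = (2/N)|X_k| for interior bins and
    (1/N)|X_k| at DC and (for even N) Nyquist.
    """
    x = np.asarray(x, dtype=float)
    N = x.shape[-1]
    amp = np.abs(np.fft.rfft(x, axis=-1))
    freqs = np.fft.rfftfreq(N, d=tr)
    scale = np.full(freqs.shape, 2.0 / N)
    scale[0] = 1.0 / N
    if N % 2 == 0:
        scale[-1] = 1.0 / N
    return freqs, amp * scale


def _band_bins(freqs: np.ndarray, band: tuple[float, float]) -> np.ndarray:
    low, high = band
    if not (0 <= low < high):
        raise ValueError("ALFF band must satisfy 0 <= low < high")
    tol = 1e-9 * max(1.0, freqs[-1])
    sel = (freqs >= low - tol) & (freqs <= high + tol)
    if not sel.any():
        raise ValueError(
            f"no DFT bin falls in band [{low}, {high}] Hz; "
            f"bin grid spacing is {freqs[1] - freqs[0]:.6g} Hz over [0, {freqs[-1]:.6g}]")
    return sel


def compute_alff(x: np.ndarray, tr: float,
                 band: tuple[float, float] = DEFAULT_ALFF_BAND) -> np.ndarray:
    """ALFF along the last axis: mean sqrt power over the in-band DFT bins.

    Untapered, FFT length equal to the segment length, band endpoints
    inclusive.  Accepts any leading shape; a 1-D input yields a scalar.
    """
    freqs, sqrtP = _sqrt_power_spectrum(x, tr)
    sel = _band_bins(freqs, band)
    out = sqrtP[..., sel].mean(axis=-1)
    return float(out) if np.ndim(out) == 0 else out


def normalize_malff(alff: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Divide by the global mean ALFF over the included units (mask).

    The masked mean of the result is exactly 1.  All-zero ALFF raises.
    """
    alff = np.asarray(alff, dtype=float)
    mask = np.ones(alff.shape[0], dtype=bool) if mask is None else np.asarray(mask, bool)
    gm = alff[mask].mean(axis=0)
    if np.any(gm <= 0):
        raise ValueError("degenerate global mean ALFF (<= 0); cannot normalise")
    return alff / gm


def aggregate_units_to_roi(values: np.ndarray, unit_roi_ids: np.ndarray,
                           roi_ids: np.ndarray) -> np.ndarray:
    """Unweighted mean of unit values per ROI, in ``roi_ids`` order.

    ``values`` may be (units,) or (units, k).  Units mapping to ids outside
    ``roi_ids`` (e.g. 0 = outside) are dropped; a ROI with no units yields NaN.
    """
    values = np.asarray(values, dtype=float)
    unit_roi_ids = np.asarray(unit_roi_ids, dtype=int)
    frame = pd.DataFrame(values if values.ndim > 1 else values[:, None])
    frame["roi_id"] = unit_roi_ids
    means = frame.groupby("roi_id").mean()
    out = means.reindex(roi_ids).to_numpy()
    return out[:, 0] if values.ndim == 1 else out


def _windowed_view(data: np.ndarray, spec: WindowSpec) -> np.ndarray:
    """(units, n_windows, length) read-only view of the sliding windows."""
    T = data.shape[-1]
    n_win = spec.n_windows(T)
    view = np.lib.stride_tricks.sliding_window_view(data, spec.length, axis=-1)
    return view[..., ::spec.step, :][..., :n_win, :]


def compute_mdalff(series: RoiTimeSeries, atlas: ParcellationAtlas,
                   spec: WindowSpec = WindowSpec(),
                   band: tuple[float, float] = DEFAULT_ALFF_BAND,
                   window_norm: bool = True) -> pd.DataFrame:
    """Sliding-window mdALFF table for one subject.

    Per window: per-unit ALFF on the windowed segment, normalised to mALFF by
    that window's global mean over units inside the (filtered) atlas, then
    averaged into ROIs.  Returns a DataFrame with columns
    ``subject_id, roi_id, mdalff_mean, mdalff_var`` (sample variance across
    windows; exactly 0 when there is a single window).

    With ``window_norm=False`` every window's map is divided by one common
    constant, the across-window mean of the global ALFF, instead of by its own
    window's global mean.
    """
    roi_ids = atlas.roi_ids
    unit_ids = (series.unit_roi_ids if series.unit_roi_ids is not None
                else roi_ids.copy())
    in_atlas = np.isin(unit_ids, roi_ids)
    if not in_atlas.any():
        raise ValueError(f"{series.subject_id}: no unit maps to an atlas ROI")

    segs = _windowed_view(series.data, spec)          # (units, n_win, L)
    try:
        alff = compute_alff(segs, series.tr, band)    # (units, n_win)
    except ValueError as err:
        raise ValueError(f"{series.subject_id}: ALFF failed within windows: {err}") from err

    gm = alff[in_atlas].mean(axis=0)                  # per-window global mean
    if np.any(gm <= 0):
        bad = int(np.flatnonzero(gm <= 0)[0])
        raise ValueError(f"{series.subject_id}: degenerate global mean ALFF in window {bad}")
    malff = alff / gm if window_norm else alff / gm.mean()

    roi_malff = aggregate_units_to_roi(malff, unit_ids, roi_ids)   # (n_roi, n_win)
    n_win = roi_malff.shape[1]
    mean = roi_malff.mean(axis=1)
    var = roi_malff.var(axis=1, ddof=1) if n_win > 1 else np.zeros_like(mean)
    return pd.DataFrame({
        "subject_id": series.subject_id,
        "roi_id": roi_ids,
        "mdalff_mean": mean,
        "mdalff_var": var,
    })


def compute_mdalff_cohort(dataset: CohortDataset, atlas: ParcellationAtlas | None = None,
                          spec: WindowSpec = WindowSpec(),
                          band: tuple[float, float] = DEFAULT_ALFF_BAND,
                          window_norm: bool = True) -> pd.DataFrame:
    """Concatenated mdALFF tables for every subject in the cohort."""
    atlas = atlas or dataset.atlas
    parts = [compute_mdalff(dataset.series[sid], atlas, spec, band, window_norm)
             for sid in dataset.phenotypes["subject_id"]]
    return pd.concat(parts, ignore_index=True)


def _standardize_windows(segs: np.ndarray, subject_id: str) -> np.ndarray:
    """Z-score each (unit, window) segment along time; zero variance raises."""
    mu = segs.mean(axis=-1, keepdims=True)
    sd = segs.std(axis=-1, keepdims=True)
    bad = np.nonzero(sd[..., 0] == 0)
    if bad[0].size:
        u, w = int(bad[0][0]), int(bad[1][0])
        raise ValueError(f"{subject_id}: zero-variance segment at unit {u}, window {w}")
    return (segs - mu) / sd


def compute_dfc_seed(series: RoiTimeSeries, seed_roi: int, atlas: ParcellationAtlas,
                     spec: WindowSpec = WindowSpec()) -> pd.DataFrame:
    """Seed-to-whole-brain dynamic connectivity for one subject.

    Per window, Pearson correlation between the seed ROI's series and every
    other atlas ROI; correlations are clipped to |r| <= 1 - 1e-7 and
    Fisher-Z transformed.  Returns columns ``subject_id, seed_roi,
    target_roi, dfc_mean, dfc_var`` (Z-scale mean and sample variance across
    windows); the seed-to-seed row is excluded.
    """
    roi_ids = atlas.roi_ids
    if seed_roi not in roi_ids:
        raise ValueError(f"seed ROI {seed_roi} not in atlas")
    unit_ids = (series.unit_roi_ids if series.unit_roi_ids is not None
                else roi_ids.copy())
    # ROI-mean series in atlas order
    roi_data = aggregate_units_to_roi(series.data, unit_ids, roi_ids)
    if np.isnan(roi_data).any():
        empty = roi_ids[np.isnan(roi_data).any(axis=1)]
        raise ValueError(f"{series.subject_id}: ROIs with no units: {list(empty)}")

    segs = _windowed_view(roi_data, spec)             # (n_roi, n_win, L)
    z = _standardize_windows(segs, series.subject_id)
    seed_pos = int(np.flatnonzero(roi_ids == seed_roi)[0])
    r = (z * z[seed_pos][None]).mean(axis=-1)         # (n_roi, n_win) Pearson r
    r = np.clip(r, -1 + FISHER_CLIP, 1 - FISHER_CLIP)
    zfc = np.arctanh(r)
    n_win = zfc.shape[1]
    mean = zfc.mean(axis=1)
    var = zfc.var(axis=1, ddof=1) if n_win > 1 else np.zeros_like(mean)
    out = pd.DataFrame({
        "subject_id": series.subject_id,
        "seed_roi": seed_roi,
        "target_roi": roi_ids,
        "dfc_mean": mean,
        "dfc_var": var,
    })
    return out[out["target_roi"] != seed_roi].reset_index(drop=True)


def compute_dfc_cohort(dataset: CohortDataset, seeds: list[int],
                       atlas: ParcellationAtlas | None = None,
                       spec: WindowSpec = WindowSpec()) -> pd.DataFrame:
    """Seed dFC tables for every subject and every seed ROI."""
    atlas = atlas or dataset.atlas
    parts = [compute_dfc_seed(dataset.series[sid], seed, atlas, spec)
             for sid in dataset.phenotypes["subject_id"] for seed in seeds]
    return pd.concat(parts, ignore_index=True)
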