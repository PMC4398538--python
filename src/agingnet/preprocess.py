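"""Resting-state BOLD signal conditioning before network construction.

The conditioning chain applied to each subject is:

1. band-pass filtering to the low-frequency resting-state band (0.01-0.08 Hz),
2. grand-mean scaling of the whole panel to a fixed global level of 100,
3. removal of nuisance signals (motion parameters, ventricular and
   white-matter means) by least-squares regression, the nuisance signals
   themselves having been passed through the same filter and scaling,
4. averaging voxel series into atlas ROIs.

"Grand mean scaling to a modal value of 100" is implemented as *global mean*
= 100: the mode of a continuous signal is ill-defined and Pearson
correlations are invariant to any single-scalar rescaling, so the choice
cannot affect the networks.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from .atlas import Atlas

#: Label value marking voxels outside every ROI.
BACKGROUND_LABEL = -1


@dataclass(frozen=True)
class TimeSeriesPanel:
    """One subject's T x R matrix of time series plus its repetition time.

    ``missing_series`` flags columns that carry no data (e.g. an ROI with no
    voxels after aggregation); such columns are NaN-filled and must be refused
    by any downstream correlation.
    """

    data: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    missing_series: np.ndarray = field(default=None)  # bool per column

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 2:
            raise ValueError("panel data must be 2-D (timepoints x series)")
        if data.shape[0] < 8:
            raise ValueError(f"need at least 8 timepoints, got {data.shape[0]}")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        missing = self.missing_series
        if missing is None:
            missing = np.zeros(data.shape[1], dtype=bool)
        else:
            missing = np.asarray(missing, dtype=bool)
            if missing.shape != (data.shape[1],):
                raise ValueError("missing_series must have one flag per column")
        if np.isnan(data[:, ~missing]).any():
            raise ValueError("panel contains missing values in non-flagged series")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "missing_series", missing)

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_series(self) -> int:
        return self.data.shape[1]

    @property
    def sampling_hz(self) -> float:
        return 1.0 / self.tr_seconds

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.tr_seconds


@dataclass(frozen=True)
class NuisanceSet:
    """T x K matrix of per-timepoint nuisance regressors (no intercept)."""

    data: np.ndarray
    subject_id: str = ""
    names: tuple[str, ...] | None = None

    def __post_init__(self):
        data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if data.ndim != 2 or data.shape[1] < 1:
            raise ValueError("nuisance data must be T x K with K >= 1")
        if np.isnan(data).any():
            raise ValueError("nuisance regressors contain missing values")
        object.__setattr__(self, "data", data)
        if self.names is not None and len(self.names) != data.shape[1]:
            raise ValueError("one name per nuisance column required")


def _butter_sos(low_hz: float, high_hz: float, fs: float, order: int):
    if low_hz > 0.0:
        return signal.butter(order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos")
    return signal.butter(order, high_hz, btype="lowpass", fs=fs, output="sos")


def bandpass(
    panel: TimeSeriesPanel,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    order: int = 4,
    method: str = "butterworth",
) -> TimeSeriesPanel:
    """Zero-phase band-pass filter every series identically.

    ``method="butterworth"`` (default) applies a forward-backward Butterworth
    filter of the given order; ``method="fft"`` applies an ideal brick-wall
    filter in the discrete Fourier domain.  Both remove the DC component
    whenever ``low_hz > 0``.
    """
    if not (0.0 <= low_hz < high_hz):
        raise ValueError(f"need 0 <= low_hz < high_hz, got ({low_hz}, {high_hz})")
    if high_hz > panel.nyquist_hz:
        raise ValueError(
            f"high_hz={high_hz} Hz exceeds Nyquist {panel.nyquist_hz:.4g} Hz "
            f"for tr={panel.tr_seconds} s"
        )
    x = panel.data
    if method == "fft":
        freqs = np.fft.rfftfreq(panel.n_timepoints, d=panel.tr_seconds)
        spec = np.fft.rfft(x, axis=0)
        keep = (freqs >= low_hz) & (freqs <= high_hz)
        spec[~keep, :] = 0.0
        out = np.fft.irfft(spec, n=panel.n_timepoints, axis=0)
    elif method == "butterworth":
        sos = _butter_sos(low_hz, high_hz, panel.sampling_hz, order)
        padlen = 3 * (2 * sos.shape[0] + 1)
        if panel.n_timepoints <= padlen:
            raise ValueError(
                f"T={panel.n_timepoints} too short for order-{order} zero-phase "
                f"filtering (needs > {padlen} timepoints)"
            )
        out = signal.sosfiltfilt(sos, x, axis=0)
    else:
        raise ValueError(f"unknown band-pass method {method!r}")
    return replace(panel, data=out)


def grand_mean_scale(panel: TimeSeriesPanel, target: float = 100.0) -> TimeSeriesPanel:
    """Multiply the whole panel by one scalar so its global mean equals ``target``."""
    valid = panel.data[:, ~panel.missing_series]
    mean = float(valid.mean())
    scale = float(np.abs(valid).max()) if valid.size else 0.0
    if abs(mean) <= 1e-12 * max(scale, 1.0) or not np.isfinite(mean):
        raise ValueError("grand-mean scaling undefined: global mean is zero")
    return replace(panel, data=panel.data * (target / mean))


def regress_out(panel: TimeSeriesPanel, nuisance: NuisanceSet) -> TimeSeriesPanel:
    """Residualize every series on [intercept, nuisance columns] by least squares.

    Residuals are exactly orthogonal to the intercept and every nuisance
    column.  A rank-deficient design is refused with the offending columns
    named.
    """
    z = nuisance.data
    if z.shape[0] != panel.n_timepoints:
        raise ValueError(
            f"nuisance has {z.shape[0]} timepoints but panel has {panel.n_timepoints}"
        )
    design = np.column_stack([np.ones(panel.n_timepoints), z])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        names = nuisance.names or tuple(f"col{j}" for j in range(z.shape[1]))
        # identify columns whose removal restores full rank
        bad = [
            names[j]
            for j in range(z.shape[1])
            if np.linalg.matrix_rank(np.delete(design, j + 1, axis=1)) == rank
        ]
        raise ValueError(f"nuisance design is rank deficient; collinear columns: {bad}")
    coef, *_ = np.linalg.lstsq(design, panel.data, rcond=None)
    resid = panel.data - design @ coef
    return replace(panel, data=resid)


def aggregate_voxels(
    voxel_panel: TimeSeriesPanel, labels, atlas: Atlas
) -> TimeSeriesPanel:
    """Average voxel series into one series per atlas region.

    ``labels`` assigns each voxel column an atlas region index, or
    ``BACKGROUND_LABEL`` for voxels outside every ROI.  Regions with no voxels
    are flagged missing (NaN series), not fatal.
    """
    labels = np.asarray(labels, dtype=int)
    if labels.shape != (voxel_panel.n_series,):
        raise ValueError("one label per voxel column required")
    valid = (labels >= 0) & (labels < atlas.n_regions)
    if not (valid | (labels == BACKGROUND_LABEL)).all():
        bad = sorted(set(labels[~(valid | (labels == BACKGROUND_LABEL))]))
        raise ValueError(f"labels outside atlas range: {bad}")
    T = voxel_panel.n_timepoints
    out = np.full((T, atlas.n_regions), np.nan)
    missing = np.ones(atlas.n_regions, dtype=bool)
    for idx in range(atlas.n_regions):
        cols = labels == idx
        if cols.any():
            out[:, idx] = voxel_panel.data[:, cols].mean(axis=1)
            missing[idx] = False
    return TimeSeriesPanel(
        data=out,
        tr_seconds=voxel_panel.tr_seconds,
        subject_id=voxel_panel.subject_id,
        missing_series=missing,
    )


def preprocess_panel(
    panel: TimeSeriesPanel,
    nuisance: NuisanceSet | None = None,
    low_hz: float = 0.01,
    high_hz: float = 0.08,
    target: float = 100.0,
    method: str = "butterworth",
) -> TimeSeriesPanel:
    """Full conditioning chain: band-pass, grand-mean scale, nuisance regression.

    The nuisance regressors are band-pass filtered with the same filter before
    removal, so that out-of-band nuisance energy cannot be reintroduced.
    Grand-mean scaling is skipped when the filtered panel has zero global mean
    (a high-pass filter removes the mean, making the rescale undefined and,
    for correlations, irrelevant).
    """
    out = bandpass(panel, low_hz, high_hz, method=method)
    if abs(float(out.data.mean())) > 1e-9 * float(np.abs(out.data).mean() + 1e-300):
        out = grand_mean_scale(out, target)
    if nuisance is not None:
        filt_n = bandpass(
            TimeSeriesPanel(nuisance.data, panel.tr_seconds, panel.subject_id),
            low_hz,
            high_hz,
            method=method,
        )
        keep = filt_n.data.std(axis=0) > 1e-12  # drop regressors the filter nulled
        if keep.any():
            out = regress_out(out, NuisanceSet(filt_n.data[:, keep], panel.subject_id))
    return out
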