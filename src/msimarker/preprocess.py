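"""Spectrum normalization and aligned peak-matrix construction.

The processing mirrors a standard MSI segmentation pipeline: every pixel
spectrum is TIC-normalized, peaks are found on the Gaussian-smoothed dataset
mean spectrum and aligned onto a common grid of fixed-width m/z intervals
(0.3 Da by default), and each matrix entry is the maximal normalized
intensity of a pixel inside an interval ("maximal interval" mode).  Peak
picking uses the smoothed mean spectrum only; per-pixel intensities are
read from the unsmoothed spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .core import Feature, MSIDataset, PeakMatrix, Spectrum, concat_meta

__all__ = ["PreprocessConfig", "tic_normalize", "mean_spectrum", "pick_peaks",
           "build_peak_matrix", "run"]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunables for normalization and peak picking.

    interval_width
        Full width (Da) of each aligned m/z interval.
    tic_target
        Post-normalization sum of intensities per spectrum.
    smoothing_sigma
        Gaussian sigma, in axis bins, applied to the mean spectrum before
        maxima detection (never to per-pixel spectra).
    min_peak_prominence
        Detection threshold as a fraction of the smoothed mean spectrum's
        maximum.
    """

    interval_width: float = 0.3
    tic_target: float = 1.0
    smoothing_sigma: float = 0.75
    min_peak_prominence: float = 0.005

    def __post_init__(self) -> None:
        if self.interval_width <= 0:
            raise ValueError("interval_width must be positive")
        if self.smoothing_sigma < 0:
            raise ValueError("smoothing_sigma must be >= 0")
        if self.tic_target <= 0:
            raise ValueError("tic_target must be positive")


def tic_normalize(spectrum: Spectrum, target: float = 1.0, *, pixel: str = "?") -> Spectrum:
    """Scale a spectrum so its total ion count equals ``target``.

    Raises ``ValueError`` (naming the pixel) for an all-zero spectrum.
    """
    total = spectrum.tic
    if total <= 0:
        raise ValueError(f"cannot TIC-normalize all-zero spectrum at pixel {pixel}")
    return Spectrum(spectrum.mz, spectrum.intensity * (target / total))


def _normalized_matrix(dataset: MSIDataset, target: float) -> np.ndarray:
    X = dataset.intensity_matrix()
    totals = X.sum(axis=1)
    bad = np.flatnonzero(totals <= 0)
    if bad.size:
        x, y = dataset.coordinates[bad[0]]
        raise ValueError(
            f"cannot TIC-normalize all-zero spectrum at pixel "
            f"{dataset.section_id}:({x},{y})"
        )
    return X * (target / totals)[:, None]


def _common_axis(datasets: Sequence[MSIDataset]) -> np.ndarray:
    if not datasets:
        raise ValueError("at least one dataset required")
    axis = datasets[0].shared_axis
    if axis is None:
        raise ValueError("datasets must share a common m/z axis for alignment")
    for ds in datasets[1:]:
        other = ds.shared_axis
        if other is None or not np.array_equal(other, axis):
            raise ValueError("all sections must share the same m/z axis")
    return axis


def mean_spectrum(datasets: Sequence[MSIDataset], config: PreprocessConfig = PreprocessConfig()) -> Spectrum:
    """Mean of all TIC-normalized pixel spectra across sections."""
    axis = _common_axis(datasets)
    total = np.zeros(axis.size)
    n = 0
    for ds in datasets:
        X = _normalized_matrix(ds, config.tic_target)
        total += X.sum(axis=0)
        n += X.shape[0]
    if n == 0:
        raise ValueError("no spectra in input")
    return Spectrum(axis, total / n)


def pick_peaks(datasets: Sequence[MSIDataset], config: PreprocessConfig = PreprocessConfig()) -> list[Feature]:
    """Detect aligned features on the smoothed mean spectrum.

    Local maxima of the smoothed mean spectrum whose prominence exceeds
    ``min_peak_prominence`` x max become features; each receives an interval
    of full width ``interval_width`` centered on the apex.  When two apexes
    are closer than one interval width the higher apex wins (ties: lower
    m/z).  The returned feature list is sorted by center m/z and its
    intervals never overlap.
    """
    mean = mean_spectrum(datasets, config)
    smoothed = (gaussian_filter1d(mean.intensity, config.smoothing_sigma)
                if config.smoothing_sigma > 0 else mean.intensity)
    top = smoothed.max() if smoothed.size else 0.0
    if top <= 0:
        return []
    idx, _ = find_peaks(smoothed, prominence=config.min_peak_prominence * top)
    if idx.size == 0:
        return []
    # greedy conflict resolution: strongest apex first, drop anything within
    # one interval width of an accepted apex
    order = sorted(range(idx.size), key=lambda k: (-smoothed[idx[k]], mean.mz[idx[k]]))
    accepted: list[float] = []
    for k in order:
        center = float(mean.mz[idx[k]])
        if all(abs(center - c) >= config.interval_width for c in accepted):
            accepted.append(center)
    hw = config.interval_width / 2.0
    return [Feature(c, hw) for c in sorted(accepted)]


def build_peak_matrix(
    datasets: Sequence[MSIDataset],
    features: Sequence[Feature],
    config: PreprocessConfig = PreprocessConfig(),
) -> PeakMatrix:
    """Extract the spectra-by-feature table of maximal interval intensities.

    Entry (i, j) is the maximum TIC-normalized intensity of spectrum i
    within feature j's interval.  A feature interval falling outside the
    m/z axis yields 0 with a single warning.
    """
    axis = _common_axis(datasets)
    lo = np.searchsorted(axis, [f.low for f in features], side="left")
    hi = np.searchsorted(axis, [f.high for f in features], side="right")
    empty = np.flatnonzero(lo >= hi)
    for j in empty:
        warnings.warn(
            f"feature {features[j].center_mz:.3f} has no axis points in range; intensity 0",
            stacklevel=2,
        )
    blocks = []
    for ds in datasets:
        X = _normalized_matrix(ds, config.tic_target)
        M = np.zeros((X.shape[0], len(features)))
        for j, (a, b) in enumerate(zip(lo, hi)):
            if a < b:
                M[:, j] = X[:, a:b].max(axis=1)
        blocks.append(M)
    return PeakMatrix(list(features), np.vstack(blocks), concat_meta(datasets))


def run(datasets: Sequence[MSIDataset], config: PreprocessConfig = PreprocessConfig()) -> PeakMatrix:
    """Convenience: pick peaks then build the matrix in one call."""
    return build_peak_matrix(datasets, pick_peaks(datasets, config), config)
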