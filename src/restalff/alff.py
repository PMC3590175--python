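"""Amplitude of low-frequency fluctuation (ALFF) maps.

ALFF summarizes the intensity of spontaneous BOLD fluctuations at a voxel:
the time series is Fourier transformed, the square root of the power
spectrum (i.e. the amplitude) is taken at each frequency, and the
amplitudes are averaged over the low-frequency band (default 0.01-0.08 Hz).
Dividing each voxel by the whole-brain mean ALFF yields the standardized
map (mALFF) that is comparable across subjects.

Amplitude convention: the single-sided amplitude at bin ``k`` is
``(2/T)*|X_k|`` for ``0 < k < T/2``, so a unit-amplitude sinusoid sitting
exactly on a bin has amplitude 1.  Any fixed convention cancels under
global-mean standardization; this one makes the numbers interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import band_bin_mask

__all__ = [
    "AlffMap",
    "alff_voxel",
    "alff_map",
    "standardize_alff",
    "regional_mean_alff",
]


@dataclass
class AlffMap:
    """A 3D ALFF (or standardized ALFF) map over a brain mask."""

    values: np.ndarray
    mask: np.ndarray
    band_hz: tuple[float, float]
    standardized: bool = False
    affine: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask shapes differ")


def _band_amplitudes(x: np.ndarray, tr_s: float, band_hz: tuple[float, float]) -> np.ndarray:
    """Single-sided amplitudes (2/T)|X_k| at the in-band bins (last axis)."""
    x = np.asarray(x, dtype=float)
    t_len = x.shape[-1]
    keep = band_bin_mask(t_len, tr_s, band_hz)
    keep = keep.copy()
    keep[0] = False  # DC never contributes
    if t_len % 2 == 0:
        keep[-1] = False  # Nyquist bin has no mirrored partner
    if not keep.any():
        raise ValueError(
            f"band {band_hz} contains no DFT bins for T={t_len}, TR={tr_s}"
        )
    spec = np.fft.rfft(x, axis=-1)
    return (2.0 / t_len) * np.abs(spec[..., keep])


def alff_voxel(timeseries: np.ndarray, tr_s: float, band_hz: tuple[float, float] = (0.01, 0.08)) -> float:
    """ALFF of a single time series: mean single-sided amplitude in band."""
    x = np.asarray(timeseries, dtype=float)
    if x.ndim != 1:
        raise ValueError("alff_voxel expects a 1D time series")
    if x.size < 16:
        raise ValueError("time series too short for a meaningful spectrum")
    return float(_band_amplitudes(x, tr_s, band_hz).mean())


def alff_map(
    series4d: np.ndarray,
    mask: np.ndarray,
    tr_s: float,
    band_hz: tuple[float, float] = (0.01, 0.08),
    affine: np.ndarray | None = None,
) -> AlffMap:
    """Voxel-wise ALFF over a mask; voxels outside the mask are 0."""
    data = np.asarray(series4d, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if data.ndim != 4 or data.shape[:3] != mask.shape:
        raise ValueError(
            f"series shape {data.shape} incompatible with mask {mask.shape}"
        )
    values = np.zeros(mask.shape, dtype=float)
    amps = _band_amplitudes(data[mask], tr_s, band_hz)
    values[mask] = amps.mean(axis=-1)
    return AlffMap(values=values, mask=mask, band_hz=band_hz, affine=affine)


def standardize_alff(amap: AlffMap) -> AlffMap:
    """Divide every in-mask voxel by the in-mask mean (mALFF)."""
    mean = float(amap.values[amap.mask].mean())
    if not np.isfinite(mean) or mean <= 0:
        raise ValueError(f"in-mask mean ALFF must be positive, got {mean}")
    values = np.zeros_like(amap.values)
    values[amap.mask] = amap.values[amap.mask] / mean
    return AlffMap(
        values=values,
        mask=amap.mask,
        band_hz=amap.band_hz,
        standardized=True,
        affine=amap.affine,
    )


def regional_mean_alff(amap: AlffMap, roi_voxels: np.ndarray) -> float:
    """Mean (standardized) ALFF over an ROI given as an (n, 3) index array
    or a 3D boolean mask; the ROI must be non-empty and inside the mask."""
    roi = np.asarray(roi_voxels)
    if roi.ndim == 3:
        roi_mask = roi.astype(bool)
    else:
        if roi.size == 0:
            raise ValueError("empty ROI")
        roi_mask = np.zeros(amap.mask.shape, dtype=bool)
        roi_mask[tuple(roi.T)] = True
    if not roi_mask.any():
        raise ValueError("empty ROI")
    if (roi_mask & ~amap.mask).any():
        raise ValueError("ROI extends outside the brain mask")
    return float(amap.values[roi_mask].mean())
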