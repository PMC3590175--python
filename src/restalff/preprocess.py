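"""Temporal and spatial preprocessing of aligned 4D BOLD series.

The stages mirror a classic resting-state ALFF pipeline operating on data
already resampled to a common grid: discard initial non-equilibrium volumes,
screen subjects for excessive head motion, smooth spatially with a Gaussian
kernel, remove per-voxel linear trends, and band-pass filter to the
low-frequency band of interest (default 0.01-0.08 Hz).

The band-pass filter is an ideal (brick-wall) frequency-domain filter:
DFT coefficients whose frequency falls inside the closed band are kept,
everything else -- including the DC component -- is zeroed.  This makes the
band edges exact and the filter idempotent, and it matches the band-bin
convention used by :mod:`restalff.alff`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "PreprocessParams",
    "MotionScreenResult",
    "discard_initial_volumes",
    "screen_motion",
    "spatial_smooth",
    "detrend_linear",
    "bandpass_filter",
    "band_bin_mask",
    "fwhm_to_sigma",
    "preprocess_series",
]

# Absolute tolerance (Hz) when deciding whether a DFT bin frequency lies on a
# band edge; guards against 1-ulp differences between k/(T*TR) and a band
# edge given as a decimal literal.
_FREQ_TOL = 1e-9


@dataclass(frozen=True)
class PreprocessParams:
    """Parameters of the preprocessing chain.

    Attributes
    ----------
    n_discard : int
        Number of initial volumes dropped before analysis (magnetization
        equilibration), default 5.
    max_translation_mm, max_rotation_deg : float
        Subject-level motion screen: a subject fails if any translation
        column exceeds ``max_translation_mm`` (mm) or any rotation column
        exceeds ``max_rotation_deg`` (degrees) in absolute value at any
        frame.  The comparison is strict ("greater than"), so a trace that
        touches the limit exactly still passes.
    fwhm_mm : float
        Full width at half maximum of the isotropic Gaussian smoothing
        kernel, in millimetres.
    band_hz : tuple of float
        Pass band (low, high) in Hz of the temporal filter.
    smooth_mode : str
        Boundary mode handed to the Gaussian filter ("nearest" replicates
        edge voxels, avoiding rim attenuation in small volumes).
    """

    n_discard: int = 5
    max_translation_mm: float = 1.0
    max_rotation_deg: float = 1.0
    fwhm_mm: float = 8.0
    band_hz: tuple[float, float] = (0.01, 0.08)
    smooth_mode: str = "nearest"

    def validate(self, tr_s: float) -> None:
        low, high = self.band_hz
        nyquist = 1.0 / (2.0 * tr_s)
        if not (0.0 < low < high <= nyquist + _FREQ_TOL):
            raise ValueError(
                f"band {self.band_hz} must satisfy 0 < low < high <= "
                f"Nyquist ({nyquist:g} Hz at TR {tr_s:g} s)"
            )


@dataclass(frozen=True)
class MotionScreenResult:
    passed: bool
    offending_frames: tuple[int, ...]

    def __bool__(self) -> bool:  # allows `if screen_motion(...)`
        return self.passed


def discard_initial_volumes(series: np.ndarray, n_discard: int) -> np.ndarray:
    """Drop the first ``n_discard`` frames of a series (time on last axis).

    Works on 1D time series and on 4D volumes alike.
    """
    if n_discard < 0:
        raise ValueError("n_discard must be non-negative")
    n_frames = series.shape[-1]
    if n_frames <= n_discard:
        raise ValueError(
            f"series has {n_frames} frames, cannot discard {n_discard}"
        )
    return series[..., n_discard:]


def screen_motion(
    motion_trace: np.ndarray,
    params: PreprocessParams | None = None,
    *,
    max_translation_mm: float | None = None,
    max_rotation_deg: float | None = None,
) -> MotionScreenResult:
    """Subject-level motion screen on a T x 6 rigid-body trace.

    Columns 0-2 are translations (mm), columns 3-5 rotations (degrees).
    The subject fails iff any translation exceeds the translation limit or
    any rotation exceeds the rotation limit in absolute value (strictly);
    the indices of all offending frames are returned.
    """
    if params is None:
        params = PreprocessParams()
    t_lim = params.max_translation_mm if max_translation_mm is None else max_translation_mm
    r_lim = params.max_rotation_deg if max_rotation_deg is None else max_rotation_deg

    trace = np.asarray(motion_trace, dtype=float)
    if trace.ndim != 2 or trace.shape[1] != 6:
        raise ValueError(
            f"motion trace must have 6 columns (3 translations mm, "
            f"3 rotations deg); got shape {trace.shape}"
        )
    bad = (np.abs(trace[:, :3]) > t_lim).any(axis=1) | (
        np.abs(trace[:, 3:]) > r_lim
    ).any(axis=1)
    offending = tuple(int(i) for i in np.flatnonzero(bad))
    return MotionScreenResult(passed=not offending, offending_frames=offending)


def fwhm_to_sigma(fwhm_mm: float, voxel_size_mm: float) -> float:
    """Gaussian sigma in voxels for a given FWHM in mm."""
    return fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size_mm


def spatial_smooth(
    series: np.ndarray,
    fwhm_mm: float,
    voxel_size_mm: float,
    mode: str = "nearest",
) -> np.ndarray:
    """Smooth each frame with an isotropic Gaussian kernel.

    ``series`` may be a 3D volume or a 4D (X, Y, Z, T) stack; in the 4D
    case the time axis is left untouched.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return np.array(series, dtype=float, copy=True)
    sigma_vox = fwhm_to_sigma(fwhm_mm, voxel_size_mm)
    data = np.asarray(series, dtype=float)
    if data.ndim == 3:
        sigma = (sigma_vox,) * 3
    elif data.ndim == 4:
        sigma = (sigma_vox, sigma_vox, sigma_vox, 0.0)
    else:
        raise ValueError("expected a 3D volume or 4D series")
    return ndimage.gaussian_filter(data, sigma=sigma, mode=mode)


def detrend_linear(timeseries: np.ndarray) -> np.ndarray:
    """Remove the least-squares line (intercept + slope) from each series.

    Accepts a 1D series or an (n_series, T) matrix; the residuals are
    orthogonal to both the constant and the linear ramp.
    """
    x = np.asarray(timeseries, dtype=float)
    t_len = x.shape[-1]
    if t_len < 3:
        raise ValueError("need at least 3 time points to detrend")
    t = np.arange(t_len, dtype=float)
    design = np.column_stack([np.ones(t_len), t])
    coef, *_ = np.linalg.lstsq(design, x.reshape(-1, t_len).T, rcond=None)
    resid = x.reshape(-1, t_len) - (design @ coef).T
    return resid.reshape(x.shape)


def band_bin_mask(n_frames: int, tr_s: float, band_hz: tuple[float, float]) -> np.ndarray:
    """Boolean mask over rfft bins whose frequency lies in the closed band.

    The DC bin is always excluded (band low must be > 0).
    """
    low, high = band_hz
    nyquist = 1.0 / (2.0 * tr_s)
    if not (0.0 < low < high <= nyquist + _FREQ_TOL):
        raise ValueError(
            f"band {band_hz} outside (0, Nyquist={nyquist:g}] at TR {tr_s:g} s"
        )
    freqs = np.fft.rfftfreq(n_frames, d=tr_s)
    return (freqs >= low - _FREQ_TOL) & (freqs <= high + _FREQ_TOL)


def bandpass_filter(
    timeseries: np.ndarray, band_hz: tuple[float, float], tr_s: float
) -> np.ndarray:
    """Ideal frequency-domain band-pass filter (real input -> real output).

    DFT coefficients with frequency in ``[low, high]`` inclusive are kept,
    all others (including DC) are zeroed.  Accepts a 1D series or any array
    with time on the last axis.
    """
    x = np.asarray(timeseries, dtype=float)
    t_len = x.shape[-1]
    keep = band_bin_mask(t_len, tr_s, band_hz)
    spec = np.fft.rfft(x, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=t_len, axis=-1)


def preprocess_series(
    series4d: np.ndarray,
    tr_s: float,
    voxel_size_mm: float,
    params: PreprocessParams | None = None,
) -> np.ndarray:
    """Full temporal/spatial chain: discard -> smooth -> detrend -> filter.

    Motion screening is a separate, subject-level decision
    (:func:`screen_motion`) and is not applied here.
    """
    if params is None:
        params = PreprocessParams()
    params.validate(tr_s)
    out = discard_initial_volumes(series4d, params.n_discard)
    out = spatial_smooth(out, params.fwhm_mm, voxel_size_mm, mode=params.smooth_mode)
    out = detrend_linear(out.reshape(-1, out.shape[-1])).reshape(out.shape)
    out = bandpass_filter(out, params.band_hz, tr_s)
    return out
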