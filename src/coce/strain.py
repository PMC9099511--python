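"""Interframe axial strain from phase variations (vector method).

The local axial gradient of the interframe phase difference is proportional
to the interframe axial strain.  Rather than unwrapping the phase, the
vector method forms axial-lag conjugate products of the interframe
phase-difference map and complex-averages them over a small window before
taking the angle: amplitude weighting suppresses low-signal speckle pixels
and the averaging happens on the unit circle, so no explicit unwrapping is
needed.  With the axial pitch expressed in air-equivalent optical depth the
conversion from phase slope to strain is refractive-index free:

    strain = angle(<d>) * lambda0 / (4 * pi * pixel_z)
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .series import AcquisitionMetadata, BScanSeries

__all__ = [
    "StrainField",
    "StrainStack",
    "interframe_product",
    "vector_strain",
    "accumulate_strain",
    "window_px",
]

log = logging.getLogger(__name__)

#: Default processing-window side (geometric µm in tissue); the mapping
#: resolution is about half of this.
DEFAULT_WINDOW_UM = 96.0

#: fraction of pi beyond which an interframe phase step is flagged as at
#: risk of wrapping
_WRAP_FLAG_FRAC = 0.95


@dataclass
class StrainField:
    """Axial strain map on the B-scan pixel grid.

    ``kind`` is ``"interframe"`` or ``"cumulative"``; ``quality`` is the
    vector-averaging magnitude ratio ``|<d>| / <|d|>`` in [0, 1] (1 for a
    perfectly coherent window) and carries the wrap flags as zeros.
    """

    values: np.ndarray
    kind: str
    frame_index: int
    quality: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("interframe", "cumulative"):
            raise ValueError("kind must be 'interframe' or 'cumulative'")
        if self.quality is not None and (
            np.nanmin(self.quality) < -1e-9 or np.nanmax(self.quality) > 1 + 1e-9
        ):
            raise ValueError("quality must lie in [0, 1]")


@dataclass
class StrainStack:
    """All strain maps of a series: interframe, cumulative, and quality."""

    interframe: np.ndarray  # (F-1, Z, X)
    cumulative: np.ndarray  # (F, Z, X), cumulative[0] == 0
    quality: np.ndarray  # (F-1, Z, X)
    meta: AcquisitionMetadata


def window_px(window_um: float | tuple[float, float], meta: AcquisitionMetadata) -> tuple[int, int]:
    """Convert a (geometric, in-tissue) window size in µm to pixel counts."""
    if np.isscalar(window_um):
        wz_um = wx_um = float(window_um)
    else:
        wz_um, wx_um = map(float, window_um)
    wz = max(int(round(wz_um * meta.n_tissue / meta.pixel_z_um)), 2)
    wx = max(int(round(wx_um / meta.pixel_x_um)), 2)
    return wz, wx


def interframe_product(frame_a: np.ndarray, frame_b: np.ndarray) -> np.ndarray:
    """Pixelwise ``b * conj(a)``; its argument is the interframe phase change."""
    frame_a = np.asarray(frame_a)
    frame_b = np.asarray(frame_b)
    if frame_a.shape != frame_b.shape:
        raise ValueError(f"frame shapes differ: {frame_a.shape} vs {frame_b.shape}")
    return frame_b * np.conj(frame_a)


def _box_sum(arr: np.ndarray, size: tuple[int, int]) -> np.ndarray:
    """Truncated-window box sum (edges use the part of the window inside)."""
    if np.iscomplexobj(arr):
        return _box_sum(arr.real, size) + 1j * _box_sum(arr.imag, size)
    n = size[0] * size[1]
    return ndimage.uniform_filter(arr, size=size, mode="constant", cval=0.0) * n


def _lag_slope(product: np.ndarray, lag: int, size: tuple[int, int]) -> np.ndarray:
    """Windowed phase slope (rad/px) from axial-lag-``lag`` conjugate products.

    The lag-``lag`` product row ``i`` spans rows ``i .. i+lag``; the result is
    re-centred onto the lag-1 grid (between rows ``z`` and ``z+1``) by an
    integer shift with edge padding.
    """
    d = product[lag:, :] * np.conj(product[:-lag, :])
    slope = np.angle(_box_sum(d, size)) / lag
    shift = (lag - 1) // 2
    pad_lo = np.repeat(slope[:1, :], shift, axis=0)
    pad_hi = np.repeat(slope[-1:, :], lag - 1 - shift, axis=0)
    return np.vstack([pad_lo, slope, pad_hi])


def vector_strain(
    product: np.ndarray,
    window_um: float | tuple[float, float],
    meta: AcquisitionMetadata,
    frame_index: int = 0,
    max_lag: int | None = None,
) -> StrainField:
    """Estimate the interframe strain map from an interframe product map.

    Axial-lag conjugate products ``d(z, x) = P(z+lag, x) * conj(P(z, x))``
    are complex-averaged over the window (weights are the product
    magnitudes, implicit in summing ``d`` itself) before the angle is
    extracted.  Lag 1 always provides the wrap-safe base estimate, the
    quality metric and the wrap flags; where the lag-1 phase ramp leaves
    headroom below the wrapping bound, longer lags (2, 4, ... up to
    ``max_lag``, default half the axial window) refine the estimate, since
    an ``L``-pixel lag multiplies the phase signal by ``L`` at constant
    phase noise.  Edge pixels use truncated windows; the last image row
    repeats the previous estimate so the output stays on the full grid.
    """
    product = np.asarray(product)
    if product.ndim != 2:
        raise ValueError("product must be a 2D map")
    wz, wx = window_px(window_um, meta)
    if wz > product.shape[0] - 1 or wx > product.shape[1]:
        raise ValueError(
            f"window {wz}x{wx} px does not fit the {product.shape} map"
        )
    if max_lag is None:
        max_lag = max(wz // 2, 1)
    d = product[1:, :] * np.conj(product[:-1, :])
    num = _box_sum(d, (wz, wx))
    den = _box_sum(np.abs(d), (wz, wx))
    with np.errstate(invalid="ignore", divide="ignore"):
        quality = np.where(den > 0, np.abs(num) / np.where(den > 0, den, 1.0), 0.0)
    quality = np.clip(quality, 0.0, 1.0)
    phase_slope = np.angle(num)  # rad per axial pixel, lag-1 base estimate

    lags = [lag for lag in (2, 4, 8, 16) if lag <= max_lag and lag < product.shape[0]]
    if lags:
        abs_slope = np.abs(phase_slope)
        refined = phase_slope.copy()
        for lag in lags:
            # headroom margin keeps the lagged phase well below +-pi even
            # with noise on the base estimate
            safe = lag * abs_slope < 0.7 * np.pi
            refined = np.where(safe, _lag_slope(product, lag, (wz, wx)), refined)
        phase_slope = refined
    strain = phase_slope * meta.lambda0_um / (4.0 * np.pi * meta.pixel_z_um)

    # wrap-risk flags: single-pixel axial phase steps close to +-pi
    wrapped = np.abs(np.angle(d)) >= _WRAP_FLAG_FRAC * np.pi
    if np.any(wrapped):
        frac = ndimage.uniform_filter(
            wrapped.astype(float), size=(wz, wx), mode="constant", cval=0.0
        )
        quality = np.where(frac > 0, 0.0, quality)

    # back to the full Z grid (d lives between rows): repeat the last row
    strain_full = np.vstack([strain, strain[-1:, :]])
    quality_full = np.vstack([quality, quality[-1:, :]])
    return StrainField(strain_full, "interframe", frame_index, quality_full)


def accumulate_strain(
    series: BScanSeries,
    window_um: float | tuple[float, float] = DEFAULT_WINDOW_UM,
) -> StrainStack:
    """Interframe strain for every consecutive pair, plus the Eulerian sum.

    Accumulation is on the fixed pixel grid (no re-registration), which is
    valid for moderate cumulative strains; a warning is logged above 10 %.
    Wrap-bound violations are carried as zero-quality pixels, never raised.
    """
    frames = series.frames
    n_f = frames.shape[0]
    inter = np.empty((n_f - 1,) + series.shape, dtype=float)
    qual = np.empty_like(inter)
    for k in range(n_f - 1):
        product = interframe_product(frames[k], frames[k + 1])
        fld = vector_strain(product, window_um, series.meta, frame_index=k)
        inter[k] = fld.values
        qual[k] = fld.quality
    cumulative = np.concatenate(
        [np.zeros((1,) + series.shape), np.cumsum(inter, axis=0)], axis=0
    )
    peak = float(np.nanmax(np.abs(cumulative[-1])))
    if peak > 0.10:
        log.warning(
            "cumulative strain reaches %.1f%%: Eulerian accumulation on a fixed "
            "grid degrades as strain grows",
            100 * peak,
        )
    return StrainStack(inter, cumulative, qual, series.meta)
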