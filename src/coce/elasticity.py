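"""Tangent Young's modulus and quadratic nonlinearity from stress-strain curves.

Each per-window curve sigma(eps) is fitted with a smooth monotone model to
suppress measurement noise; the tangent modulus is the slope of the fit,

    E(sigma0) = d sigma / d eps  at sigma = sigma0,

and the dimensionless quadratic nonlinearity parameter is half the slope of
the stiffness-stress dependence,

    beta(sigma0) = (1/2) * dE/dsigma  at sigma = sigma0.

Both are evaluated inside a standardized pressure window sigma0 +- tol so
that maps from different lateral positions (whose instantaneous local
pressure differs) are compared at the same stress.  For the quadratic law
sigma = E0*(eps + beta*eps**2) these definitions give the analytic
transforms E(sigma) = E0*sqrt(1 + 4*beta*sigma/E0) = E0*(1 + 2*beta*eps)
and beta(sigma0) = beta / (1 + 2*beta*eps(sigma0)), which the estimators are
tested against.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import interpolate, optimize

from .stress import StressStrainCurve

__all__ = [
    "SmoothingConfig",
    "FittedLaw",
    "PressureWindow",
    "ElastogramPair",
    "fit_stress_strain",
    "tangent_modulus",
    "modulus_vs_stress",
    "nonlinearity_parameter",
    "extrapolate_zero_stress",
    "map_elastograms",
    "map_modulus",
    "map_beta",
]

log = logging.getLogger(__name__)

#: display/clipping range for stiffness maps of soft-tissue samples, kPa
E_DISPLAY_RANGE_KPA = (20.0, 1000.0)


@dataclass(frozen=True)
class SmoothingConfig:
    """Curve-fit settings.

    ``backend="quadratic"`` (default) fits the adopted local constitutive
    law itself, in its strain-on-stress orientation
    ``eps(sigma) = 2*(sigma/E0) / (1 + sqrt(1 + 4*beta*sigma/E0))``,
    by nonlinear least squares.  The measurement noise lives almost
    entirely in the OCT-derived strain (the silicone stress trace is
    averaged over the whole sensor ROI and is far cleaner), so regressing
    strain on stress keeps the fit unbiased where a stress-on-strain fit
    would suffer errors-in-variables distortion.
    ``backend="spline"`` is a shape-agnostic least-squares cubic spline on
    sigma(eps) (monotone piecewise-cubic smoothing: if the fitted
    derivative goes non-positive inside the data range, the fit falls back
    to a monotone PCHIP through isotonically projected values).
    """

    backend: str = "quadratic"
    knot_spacing: int = 25
    anchor_weight: float = 10.0
    max_residual_frac: float = 0.10


@dataclass
class FittedLaw:
    """Smooth monotone representation of one stress-strain curve."""

    _sigma: object  # callable eps -> stress
    _dsigma: object  # callable eps -> d stress / d eps
    eps_max: float
    sigma_max: float
    residual_rms_kPa: float
    usable: bool
    backend: str
    note: str = ""

    def sigma(self, eps):
        return self._sigma(np.clip(eps, 0.0, self.eps_max))

    def modulus(self, eps):
        """Tangent modulus d sigma/d eps (kPa) at the given strain."""
        return self._dsigma(np.clip(eps, 0.0, self.eps_max))

    def strain_at(self, sigma0: float) -> float:
        """Invert the monotone fit: strain at which the stress reaches sigma0."""
        if not (0.0 <= sigma0 <= self.sigma_max):
            raise ValueError(f"stress {sigma0} outside the fitted range")
        if sigma0 == 0.0:
            return 0.0
        f = lambda e: float(self._sigma(e)) - sigma0
        return float(optimize.brentq(f, 0.0, self.eps_max, xtol=1e-12))


@dataclass(frozen=True)
class PressureWindow:
    """Standardized pressure sigma0 +- tol (kPa) at which maps are evaluated."""

    sigma0_kPa: float = 0.5
    tol_kPa: float = 0.5

    def __post_init__(self) -> None:
        if self.sigma0_kPa < 0:
            raise ValueError("sigma0 must be non-negative")
        if self.tol_kPa <= 0:
            raise ValueError("tol must be positive")

    @property
    def lo(self) -> float:
        return max(self.sigma0_kPa - self.tol_kPa, 0.0)

    @property
    def hi(self) -> float:
        return self.sigma0_kPa + self.tol_kPa


def _clean_curve(strain: np.ndarray, stress: np.ndarray):
    """Sort by strain, merge duplicate strain values, drop non-finite pairs."""
    ok = np.isfinite(strain) & np.isfinite(stress)
    eps, sig = strain[ok], stress[ok]
    order = np.argsort(eps, kind="stable")
    eps, sig = eps[order], sig[order]
    uniq, inv = np.unique(eps, return_inverse=True)
    if uniq.size != eps.size:
        sig = np.bincount(inv, weights=sig) / np.bincount(inv)
        eps = uniq
    return eps, sig


def fit_stress_strain(
    curve: StressStrainCurve, smoothing: SmoothingConfig | None = None
) -> FittedLaw:
    """Fit a smooth monotone sigma(eps) to one stress-strain curve.

    The fit is anchored at the origin (curves are re-based so the first
    valid frame defines zero stress and strain).  Curves that are unusable,
    too short, non-monotonic in strain after cleaning, or whose residual
    RMS exceeds ``max_residual_frac`` of the peak stress are marked
    unusable; their law still evaluates but must not enter the maps.
    """
    cfg = smoothing or SmoothingConfig()
    if not curve.usable:
        return _invalid_law(cfg.backend, curve.note or "curve marked unusable")
    eps, sig = _clean_curve(curve.strain, curve.stress_kPa)
    if eps.size < 5:
        return _invalid_law(cfg.backend, "fewer than 5 distinct points")
    if eps[-1] <= 0:
        return _invalid_law(cfg.backend, "no positive strain reached")

    if cfg.backend == "quadratic":
        law = _fit_quadratic(eps, sig)
    elif cfg.backend == "spline":
        law = _fit_spline(eps, sig, cfg)
    else:
        raise ValueError(f"unknown fit backend {cfg.backend!r}")

    resid = law._sigma(eps) - sig
    rms = float(np.sqrt(np.mean(resid**2)))
    sig_peak = float(np.max(np.abs(sig)))
    usable = law.usable and (sig_peak == 0 or rms <= cfg.max_residual_frac * sig_peak)
    note = law.note if usable else (law.note or f"residual RMS {rms:.3g} kPa too large")
    return FittedLaw(
        law._sigma, law._dsigma, law.eps_max, law.sigma_max, rms, usable, cfg.backend, note
    )


def _invalid_law(backend: str, note: str) -> FittedLaw:
    zero = lambda e: np.zeros_like(np.asarray(e, dtype=float))
    return FittedLaw(zero, zero, 0.0, 0.0, np.nan, False, backend, note)


def _quad_root_strain(sig, E0, beta):
    """Non-negative root of the quadratic law, cancellation-free form."""
    s = np.asarray(sig, float) / E0
    disc = np.maximum(1.0 + 4.0 * beta * s, 1e-12)
    return 2.0 * s / (1.0 + np.sqrt(disc))


def _fit_quadratic(eps: np.ndarray, sig: np.ndarray) -> FittedLaw:
    """Nonlinear LS of the quadratic law with strain as the response."""
    import warnings

    from scipy.optimize import OptimizeWarning, curve_fit

    eps_pk = float(np.max(eps))
    sig_pk = float(np.max(sig))
    if eps_pk <= 0 or sig_pk <= 0:
        return _invalid_law("quadratic", "degenerate curve (no load)")
    # seeds: secant modulus and a linear-in-eps expansion of the curvature
    E0_seed = sig_pk / eps_pk
    try:
        with warnings.catch_warnings():
            # perfectly linear curves make the beta column degenerate; the
            # covariance is not used
            warnings.simplefilter("ignore", OptimizeWarning)
            popt, _ = curve_fit(
                _quad_root_strain, sig, eps, p0=[E0_seed, 1.0], maxfev=2000,
                xtol=1e-14, ftol=1e-14,
            )
    except RuntimeError:
        return _invalid_law("quadratic", "constitutive fit did not converge")
    a, b_over_a = float(popt[0]), float(popt[1])
    if a <= 0 or not np.isfinite(a) or not np.isfinite(b_over_a):
        return _invalid_law("quadratic", "non-positive fitted initial modulus")
    E0, beta = a, b_over_a
    fn = lambda e: E0 * (np.asarray(e, float) + beta * np.asarray(e, float) ** 2)
    dfn = lambda e: E0 * (1.0 + 2.0 * beta * np.asarray(e, float))
    eps_max = float(eps[-1])
    # negative beta (softening) is retained but flagged unusable if the fitted
    # law loses monotonicity inside the observed strain range
    usable = bool(dfn(eps_max) > 0) if beta < 0 else True
    return FittedLaw(
        fn, dfn, eps_max, float(fn(eps_max)), 0.0, usable, "quadratic",
        "" if usable else "fitted law non-monotone in range",
    )


def _fit_spline(eps: np.ndarray, sig: np.ndarray, cfg: SmoothingConfig) -> FittedLaw:
    # anchor the origin with extra weight
    eps_a = np.concatenate([[0.0], eps]) if eps[0] > 0 else eps.copy()
    sig_a = np.concatenate([[0.0], sig]) if eps[0] > 0 else sig.copy()
    w = np.ones_like(eps_a)
    w[0] = cfg.anchor_weight
    n = eps_a.size
    if n < 8:
        return _fit_quadratic(eps, sig)
    n_interior = max((n - 2) // cfg.knot_spacing, 0)
    if n_interior > 0:
        qs = np.linspace(0, 1, n_interior + 2)[1:-1]
        interior = np.quantile(eps_a, qs)
        # knots must be strictly inside and strictly increasing
        interior = interior[(interior > eps_a[0]) & (interior < eps_a[-1])]
        interior = np.unique(interior)
    else:
        interior = np.array([])
    t = np.concatenate([[eps_a[0]] * 4, interior, [eps_a[-1]] * 4])
    try:
        spl = interpolate.make_lsq_spline(eps_a, sig_a, t, k=3, w=w)
    except Exception:  # singular design (degenerate spacing): fall back
        return _fit_quadratic(eps, sig)
    dspl = spl.derivative()
    eps_max = float(eps_a[-1])
    grid = np.linspace(0.0, eps_max, 200)
    if np.min(dspl(grid)) <= 0.0:
        return _fit_monotone_pchip(eps_a, sig_a, note="spline derivative clipped")
    fn = lambda e: spl(np.asarray(e, float))
    dfn = lambda e: dspl(np.asarray(e, float))
    return FittedLaw(fn, dfn, eps_max, float(spl(eps_max)), 0.0, True, "spline")


def _fit_monotone_pchip(eps: np.ndarray, sig: np.ndarray, note: str = "") -> FittedLaw:
    """Shape-constrained fallback: PCHIP through isotonically projected stresses."""
    from scipy.optimize import isotonic_regression

    iso = isotonic_regression(sig).x
    # PCHIP needs strictly increasing ordinates for a strictly monotone fit;
    # break exact ties with a vanishing slope-preserving nudge
    iso = iso + np.arange(iso.size) * max(1e-12, 1e-9 * (iso[-1] - iso[0] + 1.0))
    pch = interpolate.PchipInterpolator(eps, iso)
    dpch = pch.derivative()
    eps_max = float(eps[-1])
    return FittedLaw(
        lambda e: pch(np.asarray(e, float)),
        lambda e: np.maximum(dpch(np.asarray(e, float)), 0.0),
        eps_max,
        float(pch(eps_max)),
        0.0,
        True,
        "pchip",
        note,
    )


def tangent_modulus(law: FittedLaw, window: PressureWindow) -> float:
    """Mean tangent modulus (kPa) over the strain interval mapped from the window.

    Returns NaN when the curve never reaches the pressure window (such
    pixels are left out of the maps).
    """
    if not law.usable:
        return np.nan
    lo = window.lo
    hi = min(window.hi, law.sigma_max)
    if hi <= lo or lo > law.sigma_max:
        return np.nan
    e1 = law.strain_at(lo)
    e2 = law.strain_at(hi)
    if e2 - e1 < 1e-9:
        return float(law.modulus(0.5 * (e1 + e2)))
    return float((hi - lo) / (e2 - e1))


def modulus_vs_stress(law: FittedLaw, n_samples: int = 60) -> tuple[np.ndarray, np.ndarray]:
    """Sample the stiffness-stress dependence E(sigma) of a fitted law."""
    if not law.usable or law.sigma_max <= 0:
        raise ValueError("cannot sample an unusable law")
    sig = np.linspace(0.0, law.sigma_max, n_samples)
    eps = np.array([law.strain_at(s) for s in sig])
    E = np.asarray(law.modulus(eps), dtype=float)
    return sig, E


def nonlinearity_parameter(
    E_of_sigma: tuple[np.ndarray, np.ndarray],
    window: PressureWindow,
    widen_cap: float = 4.0,
) -> float:
    """Half the least-squares slope of E(sigma) inside the pressure window.

    Requires at least 3 samples inside the window; the window is widened
    symmetrically (factor 1.5 per step) until satisfied, up to
    ``widen_cap`` times the original half-width, beyond which NaN is
    returned.  The slope is dimensionless because E and sigma share units.
    """
    sig, E = map(np.asarray, E_of_sigma)
    tol = window.tol_kPa
    while True:
        lo = max(window.sigma0_kPa - tol, 0.0)
        hi = window.sigma0_kPa + tol
        sel = (sig >= lo) & (sig <= hi)
        if np.count_nonzero(sel) >= 3:
            break
        tol *= 1.5
        if tol > widen_cap * window.tol_kPa:
            return np.nan
    slope = np.polyfit(sig[sel], E[sel], 1)[0]
    return float(0.5 * slope)


def extrapolate_zero_stress(E_s: float, beta_s: float, sigma0: float) -> tuple[float, float]:
    """Map window-standardized estimates (E(sigma0), beta(sigma0)) to (E0, beta).

    For the quadratic law, ``E(sigma0)**2 = E0**2 + 4*beta*E0*sigma0`` and
    ``beta*E0 = beta(sigma0)*E(sigma0)``, hence
    ``E0 = sqrt(E_s**2 - 4*beta_s*E_s*sigma0)`` and
    ``beta = beta_s*E_s/E0``.  Returns (NaN, NaN) when the discriminant is
    non-positive (estimates inconsistent with a stiffening quadratic law).
    """
    disc = E_s**2 - 4.0 * beta_s * E_s * sigma0
    if not np.isfinite(disc) or disc <= 0:
        return np.nan, np.nan
    E0 = float(np.sqrt(disc))
    return E0, float(beta_s * E_s / E0)


@dataclass
class ElastogramPair:
    """Co-registered E and beta maps at one standardized pressure window.

    Invalid pixels are NaN in both maps with ``mask`` False; a mask is used
    (not zeros) because 0 kPa is a legal modulus limit.  Negative beta
    estimates are retained, not clipped.
    """

    E_map: np.ndarray
    beta_map: np.ndarray
    mask: np.ndarray
    window: PressureWindow
    pixel_z_um: float = 1.0
    pixel_x_um: float = 1.0

    def __post_init__(self) -> None:
        if self.E_map.shape != self.beta_map.shape or self.E_map.shape != self.mask.shape:
            raise ValueError("E, beta and mask grids must be co-registered")

    def to_hdf5(self, path) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            g = f.require_group("maps")
            g.create_dataset("E_kPa", data=self.E_map, track_times=False)
            g.create_dataset("beta", data=self.beta_map, track_times=False)
            g.create_dataset("mask", data=self.mask.astype(np.uint8), track_times=False)
            g.attrs["sigma0_kPa"] = self.window.sigma0_kPa
            g.attrs["tol_kPa"] = self.window.tol_kPa
            g.attrs["pixel_z_um"] = self.pixel_z_um
            g.attrs["pixel_x_um"] = self.pixel_x_um
            g.attrs["E_display_range_kPa"] = E_DISPLAY_RANGE_KPA

    @classmethod
    def from_hdf5(cls, path) -> "ElastogramPair":
        import h5py

        with h5py.File(path, "r") as f:
            g = f["maps"]
            return cls(
                E_map=g["E_kPa"][...],
                beta_map=g["beta"][...],
                mask=g["mask"][...].astype(bool),
                window=PressureWindow(float(g.attrs["sigma0_kPa"]), float(g.attrs["tol_kPa"])),
                pixel_z_um=float(g.attrs["pixel_z_um"]),
                pixel_x_um=float(g.attrs["pixel_x_um"]),
            )

    def render_png(self, path, e_range=E_DISPLAY_RANGE_KPA) -> None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 2, figsize=(10, 4))
        shown = np.where(self.mask, self.E_map, np.nan)
        im0 = axes[0].imshow(shown, cmap="turbo", vmin=e_range[0], vmax=e_range[1])
        axes[0].set_title(f"E at {self.window.sigma0_kPa}±{self.window.tol_kPa} kPa")
        fig.colorbar(im0, ax=axes[0], label="kPa")
        shown_b = np.where(self.mask, self.beta_map, np.nan)
        im1 = axes[1].imshow(shown_b, cmap="gray")
        axes[1].set_title("nonlinearity beta")
        fig.colorbar(im1, ax=axes[1])
        fig.savefig(path, dpi=120)
        plt.close(fig)


def map_elastograms(
    curves: list[StressStrainCurve],
    window: PressureWindow,
    grid_shape: tuple[int, int],
    smoothing: SmoothingConfig | None = None,
    pixel_z_um: float = 1.0,
    pixel_x_um: float = 1.0,
) -> ElastogramPair:
    """Pressure-standardized E and beta maps from per-window curves.

    Each processing window paints the central stride-sized block of the
    output grid (windows overlap by half their size, so the central blocks
    tile the grid without mixing neighbouring windows).  Windows whose
    local stress never enters the pressure window stay masked.
    """
    E_map = np.full(grid_shape, np.nan)
    beta_map = np.full(grid_shape, np.nan)
    for c in curves:
        law = fit_stress_strain(c, smoothing)
        E_val = tangent_modulus(law, window)
        if np.isfinite(E_val):
            try:
                beta_val = nonlinearity_parameter(modulus_vs_stress(law), window)
            except ValueError:
                beta_val = np.nan
        else:
            beta_val = np.nan
        if not np.isfinite(E_val):
            continue
        dz = max(c.wz // 4, 1)
        dx = max(c.wx // 4, 1)
        zc = c.z0 + c.wz // 2
        xc = c.x0 + c.wx // 2
        z_sl = slice(max(zc - dz, 0), min(zc + dz, grid_shape[0]))
        x_sl = slice(max(xc - dx, 0), min(xc + dx, grid_shape[1]))
        E_map[z_sl, x_sl] = E_val
        beta_map[z_sl, x_sl] = beta_val
    mask = np.isfinite(E_map)
    return ElastogramPair(E_map, beta_map, mask, window, pixel_z_um, pixel_x_um)


def map_modulus(curves, window, grid_shape, smoothing=None, **kw) -> np.ndarray:
    """Stiffness map alone (see ``map_elastograms``)."""
    return map_elastograms(curves, window, grid_shape, smoothing, **kw).E_map


def map_beta(curves, window, grid_shape, smoothing=None, **kw) -> np.ndarray:
    """Nonlinearity map alone (see ``map_elastograms``)."""
    return map_elastograms(curves, window, grid_shape, smoothing, **kw).beta_map
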