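"""Synthetic phase-sensitive OCT compression phantoms with known ground truth.

The phantom is a two-layer medium: a highly linear reference silicone on top
of a laterally heterogeneous "tissue" whose columns obey the local quadratic
stress-strain law

    sigma = E0 * (eps + beta * eps**2),

with compressive strain and pressure taken positive.  The applied axial
pressure is depth-independent within each lateral column (thin-sample,
uniaxial-compression regime), so the per-column stress schedule plus the
constitutive parameters fully determine the strain and displacement fields.
The rendered series emulates a phase-sensitive OCT signal: a speckle
envelope formed by discrete sub-resolution scatterers, whose per-pixel phase
advances in proportion to the accumulated axial displacement of the
material above and at each depth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .series import AcquisitionMetadata, BScanSeries

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "solve_layer_strain",
    "make_ground_truth",
    "render_series",
    "simulate",
    "seven_region_spec",
    "two_class_overlap_spec",
    "SEVEN_CLASS_PARAMS",
]

log = logging.getLogger(__name__)

#: Default constitutive parameters (E0 kPa, beta) used for the bundled
#: seven-region demonstration phantom.  They follow the qualitative ordering
#: reported for breast-tissue morphotypes: adipose is soft and nearly linear,
#: solid carcinomas are stiff, and hyalinosis combines high stiffness with
#: extreme elastic nonlinearity.
SEVEN_CLASS_PARAMS: dict[str, tuple[float, float]] = {
    "adipose": (25.0, 1.0),
    "fibrous stroma": (60.0, 3.0),
    "IDC scirrhous": (80.0, 8.0),
    "IDC solid-scirrhous": (120.0, 12.0),
    "IDC solid": (300.0, 18.0),
    "ILC solid": (250.0, 25.0),
    "hyalinosis": (350.0, 40.0),
}

#: Optical resolution of the emulated system (full width at half maximum).
AXIAL_FWHM_UM = 10.0
LATERAL_FWHM_UM = 15.0
_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass
class PhantomSpec:
    """Full description of a synthetic compression experiment.

    ``pressure_schedule`` has shape ``(n_frames,)`` (laterally uniform) or
    ``(n_frames, n_x)`` and must be non-decreasing along frames for every
    column.  ``region_map`` is an integer label grid over the tissue zone
    (shape ``(n_z - silicone_px, n_x)``); every label must appear in
    ``class_params`` mapping label -> (E0 kPa, beta).
    """

    lateral_width_mm: float = 4.0
    depth_air_mm: float = 2.0
    n_z: int = 256
    n_x: int = 256
    lambda0_um: float = 1.3
    n_silicone: float = 1.4
    n_tissue: float = 1.4
    silicone_thickness_um: float = 360.0
    E_sil_kPa: float = 100.0
    region_map: np.ndarray = None
    class_params: dict = field(default_factory=dict)
    pressure_schedule: np.ndarray = None
    scatterers_per_cell: float = 3.0
    snr_db: float | None = None
    seed: int = 0
    max_cum_strain: float = 0.30

    def __post_init__(self) -> None:
        if self.lateral_width_mm <= 0 or self.depth_air_mm <= 0:
            raise ValueError("phantom extents must be positive")
        if self.n_z < 4 or self.n_x < 2:
            raise ValueError("pixel grid too small")
        if self.E_sil_kPa <= 0:
            raise ValueError("silicone Young's modulus must be positive")
        if self.silicone_px >= self.n_z - 1:
            raise ValueError("silicone layer must leave room for tissue in depth")
        if self.region_map is None:
            self.region_map = np.zeros((self.n_z - self.silicone_px, self.n_x), dtype=int)
            self.class_params = dict(self.class_params) or {0: (100.0, 0.0)}
        self.region_map = np.asarray(self.region_map, dtype=int)
        if self.region_map.shape != (self.n_z - self.silicone_px, self.n_x):
            raise ValueError(
                f"region_map shape {self.region_map.shape} does not match the "
                f"tissue zone {(self.n_z - self.silicone_px, self.n_x)}"
            )
        labels = np.unique(self.region_map)
        missing = [int(l) for l in labels if int(l) not in self.class_params]
        if missing:
            raise ValueError(f"region_map labels {missing} absent from class_params")
        for label, (e0, beta) in self.class_params.items():
            if e0 <= 0:
                raise ValueError(f"E0 must be positive (class {label})")
            if beta < 0:
                raise ValueError(f"beta must be non-negative (class {label})")
        if self.pressure_schedule is None:
            self.pressure_schedule = np.linspace(0.0, 2.0, 40)
        sched = np.atleast_1d(np.asarray(self.pressure_schedule, dtype=float))
        if sched.ndim == 1:
            sched = np.broadcast_to(sched[:, None], (sched.shape[0], self.n_x)).copy()
        if sched.ndim != 2 or sched.shape[1] != self.n_x:
            raise ValueError("pressure_schedule must be (n_frames,) or (n_frames, n_x)")
        if sched.shape[0] < 2:
            raise ValueError("pressure_schedule needs at least 2 frames")
        if np.any(sched < 0):
            raise ValueError("pressure must be non-negative")
        if np.any(np.diff(sched, axis=0) < -1e-12):
            raise ValueError("pressure_schedule must be non-decreasing in frame index")
        self.pressure_schedule = sched

    # -- derived geometry ---------------------------------------------------
    @property
    def pixel_z_um(self) -> float:
        """Axial pitch in air-equivalent optical depth (µm)."""
        return self.depth_air_mm * 1000.0 / self.n_z

    @property
    def pixel_x_um(self) -> float:
        return self.lateral_width_mm * 1000.0 / self.n_x

    @property
    def silicone_px(self) -> int:
        """Rows occupied by the silicone layer (optical thickness / pitch)."""
        return int(round(self.silicone_thickness_um * self.n_silicone / self.pixel_z_um))

    @property
    def n_frames(self) -> int:
        return self.pressure_schedule.shape[0]

    def metadata(self) -> AcquisitionMetadata:
        return AcquisitionMetadata(
            lambda0_um=self.lambda0_um,
            pixel_z_um=self.pixel_z_um,
            pixel_x_um=self.pixel_x_um,
            n_silicone=self.n_silicone,
            n_tissue=self.n_tissue,
            E_sil_kPa=self.E_sil_kPa,
            silicone_px=self.silicone_px,
        )

    def constitutive_maps(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-pixel (E0, beta) maps over the tissue zone."""
        e0 = np.empty(self.region_map.shape, dtype=float)
        beta = np.empty(self.region_map.shape, dtype=float)
        for label, (e, b) in self.class_params.items():
            sel = self.region_map == label
            e0[sel] = e
            beta[sel] = b
        return e0, beta

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "lateral_width_mm": self.lateral_width_mm,
            "depth_air_mm": self.depth_air_mm,
            "n_z": self.n_z,
            "n_x": self.n_x,
            "lambda0_um": self.lambda0_um,
            "n_silicone": self.n_silicone,
            "n_tissue": self.n_tissue,
            "silicone_thickness_um": self.silicone_thickness_um,
            "E_sil_kPa": self.E_sil_kPa,
            "region_map": self.region_map.tolist(),
            "class_params": {str(k): list(v) for k, v in self.class_params.items()},
            "pressure_schedule": self.pressure_schedule.tolist(),
            "scatterers_per_cell": self.scatterers_per_cell,
            "snr_db": self.snr_db,
            "seed": self.seed,
            "max_cum_strain": self.max_cum_strain,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        d = dict(d)
        if "class_params" in d:
            d["class_params"] = {int(k): tuple(v) for k, v in d["class_params"].items()}
        if "region_map" in d:
            rm = d["region_map"]
            if isinstance(rm, str):
                import tifffile

                rm = tifffile.imread(rm)
            d["region_map"] = np.asarray(rm, dtype=int)
        if "pressure_schedule" in d:
            d["pressure_schedule"] = np.asarray(d["pressure_schedule"], dtype=float)
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def from_file(cls, path: str | Path) -> "PhantomSpec":
        """Load a spec from a JSON or YAML document."""
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            d = yaml.safe_load(text)
        else:
            d = json.loads(text)
        return cls.from_dict(d)


@dataclass
class GroundTruth:
    """Known stress/strain fields of a simulated compression.

    ``stress`` is depth-independent per column: shape ``(n_frames, n_x)``.
    ``cumulative`` and ``interframe`` are full-grid strain fields,
    ``(n_frames, n_z, n_x)`` and ``(n_frames - 1, n_z, n_x)``.
    """

    stress: np.ndarray
    cumulative: np.ndarray
    interframe: np.ndarray
    region_map: np.ndarray


def solve_layer_strain(sigma, E0, beta):
    """Invert ``sigma = E0*(eps + beta*eps**2)`` for the non-negative strain.

    Uses the cancellation-free form of the quadratic root,
    ``eps = 2*(sigma/E0) / (1 + sqrt(1 + 4*beta*sigma/E0))``,
    which reduces smoothly to ``sigma/E0`` as ``beta -> 0``.  All arguments
    broadcast; compressive stress and strain are positive numbers.
    """
    sigma = np.asarray(sigma, dtype=float)
    E0 = np.asarray(E0, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if np.any(sigma < 0):
        raise ValueError("stress must be non-negative")
    if np.any(E0 <= 0):
        raise ValueError("E0 must be positive")
    if np.any(beta < 0):
        raise ValueError("beta must be non-negative")
    s = sigma / E0
    eps = 2.0 * s / (1.0 + np.sqrt(1.0 + 4.0 * beta * s))
    if eps.ndim == 0:
        return float(eps)
    return eps


def make_ground_truth(spec: PhantomSpec) -> GroundTruth:
    """Evaluate the exact stress/strain fields implied by a phantom spec.

    Per column and frame the silicone strain is ``sigma / E_sil`` (linear
    sensor) and the tissue strain follows the quadratic law of each region.
    Raises if the schedule drives the cumulative strain beyond
    ``spec.max_cum_strain`` anywhere (phase-tracking validity bound).
    """
    sched = spec.pressure_schedule  # (F, X)
    n_f, n_x = sched.shape
    n_z = spec.n_z
    sil_px = spec.silicone_px

    e0_map, beta_map = spec.constitutive_maps()  # (Zt, X)
    cumulative = np.empty((n_f, n_z, n_x), dtype=float)
    cumulative[:, :sil_px, :] = (sched / spec.E_sil_kPa)[:, None, :]
    # tissue strain: broadcast sigma over depth within the tissue zone
    sigma_t = sched[:, None, :]  # (F, 1, X)
    cumulative[:, sil_px:, :] = solve_layer_strain(
        sigma_t, e0_map[None, :, :], beta_map[None, :, :]
    )
    max_strain = float(cumulative.max(initial=0.0))
    if max_strain > spec.max_cum_strain:
        raise ValueError(
            f"schedule drives cumulative strain to {max_strain:.3f}, beyond the "
            f"configured maximum {spec.max_cum_strain:.2f}; reduce the pressure "
            f"ramp or raise max_cum_strain"
        )
    interframe = np.diff(cumulative, axis=0)
    return GroundTruth(
        stress=sched.copy(),
        cumulative=cumulative,
        interframe=interframe,
        region_map=spec.region_map.copy(),
    )


def _displacement_phase(spec: PhantomSpec, gt: GroundTruth) -> np.ndarray:
    """Per-pixel phase advance (radians) of each frame relative to frame 0.

    The optical path above depth-row ``z`` shortens by the integral of the
    cumulative strain over the rows above it; with the axial pitch expressed
    in optical depth the layer refractive indices cancel, giving a phase
    advance per pixel row equal to ``4*pi*pixel_z_um*strain/lambda0_um``.
    """
    # displacement (in optical pixels) of material at the TOP edge of row z
    u_px = np.concatenate(
        [
            np.zeros((gt.cumulative.shape[0], 1, spec.n_x)),
            np.cumsum(gt.cumulative, axis=1)[:, :-1, :],
        ],
        axis=1,
    )
    return 4.0 * np.pi * spec.pixel_z_um / spec.lambda0_um * u_px


def _speckle_envelope(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Coherent sum of randomly placed scatterers under a separable Gaussian PSF."""
    sigma_z = AXIAL_FWHM_UM * _FWHM_TO_SIGMA / spec.pixel_z_um
    sigma_x = LATERAL_FWHM_UM * _FWHM_TO_SIGMA / spec.pixel_x_um
    cells = (spec.n_z / max(AXIAL_FWHM_UM / spec.pixel_z_um, 1.0)) * (
        spec.n_x / max(LATERAL_FWHM_UM / spec.pixel_x_um, 1.0)
    )
    n_scat = max(int(spec.scatterers_per_cell * cells), 16)
    z_s = rng.uniform(0, spec.n_z, n_scat)
    x_s = rng.uniform(0, spec.n_x, n_scat)
    refl = rng.standard_normal(n_scat) + 1j * rng.standard_normal(n_scat)
    # carrier phase from optical depth position
    refl = refl * np.exp(-1j * 4.0 * np.pi * spec.pixel_z_um / spec.lambda0_um * z_s)

    field_out = np.zeros((spec.n_z, spec.n_x), dtype=complex)
    z0 = np.floor(z_s).astype(int)
    x0 = np.floor(x_s).astype(int)
    rz = int(np.ceil(3 * sigma_z))
    rx = int(np.ceil(3 * sigma_x))
    for dz in range(-rz, rz + 1):
        zi = z0 + dz
        okz = (zi >= 0) & (zi < spec.n_z)
        wz = np.exp(-((zi - z_s) ** 2) / (2 * sigma_z**2))
        for dx in range(-rx, rx + 1):
            xi = x0 + dx
            ok = okz & (xi >= 0) & (xi < spec.n_x)
            w = wz * np.exp(-((xi - x_s) ** 2) / (2 * sigma_x**2))
            contrib = refl[ok] * w[ok]
            flat = zi[ok] * spec.n_x + xi[ok]
            field_out.real += np.bincount(
                flat, weights=contrib.real, minlength=spec.n_z * spec.n_x
            ).reshape(spec.n_z, spec.n_x)
            field_out.imag += np.bincount(
                flat, weights=contrib.imag, minlength=spec.n_z * spec.n_x
            ).reshape(spec.n_z, spec.n_x)
    return field_out


def render_series(
    spec: PhantomSpec, gt: GroundTruth, signal_model: str = "phase"
) -> BScanSeries:
    """Render the complex B-scan stack for a phantom.

    ``signal_model="phase"`` (default) renders a speckle envelope once from
    discrete random scatterers and advances each pixel's phase by the exact
    displacement-induced optical-path change, so the per-pixel interframe
    phase advance equals ``4*pi*n/lambda0`` times the axial displacement
    increment.  ``signal_model="scatterer"`` re-renders every frame from the
    displaced scatterers instead, which additionally produces speckle
    decorrelation at large strains.

    Raises if any single-frame phase increment reaches ``pi`` anywhere
    (phase wrapping would make the interframe strain ambiguous).
    """
    rng = np.random.default_rng(spec.seed)
    phase = _displacement_phase(spec, gt)
    dphi = np.diff(phase, axis=0)
    # wrapping budget: the interframe phase advance itself may span many
    # radians at depth (the conjugate products cancel it), but its AXIAL
    # increment per pixel row -- the strain signal -- must stay below pi
    axial_step = np.abs(np.diff(dphi, axis=1))
    worst = float(axial_step.max(initial=0.0))
    if worst >= np.pi:
        raise ValueError(
            f"max single-frame axial phase step {worst:.2f} rad >= pi: the "
            f"interframe strain would wrap; use more frames or a gentler ramp"
        )

    if signal_model == "phase":
        envelope = _speckle_envelope(spec, rng)
        frames = envelope[None, :, :] * np.exp(1j * phase)
    elif signal_model == "scatterer":
        frames = _render_scatterer_frames(spec, gt, rng)
    else:
        raise ValueError(f"unknown signal_model {signal_model!r}")

    if spec.snr_db is not None:
        tissue = frames[0, spec.silicone_px :, :]
        p_sig = float(np.mean(np.abs(tissue) ** 2))
        p_noise = p_sig / 10.0 ** (spec.snr_db / 10.0)
        noise_sd = np.sqrt(p_noise / 2.0)
        frames = frames + noise_sd * (
            rng.standard_normal(frames.shape) + 1j * rng.standard_normal(frames.shape)
        )

    ground_truth = {
        "stress_kPa": gt.stress,
        "cumulative_strain": gt.cumulative,
        "interframe_strain": gt.interframe,
        "region_map": gt.region_map,
    }
    return BScanSeries(frames, spec.metadata(), ground_truth)


def _render_scatterer_frames(
    spec: PhantomSpec, gt: GroundTruth, rng: np.random.Generator
) -> np.ndarray:
    """Re-render every frame from scatterers displaced by the ground truth."""
    sigma_z = AXIAL_FWHM_UM * _FWHM_TO_SIGMA / spec.pixel_z_um
    sigma_x = LATERAL_FWHM_UM * _FWHM_TO_SIGMA / spec.pixel_x_um
    cells = (spec.n_z / max(AXIAL_FWHM_UM / spec.pixel_z_um, 1.0)) * (
        spec.n_x / max(LATERAL_FWHM_UM / spec.pixel_x_um, 1.0)
    )
    n_scat = max(int(spec.scatterers_per_cell * cells), 16)
    z_s = rng.uniform(0, spec.n_z, n_scat)
    x_s = rng.uniform(0, spec.n_x, n_scat)
    refl = rng.standard_normal(n_scat) + 1j * rng.standard_normal(n_scat)

    # displacement of material at optical depth z (in optical pixels), per frame
    n_f = gt.cumulative.shape[0]
    u_rows = np.concatenate(
        [
            np.zeros((n_f, 1, spec.n_x)),
            np.cumsum(gt.cumulative, axis=1),
        ],
        axis=1,
    )  # (F, Z+1, X) displacement at row top edges
    xi = np.clip(np.floor(x_s).astype(int), 0, spec.n_x - 1)
    k_phase = 4.0 * np.pi * spec.pixel_z_um / spec.lambda0_um
    rz = int(np.ceil(3 * sigma_z))
    rx = int(np.ceil(3 * sigma_x))
    frames = np.zeros((n_f, spec.n_z, spec.n_x), dtype=complex)
    rows = np.arange(spec.n_z + 1)
    for f in range(n_f):
        u_f = np.array(
            [np.interp(z_s[i], rows, u_rows[f, :, xi[i]]) for i in range(n_scat)]
        )
        z_f = z_s - u_f
        amp = refl * np.exp(-1j * k_phase * z_f)
        z0 = np.floor(z_f).astype(int)
        x0 = np.floor(x_s).astype(int)
        for dz in range(-rz, rz + 1):
            zz = z0 + dz
            okz = (zz >= 0) & (zz < spec.n_z)
            wz = np.exp(-((zz - z_f) ** 2) / (2 * sigma_z**2))
            for dx in range(-rx, rx + 1):
                xx = x0 + dx
                ok = okz & (xx >= 0) & (xx < spec.n_x)
                w = wz * np.exp(-((xx - x_s) ** 2) / (2 * sigma_x**2))
                contrib = amp[ok] * w[ok]
                flat = zz[ok] * spec.n_x + xx[ok]
                frames[f].real += np.bincount(
                    flat, weights=contrib.real, minlength=spec.n_z * spec.n_x
                ).reshape(spec.n_z, spec.n_x)
                frames[f].imag += np.bincount(
                    flat, weights=contrib.imag, minlength=spec.n_z * spec.n_x
                ).reshape(spec.n_z, spec.n_x)
    return frames


def simulate(spec: PhantomSpec, signal_model: str = "phase") -> BScanSeries:
    """Ground truth + rendering in one call."""
    gt = make_ground_truth(spec)
    return render_series(spec, gt, signal_model=signal_model)


# ---------------------------------------------------------------------------
# bundled phantom factories
# ---------------------------------------------------------------------------

def seven_region_spec(
    n_frames: int = 50,
    max_pressure_kPa: float = 3.0,
    snr_db: float | None = None,
    seed: int = 0,
    n_z: int = 256,
    n_x: int = 256,
    pressure_profile: np.ndarray | None = None,
    class_params: dict[str, tuple[float, float]] | None = None,
) -> PhantomSpec:
    """Seven vertical stripes, one per breast-tissue morphotype.

    ``pressure_profile`` optionally scales the ramp per lateral column to
    emulate a tilted or uneven probe contact.
    """
    params = class_params or SEVEN_CLASS_PARAMS
    names = list(params)
    spec_geom = PhantomSpec(n_z=n_z, n_x=n_x)
    zt = n_z - spec_geom.silicone_px
    region = np.zeros((zt, n_x), dtype=int)
    edges = np.linspace(0, n_x, len(names) + 1).astype(int)
    for i in range(len(names)):
        region[:, edges[i] : edges[i + 1]] = i
    ramp = np.linspace(0.0, max_pressure_kPa, n_frames)
    if pressure_profile is not None:
        profile = np.asarray(pressure_profile, dtype=float)
        if profile.shape != (n_x,):
            raise ValueError("pressure_profile must have shape (n_x,)")
        sched = ramp[:, None] * profile[None, :]
    else:
        sched = ramp
    return PhantomSpec(
        n_z=n_z,
        n_x=n_x,
        region_map=region,
        class_params={i: params[name] for i, name in enumerate(names)},
        pressure_schedule=sched,
        snr_db=snr_db,
        seed=seed,
    )


def two_class_overlap_spec(
    n_frames: int = 50,
    max_pressure_kPa: float = 3.0,
    snr_db: float | None = None,
    seed: int = 0,
    n_z: int = 256,
    n_x: int = 256,
    n_stripes: int = 16,
    e_obs_range_kPa: tuple[float, float] = (60.0, 100.0),
    sigma0_ref_kPa: float = 0.5,
    beta_range_a: tuple[float, float] = (1.0, 3.0),
    beta_range_b: tuple[float, float] = (10.0, 16.0),
) -> tuple[PhantomSpec, np.ndarray]:
    """Two tissue classes with coinciding stiffness but disjoint nonlinearity.

    Emulates the benign-fibrosis vs scirrhous-tumor situation: at the
    standardized low pressure both classes present the same range of
    apparent stiffness, and only the nonlinearity parameter separates
    them.  Alternating lateral stripes belong to class A (nearly linear)
    or class B (strongly nonlinear); the *observed* tangent moduli
    ``E(sigma0_ref)`` of all stripes are placed on one interleaved grid
    spanning ``e_obs_range_kPa`` (with a small random jitter), so the two
    stiffness distributions overlap by construction and no single
    stiffness threshold can separate the classes.  The zero-stress modulus
    of each stripe follows exactly from its beta via
    ``E0 = -2*beta*sigma0 + sqrt(4*beta**2*sigma0**2 + E_obs**2)``.

    Returns the spec and the per-stripe class assignment (0/1 array, one
    entry per region label).
    """
    rng = np.random.default_rng(seed)
    spec_geom = PhantomSpec(n_z=n_z, n_x=n_x)
    zt = n_z - spec_geom.silicone_px
    region = np.zeros((zt, n_x), dtype=int)
    edges = np.linspace(0, n_x, n_stripes + 1).astype(int)
    lo, hi = e_obs_range_kPa
    grid_step = (hi - lo) / n_stripes
    e_obs = lo + grid_step * (np.arange(n_stripes) + 0.5)
    e_obs = e_obs + rng.uniform(-0.2, 0.2, n_stripes) * grid_step
    order = rng.permutation(n_stripes)  # stripes in random spatial order
    class_params = {}
    stripe_class = np.zeros(n_stripes, dtype=int)
    for i in range(n_stripes):
        region[:, edges[i] : edges[i + 1]] = i
        # the observed-stiffness grid alternates classes, so the class-
        # conditional stiffness distributions interleave
        rank = order[i]
        cls = rank % 2
        stripe_class[i] = cls
        beta = rng.uniform(*(beta_range_a if cls == 0 else beta_range_b))
        e_s = e_obs[rank]
        e0 = -2.0 * beta * sigma0_ref_kPa + np.sqrt(
            4.0 * beta**2 * sigma0_ref_kPa**2 + e_s**2
        )
        class_params[i] = (float(e0), float(beta))
    spec = PhantomSpec(
        n_z=n_z,
        n_x=n_x,
        region_map=region,
        class_params=class_params,
        pressure_schedule=np.linspace(0.0, max_pressure_kPa, n_frames),
        snr_db=snr_db,
        seed=int(rng.integers(2**31 - 1)),
    )
    return spec, stripe_class
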