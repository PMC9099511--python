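"""Complex OCT B-scan series container and HDF5 round-tripping.

A compression OCE acquisition is an ordered stack of complex-valued
phase-sensitive B-scans of the sample while it is slowly compressed by the
probe through a precalibrated reference silicone layer.  The axial pixel
pitch is the optical (air-equivalent) sampling step of the spectral-domain
system; geometric depth inside a layer is the optical depth divided by that
layer's group refractive index.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

__all__ = ["AcquisitionMetadata", "BScanSeries"]


@dataclass(frozen=True)
class AcquisitionMetadata:
    """Acquisition geometry and calibration needed to quantify strain.

    Parameters
    ----------
    lambda0_um:
        Central wavelength of the source, micrometres.
    pixel_z_um:
        Axial sampling pitch in air-equivalent optical depth, micrometres.
        The geometric pitch inside a layer of refractive index ``n`` is
        ``pixel_z_um / n``.
    pixel_x_um:
        Lateral A-line pitch, micrometres.
    n_silicone, n_tissue:
        Group refractive indices of the reference silicone and the tissue.
    E_sil_kPa:
        Calibrated Young's modulus of the reference silicone, kPa.
    silicone_px:
        Number of topmost image rows occupied by the silicone layer.
    """

    lambda0_um: float = 1.3
    pixel_z_um: float = 7.8125
    pixel_x_um: float = 15.625
    n_silicone: float = 1.4
    n_tissue: float = 1.4
    E_sil_kPa: float = 100.0
    silicone_px: int = 64

    def __post_init__(self) -> None:
        if self.lambda0_um <= 0 or self.pixel_z_um <= 0 or self.pixel_x_um <= 0:
            raise ValueError("wavelength and pixel pitches must be positive")
        if self.n_silicone < 1 or self.n_tissue < 1:
            raise ValueError("refractive indices must be >= 1")
        if self.E_sil_kPa <= 0:
            raise ValueError("silicone Young's modulus must be positive")
        if self.silicone_px < 0:
            raise ValueError("silicone_px must be non-negative")

    def refractive_index(self, z_rows: np.ndarray) -> np.ndarray:
        """Per-row refractive index (silicone above ``silicone_px``, tissue below)."""
        z_rows = np.asarray(z_rows)
        return np.where(z_rows < self.silicone_px, self.n_silicone, self.n_tissue)

    @property
    def wrap_strain_bound(self) -> float:
        """Largest per-pixel interframe strain before the phase difference wraps.

        The interframe axial phase increment per pixel is
        ``4*pi*pixel_z_um*strain/lambda0_um`` (refractive index cancels when the
        axial pitch is expressed in optical depth), so wrapping occurs at
        ``strain = lambda0_um / (4 * pixel_z_um)``.
        """
        return self.lambda0_um / (4.0 * self.pixel_z_um)


_META_ATTRS = (
    "lambda0_um",
    "pixel_z_um",
    "pixel_x_um",
    "n_silicone",
    "n_tissue",
    "E_sil_kPa",
    "silicone_px",
)


@dataclass
class BScanSeries:
    """Stack of complex B-scans ``frames[frame, z, x]`` plus metadata."""

    frames: np.ndarray
    meta: AcquisitionMetadata
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3D (frame, z, x) array")
        if self.frames.shape[0] < 2:
            raise ValueError("a compression series needs at least 2 frames")
        if not np.iscomplexobj(self.frames):
            raise ValueError("frames must be complex-valued")
        if not np.all(np.isfinite(self.frames.view(float))):
            raise ValueError("frames contain non-finite values")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def with_frames(self, frames: np.ndarray) -> "BScanSeries":
        return BScanSeries(frames, replace(self.meta), dict(self.ground_truth))

    def to_hdf5(self, path: str | Path) -> None:
        with h5py.File(path, "w") as f:
            f.create_dataset("frames", data=self.frames.astype(np.complex64), track_times=False)
            grp = f.require_group("metadata")
            for name in _META_ATTRS:
                grp.attrs[name] = getattr(self.meta, name)
            if self.ground_truth:
                gt = f.require_group("ground_truth")
                for key, value in self.ground_truth.items():
                    gt.create_dataset(key, data=np.asarray(value), track_times=False)

    @classmethod
    def from_hdf5(cls, path: str | Path) -> "BScanSeries":
        with h5py.File(path, "r") as f:
            if "frames" not in f:
                raise KeyError("dataset '/frames' missing from series file")
            frames = f["frames"][...]
            if "metadata" not in f:
                raise KeyError("group '/metadata' missing from series file")
            attrs = f["metadata"].attrs
            missing = [a for a in _META_ATTRS if a not in attrs]
            if missing:
                raise KeyError(f"metadata attributes missing: {missing}")
            meta = AcquisitionMetadata(
                lambda0_um=float(attrs["lambda0_um"]),
                pixel_z_um=float(attrs["pixel_z_um"]),
                pixel_x_um=float(attrs["pixel_x_um"]),
                n_silicone=float(attrs["n_silicone"]),
                n_tissue=float(attrs["n_tissue"]),
                E_sil_kPa=float(attrs["E_sil_kPa"]),
                silicone_px=int(attrs["silicone_px"]),
            )
            ground_truth = {}
            if "ground_truth" in f:
                for key, ds in f["ground_truth"].items():
                    ground_truth[key] = ds[...]
        return cls(frames, meta, ground_truth)
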