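"""HDF5 / TIFF persistence for sinograms, priors and images."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import tifffile

from .decompose import BasisSinogram, MetalPrior
from .projector import Geometry, Sinogram, SpectralSinogram
from .recon import ReconImage
from .spectrum import BinScheme

__all__ = [
    "save_spectral_sinogram", "load_spectral_sinogram",
    "save_basis_sinogram", "load_basis_sinogram",
    "save_sinogram", "load_sinogram",
    "save_prior", "load_prior",
    "save_image", "load_image",
]


def _write_geometry(grp: h5py.Group, geometry: Geometry) -> None:
    for key in ("source_to_detector", "source_to_isocenter", "n_detector",
                "detector_pitch", "n_views"):
        grp.attrs[key] = getattr(geometry, key)


def _read_geometry(grp: h5py.Group) -> Geometry:
    return Geometry(
        source_to_detector=float(grp.attrs["source_to_detector"]),
        source_to_isocenter=float(grp.attrs["source_to_isocenter"]),
        n_detector=int(grp.attrs["n_detector"]),
        detector_pitch=float(grp.attrs["detector_pitch"]),
        n_views=int(grp.attrs["n_views"]),
    )


def save_spectral_sinogram(path, sino: SpectralSinogram) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("counts", data=sino.counts, compression="gzip")
        fh.create_dataset("incident", data=sino.incident)
        fh.create_dataset("bin_edges", data=sino.bin_scheme.edges)
        if sino.seed is not None:
            fh.attrs["seed"] = sino.seed
        _write_geometry(fh, sino.geometry)


def load_spectral_sinogram(path) -> SpectralSinogram:
    with h5py.File(path, "r") as fh:
        return SpectralSinogram(
            counts=fh["counts"][...],
            bin_scheme=BinScheme(fh["bin_edges"][...]),
            geometry=_read_geometry(fh),
            incident=fh["incident"][...],
            seed=int(fh.attrs["seed"]) if "seed" in fh.attrs else None,
        )


def save_basis_sinogram(path, basis: BasisSinogram) -> None:
    with h5py.File(path, "w") as fh:
        for name in ("a1_line", "a2_line", "a3_line", "negloglik"):
            fh.create_dataset(name, data=getattr(basis, name), compression="gzip")
        fh.create_dataset("converged", data=basis.converged)
        _write_geometry(fh, basis.geometry)


def load_basis_sinogram(path) -> BasisSinogram:
    with h5py.File(path, "r") as fh:
        return BasisSinogram(
            a1_line=fh["a1_line"][...],
            a2_line=fh["a2_line"][...],
            a3_line=fh["a3_line"][...],
            geometry=_read_geometry(fh),
            converged=fh["converged"][...].astype(bool),
            negloglik=fh["negloglik"][...],
        )


def save_sinogram(path, sino: Sinogram) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("values", data=sino.values, compression="gzip")
        fh.attrs["domain"] = sino.domain
        if sino.source_intensity is not None:
            fh.attrs["source_intensity"] = sino.source_intensity
        _write_geometry(fh, sino.geometry)


def load_sinogram(path) -> Sinogram:
    with h5py.File(path, "r") as fh:
        return Sinogram(
            values=fh["values"][...],
            geometry=_read_geometry(fh),
            domain=str(fh.attrs["domain"]),
            source_intensity=(
                float(fh.attrs["source_intensity"])
                if "source_intensity" in fh.attrs else None
            ),
        )


def save_prior(path, prior: MetalPrior) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("density", data=prior.density_image, compression="gzip")
        fh.create_dataset("mask", data=prior.mask)
        fh.attrs["threshold_fraction"] = prior.threshold_fraction
        fh.attrs["pixel_size"] = prior.pixel_size


def load_prior(path) -> MetalPrior:
    with h5py.File(path, "r") as fh:
        return MetalPrior(
            density_image=fh["density"][...],
            mask=fh["mask"][...].astype(bool),
            threshold_fraction=float(fh.attrs["threshold_fraction"]),
            pixel_size=float(fh.attrs["pixel_size"]),
        )


def save_image(path, image: ReconImage) -> None:
    """32-bit TIFF with pixel size and mono energy in the description."""
    path = Path(path)
    tifffile.imwrite(
        path,
        image.mu.astype(np.float32),
        description=(
            f"mu(1/cm)@{image.mono_energy}keV;pixel_size_cm={image.pixel_size};"
            f"method={image.method}"
        ),
    )


def load_image(path) -> ReconImage:
    with tifffile.TiffFile(path) as tf:
        mu = tf.asarray().astype(float)
        desc = tf.pages[0].description or ""
    meta = dict(
        item.split("=", 1) for item in desc.split(";") if "=" in item
    )
    energy = 55.0
    if desc.startswith("mu(1/cm)@"):
        energy = float(desc.split("@")[1].split("keV")[0])
    return ReconImage(
        np.clip(mu, 0.0, None),
        pixel_size=float(meta.get("pixel_size_cm", 0.05)),
        mono_energy=energy,
        method=meta.get("method", "unknown"),
    )
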