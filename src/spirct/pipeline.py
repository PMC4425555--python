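"""End-to-end orchestration: simulate -> decompose -> reconstruct -> evaluate.

A :class:`RunConfig` (YAML-serializable) pins every knob and seed; one
master seed spawns independent per-stage seeds (acquisition noise, subset
shuffling) so a run is exactly reproducible.  ``run_pipeline`` executes the
two-step workflow and writes every artifact plus a manifest with content
hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as spio
from .decompose import (
    SpectralModel,
    decompose_sinogram,
    extract_metal_prior,
    pseudo_mono_sinogram,
)
from .evaluate import (
    LineSpec,
    artifact_index,
    compare_masks,
    line_profile,
    profile_rmse,
)
from .phantom import PhantomSpec, build_jaw_phantom
from .projector import Geometry, simulate_acquisition
from .recon import ReconConfig, fbp_reconstruct, reconstruct
from .spectrum import default_spectrum, load_spectrum, make_bin_scheme

__all__ = ["RunConfig", "run_pipeline"]

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything one desk-scale study run depends on."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    geometry: Geometry = field(default_factory=Geometry)
    spectrum_path: str | None = None  # None: shipped 125-kVp fixture
    n_windows: int = 6
    photon_budget: float = 1e13
    mono_energy: float = 55.0
    threshold_fraction: float = 0.10
    recon: ReconConfig = field(default_factory=ReconConfig)
    master_seed: int = 0
    output_dir: str = "spirct_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "phantom" in kwargs:
            kwargs["phantom"] = PhantomSpec(**kwargs["phantom"])
        if "geometry" in kwargs:
            kwargs["geometry"] = Geometry(**kwargs["geometry"])
        if "recon" in kwargs:
            kwargs["recon"] = ReconConfig(**kwargs["recon"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        payload = {k: v for k, v in self.to_dict().items() if k != "output_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]

    def stage_seeds(self) -> dict[str, int]:
        """Independent per-stage seeds below 2^31, spawned from master_seed."""
        ss = np.random.SeedSequence(self.master_seed)
        acq, shuffle = ss.spawn(2)
        return {
            "acquisition": int(acq.generate_state(1)[0] % (2**31)),
            "subsets": int(shuffle.generate_state(1)[0] % (2**31)),
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full two-step workflow; returns the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = config.stage_seeds()
    chash = config.config_hash()
    n = config.phantom.grid_size
    h = config.phantom.pixel_size
    artifacts: dict[str, str] = {}

    def emit(name, saver, obj):
        path = out / name
        saver(path, obj)
        artifacts[name] = _sha256(path)
        return path

    log.info("stage: simulate (seed %d)", seeds["acquisition"])
    material = build_jaw_phantom(config.phantom)
    spectrum = (
        default_spectrum()
        if config.spectrum_path is None
        else load_spectrum(config.spectrum_path)
    )
    bins = make_bin_scheme(n_windows=config.n_windows, spectrum=spectrum)
    spectral = simulate_acquisition(
        material, spectrum, bins, config.geometry,
        photon_budget=config.photon_budget, seed=seeds["acquisition"],
    )
    emit("spectral.h5", spio.save_spectral_sinogram, spectral)

    log.info("stage: decompose")
    model = SpectralModel.from_sinogram(spectral, spectrum)
    basis = decompose_sinogram(spectral, model)
    emit("basis.h5", spio.save_basis_sinogram, basis)
    prior = extract_metal_prior(
        basis, config.geometry, n, h, threshold_fraction=config.threshold_fraction
    )
    emit("prior.h5", spio.save_prior, prior)
    y_star = pseudo_mono_sinogram(
        basis, config.mono_energy, source_intensity=config.photon_budget
    )
    emit("mono.h5", spio.save_sinogram, y_star)

    log.info("stage: reconstruct (fbp, ir, spir)")
    rcfg = ReconConfig(
        **{**asdict(config.recon),
           "seed": seeds["subsets"], "mono_energy": config.mono_energy}
    )
    fbp = fbp_reconstruct(y_star, config.geometry, n, h)
    emit("fbp.tiff", spio.save_image, fbp)
    ir, ir_trace = reconstruct(y_star, config.geometry, rcfg, n_pixels=n, pixel_size=h)
    emit("ir.tiff", spio.save_image, ir)
    spir, spir_trace = reconstruct(
        y_star, config.geometry, rcfg, prior=prior, n_pixels=n, pixel_size=h
    )
    emit("spir.tiff", spio.save_image, spir)

    log.info("stage: evaluate")
    truth_mask = material.metal_mask
    report: dict = {"config_hash": chash, "seeds": seeds}
    if truth_mask.any():
        mask_report = compare_masks(prior, truth_mask, config.phantom.implant_density)
        report["mask"] = {
            "hausdorff_px": mask_report.mask_boundary_distance_max,
            "mean_boundary_px": mask_report.mask_boundary_distance_mean,
            "xor_px": mask_report.xor_pixels,
            "density_error_pct": mask_report.mean_density_error_pct,
            "density_error_g_cm3": mask_report.mean_density_error_abs,
        }
        rows, cols = np.nonzero(truth_mask)
        line = LineSpec(index=int(round(cols.mean())))
        profile = line_profile(
            {"fbp": fbp, "ir": ir, "spir": spir}, line, material, config.mono_energy
        )
        report["profile_rmse"] = {
            m: profile_rmse(profile, m) for m in profile.values
        }
        report["artifact_index_hu"] = {
            m: artifact_index(img, material)
            for m, img in [("fbp", fbp), ("ir", ir), ("spir", spir)]
        }
    report["convergence"] = {
        "ir_rel_change": ir_trace["rel_change"],
        "spir_rel_change": spir_trace["rel_change"],
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    artifacts["report.json"] = _sha256(out / "report.json")

    manifest = {
        "config": config.to_dict(),
        "config_hash": chash,
        "seeds": seeds,
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
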