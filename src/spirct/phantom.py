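"""Rasterized jaw phantom: soft-tissue body, spine with marrow, a molar arch
with a two-tooth gap, and a pure-gold implant embedded in one molar.

Every material is represented exactly in the two non-gold bases: its
published attenuation curve is least-squares projected onto
[E^-3, f_KN(E)], so the phantom IS the model mu(E) = a1 E^-3 + a2 f_KN(E)
(+ a3 f_Au(E) on the implant).  Geometry is a desk-scale stand-in: a
256 x 256 grid at 0.05 cm/pixel by default, implant diameter ~10 pixels so a
one-pixel boundary error is measurable.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import scipy.ndimage as ndi
from scipy.optimize import nnls

from .physics import BasisCoefficients, klein_nishina_basis, photoelectric_basis

__all__ = [
    "PhantomSpec",
    "MaterialMap",
    "material_coefficients",
    "build_jaw_phantom",
    "implant_mask",
    "perturb_mask",
]

GOLD_DENSITY = 19.3  # g/cm^3, pure gold

_MATERIAL_FIT: dict[str, BasisCoefficients] | None = None


def material_coefficients() -> dict[str, BasisCoefficients]:
    """(a1, a2) per phantom material, fitted to the shipped attenuation table.

    Non-negative least squares of each material's linear attenuation curve
    (20-120 keV) onto the photoelectric and Klein-Nishina bases.
    """
    global _MATERIAL_FIT
    if _MATERIAL_FIT is not None:
        return _MATERIAL_FIT
    path = resources.files("spirct.data").joinpath("material_attenuation_approx.csv")
    with path.open() as fh:
        header = None
        rows = []
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split(",")
            else:
                rows.append([float(x) for x in line.split(",")])
    table = np.asarray(rows)
    energies = table[:, 0]
    design = np.stack(
        [photoelectric_basis(energies), klein_nishina_basis(energies)], axis=1
    )
    fit = {}
    for j, name in enumerate(header[1:], start=1):
        coef, _ = nnls(design, table[:, j])
        fit[name] = BasisCoefficients(float(coef[0]), float(coef[1]), 0.0)
    _MATERIAL_FIT = fit
    return fit


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric description of the jaw phantom (lengths in cm)."""

    grid_size: int = 256
    pixel_size: float = 0.05
    implant_shape: str = "circle"  # circle | horseshoe | triangle | none
    implant_density: float = GOLD_DENSITY
    implant_radius: float = 0.25
    body_center: tuple[float, float] = (0.0, 0.0)
    body_axes: tuple[float, float] = (5.3, 4.3)  # (x, y) semi-axes
    spine_center: tuple[float, float] = (0.0, -2.6)
    spine_radius: float = 0.9
    marrow_radius: float = 0.45
    arch_center: tuple[float, float] = (0.0, 0.9)
    arch_radius: float = 3.0
    n_molars: int = 16
    gap_teeth: tuple[int, ...] = (4, 5)  # removed molars (the gap)
    implant_tooth: int = 11
    tooth_radius: float = 0.33

    def __post_init__(self):
        if self.grid_size < 64:
            raise ValueError("grid_size must be at least 64")
        if self.implant_density < 0:
            raise ValueError("implant density must be non-negative")
        if self.implant_shape not in {"circle", "horseshoe", "triangle", "none"}:
            raise ValueError(f"unknown implant shape {self.implant_shape!r}")
        if self.implant_radius > self.tooth_radius + 1e-9 and self.implant_shape != "none":
            raise ValueError("implant must fit inside one tooth")


@dataclass
class MaterialMap:
    """Per-pixel basis coefficient planes (a1, a2, a3) plus metadata."""

    a1: np.ndarray  # keV^3/cm
    a2: np.ndarray  # 1/cm
    a3: np.ndarray  # g/cm^3
    pixel_size: float  # cm

    def __post_init__(self):
        for plane in (self.a1, self.a2, self.a3):
            if plane.shape != self.a1.shape or np.any(plane < 0):
                raise ValueError("coefficient planes must match and be non-negative")

    @property
    def metal_mask(self) -> np.ndarray:
        return self.a3 > 0

    @property
    def shape(self) -> tuple[int, int]:
        return self.a1.shape

    def attenuation_image(self, energy: float, gold_table=None) -> np.ndarray:
        """True mu (1/cm) at ``energy`` keV per pixel."""
        from .physics import gold_attenuation_basis

        return (
            self.a1 * photoelectric_basis(energy)
            + self.a2 * klein_nishina_basis(energy)
            + self.a3 * gold_attenuation_basis(energy, gold_table)
        )


def _pixel_grid(n: int, h: float):
    """Physical (x, y) of pixel centers; array row r maps to y, column c to x."""
    coords = (np.arange(n) - (n - 1) / 2.0) * h
    x = coords[np.newaxis, :]
    y = coords[:, np.newaxis]
    return x, y


def _implant_stamp(shape: str, x, y, cx, cy, radius):
    dx, dy = x - cx, y - cy
    r2 = dx**2 + dy**2
    if shape == "circle":
        return r2 <= radius**2
    if shape == "horseshoe":
        ring = (r2 <= radius**2) & (r2 >= (0.5 * radius) ** 2)
        opening = (np.abs(np.degrees(np.arctan2(dy, dx)) - 90.0) < 40.0)
        return ring & ~opening
    if shape == "triangle":
        # equilateral triangle, apex up, circumscribed radius = radius
        angles = np.deg2rad([90.0, 210.0, 330.0])
        inside = np.ones_like(r2, dtype=bool)
        for k in range(3):
            # half-plane inside each edge (edge between vertex k and k+1)
            x1, y1 = radius * np.cos(angles[k]), radius * np.sin(angles[k])
            x2, y2 = radius * np.cos(angles[(k + 1) % 3]), radius * np.sin(angles[(k + 1) % 3])
            inside &= (x2 - x1) * (dy - y1) - (y2 - y1) * (dx - x1) >= 0
        return inside
    raise ValueError(shape)


def build_jaw_phantom(spec: PhantomSpec = PhantomSpec()) -> MaterialMap:
    """Deterministically rasterize ``spec`` into basis-coefficient planes."""
    mats = material_coefficients()
    n, h = spec.grid_size, spec.pixel_size
    x, y = _pixel_grid(n, h)
    a1 = np.zeros((n, n))
    a2 = np.zeros((n, n))
    a3 = np.zeros((n, n))

    def paint(mask, material):
        c = mats[material]
        a1[mask] = c.a1
        a2[mask] = c.a2

    (bx, by), (ax_, ay_) = spec.body_center, spec.body_axes
    body = ((x - bx) / ax_) ** 2 + ((y - by) / ay_) ** 2 <= 1.0
    paint(body, "soft_tissue")

    sx, sy = spec.spine_center
    spine = (x - sx) ** 2 + (y - sy) ** 2 <= spec.spine_radius**2
    paint(spine, "bone_cortical")
    marrow = (x - sx) ** 2 + (y - sy) ** 2 <= spec.marrow_radius**2
    paint(marrow, "marrow")

    # molar arch: evenly spaced positions on an arc, minus the gap teeth
    thetas = np.deg2rad(np.linspace(-15.0, 195.0, spec.n_molars))
    cxs = spec.arch_center[0] + spec.arch_radius * np.cos(thetas)
    cys = spec.arch_center[1] + spec.arch_radius * np.sin(thetas)
    implant_center = None
    for i, (tx, ty) in enumerate(zip(cxs, cys)):
        if i in spec.gap_teeth:
            continue
        tooth = (x - tx) ** 2 + (y - ty) ** 2 <= spec.tooth_radius**2
        paint(tooth, "tooth")
        if i == spec.implant_tooth:
            implant_center = (tx, ty)

    if spec.implant_shape != "none":
        if implant_center is None:
            raise ValueError("implant tooth was removed by the gap")
        stamp = _implant_stamp(
            spec.implant_shape, x, y, implant_center[0], implant_center[1], spec.implant_radius
        )
        # the implant replaces tooth material: gold-only pixels
        a1[stamp] = 0.0
        a2[stamp] = 0.0
        a3[stamp] = spec.implant_density
    return MaterialMap(a1, a2, a3, h)


def implant_mask(material_map: MaterialMap) -> np.ndarray:
    """Ground-truth boolean metal mask (a3 > 0)."""
    return material_map.metal_mask


def perturb_mask(mask: np.ndarray, pixels: int) -> np.ndarray:
    """Erode (pixels < 0) or dilate (pixels > 0) a mask by |pixels|.

    Used for the inaccurate-prior experiment: the enforced implant footprint
    is made 1-2 pixels smaller or larger than the decomposed one.
    """
    if abs(pixels) > 2:
        raise ValueError("only perturbations within +/-2 pixels are supported")
    if pixels == 0:
        return mask.copy()
    structure = ndi.generate_binary_structure(2, 1)  # unit-radius cross (4-conn)
    if pixels > 0:
        return ndi.binary_dilation(mask, structure, iterations=pixels)
    out = ndi.binary_erosion(mask, structure, iterations=-pixels)
    if mask.any() and not out.any():
        raise ValueError("erosion emptied the mask")
    return out
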