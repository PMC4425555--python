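"""Projection-domain material decomposition by Poisson maximum likelihood.

Per ray, the expected counts in window n are

    lambda_n(A) = sum_E S_n(E) Phi(E) exp(-A1 E^-3 - A2 f_KN(E) - A3 f_Au(E)),

and the decomposition minimizes the negative Poisson log-likelihood
sum_n [lambda_n - m_n ln lambda_n] over the three basis line integrals
A = (A1, A2, A3).  The sinogram-level driver sweeps across detector
elements, warm-starting each ray from its neighbour, which keeps the
solution continuous through photon-starved rays behind the implant where
the likelihood is nearly flat.

From the decomposed basis sinograms the module synthesizes the
pseudo-monochromatic counts sinogram at a chosen energy (default 55 keV)
and the thresholded gold prior image used by the prior-driven
reconstruction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

from .fbp import fbp_line_integrals
from .physics import (
    BasisSet,
    GoldTable,
    default_basis_set,
    gold_attenuation_basis,
    klein_nishina_basis,
    photoelectric_basis,
)
from .projector import Geometry, Sinogram, SpectralSinogram
from .spectrum import BinScheme, Spectrum

__all__ = [
    "SpectralModel",
    "BasisSinogram",
    "MetalPrior",
    "neg_log_likelihood",
    "decompose_ray",
    "decompose_sinogram",
    "pseudo_mono_sinogram",
    "extract_metal_prior",
]

LAMBDA_FLOOR = 1e-12


class SpectralModel:
    """Per-ray forward model context: spectrum, windows, basis functions.

    The spectrum must be normalized to the per-ray photon budget of the
    acquisition being decomposed (``from_sinogram`` does this from the
    recorded incident counts).
    """

    def __init__(self, spectrum: Spectrum, bins: BinScheme, basis: BasisSet | None = None):
        if basis is None:
            basis = default_basis_set(spectrum.energies)
        if basis.energies.shape != spectrum.energies.shape:
            raise ValueError("basis set must be evaluated on the spectrum grid")
        self.spectrum = spectrum
        self.bins = bins
        self.basis = basis
        self.window = bins.window_matrix(spectrum.energies)  # (N, nE)
        self.fluence = spectrum.fluence
        self.incident = self.window @ self.fluence  # (N,)
        # internal variable scaling: z_j = a_j * c_j with c_j the
        # fluence-weighted mean basis value, so z is an optical-depth scale
        w = self.fluence / self.fluence.sum()
        self.scale = basis.matrix.T @ w  # (3,)
        self.scaled_matrix = basis.matrix / self.scale  # (nE, 3), columns O(1)

    @classmethod
    def from_sinogram(
        cls,
        spectral: SpectralSinogram,
        spectrum: Spectrum,
        gold_table: GoldTable | None = None,
    ) -> "SpectralModel":
        budget = float(spectral.incident[0].sum())
        spec = spectrum.normalized(budget)
        return cls(spec, spectral.bin_scheme, default_basis_set(spec.energies, gold_table))

    @property
    def n_bins(self) -> int:
        return self.bins.n_bins

    def expected_counts(self, a: np.ndarray) -> np.ndarray:
        """lambda_n for line integrals ``a`` (..., 3); floored at 1e-12."""
        depth = np.asarray(a, dtype=float) @ self.basis.matrix.T
        lam = (self.fluence * np.exp(-np.clip(depth, -50.0, 700.0))) @ self.window.T
        return np.maximum(lam, LAMBDA_FLOOR)


def neg_log_likelihood(a, counts, model: SpectralModel) -> float:
    """sum_n [lambda_n(a) - m_n ln lambda_n(a)] (the m_n! term is dropped)."""
    m = np.asarray(counts, dtype=float)
    if np.any(m < 0):
        raise ValueError("counts must be non-negative")
    lam = model.expected_counts(a)
    return float(np.sum(lam - np.where(m > 0, m * np.log(lam), 0.0)))


def _effective_basis(model: SpectralModel) -> np.ndarray:
    """(N, 3) fluence-weighted mean basis value per window."""
    num = model.window @ (model.fluence[:, None] * model.basis.matrix)
    return num / model.incident[:, None]


def linearized_init(counts: np.ndarray, model: SpectralModel) -> np.ndarray:
    """Water-equivalent-style start from windowed log ratios.

    Solves the linearized system  ln(I_n / m_n) = sum_j Fbar_nj a_j  by
    count-weighted least squares over windows with m_n > 0.
    """
    m = np.asarray(counts, dtype=float)
    pos = m > 0
    if pos.sum() < 3:
        return np.zeros(3)
    l = np.log(model.incident[pos] / m[pos])
    design = _effective_basis(model)[pos]
    w = np.sqrt(m[pos])
    sol, *_ = np.linalg.lstsq(design * w[:, None], l * w, rcond=None)
    return sol


def decompose_ray(
    counts,
    model: SpectralModel,
    init=None,
    xatol: float = 1e-7,
    fatol: float = 1e-9,
    maxfev: int = 2000,
):
    """Nelder-Mead minimization of the per-ray negative log-likelihood.

    Optimization runs unconstrained in internally scaled variables
    (optical-depth units); the returned line integrals are clipped at zero.
    Returns ``(a, negloglik, converged)``.
    """
    m = np.asarray(counts, dtype=float)
    if m.size < 3:
        raise ValueError("need at least as many windows as basis functions (3)")
    a0 = linearized_init(m, model) if init is None else np.asarray(init, dtype=float)
    z0 = a0 * model.scale

    def objective(z):
        return neg_log_likelihood(z / model.scale, m, model)

    res = minimize(
        objective,
        z0,
        method="Nelder-Mead",
        options={"xatol": xatol, "fatol": fatol, "maxfev": maxfev},
    )
    a = np.clip(res.x / model.scale, 0.0, None)
    return a, neg_log_likelihood(a, m, model), bool(res.success)


def _newton_sweep_step(z, m, model, max_iter=60, gtol=1e-9, step_tol=1e-10):
    """Damped-Newton NLL minimization, vectorized over rays.

    ``z``: (R, 3) scaled line integrals (warm starts, modified-free);
    ``m``: (R, N) counts.  Returns (z_opt, nll, converged).
    """
    Fs = model.scaled_matrix  # (nE, 3)
    phi = model.fluence
    W = model.window  # (N, nE)
    R = z.shape[0]
    nu = np.full(R, 1e-3)
    eye = np.eye(3)

    def nll_of(zz):
        depth = np.clip(zz @ Fs.T, -50.0, 700.0)
        lam = np.maximum((phi * np.exp(-depth)) @ W.T, LAMBDA_FLOOR)
        return np.sum(lam - np.where(m > 0, m * np.log(lam), 0.0), axis=1), lam

    nll, lam = nll_of(z)
    converged = np.zeros(R, dtype=bool)
    for _ in range(max_iter):
        active = ~converged
        if not active.any():
            break
        u = phi * np.exp(-np.clip(z @ Fs.T, -50.0, 700.0))  # (R, nE)
        dlam = -np.einsum("re,ej,ne->rnj", u, Fs, W, optimize=True)  # (R,N,3)
        d2lam = np.einsum("re,ej,ek,ne->rnjk", u, Fs, Fs, W, optimize=True)
        ratio = m / lam  # (R, N)
        g = np.einsum("rn,rnj->rj", 1.0 - ratio, dlam)
        H = np.einsum("rn,rnjk->rjk", 1.0 - ratio, d2lam)
        H += np.einsum("rn,rnj,rnk->rjk", ratio / lam, dlam, dlam)
        diag = np.einsum("rjj->rj", H).copy()
        damp = nu[:, None, None] * (np.abs(diag)[:, :, None] * eye + 1e-9 * eye)
        try:
            step = np.linalg.solve(H + damp, -g[..., np.newaxis])[..., 0]
        except np.linalg.LinAlgError:
            step = -g
        # trust-region cap keeps flat (starved) rays anchored near warm start
        norms = np.linalg.norm(step, axis=1)
        cap = 5.0
        shrink = np.where(norms > cap, cap / np.maximum(norms, 1e-300), 1.0)
        step = step * shrink[:, None]
        z_trial = z + np.where(active[:, None], step, 0.0)
        nll_trial, lam_trial = nll_of(z_trial)
        better = nll_trial <= nll + 1e-9 * np.abs(nll)
        accept = active & better
        z[accept] = z_trial[accept]
        nll[accept] = nll_trial[accept]
        lam[accept] = lam_trial[accept]
        nu[accept] = np.maximum(nu[accept] / 3.0, 1e-8)
        nu[active & ~better] *= 10.0
        gnorm = np.linalg.norm(g, axis=1)
        small_step = np.linalg.norm(step, axis=1) < step_tol
        converged |= active & (
            (gnorm < gtol * (1.0 + np.abs(nll))) | (accept & small_step)
        )
        converged |= active & (nu > 1e12)  # damping exhausted: flat likelihood
    return z, nll, converged


STARVED_MIN_COUNTS = 10.0  # a window "measures" a ray if it holds >= this
GOLD_LINE_MAX = 40.0  # g/cm^2 search bound for the 1-D gold re-estimate


def _rescue_starved_rays(counts, a_out, conv_out, nll_out, model: SpectralModel):
    """Re-estimate the gold line integral on photon-starved rays.

    A ray with fewer than three windows holding at least
    ``STARVED_MIN_COUNTS`` counts cannot determine all three line integrals:
    its likelihood is flat along a ridge and the three-parameter estimate is
    arbitrary along it.  Behind the implant the non-gold anatomy varies
    smoothly across the narrow shadow, so for every starved run within a
    view the photoelectric and Compton line integrals are linearly
    interpolated from the flanking well-determined rays and only the gold
    line integral is re-estimated by one-dimensional maximum likelihood.
    Modifies ``a_out``/``conv_out``/``nll_out`` in place.
    """
    from scipy.optimize import minimize_scalar

    nv, nd = counts.shape[:2]
    informative = (counts >= STARVED_MIN_COUNTS).sum(axis=2)  # (nv, nd)
    starved = informative < 3
    det = np.arange(nd)
    for v in range(nv):
        bad = starved[v]
        good = ~bad & conv_out[v]  # anchor only on well-determined solutions
        if not bad.any() or not good.any():
            continue
        for j in (0, 1):
            a_out[v, bad, j] = np.interp(det[bad], det[good], a_out[v, good, j])
        fixed = a_out[v, :, :2]
        for d in np.nonzero(bad)[0]:
            m = counts[v, d]
            a12 = fixed[d]

            def nll_a3(a3, a12=a12, m=m):
                return neg_log_likelihood([a12[0], a12[1], a3], m, model)

            res = minimize_scalar(
                nll_a3, bounds=(0.0, GOLD_LINE_MAX), method="bounded",
                options={"xatol": 1e-8},
            )
            a_out[v, d, 2] = res.x
            nll_out[v, d] = res.fun
            # saturation at the search bound means the ray stays unresolved
            conv_out[v, d] = bool(res.success) and res.x < GOLD_LINE_MAX * 0.999
    return starved


@dataclass
class BasisSinogram:
    """Decomposed basis line integrals per (view, detector element)."""

    a1_line: np.ndarray  # keV^3/cm * cm
    a2_line: np.ndarray  # 1/cm * cm
    a3_line: np.ndarray  # g/cm^2
    geometry: Geometry
    converged: np.ndarray  # bool per ray
    negloglik: np.ndarray  # per ray

    def __post_init__(self):
        shape = (self.geometry.n_views, self.geometry.n_detector)
        for arr in (self.a1_line, self.a2_line, self.a3_line, self.converged, self.negloglik):
            if arr.shape != shape:
                raise ValueError("basis sinogram planes must match geometry")
        for arr in (self.a1_line, self.a2_line, self.a3_line, self.negloglik):
            if not np.all(np.isfinite(arr)):
                raise ValueError("basis sinogram must be finite")

    @property
    def lines(self) -> np.ndarray:
        return np.stack([self.a1_line, self.a2_line, self.a3_line], axis=-1)


def decompose_sinogram(
    spectral: SpectralSinogram,
    model: SpectralModel,
    engine: str = "newton",
    nelder_mead_fallback: bool = True,
) -> BasisSinogram:
    """Per-ray ML decomposition of a full spectral sinogram.

    Sweeps detector elements in order, warm-starting every ray from the
    solution of its neighbouring detector element in the same view (the
    first element starts from air).  The default engine is a vectorized
    damped-Newton minimizer of the same negative log-likelihood as
    :func:`decompose_ray`; rays it flags as non-converged are re-solved
    with Nelder-Mead.  Deterministic given its inputs.
    """
    nv, nd = spectral.geometry.n_views, spectral.geometry.n_detector
    counts = np.asarray(spectral.counts, dtype=float)
    z = np.zeros((nv, 3))  # air warm start for detector element 0
    a_out = np.zeros((nv, nd, 3))
    nll_out = np.zeros((nv, nd))
    conv_out = np.zeros((nv, nd), dtype=bool)
    if engine not in {"newton", "nelder-mead"}:
        raise ValueError(f"unknown engine {engine!r}")
    for d in range(nd):
        m = counts[:, d, :]
        if engine == "newton":
            z, nll, conv = _newton_sweep_step(z.copy(), m, model)
            if not conv.all():
                # retry stragglers from the linearized start: a ray whose
                # warm start was wrecked upstream can need a fresh origin
                retry = np.nonzero(~conv)[0]
                z2 = np.stack([linearized_init(m[v], model) for v in retry]) * model.scale
                z2, nll2, conv2 = _newton_sweep_step(z2, m[retry], model)
                better = nll2 < nll[retry]
                z[retry[better]] = z2[better]
                nll[retry[better]] = nll2[better]
                conv[retry[better]] = conv2[better]
        else:
            z_new = np.empty_like(z)
            nll = np.empty(nv)
            conv = np.empty(nv, dtype=bool)
            for v in range(nv):
                a, fval, ok = decompose_ray(m[v], model, init=z[v] / model.scale)
                z_new[v] = a * model.scale
                nll[v] = fval
                conv[v] = ok
            z = z_new
        a_out[:, d, :] = z / model.scale
        nll_out[:, d] = nll
        conv_out[:, d] = conv
    informative = (counts >= STARVED_MIN_COUNTS).sum(axis=2)
    starved = informative < 3
    if nelder_mead_fallback and engine == "newton" and not conv_out.all():
        # starved rays skip this: their unconstrained likelihood is flat and
        # Nelder-Mead would wander along the ridge; they are rescued below
        for v, d in zip(*np.nonzero(~conv_out & ~starved)):
            init = a_out[v, d - 1] if d > 0 else None
            a, fval, ok = decompose_ray(counts[v, d], model, init=init)
            if fval <= nll_out[v, d]:
                a_out[v, d] = a
                nll_out[v, d] = fval
                conv_out[v, d] = ok
    _rescue_starved_rays(counts, a_out, conv_out, nll_out, model)
    a_out = np.clip(a_out, 0.0, None)
    return BasisSinogram(
        a1_line=a_out[..., 0],
        a2_line=a_out[..., 1],
        a3_line=a_out[..., 2],
        geometry=spectral.geometry,
        converged=conv_out,
        negloglik=nll_out,
    )


def pseudo_mono_sinogram(
    basis: BasisSinogram,
    energy: float = 55.0,
    source_intensity: float = 1e13,
    gold_table: GoldTable | None = None,
) -> Sinogram:
    """Synthesize the monochromatic counts sinogram y* = b exp(-l) at ``energy``."""
    if source_intensity <= 0:
        raise ValueError("source intensity must be positive")
    l = (
        basis.a1_line * photoelectric_basis(energy)
        + basis.a2_line * klein_nishina_basis(energy)
        + basis.a3_line * gold_attenuation_basis(energy, gold_table)
    )
    return Sinogram(
        source_intensity * np.exp(-l),
        basis.geometry,
        domain="counts",
        source_intensity=source_intensity,
    )


@dataclass
class MetalPrior:
    """Thresholded gold density image enforced during reconstruction."""

    density_image: np.ndarray  # g/cm^3, zero outside the mask
    mask: np.ndarray  # boolean
    threshold_fraction: float = 0.10
    pixel_size: float = 0.05

    def __post_init__(self):
        if not 0.0 < self.threshold_fraction < 1.0:
            raise ValueError("threshold fraction must be in (0, 1)")
        if np.any((self.density_image > 0) != self.mask):
            raise ValueError("density image must be positive exactly on the mask")

    @property
    def is_empty(self) -> bool:
        return not bool(self.mask.any())

    def perturbed(self, pixels: int) -> "MetalPrior":
        """Prior with the footprint eroded/dilated by |pixels| (+-2 max).

        Pixels added by dilation take the mean density of the original mask.
        """
        from .phantom import perturb_mask

        new_mask = perturb_mask(self.mask, pixels)
        density = np.where(new_mask & self.mask, self.density_image, 0.0)
        grown = new_mask & ~self.mask
        if grown.any():
            density[grown] = self.density_image[self.mask].mean()
        return MetalPrior(density, new_mask, self.threshold_fraction, self.pixel_size)


def extract_metal_prior(
    basis: BasisSinogram,
    geometry: Geometry,
    n_pixels: int,
    pixel_size: float,
    threshold_fraction: float = 0.10,
    apodization: str | None = None,
    refit_density: bool = True,
    min_peak_density: float = 0.5,
) -> MetalPrior:
    """FBP the gold channel and zero pixels below ``threshold_fraction`` of max.

    The reconstructed gold image is in density units (g/cm^3) because the
    gold line integrals are in g/cm^2.  With ``refit_density`` (default) the
    densities on the thresholded support are then re-estimated by
    non-negative least squares against the gold sinogram itself: the FBP
    point-spread smears the implant boundary by about a pixel and the 10%
    threshold keeps that skirt, whereas the sinogram-consistent refit
    concentrates the density on the true footprint and drops skirt pixels
    to zero.  An all-zero gold channel yields a valid empty prior.
    """
    density = fbp_line_integrals(
        basis.a3_line, geometry, n_pixels, pixel_size, apodization=apodization
    )
    peak = density.max()
    # a relative threshold on pure decomposition noise would keep noise:
    # below any physical metal density the object holds no metal at all
    if peak <= min_peak_density:
        return MetalPrior(
            np.zeros_like(density), np.zeros_like(density, dtype=bool),
            threshold_fraction, pixel_size,
        )
    density = np.where(density < threshold_fraction * peak, 0.0, density)
    if refit_density and np.any(density > 0):
        from scipy.optimize import nnls
        from .projector import get_projector

        support = np.flatnonzero(density.ravel() > 0)
        proj = get_projector(geometry, n_pixels, pixel_size)
        a_cols = np.asarray(proj.matrix[:, support].todense())
        sol, _ = nnls(a_cols, basis.a3_line.ravel())
        refit = np.zeros(density.size)
        refit[support] = sol
        # the implant raster has no partial pixels: a few percent of the
        # peak is attribution leakage from line-integral errors, not metal
        refit[refit < 0.02 * refit.max()] = 0.0
        density = refit.reshape(density.shape)
    return MetalPrior(density, density > 0, threshold_fraction, pixel_size)
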