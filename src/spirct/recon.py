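"""Image reconstruction: FBP, prior-free penalized ML (IR), and SPIR.

All three methods reconstruct the pseudo-monochromatic counts sinogram
y* = b exp(-FP[mu]).  The penalized-ML methods maximize

    Psi(mu) = L(mu) - beta R(mu),
    L(mu)   = sum_i [y*_i ln(b e^{-l_i}) - b e^{-l_i}],   l = FP[mu],
    R(mu)   = (1/2) sum_j sum_{k in N8(j)} w_jk psi(mu_j - mu_k),

with the Lange edge-preserving penalty psi and separable paraboloidal
surrogate (SPS) updates over random 3-angle subsets:

    mu <- [ mu* + ( BP[b e^{-FP[mu*]} - y*] - beta R' )
                 / ( BP[y* FP[1]] + beta R'' ) ]_+

where mu* is mu with the metal-prior pixels overwritten by the decomposed
gold attenuation (SPIR) or mu itself (IR).  One full iteration consumes all
views once, in seeded random subsets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .decompose import MetalPrior
from .fbp import fbp_line_integrals
from .phantom import material_coefficients
from .physics import GoldTable, attenuation_at, gold_attenuation_basis
from .projector import Geometry, Sinogram, get_projector

__all__ = [
    "ReconConfig",
    "ReconImage",
    "fbp_reconstruct",
    "lange_penalty",
    "regularizer",
    "sps_update",
    "reconstruct",
    "water_attenuation",
    "mu_to_hu",
]

log = logging.getLogger(__name__)

# Shipped regularization defaults for the desk-scale default phantom, set by
# the target-noise procedure in scripts/calibrate_regularization.py
# (soft-tissue ROI noise target ~30 HU at the default photon budget).
DEFAULT_BETA = 1e10
DEFAULT_DELTA = 0.1  # 1/cm edge threshold; ~half the tissue-bone contrast


@dataclass(frozen=True)
class ReconConfig:
    """Knobs of the penalized-ML reconstruction."""

    beta: float = DEFAULT_BETA
    delta: float = DEFAULT_DELTA  # Lange edge threshold, 1/cm
    n_full_iterations: int = 15
    subset_size: int = 3
    relaxation_tau: float = 1.0  # step alpha_k = tau/(tau+k); <= 0 disables
    seed: int = 0
    mono_energy: float = 55.0  # keV
    source_intensity: float | None = None  # b; default: sinogram's own
    enforce_prior: bool = True

    def __post_init__(self):
        if self.beta < 0 or self.delta <= 0:
            raise ValueError("need beta >= 0 and delta > 0")
        if self.n_full_iterations < 1 or self.subset_size < 1:
            raise ValueError("need at least one iteration and one angle per subset")


@dataclass
class ReconImage:
    """Attenuation image (1/cm at ``mono_energy``) with provenance."""

    mu: np.ndarray
    pixel_size: float
    mono_energy: float = 55.0
    method: str = "unknown"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if not np.all(np.isfinite(self.mu)):
            raise ValueError("reconstruction must be finite")
        if np.any(self.mu < 0):
            raise ValueError("attenuation image must be non-negative")


def fbp_reconstruct(
    sino: Sinogram,
    geometry: Geometry | None = None,
    n_pixels: int = 256,
    pixel_size: float = 0.05,
    apodization: str | None = None,
) -> ReconImage:
    """Fan-beam FBP.  Counts-domain input is log-converted with y* floored
    at one count; negative output pixels are clipped at zero."""
    geometry = geometry or sino.geometry
    if sino.domain == "counts":
        b = sino.source_intensity
        if b is None:
            raise ValueError("counts-domain sinogram needs a source intensity")
        floored = np.maximum(sino.values, 1.0)
        n_floored = int(np.count_nonzero(sino.values < 1.0))
        if n_floored:
            log.info("fbp: floored %d starved ray(s) at one count", n_floored)
        lines = np.log(b / floored)
    else:
        lines = sino.values
    image = fbp_line_integrals(lines, geometry, n_pixels, pixel_size, apodization)
    return ReconImage(
        np.clip(image, 0.0, None), pixel_size,
        method="fbp", meta={"apodization": apodization},
    )


def lange_penalty(t, delta: float):
    """Lange's edge-preserving penalty and its derivatives.

    psi(t)   = delta^2 [ |t/delta| - ln(1 + |t/delta|) ]
    psi'(t)  = t / (1 + |t|/delta)        (odd, bounded by delta)
    psi''(t) = 1 / (1 + |t|/delta)^2      (in (0, 1])
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    t = np.asarray(t, dtype=float)
    r = np.abs(t) / delta
    psi = delta**2 * (r - np.log1p(r))
    dpsi = t / (1.0 + r)
    d2psi = 1.0 / (1.0 + r) ** 2
    if t.ndim == 0:
        return float(psi), float(dpsi), float(d2psi)
    return psi, dpsi, d2psi


_NEIGHBOR_OFFSETS = (
    (0, 1, 1.0),
    (1, 0, 1.0),
    (1, 1, 1.0 / np.sqrt(2.0)),
    (1, -1, 1.0 / np.sqrt(2.0)),
)


def regularizer(mu: np.ndarray, delta: float, majorizer: bool = False):
    """8-neighbour Lange roughness penalty.

    Returns ``(value, gradient, curvature)`` where gradient_j =
    sum_k w_jk psi'(mu_j - mu_k) and curvature_j = sum_k w_jk psi''.
    Axial pairs weigh 1, diagonal pairs 1/sqrt(2).

    With ``majorizer=True`` the curvature uses psi'(t)/t = 1/(1 + |t|/delta)
    instead of psi'': psi'' under-curves away from zero and is not a valid
    surrogate curvature, which destabilizes strongly regularized updates;
    psi'/t majorizes the penalty (standard half-quadratic curvature).
    """
    mu = np.asarray(mu, dtype=float)
    value = 0.0
    grad = np.zeros_like(mu)
    curv = np.zeros_like(mu)
    n0, n1 = mu.shape
    for dy, dx, w in _NEIGHBOR_OFFSETS:
        s0a = slice(max(dy, 0), n0 + min(dy, 0) or n0)
        s0b = slice(max(-dy, 0), n0 + min(-dy, 0) or n0)
        s1a = slice(max(dx, 0), n1 + min(dx, 0) or n1)
        s1b = slice(max(-dx, 0), n1 + min(-dx, 0) or n1)
        d = mu[s0a, s1a] - mu[s0b, s1b]
        psi, dpsi, d2psi = lange_penalty(d, delta)
        if majorizer:
            d2psi = 1.0 / (1.0 + np.abs(d) / delta)
        value += w * psi.sum()
        grad[s0a, s1a] += w * dpsi
        grad[s0b, s1b] -= w * dpsi
        curv[s0a, s1a] += w * d2psi
        curv[s0b, s1b] += w * d2psi
    return value, grad, curv


def _prior_mu(prior: MetalPrior, mono_energy: float, gold_table: GoldTable | None) -> np.ndarray:
    """Decomposed gold density converted to 1/cm at the mono energy."""
    return prior.density_image * gold_attenuation_basis(mono_energy, gold_table)


def sps_update(
    mu: np.ndarray,
    y_star: np.ndarray,
    projector,
    view_indices: np.ndarray,
    config: ReconConfig,
    b: float,
    prior_mu: np.ndarray | None = None,
    prior_mask: np.ndarray | None = None,
    step_scale: float = 1.0,
):
    """One separable-paraboloidal-surrogate update over a subset of angles.

    ``y_star`` is the full counts sinogram; only rows in ``view_indices``
    are used.  ``step_scale`` is the ordered-subsets relaxation factor (a
    diminishing step suppresses the subset limit cycle).  Returns
    ``(mu_new, n_zero_denominator)``.
    """
    mu_star = mu
    if prior_mask is not None and prior_mask.any():
        mu_star = mu.copy()
        mu_star[prior_mask] = prior_mu[prior_mask]
    y_sub = y_star[view_indices]
    l = projector.fp(mu_star, view_indices)
    lam_bar = b * np.exp(-l)
    numerator = projector.bp(lam_bar - y_sub, view_indices)
    # Safeguarded surrogate curvature: the y* FP[1] form assumes the model
    # counts track the measurement; far from convergence (and on starved
    # rays, y* ~ 0) that curvature underestimates and the step explodes.
    # Evaluating it at max(y*, model, 1) keeps every step a damped Newton
    # step and coincides with the plain form once the fit has settled.
    curve_counts = np.maximum(np.maximum(y_sub, lam_bar), 1.0)
    denominator = projector.bp(
        curve_counts * projector.ray_lengths(view_indices), view_indices
    )
    if config.beta > 0:
        _, rgrad, rcurv = regularizer(mu_star, config.delta, majorizer=True)
        numerator -= config.beta * rgrad
        denominator += config.beta * rcurv
    ok = denominator > 0
    n_zero = int(np.count_nonzero(~ok))
    update = np.where(ok, numerator / np.where(ok, denominator, 1.0), 0.0)
    return np.clip(mu_star + step_scale * update, 0.0, None), n_zero


def reconstruct(
    y_star: Sinogram,
    geometry: Geometry | None = None,
    config: ReconConfig = ReconConfig(),
    prior: MetalPrior | None = None,
    init: ReconImage | None = None,
    n_pixels: int = 256,
    pixel_size: float = 0.05,
    gold_table: GoldTable | None = None,
):
    """Penalized-ML reconstruction: IR (no prior) or SPIR (metal prior).

    Runs ``config.n_full_iterations`` full iterations; each shuffles the view
    list with the seeded RNG and consumes it in subsets of
    ``config.subset_size`` angles, applying one SPS update per subset.  With
    a prior, metal pixels are overwritten before every update and once more
    at the end.  Returns ``(ReconImage, trace)`` where ``trace`` records the
    penalized objective and relative image change per full iteration.
    """
    if y_star.domain != "counts":
        raise ValueError("penalized-ML reconstruction expects a counts-domain sinogram")
    geometry = geometry or y_star.geometry
    b = config.source_intensity or y_star.source_intensity
    if b is None:
        raise ValueError("source intensity b is required")
    if init is not None:
        n_pixels, pixel_size = init.mu.shape[0], init.pixel_size
    projector = get_projector(geometry, n_pixels, pixel_size)
    if init is None:
        init = fbp_reconstruct(y_star, geometry, n_pixels, pixel_size)
    mu = init.mu.astype(float).copy()

    use_prior = prior is not None and config.enforce_prior and not prior.is_empty
    prior_mu = prior_mask = None
    if use_prior:
        prior_mu = _prior_mu(prior, config.mono_energy, gold_table)
        prior_mask = prior.mask

    rng = np.random.default_rng(config.seed)
    n_views = geometry.n_views
    trace = {"objective": [], "rel_change": [], "zero_denominator_pixels": 0}

    def objective(m):
        l = projector.fp(m)
        lam = b * np.exp(-l)
        loglik = np.sum(y_star.values * (np.log(b) - l) - lam)
        rval, _, _ = regularizer(m, config.delta)
        return loglik - config.beta * rval

    for it in range(config.n_full_iterations):
        mu_prev = mu.copy()
        order = rng.permutation(n_views)
        if config.relaxation_tau > 0 and config.subset_size < n_views:
            alpha = config.relaxation_tau / (config.relaxation_tau + it)
        else:
            alpha = 1.0
        for start in range(0, n_views, config.subset_size):
            subset = order[start : start + config.subset_size]
            mu, n_zero = sps_update(
                mu, y_star.values, projector, subset, config, b, prior_mu, prior_mask,
                step_scale=alpha,
            )
            trace["zero_denominator_pixels"] += n_zero
            if not np.all(np.isfinite(mu)):
                raise RuntimeError(
                    f"non-finite image at full iteration {it}, subset start {start}"
                )
        denom = np.linalg.norm(mu_prev) or 1.0
        trace["rel_change"].append(float(np.linalg.norm(mu - mu_prev) / denom))
        trace["objective"].append(float(objective(mu)))
    if use_prior:
        mu[prior_mask] = prior_mu[prior_mask]
    method = "spir" if use_prior else "ir"
    image = ReconImage(
        mu, pixel_size, config.mono_energy, method=method,
        meta={"config": replace(config), "n_pixels": n_pixels},
    )
    return image, trace


_WATER_MU_CACHE: dict[float, float] = {}


def water_attenuation(energy: float = 55.0) -> float:
    """Water linear attenuation (1/cm) at ``energy``, from the in-model fit."""
    if energy not in _WATER_MU_CACHE:
        _WATER_MU_CACHE[energy] = float(
            attenuation_at(material_coefficients()["water"], energy)
        )
    return _WATER_MU_CACHE[energy]


def mu_to_hu(image: ReconImage | np.ndarray, mu_water: float | None = None) -> np.ndarray:
    """Hounsfield units: 1000 (mu - mu_water) / mu_water."""
    if isinstance(image, ReconImage):
        mu_water = mu_water or water_attenuation(image.mono_energy)
        mu = image.mu
    else:
        if mu_water is None or mu_water <= 0:
            raise ValueError("mu_water must be positive")
        mu = np.asarray(image, dtype=float)
    return 1000.0 * (mu - mu_water) / mu_water
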