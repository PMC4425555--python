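# Methods

This note records the models, the numerical choices, and the places where
the design was genuinely open, in enough detail to reproduce or audit every
number the package computes.

## Attenuation model and basis functions

Linear attenuation is modeled as `mu(x,E) = A1 E^-3 + A2 f_KN(E) + A3 f_Au(E)`.

- **Photoelectric basis**: `E^-3` with E in keV, so `A1` carries keV^3/cm.
- **Klein–Nishina basis**: the raw total-cross-section closed form in
  `alpha = E/510.975 keV`, unnormalized (its Thomson limit is 4/3; all
  constant factors are absorbed into `A2`, units 1/cm). Simulator and
  decomposer share this convention — only consistency matters. Below
  `alpha = 0.01` the closed form cancels catastrophically in float64 and is
  replaced by its fifth-order Taylor series (agreement ~1e-10 at the
  crossover).
- **Gold basis**: mass attenuation of gold (cm^2/g) from the shipped table
  `data/gold_mu_over_rho_synthetic.csv`, log-log interpolated within two
  one-sided segments that meet at the K-edge (80.7249 keV, stored as a
  doubled node), so interpolation never bridges the discontinuity. The
  table is *synthetic*: a parametric cross-section model (photoelectric
  power laws split at the edge, Klein–Nishina incoherent term at
  Z/A = 0.401, a coherent power law) anchored to well-known tabulated gold
  values (7.256 cm^2/g at 50 keV, ~2.1 → 8.9 across the edge, 5.158 at
  100 keV), regenerable with `scripts/make_gold_fixture.py`. L/M-edge
  structure below 15 keV is deliberately smoothed away; the model carries
  exactly one discontinuity. Sub-percent deviations from any particular
  published tabulation are irrelevant here because simulator and decomposer
  use the same table.

## Spectrum, detector, windows

The fixture spectrum (`data/spectrum_125kvp_w_al.csv`) models a 125-kVp
tungsten anode: Kramers bremsstrahlung plus W K-lines (8% of filtered
fluence), filtered by 2.7 mm added aluminium and 1.0 mm Al-equivalent
inherent tube filtration. The inherent term is standard tube physics, and
with it the fixture's mean energy lands at 55.41 keV, consistent with the
55.457 keV such a beam should have. The fine grid is 62 bins of 2 keV on
[1, 125] keV; the detector is ideal (D(E) = 1, no charge sharing, no
electronic noise, every photon counted in the window containing its
energy).

The six analysis windows are contiguous groups of fine bins holding
approximately equal incident fluence, with one boundary snapped to the
81 keV fine-bin edge so the gold K-edge separates the two highest windows —
without a K-edge-straddling boundary the gold channel would be barely
identifiable. Explicit window edges can be supplied instead.

## Phantom

A 256 × 256 raster at 0.05 cm/pixel (12.8 cm field of view): a soft-tissue
ellipse (5.3 × 4.3 cm half-axes), a spine disk (cortical bone, 0.9 cm) with
a marrow core, 16 molar positions on a 3 cm arch of which two adjacent ones
are removed (the gap) and 14 are rendered (0.33 cm radius, dentin-like),
and a pure-gold implant (19.3 g/cm^3) embedded in one molar — circle
(0.25 cm radius ≈ 10 px diameter), horseshoe, or triangle. Implant pixels
are gold only (`A3 = 19.3`, `A1 = A2 = 0`).

Each non-gold material's `(A1, A2)` pair is the non-negative least-squares
projection of an approximate published linear-attenuation curve
(20–120 keV anchor table in `data/material_attenuation_approx.csv`) onto
the two non-gold bases. The phantom is therefore exact *in-model* by
construction; the anchor tables only set plausible contrast scales, and the
two-basis fits track them to better than 10% everywhere (most materials to
~1%).

## Acquisition simulator

Fan-beam geometry: source–isocenter 60 cm, source–detector 80 cm, flat
detector of 256 elements at 0.07 cm pitch, 360 uniform views over 360°
(the view count makes 120 three-angle subsets tile a full rotation). The
forward projector computes exact Siddon intersection lengths into an
explicit sparse matrix; back projection is the literal transpose, so the
pair is adjoint to machine precision — the property the SPS update
requires. Expected window counts follow the polyenergetic Beer–Lambert
integral evaluated by the midpoint rule on the 2-keV grid (the grid the
model is defined on, so the quadrature is the model); measured counts are
Poisson draws from a seeded generator. Scatter is explicitly absent.

**Photon budget.** The desk-scale implant is 0.5 cm of gold — about five
times the optical depth of a ~1 mm clinical inlay — so the budget that
reproduces the *regime* of a realistic scan (every non-metal ray well
measured, through-metal rays photon-starved) is large in absolute terms.
The default, 1e13 photons/ray, was chosen so that the deepest gold chord
(optical depth ≈ 23 at its most transparent energy, just below the K-edge)
still expects ≥ 20 counts in its best window, making the decomposition
quasi-noiseless, while rays through the implant at 55 keV remain starved
(transmission e^-55). At this budget non-metal rays carry ≥ 1e8 counts.

## Decomposition

Per ray, the negative Poisson log-likelihood
`sum_n [lambda_n - m_n ln lambda_n]` is minimized over the three line
integrals. Numerics:

- `lambda` is floored at 1e-12 and the exponent clipped, so zero-count bins
  (which contribute `lambda_n` only) never produce log-domain blowups; no
  data are excluded.
- Optimization runs in scaled variables `z_j = A_j * c_j` with `c_j` the
  fluence-weighted mean basis value, putting all three unknowns on an
  optical-depth scale.
- `decompose_ray` is Nelder–Mead (tolerances 1e-7/1e-9 in scaled units,
  2000 evaluations max) from a count-weighted log-linear least-squares
  start. `decompose_sinogram` sweeps detector elements, warm-starting every
  ray from its neighbour in the same view, and uses a vectorized damped
  (Levenberg-style, trust-region-capped) Newton minimizer of the identical
  objective as its engine; rays it cannot converge are retried from the
  linearized start and finally fall back to Nelder–Mead. The two engines
  agree with each other and with an exhaustive grid-search oracle in the
  tests.
- **Photon-starved rays.** A ray with fewer than three windows holding at
  least 10 counts cannot determine three unknowns: its likelihood is flat
  along a ridge, and any unconstrained optimizer parks at an arbitrary
  ridge point. Behind the implant the non-gold anatomy varies smoothly
  across the narrow shadow, so for each starved run the photoelectric and
  Compton line integrals are linearly interpolated from the flanking
  converged rays and only the gold line integral is re-estimated by
  bounded one-dimensional ML (bound 40 g/cm^2; a ray that saturates the
  bound is flagged unresolved). Without this anchoring the gold channel is
  wrong by tens of percent behind the metal; with it, noiseless round
  trips recover all measured rays to 0.1%.

The pseudo-monochromatic sinogram is `y* = b exp(-l)` with
`l = A1 E^-3 + A2 f_KN + A3 f_Au` at 55 keV; `b` defaults to the per-ray
photon budget so `y*` is on the scale of actually transmitted counts and
the SPS statistical weights are meaningful.

**Metal prior.** The gold channel is reconstructed by fan-beam FBP
(Ram-Lak; Hann optional) and pixels below 10% of the image maximum are set
to zero. The FBP point spread smears the implant boundary by about one
pixel, and the relative threshold keeps that skirt at partial densities;
enforcing the skirt measurably poisons the surrounding tissue. The
densities on the thresholded support are therefore re-estimated by
non-negative least squares against the gold sinogram itself (a few hundred
unknowns; the support is unchanged, skirt pixels drop out). Because the
rasterized implant has no partial pixels, refit values below 2% of the
peak are attribution leakage and are zeroed. If the gold FBP peak is below
0.5 g/cm^3 — pure decomposition noise — the prior is empty (no metal in
the object) rather than thresholded noise.

## Reconstruction

All three methods consume `y*`. FBP floors starved rays at one count
before the log. The penalized-ML methods maximize `L - beta R` with the
8-neighbour Lange regularizer (axial weight 1, diagonal 1/sqrt(2)) by SPS
updates over seeded random 3-angle subsets (a full iteration consumes all
360 views), 15 full iterations by default, initialized from FBP. Three
implementation choices matter:

- **Safeguarded curvature.** The textbook subset denominator
  `BP[y* FP[1]]` assumes the model counts track the measurement; far from
  convergence, and wherever `y* ≈ 0`, it vanishes under a non-zero
  numerator and the update explodes. The curvature is evaluated at
  `max(y*, model counts, 1)` per ray, which majorizes the data term in the
  regime that matters and coincides with the plain form once the fit has
  settled.
- **Penalty curvature.** `psi''` of the Lange penalty under-curves away
  from zero and is not a valid surrogate curvature; the update uses the
  half-quadratic majorizer `psi'(t)/t = 1/(1+|t|/delta)` instead
  (`regularizer(..., majorizer=True)`); `psi''` itself remains available.
- **Subset relaxation.** Plain 3-angle ordered subsets limit-cycle at a
  relative image change of ~1e-2 per full iteration. A diminishing step
  `alpha_k = tau/(tau+k)` with tau = 1 suppresses the cycle; the default
  SPIR run crosses the 1e-3 relative-change threshold around full
  iteration 8–12, consistent with the expected 10–15-iteration horizon.

With a prior, the metal pixels are overwritten with
`density * f_Au(55 keV)` before every update and once more at the end; a
zero denominator leaves a pixel unchanged (counted and logged). Outputs are
clipped non-negative by the `[.]+` operation.

**Regularization constants.** `beta` and `delta` were set by the
target-noise procedure (`scripts/calibrate_regularization.py`): grid over
`(beta, delta)`, IR noise measured in a verified-homogeneous soft-tissue
ROI against a ~30 HU target, tooth contrast and the SPIR near-implant
index watched for degradation. Shipped defaults: `beta = 1e10`
(dimensionally, counts-scale: it balances a data term whose weights are
transmitted counts at 1e13 photons/ray), `delta = 0.1 1/cm` (about half
the tissue–bone contrast at 55 keV, so genuine edges saturate the penalty
while streak-scale fluctuations stay in its quadratic regime).

## Evaluation

- **Line profile**: nearest-pixel samples along a pixel line (default: the
  vertical line through the implant centroid), compared with the phantom's
  true attenuation at 55 keV. RMSE excludes samples within the true mask
  dilated by one pixel: the decomposed footprint is legitimately accurate
  only to ~1 px, so the enforced boundary layer is partial-volume, not
  anatomy. The metal-inclusive RMSE is also available.
- **Mask agreement**: symmetric boundary (Hausdorff and mean) distance in
  pixels via Euclidean distance transforms of the two mask boundaries,
  plus the XOR pixel count; density errors are reported as mean absolute
  g/cm^3 and percent of the true 19.3 g/cm^3 (mutually consistent by
  construction).
- **Artifact index**: mean |HU deviation| from truth in the 2–7 px annulus
  outside the true implant (starting at 2 px for the same boundary-layer
  reason). HU uses the water attenuation of the in-model water fit at
  55 keV (0.2148 1/cm).
- **Prior sensitivity**: SPIR rerun with the prior footprint eroded or
  dilated by 1–2 px (4-connected structuring element; dilated pixels take
  the mean prior density), reporting the artifact index per perturbation.

## What the synthetic data does and does not show

The simulator is an analytic, scatter-free stand-in for Monte-Carlo photon
transport: no Rayleigh or Compton-scattered photons reach the detector, no
detector blur, charge sharing, pulse pile-up or K-fluorescence escape, a
2-D slice rather than a cone beam, and the in-model phantom means the
decomposition faces no basis-mismatch error. Passing tests therefore
demonstrate the internal consistency and statistical efficiency of the
two-step method — decomposition accuracy at the counting limit, the value
of the metal prior, the sensitivity to prior errors — not its robustness
to scatter, spectrum miscalibration, or real detector physics. The
desk-scale geometry (256 detectors vs thousands, 0.05 cm pixels, one
slice) keeps every experiment within minutes on one CPU; problem sizes
used by the test suite are smaller still (64–128 px grids, 60–90 views)
except for the end-to-end checks, which run at the full default scale.

## Known limitations

- Only the three shipped bases; contrast-agent K-edges would need a fourth
  basis column (the architecture permits it, nothing else is wired).
- The starved-ray rescue assumes the metal shadow is a contiguous run
  within a view with well-measured flanks; a phantom with metal touching
  the object boundary would need constant extrapolation (implemented) but
  has not been exercised.
- The pseudo-monochromatic likelihood treats `y*` as Poisson counts; the
  actual uncertainty of the synthesized values is inherited from the
  decomposition and is not propagated ray by ray.
- `beta`, `delta` are calibrated for the default phantom, budget and
  grid; other configurations should rerun the calibration script.
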