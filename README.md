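# spirct

Metal artifacts are the bane of dental CT: a gold inlay is optically thick,
so every ray through it arrives photon-starved and analytic reconstruction
(FBP) fills the image with streaks and shading. `spirct` implements, end to
end and at desk scale, a spectral-CT answer to this problem: use the energy
information of a photon-counting detector to *find* the metal in projection
space, then *tell* the reconstruction about it. The package is aimed at
researchers in CT reconstruction and spectral imaging who want a compact,
fully inspectable reference implementation of the two-step workflow —
simulation included, no external data needed.

## The model

In the diagnostic range the linear attenuation of the object is expanded in
three energy basis functions,

    mu(x, E) = A1(x) E^-3 + A2(x) f_KN(E) + A3(x) f_Au(E),

photoelectric absorption (`E^-3`), Compton scattering (the Klein–Nishina
shape `f_KN`), and the mass attenuation of gold `f_Au`, whose K-edge at
80.7249 keV makes the metal spectrally identifiable. An ideal
photon-counting detector bins photons into N = 6 energy windows; the
expected counts of window n are

    lambda_n(A) = ∫ S_n(E) Phi(E) exp(-A1 E^-3 - A2 f_KN - A3 f_Au) dE,

and each ray's basis line integrals `A = (A1, A2, A3)` are estimated by
minimizing the Poisson negative log-likelihood
`sum_n [lambda_n(A) - m_n ln lambda_n(A)]`.

From the decomposition the package synthesizes a pseudo-monochromatic
sinogram `y* = b exp(-l)` at 55 keV (free of beam hardening) and a gold
prior image (FBP of the gold channel, pixels below 10% of the maximum set
to zero, densities refit against the gold sinogram). Reconstruction then
maximizes the penalized likelihood `Psi(mu) = L(mu) - beta R(mu)` with an
edge-preserving Lange penalty `psi(t) = delta^2 [|t/delta| - ln(1+|t/delta|)]`
by separable-paraboloidal-surrogate (SPS) updates over random 3-angle
subsets,

    mu <- [ mu* + (BP[b e^-FP[mu*] - y*] - beta R') / (BP[y* FP[1]] + beta R'') ]+

where `mu*` is the current image with the prior's metal pixels overwritten
by the decomposed gold attenuation (SPIR). Omitting the prior gives the IR
comparator; FBP of `y*` is the analytic baseline.

## Worked example

`examples/` holds one short script per capability. The core of the
workflow (examples 03 and 04):

```python
from spirct import *

phantom  = build_jaw_phantom(PhantomSpec())        # 256x256, gold inlay in one molar
geometry = Geometry()                              # 80/60 cm fan beam, 360 views
spectrum = default_spectrum()                      # 125-kVp W anode + Al filter
bins     = make_bin_scheme(spectrum=spectrum)      # 6 windows, one edge at 81 keV
spectral = simulate_acquisition(phantom, spectrum, bins, geometry,
                                photon_budget=1e13, seed=1)

model = SpectralModel.from_sinogram(spectral, spectrum)
basis = decompose_sinogram(spectral, model)        # per-ray ML decomposition
prior = extract_metal_prior(basis, geometry, 256, 0.05)
y_star = pseudo_mono_sinogram(basis, 55.0, source_intensity=1e13)

fbp      = fbp_reconstruct(y_star, geometry, 256, 0.05)
ir, _    = reconstruct(y_star, geometry, ReconConfig(seed=0))
spir, _  = reconstruct(y_star, geometry, ReconConfig(seed=0), prior=prior)
```

Output of the example scripts for this run:

```
detected implant: 78 px (truth 78 px)
boundary distance vs truth: max 0.0 px, mean 0.00 px
density over the implant interior: 19.18 g/cm^3 (truth 19.30); mean |error| 0.66% = 0.127 g/cm^3

line-profile RMSE vs truth (1/cm, metal margin excluded):
  fbp   0.4402
  ir    0.0475
  spir  0.0352
near-implant artifact index (mean |delta HU|, 2-7 px annulus):
  fbp      3168 HU
  ir        682 HU
  spir      564 HU
```

The decomposition localizes the implant to within a pixel and recovers its
density to better than a percent; along the line through the implant, SPIR
tracks the true attenuation best, IR suppresses the streaks but keeps
shading near the metal, and FBP is dominated by artifacts — the expected
ordering SPIR < IR < FBP. `examples/05_prior_sensitivity.py` shows that a
prior even one pixel too small or too large degrades the neighbourhood of
the implant again.

A thin CLI mirrors the library:
`spirct run --config run.yaml` executes the full pipeline and writes a
manifest; `spirct simulate / decompose / reconstruct / evaluate` expose the
individual stages.

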