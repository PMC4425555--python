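"""FBP vs prior-free penalized ML (IR) vs metal-prior SPIR.

Runs all three reconstructions of the pseudo-monochromatic 55-keV sinogram
and compares them along the vertical line through the implant and in a
near-implant annulus.
"""

import numpy as np

from spirct import (
    Geometry,
    LineSpec,
    PhantomSpec,
    ReconConfig,
    SpectralModel,
    artifact_index,
    build_jaw_phantom,
    decompose_sinogram,
    default_spectrum,
    extract_metal_prior,
    fbp_reconstruct,
    line_profile,
    make_bin_scheme,
    profile_rmse,
    pseudo_mono_sinogram,
    reconstruct,
    simulate_acquisition,
)

phantom = build_jaw_phantom(PhantomSpec())
geometry = Geometry()
spectrum = default_spectrum()
bins = make_bin_scheme(spectrum=spectrum)
spectral = simulate_acquisition(phantom, spectrum, bins, geometry,
                                photon_budget=1e13, seed=1)
model = SpectralModel.from_sinogram(spectral, spectrum)
basis = decompose_sinogram(spectral, model)
prior = extract_metal_prior(basis, geometry, 256, 0.05)
y_star = pseudo_mono_sinogram(basis, 55.0, source_intensity=1e13)

config = ReconConfig(seed=0)  # shipped beta/delta, 15 full iterations
fbp = fbp_reconstruct(y_star, geometry, 256, 0.05)
ir, _ = reconstruct(y_star, geometry, config)
spir, trace = reconstruct(y_star, geometry, config, prior=prior)
print("SPIR relative image change per full iteration:")
print(" ", ["%.0e" % r for r in trace["rel_change"]])

rows, cols = np.nonzero(phantom.metal_mask)
line = LineSpec(index=int(round(cols.mean())))
report = line_profile({"fbp": fbp, "ir": ir, "spir": spir}, line, phantom)
print("\nline-profile RMSE vs truth (1/cm, metal margin excluded):")
for method in ("fbp", "ir", "spir"):
    print(f"  {method:5s} {profile_rmse(report, method):.4f}")
print("\nnear-implant artifact index (mean |delta HU|, 2-7 px annulus):")
for method, image in (("fbp", fbp), ("ir", ir), ("spir", spir)):
    print(f"  {method:5s} {artifact_index(image, phantom):7.0f} HU")
# expected ordering: SPIR < IR < FBP on both measures — the metal prior
# removes the streaks the starved rays leave behind
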