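"""Regenerate the synthetic gold mass-attenuation fixture.

The shipped table ``src/spirct/data/gold_mu_over_rho_synthetic.csv`` is a
synthetic stand-in for a tabulated gold cross-section file: it is computed
from a parametric model (photoelectric power laws split at the 80.7249 keV
K-edge, Klein-Nishina incoherent scattering at Z/A = 0.401, and a coherent
power-law term) anchored to well-known tabulated values of mu/rho for gold
(7.256 cm^2/g at 50 keV, ~2.1 -> 8.904 cm^2/g across the K-edge, 5.158
cm^2/g at 100 keV).  L/M-edge structure below 15 keV is deliberately
smoothed out: the model carries exactly one discontinuity, the K-edge.

Run from the repository root:  python scripts/make_gold_fixture.py
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from spirct.physics import GOLD_K_EDGE_KEV, klein_nishina_basis

Z_OVER_A = 0.401          # gold
SIGMA_T_MASS = 0.1606     # Thomson-limit incoherent mu/rho, cm^2/g
KN_ZERO = 4.0 / 3.0       # Klein-Nishina closed form at E -> 0


def incoherent(e):
    return SIGMA_T_MASS * np.asarray(klein_nishina_basis(e)) / KN_ZERO


def coherent(e):
    return 0.35 * (60.0 / np.asarray(e, dtype=float)) ** 1.9


# photoelectric below the edge: anchor total 7.256 cm^2/g at 50 keV
_TAU50 = 7.256 - incoherent(50.0) - coherent(50.0)
# photoelectric above the edge: anchor total 8.904 cm^2/g at the edge
_TAU_EDGE_HI = 8.904 - incoherent(GOLD_K_EDGE_KEV) - coherent(GOLD_K_EDGE_KEV)


def photoelectric(e, above_edge):
    e = np.asarray(e, dtype=float)
    if above_edge:
        return _TAU_EDGE_HI * (GOLD_K_EDGE_KEV / e) ** 2.6
    return _TAU50 * (50.0 / e) ** 2.85


def mu_over_rho(e, above_edge=None):
    e = np.asarray(e, dtype=float)
    if above_edge is None:
        above_edge = e > GOLD_K_EDGE_KEV
    tau = np.where(
        above_edge,
        photoelectric(e, True),
        photoelectric(e, False),
    )
    return tau + incoherent(e) + coherent(e)


def main():
    grid = np.arange(1.0, 151.0)
    below = grid[grid < GOLD_K_EDGE_KEV]
    above = grid[grid > GOLD_K_EDGE_KEV]
    energies = np.concatenate([below, [GOLD_K_EDGE_KEV, GOLD_K_EDGE_KEV], above])
    sides = np.concatenate(
        [
            np.zeros(below.size, dtype=bool),
            [False, True],
            np.ones(above.size, dtype=bool),
        ]
    )
    values = mu_over_rho(energies, sides)
    out = Path(__file__).resolve().parents[1] / "src/spirct/data/gold_mu_over_rho_synthetic.csv"
    with out.open("w") as fh:
        fh.write("energy_keV,mu_over_rho_cm2_per_g\n")
        for e, v in zip(energies, values):
            fh.write(f"{e:.4f},{v:.6g}\n")
    print(f"wrote {out} ({energies.size} rows)")
    print(f"  f_Au(55 keV)  = {mu_over_rho(55.0):.4f} cm^2/g")
    print(f"  K-edge jump   = {mu_over_rho(GOLD_K_EDGE_KEV, True) / mu_over_rho(GOLD_K_EDGE_KEV, False):.3f}")


if __name__ == "__main__":
    main()
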