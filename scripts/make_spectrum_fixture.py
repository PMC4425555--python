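"""Regenerate the 125-kVp tungsten spectrum fixture.

Model: Kramers bremsstrahlung N(E) ~ (E0 - E)/E with tungsten K
characteristic lines (K-alpha/K-beta, ~8% of filtered fluence), filtered by
2.7 mm of added aluminium plus 1.0 mm Al-equivalent inherent tube
filtration.  Tabulated on the 62-bin, 2-keV fine grid (bin centers
2..124 keV) used by the photon-counting acquisition model.

Run from the repository root:  python scripts/make_spectrum_fixture.py
"""

from pathlib import Path

import numpy as np

E0 = 125.0           # kVp
AL_THICK_CM = 0.37   # 2.7 mm added + 1.0 mm inherent
AL_RHO = 2.699       # g/cm^3

# NIST aluminium mu/rho anchors (cm^2/g), log-log interpolated
_AL_E = np.array([2, 3, 4, 5, 6, 8, 10, 15, 20, 30, 40, 50, 60, 80, 100, 125, 150], float)
_AL_MU = np.array(
    [2263.0, 788.0, 360.5, 193.4, 115.3, 50.33, 26.23, 7.955, 3.441,
     1.128, 0.5685, 0.3681, 0.2778, 0.2018, 0.1704, 0.1536, 0.1378]
)

# W K lines: energy (keV), relative intensity
_W_LINES = [(57.98, 58.0), (59.32, 100.0), (67.24, 30.0), (69.07, 8.0)]
_LINE_FRACTION = 0.08  # of total filtered fluence


def al_transmission(e):
    mu = np.exp(np.interp(np.log(e), np.log(_AL_E), np.log(_AL_MU)))
    return np.exp(-mu * AL_RHO * AL_THICK_CM)


def main():
    centers = np.arange(2.0, 125.0, 2.0)  # 62 fine bins on [1, 125]
    brems = np.clip(E0 - centers, 0.0, None) / centers
    fluence = brems * al_transmission(centers)
    line_total = _LINE_FRACTION * fluence.sum() / (1.0 - _LINE_FRACTION)
    weights = np.array([w for _, w in _W_LINES])
    for (e_line, w), share in zip(_W_LINES, weights / weights.sum()):
        idx = int(np.argmin(np.abs(centers - e_line)))
        fluence[idx] += line_total * share * al_transmission(np.array([e_line]))[0] / al_transmission(np.array([centers[idx]]))[0]
    fluence /= fluence.sum()
    mean_e = float(np.sum(centers * fluence))
    out = Path(__file__).resolve().parents[1] / "src/spirct/data/spectrum_125kvp_w_al.csv"
    with out.open("w") as fh:
        fh.write("energy_keV,relative_fluence\n")
        for e, f in zip(centers, fluence):
            fh.write(f"{e:.1f},{f:.8e}\n")
    print(f"wrote {out} ({centers.size} rows), mean energy {mean_e:.3f} keV")


if __name__ == "__main__":
    main()
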