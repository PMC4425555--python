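"""Attenuation basis functions for three-material spectral decomposition.

The linear attenuation coefficient of any material in the diagnostic range is
modelled as a linear combination of three energy basis functions,

    mu(E) = a1 * E^-3  +  a2 * f_KN(E)  +  a3 * f_Au(E),

where ``E^-3`` captures photoelectric absorption, ``f_KN`` is the
Klein-Nishina total cross-section shape of Compton scattering, and ``f_Au`` is
the mass attenuation of gold (cm^2/g) carrying the K-edge discontinuity at
80.7249 keV that makes the implant spectrally identifiable.

Units: ``a1`` in keV^3/cm, ``a2`` in 1/cm (the raw Klein-Nishina closed form
is used unnormalized; its scale is absorbed into ``a2``), ``a3`` in g/cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = [
    "ELECTRON_REST_KEV",
    "GOLD_K_EDGE_KEV",
    "BasisCoefficients",
    "BasisSet",
    "GoldTable",
    "photoelectric_basis",
    "klein_nishina_basis",
    "gold_attenuation_basis",
    "attenuation_at",
    "default_basis_set",
]

ELECTRON_REST_KEV = 510.975
GOLD_K_EDGE_KEV = 80.7249


def photoelectric_basis(energy):
    """Photoelectric basis value E^-3 (keV^-3). ``energy`` in keV, > 0."""
    e = np.asarray(energy, dtype=float)
    if np.any(e <= 0.0):
        raise ValueError("photoelectric basis requires energy > 0 keV")
    out = e ** -3.0
    return out if out.ndim else float(out)


def klein_nishina_basis(energy):
    """Klein-Nishina total cross-section shape (dimensionless).

    With alpha = E / 510.975 keV:

        f(a) = (1+a)/a^2 * [2(1+a)/(1+2a) - ln(1+2a)/a]
               + ln(1+2a)/(2a) - (1+3a)/(1+2a)^2

    The raw closed form is returned (f -> 4/3 as E -> 0, i.e. the Thomson
    limit in units of 2*pi*r_e^2); any constant factor is absorbed into the
    Compton coefficient a2.  Simulator and decomposer share this convention.
    """
    e = np.asarray(energy, dtype=float)
    if np.any(e <= 0.0):
        raise ValueError("Klein-Nishina basis requires energy > 0 keV")
    a = e / ELECTRON_REST_KEV
    with np.errstate(divide="ignore", invalid="ignore"):
        ln = np.log1p(2.0 * a)
        f = ((1.0 + a) / a**2) * (2.0 * (1.0 + a) / (1.0 + 2.0 * a) - ln / a)
        f += ln / (2.0 * a) - (1.0 + 3.0 * a) / (1.0 + 2.0 * a) ** 2
    # the closed form cancels catastrophically as a -> 0; switch to its
    # Taylor series below a = 0.01 (agreement ~1e-10 at the crossover)
    series = (
        4.0 / 3.0
        - 8.0 / 3.0 * a
        + 104.0 / 15.0 * a**2
        - 266.0 / 15.0 * a**3
        + 4576.0 / 105.0 * a**4
        - 2176.0 / 21.0 * a**5
    )
    f = np.where(a < 0.01, series, f)
    return f if f.ndim else float(f)


class GoldTable:
    """Gold mass attenuation (cm^2/g) from the shipped two-column table.

    The table carries the K-edge as two rows at the identical energy; queries
    are answered by log-log linear interpolation within each one-sided
    segment, so interpolation never bridges the discontinuity.  Exact table
    values are returned at grid nodes.
    """

    def __init__(self, energies: np.ndarray, values: np.ndarray):
        energies = np.asarray(energies, dtype=float)
        values = np.asarray(values, dtype=float)
        if energies.ndim != 1 or energies.shape != values.shape:
            raise ValueError("gold table must be two matching 1-D columns")
        if np.any(values <= 0.0):
            raise ValueError("gold mass attenuation must be positive")
        dup = np.flatnonzero(np.diff(energies) == 0.0)
        if dup.size != 1:
            raise ValueError("gold table must contain exactly one doubled K-edge node")
        if values[dup[0] + 1] <= values[dup[0]]:
            raise ValueError("K-edge must be an upward jump")
        self.edge_index = int(dup[0])
        self.edge_energy = float(energies[self.edge_index])
        self.energies = energies
        self.values = values
        # one-sided segments in log-log space
        self._le_lo = np.log(energies[: self.edge_index + 1])
        self._lv_lo = np.log(values[: self.edge_index + 1])
        self._le_hi = np.log(energies[self.edge_index + 1 :])
        self._lv_hi = np.log(values[self.edge_index + 1 :])

    @classmethod
    def from_csv(cls, path) -> "GoldTable":
        raw = np.loadtxt(path, delimiter=",", skiprows=1)
        return cls(raw[:, 0], raw[:, 1])

    @property
    def energy_range(self) -> tuple[float, float]:
        return float(self.energies[0]), float(self.energies[-1])

    @property
    def edge_jump_ratio(self) -> float:
        return float(self.values[self.edge_index + 1] / self.values[self.edge_index])

    def __call__(self, energy):
        e = np.asarray(energy, dtype=float)
        lo, hi = self.energy_range
        if np.any(e < lo) or np.any(e > hi):
            raise ValueError(
                f"energy outside gold table range [{lo:g}, {hi:g}] keV"
            )
        le = np.log(e)
        below = np.interp(le, self._le_lo, self._lv_lo)
        above = np.interp(le, self._le_hi, self._lv_hi)
        # energies exactly at the doubled node report the below-edge value
        out = np.exp(np.where(e <= self.edge_energy, below, above))
        return out if out.ndim else float(out)


def _default_gold_table() -> GoldTable:
    with resources.files("spirct.data").joinpath(
        "gold_mu_over_rho_synthetic.csv"
    ).open("rb") as fh:
        return GoldTable.from_csv(fh)


_GOLD: GoldTable | None = None


def gold_attenuation_basis(energy, table: GoldTable | None = None):
    """Gold mass attenuation f_Au(E) in cm^2/g from the shipped fixture."""
    global _GOLD
    if table is None:
        if _GOLD is None:
            _GOLD = _default_gold_table()
        table = _GOLD
    return table(energy)


@dataclass(frozen=True)
class BasisCoefficients:
    """Local basis densities of one material: (a1, a2, a3)."""

    a1: float  # photoelectric, keV^3/cm
    a2: float  # Compton (Klein-Nishina scale), 1/cm
    a3: float  # gold density-equivalent, g/cm^3

    def __post_init__(self):
        if self.a1 < 0 or self.a2 < 0 or self.a3 < 0:
            raise ValueError("physical materials require non-negative coefficients")

    def as_array(self) -> np.ndarray:
        return np.array([self.a1, self.a2, self.a3], dtype=float)

    def __add__(self, other: "BasisCoefficients") -> "BasisCoefficients":
        return BasisCoefficients(
            self.a1 + other.a1, self.a2 + other.a2, self.a3 + other.a3
        )


@dataclass(frozen=True)
class BasisSet:
    """The three basis functions evaluated on a fine energy grid."""

    energies: np.ndarray  # keV, strictly increasing
    f_pe: np.ndarray  # keV^-3
    f_kn: np.ndarray  # dimensionless
    f_au: np.ndarray  # cm^2/g

    def __post_init__(self):
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        for arr in (self.f_pe, self.f_kn, self.f_au):
            if arr.shape != self.energies.shape or not np.all(np.isfinite(arr)):
                raise ValueError("basis arrays must be finite and grid-shaped")

    @property
    def matrix(self) -> np.ndarray:
        """(n_energies, 3) matrix stacking [f_pe, f_kn, f_au]."""
        return np.stack([self.f_pe, self.f_kn, self.f_au], axis=1)


def default_basis_set(energies, gold_table: GoldTable | None = None) -> BasisSet:
    """Evaluate all three bases on ``energies`` (keV)."""
    e = np.asarray(energies, dtype=float)
    return BasisSet(
        energies=e,
        f_pe=np.asarray(photoelectric_basis(e)),
        f_kn=np.asarray(klein_nishina_basis(e)),
        f_au=np.asarray(gold_attenuation_basis(e, gold_table)),
    )


def attenuation_at(coeffs: BasisCoefficients, energy, gold_table: GoldTable | None = None):
    """Linear attenuation (1/cm) of ``coeffs`` at ``energy`` keV."""
    return (
        coeffs.a1 * photoelectric_basis(energy)
        + coeffs.a2 * klein_nishina_basis(energy)
        + coeffs.a3 * gold_attenuation_basis(energy, gold_table)
    )
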