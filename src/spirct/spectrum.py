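"""Incident X-ray spectrum and energy-window binning for an ideal
photon-counting detector.

The acquisition model works on a fine 2-keV grid (62 bins covering
1-125 keV for the 125-kVp fixture); analysis windows are contiguous groups
of fine bins.  The detector is ideal: D(E) = 1, no electronic noise, every
photon lands in the window containing its energy.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources

import numpy as np

__all__ = ["Spectrum", "BinScheme", "load_spectrum", "default_spectrum", "mean_energy", "make_bin_scheme"]


@dataclass(frozen=True)
class Spectrum:
    """Fluence per fine energy-grid point for one ray, no object in beam."""

    energies: np.ndarray  # keV, fine-grid centers, strictly increasing
    fluence: np.ndarray   # photons per grid point per ray

    def __post_init__(self):
        if self.energies.ndim != 1 or self.energies.shape != self.fluence.shape:
            raise ValueError("energies and fluence must be matching 1-D arrays")
        if np.any(np.diff(self.energies) <= 0):
            raise ValueError("energy grid must be strictly increasing")
        if np.any(self.fluence < 0):
            raise ValueError("fluence must be non-negative")
        if self.fluence.sum() <= 0:
            raise ValueError("spectrum must contain photons")

    @property
    def total_photons(self) -> float:
        return float(self.fluence.sum())

    def normalized(self, photon_budget: float) -> "Spectrum":
        """Rescale so the per-ray photon total equals ``photon_budget``."""
        if photon_budget <= 0:
            raise ValueError("photon budget must be positive")
        return Spectrum(self.energies, self.fluence * (photon_budget / self.total_photons))


def load_spectrum(table, photon_budget: float | None = None) -> Spectrum:
    """Build a Spectrum from a two-column (energy_keV, fluence) table.

    ``table`` may be a path, an open text handle, or an (n, 2) array.
    """
    if isinstance(table, np.ndarray):
        raw = np.asarray(table, dtype=float)
    else:
        try:
            raw = np.loadtxt(table, delimiter=",", skiprows=1, comments="#")
        except Exception as exc:  # noqa: BLE001 - surface as a parse error
            raise ValueError(f"could not parse spectrum table: {exc}") from exc
    if raw.ndim != 2 or raw.shape[1] != 2 or raw.shape[0] == 0:
        raise ValueError("spectrum table must be a nonempty two-column table")
    spec = Spectrum(raw[:, 0].copy(), raw[:, 1].copy())
    if photon_budget is not None:
        spec = spec.normalized(photon_budget)
    return spec


def default_spectrum(photon_budget: float | None = None) -> Spectrum:
    """The shipped 125-kVp W-anode, Al-filtered fixture spectrum."""
    data = resources.files("spirct.data").joinpath("spectrum_125kvp_w_al.csv").read_text()
    return load_spectrum(io.StringIO(data), photon_budget)


def mean_energy(spec: Spectrum) -> float:
    """Fluence-weighted mean energy (keV)."""
    return float(np.sum(spec.energies * spec.fluence) / spec.fluence.sum())


@dataclass(frozen=True)
class BinScheme:
    """Contiguous analysis windows over the fine grid, given by keV edges."""

    edges: np.ndarray  # (n_bins + 1,) strictly increasing keV boundaries

    def __post_init__(self):
        if self.edges.ndim != 1 or self.edges.size < 2:
            raise ValueError("need at least two edges")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("edges must be strictly increasing")

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1

    def window_matrix(self, energies: np.ndarray) -> np.ndarray:
        """(n_bins, n_energies) indicator S_n(E) on fine-grid centers.

        Each energy belongs to exactly one window (half-open [lo, hi),
        last window closed); energies outside all windows belong to none.
        """
        e = np.asarray(energies, dtype=float)
        idx = np.searchsorted(self.edges, e, side="right") - 1
        idx = np.where((e == self.edges[-1]), self.n_bins - 1, idx)
        mat = np.zeros((self.n_bins, e.size))
        valid = (idx >= 0) & (idx < self.n_bins)
        mat[idx[valid], np.flatnonzero(valid)] = 1.0
        return mat

    def window_fluence(self, spec: Spectrum) -> np.ndarray:
        """Incident photons per window for ``spec``."""
        return self.window_matrix(spec.energies) @ spec.fluence


def make_bin_scheme(
    fine_width: float = 2.0,
    n_windows: int = 6,
    energy_range: tuple[float, float] = (1.0, 125.0),
    spectrum: Spectrum | None = None,
    snap_edge_kev: float | None = 81.0,
    edges: np.ndarray | None = None,
) -> BinScheme:
    """Group a fine grid of ``fine_width``-keV bins into analysis windows.

    With ``edges`` given they are used verbatim (snapped to fine edges is the
    caller's business).  Otherwise windows are chosen to hold approximately
    equal incident fluence (equal fine-bin counts when no spectrum is given),
    and one boundary is snapped to the fine-grid edge ``snap_edge_kev`` so the
    gold K-edge (80.7 keV) separates two windows — required for K-edge
    identifiability.
    """
    if edges is not None:
        return BinScheme(np.asarray(edges, dtype=float))
    lo, hi = energy_range
    n_fine = (hi - lo) / fine_width
    if abs(n_fine - round(n_fine)) > 1e-9:
        raise ValueError("energy range must divide into fine bins")
    n_fine = int(round(n_fine))
    if not 1 <= n_windows <= n_fine:
        raise ValueError("need 1 <= n_windows <= number of fine bins")
    fine_edges = lo + fine_width * np.arange(n_fine + 1)
    if spectrum is None:
        weights = np.ones(n_fine)
    else:
        centers = fine_edges[:-1] + fine_width / 2.0
        weights = np.interp(centers, spectrum.energies, spectrum.fluence, left=0.0, right=0.0)
        if weights.sum() <= 0:
            raise ValueError("spectrum carries no fluence inside the energy range")
    if n_windows == 1:
        return BinScheme(np.array([lo, hi]))
    cum = np.concatenate([[0.0], np.cumsum(weights)])
    cum /= cum[-1]
    # interior boundaries at equal cumulative-fluence fractions, as fine-edge indices
    targets = np.arange(1, n_windows) / n_windows
    cuts = sorted({int(np.argmin(np.abs(cum - t))) for t in targets})
    if snap_edge_kev is not None and lo < snap_edge_kev < hi:
        snap_idx = int(round((snap_edge_kev - lo) / fine_width))
        nearest = int(np.argmin([abs(c - snap_idx) for c in cuts]))
        cuts[nearest] = snap_idx
        cuts = sorted(set(cuts))
    cuts = [c for c in cuts if 0 < c < n_fine]
    if len(cuts) != n_windows - 1:
        raise ValueError("could not place distinct window boundaries; give explicit edges")
    return BinScheme(fine_edges[np.array([0, *cuts, n_fine])])
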