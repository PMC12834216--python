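"""Simulated powder X-ray diffraction patterns and their similarity.

Patterns serve as structure-identity fingerprints for duplicate removal and
trajectory merging, not as refinement-grade simulations: atomic scattering
factors are approximated by the atomic number (constant-f), intensities are
|F_hkl|^2 times the Lorentz-polarization factor, and peaks are broadened
with a fixed-width Gaussian.  Because |F_hkl| depends only on the crystal's
periodic content, a pattern is invariant under supercell construction,
unimodular cell re-settings, and rigid translations -- exactly the
equivalences a duplicate filter must ignore.

Similarity is de Gelder's weighted cross-correlation with a triangular
weighting window, which credits slightly shifted peaks and is the field's
standard full-pattern measure.
"""
from __future__ import annotations

from dataclasses import dataclass

import gemmi
import numpy as np
from scipy.signal import correlate

from ..core.structure import CrystalStructure

__all__ = ["PxrdPattern", "simulate_pxrd", "pattern_similarity"]

CU_KALPHA = 1.5406  # A


@dataclass(frozen=True)
class PxrdPattern:
    two_theta: np.ndarray  # degrees, uniform grid
    intensities: np.ndarray  # normalised, max = 1 for non-empty patterns
    wavelength: float

    def __post_init__(self) -> None:
        tt = np.asarray(self.two_theta, dtype=float)
        ii = np.asarray(self.intensities, dtype=float)
        if tt.shape != ii.shape or tt.ndim != 1:
            raise ValueError("grid and intensities must be matching 1-D arrays")
        if (ii < 0).any():
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "two_theta", tt)
        object.__setattr__(self, "intensities", ii)

    @property
    def step(self) -> float:
        return float(self.two_theta[1] - self.two_theta[0])

    def save_txt(self, path) -> None:
        np.savetxt(path, np.column_stack([self.two_theta, self.intensities]),
                   header="two_theta_deg intensity", fmt="%.6f")


def simulate_pxrd(
    structure: CrystalStructure,
    wavelength: float = CU_KALPHA,
    two_theta_range: tuple[float, float] = (5.0, 50.0),
    step: float = 0.05,
    fwhm: float = 0.3,
) -> PxrdPattern:
    """Simulate a powder pattern on a uniform 2-theta grid (degrees).

    Raises ValueError if no reflection falls inside the grid.
    """
    lo, hi = two_theta_range
    if not 0 < lo < hi < 180:
        raise ValueError(f"bad two_theta range {two_theta_range}")
    lat = structure.lattice
    # reflections with d >= d_min, i.e. |g| <= 2 pi / d_min
    d_min = wavelength / (2.0 * np.sin(np.radians(hi / 2.0)))
    g_max = 2.0 * np.pi / d_min
    G = lat.reciprocal
    hmax = np.ceil(g_max / (2 * np.pi) * np.linalg.norm(lat.matrix, axis=1)).astype(int)
    rng = [np.arange(-m, m + 1) for m in hmax]
    hkl = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
    hkl = hkl[np.any(hkl != 0, axis=1)]
    g = hkl @ G
    gnorm = np.linalg.norm(g, axis=1)
    keep = gnorm <= g_max
    hkl, gnorm = hkl[keep], gnorm[keep]
    d = 2.0 * np.pi / gnorm
    sin_theta = wavelength / (2.0 * d)
    keep = sin_theta >= np.sin(np.radians(lo / 2.0))
    hkl, sin_theta = hkl[keep], sin_theta[keep]
    if len(hkl) == 0:
        raise ValueError("no reflections in the requested two_theta range")
    theta = np.arcsin(sin_theta)
    two_theta = np.degrees(2.0 * theta)

    # constant-f structure factors over all atoms in the cell
    cart = structure.atom_coords_cart().reshape(-1, 3)
    frac = lat.to_fractional(cart)
    Z = np.array(
        [gemmi.Element(e).atomic_number for e in structure.molecule_ref.atom_elements],
        dtype=float,
    )
    Z = np.tile(Z, structure.n_molecules)
    phase = 2.0 * np.pi * (hkl @ frac.T)  # (nrefl, natom)
    F2 = (np.cos(phase) @ Z) ** 2 + (np.sin(phase) @ Z) ** 2
    lp = (1.0 + np.cos(2.0 * theta) ** 2) / (np.sin(theta) ** 2 * np.cos(theta))
    I = F2 * lp

    grid = np.arange(lo, hi + 0.5 * step, step)
    sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    prof = np.exp(-((grid[None, :] - two_theta[:, None]) ** 2) / (2.0 * sigma**2))
    pattern = I @ prof
    peak = pattern.max()
    if peak > 0:
        pattern = pattern / peak
    return PxrdPattern(grid, pattern, wavelength)


def pattern_similarity(p: PxrdPattern, q: PxrdPattern, ell: float = 1.5) -> float:
    """de Gelder weighted cross-correlation similarity in [0, 1].

    ``ell`` is the half-width (degrees 2-theta) of the triangular shift
    weighting.  Patterns must share grid and wavelength.  A flat-zero
    pattern has similarity 0 with anything by convention.
    """
    if p.two_theta.shape != q.two_theta.shape or not np.allclose(
        p.two_theta, q.two_theta
    ) or p.wavelength != q.wavelength:
        raise ValueError("patterns must share the same grid and wavelength")
    L = int(round(ell / p.step))
    w = 1.0 - np.abs(np.arange(-L, L + 1)) / (ell / p.step)
    w = np.clip(w, 0.0, None)

    def wcc(x, y):
        c = correlate(x, y, mode="full", method="auto")
        mid = len(x) - 1
        return float(w @ c[mid - L: mid + L + 1])

    denom = wcc(p.intensities, p.intensities) * wcc(q.intensities, q.intensities)
    if denom <= 0:
        return 0.0
    if np.array_equal(p.intensities, q.intensities):
        return 1.0
    val = wcc(p.intensities, q.intensities) / np.sqrt(denom)
    return float(np.clip(val, 0.0, 1.0))
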