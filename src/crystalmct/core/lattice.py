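"""Lattice mathematics: cell matrices, fractional coordinates, Niggli reduction.

The lattice is stored as a 3x3 row matrix (rows are the cell vectors a, b, c
in Angstrom), so Cartesian coordinates of a fractional point ``f`` are
``f @ matrix``.  All volumes are signed-positive: the constructor rejects
left-handed or degenerate cells.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import gemmi
import numpy as np

__all__ = ["Lattice", "niggli_reduce"]

_MIN_VOLUME = 1e-6  # A^3, below this a cell is considered degenerate


@dataclass(frozen=True)
class Lattice:
    """A periodic lattice defined by a right-handed 3x3 row matrix (Angstrom)."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError(f"lattice matrix must be 3x3, got {m.shape}")
        if np.linalg.det(m) <= _MIN_VOLUME:
            raise ValueError(
                "lattice matrix must be right-handed with positive volume "
                f"(det = {np.linalg.det(m):.3e})"
            )
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_parameters(
        cls, a: float, b: float, c: float, alpha: float, beta: float, gamma: float
    ) -> "Lattice":
        """Build a lower-triangular cell matrix from lengths (A) and angles (deg)."""
        if min(a, b, c) <= 0:
            raise ValueError("cell lengths must be positive")
        for name, ang in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name}={ang} must be in (0, 180)")
        al, be, ga = np.radians([alpha, beta, gamma])
        cx = c * np.cos(be)
        cy = c * (np.cos(al) - np.cos(be) * np.cos(ga)) / np.sin(ga)
        cz_sq = c * c - cx * cx - cy * cy
        if cz_sq <= 0:
            raise ValueError("cell angles do not define a positive-volume cell")
        m = np.array(
            [
                [a, 0.0, 0.0],
                [b * np.cos(ga), b * np.sin(ga), 0.0],
                [cx, cy, np.sqrt(cz_sq)],
            ]
        )
        return cls(m)

    @property
    def volume(self) -> float:
        return float(np.linalg.det(self.matrix))

    @property
    def parameters(self) -> tuple[float, float, float, float, float, float]:
        """(a, b, c, alpha, beta, gamma) with lengths in A and angles in degrees."""
        a, b, c = (np.linalg.norm(v) for v in self.matrix)
        va, vb, vc = self.matrix

        def ang(u, v):
            return float(
                np.degrees(
                    np.arccos(np.clip(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)), -1, 1))
                )
            )

        return (float(a), float(b), float(c), ang(vb, vc), ang(va, vc), ang(va, vb))

    @property
    def reciprocal(self) -> np.ndarray:
        """Rows are the reciprocal vectors g_i (2*pi convention): g_i . a_j = 2*pi*delta_ij."""
        return 2.0 * np.pi * np.linalg.inv(self.matrix).T

    def to_cartesian(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, dtype=float) @ self.matrix

    def to_fractional(self, cart: np.ndarray) -> np.ndarray:
        return np.asarray(cart, dtype=float) @ np.linalg.inv(self.matrix)

    def wrap(self, frac: np.ndarray) -> np.ndarray:
        """Wrap fractional coordinates into [0, 1)."""
        return np.asarray(frac, dtype=float) % 1.0

    def is_niggli(self, rel_eps: float = 1e-6) -> bool:
        """Check the Krivy-Gruber (Niggli) reduction conditions.

        Works on the metric tensor with a tolerance relative to the cell
        scale, so cells regenerated from rounded parameters still pass.
        """
        g = self.matrix @ self.matrix.T
        A, B, C = g[0, 0], g[1, 1], g[2, 2]
        xi, eta, zeta = 2 * g[1, 2], 2 * g[0, 2], 2 * g[0, 1]
        eps = rel_eps * (A * B * C) ** (1.0 / 3.0)
        if not (A <= B + eps and B <= C + eps):
            return False
        if abs(A - B) < eps and abs(xi) > abs(eta) + eps:
            return False
        if abs(B - C) < eps and abs(eta) > abs(zeta) + eps:
            return False
        type1 = xi > eps and eta > eps and zeta > eps
        type2 = xi <= eps and eta <= eps and zeta <= eps
        if not (type1 or type2):
            return False
        if abs(xi) > B + eps or abs(eta) > A + eps or abs(zeta) > A + eps:
            return False
        # cell corner condition: c is shorter than any face diagonal a+b+c
        if A + B + xi + eta + zeta < -eps:
            return False
        return True


def niggli_reduce(lattice: Lattice, eps: float = 1e-9) -> tuple[Lattice, np.ndarray]:
    """Niggli-reduce a lattice (Krivy-Gruber conditions).

    Returns the reduced lattice and the unimodular integer change-of-basis
    matrix ``P`` such that ``reduced.matrix = P @ lattice.matrix``.  Fractional
    coordinates transform as ``f_new = f_old @ inv(P)``.
    """
    if abs(lattice.volume) < _MIN_VOLUME:
        raise ValueError("cannot Niggli-reduce a degenerate lattice")
    gv = gemmi.GruberVector(
        gemmi.UnitCell(*lattice.parameters), None, track_change_of_basis=True
    )
    gv.niggli_reduce(epsilon=eps)
    op = gv.change_of_basis
    P = (np.array(op.rot, dtype=float) / op.DEN).T
    P_int = np.rint(P).astype(int)
    if not np.allclose(P, P_int, atol=1e-12) or abs(round(np.linalg.det(P_int))) != 1:
        raise RuntimeError("Niggli change of basis is not unimodular integer")
    reduced = Lattice(P_int.astype(float) @ lattice.matrix)
    return reduced, P_int
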