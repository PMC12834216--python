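"""Periodic lattice energy: isotropic exp-6 repulsion-dispersion + point-charge Ewald.

The lattice energy per molecule of a rigid-molecule crystal is

    E = 1/2 sum_pairs [ A_ij exp(-B_ij r) - C_ij r^-6 ]  +  E_Coulomb(Ewald)

summed over all intermolecular atom-atom pairs within the cutoff (periodic
images included), divided by the number of molecules in the cell.
Intramolecular pairs are excluded everywhere; because the molecules are
rigid, the excluded intramolecular Coulomb term is a constant.  A uniform
r^-6 tail correction beyond the cutoff and a neutralising-background term
for (rare) charged cells are included.

Analytic first derivatives are provided with respect to fractional molecule
centroids, body-frame rotation charts, and the full 3x3 cell matrix; they
are exact (tested against finite differences) and drive the rigid-body
minimiser.

Units: kJ/mol, Angstrom, elementary charge.
"""
from __future__ import annotations

import json
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.special import erf, erfc

from .core.lattice import Lattice
from .core.molecule import RigidMolecule
from .core.structure import CrystalStructure

__all__ = [
    "PotentialModel",
    "EnergyReport",
    "EnergyGradient",
    "lattice_energy",
    "energy_gradient",
    "ewald_energy",
    "ParameterError",
    "ClashError",
    "EvaluationOverflow",
    "COULOMB_CONSTANT",
]

COULOMB_CONSTANT = 1389.35457644382  # kJ/mol * A / e^2
CLASH_DISTANCE = 0.5  # A: intermolecular contacts below this are an error
TAPER_WIDTH = 1.0  # A: C1 switching window below the cutoff


class ParameterError(KeyError):
    """An atom-type pair has no potential parameters."""


class EvaluationOverflow(ValueError):
    """The requested lattice sum is unreasonably large (collapsed cell)."""


class ClashError(ValueError):
    """Two atoms are unphysically close."""

    def __init__(self, message: str, pair: tuple[str, str] | None = None,
                 distance: float | None = None):
        super().__init__(message)
        self.pair = pair
        self.distance = distance


@dataclass(frozen=True)
class PotentialModel:
    """exp-6 atom-atom potential parameters plus electrostatic settings.

    ``type_params`` maps atom-type labels to homo-atomic (A, B, C) with A in
    kJ/mol, B in 1/A and C in kJ/mol A^6.  Cross terms default to the
    standard combining rules A_ij = sqrt(A_ii A_jj), B_ij = (B_ii+B_jj)/2,
    C_ij = sqrt(C_ii C_jj) and can be overridden per pair in
    ``pair_params`` (keys are sorted 2-tuples of type labels).
    """

    type_params: dict[str, tuple[float, float, float]]
    pair_params: dict[tuple[str, str], tuple[float, float, float]] = field(
        default_factory=dict
    )
    cutoff: float = 15.0
    ewald_accuracy: float = 1e-6

    def __post_init__(self) -> None:
        if self.cutoff < 8.0:
            raise ValueError(f"cutoff {self.cutoff} A is below the 8 A minimum")
        if not 0 < self.ewald_accuracy < 1:
            raise ValueError("ewald_accuracy must be in (0, 1)")
        norm = {tuple(sorted(k)): tuple(map(float, v)) for k, v in self.pair_params.items()}
        object.__setattr__(self, "pair_params", norm)
        for key, (A, B, C) in list(self.type_params.items()) + list(norm.items()):
            if A <= 0 or B <= 0 or C < 0:
                raise ValueError(f"invalid exp-6 parameters for {key}: A,B>0, C>=0 required")

    def pair(self, t1: str, t2: str) -> tuple[float, float, float]:
        key = tuple(sorted((t1, t2)))
        if key in self.pair_params:
            return self.pair_params[key]
        try:
            A1, B1, C1 = self.type_params[t1]
            A2, B2, C2 = self.type_params[t2]
        except KeyError as exc:
            raise ParameterError(
                f"no exp-6 parameters for atom-type pair ({t1}, {t2})"
            ) from exc
        return (math.sqrt(A1 * A2), 0.5 * (B1 + B2), math.sqrt(C1 * C2))

    # -- file I/O -------------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "PotentialModel":
        """Load from JSON or TOML: {"types": {..}, "pairs": {"T1-T2": [A,B,C]}, ...}."""
        path = Path(path)
        if path.suffix == ".toml":
            data = tomllib.loads(path.read_text())
        else:
            data = json.loads(path.read_text())
        pairs = {
            tuple(k.split("-", 1)): tuple(v) for k, v in data.get("pairs", {}).items()
        }
        return cls(
            type_params={k: tuple(v) for k, v in data["types"].items()},
            pair_params=pairs,
            cutoff=float(data.get("cutoff", 15.0)),
            ewald_accuracy=float(data.get("ewald_accuracy", 1e-6)),
        )

    def to_file(self, path: str | Path) -> None:
        data = {
            "types": {k: list(v) for k, v in self.type_params.items()},
            "pairs": {f"{a}-{b}": list(v) for (a, b), v in self.pair_params.items()},
            "cutoff": self.cutoff,
            "ewald_accuracy": self.ewald_accuracy,
        }
        Path(path).write_text(json.dumps(data, indent=1))


@dataclass(frozen=True)
class EnergyReport:
    """Per-molecule lattice energy decomposition (kJ/mol)."""

    total_per_molecule: float
    repulsion_dispersion: float
    electrostatic: float
    gradient_norm: float | None = None


@dataclass(frozen=True)
class EnergyGradient:
    """Gradient of the per-molecule lattice energy.

    ``frac_positions``: (M, 3) d/d fractional centroid of each molecule;
    ``orientations``: (M, 3) d/d body-frame rotation chart (radians), where
    the chart perturbs R -> R @ expm([theta]_x);
    ``cell``: (3, 3) d/d cell-matrix component (rows a, b, c).
    """

    frac_positions: np.ndarray
    orientations: np.ndarray
    cell: np.ndarray

    @property
    def norm(self) -> float:
        return float(
            np.sqrt(
                np.sum(self.frac_positions**2)
                + np.sum(self.orientations**2)
                + np.sum(self.cell**2)
            )
        )


# ---------------------------------------------------------------------------
# internals


class _PairTables:
    """Per-(molecule, potential) cached atom-pair parameter matrices."""

    def __init__(self, molecule: RigidMolecule, potential: PotentialModel):
        types = molecule.atom_types
        n = len(types)
        self.A = np.empty((n, n))
        self.B = np.empty((n, n))
        self.C = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                self.A[i, j], self.B[i, j], self.C[i, j] = potential.pair(types[i], types[j])
        self.qq = np.outer(molecule.charges, molecule.charges)
        self.C_sum = float(self.C.sum())
        # inner turning point of each pair's exp-6 (for the soft-core continuation)
        self.r_inner = np.empty((n, n))
        self.k_inner = np.empty((n, n))
        for i in range(n):
            for j in range(n):
                self.r_inner[i, j], self.k_inner[i, j] = _inner_max(
                    self.A[i, j], self.B[i, j], self.C[i, j]
                )


def _inner_max(A: float, B: float, C: float) -> tuple[float, float]:
    """Radius of the inner maximum of A e^{-Br} - C r^-6 and a stiffness for
    the quadratic soft-core continuation below it."""
    if C == 0.0:
        return 0.0, 0.0  # pure exponential repulsion is finite everywhere
    # phi'(r) = -A B e^{-Br} + 6 C r^-7 changes sign where
    # f(r) = A B e^{-Br} r^7 - 6 C crosses zero; the inner root (f: - -> +)
    # is the barrier top.  f peaks at r = 7/B.
    f = lambda r: A * B * math.exp(-B * r) * r**7 - 6.0 * C
    r_peak = 7.0 / B
    if f(r_peak) <= 0:
        raise ValueError(
            "exp-6 parameters have no repulsive barrier (dispersion dominates "
            f"at all distances): A={A}, B={B}, C={C}"
        )
    lo, hi = 1e-6, r_peak
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if f(mid) < 0:
            lo = mid
        else:
            hi = mid
    r0 = 0.5 * (lo + hi)
    k = A * B * B * math.exp(-B * r0)
    return r0, k


_tables_cache: dict[tuple[int, int], _PairTables] = {}


def _get_tables(molecule: RigidMolecule, potential: PotentialModel) -> _PairTables:
    key = (id(molecule), id(potential))
    tab = _tables_cache.get(key)
    if tab is None:
        tab = _PairTables(molecule, potential)
        if len(_tables_cache) > 64:
            _tables_cache.clear()
        _tables_cache[key] = tab
    return tab


def _image_list(H: np.ndarray, radius: float) -> np.ndarray:
    """Integer lattice translations n with |n @ H| <= radius."""
    Hinv = np.linalg.inv(H)
    nmax = np.ceil(radius * np.linalg.norm(Hinv, axis=0)).astype(int)
    if np.prod((2 * nmax + 1).astype(float)) > 2e5:
        raise EvaluationOverflow(
            "lattice sum would need too many image cells; the cell has "
            "probably collapsed"
        )
    rng = [np.arange(-m, m + 1) for m in nmax]
    n = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
    keep = np.linalg.norm(n @ H, axis=1) <= radius + 1e-9
    return n[keep]


_geom_cache: dict = {}


def _cached_images(H: np.ndarray, radius: float):
    """(integer images, their Cartesian shifts, lexicographic-positive mask)
    cached on the cell matrix -- Monte Carlo moves that do not strain the
    lattice reuse the same lists."""
    key = (H.tobytes(), round(radius, 6))
    hit = _geom_cache.get(key)
    if hit is None:
        base = _image_list(H, radius)
        half = (
            (base[:, 0] > 0)
            | ((base[:, 0] == 0) & (base[:, 1] > 0))
            | ((base[:, 0] == 0) & (base[:, 1] == 0) & (base[:, 2] > 0))
        )
        hit = (base.astype(float), base @ H, half)
        if len(_geom_cache) > 16:
            _geom_cache.clear()
        _geom_cache[key] = hit
    return hit


def _ewald_alpha(potential: PotentialModel) -> float:
    return math.sqrt(-math.log(potential.ewald_accuracy)) / potential.cutoff


def _pair_sums_numpy(pa, pb, nvec, shift, offsets, A, B, C, qq, r_inner, k_inner,
                     rc, alpha, soft_core, do_grad, grad_x):
    """Vectorised evaluation of the (pair, image) block list.

    Returns (E_rd, E_real, min distance, image part of dE/dH); atom-position
    gradients are accumulated into ``grad_x`` in place.
    """
    d = (offsets[pb][:, None, :, :] + shift[:, None, None, :]) - offsets[pa][:, :, None, :]
    r = np.sqrt((d * d).sum(-1))  # (K,na,na)
    mask = r <= rc
    rmin = float(r.min())
    r_safe = np.where(mask, np.maximum(r, 1e-12), 1.0)
    if soft_core:
        hard = r_safe < r_inner
        r_eval = np.where(hard, r_inner, r_safe)
    else:
        hard = None
        r_eval = r_safe
    expterm = A * np.exp(-B * r_eval)
    inv6 = r_eval**-6
    phi = expterm - C * inv6
    dphi = -B * expterm + 6.0 * C * inv6 / r_eval
    if soft_core and hard.any():
        dr = r_safe - r_inner
        phi = np.where(hard, phi + 0.5 * k_inner * dr**2, phi)
        dphi = np.where(hard, k_inner * dr, dphi)
    # C1 taper over [rc - w, rc] so the energy is smooth at the cutoff
    t = np.clip((r_safe - (rc - TAPER_WIDTH)) / TAPER_WIDTH, 0.0, 1.0)
    S = 1.0 - t * t * (3.0 - 2.0 * t)
    dS = -6.0 * t * (1.0 - t) / TAPER_WIDTH
    dphi = dphi * S + phi * dS
    phi = phi * S
    rq = np.maximum(r_safe, CLASH_DISTANCE) if soft_core else r_safe
    erfc_t = erfc(alpha * rq)
    coul = COULOMB_CONSTANT * qq * erfc_t / rq
    dcoul = -COULOMB_CONSTANT * qq * (
        erfc_t / rq**2 + 2.0 * alpha / math.sqrt(math.pi) * np.exp(-(alpha * rq) ** 2) / rq
    )
    if soft_core:
        dcoul = np.where(r_safe < CLASH_DISTANCE, 0.0, dcoul)
    E_rd = float(np.where(mask, phi, 0.0).sum())
    E_real = float(np.where(mask, coul, 0.0).sum())
    gH = np.zeros((3, 3))
    if do_grad:
        w = np.where(mask, (dphi + dcoul) / r_safe, 0.0)[..., None] * d  # dE/dd
        np.add.at(grad_x, pb, w.sum(axis=1))
        np.add.at(grad_x, pa, -w.sum(axis=2))
        gH = np.einsum("ki,kj->ij", nvec, w.sum(axis=(1, 2)))
    return E_rd, E_real, rmin, gH


try:  # pragma: no cover - exercised indirectly
    from numba import njit as _njit

    @_njit(cache=False)
    def _pair_sums_numba(pa, pb, nvec, shift, offsets, A, B, C, qq, r_inner,
                         k_inner, rc, alpha, soft_core, do_grad, grad_x):
        K = pa.shape[0]
        na = offsets.shape[1]
        tw = TAPER_WIDTH
        ke = COULOMB_CONSTANT
        two_over_sqrt_pi = 2.0 / math.sqrt(math.pi)
        E_rd = 0.0
        E_real = 0.0
        rmin = 1e30
        gH = np.zeros((3, 3))
        rc2 = rc * rc
        for k in range(K):
            a = pa[k]
            b = pb[k]
            sx = shift[k, 0]
            sy = shift[k, 1]
            sz = shift[k, 2]
            gx = 0.0
            gy = 0.0
            gz = 0.0
            for i in range(na):
                oxi = offsets[a, i, 0]
                oyi = offsets[a, i, 1]
                ozi = offsets[a, i, 2]
                for j in range(na):
                    dx = offsets[b, j, 0] + sx - oxi
                    dy = offsets[b, j, 1] + sy - oyi
                    dz = offsets[b, j, 2] + sz - ozi
                    r2 = dx * dx + dy * dy + dz * dz
                    if r2 > rc2:
                        continue
                    r = math.sqrt(r2)
                    if r < rmin:
                        rmin = r
                    if r < 1e-12:
                        r = 1e-12
                    ri = r_inner[i, j]
                    if soft_core and r < ri:
                        re = ri
                    else:
                        re = r
                    ex = A[i, j] * math.exp(-B[i, j] * re)
                    i6 = re**-6
                    phi = ex - C[i, j] * i6
                    dphi = -B[i, j] * ex + 6.0 * C[i, j] * i6 / re
                    if soft_core and r < ri:
                        dr = r - ri
                        phi += 0.5 * k_inner[i, j] * dr * dr
                        dphi = k_inner[i, j] * dr
                    if r > rc - tw:
                        t = (r - (rc - tw)) / tw
                        S = 1.0 - t * t * (3.0 - 2.0 * t)
                        dS = -6.0 * t * (1.0 - t) / tw
                        dphi = dphi * S + phi * dS
                        phi = phi * S
                    if soft_core and r < CLASH_DISTANCE:
                        rq = CLASH_DISTANCE
                    else:
                        rq = r
                    er = math.erfc(alpha * rq)
                    coul = ke * qq[i, j] * er / rq
                    dcoul = -ke * qq[i, j] * (
                        er / (rq * rq)
                        + two_over_sqrt_pi * alpha * math.exp(-(alpha * rq) ** 2) / rq
                    )
                    if soft_core and r < CLASH_DISTANCE:
                        dcoul = 0.0
                    E_rd += phi
                    E_real += coul
                    if do_grad:
                        w = (dphi + dcoul) / r
                        wx = w * dx
                        wy = w * dy
                        wz = w * dz
                        grad_x[b, j, 0] += wx
                        grad_x[b, j, 1] += wy
                        grad_x[b, j, 2] += wz
                        grad_x[a, i, 0] -= wx
                        grad_x[a, i, 1] -= wy
                        grad_x[a, i, 2] -= wz
                        gx += wx
                        gy += wy
                        gz += wz
            if do_grad:
                for c in range(3):
                    gH[c, 0] += nvec[k, c] * gx
                    gH[c, 1] += nvec[k, c] * gy
                    gH[c, 2] += nvec[k, c] * gz
        if rmin > 1e29:
            rmin = rc
        return E_rd, E_real, rmin, gH

    _pair_sums = _pair_sums_numba
except ImportError:  # pragma: no cover
    _pair_sums = _pair_sums_numpy


def structure_arrays(structure: CrystalStructure):
    """(H, fractional centroids (M,3), rotation matrices (M,3,3))."""
    from scipy.spatial.transform import Rotation

    frac = np.array([m.frac_position for m in structure.molecules])
    quats = np.array([m.orientation for m in structure.molecules])
    rots = Rotation.from_quat(quats).as_matrix().reshape(-1, 3, 3)
    return structure.lattice.matrix, frac, rots


def _evaluate(
    structure: CrystalStructure,
    potential: PotentialModel,
    *,
    do_grad: bool,
    soft_core: bool,
    clash_check: bool = True,
):
    H, frac, rots = structure_arrays(structure)
    return evaluate_arrays(
        structure.molecule_ref, H, frac, rots, potential,
        do_grad=do_grad, soft_core=soft_core, clash_check=clash_check,
    )


def evaluate_arrays(
    mol: RigidMolecule,
    H: np.ndarray,
    frac: np.ndarray,
    rots: np.ndarray,
    potential: PotentialModel,
    *,
    do_grad: bool,
    soft_core: bool,
    clash_check: bool = True,
):
    """Energy components (per cell) and optional analytic gradients.

    Array-level core used by the minimiser, bypassing structure objects.
    Returns (E_rep_disp, E_electrostatic, grads) with grads either None or
    (dE/dfrac (M,3), dE/dtheta (M,3), dE/dH (3,3)), all per cell.
    """
    tab = _get_tables(mol, potential)
    V = float(np.linalg.det(H))
    if V <= 1e-6:
        raise EvaluationOverflow("degenerate (collapsed) cell")
    M = len(frac)
    na = mol.n_atoms
    rc = potential.cutoff
    alpha = _ewald_alpha(potential)

    offsets = np.einsum("mij,aj->mai", rots, mol.local_coords)  # (M,na,3)
    centroids = frac @ H
    charges = mol.charges

    R_out = rc + 2.0 * mol.radius + 1e-9
    # minimum-imaged centroid differences stay within half the cell diagonal
    half_diag = 0.5 * np.linalg.norm(H, axis=1).sum()
    base, baseH, halfmask = _cached_images(H, R_out + half_diag)

    # (pair, image) shortlist at the centroid level
    ia, ib = np.triu_indices(M)
    dfrac = frac[ib] - frac[ia]
    wrap = np.round(dfrac)
    d0 = (dfrac - wrap) @ H  # (P,3)
    dist2 = ((d0[:, None, :] + baseH[None, :, :]) ** 2).sum(-1)
    keep = dist2 <= R_out * R_out
    keep[ia == ib] &= halfmask[None, :]  # self-pairs: one of each +-n, no n=0
    ks, ns = np.nonzero(keep)
    pa = ia[ks]
    pb = ib[ks]
    nvec = base[ns] - wrap[ks]  # integer image in unwrapped coordinates
    shift = d0[ks] + baseH[ns]  # = (frac[pb] - frac[pa] + nvec) @ H
    K = len(pa)

    E_rd = 0.0
    E_real = 0.0
    grad_x = np.zeros((M, na, 3))  # dE/d cartesian atom position
    grad_H = np.zeros((3, 3))

    if K:
        E_rd, E_real, rmin, gH_img = _pair_sums(
            pa, pb, nvec, shift, offsets,
            tab.A, tab.B, tab.C, tab.qq, tab.r_inner, tab.k_inner,
            rc, alpha, soft_core, do_grad, grad_x,
        )
        if clash_check and rmin < CLASH_DISTANCE:
            raise ClashError(
                f"intermolecular contact {rmin:.3f} A < {CLASH_DISTANCE} A",
                distance=float(rmin),
            )
        if do_grad:
            grad_H += gH_img

    # dispersion tail correction (uniform density beyond the cutoff)
    E_tail = -2.0 * math.pi * M * M * tab.C_sum / (3.0 * V * rc**3)
    if do_grad:
        grad_H += -E_tail * np.linalg.inv(H).T

    # reciprocal-space Ewald + self + intramolecular exclusion + background
    q_all = np.tile(charges, M)
    x_all = (offsets + centroids[:, None, :]).reshape(-1, 3)
    E_recip, g_recip_x, gH_recip = _ewald_recip(
        H, V, x_all, q_all, alpha, potential.ewald_accuracy, do_grad
    )
    if do_grad:
        grad_x += g_recip_x.reshape(M, na, 3)
        grad_H += gH_recip
    E_self = -COULOMB_CONSTANT * alpha / math.sqrt(math.pi) * float((q_all**2).sum())
    qtot = float(q_all.sum())
    E_bg = -COULOMB_CONSTANT * math.pi * qtot**2 / (2.0 * alpha**2 * V)
    if do_grad and abs(qtot) > 1e-12:
        grad_H += -E_bg * np.linalg.inv(H).T
    # intramolecular exclusion: remove reciprocal-counted intra pairs (rigid => constant)
    rr = np.linalg.norm(
        mol.local_coords[:, None, :] - mol.local_coords[None, :, :], axis=-1
    )
    iu = np.triu_indices(na, k=1)
    E_intra = -COULOMB_CONSTANT * M * float(
        (tab.qq[iu] * erf(alpha * rr[iu]) / np.maximum(rr[iu], 1e-12)).sum()
    )

    E_es = E_real + E_recip + E_self + E_bg + E_intra
    E_rd_total = E_rd + E_tail

    if not do_grad:
        return E_rd_total, E_es, None

    # fold atom gradients into molecule translations/torques; add the
    # centroid-mediated cell term sum_a f_a (x) dE/dx_a
    g_frac = np.einsum("mak,ik->mi", grad_x, H)  # dE/df = (sum_a dE/dx) @ H^T
    g_theta = np.empty((M, 3))
    for m in range(M):
        h = grad_x[m] @ rots[m]  # R^T g per atom
        g_theta[m] = np.cross(mol.local_coords, h).sum(axis=0)
    grad_H += np.einsum("mi,maj->ij", frac, grad_x)
    return E_rd_total, E_es, (g_frac, g_theta, grad_H)


_recip_cache: dict = {}


def _recip_vectors(H, alpha, accuracy):
    key = (H.tobytes(), alpha, accuracy)
    hit = _recip_cache.get(key)
    if hit is not None:
        return hit
    G = 2.0 * math.pi * np.linalg.inv(H).T  # rows g_i
    kmax = 2.0 * alpha * math.sqrt(-math.log(accuracy))
    mmax = np.ceil(kmax / (2 * math.pi) * np.linalg.norm(H, axis=1) + 1).astype(int)
    if np.prod((2 * mmax + 1).astype(float)) > 2e5:
        raise EvaluationOverflow(
            "reciprocal-space sum would need too many wave vectors; "
            "the cell is unreasonably large or distorted"
        )
    rng = [np.arange(-m, m + 1) for m in mmax]
    mm = np.stack(np.meshgrid(*rng, indexing="ij"), axis=-1).reshape(-1, 3)
    # half space (exclude 0 and one of each +/- pair)
    sel = (
        (mm[:, 0] > 0)
        | ((mm[:, 0] == 0) & (mm[:, 1] > 0))
        | ((mm[:, 0] == 0) & (mm[:, 1] == 0) & (mm[:, 2] > 0))
    )
    mm = mm[sel]
    k = mm @ G
    k2 = np.einsum("ij,ij->i", k, k)
    keep = k2 <= kmax * kmax
    k, k2 = k[keep], k2[keep]
    with np.errstate(divide="ignore", invalid="ignore"):
        Afac = np.exp(-k2 / (4.0 * alpha * alpha)) / k2
    hit = (G, k, k2, Afac)
    if len(_recip_cache) > 16:
        _recip_cache.clear()
    _recip_cache[key] = hit
    return hit


def _ewald_recip(H, V, x, q, alpha, accuracy, do_grad):
    """Reciprocal-space Ewald sum and its gradients (positions and cell)."""
    G, k, k2, Afac = _recip_vectors(H, alpha, accuracy)
    if len(k) == 0:
        return 0.0, (np.zeros_like(x) if do_grad else None), np.zeros((3, 3))
    phase = k @ x.T  # (nk, N)
    cosp = np.cos(phase)
    sinp = np.sin(phase)
    Sr = cosp @ q
    Si = sinp @ q
    S2 = Sr**2 + Si**2
    pref = COULOMB_CONSTANT * 4.0 * math.pi / V  # x2 for half space
    E = float(pref * (Afac * S2).sum())
    if not do_grad:
        return E, None, np.zeros((3, 3))
    # positions
    w = pref * Afac
    coeff = (w * Si)[:, None] * cosp - (w * Sr)[:, None] * sinp  # (nk,N)
    g_x = 2.0 * np.einsum("ka,kc->ac", coeff * q[None, :], k)
    # explicit cell dependence: 1/V factor and k = m @ G(H)
    gH = np.zeros((3, 3))
    gH += -E * np.linalg.inv(H).T  # d(1/V)
    # dE/dk_c per k-vector
    dA = -Afac * (1.0 / (4 * alpha * alpha) + 1.0 / k2)  # dA/d(k2) per unit
    xs = x  # (N,3)
    dS2_dk = 2.0 * (
        (Sr[:, None]) * (-(sinp * q[None, :]) @ xs) + (Si[:, None]) * ((cosp * q[None, :]) @ xs)
    )  # (nk,3)
    dE_dk = pref * (dA[:, None] * 2.0 * k * S2[:, None] + Afac[:, None] * dS2_dk)
    # dk_c/dH_ij = -(1/2pi) k_j G_ic  =>  dE/dH_ij = -(1/2pi) sum_k k_j (dE/dk . G_i)
    T = dE_dk @ G.T  # (nk, 3) component i = dE/dk . G_i
    gH += -(1.0 / (2 * math.pi)) * np.einsum("kj,ki->ij", k, T)
    return E, g_x, gH


def ewald_energy(lattice: Lattice, positions: np.ndarray, charges: np.ndarray,
                 accuracy: float = 1e-6, cutoff: float = 10.0) -> float:
    """Total Coulomb energy (kJ/mol per cell) of point charges in a periodic
    cell, by Ewald summation.  ``positions`` are Cartesian (A).

    This is the bare charge sum used inside :func:`lattice_energy`; exposed
    for validation against analytic lattice sums (e.g. the Madelung
    constant of rock salt).
    """
    x = np.asarray(positions, dtype=float)
    q = np.asarray(charges, dtype=float)
    H = lattice.matrix
    V = lattice.volume
    alpha = math.sqrt(-math.log(accuracy)) / cutoff
    images = _image_list(H, cutoff + np.linalg.norm(H, axis=1).sum())
    E_real = 0.0
    for n in images:
        shift = n @ H
        d = x[None, :, :] + shift[None, None, :] - x[:, None, :]
        r = np.linalg.norm(d.reshape(-1, 3), axis=1).reshape(len(x), len(x))
        if (n == 0).all():
            np.fill_diagonal(r, np.inf)
        mask = r <= cutoff
        with np.errstate(divide="ignore"):
            term = np.where(mask, erfc(alpha * r) / np.where(mask, r, 1.0), 0.0)
        E_real += 0.5 * COULOMB_CONSTANT * float((np.outer(q, q) * term).sum())
    E_recip, _, _ = _ewald_recip(H, V, x, q, alpha, accuracy, False)
    E_self = -COULOMB_CONSTANT * alpha / math.sqrt(math.pi) * float((q**2).sum())
    E_bg = -COULOMB_CONSTANT * math.pi * q.sum() ** 2 / (2.0 * alpha**2 * V)
    return E_real + E_recip + E_self + E_bg


def lattice_energy(
    structure: CrystalStructure,
    potential: PotentialModel,
    *,
    soft_core: bool = False,
    clash_check: bool = True,
) -> EnergyReport:
    """Lattice energy per molecule (kJ/mol) with its components.

    Raises :class:`ClashError` if any intermolecular contact is below 0.5 A
    (unless ``clash_check`` is off) and :class:`ParameterError` for missing
    atom-type pairs.  With ``soft_core`` the exp-6 divergence at short range
    is replaced by a C1 repulsive continuation, which lets minimisers and
    Monte Carlo proposals survive bad geometries.
    """
    E_rd, E_es, _ = _evaluate(
        structure, potential, do_grad=False, soft_core=soft_core, clash_check=clash_check
    )
    n = structure.n_molecules
    return EnergyReport(
        total_per_molecule=(E_rd + E_es) / n,
        repulsion_dispersion=E_rd / n,
        electrostatic=E_es / n,
    )


def energy_gradient(
    structure: CrystalStructure,
    potential: PotentialModel,
    *,
    soft_core: bool = False,
    clash_check: bool = False,
) -> tuple[EnergyReport, EnergyGradient]:
    """Per-molecule lattice energy and its analytic gradient."""
    E_rd, E_es, grads = _evaluate(
        structure, potential, do_grad=True, soft_core=soft_core, clash_check=clash_check
    )
    n = structure.n_molecules
    g_frac, g_theta, g_H = grads
    grad = EnergyGradient(g_frac / n, g_theta / n, g_H / n)
    report = EnergyReport(
        total_per_molecule=(E_rd + E_es) / n,
        repulsion_dispersion=E_rd / n,
        electrostatic=E_es / n,
        gradient_norm=grad.norm,
    )
    return report, grad
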