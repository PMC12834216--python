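"""Local lattice-energy minimisation of rigid-molecule crystals.

A single-stage quasi-Newton (L-BFGS) minimisation over molecule centroids
(fractional), body-frame rotation vectors (exponential-map chart) and the
six independent components of a lower-triangular cell matrix.  With
``fix_symmetry`` the asymmetric unit and the crystal system's free cell
parameters are optimised and the space-group operators reapplied at every
step; otherwise every P1 degree of freedom is free.

Short-range clashes are handled with the energy model's soft-core
continuation, so minimisation survives the bad geometries produced by
random structure generation and Monte Carlo moves; non-convergence is
reported through the structure's ``converged`` flag rather than an
exception.
"""
from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy.optimize import minimize as _scipy_minimize
from scipy.spatial.transform import Rotation

from .core.lattice import Lattice
from .core.structure import (
    CrystalStructure,
    MoleculeInstance,
    expand_to_p1,
    niggli_reset,
    proper_orientation,
)
from .core.spacegroups import cell_parameter_mask, get_symmetry_ops
from .energy import (
    EvaluationOverflow,
    PotentialModel,
    energy_gradient,
    evaluate_arrays,
    lattice_energy,
)

__all__ = ["minimize_structure", "right_jacobian"]

_MIN_DIAG = 0.5  # A, lower bound on cell diagonal entries


def right_jacobian(theta: np.ndarray) -> np.ndarray:
    """Right Jacobian of the SO(3) exponential map.

    For R(t) = R0 @ expm([t]_x), a perturbation t -> t + dt corresponds to a
    local (body-frame) chart step J_r(t) @ dt.
    """
    t = np.asarray(theta, dtype=float)
    angle = np.linalg.norm(t)
    K = np.array([[0, -t[2], t[1]], [t[2], 0, -t[0]], [-t[1], t[0], 0]])
    if angle < 1e-8:
        return np.eye(3) - 0.5 * K + K @ K / 6.0
    return (
        np.eye(3)
        - (1.0 - np.cos(angle)) / angle**2 * K
        + (angle - np.sin(angle)) / angle**3 * (K @ K)
    )


def _canonicalize(structure: CrystalStructure) -> CrystalStructure:
    """Rotate the crystal so the cell matrix is lower-triangular (energy-invariant)."""
    H = structure.lattice.matrix
    G = H @ H.T
    L = np.linalg.cholesky(G)
    Q = np.linalg.inv(H) @ L  # orthogonal, maps H -> L (rows)
    mols = []
    for m in structure.molecules:
        R_new = Q.T @ m.rotation_matrix
        mols.append(MoleculeInstance.from_rotation(m.frac_position, Rotation.from_matrix(R_new)))
    return dataclasses.replace(structure, lattice=Lattice(L), molecules=tuple(mols))


def _pack_tri(H: np.ndarray) -> np.ndarray:
    return np.array([H[0, 0], H[1, 0], H[1, 1], H[2, 0], H[2, 1], H[2, 2]])


def _unpack_tri(v: np.ndarray) -> np.ndarray:
    return np.array([[v[0], 0.0, 0.0], [v[1], v[2], 0.0], [v[3], v[4], v[5]]])


def _tri_grad(gH: np.ndarray) -> np.ndarray:
    return np.array([gH[0, 0], gH[1, 0], gH[1, 1], gH[2, 0], gH[2, 1], gH[2, 2]])


def _cell_matrix(a, b, c, alpha, beta, gamma) -> np.ndarray:
    """Lower-triangular cell matrix from lengths (A) and angles (degrees)."""
    al, be, ga = np.radians([alpha, beta, gamma])
    cx = c * math.cos(be)
    cy = c * (math.cos(al) - math.cos(be) * math.cos(ga)) / math.sin(ga)
    cz_sq = c * c - cx * cx - cy * cy
    if cz_sq <= 0:
        raise ValueError("cell angles do not define a positive-volume cell")
    return np.array(
        [
            [a, 0.0, 0.0],
            [b * math.cos(ga), b * math.sin(ga), 0.0],
            [cx, cy, math.sqrt(cz_sq)],
        ]
    )


def _cell_matrix_grad(a, b, c, alpha, beta, gamma) -> dict[str, np.ndarray]:
    """Analytic dH/dparameter for the lower-triangular construction
    (angle derivatives per degree)."""
    al, be, ga = np.radians([alpha, beta, gamma])
    ca, cb, cg = math.cos(al), math.cos(be), math.cos(ga)
    sa, sb, sg = math.sin(al), math.sin(be), math.sin(ga)
    deg = math.pi / 180.0
    cx = c * cb
    cy = c * (ca - cb * cg) / sg
    cz = math.sqrt(max(c * c - cx * cx - cy * cy, 1e-300))
    out = {}
    out["a"] = np.array([[1.0, 0, 0], [0, 0, 0], [0, 0, 0]])
    out["b"] = np.array([[0, 0, 0], [cg, sg, 0.0], [0, 0, 0]])
    out["c"] = np.array([[0, 0, 0], [0, 0, 0], [cx / c, cy / c, cz / c]])
    # alpha
    dcy = -c * sa / sg
    dcz = -(cy * dcy) / cz
    out["alpha"] = deg * np.array([[0, 0, 0], [0, 0, 0], [0.0, dcy, dcz]])
    # beta
    dcx = -c * sb
    dcy = c * sb * cg / sg
    dcz = -(cx * dcx + cy * dcy) / cz
    out["beta"] = deg * np.array([[0, 0, 0], [0, 0, 0], [dcx, dcy, dcz]])
    # gamma
    dby = b * cg
    dbx = -b * sg
    dcy_g = c * (cb * sg * sg - (ca - cb * cg) * cg) / (sg * sg)
    dcz_g = -(cy * dcy_g) / cz
    out["gamma"] = deg * np.array([[0, 0, 0], [dbx, dby, 0.0], [0.0, dcy_g, dcz_g]])
    return out


def _capped_descent(objective, x0, caps, bounds, tol, maxiter=30):
    """Steepest descent with a per-component step cap and backtracking.

    Puts badly-strained starting points inside a quadratic basin before
    quasi-Newton refinement; prevents the large first steps that can throw
    weakly-bound configurations past the interaction cutoff.
    """
    x = x0.copy()
    f, g = objective(x)
    lo = np.array([-np.inf if b[0] is None else b[0] for b in bounds])
    hi = np.array([np.inf if b[1] is None else b[1] for b in bounds])
    for _ in range(maxiter):
        gnorm = np.linalg.norm(g)
        if gnorm <= tol:
            break
        # unit step along -g, shrunk so no component exceeds its cap; small
        # gradients take proportionally small steps (keeps shallow basins)
        scale = max(np.max(np.abs(g) / caps), 1.0)
        step = g / scale
        ok = False
        for _ in range(12):
            x_new = np.clip(x - step, lo, hi)
            f_new, g_new = objective(x_new)
            if f_new < f:
                x, f, g = x_new, f_new, g_new
                ok = True
                break
            step *= 0.25
        if not ok:
            break
    return x


def _penalty(x, length_indices):
    """Objective fallback for collapsed/exploded trial cells: large value
    with a gradient steering cell lengths back up."""
    grad = np.zeros_like(x)
    f = 1e6
    for d in length_indices:
        f += 1e4 * max(0.0, 4.0 - x[d])
        grad[d] = -1e4 if x[d] < 4.0 else 0.0
    return f, grad


def _rebuild(base: CrystalStructure, H: np.ndarray, frac: np.ndarray,
             rots: np.ndarray, space_group: str | None = None) -> CrystalStructure:
    quats = Rotation.from_matrix(rots).as_quat().reshape(-1, 4)
    mols = tuple(
        MoleculeInstance(frac[i], quats[i]) for i in range(len(frac))
    )
    kw = {}
    if space_group is not None:
        kw["space_group"] = space_group
    return dataclasses.replace(base, lattice=Lattice(H), molecules=mols, **kw)


def _minimize_p1(structure, potential, tol, maxiter, fix_lattice=False, prelude=True):
    base = _canonicalize(structure)
    mol = base.molecule_ref
    M = base.n_molecules
    R0 = np.array([m.rotation_matrix for m in base.molecules])
    f0 = np.array([m.frac_position for m in base.molecules])
    # scale fractional coordinates to Angstrom-like units so the quasi-Newton
    # Hessian guess is roughly isotropic across cell, position and rotation
    L0 = np.linalg.norm(base.lattice.matrix, axis=1)

    def unpack(x):
        H = _unpack_tri(x[:6])
        rest = x[6:].reshape(M, 6)
        frac = rest[:, :3] / L0[None, :]
        thetas = rest[:, 3:]
        rots = R0 @ Rotation.from_rotvec(thetas).as_matrix().reshape(M, 3, 3)
        return H, frac, thetas, rots

    def objective(x):
        H, frac, thetas, rots = unpack(x)
        try:
            E_rd, E_es, grads = evaluate_arrays(
                mol, H, frac, rots, potential,
                do_grad=True, soft_core=True, clash_check=False,
            )
        except (EvaluationOverflow, ValueError):
            return _penalty(x, (0, 2, 5))
        g_frac, g_theta, g_H = grads
        grad = np.empty_like(x)
        grad[:6] = _tri_grad(g_H) / M
        rest = np.empty((M, 6))
        rest[:, :3] = g_frac / L0[None, :] / M
        for i in range(M):
            rest[i, 3:] = right_jacobian(thetas[i]).T @ (g_theta[i] / M)
        grad[6:] = rest.reshape(-1)
        return (E_rd + E_es) / M, grad

    x0 = np.concatenate([_pack_tri(base.lattice.matrix)] +
                        [np.concatenate([f0[i] * L0, np.zeros(3)]) for i in range(M)])
    bounds = [(None, None)] * len(x0)
    for d in (0, 2, 5):
        bounds[d] = (_MIN_DIAG, None)
    if fix_lattice:
        for d in range(6):
            bounds[d] = (x0[d], x0[d])
    caps = np.full(len(x0), 0.2)
    for i in range(M):
        caps[9 + 6 * i: 12 + 6 * i] = 0.1  # rad
    if prelude:
        x0 = _capped_descent(objective, x0, caps, bounds, tol)
    # trust box per round: quasi-Newton line searches cannot jump out of a
    # shallow basin into a distant deeper one (quenches must stay local)
    box = np.full(len(x0), 1.5)
    box[:6] = 2.0
    for i in range(M):
        box[9 + 6 * i: 12 + 6 * i] = 0.6  # rad
    trust = [
        (max(b[0], x - w) if b[0] is not None else x - w,
         min(b[1], x + w) if b[1] is not None else x + w)
        for b, x, w in zip(bounds, x0, box)
    ]
    res = _scipy_minimize(
        objective, x0, jac=True, method="L-BFGS-B", bounds=trust,
        options={"maxiter": maxiter, "ftol": 1e-15, "gtol": tol * 0.1, "maxls": 60},
    )
    H, frac, thetas, rots = unpack(res.x)
    _, g = objective(res.x)
    out = _rebuild(base, H, frac % 1.0, rots)
    return out, float(np.linalg.norm(g))


def _minimize_symmetric(structure, potential, tol, maxiter):
    sg = structure.space_group
    ops = get_symmetry_ops(sg)
    free_params = cell_parameter_mask(sg)
    a0, b0, c0, al0, be0, ga0 = structure.lattice.parameters
    full0 = {"a": a0, "b": b0, "c": c0, "alpha": al0, "beta": be0, "gamma": ga0}
    mol = structure.molecule_ref
    K = len(structure.molecules)  # asymmetric-unit molecules (z')
    n_ops = len(ops)
    R0 = np.array([m.rotation_matrix for m in structure.molecules])
    f0 = np.array([m.frac_position for m in structure.molecules])
    nc = len(free_params)
    S = np.array([rot for rot, _ in ops])  # (n_ops,3,3) fractional rotations
    T = np.array([tran for _, tran in ops])

    # Cartesian operator parts and body self-maps: constant along the path
    # because the cell stays inside its crystal system in the canonical
    # lower-triangular setting (verified below).
    H_init = _cell_matrix(**full0)
    Hinv = np.linalg.inv(H_init)
    A_cart = np.array([Hinv @ rot.T @ H_init for rot, _ in ops])
    sigmas = []
    dets = []
    for k in range(n_ops):
        M_test = A_cart[k].T @ R0[0]
        sigma = np.linalg.solve(M_test, proper_orientation(mol, M_test))
        sigmas.append(sigma)
        dets.append(float(np.sign(np.linalg.det(sigma))))
    sigmas = np.array(sigmas)
    dets = np.array(dets)
    # constancy check at a perturbed cell within the same system
    pert = dict(full0)
    for name in free_params:
        pert[name] = pert[name] * 1.01 if name in ("a", "b", "c") else pert[name] + 1.0
    try:
        H_p = _cell_matrix(**pert)
        Hp_inv = np.linalg.inv(H_p)
        const_ops = all(
            np.allclose(Hp_inv @ rot.T @ H_p, A_cart[k], atol=1e-9)
            for k, (rot, _) in enumerate(ops)
        )
    except ValueError:
        const_ops = True
    if not const_ops:  # pragma: no cover - our shipped groups are all constant
        raise RuntimeError(f"symmetry operators vary with the cell for {sg}")

    AT = np.transpose(A_cart, (0, 2, 1))

    def full_params(x):
        d = dict(full0)
        for i, name in enumerate(free_params):
            d[name] = x[i]
        return d

    L0 = np.array([a0, b0, c0])

    def unpack(x):
        H = _cell_matrix(**full_params(x))
        rest = x[nc:].reshape(K, 6)
        frac_asym = rest[:, :3] / L0[None, :]
        thetas = rest[:, 3:]
        R_asym = R0 @ Rotation.from_rotvec(thetas).as_matrix().reshape(K, 3, 3)
        # expand: copy (i,k) -> index i*n_ops + k
        frac = (np.einsum("kab,ib->ika", S, frac_asym) + T[None, :, :]).reshape(-1, 3)
        rots = np.einsum("kab,ibc,kcd->ikad", AT, R_asym, sigmas).reshape(-1, 3, 3)
        return H, frac % 1.0, thetas, rots

    def objective(x):
        try:
            H, frac, thetas, rots = unpack(x)
            E_rd, E_es, grads = evaluate_arrays(
                mol, H, frac, rots, potential,
                do_grad=True, soft_core=True, clash_check=False,
            )
        except (EvaluationOverflow, ValueError):
            return _penalty(x, tuple(i for i, n in enumerate(free_params)
                                     if n in ("a", "b", "c")))
        g_frac, g_theta, g_H = grads
        grad = np.empty_like(x)
        pars = full_params(x)
        dH = _cell_matrix_grad(**pars)
        for i, name in enumerate(free_params):
            grad[i] = float(np.sum(g_H * dH[name])) / (K * n_ops)
        gf = np.einsum("ika,kab->ib", g_frac.reshape(K, n_ops, 3), S)
        gt_copies = g_theta.reshape(K, n_ops, 3)
        gt = np.einsum("k,kab,ikb->ia", dets, sigmas, gt_copies)
        rest = np.empty((K, 6))
        rest[:, :3] = gf / L0[None, :] / (K * n_ops)
        for i in range(K):
            rest[i, 3:] = right_jacobian(thetas[i]).T @ (gt[i] / (K * n_ops))
        grad[nc:] = rest.reshape(-1)
        return (E_rd + E_es) / (K * n_ops), grad

    x0 = np.concatenate(
        [np.array([full0[p] for p in free_params])]
        + [np.concatenate([f0[i] * L0, np.zeros(3)]) for i in range(K)]
    )
    bounds = [(None, None)] * len(x0)
    for i, name in enumerate(free_params):
        bounds[i] = (_MIN_DIAG, None) if name in ("a", "b", "c") else (30.0, 150.0)
    caps = np.full(len(x0), 0.2)
    caps[:nc] = [0.2 if p in ("a", "b", "c") else 2.0 for p in free_params]
    for i in range(K):
        caps[nc + 3 + 6 * i: nc + 6 + 6 * i] = 0.1
    x0 = _capped_descent(objective, x0, caps, bounds, tol)
    box = np.full(len(x0), 1.5)
    box[:nc] = [2.0 if p in ("a", "b", "c") else 15.0 for p in free_params]
    for i in range(K):
        box[nc + 3 + 6 * i: nc + 6 + 6 * i] = 0.6
    trust = [
        (max(b[0], x - w) if b[0] is not None else x - w,
         min(b[1], x + w) if b[1] is not None else x + w)
        for b, x, w in zip(bounds, x0, box)
    ]
    res = _scipy_minimize(
        objective, x0, jac=True, method="L-BFGS-B", bounds=trust,
        options={"maxiter": maxiter, "ftol": 1e-15, "gtol": tol * 0.1, "maxls": 60},
    )
    _, g = objective(res.x)
    H, frac, thetas, rots = unpack(res.x)
    rest = res.x[nc:].reshape(K, 6)
    R_asym = R0 @ Rotation.from_rotvec(rest[:, 3:]).as_matrix().reshape(K, 3, 3)
    asym = _rebuild(structure, H, (rest[:, :3] / L0[None, :]) % 1.0, R_asym)
    p1 = _rebuild(structure, H, frac, rots, space_group="P1")
    p1 = dataclasses.replace(p1, z_prime=K * n_ops)
    return asym, p1, float(np.linalg.norm(g))


def minimize_structure(
    structure: CrystalStructure,
    potential: PotentialModel,
    tol: float = 1e-4,
    fix_symmetry: bool = False,
    maxiter: int = 400,
    rounds: int = 3,
    fix_lattice: bool = False,
) -> CrystalStructure:
    """Minimise the lattice energy; returns the relaxed structure.

    ``tol`` is the target gradient norm (kJ/mol per coordinate unit).  In
    P1 mode the result is re-expressed in its Niggli-reduced cell; in
    ``fix_symmetry`` mode the conventional cell and asymmetric unit are
    kept.  Structures that fail to reach ``tol`` are returned with
    ``converged=False`` (their energy is still attached).
    """
    if fix_symmetry and structure.space_group != "P1":
        asym = structure
        gnorm = np.inf
        for _ in range(rounds):
            asym, p1, gnorm = _minimize_symmetric(asym, potential, tol, maxiter)
            if gnorm <= tol:
                break
        energy = lattice_energy(p1, potential, soft_core=True, clash_check=False)
        return dataclasses.replace(
            asym, energy=energy.total_per_molecule, converged=bool(gnorm <= tol)
        )
    current = structure if structure.space_group == "P1" else expand_to_p1(structure)
    gnorm = np.inf
    for r in range(rounds):
        current, gnorm = _minimize_p1(
            current, potential, tol, maxiter, fix_lattice, prelude=(r == 0)
        )
        if not fix_lattice:
            current = _canonicalize(niggli_reset(current))
        if gnorm <= tol:
            break
    # gradient norm can change slightly across the Niggli re-set; re-measure
    _, g = energy_gradient(current, potential, soft_core=True)
    energy = lattice_energy(current, potential, soft_core=True, clash_check=False)
    return dataclasses.replace(
        current, energy=energy.total_per_molecule, converged=bool(g.norm <= tol)
    )
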