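"""Diverse starting-structure selection on a generalized convex hull.

Trajectory starting points should span the structurally distinct low-energy
regions of a predicted landscape rather than oversample one basin.  The
selection builds a similarity kernel from powder-pattern fingerprints,
extracts the leading kernel principal components, forms the lower convex
hull over (PC_1..PC_k, energy) and picks the structures closest in energy
to that lower surface inside an energy window above the global minimum.
The global minimum is itself a lower-hull vertex and is always selected.
"""
from __future__ import annotations

import numpy as np
from scipy.interpolate import LinearNDInterpolator, interp1d
from scipy.spatial import ConvexHull, QhullError

from .pxrd import PxrdPattern, pattern_similarity, simulate_pxrd

__all__ = ["kernel_pca_features", "hull_distances", "select_starting_structures"]


def kernel_pca_features(
    patterns: list[PxrdPattern], k: int = 3, ell: float = 1.5
) -> np.ndarray:
    """Top-k kernel-PCA coordinates from the pairwise similarity kernel."""
    N = len(patterns)
    K = np.ones((N, N))
    for i in range(N):
        for j in range(i + 1, N):
            K[i, j] = K[j, i] = pattern_similarity(patterns[i], patterns[j], ell)
    # centre the kernel
    one = np.full((N, N), 1.0 / N)
    Kc = K - one @ K - K @ one + one @ K @ one
    vals, vecs = np.linalg.eigh(Kc)
    order = np.argsort(vals)[::-1][:k]
    feats = vecs[:, order] * np.sqrt(np.abs(vals[order]))[None, :]
    return feats


def hull_distances(features: np.ndarray, energies: np.ndarray) -> np.ndarray:
    """Vertical (energy) distance of each point above the lower convex hull
    built over (features, energy).

    Degenerate feature sets fall back to fewer dimensions; with no usable
    feature spread the distance is simply energy above the minimum.
    """
    energies = np.asarray(energies, dtype=float)
    feats = np.atleast_2d(np.asarray(features, dtype=float))
    if feats.shape[0] != len(energies):
        raise ValueError("features and energies must have matching lengths")
    # drop feature directions with no spread
    spread = feats.std(axis=0)
    feats = feats[:, spread > 1e-9 * max(1.0, float(np.abs(feats).max()))]
    for k in range(feats.shape[1], 0, -1):
        try:
            return _hull_distances_k(feats[:, :k], energies)
        except (QhullError, ValueError):
            continue
    return energies - energies.min()


def _hull_distances_k(feats: np.ndarray, energies: np.ndarray) -> np.ndarray:
    pts = np.column_stack([feats, energies])
    if feats.shape[1] == 1:
        hull = ConvexHull(pts)
        # lower-hull vertices: facets with downward normal
        lower = set()
        for simplex, eq in zip(hull.simplices, hull.equations):
            if eq[-2] < -1e-12:  # energy component of the outward normal
                lower.update(simplex)
        lower = sorted(lower, key=lambda i: feats[i, 0])
        f = interp1d(
            feats[lower, 0], energies[lower], bounds_error=False,
            fill_value=(energies[lower[0]], energies[lower[-1]]),
        )
        base = f(feats[:, 0])
    else:
        hull = ConvexHull(pts)
        lower = set()
        for simplex, eq in zip(hull.simplices, hull.equations):
            if eq[-2] < -1e-12:
                lower.update(simplex)
        lower = sorted(lower)
        interp = LinearNDInterpolator(feats[lower], energies[lower])
        base = interp(feats)
        # points outside the projected hull: nearest lower-hull vertex
        nan = np.isnan(base)
        if nan.any():
            lv = feats[lower]
            le = energies[lower]
            for i in np.nonzero(nan)[0]:
                base[i] = le[np.argmin(np.linalg.norm(lv - feats[i], axis=1))]
    return np.maximum(energies - base, 0.0)


def select_starting_structures(
    structures: list,
    n_extra: int,
    energy_window: float = 15.0,
    must_include: list[int] | None = None,
    k: int = 3,
    patterns: list[PxrdPattern] | None = None,
    ell: float = 1.5,
) -> list[int]:
    """Pick MCT starting structures: ``must_include`` plus the global
    minimum plus the ``n_extra`` structures nearest the generalized convex
    hull within ``energy_window`` (kJ/mol) of the global minimum.

    ``structures`` must carry energies.  Returns sorted indices.
    """
    if not structures:
        raise ValueError("empty landscape")
    energies = np.array([s.energy for s in structures], dtype=float)
    if np.isnan(energies).any():
        raise ValueError("all structures need energies before selection")
    e_min = energies.min()
    pool = np.nonzero(energies <= e_min + energy_window)[0]
    if len(pool) == 0:
        raise ValueError("energy window excludes every structure")
    chosen = set(must_include or [])
    chosen.add(int(np.argmin(energies)))
    extras = [i for i in pool if i not in chosen]
    if n_extra >= len(extras):
        chosen.update(extras)
        return sorted(chosen)
    if patterns is None:
        patterns = [simulate_pxrd(s) for s in structures]
    feats = kernel_pca_features([patterns[i] for i in pool], k=k, ell=ell)
    dist = hull_distances(feats, energies[pool])
    dist_by_idx = dict(zip(pool.tolist(), dist))
    extras.sort(key=lambda i: (dist_by_idx[i], energies[i], i))
    chosen.update(extras[:n_extra])
    return sorted(chosen)
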