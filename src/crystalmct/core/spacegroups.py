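"""Space-group operator tables for the search set.

The search uses the most common space groups for organic molecular crystals
with one molecule in the asymmetric unit.  Operators come from gemmi's
canonical tables and are exposed as (rotation, translation) pairs acting on
fractional coordinates: ``f' = f @ rot.T + trans``.
"""
from __future__ import annotations

import gemmi
import numpy as np

__all__ = ["SEARCH_SPACE_GROUPS", "CRYSTAL_SYSTEM", "get_symmetry_ops", "cell_parameter_mask"]

# The 10 most common organic-crystal space groups (plus P1 for unconstrained work).
SEARCH_SPACE_GROUPS: tuple[str, ...] = (
    "P1", "P-1", "P21", "P21/c", "C2", "Cc", "C2/c", "P212121", "Pca21", "Pna21", "Pbca",
)

CRYSTAL_SYSTEM: dict[str, str] = {
    "P1": "triclinic",
    "P-1": "triclinic",
    "P21": "monoclinic",
    "P21/c": "monoclinic",
    "C2": "monoclinic",
    "Cc": "monoclinic",
    "C2/c": "monoclinic",
    "P212121": "orthorhombic",
    "Pca21": "orthorhombic",
    "Pna21": "orthorhombic",
    "Pbca": "orthorhombic",
}

_GEMMI_NAME = {
    "P1": "P 1", "P-1": "P -1", "P21": "P 21", "P21/c": "P 21/c", "C2": "C 2",
    "Cc": "C c", "C2/c": "C 2/c", "P212121": "P 21 21 21", "Pca21": "P c a 21",
    "Pna21": "P n a 21", "Pbca": "P b c a",
}


def get_symmetry_ops(symbol: str) -> list[tuple[np.ndarray, np.ndarray]]:
    """Return the space-group operators as (3x3 rotation, translation) pairs.

    Rotations are integer matrices and translations fractional vectors; the
    list includes centring translations, so its length is the full group
    order (molecules per cell for Z' = 1).
    """
    if symbol not in _GEMMI_NAME:
        raise KeyError(
            f"space group {symbol!r} is not in the shipped search set "
            f"{sorted(_GEMMI_NAME)}"
        )
    sg = gemmi.SpaceGroup(_GEMMI_NAME[symbol])
    ops = []
    for op in sg.operations():
        rot = np.array(op.rot, dtype=float) / op.DEN
        tran = np.array(op.tran, dtype=float) / op.DEN
        ops.append((rot, tran))
    return ops


def cell_parameter_mask(symbol: str) -> list[str]:
    """Names of the free cell parameters for the group's crystal system.

    Fixed angles are 90 degrees; monoclinic keeps beta free (b-unique
    setting, matching gemmi's operator tables for P21, P21/c, C2, Cc, C2/c).
    """
    system = CRYSTAL_SYSTEM[symbol]
    if system == "triclinic":
        return ["a", "b", "c", "alpha", "beta", "gamma"]
    if system == "monoclinic":
        return ["a", "b", "c", "beta"]
    return ["a", "b", "c"]
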