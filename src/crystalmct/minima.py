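"""Registry of distinct local minima found during sampling.

Every quench result is registered against the minima already known, using
an energy pre-filter followed by the powder-pattern similarity test, so
that all trajectories of a campaign share one consistent set of minimum
identities.  The stored representative of each minimum is its lowest-energy
incarnation.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .core.structure import CrystalStructure
from .fingerprints.pxrd import PxrdPattern, pattern_similarity, simulate_pxrd

__all__ = ["MinimaStore"]


@dataclass
class _Entry:
    structure: CrystalStructure
    energy: float
    pattern: PxrdPattern


class MinimaStore:
    """Deduplicating store of crystal minima.

    ``energy_tolerance`` (kJ/mol) pre-filters candidates before the pattern
    comparison at ``similarity_threshold``.
    """

    def __init__(
        self,
        similarity_threshold: float = 0.98,
        energy_tolerance: float = 1.0,
        ell: float = 1.5,
    ):
        self.similarity_threshold = similarity_threshold
        self.energy_tolerance = energy_tolerance
        self.ell = ell
        self._entries: list[_Entry] = []

    def __len__(self) -> int:
        return len(self._entries)

    def structure(self, min_id: int) -> CrystalStructure:
        return self._entries[min_id].structure

    def energy(self, min_id: int) -> float:
        return self._entries[min_id].energy

    def pattern(self, min_id: int) -> PxrdPattern:
        return self._entries[min_id].pattern

    def structures(self) -> list[CrystalStructure]:
        return [e.structure for e in self._entries]

    def energies(self) -> np.ndarray:
        return np.array([e.energy for e in self._entries])

    def register(self, structure: CrystalStructure, energy: float | None = None) -> int:
        """Return the id of this minimum, adding it if new."""
        if energy is None:
            energy = structure.energy
        if energy is None:
            raise ValueError("minimum must carry an energy")
        pattern = simulate_pxrd(structure)
        for i, entry in enumerate(self._entries):
            if abs(entry.energy - energy) > self.energy_tolerance:
                continue
            if pattern_similarity(entry.pattern, pattern, self.ell) >= self.similarity_threshold:
                if energy < entry.energy - 1e-10:
                    self._entries[i] = _Entry(structure, energy, pattern)
                return i
        self._entries.append(_Entry(structure, float(energy), pattern))
        return len(self._entries) - 1

    # -- persistence ----------------------------------------------------

    def save(self, path: str | Path) -> None:
        data = [
            {"structure": e.structure.to_dict(), "energy": e.energy}
            for e in self._entries
        ]
        Path(path).write_text(json.dumps(data))

    @classmethod
    def load(cls, path: str | Path, **kwargs) -> "MinimaStore":
        store = cls(**kwargs)
        for item in json.loads(Path(path).read_text()):
            s = CrystalStructure.from_dict(item["structure"])
            store._entries.append(_Entry(s, item["energy"], simulate_pxrd(s)))
        return store
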