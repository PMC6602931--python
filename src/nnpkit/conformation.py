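"""The universal per-structure record: species, coordinates, optional labels.

Units are fixed package-wide: coordinates in Å, energies in kcal/mol,
forces in kcal/mol/Å. There is no internal unit switching.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

DEFAULT_ELEMENTS = ("H", "C", "N", "O")


@dataclass
class Conformation:
    """One molecular conformation with optional low/high-fidelity labels.

    Parameters
    ----------
    molecule_id : str
        Opaque identifier grouping conformers of the same molecule.
    species : tuple of str
        Element symbols, length N >= 1.
    coordinates : (N, 3) float array, Å.
    energy_low, energy_high : float or None
        Total energies (kcal/mol) at the low/high fidelity level. Absent
        labels are ``None``, never zero.
    forces : (N, 3) float array or None, kcal/mol/Å.
    """

    molecule_id: str
    species: tuple
    coordinates: np.ndarray
    energy_low: Optional[float] = None
    energy_high: Optional[float] = None
    forces: Optional[np.ndarray] = None

    def __post_init__(self):
        self.species = tuple(str(s) for s in self.species)
        if len(self.species) < 1:
            raise ValueError("a conformation needs at least one atom")
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.shape != (len(self.species), 3):
            raise ValueError(
                f"coordinates shape {self.coordinates.shape} does not match "
                f"{len(self.species)} species entries"
            )
        if not np.all(np.isfinite(self.coordinates)):
            raise ValueError("coordinates must be finite")
        if self.forces is not None:
            self.forces = np.asarray(self.forces, dtype=float)
            if self.forces.shape != self.coordinates.shape:
                raise ValueError("forces must have the same shape as coordinates")

    @property
    def n_atoms(self) -> int:
        return len(self.species)

    def energy(self, fidelity: str) -> Optional[float]:
        """Energy label at `fidelity` ('low' or 'high')."""
        if fidelity == "low":
            return self.energy_low
        if fidelity == "high":
            return self.energy_high
        raise ValueError(f"unknown fidelity {fidelity!r}")

    def with_(self, **kw) -> "Conformation":
        """Copy with fields replaced (labels, coordinates, ...)."""
        return replace(self, **kw)

    def element_counts(self, elements: Sequence[str]) -> np.ndarray:
        """Count of each element in `elements` order."""
        return np.array([self.species.count(e) for e in elements], dtype=float)
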