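"""Atomic model container: sites, covalent topology, orthogonal box.

The model is deliberately minimal -- element, position, isotropic B, occupancy
and an optional fractional charge per site, plus an explicit bond list.  It is
a P1 orthogonal-box model: no crystallographic symmetry, which is all the
synthetic desk-scale analyses here need.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = ["AtomSite", "AtomicModel"]

WATER_RESIDUES = {"HOH", "WAT", "H2O"}


@dataclass
class AtomSite:
    """One atom: element, name, residue identity, coordinates and ADP."""

    element: str
    name: str
    residue_name: str
    residue_number: int
    position: np.ndarray
    b_iso: float = 20.0
    occupancy: float = 1.0
    partial_charge: float = 0.0
    chain: str = "A"
    serial: int | None = None

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        if self.b_iso < 0:
            raise ValueError(f"b_iso must be >= 0, got {self.b_iso}")
        if not 0 < self.occupancy <= 1:
            raise ValueError(f"occupancy must be in (0, 1], got {self.occupancy}")
        if abs(self.partial_charge) > 1:
            raise ValueError(f"|partial_charge| must be <= 1, got {self.partial_charge}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() == "H"

    @property
    def is_water(self) -> bool:
        return self.residue_name.upper() in WATER_RESIDUES

    @property
    def key(self) -> tuple:
        """Identity used to match sites across models."""
        return (self.chain, self.residue_number, self.residue_name, self.name)


@dataclass
class AtomicModel:
    """Sites + covalent bonds inside an orthogonal box (cell lengths in A)."""

    sites: list[AtomSite]
    bonds: list[tuple[int, int]] = field(default_factory=list)
    cell: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.cell = np.asarray(self.cell, dtype=float).reshape(3)
        n = len(self.sites)
        for i, j in self.bonds:
            if not (0 <= i < n and 0 <= j < n):
                raise ValueError(f"bond ({i}, {j}) refers to a missing site (n={n})")

    def __len__(self) -> int:
        return len(self.sites)

    @property
    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.sites]).reshape(-1, 3)

    @property
    def elements(self) -> list[str]:
        return [s.element for s in self.sites]

    def copy(self) -> "AtomicModel":
        return AtomicModel(
            sites=[replace(s, position=s.position.copy()) for s in self.sites],
            bonds=list(self.bonds),
            cell=self.cell.copy(),
        )

    def translate(self, shift) -> "AtomicModel":
        out = self.copy()
        shift = np.asarray(shift, dtype=float)
        for s in out.sites:
            s.position += shift
        return out

    def neighbors(self, i: int) -> list[int]:
        out = []
        for a, b in self.bonds:
            if a == i:
                out.append(b)
            elif b == i:
                out.append(a)
        return out

    def bonded_hydrogens(self, i: int) -> list[int]:
        return [j for j in self.neighbors(i) if self.sites[j].is_hydrogen]

    def parent_of(self, i: int) -> int:
        """The (unique) heavy atom bonded to hydrogen site i."""
        if not self.sites[i].is_hydrogen:
            raise ValueError(f"site {i} is not a hydrogen")
        heavy = [j for j in self.neighbors(i) if not self.sites[j].is_hydrogen]
        if len(heavy) != 1:
            raise ValueError(f"hydrogen {i} has {len(heavy)} heavy neighbours")
        return heavy[0]

    def select(self, predicate: Callable[[AtomSite], bool]) -> list[int]:
        return [i for i, s in enumerate(self.sites) if predicate(s)]

    def subset(self, keep: Iterable[int]) -> "AtomicModel":
        """A copy containing only the given site indices; bonds re-indexed."""
        keep = sorted(set(keep))
        remap = {old: new for new, old in enumerate(keep)}
        sites = [replace(self.sites[i], position=self.sites[i].position.copy()) for i in keep]
        bonds = [
            (remap[a], remap[b])
            for a, b in self.bonds
            if a in remap and b in remap
        ]
        return AtomicModel(sites=sites, bonds=bonds, cell=self.cell.copy())

    def with_charges(self, assignments: Sequence[tuple[int, float]]) -> "AtomicModel":
        out = self.copy()
        for i, q in assignments:
            out.sites[i].partial_charge = q
        return out

    def neutralized(self) -> "AtomicModel":
        out = self.copy()
        for s in out.sites:
            s.partial_charge = 0.0
        return out

    def check_inside_cell(self, tol: float = 0.0) -> None:
        pos = self.positions
        if np.any(pos < -tol) or np.any(pos > self.cell + tol):
            raise ValueError("model has sites outside the box")
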