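"""Core containers for atomic structures and residue selections.

Coordinates are in Angstroms throughout.  Residues are identified by the
author numbering scheme as deposited (the numbering used in structure
papers, e.g. His274), together with the insertion code.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import numpy as np

#: residue names recognised as water
WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})

#: elements of common monatomic ions found in crystal structures
ION_ELEMENTS = frozenset({"K", "NA", "MG", "MN", "CA", "ZN", "CL", "CS", "RB", "LI", "FE", "NI", "CO", "CU", "BR", "I"})

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}


@dataclass(frozen=True)
class AtomRecord:
    """One atom as deposited: identity, position, occupancy and B-factor."""

    chain_id: str
    residue_number: int
    insertion_code: str  # single char or ""
    residue_name: str
    atom_name: str
    element: str
    altloc: str  # single char or ""
    occupancy: float
    b_factor: float
    position: tuple[float, float, float]
    het: bool = False  # deposited as HETATM

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 1.0):
            raise ValueError(f"occupancy {self.occupancy} outside [0, 1]")
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError("non-finite atom position")
        if not self.element:
            raise ValueError("element must be non-empty")

    @property
    def residue_key(self) -> tuple[str, int, str]:
        """(chain, residue_number, insertion_code) — unique residue id."""
        return (self.chain_id, self.residue_number, self.insertion_code)

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.position, dtype=float)

    def is_water(self) -> bool:
        return self.residue_name.upper() in WATER_NAMES

    def is_monatomic_ion(self) -> bool:
        return self.het and self.element.upper() in ION_ELEMENTS and not self.is_water()


def _atom_sort_key(a: AtomRecord):
    return (a.chain_id, a.residue_number, a.insertion_code, a.atom_name)


@dataclass
class Structure:
    """An ordered collection of atoms from one model of a coordinate file."""

    identifier: str
    atoms: list[AtomRecord]
    model_number: int = 1
    unit_cell: tuple[float, float, float, float, float, float] | None = None
    space_group: str | None = None

    def __len__(self) -> int:
        return len(self.atoms)

    def sort_atoms(self) -> None:
        self.atoms.sort(key=_atom_sort_key)

    def coords(self) -> np.ndarray:
        """All atom positions as an (n, 3) array."""
        if not self.atoms:
            return np.zeros((0, 3))
        return np.array([a.position for a in self.atoms], dtype=float)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)

    def residue_atoms(self) -> dict[tuple[str, int, str], list[AtomRecord]]:
        """Atoms grouped per residue, preserving order."""
        out: dict[tuple[str, int, str], list[AtomRecord]] = {}
        for a in self.atoms:
            out.setdefault(a.residue_key, []).append(a)
        return out

    def atom_map(self, atom_name: str = "CA") -> dict[tuple[str, int, str], AtomRecord]:
        """First atom of the given name per residue."""
        out: dict[tuple[str, int, str], AtomRecord] = {}
        for a in self.atoms:
            if a.atom_name == atom_name and a.residue_key not in out:
                out[a.residue_key] = a
        return out

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Copy with every atom position mapped to R x + t."""
        R = np.asarray(rotation, float)
        t = np.asarray(translation, float)
        new_atoms = [
            replace(a, position=tuple((R @ a.xyz + t).tolist()))
            for a in self.atoms
        ]
        return Structure(self.identifier, new_atoms, self.model_number,
                         self.unit_cell, self.space_group)


@dataclass(frozen=True)
class Selection:
    """Residue-range selection over a structure.

    ``chain_id=None`` is a wildcard matching every chain.  Ranges are
    inclusive intervals of author residue numbers; overlapping or adjacent
    intervals are merged on construction.  ``atom_names`` defaults to CA.
    """

    chain_id: str | None = None
    ranges: tuple[tuple[int, int], ...] = ()
    atom_names: tuple[str, ...] = ("CA",)

    def __post_init__(self) -> None:
        norm = normalize_ranges(self.ranges)
        object.__setattr__(self, "ranges", norm)
        object.__setattr__(self, "atom_names", tuple(self.atom_names))

    def contains_residue(self, chain_id: str, residue_number: int) -> bool:
        if self.chain_id is not None and chain_id != self.chain_id:
            return False
        if not self.ranges:
            return True
        return any(lo <= residue_number <= hi for lo, hi in self.ranges)

    def matches(self, atom: AtomRecord) -> bool:
        if self.atom_names and atom.atom_name not in self.atom_names:
            return False
        return self.contains_residue(atom.chain_id, atom.residue_number)

    @classmethod
    def parse(cls, text: str, atom_names: tuple[str, ...] = ("CA",)) -> "Selection":
        """Parse e.g. ``"A:180-270,271-450"`` or ``"*:1-590"`` or ``"10-20"``."""
        text = text.strip()
        if ":" in text:
            chain_part, range_part = text.split(":", 1)
            chain: str | None = chain_part.strip() or None
            if chain == "*":
                chain = None
        else:
            chain, range_part = None, text
        ranges = []
        for token in range_part.split(","):
            token = token.strip()
            if not token:
                continue
            m = re.fullmatch(r"(-?\d+)\s*-\s*(-?\d+)", token)
            if m:
                ranges.append((int(m.group(1)), int(m.group(2))))
            elif re.fullmatch(r"-?\d+", token):
                ranges.append((int(token), int(token)))
            else:
                raise ValueError(f"cannot parse selection token {token!r}")
        return cls(chain_id=chain, ranges=tuple(ranges), atom_names=atom_names)


def normalize_ranges(ranges) -> tuple[tuple[int, int], ...]:
    """Sort and merge overlapping/adjacent inclusive intervals."""
    checked = []
    for lo, hi in ranges:
        if lo > hi:
            raise ValueError(f"interval lower bound {lo} > upper bound {hi}")
        checked.append((int(lo), int(hi)))
    checked.sort()
    merged: list[list[int]] = []
    for lo, hi in checked:
        if merged and lo <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return tuple((lo, hi) for lo, hi in merged)


def three_to_one(residue_name: str) -> str:
    """Standard 20 amino acids to one-letter code; everything else 'X'."""
    return _AA3TO1.get(residue_name.upper(), "X")
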