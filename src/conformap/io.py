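"""Reading and writing macromolecular coordinate files.

PDB and mmCIF parsing is delegated to gemmi; this module flattens the
first model into the package's :class:`~conformap.structure.Structure`
container, applying a fixed altloc policy (highest occupancy wins, ties
broken by alphabetically first altloc label) so that downstream geometry
sees exactly one position per atom.
"""

from __future__ import annotations

import os
from pathlib import Path

import gemmi

from .structure import AtomRecord, Selection, Structure, three_to_one

__all__ = ["read_structure", "write_structure", "select_atoms", "extract_sequence"]


class StructureParseError(ValueError):
    """Raised when a coordinate file cannot be parsed or contains no atoms."""


def _clean_char(c: str) -> str:
    return "" if c in ("", " ", "\x00") else c


def read_structure(path: str | os.PathLike, format: str = "auto") -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    Only the first model is kept.  Alternate locations are collapsed to a
    single atom: the highest-occupancy altloc is retained, ties going to
    the alphabetically first label.  Waters and heteroatoms are retained.
    The unit cell and space group are captured when present.

    Parameters
    ----------
    path : path to the coordinate file
    format : "pdb", "mmcif" or "auto" (detect from contents/extension)
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        if format == "auto":
            st = gemmi.read_structure(str(path))
        elif format == "pdb":
            st = gemmi.read_pdb(str(path))
        elif format == "mmcif":
            doc = gemmi.cif.read(str(path))
            st = gemmi.make_structure_from_block(doc.sole_block())
        else:
            raise ValueError(f"unknown format {format!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureParseError(f"cannot parse {path.name}: {exc}") from exc

    if len(st) == 0:
        raise StructureParseError(f"{path.name}: file contains no models")
    model = st[0]

    atoms: list[AtomRecord] = []
    for chain in model:
        for residue in chain:
            # altloc collapse: group by atom name within the residue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in residue:
                by_name.setdefault(atom.name, []).append(atom)
            for name, group in by_name.items():
                best = min(group, key=lambda a: (-a.occ, _clean_char(a.altloc)))
                atoms.append(AtomRecord(
                    chain_id=chain.name,
                    residue_number=residue.seqid.num,
                    insertion_code=_clean_char(residue.seqid.icode),
                    residue_name=residue.name,
                    atom_name=name,
                    element=best.element.name,
                    altloc=_clean_char(best.altloc),
                    occupancy=min(max(best.occ, 0.0), 1.0),
                    b_factor=best.b_iso,
                    position=(best.pos.x, best.pos.y, best.pos.z),
                    het=residue.het_flag == "H",
                ))
    if not atoms:
        raise StructureParseError(f"{path.name}: no atoms in first model")

    cell = st.cell
    unit_cell = None
    if cell is not None and cell.is_crystal():
        unit_cell = (cell.a, cell.b, cell.c, cell.alpha, cell.beta, cell.gamma)
    space_group = st.spacegroup_hm or None

    try:
        model_number = int(model.name)
    except (ValueError, AttributeError):
        model_number = getattr(model, "num", 1) or 1

    return Structure(
        identifier=path.stem,
        atoms=atoms,
        model_number=model_number,
        unit_cell=unit_cell,
        space_group=space_group,
    )


def write_structure(s: Structure, path: str | os.PathLike, format: str = "pdb") -> None:
    """Write a :class:`Structure` as a PDB file.

    The output round-trips through :func:`read_structure` with identical
    atom count, names and coordinates to 3 decimals.  Residue numbers
    above 9999 do not fit fixed-column PDB records and raise instead of
    being silently truncated.
    """
    if format != "pdb":
        raise ValueError("only PDB output is supported")
    if not s.atoms:
        raise ValueError("refusing to write an empty structure")
    for a in s.atoms:
        if a.residue_number > 9999 or a.residue_number < -999:
            raise ValueError(
                f"residue number {a.residue_number} does not fit PDB format"
            )

    st = gemmi.Structure()
    st.name = s.identifier
    if s.unit_cell is not None:
        st.cell = gemmi.UnitCell(*s.unit_cell)
    if s.space_group:
        st.spacegroup_hm = s.space_group
    model = gemmi.Model(s.model_number)
    current_chain = None
    current_res = None
    current_key = None
    for a in s.atoms:
        if current_chain is None or current_chain.name != a.chain_id:
            current_chain = gemmi.Chain(a.chain_id)
            model.add_chain(current_chain)
            current_chain = model[-1]
            current_key = None
        key = (a.residue_number, a.insertion_code, a.residue_name)
        if key != current_key:
            res = gemmi.Residue()
            res.name = a.residue_name
            res.seqid = gemmi.SeqId(a.residue_number, a.insertion_code or " ")
            res.het_flag = "H" if a.het else "A"
            current_chain.add_residue(res)
            current_res = current_chain[-1]
            current_key = key
        atom = gemmi.Atom()
        atom.name = a.atom_name
        atom.element = gemmi.Element(a.element)
        atom.altloc = a.altloc or "\x00"
        atom.occ = a.occupancy
        atom.b_iso = a.b_factor
        atom.pos = gemmi.Position(*a.position)
        current_res.add_atom(atom)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def select_atoms(s: Structure, sel: Selection) -> list[AtomRecord]:
    """Atoms of ``s`` matching the selection, in structure order.

    Residues absent from the model (crystallographic disorder) are
    silently skipped; an empty result is allowed.
    """
    return [a for a in s.atoms if sel.matches(a)]


def extract_sequence(s: Structure, chain: str) -> tuple[str, dict[int, tuple[int, str]]]:
    """One-letter sequence of a chain's polymer residues.

    Returns ``(sequence, index)`` where ``index`` maps string position to
    ``(residue_number, insertion_code)``.  Modified or non-standard
    polymer residues become ``'X'``; waters and monatomic ions are
    excluded.
    """
    seen: list[tuple[tuple[str, int, str], str]] = []
    seen_keys: set[tuple[str, int, str]] = set()
    for a in s.atoms:
        if a.chain_id != chain:
            continue
        if a.is_water() or a.is_monatomic_ion():
            continue
        # polymer residues are those carrying a CA atom
        if a.atom_name != "CA" or a.element.upper() != "C":
            continue
        if a.residue_key in seen_keys:
            continue
        seen_keys.add(a.residue_key)
        seen.append((a.residue_key, three_to_one(a.residue_name)))
    if not seen and chain not in s.chains():
        raise KeyError(f"chain {chain!r} not present in structure {s.identifier}")
    sequence = "".join(letter for _, letter in seen)
    index = {i: (key[1], key[2]) for i, (key, _) in enumerate(seen)}
    return sequence, index
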