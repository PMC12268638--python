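"""Interdomain motion: rotation decomposition, helix axes, pair distances.

The interlobe rotation between two conformations is computed by the
standard two-stage rigid-body decomposition: superpose structure B onto
structure A over a reference selection (e.g. the kinase small lobe), then
fit the residual rotation of the moving selection (e.g. the large lobe)
with a second Kabsch fit.  The rotation angle is read off the trace of
that rotation matrix, the axis from its antisymmetric part.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import select_atoms
from .structure import Selection, Structure
from .superpose import (AlignmentParams, CoreMap, InsufficientCoreError,
                        kabsch, match_core_by_alignment, match_core_by_number,
                        superpose)

__all__ = [
    "RotationDecomposition", "HelixAxis", "PairDistance",
    "interlobe_rotation", "helix_axis", "interhelix_angle_change",
    "pair_distance", "rotation_angle_axis",
]


@dataclass(frozen=True)
class RotationDecomposition:
    """Rotation of a moving domain after aligning on a reference domain."""

    angle: float  # degrees, [0, 180]
    axis: np.ndarray  # unit 3-vector
    align_selection: Selection
    moving_selection: Selection
    n_align: int
    n_moving: int


@dataclass(frozen=True)
class HelixAxis:
    """Principal axis of a helical segment, sign-fixed N-to-C."""

    centroid: np.ndarray
    direction: np.ndarray  # unit vector
    residue_range: tuple[int, int]
    n_atoms: int


@dataclass(frozen=True)
class PairDistance:
    residue_a: tuple[str, int, str]
    residue_b: tuple[str, int, str]
    mode: str  # "calpha" | "closest_heavy"
    distance: float


def rotation_angle_axis(R: np.ndarray) -> tuple[float, np.ndarray]:
    """Angle (degrees, [0, 180]) and unit axis of a proper rotation.

    The axis is extracted from the antisymmetric part; for angles near
    180 deg (where that part vanishes) it falls back to the eigenvector
    of eigenvalue +1.
    """
    R = np.asarray(R, float)
    cos_t = (np.trace(R) - 1.0) / 2.0
    cos_t = min(1.0, max(-1.0, cos_t))
    angle = math.degrees(math.acos(cos_t))
    v = np.array([R[2, 1] - R[1, 2], R[0, 2] - R[2, 0], R[1, 0] - R[0, 1]])
    norm = np.linalg.norm(v)
    if norm > 1e-8:
        axis = v / norm
    else:
        # angle ~ 0 or ~ 180: take the +1 eigenvector
        w, vec = np.linalg.eigh((R + R.T) / 2.0)
        axis = vec[:, np.argmax(w)]
        axis = axis / np.linalg.norm(axis)
    return angle, axis


def _core(a: Structure, b: Structure, sel: Selection, correspondence: str,
          params: AlignmentParams | None = None) -> CoreMap:
    if correspondence == "by_number":
        return match_core_by_number(a, b, sel)
    if correspondence == "by_alignment":
        return match_core_by_alignment(a, b, sel, params)
    raise ValueError(f"unknown correspondence mode {correspondence!r}")


def interlobe_rotation(a: Structure, b: Structure, align_sel: Selection,
                       moving_sel: Selection, correspondence: str = "by_number",
                       params: AlignmentParams | None = None) -> RotationDecomposition:
    """Rotation of ``moving_sel`` between two conformations, measured in
    the frame where ``align_sel`` is superposed.

    Returns the angle in degrees together with the rotation axis.  The
    angle is symmetric in (a, b) and invariant under global rigid
    transforms of either structure.
    """
    align_core = _core(a, b, align_sel, correspondence, params)
    _, b_aligned = superpose(a, b, align_core)
    moving_core = _core(a, b_aligned, moving_sel, correspondence, params)
    ca, cb = moving_core.coordinates(a, b_aligned)
    fit = kabsch(ca, cb)
    angle, axis = rotation_angle_axis(fit.rotation)
    return RotationDecomposition(
        angle=angle, axis=axis, align_selection=align_sel,
        moving_selection=moving_sel, n_align=len(align_core),
        n_moving=len(moving_core))


def helix_axis(s: Structure, residue_range: tuple[int, int],
               chain: str | None = None, atom_name: str = "CA") -> HelixAxis:
    """Leading principal axis of the C-alpha trace of a helical window.

    The direction sign is fixed N-to-C: positive dot product with the
    vector from the first to the last atom in the range.
    """
    sel = Selection(chain_id=chain, ranges=((residue_range[0], residue_range[1]),),
                    atom_names=(atom_name,))
    atoms = select_atoms(s, sel)
    if len(atoms) < 4:
        raise ValueError(
            f"helix range {residue_range} has {len(atoms)} {atom_name} atoms; need >= 4")
    coords = np.array([a.position for a in atoms], float)
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, _, Vt = np.linalg.svd(centered, full_matrices=False)
    direction = Vt[0]
    nc = coords[-1] - coords[0]
    if float(direction @ nc) < 0:
        direction = -direction
    return HelixAxis(centroid=centroid, direction=direction,
                     residue_range=(residue_range[0], residue_range[1]),
                     n_atoms=len(atoms))


def _axis_angle(s: Structure, range1, range2, chain) -> float:
    d1 = helix_axis(s, range1, chain).direction
    d2 = helix_axis(s, range2, chain).direction
    c = float(np.clip(d1 @ d2, -1.0, 1.0))
    return math.degrees(math.acos(c))


def interhelix_angle_change(a: Structure, b: Structure,
                            range1: tuple[int, int], range2: tuple[int, int],
                            chain: str | None = None) -> float:
    """angle(range1, range2) in A minus the same angle in B, degrees.

    Each per-structure angle is orientation-aware (N-to-C signed axes)
    and lies in [0, 180], so the difference reports whether the two
    helices opened or closed between the states.
    """
    return _axis_angle(a, range1, range2, chain) - _axis_angle(b, range1, range2, chain)


def pair_distance(s: Structure, res_a: tuple[str, int] | tuple[str, int, str],
                  res_b: tuple[str, int] | tuple[str, int, str],
                  mode: str = "closest_heavy") -> PairDistance:
    """Distance between two residues.

    ``calpha`` measures CA-CA; ``closest_heavy`` the minimum over all
    non-hydrogen atom pairs (appropriate for salt bridges and hydrogen
    bonds).
    """
    key_a = tuple(res_a) + ("",) * (3 - len(res_a))
    key_b = tuple(res_b) + ("",) * (3 - len(res_b))
    residues = s.residue_atoms()
    for key in (key_a, key_b):
        if key not in residues:
            raise KeyError(f"residue {key} not present in {s.identifier}")
    if mode == "calpha":
        atoms_a = [x for x in residues[key_a] if x.atom_name == "CA"]
        atoms_b = [x for x in residues[key_b] if x.atom_name == "CA"]
        if not atoms_a or not atoms_b:
            raise KeyError("residue lacks a CA atom")
    elif mode == "closest_heavy":
        atoms_a = [x for x in residues[key_a] if x.element.upper() != "H"]
        atoms_b = [x for x in residues[key_b] if x.element.upper() != "H"]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    pa = np.array([x.position for x in atoms_a])
    pb = np.array([x.position for x in atoms_b])
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return PairDistance(residue_a=key_a, residue_b=key_b, mode=mode,
                        distance=float(d.min()))
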