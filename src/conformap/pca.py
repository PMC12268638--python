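"""Ensemble principal-component analysis of C-alpha conformations.

An ensemble of structures is reduced to a common C-alpha core (residues
resolved in every member, mapped to a reference by author numbering or
by sequence alignment), iteratively superposed onto the evolving mean
conformation, and decomposed into orthonormal modes of the 3m-dimensional
coordinate covariance.  Projections are plain dot products of centered
coordinates with the modes and therefore carry Angstrom units — the
leading mode of a kinase-domain ensemble reads out lobe opening/closing
and the second a twist between the lobes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure import Selection, Structure
from .superpose import (AlignmentParams, CoreMap, InsufficientCoreError,
                        kabsch, match_core_by_alignment, match_core_by_number)

__all__ = [
    "EnsembleCore", "PCAModel", "Projection",
    "build_ensemble_core", "align_ensemble", "fit_pca", "project",
    "significant_modes",
]

MIN_CORE_SIZE = 10


@dataclass(frozen=True)
class EnsembleCore:
    """Common residue core of an ensemble against a reference member."""

    reference_id: str
    members: tuple[str, ...]
    cores: dict[str, CoreMap]  # member id -> CoreMap (reference side first)
    selection: Selection

    def __post_init__(self) -> None:
        sizes = {len(c) for c in self.cores.values()}
        if len(sizes) > 1:
            raise ValueError(f"inconsistent core sizes {sizes}")

    @property
    def size(self) -> int:
        return len(next(iter(self.cores.values())))


@dataclass
class PCAModel:
    """Mean conformation plus orthonormal displacement modes.

    ``mean_coords`` is (m, 3); ``modes`` is (k, 3m) with unit rows;
    ``variances`` (Angstrom^2) are the corresponding sample variances,
    non-increasing.
    """

    mean_coords: np.ndarray
    modes: np.ndarray
    variances: np.ndarray
    n_members: int

    def to_json(self) -> str:
        return json.dumps({
            "mean_coords": self.mean_coords.tolist(),
            "modes": self.modes.tolist(),
            "variances": self.variances.tolist(),
            "n_members": self.n_members,
        })

    @classmethod
    def from_json(cls, text: str) -> "PCAModel":
        d = json.loads(text)
        return cls(np.array(d["mean_coords"]), np.array(d["modes"]),
                   np.array(d["variances"]), int(d["n_members"]))


@dataclass(frozen=True)
class Projection:
    structure_id: str
    pc_values: np.ndarray  # Angstrom


def build_ensemble_core(structures: list[Structure], selection: Selection,
                        mode: str = "by_number",
                        reference_id: str | None = None,
                        params: AlignmentParams | None = None) -> EnsembleCore:
    """Residues (CA-resolved) shared by every member under the selection.

    Each member is mapped onto the reference (author numbering or global
    sequence alignment); reference residues present in every member's map
    form the core, ordered by the reference's residue order.
    """
    if len(structures) < 3:
        raise ValueError("an ensemble needs at least 3 structures")
    by_id = {s.identifier: s for s in structures}
    if len(by_id) != len(structures):
        raise ValueError("duplicate structure identifiers in ensemble")
    reference_id = reference_id or structures[0].identifier
    if reference_id not in by_id:
        raise KeyError(f"reference {reference_id!r} not among members")
    ref = by_id[reference_id]

    raw: dict[str, dict] = {}
    for s in structures:
        if mode == "by_number":
            cm = match_core_by_number(ref, s, selection)
        elif mode == "by_alignment":
            cm = match_core_by_alignment(ref, s, selection, params)
        else:
            raise ValueError(f"unknown correspondence mode {mode!r}")
        raw[s.identifier] = dict(cm.pairs)

    common = [k for k in raw[reference_id]
              if all(k in m for m in raw.values())]
    if len(common) < MIN_CORE_SIZE:
        limiting = sorted(by_id, key=lambda i: len(raw[i]))[:3]
        raise InsufficientCoreError(
            f"common core has {len(common)} residues (< {MIN_CORE_SIZE}); "
            f"most restrictive members: {limiting}")
    atom_name = selection.atom_names[0] if selection.atom_names else "CA"
    cores = {
        ident: CoreMap(pairs=tuple((k, raw[ident][k]) for k in common),
                       atom_name=atom_name)
        for ident in by_id
    }
    return EnsembleCore(reference_id=reference_id, members=tuple(by_id),
                        cores=cores, selection=selection)


def _core_coords(core: CoreMap, ref: Structure, member: Structure) -> np.ndarray:
    _, cb = core.coordinates(ref, member)
    return cb


def align_ensemble(core: EnsembleCore, structures: list[Structure],
                   tol: float = 1e-4, max_iter: int = 10,
                   ) -> tuple[np.ndarray, bool]:
    """Superpose every member onto the evolving mean conformation.

    Starts from the reference member's frame, then iterates
    mean-recompute / realign until the mean moves < ``tol`` (RMSD,
    Angstrom) or ``max_iter`` iterations.  Returns the
    (n_members, 3m) aligned coordinate matrix (member order as in
    ``core.members``) and a convergence flag.
    """
    by_id = {s.identifier: s for s in structures}
    ref = by_id[core.reference_id]
    member_coords = []
    for ident in core.members:
        cb = _core_coords(core.cores[ident], ref, by_id[ident])
        member_coords.append(cb)

    ref_coords = member_coords[core.members.index(core.reference_id)]
    target = ref_coords
    aligned = list(member_coords)
    converged = False
    for _ in range(max_iter):
        aligned = []
        for cb in member_coords:
            fit = kabsch(target, cb)
            aligned.append(fit.apply(cb))
        new_mean = np.mean(aligned, axis=0)
        shift = float(np.sqrt(((new_mean - target) ** 2).sum(1).mean()))
        target = new_mean
        if shift < tol:
            converged = True
            break
    matrix = np.stack([c.reshape(-1) for c in aligned])
    return matrix, converged


def fit_pca(matrix: np.ndarray, opening: np.ndarray | None = None) -> PCAModel:
    """Principal components of an aligned (n, 3m) coordinate matrix.

    Eigendecomposition of the covariance of row-centered coordinates via
    SVD; variances are the sample (n-1) eigenvalues.  Sign convention:
    if per-member ``opening`` values are supplied, the first mode's sign
    is fixed so the member with the largest opening projects positively;
    every other mode (and the first, when ``opening`` is absent) has its
    first component of magnitude > 1e-8 made positive.
    """
    X = np.asarray(matrix, float)
    n, p = X.shape
    if n < 3:
        raise ValueError("PCA needs at least 3 members")
    if p % 3 != 0:
        raise ValueError("column count must be a multiple of 3")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    variances = s ** 2 / (n - 1)
    modes = Vt
    scores = U * s  # (n, k)

    for k in range(modes.shape[0]):
        flip = False
        if k == 0 and opening is not None:
            i_open = int(np.argmax(np.asarray(opening, float)))
            flip = scores[i_open, 0] < 0
        else:
            nz = np.flatnonzero(np.abs(modes[k]) > 1e-8)
            flip = len(nz) > 0 and modes[k, nz[0]] < 0
        if flip:
            modes[k] = -modes[k]
            scores[:, k] = -scores[:, k]

    return PCAModel(mean_coords=mean.reshape(-1, 3), modes=modes,
                    variances=variances, n_members=n)


def project(model: PCAModel, structure: Structure, core_map: CoreMap,
            reference: Structure | None = None) -> Projection:
    """Project a structure into the model's PC space.

    The structure's core atoms are superposed onto the model mean and the
    centered displacement dotted with each mode; values are in Angstrom.
    ``core_map`` maps the ensemble reference residues (left side) to this
    structure's residues (right side).
    """
    bmap = structure.atom_map(core_map.atom_name)
    missing = [kb for _, kb in core_map.pairs if kb not in bmap]
    if missing:
        raise KeyError(f"structure {structure.identifier} lacks core residues: "
                       f"{missing[:5]}{'...' if len(missing) > 5 else ''}")
    coords = np.array([bmap[kb].position for _, kb in core_map.pairs], float)
    if coords.shape[0] != model.mean_coords.shape[0]:
        raise ValueError("core size does not match the model")
    fit = kabsch(model.mean_coords, coords)
    disp = (fit.apply(coords) - model.mean_coords).reshape(-1)
    values = model.modes @ disp
    return Projection(structure_id=structure.identifier, pc_values=values)


def significant_modes(variances: np.ndarray, scree_fraction: float = 0.05,
                      median_factor: float = 2.0) -> int:
    """Number of modes above the noise floor.

    A mode counts as significant when its variance is at least
    ``scree_fraction`` of the leading variance (classic scree-plot
    threshold) and exceeds ``median_factor`` times the median nonzero
    variance (guard so that pure-noise spectra, where all eigenvalues
    share the same scale, report zero significant modes).
    """
    v = np.asarray(variances, float)
    v = v[v > 1e-12]
    if v.size == 0:
        return 0
    med = float(np.median(v))
    floor = max(scree_fraction * float(v[0]), median_factor * med)
    return int(np.sum(v >= floor))


def training_scores(model: PCAModel, matrix: np.ndarray) -> np.ndarray:
    """Scores of aligned training rows: centered rows dotted with modes."""
    Xc = np.asarray(matrix, float) - model.mean_coords.reshape(-1)
    return Xc @ model.modes.T


def projections_frame(model: PCAModel, matrix: np.ndarray,
                      ids: list[str], n_components: int = 2) -> pd.DataFrame:
    """Tabulate training-set scores as a DataFrame (id, pc1, pc2, ...)."""
    scores = training_scores(model, matrix)
    k = min(n_components, scores.shape[1])
    data = {"structure_id": list(ids)}
    for j in range(k):
        data[f"pc{j + 1}"] = scores[:, j]
    return pd.DataFrame(data)
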