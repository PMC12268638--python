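"""Residue correspondence, rigid-body superposition and RMSD.

The superposition is the classic least-squares fit of one point set onto
another (Kabsch): given paired coordinates, find the proper rotation R and
translation t minimising ``sum ||a_i - (R b_i + t)||^2``.  Reflections are
excluded by flipping the sign of the smallest singular vector when the
determinant of the candidate rotation is negative.

Residue correspondence between structures of the same protein uses author
residue numbering directly; across homologs it goes through a global
Needleman-Wunsch sequence alignment with affine gap penalties.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io import extract_sequence, select_atoms
from .structure import Selection, Structure

__all__ = [
    "AlignmentParams", "CoreMap", "SuperpositionResult",
    "kabsch", "superpose", "rmsd",
    "match_core_by_number", "align_sequences", "match_core_by_alignment",
]

ResidueKey = tuple[str, int, str]


class InsufficientCoreError(ValueError):
    """Fewer than three matched residues; a rigid fit is not defined."""


@dataclass(frozen=True)
class CoreMap:
    """Ordered residue correspondence between two structures.

    ``pairs`` follows structure A's residue order; no residue appears
    twice on either side.  The named atom (default CA) is guaranteed
    present in both structures for every pair.
    """

    pairs: tuple[tuple[ResidueKey, ResidueKey], ...]
    atom_name: str = "CA"

    def __post_init__(self) -> None:
        a_side = [p[0] for p in self.pairs]
        b_side = [p[1] for p in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("a residue appears twice in the core map")

    def __len__(self) -> int:
        return len(self.pairs)

    def coordinates(self, a: Structure, b: Structure) -> tuple[np.ndarray, np.ndarray]:
        """Paired (n, 3) coordinate arrays of the mapped atoms."""
        amap = a.atom_map(self.atom_name)
        bmap = b.atom_map(self.atom_name)
        try:
            ca = np.array([amap[ka].position for ka, _ in self.pairs])
            cb = np.array([bmap[kb].position for _, kb in self.pairs])
        except KeyError as exc:
            raise KeyError(f"core residue {exc} lacks atom {self.atom_name}") from exc
        return ca, cb

    def to_tsv(self) -> str:
        lines = ["chain_a\tresnum_a\ticode_a\tchain_b\tresnum_b\ticode_b"]
        for (ca, ra, ia), (cb, rb, ib) in self.pairs:
            lines.append(f"{ca}\t{ra}\t{ia}\t{cb}\t{rb}\t{ib}")
        return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class SuperpositionResult:
    """Optimal rigid transform of B onto A and the resulting RMSD."""

    rotation: np.ndarray  # 3x3, det +1
    translation: np.ndarray  # 3-vector, Angstrom
    rmsd: float
    n_atoms: int
    degenerate: bool = False  # input points (near-)collinear

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def to_dict(self) -> dict:
        return {
            "rotation": self.rotation.tolist(),
            "translation": self.translation.tolist(),
            "rmsd": float(self.rmsd),
            "n_atoms": int(self.n_atoms),
            "degenerate": bool(self.degenerate),
        }


def kabsch(coords_a: np.ndarray, coords_b: np.ndarray) -> SuperpositionResult:
    """Least-squares proper rotation + translation taking B onto A.

    Parameters are paired (n, 3) arrays, n >= 3.  Returns the transform
    minimising the RMSD of ``R b + t`` against ``a``.  Collinear (or
    coincident) point sets leave one rotational degree of freedom
    undetermined; the result is still optimal but is flagged
    ``degenerate``.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinate arrays must be matching (n, 3)")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 paired atoms")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValueError("non-finite coordinates")

    ca, cb = a.mean(axis=0), b.mean(axis=0)
    a0, b0 = a - ca, b - cb
    H = b0.T @ a0  # covariance, maps b-frame to a-frame
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ca - R @ cb
    diff = a - (b @ R.T + t)
    value = float(np.sqrt((diff ** 2).sum() / n))
    # collinearity: rank of either centered set < 2
    degenerate = bool(
        np.linalg.matrix_rank(a0, tol=1e-8) < 2 or np.linalg.matrix_rank(b0, tol=1e-8) < 2
    )
    return SuperpositionResult(rotation=R, translation=t, rmsd=value,
                               n_atoms=n, degenerate=degenerate)


def rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD after optimal superposition (convenience wrapper)."""
    return kabsch(coords_a, coords_b).rmsd


def match_core_by_number(a: Structure, b: Structure, sel: Selection) -> CoreMap:
    """Pair residues sharing author numbering that carry the selected atom
    in both structures.  Order follows structure A's residue order."""
    atom_name = sel.atom_names[0] if sel.atom_names else "CA"
    a_atoms = select_atoms(a, sel)
    b_keys = {x.residue_key for x in select_atoms(b, sel)}
    pairs = []
    seen: set[ResidueKey] = set()
    for atom in a_atoms:
        key = atom.residue_key
        if key in seen:
            continue
        seen.add(key)
        if key in b_keys:
            pairs.append((key, key))
    if len(pairs) < 3:
        raise InsufficientCoreError(
            f"only {len(pairs)} shared residues between {a.identifier} and {b.identifier}"
        )
    return CoreMap(pairs=tuple(pairs), atom_name=atom_name)


@dataclass(frozen=True)
class AlignmentParams:
    """Needleman-Wunsch scoring: substitution matrix + affine gap costs.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend`` (the
    first gap position pays the opening penalty).
    """

    substitution_matrix: str = "BLOSUM62"
    gap_open: float = -11.0
    gap_extend: float = -1.0

    def __post_init__(self) -> None:
        if self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("gap penalties must be <= 0")


def _load_matrix(name: str):
    from Bio.Align import substitution_matrices

    return substitution_matrices.load(name)


_NEG_INF = float("-inf")


def align_sequences(seq_a: str, seq_b: str,
                    params: AlignmentParams | None = None) -> list[tuple[int, int]]:
    """Global alignment of two sequences; returns matched position pairs.

    Needleman-Wunsch with affine gaps (Gotoh recurrences).  Only aligned
    non-gap columns are returned, as 0-based ``(pos_a, pos_b)`` pairs.
    Ties in the traceback are broken deterministically: prefer the
    diagonal (match) move, then the vertical move (gap in B), then the
    horizontal move (gap in A).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    params = params or AlignmentParams()
    mat = _load_matrix(params.substitution_matrix)
    alphabet = mat.alphabet

    def score(x: str, y: str) -> float:
        x = x if x in alphabet else "X"
        y = y if y in alphabet else "X"
        return float(mat[x, y])

    go, ge = params.gap_open, params.gap_extend
    n, m = len(seq_a), len(seq_b)
    # M: seq_a[i-1] aligned to seq_b[j-1]; Ix: gap in B (A char consumed,
    # vertical move); Iy: gap in A (B char consumed, horizontal move)
    M = np.full((n + 1, m + 1), _NEG_INF)
    Ix = np.full((n + 1, m + 1), _NEG_INF)
    Iy = np.full((n + 1, m + 1), _NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Iy[0, j] = go + (j - 1) * ge
    for i in range(1, n + 1):
        ai = seq_a[i - 1]
        for j in range(1, m + 1):
            s = score(ai, seq_b[j - 1])
            best_prev = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            M[i, j] = best_prev + s
            Ix[i, j] = max(M[i - 1, j] + go, Ix[i - 1, j] + ge, Iy[i - 1, j] + go)
            Iy[i, j] = max(M[i, j - 1] + go, Iy[i, j - 1] + ge, Ix[i, j - 1] + go)

    # traceback from the best terminal state; tie order: M (diagonal),
    # Ix (up), Iy (left)
    i, j = n, m
    state = max(("M", "Ix", "Iy"), key=lambda st: ({"M": M, "Ix": Ix, "Iy": Iy}[st][i, j],
                                                   {"M": 2, "Ix": 1, "Iy": 0}[st]))
    pairs: list[tuple[int, int]] = []
    tol = 1e-9
    while i > 0 or j > 0:
        if state == "M":
            pairs.append((i - 1, j - 1))
            s = score(seq_a[i - 1], seq_b[j - 1])
            target = M[i, j] - s
            i, j = i - 1, j - 1
            for cand in ("M", "Ix", "Iy"):
                if abs({"M": M, "Ix": Ix, "Iy": Iy}[cand][i, j] - target) <= tol:
                    state = cand
                    break
        elif state == "Ix":
            target = Ix[i, j]
            i = i - 1
            if abs(M[i, j] + go - target) <= tol:
                state = "M"
            elif abs(Ix[i, j] + ge - target) <= tol:
                state = "Ix"
            else:
                state = "Iy"
        else:  # Iy
            target = Iy[i, j]
            j = j - 1
            if abs(M[i, j] + go - target) <= tol:
                state = "M"
            elif abs(Iy[i, j] + ge - target) <= tol:
                state = "Iy"
            else:
                state = "Ix"
        if i == 0 and j == 0:
            break
    pairs.reverse()
    return pairs


def alignment_score(seq_a: str, seq_b: str, params: AlignmentParams | None = None) -> float:
    """Optimal global alignment score under the same model as
    :func:`align_sequences` (exposed for cross-checks)."""
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    params = params or AlignmentParams()
    mat = _load_matrix(params.substitution_matrix)
    alphabet = mat.alphabet

    def score(x, y):
        return float(mat[x if x in alphabet else "X", y if y in alphabet else "X"])

    go, ge = params.gap_open, params.gap_extend
    n, m = len(seq_a), len(seq_b)
    M = np.full((n + 1, m + 1), _NEG_INF)
    Ix = np.full((n + 1, m + 1), _NEG_INF)
    Iy = np.full((n + 1, m + 1), _NEG_INF)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = go + (i - 1) * ge
    for j in range(1, m + 1):
        Iy[0, j] = go + (j - 1) * ge
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = score(seq_a[i - 1], seq_b[j - 1])
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(M[i - 1, j] + go, Ix[i - 1, j] + ge, Iy[i - 1, j] + go)
            Iy[i, j] = max(M[i, j - 1] + go, Iy[i, j - 1] + ge, Ix[i, j - 1] + go)
    return float(max(M[n, m], Ix[n, m], Iy[n, m]))


def match_core_by_alignment(a: Structure, b: Structure, sel_a: Selection,
                            params: AlignmentParams | None = None,
                            chain_a: str | None = None,
                            chain_b: str | None = None) -> CoreMap:
    """Cross-homolog residue correspondence via global sequence alignment.

    Sequences are extracted per chain, aligned, and the aligned non-gap
    columns restricted to ``sel_a`` on structure A; both residues must
    carry a CA atom.
    """
    chain_a = chain_a or a.chains()[0]
    chain_b = chain_b or b.chains()[0]
    seq_a, idx_a = extract_sequence(a, chain_a)
    seq_b, idx_b = extract_sequence(b, chain_b)
    if not seq_a or not seq_b:
        raise InsufficientCoreError("a chain has no polymer residues")
    cols = align_sequences(seq_a, seq_b, params)
    atom_name = sel_a.atom_names[0] if sel_a.atom_names else "CA"
    a_map = a.atom_map(atom_name)
    b_map = b.atom_map(atom_name)
    pairs = []
    for pa, pb in cols:
        rn_a, ic_a = idx_a[pa]
        rn_b, ic_b = idx_b[pb]
        if not sel_a.contains_residue(chain_a, rn_a):
            continue
        ka = (chain_a, rn_a, ic_a)
        kb = (chain_b, rn_b, ic_b)
        if ka in a_map and kb in b_map:
            pairs.append((ka, kb))
    if len(pairs) < 3:
        raise InsufficientCoreError(
            f"only {len(pairs)} aligned residues between {a.identifier} and {b.identifier}"
        )
    return CoreMap(pairs=tuple(pairs), atom_name=atom_name)


def superpose(a: Structure, b: Structure, core: CoreMap) -> tuple[SuperpositionResult, Structure]:
    """Superpose B onto A over the core and return the moved copy of B.

    The whole of B is transformed, not only the core atoms.
    """
    ca, cb = core.coordinates(a, b)
    result = kabsch(ca, cb)
    moved = b.transformed(result.rotation, result.translation)
    return result, moved
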