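import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from conformap.structure import Selection, Structure
from conformap.superpose import (AlignmentParams, CoreMap, InsufficientCoreError,
                                 align_sequences, alignment_score, kabsch,
                                 match_core_by_alignment, match_core_by_number,
                                 superpose)

from conftest import ca_structure, random_rigid_transform, sequence_structure


def brute_force_rmsd(a, b, n_starts=600, seed=0):
    """Independent oracle: minimize the superposition RMSD directly over
    rotation vectors (for each rotation the optimal translation matches
    the centroids), from many random starting orientations."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)

    def objective(rotvec):
        R = Rotation.from_rotvec(rotvec).as_matrix()
        return np.sqrt(((a0 - b0 @ R.T) ** 2).sum() / len(a0))

    rng = np.random.default_rng(seed)
    starts = Rotation.random(n_starts, rng=rng).as_rotvec()
    best = np.inf
    for x0 in starts[np.argsort([objective(x) for x in starts])[:5]]:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 4000})
        best = min(best, res.fun)
    return best


class TestKabsch:
    def test_identical_points_zero_rmsd(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=(8, 3))
        res = kabsch(a, a)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(res.rotation, np.eye(3), atol=1e-10)

    def test_known_rotation_recovered(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(10, 3)) * 5
        R = Rotation.from_euler("z", 30, degrees=True).as_matrix()
        b = (a - [4, 5, 6]) @ R  # b such that R b + t = a
        res = kabsch(a, b)
        assert res.rmsd <= 1e-9
        angle = np.degrees(np.arccos((np.trace(res.rotation) - 1) / 2))
        assert angle == pytest.approx(30.0, abs=1e-6)

    def test_proper_rotation_even_for_mirrored_input(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(12, 3))
        b = a * [1, 1, -1]  # reflection
        res = kabsch(a, b)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(res.rotation @ res.rotation.T, np.eye(3),
                                   atol=1e-9)

    def test_collinear_flagged_degenerate(self):
        a = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        res = kabsch(a, a)
        assert res.degenerate

    def test_nan_input_rejected(self):
        a = np.zeros((4, 3))
        b = a.copy()
        b[0, 0] = np.nan
        with pytest.raises(ValueError):
            kabsch(a, b)

    def test_fewer_than_three_points_rejected(self):
        with pytest.raises(ValueError):
            kabsch(np.zeros((2, 3)), np.zeros((2, 3)))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(5):
            n = rng.integers(5, 11)
            a = rng.normal(size=(n, 3)) * 4
            b = rng.normal(size=(n, 3)) * 4
            assert kabsch(a, b).rmsd == pytest.approx(
                brute_force_rmsd(a, b), abs=1e-6)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_rmsd_symmetric_and_rigid_invariant(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=(6, 3)) * 3
        b = rng.normal(size=(6, 3)) * 3
        forward = kabsch(a, b).rmsd
        assert kabsch(b, a).rmsd == pytest.approx(forward, abs=1e-9)
        R, t = random_rigid_transform(rng)
        assert kabsch(a @ R.T + t, b).rmsd == pytest.approx(forward, abs=1e-9)
        assert kabsch(a, b @ R.T + t).rmsd == pytest.approx(forward, abs=1e-9)


def enumerate_alignments(seq_a, seq_b, score, gap_open, gap_extend):
    """Exhaustive affine-gap alignment enumeration (tiny inputs only)."""
    best = [-np.inf, []]

    def rec(i, j, pairs, total, prev):
        if i == len(seq_a) and j == len(seq_b):
            if total > best[0] + 1e-12:
                best[0], best[1] = total, [list(pairs)]
            elif abs(total - best[0]) <= 1e-12:
                best[1].append(list(pairs))
            return
        if i < len(seq_a) and j < len(seq_b):
            rec(i + 1, j + 1, pairs + [(i, j)],
                total + score(seq_a[i], seq_b[j]), "M")
        if i < len(seq_a):
            cost = gap_extend if prev == "Ix" else gap_open
            rec(i + 1, j, pairs, total + cost, "Ix")
        if j < len(seq_b):
            cost = gap_extend if prev == "Iy" else gap_open
            rec(i, j + 1, pairs, total + cost, "Iy")

    rec(0, 0, [], 0.0, None)
    return best[0], best[1]


class TestAlignSequences:
    def test_identity(self):
        assert align_sequences("ACDE", "ACDE") == [(0, 0), (1, 1), (2, 2), (3, 3)]

    def test_deletion_matches_brute_force(self):
        from Bio.Align import substitution_matrices

        mat = substitution_matrices.load("BLOSUM62")
        params = AlignmentParams(gap_open=-10.0, gap_extend=-1.0)
        pairs = align_sequences("ACDE", "ADE", params)
        assert pairs == [(0, 0), (2, 1), (3, 2)]  # C sits against a gap
        best_score, best_sets = enumerate_alignments(
            "ACDE", "ADE", lambda x, y: float(mat[x, y]), -10.0, -1.0)
        assert alignment_score("ACDE", "ADE", params) == pytest.approx(best_score)
        assert pairs in best_sets

    def test_tie_break_deterministic(self):
        first = align_sequences("AAAA", "AAA")
        for _ in range(3):
            assert align_sequences("AAAA", "AAA") == first

    def test_scores_match_biopython(self):
        from Bio.Align import PairwiseAligner, substitution_matrices

        aligner = PairwiseAligner()
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11
        aligner.extend_gap_score = -1
        aligner.mode = "global"
        rng = np.random.default_rng(3)
        aa = "ACDEFGHIKLMNPQRSTVWY"
        for _ in range(10):
            s1 = "".join(rng.choice(list(aa), rng.integers(4, 20)))
            s2 = "".join(rng.choice(list(aa), rng.integers(4, 20)))
            assert alignment_score(s1, s2) == pytest.approx(aligner.score(s1, s2))

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            align_sequences("", "ACD")


class TestCoreMatching:
    def test_identical_structures_full_core(self):
        s = ca_structure("t", [(i, "ALA", (i * 3.8, 0, 0)) for i in range(1, 11)])
        core = match_core_by_number(s, s, Selection())
        assert len(core) == 10

    def test_set_intersection_semantics(self):
        a = ca_structure("a", [(i, "ALA", (i, 0, 0)) for i in range(1, 11) if i != 5])
        b = ca_structure("b", [(i, "ALA", (i, 0, 0)) for i in range(1, 11) if i != 7])
        core = match_core_by_number(a, b, Selection(ranges=((1, 10),)))
        assert len(core) == 8
        matched = [k[1] for k, _ in core.pairs]
        assert 5 not in matched and 7 not in matched

    def test_insufficient_core(self):
        a = ca_structure("a", [(i, "ALA", (i, 0, 0)) for i in (1, 2, 3)])
        b = ca_structure("b", [(i, "ALA", (i, 0, 0)) for i in (8, 9, 10)])
        with pytest.raises(InsufficientCoreError):
            match_core_by_number(a, b, Selection())

    def test_alignment_reduces_to_numbering_for_identical_sequences(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        s = sequence_structure("s", seq)
        by_num = match_core_by_number(s, s, Selection())
        by_aln = match_core_by_alignment(s, s, Selection())
        assert by_aln.pairs == by_num.pairs

    def test_insertion_excluded_from_core(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ"
        seq_ins = seq[:12] + "GG" + seq[12:]
        a = sequence_structure("a", seq)
        b = sequence_structure("b", seq_ins)
        core = match_core_by_alignment(a, b, Selection())
        assert len(core) == len(seq)
        b_nums = [kb[1] for _, kb in core.pairs]
        assert 13 not in b_nums and 14 not in b_nums  # the inserted GG
        # correspondence shifts by 2 after the insertion point
        mapping = {ka[1]: kb[1] for ka, kb in core.pairs}
        assert mapping[12] == 12 and mapping[13] == 15


class TestSuperpose:
    def test_identical_structures_zero(self, two_lobe_closed):
        core = match_core_by_number(two_lobe_closed, two_lobe_closed, Selection())
        res, moved = superpose(two_lobe_closed, two_lobe_closed, core)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert res.n_atoms == len(core)

    def test_whole_structure_moved(self, two_lobe_closed, small_lobe_sel):
        rng = np.random.default_rng(5)
        R, t = random_rigid_transform(rng)
        b = two_lobe_closed.transformed(R, t)
        core = match_core_by_number(two_lobe_closed, b, small_lobe_sel)
        res, moved = superpose(two_lobe_closed, b, core)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        # all 180 atoms recovered, not only the 60 core atoms
        np.testing.assert_allclose(moved.coords(), two_lobe_closed.coords(),
                                   atol=1e-9)

    def test_core_map_tsv_round_trip(self):
        s = ca_structure("t", [(i, "ALA", (i, 0, 0)) for i in range(1, 6)])
        core = match_core_by_number(s, s, Selection())
        text = core.to_tsv()
        assert text.count("\n") == 6  # header + 5 pairs
        assert "resnum_a" in text.splitlines()[0]
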