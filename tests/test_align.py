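"""Alignment tests: closed forms, Kabsch, and the exhaustive-search oracle."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from pocketsig.align import (
    PocketAlignment,
    align_pockets,
    align_point_sets,
    align_to_signature,
    combined_score,
    kabsch_superpose,
    sequence_score,
    structural_score,
)
from pocketsig.params import ScoringParams
from pocketsig.signature import PositionProfile, StructuralSignature

from conftest import pocket_of, random_rotation, structure_from_points


class TestStructuralScore:
    def test_examples(self):
        assert structural_score(2.0, 64) == pytest.approx(0.5)
        assert structural_score(1.5, 27) == pytest.approx(0.5)
        assert structural_score(0.0, 10) == 0.0

    def test_n_zero_is_error(self):
        with pytest.raises(ValueError, match="undefined"):
            structural_score(1.0, 0)

    @given(
        rmsd=st.floats(0.01, 10.0),
        n=st.integers(1, 500),
    )
    def test_monotonic(self, rmsd, n):
        assert structural_score(rmsd + 0.5, n) > structural_score(rmsd, n)
        assert structural_score(rmsd, n + 1) < structural_score(rmsd, n)


class TestSequenceScore:
    def test_limits(self):
        assert sequence_score(5.0, 5.0) == pytest.approx(0.0)
        assert sequence_score(0.0, 5.0) == pytest.approx(1.0)
        assert sequence_score(2.5, 5.0) == pytest.approx(0.5)

    def test_zero_best_is_error(self):
        with pytest.raises(ValueError, match="empty profile"):
            sequence_score(0.0, 0.0)


class TestCombinedScore:
    @pytest.mark.parametrize(
        "s, q, alpha, expected",
        [(0.5, 0.0, 1.2, 0.5), (0.0, 1.0, 1.2, 1.2), (0.5, 0.5, 1.2, 1.1)],
    )
    def test_examples(self, s, q, alpha, expected):
        assert combined_score(s, q, alpha) == pytest.approx(expected)

    @given(
        s=st.floats(0.0, 5.0),
        q=st.floats(0.0, 1.0),
        alpha=st.floats(0.1, 3.0),
    )
    def test_identity(self, s, q, alpha):
        assert combined_score(s, q, alpha) == s + alpha * q


class TestKabsch:
    def test_identity(self, rng):
        P = rng.uniform(-5, 5, (6, 3))
        R, t, rmsd = kabsch_superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        assert np.allclose(R, np.eye(3), atol=1e-9)
        assert np.allclose(t, 0.0, atol=1e-9)

    def test_recovers_random_rigid_transform(self, rng):
        P = rng.uniform(-5, 5, (8, 3))
        R_true = random_rotation(rng)
        t_true = rng.uniform(-10, 10, 3)
        Q = P @ R_true.T + t_true
        R, t, rmsd = kabsch_superpose(P, Q)
        assert rmsd < 1e-9
        assert np.allclose(R, R_true, atol=1e-6)
        assert np.allclose(t, t_true, atol=1e-6)

    def test_radial_perturbation_closed_form(self):
        # regular tetrahedron; one vertex moved radially by |v|:
        # optimal rotation stays identity and rmsd = sqrt(3)/4 * |v|
        P = np.array([
            [1.0, 1.0, 1.0], [1.0, -1.0, -1.0], [-1.0, 1.0, -1.0], [-1.0, -1.0, 1.0],
        ])
        mag = 0.4
        v = P[0] / np.linalg.norm(P[0]) * mag
        Q = P.copy()
        Q[0] = P[0] + v
        _, _, rmsd = kabsch_superpose(P, Q)
        assert rmsd == pytest.approx(math.sqrt(3.0) / 4.0 * mag, rel=1e-9)

    def test_collinear_is_error(self):
        P = np.array([[0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]], dtype=float)
        with pytest.raises(ValueError, match="degenerate"):
            kabsch_superpose(P, P + 1.0)

    def test_agrees_with_scipy_align_vectors(self, rng):
        P = rng.uniform(-5, 5, (10, 3))
        Q = rng.uniform(-5, 5, (10, 3))
        R, t, rmsd = kabsch_superpose(P, Q)
        rot, rssd = Rotation.align_vectors(Q - Q.mean(0), P - P.mean(0))
        assert np.allclose(R, rot.as_matrix(), atol=1e-8)
        assert rmsd == pytest.approx(rssd / math.sqrt(len(P)), rel=1e-6)


# -- exhaustive oracle --------------------------------------------------------

def oracle_align(query, q_elems, q_res, ref, r_elems, r_res, params):
    """Independent brute force: all >=min_aligned subsets and injections,
    superposed with scipy's rotation fitting, constrained to match_distance."""
    nq, nr = len(query), len(ref)
    best = None
    for k in range(max(3, params.min_aligned), min(nq, nr) + 1):
        for qsub in itertools.combinations(range(nq), k):
            for rperm in itertools.permutations(range(nr), k):
                P = query[list(qsub)]
                Q = ref[list(rperm)]
                Pc, Qc = P - P.mean(0), Q - Q.mean(0)
                sv = np.linalg.svd(Pc, compute_uv=False)
                if sv[1] < 1e-8 * max(1.0, sv[0]):
                    continue
                rot, _ = Rotation.align_vectors(Qc, Pc)
                moved = rot.apply(Pc)
                d = np.linalg.norm(moved - Qc, axis=1)
                if d.max() > params.match_distance + 1e-9:
                    continue
                rmsd = float(np.sqrt((d**2).mean()))
                sim = sum(
                    (1.0 if q_elems[q] == r_elems[r] else 0.0)
                    + (1.0 if q_res[q] == r_res[r] else 0.0)
                    for q, r in zip(qsub, rperm)
                )
                seq = 1.0 - sim / (2.0 * k)
                score = rmsd * k ** (-1.0 / 3.0) + params.alpha * seq
                if best is None or score < best:
                    best = score
    return best


def _random_typed_points(rng, n, spread=4.0):
    elements = [str(e) for e in rng.choice(["C", "N", "O", "S"], size=n)]
    residues = [str(r) for r in rng.choice(["ALA", "GLY", "SER", "LEU"], size=n)]
    while True:
        pts = rng.uniform(-spread, spread, (n, 3))
        sv = np.linalg.svd(pts - pts.mean(0), compute_uv=False)
        if sv[1] > 0.5:
            return pts, elements, residues


class TestOracleEquivalence:
    @pytest.mark.parametrize("pair_seed", range(10))
    def test_small_pockets_match_oracle(self, pair_seed):
        rng = np.random.default_rng(1000 + pair_seed)
        n = int(rng.integers(4, 6))
        params = ScoringParams(min_aligned=3)
        pts, elems, res = _random_typed_points(rng, n)
        # reference: noisy rigid copy with scrambled atom order
        R = random_rotation(rng)
        t = rng.uniform(-5, 5, 3)
        noisy = pts @ R.T + t + rng.normal(0, 0.1, pts.shape)
        perm = rng.permutation(n)
        ref = noisy[perm]
        r_elems = [elems[i] for i in perm]
        r_res = [res[i] for i in perm]

        aln = align_point_sets(
            pts, elems, res, ref,
            [{e: 1.0} for e in r_elems], [{r: 1.0} for r in r_res],
            params,
        )
        expected = oracle_align(pts, elems, res, ref, r_elems, r_res, params)
        assert expected is not None
        assert aln.combined_score == pytest.approx(expected, abs=1e-6)

    def test_five_atom_scrambled_example(self):
        rng = np.random.default_rng(77)
        pts, elems, res = _random_typed_points(rng, 5)
        perm = [3, 1, 4, 0, 2]
        ref = pts[perm]
        r_elems = [elems[i] for i in perm]
        r_res = [res[i] for i in perm]
        params = ScoringParams(min_aligned=3)
        aln = align_point_sets(
            pts, elems, res, ref,
            [{e: 1.0} for e in r_elems], [{r: 1.0} for r in r_res],
            params,
        )
        # exact copy under permutation: perfect alignment of all 5
        assert aln.N == 5
        assert aln.rmsd < 1e-9
        assert aln.combined_score < 1e-9


class TestAlignPockets:
    def _pocket(self, rng, n=12):
        pts, elems, res = _random_typed_points(rng, n, spread=6.0)
        s = structure_from_points(pts, elements=elems, residues=res)
        return s, pocket_of(s)

    def test_self_alignment(self, rng):
        s, p = self._pocket(rng)
        aln = align_pockets(p, s, p, s, ScoringParams())
        assert aln.N == len(p.atom_indices)
        assert aln.rmsd < 1e-9
        assert aln.sequence_score == pytest.approx(0.0)
        assert aln.combined_score < 1e-9

    def test_rigid_copy_equivalent_to_self(self, rng):
        s, p = self._pocket(rng)
        R = random_rotation(rng)
        t = np.array([3.0, -7.0, 2.0])
        pts2 = np.array([a.coords for a in s.atoms]) @ R.T + t
        s2 = structure_from_points(
            pts2,
            elements=[a.element for a in s.atoms],
            residues=[a.residue_name for a in s.atoms],
            structure_id="moved",
        )
        p2 = pocket_of(s2)
        aln = align_pockets(p, s, p2, s2, ScoringParams())
        assert aln.N == len(p.atom_indices)
        assert aln.rmsd < 1e-6
        assert aln.combined_score < 1e-6

    def test_symmetry_at_optimum(self):
        rng = np.random.default_rng(5)
        pts, elems, res = _random_typed_points(rng, 5)
        noisy = pts + rng.normal(0, 0.15, pts.shape)
        sa = structure_from_points(pts, elements=elems, residues=res, structure_id="a")
        sb = structure_from_points(noisy, elements=elems, residues=res, structure_id="b")
        pa, pb = pocket_of(sa), pocket_of(sb)
        params = ScoringParams(min_aligned=3)
        ab = align_pockets(pa, sa, pb, sb, params)
        ba = align_pockets(pb, sb, pa, sa, params)
        assert ab.combined_score == pytest.approx(ba.combined_score, abs=1e-6)

    def test_too_small_returns_no_alignment(self, rng):
        s, p = self._pocket(rng, n=12)
        aln = align_pockets(p, s, p, s, ScoringParams(min_aligned=20))
        assert not aln.is_valid
        assert aln.N == 0
        assert math.isinf(aln.combined_score)


def _signature_from(coords, atom_freqs, res_freqs, preservations=None):
    n = len(coords)
    preservations = preservations or [1.0] * n
    positions = [
        PositionProfile(
            index=i, centroid=np.asarray(coords[i], float),
            atom_freqs=atom_freqs[i], res_freqs=res_freqs[i],
            preservation=preservations[i], support=max(1, int(preservations[i] * 10)),
        )
        for i in range(n)
    ]
    return StructuralSignature(
        drug_id="toy", polarity="positive", positions=positions,
        n_structures=10, preservation_cutoff=0.5, params=ScoringParams(),
    )


class TestAlignToSignature:
    def test_pocket_vs_signature_of_itself(self, rng):
        pts, elems, res = _random_typed_points(rng, 8, spread=5.0)
        s = structure_from_points(pts, elements=elems, residues=res)
        p = pocket_of(s)
        sig = _signature_from(
            pts,
            [{e: 1.0} for e in elems],
            [{r: 1.0} for r in res],
        )
        aln = align_to_signature(p, s, sig, ScoringParams(min_aligned=6))
        assert aln.N == 8
        assert aln.rmsd < 1e-9
        assert aln.sequence_score == pytest.approx(0.0)

    def test_hand_computed_frequencies(self):
        # 3-position signature with known tables; query placed exactly on
        # the centroids so all 3 align at rmsd 0. Worked by hand:
        #   sim  = (0.7 + 0.6) + (0.2 + 0.5) + (1.0 + 1.0) = 4.0
        #   best = (0.7 + 0.6) + (0.8 + 0.5) + (1.0 + 1.0) = 4.6
        #   seq  = 1 - 4.0/4.6 = 0.13043478...
        coords = [[0.0, 0.0, 0.0], [4.0, 0.0, 0.0], [0.0, 4.0, 2.0]]
        atom_freqs = [
            {"C": 0.7, "N": 0.3},
            {"O": 0.8, "N": 0.2},
            {"S": 1.0},
        ]
        res_freqs = [
            {"ALA": 0.6, "GLY": 0.4},
            {"SER": 0.5, "THR": 0.5},
            {"CYS": 1.0},
        ]
        sig = _signature_from(coords, atom_freqs, res_freqs)
        s = structure_from_points(
            coords, elements=["C", "N", "S"], residues=["ALA", "THR", "CYS"]
        )
        p = pocket_of(s)
        aln = align_to_signature(p, s, sig, ScoringParams(min_aligned=3))
        assert aln.N == 3
        assert aln.rmsd < 1e-9
        assert aln.sequence_similarity == pytest.approx(4.0)
        assert aln.best_sequence_similarity == pytest.approx(4.6)
        assert aln.sequence_score == pytest.approx(1.0 - 4.0 / 4.6)
        assert aln.combined_score == pytest.approx(1.2 * (1.0 - 4.0 / 4.6))

    def test_absent_type_contributes_zero(self):
        coords = [[0.0, 0.0, 0.0], [4.0, 0.0, 0.0], [0.0, 4.0, 2.0]]
        sig = _signature_from(
            coords,
            [{"C": 1.0}] * 3,
            [{"ALA": 1.0}] * 3,
        )
        s = structure_from_points(
            coords, elements=["N", "N", "N"], residues=["GLY", "GLY", "GLY"]
        )
        aln = align_to_signature(pocket_of(s), s, sig, ScoringParams(min_aligned=3))
        assert aln.N == 3
        assert aln.sequence_similarity == pytest.approx(0.0)
        assert aln.sequence_score == pytest.approx(1.0)


class TestInvariants:
    def test_rigid_invariance_of_combined_score(self):
        for seed in range(5):
            rng = np.random.default_rng(300 + seed)
            pts, elems, res = _random_typed_points(rng, 10, spread=6.0)
            noisy = pts + rng.normal(0, 0.2, pts.shape)
            sa = structure_from_points(pts, elements=elems, residues=res, structure_id="a")
            sb = structure_from_points(noisy, elements=elems, residues=res, structure_id="b")
            params = ScoringParams(min_aligned=6)
            base = align_pockets(pocket_of(sa), sa, pocket_of(sb), sb, params)

            R = random_rotation(rng)
            t = rng.uniform(-8, 8, 3)
            sbt = structure_from_points(
                noisy @ R.T + t, elements=elems, residues=res, structure_id="bt"
            )
            moved = align_pockets(pocket_of(sa), sa, pocket_of(sbt), sbt, params)
            assert moved.combined_score == pytest.approx(
                base.combined_score, abs=1e-6
            )

    def test_stored_fields_satisfy_identity(self, rng):
        pts, elems, res = _random_typed_points(rng, 9, spread=5.0)
        noisy = pts + rng.normal(0, 0.25, pts.shape)
        sa = structure_from_points(pts, elements=elems, residues=res, structure_id="a")
        sb = structure_from_points(noisy, elements=elems, residues=res, structure_id="b")
        params = ScoringParams(min_aligned=5)
        aln = align_pockets(pocket_of(sa), sa, pocket_of(sb), sb, params)
        assert aln.is_valid
        assert aln.structural_score == aln.rmsd * aln.N ** (-1.0 / 3.0)
        assert aln.sequence_score == 1.0 - aln.sequence_similarity / aln.best_sequence_similarity
        assert aln.combined_score == aln.structural_score + params.alpha * aln.sequence_score
        assert aln.N == len(aln.correspondences)

    def test_no_alignment_sentinel(self):
        aln = PocketAlignment.no_alignment()
        assert not aln.is_valid
        assert math.isinf(aln.combined_score)
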