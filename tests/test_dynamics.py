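"""Flexibility, correlation and contact metrics with brute-force oracles."""

import numpy as np
import pytest

from enscompare import (
    ConformationEnsemble,
    FlexibilityProfile,
    PairMatrix,
    center_ensemble,
    classify_interaction_pairs,
    combine_triangles,
    compute_contact_map,
    compute_dccm,
    compute_rmsf,
    matrix_mae,
    profile_pcc,
    resolve_selection,
    stratified_mae,
    stratify_sequence_separation,
    stratify_termini,
)
from enscompare.dynamics import CenteredEnsemble
from enscompare.synthetic import HarmonicSpec, make_backbone, make_harmonic_ensemble


def _constant_ensemble(helix10, n_frames=4):
    topo, coords = helix10
    return ConformationEnsemble(topo, np.repeat(coords[None], n_frames, axis=0))


class TestCentering:
    def test_constant_ensemble_zero_displacement(self, helix10, helix10_calpha):
        c = center_ensemble(_constant_ensemble(helix10), helix10_calpha)
        assert np.abs(c.displacements).max() == 0

    def test_two_frame_symmetry(self, helix10, helix10_calpha):
        topo, coords = helix10
        d = np.zeros_like(coords)
        d[:, 0] = 1.5
        ens = ConformationEnsemble(topo, np.stack([coords + d, coords - d]))
        c = center_ensemble(ens, helix10_calpha)
        np.testing.assert_allclose(c.mean_coords, coords[helix10_calpha.indices])
        np.testing.assert_allclose(np.abs(c.displacements[:, :, 0]), 1.5)

    def test_lossless_decomposition(self, harmonic_small, helix10_calpha):
        c = center_ensemble(harmonic_small, helix10_calpha)
        recon = c.mean_coords[None] + c.displacements
        # subtraction then re-addition round-trips to double rounding
        np.testing.assert_allclose(
            recon, harmonic_small.frames[:, helix10_calpha.indices, :],
            rtol=0, atol=1e-12,
        )


class TestRmsf:
    def test_constant_ensemble_zero(self, helix10, helix10_calpha):
        prof = compute_rmsf(center_ensemble(_constant_ensemble(helix10), helix10_calpha))
        assert np.all(prof.values == 0)

    def test_two_point_displacement(self, helix10, helix10_calpha):
        topo, coords = helix10
        d = np.zeros_like(coords)
        d[:, 0] = 0.7
        ens = ConformationEnsemble(topo, np.stack([coords + d, coords - d]))
        prof = compute_rmsf(center_ensemble(ens, helix10_calpha))
        np.testing.assert_allclose(prof.values, 0.7, atol=1e-12)

    def test_single_frame_rejected(self, helix10, helix10_calpha):
        ens = _constant_ensemble(helix10, n_frames=1)
        with pytest.raises(ValueError, match="single-frame"):
            compute_rmsf(center_ensemble(ens, helix10_calpha))

    def test_isotropic_gaussian_expectation(self):
        # sigma per coordinate 0.5 A -> RMSF converges to 0.5*sqrt(3)
        spec = HarmonicSpec(n_res=30, n_frames=5000, sigma_profile=0.5, seed=11)
        ens = make_harmonic_ensemble(spec)
        sel = resolve_selection(ens.topology, "calpha")
        prof = compute_rmsf(center_ensemble(ens, sel))
        expected = 0.5 * np.sqrt(3)
        assert np.all(np.abs(prof.values - expected) / expected < 0.03)


class TestProfilePcc:
    def test_self_correlation(self):
        p = FlexibilityProfile(np.array([1.0, 2.0, 3.0, 2.5]), list("abcd"))
        assert profile_pcc(p, p) == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        a = FlexibilityProfile(np.array([1.0, 2.0, 3.0]), list("abc"))
        b = FlexibilityProfile(10 - a.values, list("abc"))
        assert profile_pcc(a, b) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        # direct summation of the textbook formula for (1,2,3,4)/(1,2,3,5)
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 5.0])
        xc, yc = x - x.mean(), y - y.mean()
        expected = (xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum())
        got = profile_pcc(
            FlexibilityProfile(x, list("abcd")), FlexibilityProfile(y, list("abcd"))
        )
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.9827, abs=1e-4)

    def test_zero_variance_rejected(self):
        a = FlexibilityProfile(np.ones(5), list("abcde"))
        b = FlexibilityProfile(np.arange(5.0), list("abcde"))
        with pytest.raises(ValueError, match="zero-variance"):
            profile_pcc(a, b)


def _brute_force_dccm(disp):
    n_res = disp.shape[1]
    C = np.zeros((n_res, n_res))
    for i in range(n_res):
        for j in range(n_res):
            num = sum(disp[t, i] @ disp[t, j] for t in range(disp.shape[0]))
            di = sum(disp[t, i] @ disp[t, i] for t in range(disp.shape[0]))
            dj = sum(disp[t, j] @ disp[t, j] for t in range(disp.shape[0]))
            C[i, j] = num / np.sqrt(di * dj)
    return C


class TestDccm:
    def test_identical_and_opposed_series(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal((50, 1, 3))
        disp = np.concatenate([base, base, -base], axis=1)
        c = CenteredEnsemble(np.zeros((3, 3)), disp, ["r1", "r2", "r3"])
        m = compute_dccm(c).values
        assert m[0, 1] == pytest.approx(1.0)
        assert m[0, 2] == pytest.approx(-1.0)
        np.testing.assert_allclose(np.diag(m), 1.0)

    def test_matches_brute_force_on_toy(self):
        rng = np.random.default_rng(5)
        disp = rng.standard_normal((10, 5, 3))
        disp -= disp.mean(axis=0)
        c = CenteredEnsemble(np.zeros((5, 3)), disp, [f"r{i}" for i in range(5)])
        np.testing.assert_allclose(
            compute_dccm(c).values, _brute_force_dccm(disp), atol=1e-12
        )

    def test_independent_residues_near_zero(self):
        spec = HarmonicSpec(n_res=12, n_frames=5000, sigma_profile=0.5, seed=21)
        ens = make_harmonic_ensemble(spec)
        sel = resolve_selection(ens.topology, "calpha")
        m = compute_dccm(center_ensemble(ens, sel)).values
        off = m[~np.eye(12, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_block_correlation_recovered(self):
        spec = HarmonicSpec(
            n_res=12, n_frames=5000, sigma_profile=0.5,
            correlation_blocks=[(range(0, 4), range(4, 8), 0.8)], seed=2,
        )
        ens = make_harmonic_ensemble(spec)
        sel = resolve_selection(ens.topology, "calpha")
        m = compute_dccm(center_ensemble(ens, sel)).values
        block = m[np.ix_(range(0, 4), range(4, 8))]
        assert np.abs(block - 0.8).max() < 0.05
        np.testing.assert_array_equal(m, m.T)

    def test_zero_displacement_residue_listed(self, helix10, helix10_calpha):
        disp = np.zeros((5, 10, 3))
        disp[:, :9, :] = np.random.default_rng(0).standard_normal((5, 9, 3))
        c = CenteredEnsemble(np.zeros((10, 3)), disp - disp.mean(axis=0),
                             [f"r{i}" for i in range(10)])
        with pytest.raises(ValueError, match="r9"):
            compute_dccm(c)


class TestMae:
    def test_identity_and_offset(self):
        rng = np.random.default_rng(1)
        v = rng.random((6, 6))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        m = PairMatrix("mean_min_distance", v, [str(i) for i in range(6)])
        assert matrix_mae(m, m) == 0.0
        shifted = PairMatrix("mean_min_distance", v + 0.37, m.residue_labels)
        assert matrix_mae(shifted, m) == pytest.approx(0.37, abs=1e-12)

    def test_hand_arithmetic(self):
        a = PairMatrix("mean_min_distance", np.array([[0.0, 1.0], [1.0, 0.0]]), ["a", "b"])
        b = PairMatrix("mean_min_distance",
                       np.array([[0.1, 1.3], [1.3, 0.1]]), ["a", "b"])
        assert matrix_mae(a, b) == pytest.approx(0.2, abs=1e-12)

    def test_kind_mismatch(self):
        a = PairMatrix("correlation", np.eye(3), list("abc"))
        b = PairMatrix("mean_min_distance", np.zeros((3, 3)), list("abc"))
        with pytest.raises(ValueError, match="kind"):
            matrix_mae(a, b)


def _brute_force_contact_map(ensemble, selection):
    n_res = ensemble.topology.n_residues
    D = np.zeros((n_res, n_res))
    for i in range(n_res):
        for j in range(n_res):
            if i == j:
                continue
            vals = []
            for f in range(ensemble.n_frames):
                best = np.inf
                for a in selection.per_residue_groups[i]:
                    for b in selection.per_residue_groups[j]:
                        d = np.linalg.norm(ensemble.frames[f, a] - ensemble.frames[f, b])
                        best = min(best, d)
                vals.append(best)
            D[i, j] = np.mean(vals)
    return D


class TestContactMap:
    def test_matches_brute_force_exactly(self):
        spec = HarmonicSpec(n_res=4, n_frames=3, sigma_profile=0.5, seed=9)
        ens = make_harmonic_ensemble(spec)
        sel = resolve_selection(ens.topology, "backbone_cb")
        got = compute_contact_map(ens, sel).values
        expected = _brute_force_contact_map(ens, sel)
        np.testing.assert_allclose(got, expected, atol=1e-12)

    def test_mean_of_per_frame_minima(self, helix10):
        topo, coords = helix10
        f2 = coords.copy()
        f2 += 0  # same topology, shifted residue 1 below
        # move residue 1 so its min distance to residue 0 changes 3 -> 5
        sel = resolve_selection(topo, "backbone_cb")
        ens = ConformationEnsemble(topo, np.stack([coords, f2]))
        m1 = compute_contact_map(
            ConformationEnsemble(topo, coords[None]), sel
        ).values
        d = compute_contact_map(ens, sel).values
        np.testing.assert_allclose(d, m1, atol=1e-12)  # identical frames
        assert np.all(np.diag(d) == 0)

    def test_arithmetic_mean_of_frame_minima(self):
        # two frames engineered so one pair has minima 3.0 and 5.0
        topo, coords = make_backbone(2)
        sel = resolve_selection(topo, "backbone_cb")
        base = np.zeros_like(coords)
        g1 = sel.per_residue_groups[1]
        f1, f2 = base.copy(), base.copy()
        f1[g1] += np.array([3.0, 0, 0])
        f2[g1] += np.array([5.0, 0, 0])
        # spread residue-0 atoms at origin, residue-1 atoms offset on x
        ens = ConformationEnsemble(topo, np.stack([f1, f2]))
        d = compute_contact_map(ens, sel).values
        assert d[0, 1] == pytest.approx(4.0, abs=1e-12)

    def test_symmetry_nonneg(self, harmonic_small):
        sel = resolve_selection(harmonic_small.topology, "backbone_cb")
        d = compute_contact_map(harmonic_small, sel).values
        np.testing.assert_array_equal(d, d.T)
        assert d.min() >= 0


class TestCombineTriangles:
    def test_identical_inputs_symmetric(self):
        rng = np.random.default_rng(0)
        v = rng.random((5, 5))
        v = (v + v.T) / 2
        m = PairMatrix("mean_min_distance", np.abs(v), [str(i) for i in range(5)])
        out = combine_triangles(m, m).values
        np.testing.assert_array_equal(out, out.T)

    def test_elements_from_correct_triangles(self):
        a = PairMatrix("mean_min_distance", np.full((4, 4), 1.0), list("abcd"))
        b = PairMatrix("mean_min_distance", np.full((4, 4), 2.0), list("abcd"))
        out = combine_triangles(a, b).values
        assert out[1, 3] == 1.0 and out[3, 1] == 2.0 and out[2, 2] == 1.0

    def test_transpose_identity(self):
        rng = np.random.default_rng(8)
        va, vb = rng.random((4, 4)), rng.random((4, 4))
        va, vb = (va + va.T) / 2, (vb + vb.T) / 2
        a = PairMatrix("mean_min_distance", va, list("abcd"))
        b = PairMatrix("mean_min_distance", vb, list("abcd"))
        ab = combine_triangles(a, b).values
        ba = combine_triangles(b, a).values
        off = ~np.eye(4, dtype=bool)
        np.testing.assert_array_equal(ab.T[off], ba[off])


class TestStrata:
    def test_sequence_separation_thresholds(self):
        s = stratify_sequence_separation(100)
        assert s.labels[(0, 10)] == "close"
        assert s.labels[(0, 85)] == "far"
        assert s.labels[(0, 20)] == "middle"   # boundary falls to middle
        assert s.labels[(0, 80)] == "middle"

    def test_termini_counts(self):
        s = stratify_termini(100, 10)
        labs = list(s.labels.values())
        assert labs.count("terminal") == 20 and labs.count("middle") == 80

    def test_termini_zero_and_too_large(self):
        assert set(stratify_termini(20, 0).labels.values()) == {"middle"}
        with pytest.raises(ValueError, match="too large"):
            stratify_termini(20, 10)

    def test_interaction_classes(self):
        names = ["ASP", "LYS", "PHE", "TYR", "LEU", "ILE"]
        topo, _ = make_backbone(6, names)
        d = np.full((6, 6), 8.0)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 4.0   # ASP-LYS salt bridge
        d[2, 3] = d[3, 2] = 4.0   # PHE-TYR stacking
        ref = PairMatrix("mean_min_distance", d, topo.residue_labels())
        s = classify_interaction_pairs(topo, ref, close_cutoff=5.0)
        assert s.labels[(0, 1)] == "polar_polar"
        assert s.labels[(2, 3)] == "pi_pi"
        assert (4, 5) not in s.labels   # LEU-ILE at 8 A excluded by cutoff

    def test_unknown_residue_warns_other(self):
        topo, _ = make_backbone(3, ["ASP", "XYZ", "LYS"])
        d = np.full((3, 3), 2.0)
        np.fill_diagonal(d, 0.0)
        ref = PairMatrix("mean_min_distance", d, topo.residue_labels())
        with pytest.warns(UserWarning, match="XYZ"):
            s = classify_interaction_pairs(topo, ref)
        assert s.labels[(0, 1)] == "other"
        assert s.labels[(0, 2)] == "polar_polar"


class TestStratifiedMae:
    def _pair(self, rng, n=6):
        a = rng.random((n, n))
        a = (a + a.T) / 2
        b = rng.random((n, n))
        b = (b + b.T) / 2
        labels = [str(i) for i in range(n)]
        return (
            PairMatrix("mean_min_distance", a, labels),
            PairMatrix("mean_min_distance", b, labels),
        )

    def test_single_stratum_equals_offdiag_mae(self, rng):
        m, ref = self._pair(rng)
        strata = stratify_sequence_separation(6, near_frac=0.0, far_frac=1.1)
        out = stratified_mae(m, ref, strata)
        n = 6
        iu = np.triu_indices(n, k=1)
        expected = np.abs(m.values - ref.values)[iu].mean()
        assert out["middle"] == pytest.approx(expected, abs=1e-12)

    def test_hand_built_strata(self):
        v = np.zeros((3, 3))
        w = np.array([[0.0, 0.1, 0.4], [0.1, 0.0, 0.2], [0.4, 0.2, 0.0]])
        labels = list("abc")
        m = PairMatrix("mean_min_distance", v, labels)
        ref = PairMatrix("mean_min_distance", w, labels)
        from enscompare import StratumAssignment

        strata = StratumAssignment(
            "pair", {(0, 1): "x", (0, 2): "y", (1, 2): "x"}
        )
        out = stratified_mae(m, ref, strata)
        assert out["x"] == pytest.approx(0.15, abs=1e-12)
        assert out["y"] == pytest.approx(0.4, abs=1e-12)

    def test_pair_count_weighted_recombination(self, rng):
        m, ref = self._pair(rng, n=9)
        strata = stratify_sequence_separation(9)
        out = stratified_mae(m, ref, strata)
        counts = {}
        for lab in strata.labels.values():
            counts[lab] = counts.get(lab, 0) + 1
        recombined = sum(out[lab] * counts[lab] for lab in out) / sum(counts.values())
        iu = np.triu_indices(9, k=1)
        overall = np.abs(m.values - ref.values)[iu].mean()
        assert recombined == pytest.approx(overall, abs=1e-12)
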