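import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from rfamap import pose_consensus as pc
from rfamap.structure_io import Pose, PoseEnsemble
from rfamap.synthetic_data import (FRRFA_SEQUENCE, KNFLRFA_SEQUENCE,
                                   PoseGenSpec, gen_pose_ensembles,
                                   make_peptide_template)

finite = st.floats(-50, 50)


def random_frame(rng):
    return pc.RfaFrame(coords=rng.uniform(-20, 20, (9, 3)), source_pose="x")


class TestExtractRfaFrame:
    def test_frrfa_frame_uses_residues_3_and_4(self):
        pose = make_peptide_template(FRRFA_SEQUENCE)
        frame = pc.extract_rfa_frame(pose)
        arg_n = next(a for a in pose.atoms if a.res_seq == 3 and a.name == "N")
        phe_cz = next(a for a in pose.atoms if a.res_seq == 4 and a.name == "CZ")
        np.testing.assert_allclose(frame.coords[0], arg_n.coords)
        np.testing.assert_allclose(frame.coords[7], phe_cz.coords)

    def test_knflrfa_frame_uses_residues_5_and_6(self):
        pose = make_peptide_template(KNFLRFA_SEQUENCE)
        frame = pc.extract_rfa_frame(pose)
        arg_ca = next(a for a in pose.atoms if a.res_seq == 5 and a.name == "CA")
        np.testing.assert_allclose(frame.coords[1], arg_ca.coords)

    def test_shared_cterminal_geometry_across_templates(self):
        fa = pc.extract_rfa_frame(make_peptide_template(FRRFA_SEQUENCE))
        fb = pc.extract_rfa_frame(make_peptide_template(KNFLRFA_SEQUENCE))
        assert pc.rfa_rmsd(fa, fb) == pytest.approx(0.0, abs=1e-12)

    def test_missing_amide_is_motif_error(self):
        pose = make_peptide_template(FRRFA_SEQUENCE)
        bare = Pose([a for a in pose.atoms if a.res_name != "NH2"], -7.0, "bare")
        with pytest.raises(pc.RfaMotifError, match="amide"):
            pc.extract_rfa_frame(bare)

    def test_missing_cz_error_names_atom(self):
        pose = make_peptide_template(FRRFA_SEQUENCE)
        pruned = Pose([a for a in pose.atoms
                       if not (a.res_seq == 4 and a.name == "CZ")], -7.0, "p")
        with pytest.raises(pc.RfaMotifError, match="CZ"):
            pc.extract_rfa_frame(pruned)

    def test_wrong_motif_error(self):
        pose = make_peptide_template(("ARG", "ARG"))  # no C-terminal Phe
        with pytest.raises(pc.RfaMotifError, match="ARG-PHE"):
            pc.extract_rfa_frame(pose)


class TestRfaRmsd:
    def test_identical_frames_zero(self):
        f = random_frame(np.random.default_rng(0))
        assert pc.rfa_rmsd(f, f) == 0.0

    def test_translation_by_3A_gives_3(self):
        f = random_frame(np.random.default_rng(1))
        g = pc.RfaFrame(f.coords + np.array([3.0, 0.0, 0.0]), "y")
        assert pc.rfa_rmsd(f, g) == pytest.approx(3.0, abs=1e-12)

    def test_matches_arithmetic_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            a, b = random_frame(rng), random_frame(rng)
            acc = 0.0
            for i in range(9):
                dx = a.coords[i] - b.coords[i]
                acc += dx[0] ** 2 + dx[1] ** 2 + dx[2] ** 2
            assert pc.rfa_rmsd(a, b) == pytest.approx((acc / 9.0) ** 0.5, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000), tx=finite, ty=finite, tz=finite)
    def test_translation_law_and_symmetry(self, seed, tx, ty, tz):
        f = random_frame(np.random.default_rng(seed))
        t = np.array([tx, ty, tz])
        g = pc.RfaFrame(f.coords + t, "t")
        assert pc.rfa_rmsd(f, g) == pytest.approx(np.linalg.norm(t), abs=1e-9)
        assert pc.rfa_rmsd(g, f) == pc.rfa_rmsd(f, g)


def _scored_ensemble(scores, seed=0):
    tmpl = make_peptide_template(FRRFA_SEQUENCE)
    rng = np.random.default_rng(seed)
    poses = [tmpl.translated(rng.uniform(-30, 30, 3), pose_id=f"p{i:02d}")
             for i in range(len(scores))]
    poses = [Pose(p.atoms, s, p.pose_id) for p, s in zip(poses, scores)]
    return PoseEnsemble("pep", poses, receptor_id="r")


class TestEnergyWindow:
    def test_one_kcal_window_keeps_first_two(self):
        ens = _scored_ensemble([-8.0, -7.5, -6.9])
        kept = pc.energy_window(ens, 1.0)
        assert [p.score for p in kept.poses] == [-8.0, -7.5]

    def test_zero_window_keeps_ties_with_best(self):
        ens = _scored_ensemble([-8.0, -8.0, -7.9])
        kept = pc.energy_window(ens, 1e-12)
        assert [p.score for p in kept.poses] == [-8.0, -8.0]

    def test_empty_ensemble_error(self):
        ens = PoseEnsemble("pep", [], receptor_id="r")
        with pytest.raises(ValueError):
            pc.energy_window(ens, 1.0)

    def test_monotone_in_window(self):
        ens = _scored_ensemble(list(np.linspace(-9, -4, 11)))
        sizes = [len(pc.energy_window(ens, w)) for w in (0.5, 1.0, 2.0, 5.0)]
        assert sizes == sorted(sizes)
        assert sizes[-1] == len(ens)


class TestMatchConsensus:
    def test_planted_match_recovered_exactly(self):
        ens_a, ens_b, truth = gen_pose_ensembles(
            PoseGenSpec(seed=11, n_planted=1, n_decoys_a=8, n_decoys_b=8))
        matches = pc.match_consensus(ens_a, ens_b)
        assert [(m.pose_a, m.pose_b) for m in matches] == \
            [(t["pose_a"], t["pose_b"]) for t in truth]
        assert matches[0].rmsd == pytest.approx(0.5, abs=1e-9)

    def test_no_pair_below_cutoff_gives_empty(self):
        ens_a, ens_b, _ = gen_pose_ensembles(
            PoseGenSpec(seed=5, n_planted=0, n_decoys_a=6, n_decoys_b=6))
        assert pc.match_consensus(ens_a, ens_b) == []

    def test_receptor_mismatch_error(self):
        a = _scored_ensemble([-8.0])
        b = PoseEnsemble("pep2", _scored_ensemble([-7.0]).poses, receptor_id="other")
        with pytest.raises(ValueError, match="receptor"):
            pc.match_consensus(a, b)

    def test_matches_brute_force_on_random_ensembles(self):
        rng = np.random.default_rng(2024)
        tmpl_a = make_peptide_template(FRRFA_SEQUENCE)
        tmpl_b = make_peptide_template(KNFLRFA_SEQUENCE)
        for _ in range(5):
            poses_a = [Pose(tmpl_a.translated(rng.uniform(-3, 3, 3)).atoms,
                            float(rng.uniform(-9, -6)), f"A{i:02d}") for i in range(10)]
            poses_b = [Pose(tmpl_b.translated(rng.uniform(-3, 3, 3)).atoms,
                            float(rng.uniform(-9, -6)), f"B{i:02d}") for i in range(10)]
            ens_a = PoseEnsemble("a", poses_a, "r")
            ens_b = PoseEnsemble("b", poses_b, "r")
            params = pc.ConsensusParams(energy_window=1.0, rmsd_cutoff=1.0)
            got = [(m.pose_a, m.pose_b, round(m.rmsd, 10))
                   for m in pc.match_consensus(ens_a, ens_b, params)]
            # independent exhaustive double loop
            best = ens_a.best_score
            expected = []
            for pa in sorted(ens_a.poses, key=lambda p: (p.score, p.pose_id)):
                if pa.score > best + 1.0:
                    continue
                fa = pc.extract_rfa_frame(pa)
                pairs = sorted(
                    ((pc.rfa_rmsd(fa, pc.extract_rfa_frame(pb)), pb.pose_id)
                     for pb in ens_b.poses))
                if pairs[0][0] < 1.0:
                    expected.append((pa.pose_id, pairs[0][1], round(pairs[0][0], 10)))
            assert got == expected

    def test_invariant_to_input_pose_order(self):
        ens_a, ens_b, _ = gen_pose_ensembles(
            PoseGenSpec(seed=8, n_planted=2, n_decoys_a=6, n_decoys_b=6))
        ref = pc.match_consensus(ens_a, ens_b)
        rng = np.random.default_rng(0)
        shuffled_a = PoseEnsemble(ens_a.peptide_name,
                                  list(rng.permutation(np.array(ens_a.poses, dtype=object))),
                                  ens_a.receptor_id)
        shuffled_b = PoseEnsemble(ens_b.peptide_name,
                                  list(rng.permutation(np.array(ens_b.poses, dtype=object))),
                                  ens_b.receptor_id)
        got = pc.match_consensus(shuffled_a, shuffled_b)
        assert [(m.pose_a, m.pose_b) for m in got] == [(m.pose_a, m.pose_b) for m in ref]


@pytest.fixture(scope="module")
def pocket():
    from rfamap.pocket_analysis import GridSpec, probe_accessible_cavities
    from rfamap.synthetic_data import gen_cavity_structure
    st_, _ = gen_cavity_structure("open_pocket", radius=6.0, mouth_radius=2.5)
    cm = probe_accessible_cavities(st_, GridSpec(spacing=0.5))
    return cm[0]


class TestNtermOrientation:
    def test_nterm_at_mouth_is_ok(self, pocket):
        from conftest import pocket_directed_pose
        pose = pocket_directed_pose(make_peptide_template(("ARG", "PHE")), 1.0, "in")
        assert pc.nterm_orientation_ok(pose, pocket) is True

    def test_reversed_pose_fails(self, pocket):
        tmpl = make_peptide_template(("ARG", "PHE"))
        rot = np.array([[0.0, 0.0, -1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]])
        pose = tmpl.transformed(rot, np.array([0.0, 0.0, 1.0]), pose_id="rev")
        assert pc.nterm_orientation_ok(pose, pocket) is False

    def test_pose_in_bulk_solvent_errors(self, pocket):
        pose = make_peptide_template(("ARG", "PHE")).translated(
            np.array([50.0, 0.0, 0.0]), pose_id="bulk")
        with pytest.raises(ValueError, match="outside cavity|bulk"):
            pc.nterm_orientation_ok(pose, pocket)
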