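import numpy as np
import pytest

from rfamap import pocket_analysis as pa
from rfamap.structure_io import Pose, Structure
from rfamap.synthetic_data import (FRRFA_SEQUENCE, gen_cavity_structure,
                                   make_peptide_template)
from conftest import atom


@pytest.fixture(scope="module")
def sphere_map():
    st, truth = gen_cavity_structure("sealed_sphere", radius=5.0)
    cm = pa.probe_accessible_cavities(st, pa.GridSpec(spacing=0.4))
    return cm, truth


class TestCavityDetection:
    def test_sealed_sphere_volume_within_5pct(self, sphere_map):
        cm, truth = sphere_map
        assert len(cm) == 1
        reg = cm[0]
        assert reg.sealed is True
        assert abs(reg.volume - truth["volume"]) / truth["volume"] < 0.05
        assert reg.volume == pytest.approx(reg.voxel_count * 0.4 ** 3)

    def test_centroid_near_sphere_center(self, sphere_map):
        cm, truth = sphere_map
        assert np.linalg.norm(cm[0].centroid - truth["center"]) < 0.5

    def test_open_pocket_detected_and_unsealed(self):
        st, _ = gen_cavity_structure("open_pocket", radius=5.0, mouth_radius=2.5)
        cm = pa.probe_accessible_cavities(st, pa.GridSpec(spacing=0.5))
        assert len(cm) >= 1
        assert cm[0].sealed is False

    def test_double_void_two_equal_regions(self):
        st, _ = gen_cavity_structure("double_void", radius=4.0)
        cm = pa.probe_accessible_cavities(st, pa.GridSpec(spacing=0.5))
        assert len(cm) == 2
        v1, v2 = cm[0].volume, cm[1].volume
        assert abs(v1 - v2) <= 0.5 ** 3 + 1e-9  # within one voxel

    def test_empty_structure_error(self):
        with pytest.raises((ValueError, TypeError)):
            pa.probe_accessible_cavities(Structure(atoms=[], id="x"),
                                         pa.GridSpec())

    def test_voxel_budget_error_advises_spacing(self):
        st, _ = gen_cavity_structure("sealed_sphere", radius=5.0)
        with pytest.raises(ValueError, match="spacing"):
            pa.probe_accessible_cavities(st, pa.GridSpec(spacing=0.05,
                                                         voxel_budget=10_000))

    def test_flood_fill_conservation(self, sphere_map):
        cm, _ = sphere_map
        total = np.prod(cm.shape)
        occupied = total - cm.free_vdw.sum()
        bulk_free = (cm.free_vdw & cm.bulk_solvent).sum()
        cavity_space = (cm.free_vdw & ~cm.bulk_solvent).sum()
        assert occupied + bulk_free + cavity_space == total
        assert sum(r.voxel_count for r in cm) <= cavity_space

    def test_lining_residues_are_shell_atoms(self, sphere_map):
        cm, _ = sphere_map
        assert cm[0].lining_residues  # shell pseudo-residues line the void
        assert all(rn == "SPH" for _, _, rn in cm[0].lining_residues)


class TestLandmarks:
    def test_landmark_renames_matching_region(self, sphere_map):
        cm, _ = sphere_map
        regions = [pa.PocketRegion(label=r.label, voxel_count=r.voxel_count,
                                   volume=r.volume, centroid=r.centroid,
                                   lining_residues=[("A", 237, "ASP"),
                                                    ("A", 242, "GLU"),
                                                    ("B", 347, "ASP")],
                                   sealed=r.sealed, voxel_indices=r.voxel_indices,
                                   parent_map=r.parent_map) for r in cm]
        pa._apply_landmarks(regions, {"acidic_pocket": ["D237", "E242", "D347"]})
        assert regions[0].label == "acidic_pocket"

    def test_default_landmarks_ship_with_package(self):
        lm = pa.default_landmarks()
        assert "acidic_pocket" in lm and "side_cavity" in lm


class TestAssignPosePocket:
    def test_pose_at_centroid_gets_label(self, sphere_map):
        cm, truth = sphere_map
        tmpl = make_peptide_template(("ARG", "PHE"))
        pose = tmpl.translated(truth["center"] - tmpl.coords.mean(axis=0),
                               pose_id="center")
        assert pa.assign_pose_pocket(pose, cm) == cm[0].label

    def test_far_pose_unassigned(self, sphere_map):
        cm, _ = sphere_map
        pose = make_peptide_template(("ARG", "PHE")).translated(
            np.array([50.0, 0.0, 0.0]))
        assert pa.assign_pose_pocket(pose, cm) is None

    def test_straddling_pose_with_majority_inside_assigned(self, sphere_map):
        cm, truth = sphere_map
        centers = cm.voxel_centers(cm[0].voxel_indices)
        inside = centers[np.argsort(np.linalg.norm(centers - truth["center"],
                                                   axis=1))[:6]]
        coords = list(inside) + [truth["center"] + np.array([40.0, 0, i])
                                 for i in range(4)]
        pose = Pose([atom(i + 1, "CA", "C", "GLY", i + 1, "P", c)
                     for i, c in enumerate(coords)], -5.0, "straddle")
        assert pa.assign_pose_pocket(pose, cm) == cm[0].label

    def test_empty_cavity_list_error(self):
        pose = make_peptide_template(("ARG", "PHE"))
        with pytest.raises(ValueError):
            pa.assign_pose_pocket(pose, [])

    def test_invariant_to_region_order(self):
        st, _ = gen_cavity_structure("double_void", radius=4.0)
        cm = pa.probe_accessible_cavities(st, pa.GridSpec(spacing=0.5))
        tmpl = make_peptide_template(("ARG", "PHE"))
        pose = tmpl.translated(-tmpl.coords.mean(axis=0), pose_id="v1")
        assert pa.assign_pose_pocket(pose, cm) == \
            pa.assign_pose_pocket(pose, list(reversed(cm.regions)))


def _ring(z, res_seq, chain, start, res="PHE"):
    names = ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"]
    return [atom(start + i, n, "C", res, res_seq, chain,
                 (np.cos(a) * 1.4, np.sin(a) * 1.4, z))
            for i, (n, a) in enumerate(zip(names,
                                           np.linspace(0, 2 * np.pi, 6,
                                                       endpoint=False)))]


class TestDetectInteractions:
    def test_backbone_hbond_detected(self):
        pose = Pose([atom(1, "N", "N", "ARG", 1, "P", (0, 0, 0)),
                     atom(2, "H", "H", "ARG", 1, "P", (0, 0.98, 0.1)),
                     atom(3, "CA", "C", "ARG", 1, "P", (1.3, 0.5, 0))], -7, "p")
        rec = Structure([atom(1, "O", "O", "GLY", 10, "A", (0.2, 2.85, 0.25)),
                         atom(2, "C", "C", "GLY", 10, "A", (1.2, 3.5, 0.3))], "r")
        fp = pa.detect_interactions(pose, rec)
        hb = [x for x in fp.interactions if x.kind == "hbond"]
        assert len(hb) == 1
        assert hb[0].distance == pytest.approx(2.87, abs=0.02)
        assert hb[0].angle > 150

    def test_hbond_rejected_on_bad_angle(self):
        # hydrogen pointing away from the acceptor
        pose = Pose([atom(1, "N", "N", "ARG", 1, "P", (0, 0, 0)),
                     atom(2, "H", "H", "ARG", 1, "P", (0, -0.98, 0.0)),
                     atom(3, "CA", "C", "ARG", 1, "P", (1.3, 0.5, 0))], -7, "p")
        rec = Structure([atom(1, "O", "O", "GLY", 10, "A", (0.0, 2.9, 0.0))], "r")
        fp = pa.detect_interactions(pose, rec)
        assert not [x for x in fp.interactions if x.kind == "hbond"]

    def test_parallel_stacking_detected(self):
        pose = Pose(_ring(0.0, 1, "P", 1), -7, "p")
        rec = Structure(_ring(4.0, 20, "A", 10), "r")
        fp = pa.detect_interactions(pose, rec)
        stack = [x for x in fp.interactions if x.kind == "stacking"]
        assert len(stack) == 1
        assert stack[0].distance == pytest.approx(4.0, abs=1e-6)
        assert stack[0].angle == pytest.approx(0.0, abs=5.0)

    def test_salt_bridge_and_cation_pi(self):
        pose = Pose([atom(1, "NZ", "N", "LYS", 1, "P", (0, 0, 0)),
                     atom(2, "CA", "C", "LYS", 1, "P", (1.5, 0, 0))], -7, "p")
        rec = Structure([atom(1, "OE1", "O", "GLU", 5, "A", (0, 3.5, 0)),
                         atom(2, "OE2", "O", "GLU", 5, "A", (1.0, 3.9, 0))]
                        + _ring(-4.5, 8, "A", 10, "TYR"), "r")
        kinds = {x.kind for x in pa.detect_interactions(pose, rec).interactions}
        assert "salt_bridge" in kinds
        assert "cation_pi" in kinds

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(3)
        pose = Pose(_ring(0.0, 1, "P", 1)
                    + [atom(7, "N", "N", "PHE", 1, "P", (2.5, 0, -1))], -7, "p")
        rec = Structure(_ring(3.7, 20, "A", 10)
                        + [atom(16, "O", "O", "GLY", 21, "A", (2.6, 0.4, 1.8))], "r")
        ref = pa.detect_interactions(pose, rec)

        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        rot = np.array([[1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
                        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
                        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)]])
        t = rng.uniform(-30, 30, 3)
        pose2 = pose.transformed(rot, t)
        rec2 = Structure([a.moved(rot @ a.coords + t) for a in rec.atoms], "r2")
        moved = pa.detect_interactions(pose2, rec2)
        assert [(i.kind, i.peptide_atom, i.receptor_residue[1:]) for i in ref.interactions] == \
            [(i.kind, i.peptide_atom, i.receptor_residue[1:]) for i in moved.interactions]
        for a, b in zip(ref.interactions, moved.interactions):
            assert a.distance == pytest.approx(b.distance, abs=1e-3)

    def test_chain_relabel_invariance(self):
        pose = Pose(_ring(0.0, 1, "P", 1), -7, "p")
        rec = Structure(_ring(4.0, 20, "A", 10), "r")
        rec_relab = Structure([atom(a.serial, a.name, a.element, a.res_name,
                                    a.res_seq, "Z", a.coords)
                               for a in rec.atoms], "r2")
        a = pa.detect_interactions(pose, rec).interactions
        b = pa.detect_interactions(pose, rec_relab).interactions
        assert [(i.kind, round(i.distance, 6)) for i in a] == \
            [(i.kind, round(i.distance, 6)) for i in b]

    def test_frrfa_template_against_shell_is_deterministic(self):
        st, truth = gen_cavity_structure("sealed_sphere", radius=8.0,
                                         atom_spacing=1.0)
        tmpl = make_peptide_template(FRRFA_SEQUENCE)
        pose = tmpl.translated(truth["center"] - tmpl.coords.mean(axis=0), "c")
        fp1 = pa.detect_interactions(pose, st)
        fp2 = pa.detect_interactions(pose, st)
        assert [(i.kind, i.peptide_atom, i.distance) for i in fp1.interactions] == \
            [(i.kind, i.peptide_atom, i.distance) for i in fp2.interactions]
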