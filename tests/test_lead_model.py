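import math

import numpy as np
import pytest

from leadtract.lead_model import (
    Contact,
    LeadPose,
    LeadSpec,
    build_contacts,
    contact_subsources,
    read_lead_poses,
)


@pytest.fixture
def upright_pose():
    return LeadPose(tip=(0.0, 0.0, 0.0), direction=(0.0, 0.0, 1.0), rotation=0.0)


class TestSpecAndPose:
    def test_default_spec_is_1331(self):
        spec = LeadSpec()
        assert sum(spec.contacts_per_level) == 8
        assert spec.contacts_per_level == (1, 3, 3, 1)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"contacts_per_level": (1, 3, 3), "n_levels": 3},  # 7 contacts
            {"contact_length": 0.0},
            {"segment_arc": 200.0},
            {"lead_radius": -1.0},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            LeadSpec(**kwargs)

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValueError, match="unit vector"):
            LeadPose(tip=(0, 0, 0), direction=(0, 0, 2.0))

    def test_from_vector_normalizes(self):
        pose = LeadPose.from_vector((0, 0, 0), (0, 0, 5.0), rotation=380.0)
        assert pose.direction == (0.0, 0.0, 1.0)
        assert pose.rotation == pytest.approx(20.0)


class TestBuildContacts:
    def test_level_centers_along_shaft(self, upright_pose):
        contacts = build_contacts(LeadSpec(), upright_pose)
        z = {c.level: c.axis_center[2] for c in contacts}
        assert z == {1: 0.75, 2: 2.75, 3: 4.75, 4: 6.75}

    def test_layout_ring_segment_ring(self, upright_pose):
        contacts = build_contacts(LeadSpec(), upright_pose)
        kinds = [c.kind for c in contacts]
        assert kinds == ["ring"] + ["segment"] * 6 + ["ring"]
        assert [c.id for c in contacts] == list(range(1, 9))
        assert contacts[0].normal is None and contacts[7].normal is None

    def test_rotation_120_is_cyclic_permutation(self, upright_pose):
        spec = LeadSpec()
        base = build_contacts(spec, upright_pose)
        rot = build_contacts(
            spec, LeadPose(tip=(0, 0, 0), direction=(0, 0, 1.0), rotation=120.0)
        )
        # contact 2 rotated by 120 deg coincides with contact 3 at rotation 0
        for src, dst in [(2, 3), (3, 4), (4, 2), (5, 6), (6, 7), (7, 5)]:
            np.testing.assert_allclose(
                rot[src - 1].center, base[dst - 1].center, atol=1e-9
            )

    def test_flipped_direction_mirrors_levels(self):
        spec = LeadSpec()
        up = build_contacts(spec, LeadPose((0, 0, 0), (0, 0, 1.0)))
        down = build_contacts(spec, LeadPose((0, 0, 0), (0, 0, -1.0)))
        for cu, cd in zip(up, down):
            assert cd.axis_center[2] == pytest.approx(-cu.axis_center[2])

    def test_inter_level_spacing(self, upright_pose):
        spec = LeadSpec()
        contacts = build_contacts(spec, upright_pose)
        z = sorted({c.axis_center[2] for c in contacts})
        gaps = np.diff(z)
        np.testing.assert_allclose(gaps, spec.contact_length + spec.inter_level_gap)

    def test_segment_normals_at_120_degrees(self, upright_pose):
        contacts = build_contacts(LeadSpec(), upright_pose)
        for trio in ([1, 2, 3], [4, 5, 6]):  # indices of segments per level
            normals = [np.asarray(contacts[i].normal) for i in trio]
            for a, b in [(0, 1), (1, 2), (2, 0)]:
                assert np.dot(normals[a], normals[b]) == pytest.approx(
                    math.cos(math.radians(120.0)), abs=1e-9
                )

    def test_segment_normals_perpendicular_to_shaft(self, rng):
        d = rng.normal(size=3)
        pose = LeadPose.from_vector(rng.normal(size=3), d, rotation=rng.uniform(0, 360))
        for c in build_contacts(LeadSpec(), pose):
            if c.kind == "segment":
                assert abs(np.dot(c.normal, pose.direction)) < 1e-9
                assert np.linalg.norm(c.normal) == pytest.approx(1.0)

    def test_rigid_transform_equivariance(self, rng):
        """Rotating+translating the pose rigidly moves all contacts."""
        from scipy.spatial.transform import Rotation

        spec = LeadSpec()
        pose = LeadPose((1.0, -2.0, 3.0), (0.0, 0.0, 1.0), rotation=40.0)
        base = build_contacts(spec, pose)
        R = Rotation.from_euler("z", 73.0, degrees=True).as_matrix()
        t = np.array([5.0, -1.0, 2.0])
        # rotation about z preserves the anterior reference construction,
        # so the transformed pose has rotation shifted by the same angle
        moved_pose = LeadPose.from_vector(
            R @ np.asarray(pose.tip) + t, R @ np.asarray(pose.direction),
            rotation=pose.rotation + 73.0,
        )
        moved = build_contacts(spec, moved_pose)
        for c0, c1 in zip(base, moved):
            np.testing.assert_allclose(
                np.asarray(c1.center), R @ np.asarray(c0.center) + t, atol=1e-9
            )


class TestSubsources:
    def test_ring_single_source_on_axis(self, upright_pose):
        spec = LeadSpec()
        ring = build_contacts(spec, upright_pose)[0]
        pts, w = contact_subsources(ring, spec, 1)
        np.testing.assert_allclose(pts[0], ring.axis_center, atol=1e-12)
        assert w.sum() == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [1, 2, 7, 50])
    def test_weights_sum_to_one(self, upright_pose, n):
        spec = LeadSpec()
        for contact in build_contacts(spec, upright_pose):
            _, w = contact_subsources(contact, spec, n)
            assert w.sum() == pytest.approx(1.0)
            assert len(w) == n

    def test_segment_centroid_converges_to_patch_centroid(self, upright_pose):
        spec = LeadSpec()
        seg = build_contacts(spec, upright_pose)[1]
        pts, _ = contact_subsources(seg, spec, 1000)
        mc = pts.mean(axis=0)
        half = math.radians(spec.segment_arc) / 2.0
        analytic = np.asarray(seg.axis_center) + (
            spec.lead_radius * math.sin(half) / half
        ) * np.asarray(seg.normal)
        np.testing.assert_allclose(mc, analytic, atol=1e-2)

    def test_ring_centroid_converges_to_axis(self, upright_pose):
        spec = LeadSpec()
        ring = build_contacts(spec, upright_pose)[0]
        pts, _ = contact_subsources(ring, spec, 2000)
        np.testing.assert_allclose(pts.mean(axis=0), ring.axis_center, atol=1e-2)
        # all points on the cylinder surface
        radial = pts - np.asarray(ring.axis_center)
        radial[:, 2] = 0.0
        np.testing.assert_allclose(np.linalg.norm(radial, axis=1), spec.lead_radius)

    def test_n_below_one_rejected(self, upright_pose):
        spec = LeadSpec()
        ring = build_contacts(spec, upright_pose)[0]
        with pytest.raises(ValueError):
            contact_subsources(ring, spec, 0)


class TestPoseIO:
    def test_read_lead_poses_csv(self, tmp_path):
        csv = tmp_path / "leads.csv"
        csv.write_text(
            "patient_id,hemisphere,tip_x,tip_y,tip_z,dir_x,dir_y,dir_z,rotation_deg\n"
            "P01,L,1.0,2.0,3.0,0.0,0.0,2.0,45.0\n"
        )
        df = read_lead_poses(csv)
        pose = df.pose.iloc[0]
        assert pose.direction == (0.0, 0.0, 1.0)  # normalized
        assert pose.rotation == 45.0

    def test_missing_columns(self, tmp_path):
        csv = tmp_path / "leads.csv"
        csv.write_text("patient_id,tip_x\nP01,0\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_lead_poses(csv)
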