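import math

import numpy as np
import pandas as pd
import pytest

from leadtract.field_vta import FieldModelParams, StimulationSetting, compute_vta
from leadtract.lead_model import LeadPose, LeadSpec, build_contacts
from leadtract.synthetic_data import (
    SyntheticCohortConfig,
    build_cohort_geometry,
    decompose_trs_sum,
    make_lead_poses,
    make_tract_map,
    simulate_improvements,
    write_cohort,
)
from leadtract.tract_overlap import score_overlap


@pytest.fixture(scope="module")
def config():
    return SyntheticCohortConfig(rng_seed=7)


class TestTractMap:
    def test_centerline_voxel_is_one(self, config):
        tmap = make_tract_map(config, "R")
        # the middle control point (14, 0, 0) coincides with a voxel centre
        idx = tmap.grid.world_to_voxel(np.array([14.0, 0.0, 0.0]))
        np.testing.assert_allclose(idx, np.round(idx), atol=1e-9)
        i, j, k = idx.astype(int)
        assert tmap.grid.data[i, j, k] == pytest.approx(1.0)

    def test_gaussian_profile_at_one_radius(self, config):
        tmap = make_tract_map(config, "R")
        grid = tmap.grid
        # one tract-radius perpendicular from the middle control point
        probe = np.array([14.0 + config.tract_radius_mm, 0.0, 0.0])
        d_probe = config.tract_radius_mm
        from leadtract.synthetic_data import _hemi_centerline, _polyline_distance

        d = _polyline_distance(probe[None, :], _hemi_centerline(config, "R"))[0]
        assert d == pytest.approx(d_probe, abs=0.05)
        # interpolate the stored value at the probe by nearest voxel
        idx = np.round(grid.world_to_voxel(probe)).astype(int)
        val = grid.data[tuple(idx)]
        d_vox = _polyline_distance(
            grid.voxel_to_world(idx.astype(float))[None, :],
            _hemi_centerline(config, "R"),
        )[0]
        assert val == pytest.approx(
            math.exp(-(d_vox**2) / (2 * config.tract_radius_mm**2)), rel=1e-9
        )

    def test_left_right_mirror_symmetry(self, config):
        right = make_tract_map(config, "R").grid.data
        left = make_tract_map(config, "L").grid.data
        np.testing.assert_allclose(left, np.flip(right, axis=0), atol=1e-12)

    def test_values_in_unit_interval(self, config):
        vals = make_tract_map(config, "R").grid.data
        assert vals.min() >= 0.0 and vals.max() <= 1.0
        assert (vals > 0).any()

    def test_centerline_outside_grid_rejected(self):
        cfg = SyntheticCohortConfig(
            centerline=((200.0, 0.0, 0.0), (210.0, 0.0, 0.0))
        )
        with pytest.raises(ValueError, match="outside the grid"):
            make_tract_map(cfg, "R")


class TestLeadPoses:
    def test_determinism_under_seed(self, config):
        a = make_lead_poses(config, 0)
        b = make_lead_poses(config, 0)
        assert a == b

    def test_different_patients_differ(self, config):
        assert make_lead_poses(config, 0) != make_lead_poses(config, 1)

    def test_zero_displacement_shaft_through_centerline(self):
        cfg = SyntheticCohortConfig(displacement_range_mm=(0.0, 0.0), rng_seed=3)
        pose = make_lead_poses(cfg, 0)["R"]
        cl = np.asarray(cfg.centerline)
        anchor = 0.5 * (cl[0] + cl[-1])
        # anchor lies on the shaft line
        v = anchor - np.asarray(pose.tip)
        d = np.asarray(pose.direction)
        perp = v - (v @ d) * d
        assert np.linalg.norm(perp) == pytest.approx(0.0, abs=1e-9)

    def test_displacement_decreases_best_overlap(self):
        """Pushing the lead off the tract strictly lowers the best
        per-contact overlap (checked via the full scoring pipeline)."""
        cfg = SyntheticCohortConfig(rng_seed=1)
        tmap = make_tract_map(cfg, "R")
        cl = np.asarray(cfg.centerline)
        direction = (cl[-1] - cl[0]) / np.linalg.norm(cl[-1] - cl[0])
        anchor = 0.5 * (cl[0] + cl[-1])
        u = np.array([1.0, 0.0, 0.0])
        u = u - (u @ direction) * direction
        u /= np.linalg.norm(u)
        spec = LeadSpec()
        params = FieldModelParams(grid_resolution_mm=cfg.voxel_size_mm)
        best = []
        for disp in [0.0, 2.0, 4.0, 6.0, 8.0]:
            tip = anchor - 3.75 * direction + disp * u
            contacts = build_contacts(spec, LeadPose.from_vector(tip, direction))
            scores = [
                score_overlap(
                    compute_vta(contacts, StimulationSetting(cid), params, tmap.grid),
                    tmap,
                ).value
                for cid in range(1, 9)
            ]
            best.append(max(scores))
        assert all(a > b for a, b in zip(best, best[1:]))


class TestDecomposeTrs:
    @pytest.mark.parametrize("total", range(13))
    def test_valid_decomposition(self, total):
        p, i, r = decompose_trs_sum(total)
        assert p + i + r == total
        assert all(0 <= v <= 4 for v in (p, i, r))

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            decompose_trs_sum(13)


class TestSimulateImprovements:
    def _overlaps(self, n_leads=4, rng=None):
        rng = rng or np.random.default_rng(0)
        rows = []
        for lead in range(n_leads):
            for c in range(1, 9):
                rows.append(
                    {
                        "patient_id": f"P{lead // 2}",
                        "hemisphere": "LR"[lead % 2],
                        "contact_id": c,
                        "overlap_mm3": rng.uniform(0, 60),
                    }
                )
        return pd.DataFrame(rows)

    def test_noiseless_proportional_before_rounding(self):
        cfg = SyntheticCohortConfig(beta0=0.0, beta1=0.5, sigma_lead=0.0, sigma_resid=0.0)
        ov = self._overlaps()
        _, _, latent = simulate_improvements(ov, cfg, np.random.default_rng(0))
        np.testing.assert_allclose(
            latent.latent_improvement_pct,
            np.minimum(0.5 * latent.overlap_mm3, 100.0),
            atol=1e-12,
        )

    def test_75_percent_maps_to_on_sum_two(self):
        cfg = SyntheticCohortConfig(beta0=75.0, beta1=0.0, sigma_lead=0.0, sigma_resid=0.0)
        ov = self._overlaps(n_leads=2)
        imp, trs, _ = simulate_improvements(ov, cfg, np.random.default_rng(0))
        on = trs[trs.condition != "OFF"]
        assert ((on.postural + on.intention + on.rest) == 2).all()
        assert (imp.improvement_pct == 75.0).all()

    def test_observed_within_one_baseline_unit_of_latent(self, config):
        ov = self._overlaps(n_leads=6)
        imp, _, latent = simulate_improvements(ov, config, np.random.default_rng(1))
        base_sum = sum(config.baseline_trs)
        granularity = 100.0 / base_sum
        merged = imp.merge(latent, on=["patient_id", "hemisphere", "contact_id"])
        clipped = merged.latent_improvement_pct.clip(
            upper=100.0, lower=-(12 - base_sum) * granularity
        )
        assert (np.abs(merged.improvement_pct - clipped) <= granularity / 2 + 1e-9).all()

    def test_subscores_always_valid(self, config):
        _, trs, _ = simulate_improvements(
            self._overlaps(n_leads=8), config, np.random.default_rng(2)
        )
        for col in ("postural", "intention", "rest"):
            assert trs[col].between(0, 4).all()

    def test_ties_occur_with_integer_scores(self, config):
        imp, _, _ = simulate_improvements(
            self._overlaps(n_leads=10), config, np.random.default_rng(3)
        )
        has_tie = (
            imp.groupby(["patient_id", "hemisphere"]).improvement_pct
            .apply(lambda s: s.max() == s.nlargest(2).min())
        )
        assert has_tie.any()


class TestCohortOutput:
    def test_write_cohort_files(self, tmp_path):
        cfg = SyntheticCohortConfig(n_patients=2, rng_seed=5)
        cohort = build_cohort_geometry(cfg)
        out = write_cohort(cohort, tmp_path / "cohort")
        assert len(list(out.glob("tract_*.nii.gz"))) == 4
        assert (out / "leads.csv").exists()
        assert (out / "truth.json").exists()

    def test_byte_identical_under_seed(self, tmp_path):
        cfg = SyntheticCohortConfig(n_patients=2, rng_seed=5)
        a = write_cohort(build_cohort_geometry(cfg), tmp_path / "a")
        b = write_cohort(build_cohort_geometry(cfg), tmp_path / "b")
        assert (a / "leads.csv").read_bytes() == (b / "leads.csv").read_bytes()
        import gzip

        for fa in sorted(a.glob("tract_*.nii.gz")):
            fb = b / fa.name
            assert gzip.decompress(fa.read_bytes()) == gzip.decompress(fb.read_bytes())
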