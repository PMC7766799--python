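"""Fully synthetic cohort generator for the contact-selection pipeline.

Real inputs — individual tract probability maps, reconstructed lead
poses, per-contact tremor scores — are private clinical data, so this
module fabricates a cohort with the statistical structure the analysis
assumes:

* the tract is a Gaussian tube around a piecewise-linear centerline,
  ``p(voxel) = exp(-d^2 / (2 * radius^2))`` with ``d`` the distance
  from the voxel centre to the centerline, mirrored across the
  midsagittal plane for the opposite hemisphere.  The closed-form
  profile makes voxel values oracle-checkable while preserving the
  spatial falloff the overlap score depends on;
* leads are dropped roughly parallel to the tract with a random
  perpendicular displacement and a random axial rotation, emulating
  the clinical observation that poorly performing leads sit displaced
  from the tract;
* tremor improvement follows the linear mixed model the analysis
  fits: ``beta0 + beta1 * overlap + u_lead + eps`` with Gaussian
  per-lead intercepts and residuals, clipped at 100% (tremor-free),
  then discretized back through integer 0-4 tremor-rating items so
  that the observed improvements carry realistic coarseness and ties.

Everything is deterministic under ``rng_seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .grids_io import TractProbabilityMap, VolumeGrid, write_volume
from .lead_model import LeadPose, LeadSpec

__all__ = [
    "SyntheticCohortConfig",
    "CohortData",
    "make_tract_map",
    "make_lead_poses",
    "simulate_improvements",
    "build_cohort_geometry",
    "write_cohort",
    "decompose_trs_sum",
]


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the clinical setting being emulated: 7 patients
    with bilateral leads (14 hemispheres), a 2.0 mm isotropic grid
    (the usual diffusion-space voxel size), a tract tube of 2.5 mm
    Gaussian radius, and lead tips scattered up to 6 mm off the tract.
    The response model is improvement = beta0 + beta1*overlap + u + e
    in percent, with overlap in mm^3.
    """

    n_patients: int = 7
    grid_shape: tuple[int, int, int] = (41, 41, 41)
    voxel_size_mm: float = 2.0
    # right-hemisphere centerline control points, world mm (x > 0);
    # the left tract is the mirror image across x = 0
    centerline: tuple[tuple[float, float, float], ...] = (
        (12.0, -8.0, -26.0),
        (14.0, 0.0, 0.0),
        (16.0, 10.0, 26.0),
    )
    tract_radius_mm: float = 2.5
    displacement_range_mm: tuple[float, float] = (0.0, 6.0)
    beta0: float = 5.0
    beta1: float = 0.8  # percent per mm^3
    sigma_lead: float = 10.0
    sigma_resid: float = 8.0
    baseline_trs: tuple[int, int, int] = (3, 3, 2)
    n_streamlines: int = 5000
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.voxel_size_mm <= 0 or self.tract_radius_mm <= 0:
            raise ValueError("voxel size and tract radius must be > 0")
        lo, hi = self.displacement_range_mm
        if lo < 0 or hi < lo:
            raise ValueError("displacement range must satisfy 0 <= lo <= hi")
        if min(self.grid_shape) < 2:
            raise ValueError("grid axes must have extent >= 2")

    @property
    def affine(self) -> np.ndarray:
        """2 mm-style isotropic affine with the midsagittal plane at x=0."""
        s = self.voxel_size_mm
        a = np.diag([s, s, s, 1.0])
        a[:3, 3] = [-(n - 1) * s / 2.0 for n in self.grid_shape]
        return a


def _polyline_distance(points: np.ndarray, centerline: np.ndarray) -> np.ndarray:
    """Min distance from each of ``points`` (N,3) to a piecewise-linear
    centerline given by its control points (M,3)."""
    best = np.full(len(points), np.inf)
    for a, b in zip(centerline[:-1], centerline[1:]):
        ab = b - a
        denom = float(ab @ ab)
        t = np.clip((points - a) @ ab / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab[None, :]
        d = np.linalg.norm(points - proj, axis=1)
        np.minimum(best, d, out=best)
    return best


def _hemi_centerline(config: SyntheticCohortConfig, hemisphere: str) -> np.ndarray:
    pts = np.asarray(config.centerline, dtype=float)
    if hemisphere.upper() == "R":
        return pts
    if hemisphere.upper() == "L":
        mirrored = pts.copy()
        mirrored[:, 0] *= -1.0
        return mirrored
    raise ValueError(f"hemisphere must be 'L' or 'R', got {hemisphere!r}")


def make_tract_map(
    config: SyntheticCohortConfig, hemisphere: str
) -> TractProbabilityMap:
    """Gaussian-tube tract probability map for one hemisphere.

    Voxel value = exp(-d^2 / (2 radius^2)) with d the distance from
    the voxel centre to the centerline; exactly 1 on the centerline.
    """
    grid = VolumeGrid(
        data=np.zeros(config.grid_shape, dtype=float), affine=config.affine
    )
    cl = _hemi_centerline(config, hemisphere)
    lo = grid.world_to_voxel(cl.min(axis=0))
    hi = grid.world_to_voxel(cl.max(axis=0))
    shape = np.asarray(config.grid_shape)
    if (lo < -0.5).any() or (hi > shape - 0.5).any():
        raise ValueError("tract centerline extends outside the grid")
    centers = grid.voxel_centers_world().reshape(-1, 3)
    d = _polyline_distance(centers, cl)
    vals = np.exp(-(d**2) / (2.0 * config.tract_radius_mm**2))
    return TractProbabilityMap(
        grid=grid.like(vals.reshape(config.grid_shape)),
        n_streamlines=config.n_streamlines,
    )


def _lead_rng(config: SyntheticCohortConfig, *keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.rng_seed, *keys)))


def make_lead_poses(
    config: SyntheticCohortConfig, patient_index: int
) -> dict[str, LeadPose]:
    """One lead pose per hemisphere for one patient.

    The shaft runs parallel to the tract's overall course; the contact
    array centre starts on the centerline and is pushed perpendicular
    to the shaft by a displacement drawn uniformly from the configured
    range at a uniform random azimuth, with a uniform random axial
    rotation.  Deterministic given the config seed and patient index.
    """
    spec = LeadSpec()
    array_mid = (
        spec.level_center_offset(1) + spec.level_center_offset(spec.n_levels)
    ) / 2.0
    poses: dict[str, LeadPose] = {}
    for h_idx, hemi in enumerate(("L", "R")):
        rng = _lead_rng(config, patient_index, h_idx)
        cl = _hemi_centerline(config, hemi)
        chord = cl[-1] - cl[0]
        direction = chord / np.linalg.norm(chord)
        # anchor mid-course so the contact array straddles the tract
        anchor = 0.5 * (cl[0] + cl[-1])
        lo, hi = config.displacement_range_mm
        magnitude = rng.uniform(lo, hi)
        azimuth = rng.uniform(0.0, 2.0 * np.pi)
        # orthonormal frame perpendicular to the shaft
        ref = np.array([1.0, 0.0, 0.0])
        if abs(direction @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = ref - (ref @ direction) * direction
        u /= np.linalg.norm(u)
        v = np.cross(direction, u)
        offset = magnitude * (np.cos(azimuth) * u + np.sin(azimuth) * v)
        tip = anchor - array_mid * direction + offset
        poses[hemi] = LeadPose.from_vector(
            tip=tip, direction=direction, rotation=rng.uniform(0.0, 360.0)
        )
    return poses


def decompose_trs_sum(total: int) -> tuple[int, int, int]:
    """Split a 0-12 item sum into (postural, intention, rest), each 0-4,
    filling items greedily."""
    if not 0 <= total <= 12:
        raise ValueError("TRS sum must be in 0..12")
    p = min(4, total)
    i = min(4, total - p)
    r = total - p - i
    return p, i, r


def simulate_improvements(
    overlaps: pd.DataFrame,
    config: SyntheticCohortConfig,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate tremor responses for the cohort's overlap table.

    ``overlaps`` needs columns patient_id, hemisphere, contact_id,
    overlap_mm3.  Latent improvement is beta0 + beta1*overlap + u_lead
    + eps, clipped at 100%; the observed improvement is re-derived
    from integer tremor-rating tables (fixed baseline, ON sum =
    round(baseline * (1 - latent/100)) clamped to 0..12), so observed
    values move on the baseline's 100/baseline-percent lattice and
    ties between similar contacts occur naturally.

    Returns (improvements, trs_scores, latent) tables; ``latent``
    records the pre-discretization values and the drawn per-lead
    intercepts for parameter-recovery tests.
    """
    if config.beta1 < 0:
        import warnings

        warnings.warn("beta1 < 0 produces mostly negative improvements", stacklevel=2)
    base_p, base_i, base_r = config.baseline_trs
    base_sum = base_p + base_i + base_r
    if base_sum == 0:
        raise ValueError("baseline TRS sum must be positive")

    imp_rows, trs_rows, latent_rows = [], [], []
    for (pid, hemi), grp in overlaps.groupby(["patient_id", "hemisphere"], sort=True):
        u = rng.normal(0.0, config.sigma_lead)
        trs_rows.append(
            {
                "patient_id": pid,
                "hemisphere": hemi,
                "condition": "OFF",
                "postural": base_p,
                "intention": base_i,
                "rest": base_r,
            }
        )
        for row in grp.sort_values("contact_id").itertuples():
            eps = rng.normal(0.0, config.sigma_resid)
            latent = config.beta0 + config.beta1 * row.overlap_mm3 + u + eps
            latent = min(latent, 100.0)
            on_sum = int(np.clip(np.rint(base_sum * (1.0 - latent / 100.0)), 0, 12))
            p, i, r = decompose_trs_sum(on_sum)
            observed = 100.0 * (base_sum - on_sum) / base_sum
            trs_rows.append(
                {
                    "patient_id": pid,
                    "hemisphere": hemi,
                    "condition": str(int(row.contact_id)),
                    "postural": p,
                    "intention": i,
                    "rest": r,
                }
            )
            imp_rows.append(
                {
                    "patient_id": pid,
                    "hemisphere": hemi,
                    "contact_id": int(row.contact_id),
                    "improvement_pct": observed,
                }
            )
            latent_rows.append(
                {
                    "patient_id": pid,
                    "hemisphere": hemi,
                    "contact_id": int(row.contact_id),
                    "overlap_mm3": float(row.overlap_mm3),
                    "latent_improvement_pct": latent,
                    "u_lead": u,
                }
            )
    return (
        pd.DataFrame(imp_rows),
        pd.DataFrame(trs_rows),
        pd.DataFrame(latent_rows),
    )


@dataclass
class CohortData:
    """In-memory synthetic cohort: maps, poses and pose table."""

    config: SyntheticCohortConfig
    tract_maps: dict[str, TractProbabilityMap]  # keyed "{pid}_{hemi}"
    poses: dict[str, LeadPose]
    leads: pd.DataFrame


def build_cohort_geometry(config: SyntheticCohortConfig) -> CohortData:
    """Tract maps and lead poses for every patient and hemisphere."""
    maps = {h: make_tract_map(config, h) for h in ("L", "R")}
    tract_maps: dict[str, TractProbabilityMap] = {}
    poses: dict[str, LeadPose] = {}
    rows = []
    for p_idx in range(config.n_patients):
        pid = f"P{p_idx + 1:02d}"
        pose_pair = make_lead_poses(config, p_idx)
        for hemi in ("L", "R"):
            key = f"{pid}_{hemi}"
            tract_maps[key] = maps[hemi]  # same anatomy per hemisphere
            poses[key] = pose_pair[hemi]
            pose = pose_pair[hemi]
            rows.append(
                {
                    "patient_id": pid,
                    "hemisphere": hemi,
                    "tip_x": pose.tip[0],
                    "tip_y": pose.tip[1],
                    "tip_z": pose.tip[2],
                    "dir_x": pose.direction[0],
                    "dir_y": pose.direction[1],
                    "dir_z": pose.direction[2],
                    "rotation_deg": pose.rotation,
                }
            )
    return CohortData(
        config=config, tract_maps=tract_maps, poses=poses, leads=pd.DataFrame(rows)
    )


def write_cohort(
    cohort: CohortData,
    out_dir: str | Path,
    trs_scores: pd.DataFrame | None = None,
    latent: pd.DataFrame | None = None,
) -> Path:
    """Write a cohort directory: tract_{pid}_{hemi}.nii.gz, leads.csv,
    and, when provided, trs_scores.csv and truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for key, tmap in cohort.tract_maps.items():
        write_volume(tmap.grid, out / f"tract_{key}.nii.gz")
    cohort.leads.to_csv(out / "leads.csv", index=False)
    if trs_scores is not None:
        trs_scores.to_csv(out / "trs_scores.csv", index=False)
    truth = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(cohort.config).items()
        }
    }
    if latent is not None:
        truth["latent"] = latent.to_dict(orient="records")
    (out / "truth.json").write_text(json.dumps(truth, indent=2, default=_jsonify))
    return out


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
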