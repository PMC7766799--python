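"""End-to-end orchestration: simulate -> score -> evaluate.

Each stage reads and writes plain CSV/JSON (plus NIfTI for volumes) so
intermediate results are independently inspectable:

* ``run_simulate`` writes a synthetic cohort directory,
* ``run_score`` builds every contact's VTA at the test amplitude and
  scores its tract overlap (one row per lead x contact),
* ``run_evaluate`` assembles per-hemisphere rankings, cohort
  concordance rates, and the mixed-model variance decomposition into
  a JSON report with optional figures.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clinical_scoring import improvements_from_table, read_trs_scores
from .field_vta import FieldModelParams, StimulationSetting, compute_vta, vta_volume
from .grids_io import read_volume, TractProbabilityMap
from .lead_model import LeadSpec, build_contacts, read_lead_poses
from .mixed_model import fit_lmm, slope_positivity_by_lead
from .selection_eval import (
    chance_baseline,
    rankings_from_tables,
    summarize_concordance,
)
from .synthetic_data import (
    SyntheticCohortConfig,
    build_cohort_geometry,
    simulate_improvements,
    write_cohort,
)
from .tract_overlap import score_overlap

log = logging.getLogger(__name__)

__all__ = [
    "run_simulate",
    "score_cohort",
    "run_score",
    "run_evaluate",
]


def run_simulate(config: SyntheticCohortConfig, out_dir: str | Path) -> Path:
    """Generate and write a complete synthetic cohort directory.

    Overlaps are computed once with the default field model so the
    simulated tremor responses are consistent with the geometry.
    """
    cohort = build_cohort_geometry(config)
    overlaps = score_cohort(
        tract_maps=cohort.tract_maps,
        poses=cohort.poses,
        params=FieldModelParams(grid_resolution_mm=config.voxel_size_mm),
    )
    rng = np.random.default_rng(np.random.SeedSequence((config.rng_seed, 9999)))
    improvements, trs, latent = simulate_improvements(overlaps, config, rng)
    out = write_cohort(cohort, out_dir, trs_scores=trs, latent=latent)
    log.info(
        "simulated cohort: %d patients, %d leads -> %s",
        config.n_patients,
        2 * config.n_patients,
        out,
    )
    return out


def score_cohort(
    tract_maps: dict[str, TractProbabilityMap],
    poses,
    params: FieldModelParams | None = None,
    setting_template: StimulationSetting | None = None,
    spec: LeadSpec | None = None,
) -> pd.DataFrame:
    """Score every contact of every lead against its hemisphere's tract.

    ``tract_maps`` and ``poses`` are keyed ``"{patient_id}_{hemisphere}"``.
    Returns one row per (lead, contact): patient_id, hemisphere,
    contact_id, overlap_mm3, vta_mm3.
    """
    params = params or FieldModelParams()
    spec = spec or LeadSpec()
    template = setting_template or StimulationSetting(contact_id=1)
    rows = []
    for key, pose in poses.items():
        pid, hemi = key.rsplit("_", 1)
        tract = tract_maps[key]
        contacts = build_contacts(spec, pose)
        vols, ovs = [], []
        for contact in contacts:
            setting = StimulationSetting(
                contact_id=contact.id,
                amplitude_ma=template.amplitude_ma,
                frequency_hz=template.frequency_hz,
                pulse_width_us=template.pulse_width_us,
            )
            vta = compute_vta(contacts, setting, params, tract.grid, spec)
            score = score_overlap(
                vta, tract, contact_id=contact.id, hemisphere=hemi, patient_id=pid
            )
            vols.append(vta_volume(vta))
            ovs.append(score.value)
            rows.append(
                {
                    "patient_id": pid,
                    "hemisphere": hemi,
                    "contact_id": contact.id,
                    "overlap_mm3": score.value,
                    "vta_mm3": vols[-1],
                }
            )
        log.info(
            "scored %s: 8 contacts, VTA %.1f-%.1f mm^3, overlap %.2f-%.2f mm^3",
            key,
            min(vols),
            max(vols),
            min(ovs),
            max(ovs),
        )
    return pd.DataFrame(rows)


def run_score(
    cohort_dir: str | Path,
    out_csv: str | Path | None = None,
    amplitude_ma: float = 2.0,
    conductivity_s_per_m: float = 0.1,
    e_threshold_v_per_mm: float = 0.2,
    n_subsources: int = 1,
) -> pd.DataFrame:
    """Score a cohort directory (tract_*.nii.gz + leads.csv) to a CSV."""
    cohort_dir = Path(cohort_dir)
    leads = read_lead_poses(cohort_dir / "leads.csv")
    tract_maps, poses = {}, {}
    for row in leads.itertuples():
        key = f"{row.patient_id}_{row.hemisphere}"
        path = cohort_dir / f"tract_{key}.nii.gz"
        if not path.exists():
            path = cohort_dir / f"tract_{key}.nii"
        if not path.exists():
            raise FileNotFoundError(f"missing tract map for {key}: {path}")
        grid = read_volume(path)
        tract_maps[key] = TractProbabilityMap(grid=grid, n_streamlines=1)
        poses[key] = row.pose
    params = FieldModelParams(
        conductivity_s_per_m=conductivity_s_per_m,
        e_threshold_v_per_mm=e_threshold_v_per_mm,
        n_subsources=n_subsources,
        grid_resolution_mm=float(
            np.cbrt(next(iter(tract_maps.values())).grid.voxel_volume)
        ),
    )
    template = StimulationSetting(contact_id=1, amplitude_ma=amplitude_ma)
    overlaps = score_cohort(tract_maps, poses, params, template)
    if out_csv is not None:
        overlaps.to_csv(out_csv, index=False)
    return overlaps


def run_evaluate(
    overlaps: pd.DataFrame,
    trs_scores: pd.DataFrame,
    out_dir: str | Path | None = None,
    directional_only: bool = False,
    make_figures: bool = False,
) -> dict:
    """Concordance + mixed-model report from the two long tables.

    Returns (and optionally writes) a JSON-serializable report with
    per-hemisphere rankings, top-1/top-2 and directional rates, the
    chance baseline, and the mixed model with marginal/conditional R^2.
    """
    improvements = improvements_from_table(trs_scores)
    rankings = rankings_from_tables(overlaps, improvements)
    summary = summarize_concordance(rankings, directional_only=directional_only)

    lmm_data = overlaps.merge(
        improvements, on=["patient_id", "hemisphere", "contact_id"], how="inner"
    )
    lmm_data["lead_id"] = lmm_data.patient_id.astype(str) + "_" + lmm_data.hemisphere
    result = fit_lmm(lmm_data)
    per_lead = slope_positivity_by_lead(result, lmm_data)

    report = {
        "version": __version__,
        "n_hemispheres": summary.n_hemispheres,
        "concordance": asdict(summary),
        "chance_baseline_directional_pct": chance_baseline(6),
        "mixed_model": {
            "beta0": result.beta0,
            "beta1": result.beta1,
            "se_beta1": result.se_beta1,
            "p_fixed": result.p_fixed,
            "sigma2_fixed": result.sigma2_fixed,
            "sigma2_random": result.sigma2_random,
            "sigma2_resid": result.sigma2_resid,
            "r2_marginal": result.r2_marginal,
            "r2_conditional": result.r2_conditional,
            "n_obs": result.n_obs,
            "n_leads": result.n_leads,
        },
        "all_leads_positive_slope": bool((per_lead["sign"] > 0).all()),
        "rankings": [
            {
                "patient_id": r.patient_id,
                "hemisphere": r.hemisphere,
                "entries": [asdict(e) for e in r.entries],
            }
            for r in rankings
        ],
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        if make_figures:
            from .plotting import plot_contact_ranking, plot_mixed_model_fit

            plot_contact_ranking(rankings, out / "contact_ranking.png")
            plot_mixed_model_fit(result, lmm_data, out / "mixed_model_fit.png")
    return report
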