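"""Per-contact tremor assessments and percent improvement vs baseline.

Each test condition (stimulation OFF, or one contact active at the
test amplitude) is scored on three tremor-rating-scale items of the
contralateral upper limb — postural, intention and rest tremor — each
an integer from 0 (no tremor) to 4 (most severe).  Contact effect is
the percentage change of the item sum relative to the OFF baseline;
positive values mean tremor reduction, negative mean worsening.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "TremorAssessment",
    "ImprovementRecord",
    "score_sum",
    "improvement_percent",
    "read_trs_scores",
    "improvements_from_table",
]

log = logging.getLogger(__name__)

OFF_CONDITION = "OFF"


@dataclass(frozen=True)
class TremorAssessment:
    """One tremor-rating-scale assessment (integer items 0-4 each)."""

    postural: int
    intention: int
    rest: int
    condition: str = OFF_CONDITION  # "OFF" or the active contact id as text

    def __post_init__(self) -> None:
        for name in ("postural", "intention", "rest"):
            v = getattr(self, name)
            if not isinstance(v, int) or not 0 <= v <= 4:
                raise ValueError(
                    f"{name} score must be an integer in 0..4, got {v!r}"
                )


@dataclass(frozen=True)
class ImprovementRecord:
    """Percent tremor improvement of one contact vs the OFF baseline."""

    patient_id: str
    hemisphere: str
    contact_id: int
    improvement: float  # percent; <= 100, may be negative

    def __post_init__(self) -> None:
        if self.improvement > 100.0 + 1e-9:
            raise ValueError("improvement cannot exceed 100%")


def score_sum(a: TremorAssessment) -> int:
    """Sum of the three tremor items (0..12)."""
    return a.postural + a.intention + a.rest


def improvement_percent(baseline: TremorAssessment, on: TremorAssessment) -> float:
    """Percent change of the score sum vs the OFF baseline.

    100 * (sum(baseline) - sum(on)) / sum(baseline); positive =
    improvement.  Undefined (error) for a zero baseline: there is no
    tremor to suppress.
    """
    base = score_sum(baseline)
    if base == 0:
        raise ValueError("undefined improvement: OFF baseline sum is zero")
    return 100.0 * (base - score_sum(on)) / base


def read_trs_scores(path) -> pd.DataFrame:
    """Read a tremor-score table from CSV.

    Expected columns: patient_id, hemisphere, condition (``OFF`` or a
    contact id 1-8), postural, intention, rest.
    """
    df = pd.read_csv(path, dtype={"condition": str})
    required = {"patient_id", "hemisphere", "condition", "postural", "intention", "rest"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"tremor score table missing columns: {sorted(missing)}")
    return df


def improvements_from_table(scores: pd.DataFrame) -> pd.DataFrame:
    """Per-contact percent improvements from a long score table.

    Hemispheres whose OFF baseline sum is zero are excluded with a
    warning.  Returns columns patient_id, hemisphere, contact_id,
    improvement_pct.
    """
    rows = []
    for (pid, hemi), grp in scores.groupby(["patient_id", "hemisphere"], sort=True):
        off = grp[grp["condition"].astype(str).str.upper() == OFF_CONDITION]
        if len(off) != 1:
            raise ValueError(
                f"{pid}/{hemi}: expected exactly one OFF baseline row, got {len(off)}"
            )
        baseline = TremorAssessment(
            int(off.iloc[0].postural), int(off.iloc[0].intention), int(off.iloc[0].rest)
        )
        if score_sum(baseline) == 0:
            log.warning(
                "%s/%s: zero OFF baseline, hemisphere excluded from analysis", pid, hemi
            )
            continue
        on_rows = grp[grp["condition"].astype(str).str.upper() != OFF_CONDITION]
        for r in on_rows.itertuples():
            on = TremorAssessment(
                int(r.postural), int(r.intention), int(r.rest), condition=str(r.condition)
            )
            rows.append(
                {
                    "patient_id": pid,
                    "hemisphere": hemi,
                    "contact_id": int(r.condition),
                    "improvement_pct": improvement_percent(baseline, on),
                }
            )
    return pd.DataFrame(rows, columns=["patient_id", "hemisphere", "contact_id", "improvement_pct"])
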