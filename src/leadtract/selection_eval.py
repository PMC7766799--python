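"""Hemisphere-wise contact ranking and concordance with clinical outcome.

Contacts are ranked within each hemisphere by their tract-overlap
score (competition ranking: ties share the better rank, the next rank
is skipped).  A hemisphere counts as a top-k hit when any contact with
overlap rank <= k belongs to the best-clinical set — all contacts
attaining the maximum tremor improvement, ties included.  The
directional-only analysis restricts both the ranking and the
best-clinical set to the six segmented contacts (2-7) before
evaluating, for which uniform chance of picking the best contact is
100/6 ~ 16.7%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RankedContact",
    "HemisphereRanking",
    "ConcordanceSummary",
    "rank_by_overlap",
    "top_k_hit",
    "summarize_concordance",
    "chance_baseline",
    "rankings_from_tables",
    "DIRECTIONAL_CONTACTS",
]

DIRECTIONAL_CONTACTS = (2, 3, 4, 5, 6, 7)


@dataclass(frozen=True)
class RankedContact:
    contact_id: int
    overlap_mm3: float
    overlap_rank: int
    improvement_pct: float
    is_best_clinical: bool


@dataclass(frozen=True)
class HemisphereRanking:
    """Per-hemisphere contact ranking by overlap, with clinical flags."""

    patient_id: str
    hemisphere: str
    entries: tuple[RankedContact, ...]

    def restricted(self, contact_ids) -> "HemisphereRanking":
        """Re-rank using only ``contact_ids`` (re-evaluates the
        best-clinical set within the restricted candidates)."""
        keep = [e for e in self.entries if e.contact_id in set(contact_ids)]
        if not keep:
            raise ValueError("restriction removed every contact")
        return rank_by_overlap(
            {e.contact_id: e.overlap_mm3 for e in keep},
            {e.contact_id: e.improvement_pct for e in keep},
            patient_id=self.patient_id,
            hemisphere=self.hemisphere,
        )


@dataclass(frozen=True)
class ConcordanceSummary:
    """Cohort-level hit rates of overlap-based contact selection."""

    n_hemispheres: int
    top1_hits: int
    top2_hits: int
    top1_rate: float  # percent, 1 decimal
    top2_rate: float
    directional_top1_hits: int
    directional_top1_rate: float


def _competition_ranks(values: np.ndarray) -> np.ndarray:
    """Descending competition ranks: ties share the better rank."""
    order = np.argsort(-values, kind="stable")
    ranks = np.empty(len(values), dtype=int)
    sorted_vals = values[order]
    for pos, idx in enumerate(order):
        if pos > 0 and sorted_vals[pos] == sorted_vals[pos - 1]:
            ranks[idx] = ranks[order[pos - 1]]
        else:
            ranks[idx] = pos + 1
    return ranks


def rank_by_overlap(
    overlaps: dict[int, float],
    improvements: dict[int, float],
    patient_id: str = "",
    hemisphere: str = "",
) -> HemisphereRanking:
    """Rank one hemisphere's contacts by overlap (descending).

    ``overlaps`` and ``improvements`` map contact id -> value and must
    cover the same contacts.  Entries are ordered by rank, exact
    overlap ties broken by lower contact id for display only.
    """
    if len(overlaps) < 2:
        raise ValueError("need at least 2 contacts to rank")
    ids = sorted(overlaps)
    if len(set(ids)) != len(list(overlaps)):
        raise ValueError("duplicate contact ids")  # pragma: no cover
    if set(improvements) != set(ids):
        raise ValueError("improvements must cover exactly the ranked contacts")
    vals = np.asarray([float(overlaps[i]) for i in ids])
    ranks = _competition_ranks(vals)
    best = max(improvements.values())
    entries = [
        RankedContact(
            contact_id=i,
            overlap_mm3=float(overlaps[i]),
            overlap_rank=int(r),
            improvement_pct=float(improvements[i]),
            is_best_clinical=bool(improvements[i] == best),
        )
        for i, r in zip(ids, ranks)
    ]
    entries.sort(key=lambda e: (e.overlap_rank, e.contact_id))
    return HemisphereRanking(
        patient_id=patient_id, hemisphere=hemisphere, entries=tuple(entries)
    )


def top_k_hit(ranking: HemisphereRanking, k: int) -> bool:
    """True iff a contact with overlap rank <= k attains the best
    clinical improvement (clinical ties all count as best)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return any(e.is_best_clinical for e in ranking.entries if e.overlap_rank <= k)


def summarize_concordance(
    rankings: list[HemisphereRanking], directional_only: bool = False
) -> ConcordanceSummary:
    """Cohort top-1/top-2 hit rates, plus the directional-only top-1 rate.

    With ``directional_only=True`` the top-1/top-2 rates themselves are
    computed on the six segmented contacts; otherwise on all eight.
    The directional top-1 rate is always reported.
    """
    if not rankings:
        raise ValueError("no hemispheres to summarize")
    base = (
        [r.restricted(DIRECTIONAL_CONTACTS) for r in rankings]
        if directional_only
        else list(rankings)
    )
    n = len(base)
    top1 = sum(top_k_hit(r, 1) for r in base)
    top2 = sum(top_k_hit(r, 2) for r in base)
    dir1 = sum(top_k_hit(r.restricted(DIRECTIONAL_CONTACTS), 1) for r in rankings)
    return ConcordanceSummary(
        n_hemispheres=n,
        top1_hits=top1,
        top2_hits=top2,
        top1_rate=round(100.0 * top1 / n, 1),
        top2_rate=round(100.0 * top2 / n, 1),
        directional_top1_hits=dir1,
        directional_top1_rate=round(100.0 * dir1 / len(rankings), 1),
    )


def chance_baseline(n_candidates: int) -> float:
    """Hit rate (percent, 1 decimal) of uniformly guessing one contact."""
    if n_candidates < 1:
        raise ValueError("need at least one candidate contact")
    return round(100.0 / n_candidates, 1)


def rankings_from_tables(
    overlaps: pd.DataFrame, improvements: pd.DataFrame
) -> list[HemisphereRanking]:
    """Build per-hemisphere rankings from the pipeline's long tables.

    ``overlaps`` has columns patient_id, hemisphere, contact_id,
    overlap_mm3; ``improvements`` has patient_id, hemisphere,
    contact_id, improvement_pct.  Hemispheres present in only one table
    (e.g. excluded for a zero baseline) are dropped.
    """
    merged = overlaps.merge(
        improvements, on=["patient_id", "hemisphere", "contact_id"], how="inner"
    )
    out = []
    for (pid, hemi), grp in merged.groupby(["patient_id", "hemisphere"], sort=True):
        out.append(
            rank_by_overlap(
                dict(zip(grp.contact_id.astype(int), grp.overlap_mm3)),
                dict(zip(grp.contact_id.astype(int), grp.improvement_pct)),
                patient_id=str(pid),
                hemisphere=str(hemi),
            )
        )
    return out
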