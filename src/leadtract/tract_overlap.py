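"""Tract probability normalization and the weighted VTA-tract overlap score.

The overlap between a stimulation volume and a tract is the sum of the
track-probability values over all voxels covered by the VTA, multiplied
by the voxel volume in mm^3 — a probability-weighted overlap volume.
Scoring requires both images on the same grid; a geometry mismatch is
an error (overlap values depend on voxel size) and the caller must
resample explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids_io import TractProbabilityMap, VolumeGrid, VTAMask, grids_aligned

__all__ = [
    "OverlapScore",
    "normalize_frequency_map",
    "score_overlap",
    "threshold_map_for_display",
]


@dataclass(frozen=True)
class OverlapScore:
    """Probability-weighted overlap (mm^3) of one contact's VTA with a tract."""

    value: float
    contact_id: int
    hemisphere: str = ""
    patient_id: str = ""

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("overlap score cannot be negative")


def normalize_frequency_map(
    freq: VolumeGrid, n_streamlines: int
) -> TractProbabilityMap:
    """Turn a streamline visitation-count map into a probability map.

    Each voxel count is divided by the total number of streamline
    samples retained by the tracking run (the "waytotal" convention),
    yielding values in [0, 1].
    """
    counts = np.asarray(freq.data, dtype=float)
    if (counts < 0).any():
        raise ValueError("streamline counts must be non-negative")
    if not (counts > 0).any():
        raise ValueError("empty tract map: all streamline counts are zero")
    if n_streamlines < counts.max():
        raise ValueError(
            "inconsistent normalizer: n_streamlines is smaller than the "
            "largest voxel count"
        )
    return TractProbabilityMap(
        grid=freq.like(counts / float(n_streamlines)), n_streamlines=int(n_streamlines)
    )


def score_overlap(
    vta: VTAMask,
    tract: TractProbabilityMap,
    contact_id: int = 0,
    hemisphere: str = "",
    patient_id: str = "",
) -> OverlapScore:
    """Probability-weighted overlap of a VTA with a tract map.

    value = (sum of tract probabilities over voxels where the mask is 1)
            * voxel volume in mm^3.
    """
    if not grids_aligned(vta.grid, tract.grid):
        raise ValueError(
            "VTA and tract map are on different grids; resample one onto the "
            "other explicitly (grids_io.resample_to) before scoring"
        )
    inside = vta.grid.data.astype(bool)
    value = float(tract.grid.data[inside].sum() * tract.grid.voxel_volume)
    return OverlapScore(
        value=value,
        contact_id=contact_id,
        hemisphere=hemisphere,
        patient_id=patient_id,
    )


def threshold_map_for_display(
    tract: TractProbabilityMap, top_fraction: float
) -> VolumeGrid:
    """Keep only the top fraction of positive probabilities (visualization).

    Voxels below the (1 - top_fraction) quantile of the *positive*
    values are zeroed.  Scoring always uses the full map; this mirrors
    the common display convention of showing only the highest-
    probability core of a tract.
    """
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must be in (0, 1]")
    vals = np.asarray(tract.grid.data, dtype=float)
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ValueError("no positive voxels to threshold")
    if top_fraction == 1.0:
        return tract.grid.like(vals.copy())
    cut = float(np.quantile(pos, 1.0 - top_fraction))
    out = np.where(vals > cut, vals, 0.0)
    return tract.grid.like(out)
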