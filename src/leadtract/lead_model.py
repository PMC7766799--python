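"""Geometry of an 8-contact directional DBS lead (1-3-3-1 layout).

The modelled hardware has four contact levels along the shaft: a
ventral ring (contact 1), two directional levels of three 120-degree
segments each (contacts 2-4 "Dir 1" ventral, 5-7 "Dir 2" dorsal), and
a dorsal ring (contact 8).  Given a pose (tip position, shaft
direction, axial rotation) the module produces world-space contact
centres, outward segment normals, and weighted sub-source points used
to discretize each contact for the field model.

Default dimensions follow the manufacturer's directional-lead layout
(1.5 mm contacts, 0.5 mm gaps, 0.65 mm radius, ~90 degree segment
arc); all of them are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "LeadSpec",
    "LeadPose",
    "Contact",
    "build_contacts",
    "contact_subsources",
    "read_lead_poses",
]

_GOLDEN = (math.sqrt(5.0) - 1.0) / 2.0


@dataclass(frozen=True)
class LeadSpec:
    """Dimensions of the directional lead.

    ``contacts_per_level`` must describe the 1-3-3-1 layout (8 contacts
    total); lengths in mm, ``segment_arc`` in degrees.
    """

    n_levels: int = 4
    contacts_per_level: tuple[int, ...] = (1, 3, 3, 1)
    contact_length: float = 1.5
    inter_level_gap: float = 0.5
    lead_radius: float = 0.65
    segment_arc: float = 90.0
    tip_to_first_contact: float = 0.0

    def __post_init__(self) -> None:
        if self.n_levels != len(self.contacts_per_level):
            raise ValueError("n_levels must match contacts_per_level")
        if sum(self.contacts_per_level) != 8:
            raise ValueError("total contact count must be 8")
        for name in ("contact_length", "inter_level_gap", "lead_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not (0.0 < self.segment_arc <= 120.0):
            raise ValueError("segment_arc must be in (0, 120] degrees")
        if self.tip_to_first_contact < 0:
            raise ValueError("tip_to_first_contact must be >= 0")

    def level_center_offset(self, level: int) -> float:
        """Axial distance from the tip to the centre of ``level`` (1-based)."""
        return (
            self.tip_to_first_contact
            + self.contact_length / 2.0
            + (level - 1) * (self.contact_length + self.inter_level_gap)
        )


@dataclass(frozen=True)
class LeadPose:
    """Placement of a lead in world space.

    ``direction`` points ventral -> dorsal along the shaft and must be a
    unit vector; ``rotation`` (degrees, normalized to [0, 360)) turns
    the segment array about the shaft axis, with 0 meaning the
    reference segment faces anterior (+y in RAS world space).
    """

    tip: tuple[float, float, float]
    direction: tuple[float, float, float]
    rotation: float = 0.0

    def __post_init__(self) -> None:
        d = np.asarray(self.direction, dtype=float)
        if abs(np.linalg.norm(d) - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector (use LeadPose.from_vector)")
        object.__setattr__(self, "rotation", float(self.rotation) % 360.0)

    @classmethod
    def from_vector(
        cls, tip, direction, rotation: float = 0.0
    ) -> "LeadPose":
        """Build a pose, normalizing ``direction`` to unit length."""
        d = np.asarray(direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0:
            raise ValueError("direction must be nonzero")
        d = d / n
        return cls(tip=tuple(np.asarray(tip, float)), direction=tuple(d), rotation=rotation)

    @property
    def tip_arr(self) -> np.ndarray:
        return np.asarray(self.tip, dtype=float)

    @property
    def dir_arr(self) -> np.ndarray:
        return np.asarray(self.direction, dtype=float)


@dataclass(frozen=True)
class Contact:
    """One physical contact in world space.

    Rings have ``normal=None``; segment normals are outward radial unit
    vectors perpendicular to the shaft.  ``center`` for a segment lies
    on the cylinder surface at mid-arc, mid-height.
    """

    id: int
    level: int
    kind: str  # "ring" | "segment"
    center: tuple[float, float, float]
    normal: tuple[float, float, float] | None
    label: str
    shaft_dir: tuple[float, float, float]
    axis_center: tuple[float, float, float]

    @property
    def center_arr(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)

    @property
    def normal_arr(self) -> np.ndarray | None:
        return None if self.normal is None else np.asarray(self.normal, dtype=float)


def _rodrigues(v: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotate ``v`` about unit ``axis`` by ``angle_rad`` (right-handed)."""
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    return v * c + np.cross(axis, v) * s + axis * np.dot(axis, v) * (1.0 - c)


def _anterior_reference(direction: np.ndarray) -> np.ndarray:
    """Unit vector perpendicular to the shaft, as close to +y (anterior)
    as possible; falls back to +x for shafts along the y axis."""
    for cand in (np.array([0.0, 1.0, 0.0]), np.array([1.0, 0.0, 0.0])):
        perp = cand - np.dot(cand, direction) * direction
        n = np.linalg.norm(perp)
        if n > 1e-8:
            return perp / n
    raise ValueError("degenerate shaft direction")  # pragma: no cover


_LEVEL_LABELS = {1: "ventral ring", 2: "Dir 1", 3: "Dir 2", 4: "dorsal ring"}


def build_contacts(spec: LeadSpec, pose: LeadPose) -> list[Contact]:
    """World-space contacts 1 (ventral) .. 8 (dorsal) for a posed lead.

    Segments within a level sit at 120-degree spacing starting from the
    pose's rotation angle measured from the anterior reference.
    """
    d = pose.dir_arr
    tip = pose.tip_arr
    ref = _anterior_reference(d)
    rot0 = math.radians(pose.rotation)

    contacts: list[Contact] = []
    cid = 1
    for level, n_at_level in enumerate(spec.contacts_per_level, start=1):
        axis_center = tip + d * spec.level_center_offset(level)
        label = _LEVEL_LABELS.get(level, f"level {level}")
        if n_at_level == 1:
            contacts.append(
                Contact(
                    id=cid,
                    level=level,
                    kind="ring",
                    center=tuple(axis_center),
                    normal=None,
                    label=label,
                    shaft_dir=tuple(d),
                    axis_center=tuple(axis_center),
                )
            )
            cid += 1
        else:
            step = 2.0 * math.pi / n_at_level
            for k in range(n_at_level):
                normal = _rodrigues(ref, d, rot0 + k * step)
                center = axis_center + spec.lead_radius * normal
                contacts.append(
                    Contact(
                        id=cid,
                        level=level,
                        kind="segment",
                        center=tuple(center),
                        normal=tuple(normal),
                        label=f"{label} seg {k + 1}",
                        shaft_dir=tuple(d),
                        axis_center=tuple(axis_center),
                    )
                )
                cid += 1
    return contacts


def contact_subsources(
    contact: Contact, spec: LeadSpec, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """Discretize a contact into ``n`` point current sources.

    Returns ``(points, weights)`` with points of shape (n, 3) and
    weights summing to 1.  With ``n=1`` the analytic centroid is used:
    the on-axis centre for a ring, the cylindrical-patch centroid for a
    segment (radial distance ``r * sin(a/2) / (a/2)`` for arc ``a``).
    With ``n>1`` points cover the contact surface quasi-uniformly
    (stratified angles, golden-ratio heights).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    d = np.asarray(contact.shaft_dir, float)
    axis_c = np.asarray(contact.axis_center, float)
    r = spec.lead_radius
    L = spec.contact_length
    weights = np.full(n, 1.0 / n)

    if contact.kind == "ring":
        if n == 1:
            return axis_c[None, :], weights
        ref = _anterior_reference(d)
        i = np.arange(n)
        theta = 2.0 * math.pi * ((i + 0.5) / n)
        z = L * (np.modf(i * _GOLDEN)[0] - 0.5)
        pts = np.array(
            [axis_c + r * _rodrigues(ref, d, t) + zz * d for t, zz in zip(theta, z)]
        )
        return pts, weights

    normal = np.asarray(contact.normal, float)
    half_arc = math.radians(spec.segment_arc) / 2.0
    if n == 1:
        radial = r * math.sin(half_arc) / half_arc
        return (axis_c + radial * normal)[None, :], weights
    i = np.arange(n)
    theta = 2.0 * half_arc * ((i + 0.5) / n) - half_arc
    z = L * (np.modf(i * _GOLDEN)[0] - 0.5)
    pts = np.array(
        [axis_c + r * _rodrigues(normal, d, t) + zz * d for t, zz in zip(theta, z)]
    )
    return pts, weights


def read_lead_poses(path) -> "pd.DataFrame":
    """Read lead poses from CSV.

    Expected columns: patient_id, hemisphere (L/R), tip_x/y/z (mm),
    dir_x/y/z, rotation_deg.  Returns the table with an added ``pose``
    column of :class:`LeadPose` objects (directions normalized).
    """
    import pandas as pd

    df = pd.read_csv(path)
    required = {
        "patient_id", "hemisphere",
        "tip_x", "tip_y", "tip_z",
        "dir_x", "dir_y", "dir_z",
        "rotation_deg",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"lead pose table missing columns: {sorted(missing)}")
    df = df.copy()
    df["pose"] = [
        LeadPose.from_vector(
            (row.tip_x, row.tip_y, row.tip_z),
            (row.dir_x, row.dir_y, row.dir_z),
            row.rotation_deg,
        )
        for row in df.itertuples()
    ]
    return df
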