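"""Membrane-frame geometry: insertion depth, deformation scans, tilt.

The insertion depth of a residue is measured against a *local* surface
reference — the mean z of nearby phosphate atoms of the same leaflet —
rather than a global plane, so the metric stays meaningful when the peptide
deforms the bilayer.  Deformation itself is quantified by a radial annulus
scan of per-leaflet half-thickness around the peptide, reported as the
deviation from the bulk (far-field) half-thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import minimum_image, pairwise_distances

__all__ = [
    "SurfaceReference",
    "InsertionDepth",
    "DeformationProfile",
    "local_surface_z",
    "insertion_depth",
    "assign_leaflets",
    "half_thickness_scan",
    "pool_deformation_profiles",
    "tilt_angle",
]


@dataclass(frozen=True)
class SurfaceReference:
    """Local phosphate-surface reference: mean z of the supporting atoms."""

    mean_z: float
    n_support_atoms: int
    radius_xy: float

    def __post_init__(self):
        if self.radius_xy <= 0:
            raise ValueError("radius_xy must be positive")
        if self.n_support_atoms < 1:
            raise ValueError("surface reference needs at least one support atom")


@dataclass(frozen=True)
class InsertionDepth:
    """Signed insertion depth in Å; negative = below the phosphate surface."""

    value: float
    frame_time: float = float("nan")

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValueError("insertion depth must be finite")


@dataclass(frozen=True)
class DeformationProfile:
    """Per-annulus half-thickness deviation from bulk, for each leaflet.

    ``radii`` are annulus midpoints; deviations are ``NaN`` where an annulus
    holds no atoms (flagged, never interpolated).
    """

    radii: np.ndarray
    upper_dev: np.ndarray
    lower_dev: np.ndarray
    bulk_half_thickness: float
    upper_counts: np.ndarray = field(default=None)
    lower_counts: np.ndarray = field(default=None)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "radius_A": self.radii,
                "upper_dev_A": self.upper_dev,
                "lower_dev_A": self.lower_dev,
                "upper_count": self.upper_counts,
                "lower_count": self.lower_counts,
            }
        )


def local_surface_z(
    residue_xy,
    phosphate_coords,
    box_xy=None,
    radius_xy: float = 6.0,
    min_atoms: int = 10,
    expand_step: float = 1.0,
    max_radius: float = 12.0,
) -> SurfaceReference:
    """Mean z of phosphate atoms near the residue in the xy plane.

    Counts every phosphate atom within ``radius_xy`` of the residue
    (minimum-image xy distance).  If fewer than ``min_atoms`` qualify the
    radius widens in ``expand_step`` increments up to ``max_radius``; running
    out of radius raises, since a surface built from too few or too distant
    atoms is not a meaningful local reference.
    """
    coords = np.atleast_2d(np.asarray(phosphate_coords, dtype=float))
    if coords.size == 0:
        raise ValueError("phosphate coordinate set is empty")
    residue_xy = np.asarray(residue_xy, dtype=float)[:2]
    d_xy = pairwise_distances(residue_xy, coords[:, :2], box=box_xy)[0]
    radius = float(radius_xy)
    while True:
        mask = d_xy <= radius
        n = int(np.count_nonzero(mask))
        if n >= min_atoms:
            return SurfaceReference(
                mean_z=float(np.mean(coords[mask, 2])),
                n_support_atoms=n,
                radius_xy=radius,
            )
        if radius + expand_step > max_radius + 1e-9:
            raise ValueError(
                f"only {n} phosphate atoms within {radius:.1f} Å "
                f"(need {min_atoms}; cap {max_radius:.1f} Å)"
            )
        radius += expand_step


def insertion_depth(
    residue_z: float, surface: SurfaceReference, frame_time: float = float("nan")
) -> InsertionDepth:
    """Signed depth: residue z minus the local surface z (negative = inserted)."""
    return InsertionDepth(value=float(residue_z) - surface.mean_z, frame_time=frame_time)


def assign_leaflets(phosphate_coords):
    """Split phosphates into (upper, lower) by z against the instantaneous midplane."""
    coords = np.atleast_2d(np.asarray(phosphate_coords, dtype=float))
    if coords.size == 0:
        raise ValueError("phosphate coordinate set is empty")
    midplane = float(np.mean(coords[:, 2]))
    upper = coords[coords[:, 2] >= midplane]
    lower = coords[coords[:, 2] < midplane]
    return upper, lower


def half_thickness_scan(
    upper_coords,
    lower_coords,
    center_xy,
    box_xy=None,
    annulus_width: float = 0.5,
    r_max: float = 25.0,
    bulk_min: float = 15.0,
) -> DeformationProfile:
    """Radial scan of per-leaflet half-thickness deviation around ``center_xy``.

    Annuli are half-open ``[r, r + width)`` in lateral distance from the
    center.  The local half-thickness of a leaflet in an annulus is the
    absolute distance of its mean z from the bilayer midplane (mean z of all
    phosphates); the deviation subtracts the leaflet's bulk half-thickness,
    pooled over all atoms beyond ``bulk_min``.
    """
    upper = np.atleast_2d(np.asarray(upper_coords, dtype=float))
    lower = np.atleast_2d(np.asarray(lower_coords, dtype=float))
    if upper.size == 0 or lower.size == 0:
        raise ValueError("both leaflets must be non-empty")
    center = np.asarray(center_xy, dtype=float)[:2]
    midplane = float(np.mean(np.concatenate([upper[:, 2], lower[:, 2]])))

    edges = np.arange(0.0, r_max + annulus_width / 2, annulus_width)
    radii = edges[:-1] + annulus_width / 2.0

    devs, counts, bulks = [], [], []
    for coords in (upper, lower):
        d = pairwise_distances(center, coords[:, :2], box=box_xy)[0]
        half = np.abs(coords[:, 2] - midplane)
        bulk_mask = d > bulk_min
        if not np.any(bulk_mask):
            raise ValueError(f"no atoms beyond bulk_min = {bulk_min} Å; bulk undefined")
        bulk = float(np.mean(half[bulk_mask]))
        idx = np.floor(d / annulus_width).astype(int)
        dev = np.full(radii.shape, np.nan)
        cnt = np.zeros(radii.shape, dtype=int)
        in_range = idx < len(radii)
        for k in np.unique(idx[in_range]):
            sel = idx == k
            cnt[k] = int(np.count_nonzero(sel))
            dev[k] = float(np.mean(half[sel])) - bulk
        devs.append(dev)
        counts.append(cnt)
        bulks.append(bulk)

    return DeformationProfile(
        radii=radii,
        upper_dev=devs[0],
        lower_dev=devs[1],
        bulk_half_thickness=float(np.mean(bulks)),
        upper_counts=counts[0],
        lower_counts=counts[1],
    )


def pool_deformation_profiles(profiles) -> DeformationProfile:
    """Count-weighted average of per-frame deformation profiles.

    Deformation statistics from single snapshots are sparse near the center;
    pooling over snapshots is how the per-frame scans become a stable radial
    profile.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles to pool")
    radii = profiles[0].radii
    for p in profiles:
        if not np.array_equal(p.radii, radii):
            raise ValueError("profiles must share the same annulus grid")

    def _pool(devs, counts):
        devs = np.array(devs)
        counts = np.array(counts, dtype=float)
        w = np.where(np.isfinite(devs), counts, 0.0)
        total = w.sum(axis=0)
        num = np.where(np.isfinite(devs), devs, 0.0) * w
        with np.errstate(invalid="ignore"):
            pooled = np.where(total > 0, num.sum(axis=0) / np.where(total > 0, total, 1), np.nan)
        return pooled, total.astype(int)

    up, nup = _pool([p.upper_dev for p in profiles], [p.upper_counts for p in profiles])
    lo, nlo = _pool([p.lower_dev for p in profiles], [p.lower_counts for p in profiles])
    return DeformationProfile(
        radii=radii,
        upper_dev=up,
        lower_dev=lo,
        bulk_half_thickness=float(np.mean([p.bulk_half_thickness for p in profiles])),
        upper_counts=nup,
        lower_counts=nlo,
    )


def tilt_angle(tm_start_coord, tm_end_coord, membrane_normal=(0.0, 0.0, 1.0)) -> float:
    """Angle (degrees, folded into [0, 90]) between a segment axis and the normal."""
    axis = np.asarray(tm_end_coord, dtype=float) - np.asarray(tm_start_coord, dtype=float)
    norm = np.asarray(membrane_normal, dtype=float)
    la, ln = np.linalg.norm(axis), np.linalg.norm(norm)
    if la == 0:
        raise ValueError("segment endpoints coincide; axis undefined")
    if ln == 0:
        raise ValueError("membrane normal must be non-zero")
    cosang = abs(float(np.dot(axis, norm)) / (la * ln))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
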