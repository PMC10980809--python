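"""Spheroid-outgrowth, perpendicular-extent and tissue-infiltration statistics.

Outgrowth from a cell spheroid is quantified by casting a fixed number of
rays (default eight) from the spheroid centre and recording, per ray, the
distance to the farthest cell-positive pixel; the spheroid radius is then
subtracted from the ray average.  Infiltration of cells into a hydrogel from
overlying tissue is summarised by the 95th-percentile depth ("maximum
infiltration") and by the fraction of cells per depth bin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "OutgrowthMeasurement",
    "InfiltrationProfile",
    "radial_outgrowth",
    "perpendicular_extent",
    "infiltration_stats",
]


@dataclass(frozen=True)
class OutgrowthMeasurement:
    """Per-ray distances (um), their mean minus the spheroid radius, and flags."""

    per_ray_distance: np.ndarray  # um, one per ray
    mean_outgrowth: float  # um, floored at 0
    center: tuple[float, float]  # pixel coordinates (row, col)
    spheroid_radius: float  # um
    empty_rays: np.ndarray  # boolean, rays that hit no positive pixel


@dataclass(frozen=True)
class InfiltrationProfile:
    """Depth summary of infiltrating cells."""

    depths: np.ndarray  # um
    max_infiltration: float  # 95th-percentile depth, um
    bin_edges: np.ndarray  # um
    bin_fractions: np.ndarray  # fraction of cells per bin, sums to 1


def radial_outgrowth(
    mask: np.ndarray,
    center: tuple[float, float],
    spheroid_radius: float,
    pixel_size: float = 1.0,
    n_rays: int = 8,
    start_angle_deg: float = 0.0,
    step_px: float = 0.25,
) -> OutgrowthMeasurement:
    """Mean radial outgrowth of cells from a spheroid, from a binary mask.

    ``n_rays`` equally spaced rays are cast from ``center`` (row, col pixel
    coordinates); along each, positions are sampled every ``step_px`` pixels
    and the farthest positive-mask sample is recorded.  Ray distances are
    averaged and the spheroid radius subtracted; a negative difference
    (all ray maxima inside the spheroid) is floored at zero.  Rays that hit
    no positive pixel contribute distance 0 and are flagged.

    Angles are measured from ``start_angle_deg`` (0 = +col direction,
    counterclockwise in image coordinates).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.ndim != 2:
        raise ValueError("mask must be 2D")
    if not mask.any():
        raise ValueError("mask has no positive pixel")
    r0, c0 = center
    if not (0 <= r0 < mask.shape[0] and 0 <= c0 < mask.shape[1]):
        raise ValueError("center must lie inside the image")
    if spheroid_radius < 0 or pixel_size <= 0:
        raise ValueError("spheroid_radius must be >= 0 and pixel_size > 0")

    # max ray length: far corner distance
    corners = np.array([[0, 0], [0, mask.shape[1] - 1],
                        [mask.shape[0] - 1, 0], [mask.shape[0] - 1, mask.shape[1] - 1]])
    max_len = float(np.max(np.hypot(corners[:, 0] - r0, corners[:, 1] - c0)))
    radii = np.arange(0.0, max_len + step_px, step_px)

    angles = np.deg2rad(start_angle_deg + 360.0 * np.arange(n_rays) / n_rays)
    per_ray = np.zeros(n_rays)
    empty = np.zeros(n_rays, dtype=bool)
    for i, ang in enumerate(angles):
        rr = r0 - radii * np.sin(ang)  # image rows grow downwards
        cc = c0 + radii * np.cos(ang)
        inside = (rr >= 0) & (rr <= mask.shape[0] - 1) & (cc >= 0) & (cc <= mask.shape[1] - 1)
        hit = np.zeros_like(radii, dtype=bool)
        hit[inside] = mask[np.round(rr[inside]).astype(int), np.round(cc[inside]).astype(int)]
        if hit.any():
            per_ray[i] = radii[hit][-1] * pixel_size
        else:
            empty[i] = True
    mean_out = max(float(per_ray.mean()) - spheroid_radius, 0.0)
    return OutgrowthMeasurement(per_ray, mean_out, (float(r0), float(c0)),
                                float(spheroid_radius), empty)


def perpendicular_extent(points: np.ndarray) -> tuple[float, bool]:
    """Extent of a 3D point cloud along its least-variance principal axis.

    Approximates the shortest side of an object-oriented bounding box by the
    max - min of point projections on the smallest-variance eigenvector of
    the point covariance.  Returns ``(extent_um, degenerate)``; coplanar
    point sets give extent 0 with the degenerate flag set.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise ValueError("points must be (n, 3)")
    if pts.shape[0] < 2:
        raise ValueError("need >= 2 points")
    centered = pts - pts.mean(axis=0)
    cov = centered.T @ centered / pts.shape[0]
    eigvals, eigvecs = np.linalg.eigh(cov)  # ascending
    axis = eigvecs[:, 0]
    proj = centered @ axis
    extent = float(proj.max() - proj.min())
    scale = float(np.sqrt(max(eigvals[-1], 1e-300)))
    degenerate = extent <= 1e-9 * max(scale, 1.0) or pts.shape[0] < 4
    return extent, degenerate


def infiltration_stats(
    depths: np.ndarray,
    bin_edges: np.ndarray | list[float] = (0.0, 50.0, 100.0),
    quantile: float = 95.0,
) -> InfiltrationProfile:
    """Maximum infiltration (95th-percentile depth) and per-bin cell fractions.

    The percentile uses linear interpolation between order statistics.  Bins
    are half-open ``[edge_i, edge_{i+1})`` with the last bin closed; cells
    deeper than the final edge are counted in the last bin.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise ValueError("no depths provided")
    if np.any(depths < 0):
        raise ValueError("depths must be >= 0")
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be increasing with >= 2 entries")
    q = float(np.percentile(depths, quantile, method="linear"))
    idx = np.clip(np.digitize(depths, edges) - 1, 0, edges.size - 2)
    counts = np.bincount(idx, minlength=edges.size - 1)
    return InfiltrationProfile(depths, q, edges, counts / depths.size)
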