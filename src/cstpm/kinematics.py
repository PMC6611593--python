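"""Functional read-outs from myocardial velocity fields.

From a per-pixel velocity field the module derives the quantities used to
characterise regional myocardial function on a short-axis slice:

* transmural-averaged radial velocity (in-plane velocity projected toward
  the cavity centroid; positive during systolic contraction) and
  longitudinal (through-plane) velocity, globally and for six angular
  segments of the myocardium;
* circumferential strain, obtained by integrating the velocity field in
  time to track a closed midwall contour and measuring the fractional
  change of its arc length, reported in %strain (negative during systolic
  shortening).

Tracking integrates ``dx/dt = v(x, t)`` with an explicit midpoint (RK2)
scheme and bilinear interpolation of the velocity field at continuous
positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import map_coordinates

from .velocity import VelocityField

__all__ = [
    "Segmentation",
    "Trajectories",
    "KinematicsResult",
    "sectorize",
    "regional_velocities",
    "track_displacement",
    "circumferential_strain",
    "midwall_contour",
    "analyze",
]

CM_PER_S_TO_MM_PER_MS = 0.01  # 1 cm/s = 0.01 mm/ms


@dataclass
class Segmentation:
    """Angular-sector segmentation of a myocardial mask."""

    mask: np.ndarray  # (y, x) bool
    centroid: tuple[float, float]  # (y, x)
    n_segments: int
    labels: np.ndarray  # (y, x) int, sector 0..n-1 inside mask, -1 outside
    reference_angle: float = 0.0

    def segment_of(self, y: float, x: float) -> int:
        """Sector index of an arbitrary (possibly off-grid) point."""
        return _sector_of_angle(
            np.arctan2(y - self.centroid[0], x - self.centroid[1]),
            self.n_segments,
            self.reference_angle,
        )


def _sector_of_angle(theta, n_segments: int, reference_angle: float):
    rel = np.mod(theta - reference_angle, 2 * np.pi)
    idx = np.floor(n_segments * rel / (2 * np.pi)).astype(int)
    return np.clip(idx, 0, n_segments - 1)


def sectorize(
    mask: np.ndarray,
    centroid: tuple[float, float] | None = None,
    n_segments: int = 6,
    reference_angle: float = 0.0,
) -> Segmentation:
    """Partition a mask into contiguous angular sectors about its centroid."""
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("empty mask")
    yy, xx = np.nonzero(mask)
    if centroid is None:
        centroid = (float(yy.mean()), float(xx.mean()))
    theta = np.arctan2(yy - centroid[0], xx - centroid[1])
    sector = _sector_of_angle(theta, n_segments, reference_angle)
    labels = np.full(mask.shape, -1, dtype=int)
    labels[yy, xx] = sector
    counts = np.bincount(sector, minlength=n_segments)
    if np.any(counts == 0):
        empty = np.flatnonzero(counts == 0).tolist()
        raise ValueError(f"empty sector(s) {empty}; mask does not cover all angles")
    return Segmentation(
        mask=mask,
        centroid=centroid,
        n_segments=n_segments,
        labels=labels,
        reference_angle=reference_angle,
    )


def regional_velocities(
    field: VelocityField, seg: Segmentation
) -> dict[str, np.ndarray]:
    """Global and per-segment transmural-averaged velocity curves.

    Radial velocity is the in-plane velocity projected on the unit vector
    from each pixel toward the centroid (positive = toward the centroid,
    i.e. contraction).  Longitudinal velocity is the through-plane (z)
    component.  Per-segment values are means over the segment's pixels;
    global values are means over the whole mask.
    """
    if field.v.shape[1:3] != seg.mask.shape:
        raise ValueError("velocity field and segmentation extents differ")
    yy, xx = np.nonzero(seg.mask)
    dy = seg.centroid[0] - yy
    dx = seg.centroid[1] - xx
    norm = np.hypot(dy, dx)
    norm[norm == 0] = 1.0  # centroid pixel: radial direction undefined -> 0
    uy, ux = dy / norm, dx / norm

    vx = field.v[:, yy, xx, 0]  # (frame, pixel)
    vy = field.v[:, yy, xx, 1]
    vz = field.v[:, yy, xx, 2]
    v_rad = vx * ux + vy * uy  # positive toward centroid
    labels = seg.labels[yy, xx]

    n_seg = seg.n_segments
    v_rad_seg = np.stack([v_rad[:, labels == s].mean(axis=1) for s in range(n_seg)])
    v_long_seg = np.stack([vz[:, labels == s].mean(axis=1) for s in range(n_seg)])
    return {
        "v_rad_global": v_rad.mean(axis=1),
        "v_long_global": vz.mean(axis=1),
        "v_rad_seg": v_rad_seg,  # (segment, frame)
        "v_long_seg": v_long_seg,
    }


@dataclass
class Trajectories:
    """Tracked material-point positions in pixel coordinates."""

    positions: np.ndarray  # (point, frame, 2) as (y, x)
    seeds: np.ndarray  # (point, 2)
    clamped: np.ndarray  # (point,) bool: left the image and was clamped

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]


def _sample_velocity(v_frame: np.ndarray, pos: np.ndarray) -> np.ndarray:
    """Bilinear sample of an in-plane (y, x, comp) velocity frame at (y, x) points."""
    coords = pos.T  # (2, point)
    out = np.empty((pos.shape[0], v_frame.shape[-1]))
    for comp in range(v_frame.shape[-1]):
        out[:, comp] = map_coordinates(
            v_frame[..., comp], coords, order=1, mode="nearest"
        )
    return out


def track_displacement(
    field: VelocityField,
    seeds: np.ndarray,
    frame_interval: float | None = None,
    pixel_spacing: tuple[float, float] | None = None,
) -> Trajectories:
    """Integrate the velocity field in time from seed positions.

    Positions are in pixel coordinates (y, x); the in-plane velocity
    components (cm/s) are converted through ``pixel_spacing`` (mm) and
    ``frame_interval`` (ms) into pixels per frame.  One explicit-midpoint
    step is taken per frame interval, with the midpoint velocity taken as
    the average of the bracketing frames (periodic in the cardiac cycle).
    Trajectories leaving the image are clamped to the boundary and flagged.
    """
    if frame_interval is None:
        frame_interval = field.frame_interval
    if pixel_spacing is None:
        pixel_spacing = field.pixel_spacing
    seeds = np.atleast_2d(np.asarray(seeds, float))
    n_frames = field.n_frames
    ny, nx = field.v.shape[1:3]
    if np.any(seeds < -0.5) or np.any(seeds[:, 0] > ny - 0.5) or np.any(seeds[:, 1] > nx - 0.5):
        raise ValueError("seed positions outside the image")

    # velocity (cm/s) -> pixel displacement per ms, per axis (y, x)
    scale = np.array(
        [
            CM_PER_S_TO_MM_PER_MS / pixel_spacing[0],
            CM_PER_S_TO_MM_PER_MS / pixel_spacing[1],
        ]
    )

    def v_pixels(frame_v: np.ndarray, pos: np.ndarray) -> np.ndarray:
        s = _sample_velocity(frame_v, pos)  # (point, 3) cm/s, (vx, vy, vz)
        return np.stack([s[:, 1] * scale[0], s[:, 0] * scale[1]], axis=1)

    positions = np.empty((seeds.shape[0], n_frames, 2))
    positions[:, 0] = seeds
    clamped = np.zeros(seeds.shape[0], bool)
    dt = frame_interval
    pos = seeds.copy()
    for f in range(n_frames - 1):
        v_now = field.v[f]
        v_next = field.v[(f + 1) % n_frames]
        v_mid = 0.5 * (v_now + v_next)
        half = pos + 0.5 * dt * v_pixels(v_now, pos)
        pos = pos + dt * v_pixels(v_mid, half)
        out = (
            (pos[:, 0] < 0)
            | (pos[:, 0] > ny - 1)
            | (pos[:, 1] < 0)
            | (pos[:, 1] > nx - 1)
        )
        clamped |= out
        pos[:, 0] = np.clip(pos[:, 0], 0, ny - 1)
        pos[:, 1] = np.clip(pos[:, 1], 0, nx - 1)
        positions[:, f + 1] = pos
    return Trajectories(positions=positions, seeds=seeds, clamped=clamped)


def midwall_contour(
    centroid: tuple[float, float], radius_px: float, n_points: int = 72
) -> np.ndarray:
    """Ordered closed midwall contour seeds (y, x), counter-clockwise."""
    theta = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    return np.stack(
        [
            centroid[0] + radius_px * np.sin(theta),
            centroid[1] + radius_px * np.cos(theta),
        ],
        axis=1,
    )


def circumferential_strain(
    traj: Trajectories,
    seg: Segmentation,
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> dict[str, np.ndarray]:
    """Engineering circumferential strain from a tracked closed contour.

    The contour is treated as a closed polyline; each edge is assigned to
    the angular segment of its frame-0 midpoint.  Strain of a segment at
    frame ``t`` is ``100 * (L_seg(t) - L_seg(0)) / L_seg(0)`` with ``L_seg``
    the summed physical length of the segment's edges; global strain uses
    the full closed-contour length.  Strain at frame 0 is identically 0.
    """
    pos = traj.positions  # (point, frame, 2)
    n_pts, n_frames, _ = pos.shape
    # frame-0 edge midpoints decide segment membership (fixed over time)
    mid0 = 0.5 * (pos[:, 0] + np.roll(pos[:, 0], -1, axis=0))
    edge_seg = _sector_of_angle(
        np.arctan2(mid0[:, 0] - seg.centroid[0], mid0[:, 1] - seg.centroid[1]),
        seg.n_segments,
        seg.reference_angle,
    )
    counts = np.bincount(edge_seg, minlength=seg.n_segments)
    if np.any(counts < 3):
        raise ValueError(
            "fewer than 3 contour points in a segment; use a denser contour"
        )

    spacing = np.array(pixel_spacing)  # (dy, dx) mm
    diffs = (np.roll(pos, -1, axis=0) - pos) * spacing  # (point, frame, 2) mm
    edge_len = np.linalg.norm(diffs, axis=2)  # (point, frame)

    total = edge_len.sum(axis=0)  # (frame,)
    strain_global = 100.0 * (total - total[0]) / total[0]
    seg_curves = []
    for s in range(seg.n_segments):
        l_seg = edge_len[edge_seg == s].sum(axis=0)
        seg_curves.append(100.0 * (l_seg - l_seg[0]) / l_seg[0])
    return {
        "strain_circ_global": strain_global,
        "strain_circ_seg": np.stack(seg_curves),  # (segment, frame)
        "segment_lengths0": np.array(
            [edge_len[edge_seg == s, 0].sum() for s in range(seg.n_segments)]
        ),
    }


@dataclass
class KinematicsResult:
    """Global and 6-segment functional curves over the cardiac cycle."""

    t: np.ndarray  # frame times, ms
    v_rad_global: np.ndarray  # cm/s, (frame,)
    v_long_global: np.ndarray
    v_rad_seg: np.ndarray  # (segment, frame)
    v_long_seg: np.ndarray
    strain_circ_global: np.ndarray  # %strain, (frame,)
    strain_circ_seg: np.ndarray  # (segment, frame)

    @property
    def n_segments(self) -> int:
        return self.v_rad_seg.shape[0]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (frame, scope)."""
        rows = []
        n_frames = len(self.t)
        for f in range(n_frames):
            rows.append(
                {
                    "frame": f,
                    "time_ms": self.t[f],
                    "scope": "global",
                    "v_rad_cm_s": self.v_rad_global[f],
                    "v_long_cm_s": self.v_long_global[f],
                    "strain_circ_pct": self.strain_circ_global[f],
                }
            )
            for s in range(self.n_segments):
                rows.append(
                    {
                        "frame": f,
                        "time_ms": self.t[f],
                        "scope": f"seg{s + 1}",
                        "v_rad_cm_s": self.v_rad_seg[s, f],
                        "v_long_cm_s": self.v_long_seg[s, f],
                        "strain_circ_pct": self.strain_circ_seg[s, f],
                    }
                )
        return pd.DataFrame(rows)


def analyze(
    field: VelocityField,
    seg: Segmentation,
    contour_seeds: np.ndarray,
) -> KinematicsResult:
    """Full kinematic analysis: regional velocities plus contour strain."""
    vel = regional_velocities(field, seg)
    traj = track_displacement(field, contour_seeds)
    strain = circumferential_strain(traj, seg, pixel_spacing=field.pixel_spacing)
    t = np.arange(field.n_frames) * field.frame_interval
    return KinematicsResult(
        t=t,
        v_rad_global=vel["v_rad_global"],
        v_long_global=vel["v_long_global"],
        v_rad_seg=vel["v_rad_seg"],
        v_long_seg=vel["v_long_seg"],
        strain_circ_global=strain["strain_circ_global"],
        strain_circ_seg=strain["strain_circ_seg"],
    )
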