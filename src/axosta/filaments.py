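"""Filament centerlines: periodic picking, duplicate removal, numbering.

A ``FilamentTrack`` is an ordered polyline through a filament axis
(doublet microtubule or central-pair singlet), parameterised by
chord-length arc distance.  Subvolume picking walks the track at a fixed
longitudinal interval — 240 A (24 nm) for doublets, 160 A (16 nm) for
the central pair — and seeds each record's orientation from the local
tangent frame so that the box x-axis runs along the filament.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.stats import circmean, circstd

from .io import (
    EULER_COLUMNS,
    POSITION_COLUMNS,
    matrix_to_euler,
    new_particle_table,
    validate_particles,
)

__all__ = [
    "FilamentTrack",
    "PairOffset",
    "pick_along",
    "remove_duplicates",
    "assign_doublet_numbers",
    "measure_pair_offset",
]


@dataclass
class FilamentTrack:
    """Ordered control points (Angstroms) with arc-length lookup.

    ``polarity`` flips the stored point order so that the track always
    runs base-to-tip; tangents follow the (possibly flipped) order.
    """

    points: np.ndarray
    filament_id: str = "fil0"
    tomogram_id: str = "tomo0"
    polarity: int = 1
    _arc: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 3)
        if self.polarity < 0:
            pts = pts[::-1]
        if len(pts) < 2:
            raise ValueError("a track needs at least two control points")
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        if np.any(seg == 0):
            raise ValueError("consecutive control points must be distinct")
        self.points = pts
        self._arc = np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length(self) -> float:
        """Total arc length in Angstroms."""
        return float(self._arc[-1])

    def point_at(self, s: float | np.ndarray) -> np.ndarray:
        """Position at arc distance ``s`` (piecewise-linear)."""
        s = np.clip(np.asarray(s, dtype=float), 0.0, self.length)
        out = np.empty(np.shape(s) + (3,))
        for axis in range(3):
            out[..., axis] = np.interp(s, self._arc, self.points[:, axis])
        return out

    def tangent_at(self, s: float | np.ndarray) -> np.ndarray:
        """Unit tangent at arc distance ``s``."""
        s = np.atleast_1d(np.asarray(s, dtype=float))
        idx = np.clip(np.searchsorted(self._arc, s, side="right") - 1, 0,
                      len(self.points) - 2)
        seg = self.points[idx + 1] - self.points[idx]
        t = seg / np.linalg.norm(seg, axis=-1, keepdims=True)
        return t[0] if np.isscalar(s) or t.shape[0] == 1 else t

    def frame_at(self, s: float) -> np.ndarray:
        """Right-handed local frame at ``s`` as matrix columns (t, n, b).

        The normal is built from a fixed world up-vector (the one least
        parallel to the tangent), giving a deterministic roll.
        """
        t = np.atleast_2d(self.tangent_at(s))[0]
        up = np.zeros(3)
        up[np.argmin(np.abs(t))] = 1.0
        n = up - np.dot(up, t) * t
        n /= np.linalg.norm(n)
        b = np.cross(t, n)
        return np.column_stack([t, n, b])


def pick_along(track: FilamentTrack, spacing_ang: float) -> pd.DataFrame:
    """Pick particle records every ``spacing_ang`` of arc along a track.

    Records sit at arc positions 0, s, 2s, ... <= length, i.e.
    ``floor(length / spacing) + 1`` of them; each orientation is the
    local tangent frame (box x-axis along the filament).
    """
    if spacing_ang <= 0:
        raise ValueError("spacing must be positive")
    if track.length < spacing_ang:
        raise ValueError("track shorter than one picking interval")
    n = int(np.floor(track.length / spacing_ang)) + 1
    table = new_particle_table(n)
    table["tomogram_id"] = track.tomogram_id
    table["filament_id"] = track.filament_id
    arcs = np.arange(n) * spacing_ang
    table[POSITION_COLUMNS] = track.point_at(arcs)
    for i, s in enumerate(arcs):
        table.loc[i, EULER_COLUMNS] = matrix_to_euler(track.frame_at(float(s)))
    table["arc_s"] = arcs
    return table


def remove_duplicates(table: pd.DataFrame, min_dist_ang: float) -> pd.DataFrame:
    """Greedy duplicate removal: keep best-scoring record in each clump.

    Records are visited in descending score order; one is kept iff no
    already-kept record lies within ``min_dist_ang`` (Euclidean).  The
    result is maximal: every removed record violates the distance
    constraint against some survivor.
    """
    if min_dist_ang < 0:
        raise ValueError("min_dist must be non-negative")
    validate_particles(table)
    if min_dist_ang == 0 or len(table) == 0:
        return table.copy()
    order = np.argsort(-table["score"].to_numpy(dtype=float), kind="stable")
    pos = table[POSITION_COLUMNS].to_numpy(dtype=float)
    kept: list[int] = []
    tree: cKDTree | None = None
    for idx in order:
        if tree is None or not tree.query_ball_point(pos[idx], min_dist_ang):
            kept.append(idx)
            tree = cKDTree(pos[kept])
    kept_sorted = np.sort(kept)
    return table.iloc[kept_sorted].reset_index(drop=True)


def _mean_direction(track: FilamentTrack) -> np.ndarray:
    d = track.points[-1] - track.points[0]
    return d / np.linalg.norm(d)


def assign_doublet_numbers(
    doublet_axes: list[FilamentTrack],
    cp_axis: FilamentTrack,
    cp_plane_normal: np.ndarray,
    polarity: int = 1,
) -> dict[str, int]:
    """Number nine doublet axes 1-9 by angular position around the CP.

    Angles are measured in the plane perpendicular to the central-pair
    axis, starting at the reference direction ``cp_plane_normal`` and
    increasing with the handedness set by ``polarity`` (viewed along the
    CP axis).  Doublet 1 is the axis closest to the reference direction.

    Returns a mapping filament_id -> doublet number.
    """
    if len(doublet_axes) != 9:
        raise ValueError(f"expected 9 doublet axes, got {len(doublet_axes)}")
    t = _mean_direction(cp_axis)
    for ax in doublet_axes:
        cosang = abs(np.dot(_mean_direction(ax), t))
        if cosang < np.cos(np.deg2rad(20.0)):
            raise ValueError(f"axis {ax.filament_id} not parallel to CP axis (>20 deg)")
    u = np.asarray(cp_plane_normal, dtype=float)
    u = u - np.dot(u, t) * t
    if np.linalg.norm(u) == 0:
        raise ValueError("cp_plane_normal is parallel to the CP axis")
    u /= np.linalg.norm(u)
    w = np.sign(polarity) * np.cross(t, u)
    center = cp_axis.points.mean(axis=0)
    angles = []
    for ax in doublet_axes:
        p = ax.points.mean(axis=0) - center
        p = p - np.dot(p, t) * t
        angles.append(np.arctan2(np.dot(p, w), np.dot(p, u)) % (2 * np.pi))
    angles = np.asarray(angles)
    # doublet 1 = closest to the reference angle (circular distance to 0)
    start = int(np.argmin(np.minimum(angles, 2 * np.pi - angles)))
    order = np.argsort((angles - angles[start]) % (2 * np.pi), kind="stable")
    return {doublet_axes[i].filament_id: rank + 1 for rank, i in enumerate(order)}


@dataclass(frozen=True)
class PairOffset:
    """Longitudinal phase offset between two filaments, modulo the repeat."""

    mean_ang: float
    sd_ang: float
    per_tomogram_ang: dict[str, float]


def _phases(table: pd.DataFrame, axis_dir: np.ndarray, repeat_ang: float) -> np.ndarray:
    s = table[POSITION_COLUMNS].to_numpy(dtype=float) @ axis_dir
    return s % repeat_ang


def measure_pair_offset(
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    repeat_ang: float,
    axis_dir: np.ndarray | None = None,
) -> PairOffset:
    """Circular statistics of the phase offset (B - A) modulo the repeat.

    Both tables must be registry-resolved, i.e. their positions must sit
    on the true repeat lattice (after recentering).  The phase of each
    record is its projection onto ``axis_dir`` (default: the dominant
    direction of table A's positions) modulo ``repeat_ang``; offsets are
    compared per tomogram and pooled with circular mean/sd.
    """
    if len(table_a) == 0 or len(table_b) == 0:
        raise ValueError("empty particle table")
    if axis_dir is None:
        pos = table_a[POSITION_COLUMNS].to_numpy(dtype=float)
        pos = pos - pos.mean(axis=0)
        _, _, vt = np.linalg.svd(pos, full_matrices=False)
        axis_dir = vt[0]
        first = table_a.iloc[-1][POSITION_COLUMNS].to_numpy(dtype=float) - \
            table_a.iloc[0][POSITION_COLUMNS].to_numpy(dtype=float)
        if np.dot(axis_dir, first) < 0:
            axis_dir = -axis_dir
    axis_dir = np.asarray(axis_dir, dtype=float)
    axis_dir = axis_dir / np.linalg.norm(axis_dir)

    per_tomo: dict[str, float] = {}
    tomos = sorted(set(table_a["tomogram_id"]) & set(table_b["tomogram_id"]))
    if not tomos:
        raise ValueError("tables share no tomograms")
    for tomo in tomos:
        pa = _phases(table_a[table_a["tomogram_id"] == tomo], axis_dir, repeat_ang)
        pb = _phases(table_b[table_b["tomogram_id"] == tomo], axis_dir, repeat_ang)
        ma = circmean(pa, high=repeat_ang, low=0.0)
        mb = circmean(pb, high=repeat_ang, low=0.0)
        per_tomo[tomo] = float((mb - ma) % repeat_ang)
    values = np.array(list(per_tomo.values()))
    return PairOffset(
        mean_ang=float(circmean(values, high=repeat_ang, low=0.0)),
        sd_ang=float(circstd(values, high=repeat_ang, low=0.0)),
        per_tomogram_ang=per_tomo,
    )
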