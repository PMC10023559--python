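"""Contextual sorting: whole-axoneme context resolves the nine doublets.

The central observation this module operationalises: once subvolumes
are aligned on the central pair, re-extracting much larger boxes at the
same poses and averaging them *without further alignment* reveals nine
distinct doublet densities at fixed radial positions — the axoneme's
radial arrangement is consistent across tomograms.  The nine rod axes
detected in that context average are remapped into each tomogram, every
doublet pick is labelled by its nearest axis, and per-doublet averages
expose the asymmetric decoration pattern (barrel, RS2-RS3 cross-linker,
RS3 scaffold) that a global consensus average smears away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.signal import find_peaks

from .engine import extract
from .filaments import FilamentTrack
from .io import EULER_COLUMNS, POSITION_COLUMNS, Volume, euler_to_matrix

__all__ = [
    "expand_and_average",
    "angular_profile",
    "detect_doublet_axes",
    "remap_axes",
    "sort_by_doublet",
    "per_doublet_average",
    "occupancy_profile",
    "OccupancyProfile",
    "AngularProfile",
]

FEATURES = ("barrel", "rs2_rs3_crosslinker", "rs3_scaffold")


def expand_and_average(
    volumes: dict[str, Volume],
    cp_table: pd.DataFrame,
    big_box: int,
    big_voxel_ang: float,
) -> Volume:
    """Average threefold-expanded boxes in the central-pair frame.

    For every CP-aligned record, a ``big_box``-cubed subvolume at pitch
    ``big_voxel_ang`` is re-extracted around the record's pose (samples
    beyond the tomogram read as zero) and all boxes are averaged with no
    further alignment.
    """
    total = None
    count = 0
    for tomo, vol in volumes.items():
        rows = cp_table[cp_table["tomogram_id"] == tomo]
        if len(rows) == 0:
            continue
        stack, _ = extract(vol, rows, big_box, out_voxel_ang=big_voxel_ang,
                           allow_partial=True)
        if len(stack):
            s = stack.sum(axis=0, dtype=np.float64)
            total = s if total is None else total + s
            count += len(stack)
    if count == 0:
        raise ValueError("no central-pair records to average")
    return Volume((total / count).astype(np.float32), big_voxel_ang)


@dataclass(frozen=True)
class AngularProfile:
    """Density versus angle at the doublet-ring radius."""

    angles_deg: np.ndarray
    values: np.ndarray
    peak_angles_deg: np.ndarray
    contrast: float


def angular_profile(
    average: Volume,
    ring_radius_ang: float,
    band_halfwidth_ang: float = 150.0,
    n_angles: int = 360,
    peak_rel_height: float = 0.3,
) -> AngularProfile:
    """Angular density profile of a context average around the CP axis.

    The volume is collapsed along the filament (x) axis, then sampled on
    rings spanning ``ring_radius_ang +/- band_halfwidth_ang``.  Peaks
    are detected on the circular profile with a prominence threshold
    relative to the profile range; the peak:trough contrast divides the
    background-subtracted mean peak height by the mean trough height,
    with the background estimated well outside the ring.
    """
    img = average.data.mean(axis=2)  # (z, y)
    nz, ny = img.shape
    cy = (ny // 2) * average.voxel_size
    cz = (nz // 2) * average.voxel_size
    theta = np.deg2rad(np.arange(n_angles) * 360.0 / n_angles)
    radii = np.linspace(ring_radius_ang - band_halfwidth_ang,
                        ring_radius_ang + band_halfwidth_ang, 7)

    def ring_mean(rset):
        acc = np.zeros(n_angles)
        for r in rset:
            y = (cy + r * np.cos(theta)) / average.voxel_size
            z = (cz + r * np.sin(theta)) / average.voxel_size
            acc += ndimage.map_coordinates(img, np.vstack([z, y]), order=1,
                                           mode="nearest")
        return acc / len(rset)

    prof = ring_mean(radii)
    background = float(np.mean(ring_mean([ring_radius_ang + 4 * band_halfwidth_ang])))

    # circular peak finding: tile the profile
    tiled = np.tile(prof, 3)
    rng_prof = prof.max() - prof.min()
    peaks, _ = find_peaks(tiled, prominence=peak_rel_height * max(rng_prof, 1e-12),
                          distance=max(n_angles // 36, 1))
    peaks = peaks[(peaks >= n_angles) & (peaks < 2 * n_angles)] - n_angles
    peak_angles = np.sort(peaks * 360.0 / n_angles)

    if len(peaks):
        peak_mean = prof[peaks].mean() - background
        troughs = []
        ordered = np.sort(peaks)
        for a, b in zip(ordered, np.roll(ordered, -1)):
            span = (b - a) % n_angles or n_angles
            troughs.append(prof[(a + span // 2) % n_angles])
        trough_mean = float(np.mean(troughs)) - background
        contrast = peak_mean / max(trough_mean, 0.01 * max(peak_mean, 1e-12))
        contrast = float(min(contrast, 99.0))
    else:
        contrast = 1.0
    return AngularProfile(np.arange(n_angles) * 360.0 / n_angles, prof,
                          peak_angles, contrast)


def detect_doublet_axes(
    average: Volume,
    ring_radius_ang: float,
    expected: int = 9,
    slab_vox: int = 4,
    com_radius_ang: float = 220.0,
    min_contrast: float = 3.0,
) -> tuple[list[FilamentTrack], np.ndarray]:
    """Fit one axis per angular peak of the context average.

    Each axis is traced by centre-of-mass per longitudinal slab inside a
    cylinder around the peak's ring position.  Raises if the number of
    detected peaks differs from ``expected`` or the ring profile is too
    smeared (peak:trough contrast below ``min_contrast``) to trust them.
    """
    prof = angular_profile(average, ring_radius_ang)
    k = len(prof.peak_angles_deg)
    if k != expected or prof.contrast < min_contrast:
        raise ValueError(
            f"peaks={k}!={expected} or contrast {prof.contrast:.2f} < "
            f"{min_contrast}: radial positions unresolved"
        )
    vox = average.voxel_size
    nz, ny, nx = average.data.shape
    cy = (ny // 2) * vox
    cz = (nz // 2) * vox
    zz, yy = np.meshgrid(np.arange(nz) * vox, np.arange(ny) * vox, indexing="ij")
    tracks = []
    for ang in prof.peak_angles_deg:
        a = np.deg2rad(ang)
        py = cy + ring_radius_ang * np.cos(a)
        pz = cz + ring_radius_ang * np.sin(a)
        sel = (yy - py) ** 2 + (zz - pz) ** 2 <= com_radius_ang**2
        pts = []
        for x0 in range(0, nx - slab_vox + 1, slab_vox):
            slab = average.data[:, :, x0:x0 + slab_vox].mean(axis=2)
            w = np.clip(slab, 0.0, None) * sel
            if w.sum() <= 0:
                continue
            ym = float((w * yy).sum() / w.sum())
            zm = float((w * zz).sum() / w.sum())
            pts.append([(x0 + slab_vox / 2) * vox, ym, zm])
        if len(pts) < 2:
            raise ValueError(f"axis at {ang:.1f} deg has no density")
        tracks.append(FilamentTrack(np.asarray(pts), filament_id=f"axis{ang:.0f}"))
    return tracks, prof.peak_angles_deg


def remap_axes(
    tracks: list[FilamentTrack],
    cp_table: pd.DataFrame,
    box_center_ang: np.ndarray,
) -> dict[str, list[FilamentTrack]]:
    """Express context-frame axes in each tomogram's coordinates.

    The context average lives in the CP-aligned box frame.  For each
    tomogram, every axis line is carried over by averaging, across that
    tomogram's CP records, the record pose applied to the axis's
    transverse offset — a line-averaged version of per-subvolume
    remapping, stable when individual poses are noisy.
    """
    out: dict[str, list[FilamentTrack]] = {}
    for tomo in sorted(pd.unique(cp_table["tomogram_id"])):
        rows = cp_table[cp_table["tomogram_id"] == tomo]
        rots = [euler_to_matrix(*r[EULER_COLUMNS].to_numpy(dtype=float))
                for _, r in rows.iterrows()]
        poss = rows[POSITION_COLUMNS].to_numpy(dtype=float)
        mapped = []
        for tr in tracks:
            mid = tr.point_at(tr.length / 2.0) - box_center_ang
            perp = mid.copy()
            perp[0] = 0.0  # transverse offset in the box frame
            pts, dirs = [], []
            for rot, pos in zip(rots, poss):
                pts.append(pos + rot @ perp)
                dirs.append(rot @ np.array([1.0, 0.0, 0.0]))
            anchor = np.mean(pts, axis=0)
            direction = np.mean(dirs, axis=0)
            direction /= np.linalg.norm(direction)
            span = max(tr.length, poss[:, 0].max() - poss[:, 0].min() + 2000.0)
            mapped.append(FilamentTrack(
                np.array([anchor - direction * span, anchor + direction * span]),
                filament_id=tr.filament_id, tomogram_id=tomo,
            ))
        out[tomo] = mapped
    return out


def sort_by_doublet(
    doublet_table: pd.DataFrame,
    axes: dict[str, dict[int, FilamentTrack]],
    tol_ang: float = 300.0,
) -> pd.DataFrame:
    """Label each record with the doublet number of its nearest axis.

    ``axes`` maps tomogram -> {doublet number -> track in tomogram
    coordinates}.  Records farther than ``tol_ang`` from every axis stay
    unassigned.
    """
    out = doublet_table.copy().reset_index(drop=True)
    labels = pd.array([pd.NA] * len(out), dtype="Int64")
    for tomo in pd.unique(out["tomogram_id"]):
        if tomo not in axes:
            raise ValueError(f"no axes for tomogram {tomo}")
        sel = np.nonzero((out["tomogram_id"] == tomo).to_numpy())[0]
        pos = out.loc[sel, POSITION_COLUMNS].to_numpy(dtype=float)
        dists = []
        numbers = sorted(axes[tomo])
        for num in numbers:
            tr = axes[tomo][num]
            samples = tr.point_at(np.linspace(0, tr.length, 512))
            d = np.min(
                np.linalg.norm(pos[:, None, :] - samples[None, :, :], axis=2),
                axis=1,
            )
            dists.append(d)
        dists = np.vstack(dists)
        best = np.argmin(dists, axis=0)
        ok = dists[best, np.arange(len(sel))] <= tol_ang
        for j, idx in enumerate(sel):
            if ok[j]:
                labels[idx] = numbers[best[j]]
    out["doublet_number"] = labels
    return out


def per_doublet_average(
    stack: np.ndarray,
    table: pd.DataFrame,
    min_count: int = 5,
) -> tuple[dict[int, np.ndarray], dict[int, int], set[int]]:
    """Mean map per doublet number.

    Returns (averages, counts, low_confidence) where low_confidence
    holds the labels whose count fell below ``min_count``.
    """
    labels = table["doublet_number"]
    averages: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    low: set[int] = set()
    for num in sorted(pd.unique(labels.dropna())):
        sel = (labels == num).to_numpy()
        averages[int(num)] = stack[sel].mean(axis=0)
        counts[int(num)] = int(sel.sum())
        if counts[int(num)] < min_count:
            low.add(int(num))
    return averages, counts, low


@dataclass(frozen=True)
class OccupancyProfile:
    """Per-doublet, per-feature occupancy ratios and presence calls."""

    ratios: pd.DataFrame  # index doublet 1-9, columns features
    calls: pd.DataFrame   # present / low / absent

    def to_tsv(self, path) -> None:
        merged = self.ratios.round(3).astype(str) + " (" + self.calls + ")"
        merged.to_csv(path, sep="\t")

    def presence_matrix(self) -> str:
        """Text figure: one row per feature, one column per doublet."""
        symbols = {"present": "#", "low": "+", "absent": "."}
        lines = ["doublet:  " + " ".join(str(d) for d in self.ratios.index)]
        for feat in self.calls.columns:
            marks = " ".join(symbols[c] for c in self.calls[feat])
            lines.append(f"{feat:>22s}  {marks}")
        return "\n".join(lines)


def occupancy_profile(
    averages: dict[int, np.ndarray],
    masks: dict[str, Volume],
    low_threshold: float = 0.25,
    present_threshold: float = 0.75,
) -> OccupancyProfile:
    """Occupancy of each decoration relative to the RS1 reference.

    ratio = (mean under feature mask - background) /
            (mean under RS1 mask - background); calls are 'present'
    above ``present_threshold``, 'absent' below ``low_threshold``, and
    'low' between.  A reference signal at or below background is an
    error (the ratio is undefined).
    """
    bg_mask = masks["background"].data > 0
    ref_mask = masks["rs1"].data > 0
    ratios = {}
    calls = {}
    for num, avg in averages.items():
        bg = float(avg[bg_mask].mean())
        ref = float(avg[ref_mask].mean()) - bg
        if ref <= 0:
            raise ValueError(f"doublet {num}: reference signal below background")
        row_r, row_c = {}, {}
        for feat in FEATURES:
            fm = masks[feat].data > 0
            ratio = (float(avg[fm].mean()) - bg) / ref
            row_r[feat] = max(ratio, 0.0)
            if ratio >= present_threshold:
                row_c[feat] = "present"
            elif ratio >= low_threshold:
                row_c[feat] = "low"
            else:
                row_c[feat] = "absent"
        ratios[num] = row_r
        calls[num] = row_c
    idx = sorted(ratios)
    return OccupancyProfile(
        pd.DataFrame([ratios[i] for i in idx], index=idx),
        pd.DataFrame([calls[i] for i in idx], index=idx),
    )
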