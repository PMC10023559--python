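"""Registry classification of periodic picks.

Picking a 96-nm-repeating filament every 24 nm leaves a fourfold phase
ambiguity: each pick sits at registry 0, 24, 48 or 72 nm within the
repeat.  Supervised classification against four references staggered by
the picking interval resolves the phase; recentering every class on a
shared landmark (the base of RS2) then collapses all registries onto a
single one.  The central-pair analogue is an unsupervised two-class
split of 16-nm picks of the 32-nm-periodic protrusions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .io import EULER_COLUMNS, POSITION_COLUMNS, Volume, euler_to_matrix

__all__ = [
    "make_registry_references",
    "supervised_registry",
    "class_averages",
    "measure_stagger",
    "recenter",
    "focused_two_class",
    "TwoClassResult",
]

_EPS = 1e-12


def _masked_ncc_zero_shift(a: np.ndarray, b: np.ndarray, mask: np.ndarray) -> float:
    """Masked NCC between two boxes at zero displacement."""
    m = mask > 0
    n = m.sum()
    if n == 0:
        raise ValueError("empty mask")
    fa = a[m].astype(float)
    fb = b[m].astype(float)
    fa = fa - fa.mean()
    fb = fb - fb.mean()
    denom = np.sqrt((fa * fa).sum() * (fb * fb).sum())
    return float((fa * fb).sum() / denom) if denom > _EPS else 0.0


def make_registry_references(
    consensus: np.ndarray, spacing_ang: float, k: int, voxel_size_ang: float
) -> list[np.ndarray]:
    """Self-bootstrapped references: the consensus shifted by 0..(k-1) spacings.

    Shifts are applied along the box x-axis with periodic (Fourier)
    wrap, which is exact for a box holding an integer number of repeats.
    """
    if k < 2:
        raise ValueError("need at least two registries")
    refs = []
    shift_vox = spacing_ang / voxel_size_ang
    for j in range(k):
        f = np.fft.fftn(consensus)
        shifted = ndimage.fourier_shift(f, (0.0, 0.0, j * shift_vox))
        refs.append(np.real(np.fft.ifftn(shifted)).astype(np.float32))
    return refs


def supervised_registry(
    stack: np.ndarray,
    table: pd.DataFrame,
    references: list[np.ndarray],
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Assign each pick the registry of its best-correlating reference.

    Returns a copy of ``table`` with ``registry_class`` (0-based) and
    per-record scores; class populations can be read off the column.
    """
    if len(references) < 2:
        raise ValueError("need at least two references")
    shape = stack.shape[1:]
    for r in references:
        if r.shape != shape:
            raise ValueError("reference box does not match stack")
    if mask is None:
        mask = np.ones(shape, dtype=np.float32)
    out = table.copy().reset_index(drop=True)
    labels = np.empty(len(stack), dtype=int)
    scores = np.empty(len(stack))
    for i in range(len(stack)):
        ncc = [_masked_ncc_zero_shift(stack[i], r, mask) for r in references]
        labels[i] = int(np.argmax(ncc))
        scores[i] = max(ncc)
    out["registry_class"] = pd.array(labels, dtype="Int64")
    out["score"] = scores
    return out


def class_averages(stack: np.ndarray, table: pd.DataFrame) -> dict[int, np.ndarray]:
    """Per-registry mean maps."""
    labels = table["registry_class"].to_numpy()
    return {
        int(c): stack[labels == c].mean(axis=0)
        for c in sorted(pd.unique(table["registry_class"].dropna()))
    }


def _axial_shift(a: np.ndarray, b: np.ndarray, voxel_size_ang: float) -> float:
    """Longitudinal (x) displacement of ``b`` relative to ``a`` (A).

    Circular cross-correlation along x only (summed over transverse
    voxels, which keeps off-axis information that plain axial profiles
    would destroy) with three-point parabolic refinement.
    """
    fa = np.fft.fft(a - a.mean(), axis=2)
    fb = np.fft.fft(b - b.mean(), axis=2)
    cc = np.real(np.fft.ifft(fb * np.conj(fa), axis=2)).sum(axis=(0, 1))
    i = int(np.argmax(cc))
    n = len(cc)
    y0, y1, y2 = cc[(i - 1) % n], cc[i], cc[(i + 1) % n]
    denom = y0 - 2 * y1 + y2
    d = 0.5 * (y0 - y2) / denom if abs(denom) > _EPS else 0.0
    shift = i + np.clip(d, -0.5, 0.5)
    if shift > n / 2:
        shift -= n
    return float(shift * voxel_size_ang)


def measure_stagger(
    averages: dict[int, np.ndarray], voxel_size_ang: float, repeat_ang: float
) -> float:
    """Mean longitudinal stagger between consecutive class averages (A).

    Each consecutive pair's displacement is folded modulo the repeat and
    reported as the stagger magnitude min(d, repeat - d); the mean over
    pairs is returned.
    """
    keys = sorted(averages)
    if len(keys) < 2:
        raise ValueError("need at least two class averages")
    staggers = []
    for c0, c1 in zip(keys, keys[1:]):
        d = _axial_shift(averages[c0], averages[c1], voxel_size_ang) % repeat_ang
        staggers.append(min(d, repeat_ang - d))
    return float(np.mean(staggers))


def recenter(
    table: pd.DataFrame,
    landmark_offsets_ang: dict[int, np.ndarray],
    box_extent_ang: tuple[float, float, float] | None = None,
) -> pd.DataFrame:
    """Shift every record so a per-class landmark becomes the box centre.

    ``landmark_offsets_ang`` maps registry class -> (x, y, z) offset of
    the landmark from the box centre, in the box frame (A).  Positions
    move by ``R @ offset`` in the tomogram frame; registry labels are
    cleared (all classes share one phase afterwards).  When the physical
    box extent is given, landmarks outside the box are rejected.
    """
    out = table.copy().reset_index(drop=True)
    if box_extent_ang is not None:
        half = np.asarray(box_extent_ang, dtype=float) / 2.0
        for off in landmark_offsets_ang.values():
            if (np.abs(np.asarray(off, dtype=float)) > half).any():
                raise ValueError(f"landmark offset {off} outside the box")
    for i in range(len(out)):
        cls = out.loc[i, "registry_class"]
        if pd.isna(cls):
            continue
        off = np.asarray(landmark_offsets_ang[int(cls)], dtype=float)
        rot = euler_to_matrix(*out.loc[i, EULER_COLUMNS].to_numpy(dtype=float))
        out.loc[i, POSITION_COLUMNS] = (
            out.loc[i, POSITION_COLUMNS].to_numpy(dtype=float) + rot @ off
        )
    out["registry_class"] = pd.array([pd.NA] * len(out), dtype="Int64")
    return out


@dataclass
class TwoClassResult:
    """Outcome of the focused two-class split."""

    labels: np.ndarray            # 0/1 per particle
    averages: dict[int, np.ndarray]
    populations: np.ndarray       # fractions, sum 1
    offset_ang: float             # longitudinal offset between the averages
    degenerate: bool              # one class below the degeneracy threshold
    n_iter: int


def focused_two_class(
    stack: np.ndarray,
    mask: np.ndarray,
    voxel_size_ang: float,
    seed: int = 0,
    max_iter: int = 25,
    degenerate_frac: float = 0.05,
) -> TwoClassResult:
    """Unsupervised two-class split under a focus mask.

    Iterative assign-to-nearest-class-average with a masked correlation
    metric, initialised from a seeded random split; converges when fewer
    than 1% of labels change.  A split leaving one class below
    ``degenerate_frac`` of the particles is flagged degenerate (the
    expected outcome for a single-registry stack).
    """
    if mask.sum() == 0:
        raise ValueError("empty mask")
    n = len(stack)
    if n < 4:
        raise ValueError("too few particles to classify")
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, size=n)
    if labels.min() == labels.max():
        labels[: n // 2] = 1 - labels[0]
    n_iter = 0
    sums = {c: stack[labels == c].sum(axis=0) for c in (0, 1)}
    counts = {c: int((labels == c).sum()) for c in (0, 1)}
    for n_iter in range(1, max_iter + 1):
        new = np.empty(n, dtype=int)
        for i in range(n):
            scores = []
            for c in (0, 1):
                # leave-one-out mean: a particle must not vote for the
                # class average it is itself part of
                if labels[i] == c:
                    cnt = counts[c] - 1
                    m = (sums[c] - stack[i]) / cnt if cnt > 0 else None
                else:
                    cnt = counts[c]
                    m = sums[c] / cnt if cnt > 0 else None
                scores.append(
                    _masked_ncc_zero_shift(stack[i], m, mask)
                    if m is not None else -np.inf
                )
            new[i] = int(scores[1] > scores[0])
        changed = (new != labels).sum()
        labels = new
        sums = {c: stack[labels == c].sum(axis=0) for c in (0, 1)}
        counts = {c: int((labels == c).sum()) for c in (0, 1)}
        if changed < max(1, int(0.01 * n)):
            break
    averages = {c: stack[labels == c].mean(axis=0) for c in (0, 1)
                if (labels == c).any()}
    counts = np.array([(labels == 0).sum(), (labels == 1).sum()])
    populations = counts / n
    degenerate = bool(populations.min() < degenerate_frac)
    if len(averages) == 2 and not degenerate:
        offset = abs(_axial_shift(averages[0], averages[1], voxel_size_ang))
    else:
        offset = float("nan")
    return TwoClassResult(labels, averages, populations, offset, degenerate, n_iter)
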