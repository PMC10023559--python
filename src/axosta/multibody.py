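"""Relative motion of two rigid bodies across particles.

Refining the radial-spoke unit and the central-pair protrusions as two
independently masked rigid bodies gives, per particle, two alignment
parameter sets — three shifts and three Euler angles each.  The
12-vector of both sets, expressed in the particle frame, describes the
bodies' relative placement; principal-component analysis of those
12-vectors across particles exposes the dominant mode of relative
motion (for bent axonemes: longitudinal inter-filament sliding), and a
quantile binning along PC1 yields a morph series for animation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import align
from .io import (
    EULER_COLUMNS,
    POSITION_COLUMNS,
    Volume,
    euler_to_matrix,
    matrix_to_euler,
)

__all__ = [
    "RELATIVE_POSE_COLUMNS",
    "refine_two_bodies",
    "pca",
    "PCAResult",
    "bin_and_morph",
    "BodyPlacement",
]

RELATIVE_POSE_COLUMNS = [
    f"{body}_{p}" for body in ("a", "b")
    for p in ("dx", "dy", "dz", "alpha", "beta", "gamma")
]

#: Index of the longitudinal (box x) shift of body B within the 12-vector.
LONGITUDINAL_AXIS_B = RELATIVE_POSE_COLUMNS.index("b_dx")


def _residual_params(prior_row, new_row) -> np.ndarray:
    """Shift (A) and Euler residuals (deg) of a refined pose, box frame."""
    r_prior = euler_to_matrix(*prior_row[EULER_COLUMNS].to_numpy(dtype=float))
    r_new = euler_to_matrix(*new_row[EULER_COLUMNS].to_numpy(dtype=float))
    dpos = (new_row[POSITION_COLUMNS].to_numpy(dtype=float)
            - prior_row[POSITION_COLUMNS].to_numpy(dtype=float))
    dt = r_prior.T @ dpos
    ang = matrix_to_euler(r_prior.T @ r_new)
    return np.concatenate([dt, ang])


def refine_two_bodies(
    stack: np.ndarray,
    table: pd.DataFrame,
    ref_a: Volume,
    mask_a: Volume,
    ref_b: Volume,
    mask_b: Volume,
    angular_step: float = 4.0,
    shift_limit_ang: float | None = None,
    overlap_tolerance: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Refine each body locally under its mask; assemble 12-vectors.

    The two masks must be essentially disjoint (overlap below
    ``overlap_tolerance`` of the box).  Returns
    ``(poses_a, poses_b, relative)`` where ``relative`` holds one
    12-parameter row per particle in :data:`RELATIVE_POSE_COLUMNS`
    order (shifts in Angstroms, angles in degrees, particle frame).
    """
    for name, m in (("A", mask_a), ("B", mask_b)):
        if m.data.sum() == 0:
            raise ValueError(f"empty mask for body {name}")
    overlap = float(((mask_a.data > 0) & (mask_b.data > 0)).sum())
    if overlap > overlap_tolerance * mask_a.data.size:
        raise ValueError("body masks overlap beyond tolerance")
    poses = []
    for ref, mask in ((ref_a, mask_a), (ref_b, mask_b)):
        poses.append(align(
            stack, table, ref, mask,
            angular_step=angular_step,
            shift_limit_ang=shift_limit_ang,
            local_only=True,
        ))
    rows = []
    base = table.reset_index(drop=True)
    for i in range(len(base)):
        va = _residual_params(base.loc[i], poses[0].loc[i])
        vb = _residual_params(base.loc[i], poses[1].loc[i])
        rows.append(np.concatenate([va, vb]))
    relative = pd.DataFrame(rows, columns=RELATIVE_POSE_COLUMNS)
    return poses[0], poses[1], relative


@dataclass(frozen=True)
class PCAResult:
    """Eigen-decomposition of the relative-pose covariance."""

    components: np.ndarray          # (12, 12), rows = eigenvectors
    explained_variance: np.ndarray  # eigenvalues, non-increasing
    explained_fraction: np.ndarray  # sums to 1 (0 for rank-0 data)
    projections: np.ndarray         # (n, 12)
    mean: np.ndarray
    scale: np.ndarray               # per-axis divisor (1s when unstandardised)


def pca(relative: pd.DataFrame, standardize: bool = False) -> PCAResult:
    """PCA of the 12-parameter relative poses.

    By default the raw covariance is decomposed — shifts in Angstroms
    and angles in degrees are numerically commensurate for this
    problem, and the direction of the leading component is then
    physically interpretable (e.g. parallel to the longitudinal axis
    under sliding).  ``standardize`` z-scores each axis first instead;
    zero-variance axes are left untouched and receive zero eigenvalue
    either way.
    """
    x = relative[RELATIVE_POSE_COLUMNS].to_numpy(dtype=float)
    if len(x) < x.shape[1] + 1:
        raise ValueError("need at least 13 particles for a 12-D PCA")
    mean = x.mean(axis=0)
    xc = x - mean
    scale = np.ones(x.shape[1])
    if standardize:
        sd = xc.std(axis=0, ddof=1)
        scale = np.where(sd > 0, sd, 1.0)
        xc = xc / scale
    cov = np.cov(xc, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order].T
    # sign gauge: orient each component so its largest entry is positive
    for j in range(evecs.shape[0]):
        lead = np.argmax(np.abs(evecs[j]))
        if evecs[j, lead] < 0:
            evecs[j] = -evecs[j]
    total = evals.sum()
    frac = evals / total if total > 0 else np.zeros_like(evals)
    return PCAResult(
        components=evecs,
        explained_variance=evals,
        explained_fraction=frac,
        projections=xc @ evecs.T,
        mean=mean,
        scale=scale,
    )


@dataclass(frozen=True)
class BodyPlacement:
    """Mean placement of both bodies for one morph frame."""

    mean_vector: np.ndarray  # 12-vector in original units
    shift_a: np.ndarray
    euler_a: np.ndarray
    shift_b: np.ndarray
    euler_b: np.ndarray
    n: int


def bin_and_morph(
    result: PCAResult,
    component: int = 1,
    nbins: int = 10,
) -> list[BodyPlacement]:
    """Quantile-bin particles along a component; one mean pose per bin.

    Particles are ranked by their projection on the chosen component
    (1-based) and split into ``nbins`` equal-count groups (sizes differ
    by at most one); each group's mean 12-vector, back in original
    units, is realised as a paired-body placement.  The ordered list is
    the morph series.
    """
    if nbins < 1:
        raise ValueError("nbins must be >= 1")
    proj = result.projections[:, component - 1]
    if len(proj) < nbins:
        raise ValueError("fewer particles than bins")
    order = np.argsort(proj, kind="stable")
    placements = []
    for chunk in np.array_split(order, nbins):
        centred = result.projections[chunk].mean(axis=0) @ result.components
        vec = centred * result.scale + result.mean
        placements.append(BodyPlacement(
            mean_vector=vec,
            shift_a=vec[0:3], euler_a=vec[3:6],
            shift_b=vec[6:9], euler_b=vec[9:12],
            n=len(chunk),
        ))
    return placements
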