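"""Canned desk-scale experiments combining the pipeline stages.

Each function renders its own phantoms, runs the relevant stages end to
end and returns the measured quantities, so a single call reproduces a
whole experiment from a seed.  Problem sizes are chosen to finish in
seconds to a few minutes on one core while leaving comfortable margins
on every measured quantity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import context, engine, filaments, phantom, registry
from .filaments import FilamentTrack, assign_doublet_numbers
from .io import POSITION_COLUMNS

__all__ = [
    "registry_experiment",
    "cp_split_experiment",
    "periodicity_experiment",
    "asymmetry_experiment",
    "context_contrast_experiment",
    "RegistryOutcome",
    "CPSplitOutcome",
    "AsymmetryOutcome",
]

NM = 10.0
DOUBLET_PICK_NM = 24.0   # doublet picking interval
CP_PICK_NM = 16.0        # central-pair picking interval


@dataclass(frozen=True)
class RegistryOutcome:
    stagger_nm: float
    agreement: float          # fraction matching ground-truth phase
    populations: np.ndarray   # class fractions
    n: int


def registry_experiment(
    seed: int = 0,
    snr: float = 0.5,
    extent_nm: float = 2000.0,
    voxel_ang: float = 20.0,
    k: int = 4,
) -> RegistryOutcome:
    """Pick a noisy doublet filament every 24 nm and classify registries.

    A straight phantom doublet is picked at the doublet interval, the
    picks are classified against ``k`` self-bootstrapped references
    staggered by the picking interval, and the longitudinal stagger
    between consecutive class averages is measured.
    """
    extent = extent_nm * NM
    clean, _ = phantom.render_doublet_filament(extent_ang=extent,
                                               voxel_size_ang=voxel_ang)
    sd = phantom.noise_sd_for_snr(clean.data, snr)
    vol, _ = phantom.render_doublet_filament(
        extent_ang=extent, voxel_size_ang=voxel_ang, noise_sd=sd, seed=seed
    )
    c = (vol.data.shape[1] // 2) * voxel_ang
    track = FilamentTrack(np.array([[0.0, c, c], [extent, c, c]]), "doublet")
    picks = filaments.pick_along(track, DOUBLET_PICK_NM * NM)
    box = int(round(96.0 * NM / voxel_ang))
    stack, kept = engine.extract(vol, picks, box)
    # bootstrap a single-registry consensus from every k-th pick (same
    # phase by construction along one filament), then classify against
    # the k staggered copies
    consensus = stack[::k].mean(axis=0)
    refs = registry.make_registry_references(
        consensus, DOUBLET_PICK_NM * NM, k, voxel_ang
    )
    labelled = registry.supervised_registry(stack, kept, refs)
    labels = labelled["registry_class"].to_numpy(dtype=int)
    idx = np.arange(len(labels))
    agreement = max(
        float((((labels + idx) - c0) % k == 0).mean()) for c0 in range(k)
    )
    averages = registry.class_averages(stack, labelled)
    stagger = registry.measure_stagger(averages, voxel_ang, 96.0 * NM)
    pops = np.array([(labels == c).mean() for c in range(k)])
    return RegistryOutcome(stagger / NM, agreement, pops, len(labels))


@dataclass(frozen=True)
class CPSplitOutcome:
    populations: np.ndarray   # two class fractions
    offset_nm: float
    agreement: float
    degenerate: bool
    n: int


def cp_split_experiment(
    seed: int = 0,
    snr: float = 0.5,
    extent_nm: float = 2000.0,
    voxel_ang: float = 20.0,
) -> CPSplitOutcome:
    """Pick a central-pair phantom every 16 nm and split the registries.

    Focused two-class classification under a protrusion mask separates
    the two 32-nm registries; the class populations and the
    longitudinal offset between the class averages are returned.
    """
    extent = extent_nm * NM
    clean, _ = phantom.render_cp_filament(extent_ang=extent,
                                          voxel_size_ang=voxel_ang)
    sd = phantom.noise_sd_for_snr(clean.data, snr)
    vol, _ = phantom.render_cp_filament(
        extent_ang=extent, voxel_size_ang=voxel_ang, noise_sd=sd, seed=seed
    )
    c = (vol.data.shape[1] // 2) * voxel_ang
    track = FilamentTrack(np.array([[0.0, c, c], [extent, c, c]]), "cp")
    picks = filaments.pick_along(track, CP_PICK_NM * NM)
    box = (64, 64, 32)
    stack, kept = engine.extract(vol, picks, box)
    yy = (np.arange(box[1]) - box[1] // 2)[None, :, None] * voxel_ang
    mask = np.broadcast_to(
        (np.abs(yy) > 260.0) & (np.abs(yy) < 580.0), box
    ).astype(np.float32)
    res = registry.focused_two_class(stack, mask, voxel_ang, seed=seed)
    labels = res.labels
    idx = np.arange(len(labels))
    agreement = max(float((labels == (idx + c0) % 2).mean()) for c0 in range(2))
    return CPSplitOutcome(res.populations, res.offset_ang / NM, agreement,
                          res.degenerate, len(labels))


def periodicity_experiment(
    extent_nm: float = 2000.0,
    voxel_ang: float = 20.0,
    window_nm: tuple[float, float] = (60.0, 150.0),
) -> float:
    """Dominant period (nm) of the radial-spoke trace of a clean doublet."""
    vol, _ = phantom.render_doublet_filament(
        extent_ang=extent_nm * NM, voxel_size_ang=voxel_ang
    )
    rs_row = vol.data.shape[1] // 2 + int(round(phantom.RS_RADIAL_NM * NM
                                                / voxel_ang))
    trace = vol.data[vol.data.shape[0] // 2, rs_row, :]
    spectrum = engine.periodicity(
        trace, voxel_ang, (window_nm[0] * NM, window_nm[1] * NM)
    )
    if spectrum.dominant_ang is None:
        raise RuntimeError("no dominant period found")
    return spectrum.dominant_ang / NM


@dataclass(frozen=True)
class AsymmetryOutcome:
    profile: context.OccupancyProfile
    counts: dict[int, int]
    sorting_accuracy: float
    n_tomograms: int
    matches_mouse: bool


def _expected_mouse_calls() -> pd.DataFrame:
    rows = {}
    for k, flags in phantom.default_mouse_profile().items():
        rows[k] = {
            "barrel": flags.barrel,
            "rs2_rs3_crosslinker": "present" if flags.rs2_rs3_crosslinker
            else "absent",
            "rs3_scaffold": "present" if flags.rs3_scaffold else "absent",
        }
    return pd.DataFrame([rows[k] for k in sorted(rows)], index=sorted(rows))


def asymmetry_experiment(
    seed: int = 0,
    n_tomograms: int = 20,
    snr: float = 0.1,
    extent_nm: float = 528.0,
    voxel_ang: float = 40.0,
    twist_sd_deg: float = 0.0,
) -> AsymmetryOutcome:
    """Recover the mouse decoration asymmetry from noisy phantoms.

    Renders ``n_tomograms`` (9+2) phantoms, context-averages the
    central-pair picks, detects and numbers the nine doublet axes, sorts
    every doublet pick by nearest axis, averages per doublet, and calls
    the per-doublet occupancy of each decoration.
    """
    extent = extent_nm * NM
    clean, _ = phantom.render_axoneme(
        phantom.AxonemeSpec(seed=seed), extent_ang=extent,
        voxel_size_ang=voxel_ang,
    )
    sd = phantom.noise_sd_for_snr(clean.data, snr)
    volumes: dict[str, phantom.Volume] = {}
    cp_tabs, dbl_tabs = [], []
    for j in range(n_tomograms):
        spec = phantom.AxonemeSpec(seed=seed + j, noise_sd=sd,
                                   radial_twist_sd_deg=twist_sd_deg)
        vol, truth = phantom.render_axoneme(spec, extent_ang=extent,
                                            voxel_size_ang=voxel_ang)
        tomo = f"tomo{j}"
        volumes[tomo] = vol
        cp = truth.tables["cp"].copy()
        cp["tomogram_id"] = tomo
        cp_tabs.append(cp.iloc[::3])
        for k in range(1, 10):
            t = truth.tables[f"d{k}"].copy()
            t["tomogram_id"] = tomo
            t["half_set"] = 1 + j % 2
            dbl_tabs.append(t)
    cp_table = pd.concat(cp_tabs, ignore_index=True)
    dbl_table = pd.concat(dbl_tabs, ignore_index=True)
    truth_labels = dbl_table["doublet_number"].to_numpy(dtype=int)
    blind = dbl_table.copy()
    blind["doublet_number"] = pd.NA

    big_box, big_voxel = 40, 80.0
    avg = context.expand_and_average(volumes, cp_table, big_box, big_voxel)
    ring_ang = phantom.AxonemeSpec(seed=seed).ring_radius_nm * NM
    tracks, _ = context.detect_doublet_axes(avg, ring_ang)
    box_center = np.array([(big_box // 2) * big_voxel] * 3)
    per_tomo = context.remap_axes(tracks, cp_table, box_center)
    axes = {}
    for tomo, trs in per_tomo.items():
        rows = cp_table[cp_table["tomogram_id"] == tomo]
        pts = rows[POSITION_COLUMNS].to_numpy(dtype=float)
        cp_axis = FilamentTrack(pts[[0, -1]])
        nums = assign_doublet_numbers(trs, cp_axis, np.array([0.0, 1.0, 0.0]))
        axes[tomo] = {nums[tr.filament_id]: tr for tr in trs}
    labelled = context.sort_by_doublet(blind, axes, tol_ang=300.0)
    got = labelled["doublet_number"]
    accuracy = float((got.to_numpy() == truth_labels).mean())

    unit_box = (24, 24, 24)
    stacks, tabs = [], []
    for tomo, vol in volumes.items():
        rows = labelled[labelled["tomogram_id"] == tomo]
        stack, kept = engine.extract(vol, rows, unit_box)
        stacks.append(stack)
        tabs.append(kept)
    stack = np.concatenate(stacks)
    table = pd.concat(tabs, ignore_index=True)
    averages, counts, _ = context.per_doublet_average(stack, table)
    masks = phantom.feature_masks(voxel_ang, unit_box)
    profile = context.occupancy_profile(averages, masks)
    matches = bool((profile.calls == _expected_mouse_calls()).all().all())
    return AsymmetryOutcome(profile, counts, accuracy, n_tomograms, matches)


def context_contrast_experiment(
    seed: int = 0,
    n_tomograms: int = 20,
    snr: float = 0.1,
    twist_sd_deg: float = 0.0,
    extent_nm: float = 528.0,
    voxel_ang: float = 40.0,
) -> context.AngularProfile:
    """Angular profile of the alignment-free expanded average.

    With ``twist_sd_deg`` = 0 the nine doublets produce nine sharp
    angular peaks; randomising the ring twist smears them away.
    """
    extent = extent_nm * NM
    clean, _ = phantom.render_axoneme(
        phantom.AxonemeSpec(seed=seed), extent_ang=extent,
        voxel_size_ang=voxel_ang,
    )
    sd = phantom.noise_sd_for_snr(clean.data, snr)
    volumes, cp_tabs = {}, []
    for j in range(n_tomograms):
        spec = phantom.AxonemeSpec(seed=seed + 100 + j, noise_sd=sd,
                                   radial_twist_sd_deg=twist_sd_deg)
        vol, truth = phantom.render_axoneme(spec, extent_ang=extent,
                                            voxel_size_ang=voxel_ang)
        tomo = f"tomo{j}"
        volumes[tomo] = vol
        cp = truth.tables["cp"].copy()
        cp["tomogram_id"] = tomo
        cp_tabs.append(cp.iloc[::3])
    cp_table = pd.concat(cp_tabs, ignore_index=True)
    avg = context.expand_and_average(volumes, cp_table, 40, 80.0)
    ring_ang = phantom.AxonemeSpec(seed=seed).ring_radius_nm * NM
    return context.angular_profile(avg, ring_ang)
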