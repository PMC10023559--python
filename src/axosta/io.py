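"""Volumes, particle tables, and the on-disk formats that carry them.

Two containers flow through every stage of the pipeline:

``Volume``
    A 3-D density grid with an isotropic voxel size, stored on disk as
    an MRC2014 map (via gemmi's CCP4/MRC reader-writer).

``ParticleTable``
    A pandas DataFrame of per-subvolume records — position, orientation,
    provenance labels and alignment score — stored as a one-loop
    STAR-dialect file or tab-separated text.

Conventions used throughout the package:

* all lengths are Angstroms; positions are the physical coordinates of
  the *centre* of a particle's box in the tomogram frame;
* orientations are intrinsic ZYZ Euler angles in degrees, the rotation
  that maps the reference (box) frame into the particle's placement in
  the tomogram; angles are normalised to [-180, 180);
* ``Volume.data`` is indexed ``[z, y, x]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import gemmi
import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

__all__ = [
    "Volume",
    "POSITION_COLUMNS",
    "EULER_COLUMNS",
    "PARTICLE_COLUMNS",
    "new_particle_table",
    "validate_particles",
    "normalize_angles",
    "euler_to_matrix",
    "matrix_to_euler",
    "read_volume",
    "write_volume",
    "read_particles",
    "write_particles",
]

POSITION_COLUMNS = ["pos_x", "pos_y", "pos_z"]
EULER_COLUMNS = ["euler_alpha", "euler_beta", "euler_gamma"]
#: Canonical particle-table schema.  Extra columns are carried through I/O
#: untouched as opaque text.
PARTICLE_COLUMNS = [
    "tomogram_id",
    "filament_id",
    "doublet_number",
    *POSITION_COLUMNS,
    *EULER_COLUMNS,
    "registry_class",
    "score",
    "half_set",
]

_MANDATORY = POSITION_COLUMNS + EULER_COLUMNS


@dataclass
class Volume:
    """A density map on a regular lattice with isotropic voxel size.

    Attributes
    ----------
    data:
        float32 array indexed ``[z, y, x]``.
    voxel_size:
        Edge length of one voxel in Angstroms.
    origin:
        Physical (x, y, z) coordinate of voxel ``[0, 0, 0]`` in Angstroms.
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3 or min(self.data.shape) < 1:
            raise ValueError("Volume.data must be a 3-D array with positive dims")
        if not self.voxel_size > 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape_xyz(self) -> tuple[int, int, int]:
        nz, ny, nx = self.data.shape
        return nx, ny, nz

    @property
    def extent_ang(self) -> np.ndarray:
        """Physical (x, y, z) extent of the grid in Angstroms."""
        return np.array(self.shape_xyz, dtype=float) * self.voxel_size

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_size, self.origin.copy())

    def index_of(self, position_ang: np.ndarray) -> np.ndarray:
        """Fractional (x, y, z) voxel index of a physical position."""
        return (np.asarray(position_ang, dtype=float) - self.origin) / self.voxel_size


# ---------------------------------------------------------------------------
# Euler-angle conventions (single source of truth for every module)

def normalize_angles(angles_deg: np.ndarray) -> np.ndarray:
    """Map angles (degrees) into [-180, 180)."""
    a = np.asarray(angles_deg, dtype=float)
    return (a + 180.0) % 360.0 - 180.0


def euler_to_matrix(alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Rotation matrix for intrinsic ZYZ Euler angles in degrees.

    The returned matrix maps reference-frame (box) vectors into the
    tomogram frame: ``v_tomo = R @ v_box``.
    """
    return Rotation.from_euler("ZYZ", [alpha, beta, gamma], degrees=True).as_matrix()


def matrix_to_euler(matrix: np.ndarray) -> np.ndarray:
    """Inverse of :func:`euler_to_matrix`; angles normalised to [-180, 180).

    At beta = 0 the decomposition is degenerate (alpha and gamma
    coalesce); the third angle is set to zero, silently.
    """
    import warnings

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="Gimbal lock")
        ang = Rotation.from_matrix(matrix).as_euler("ZYZ", degrees=True)
    return normalize_angles(ang)


# ---------------------------------------------------------------------------
# Particle tables

def new_particle_table(n: int = 0) -> pd.DataFrame:
    """An empty canonical particle table with ``n`` default rows."""
    return pd.DataFrame(
        {
            "tomogram_id": ["tomo0"] * n,
            "filament_id": ["fil0"] * n,
            "doublet_number": pd.array([pd.NA] * n, dtype="Int64"),
            "pos_x": np.zeros(n),
            "pos_y": np.zeros(n),
            "pos_z": np.zeros(n),
            "euler_alpha": np.zeros(n),
            "euler_beta": np.zeros(n),
            "euler_gamma": np.zeros(n),
            "registry_class": pd.array([pd.NA] * n, dtype="Int64"),
            "score": np.zeros(n),
            "half_set": np.ones(n, dtype=int),
        }
    )


def validate_particles(table: pd.DataFrame) -> pd.DataFrame:
    """Check mandatory columns and invariants; returns the table.

    Raises ``ValueError`` naming any missing mandatory column, on
    non-finite positions, or on an invalid half-set partition.
    """
    missing = [c for c in _MANDATORY if c not in table.columns]
    if missing:
        raise ValueError(f"particle table missing mandatory columns: {missing}")
    pos = table[POSITION_COLUMNS].to_numpy(dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("particle positions must be finite")
    if "half_set" in table.columns:
        hs = set(pd.unique(table["half_set"].dropna()))
        if not hs <= {1, 2}:
            raise ValueError(f"half_set must partition into {{1, 2}}, got {hs}")
    return table


# ---------------------------------------------------------------------------
# MRC volumes (gemmi-backed)

def read_volume(path) -> Volume:
    """Read an MRC2014 map.

    Rejects files without the MRC magic and maps whose voxel size is
    anisotropic (this package assumes cubic voxels throughout).
    """
    path = str(path)
    try:
        with open(path, "rb") as fh:
            header = fh.read(212)
    except FileNotFoundError:
        raise FileNotFoundError(f"no such volume: {path}")
    if len(header) < 212 or header[208:212] not in (b"MAP ", b"MAP\x00"):
        raise ValueError(f"invalid MRC file (bad magic): {path}")
    try:
        m = gemmi.read_ccp4_map(path)
    except Exception as exc:  # pragma: no cover - gemmi error text varies
        raise ValueError(f"invalid MRC file: {path}: {exc}") from exc
    spacing = np.asarray(m.grid.spacing, dtype=float)
    if not np.allclose(spacing, spacing[0], rtol=1e-4):
        raise ValueError(
            f"anisotropic voxel size {tuple(np.round(spacing, 4))} not supported"
        )
    data = np.array(m.grid, copy=True).T.astype(np.float32)  # -> [z, y, x]
    origin = np.array([m.header_float(i) for i in (50, 51, 52)], dtype=float)
    return Volume(data, float(spacing[0]), origin)


def write_volume(volume: Volume, path, overwrite: bool = True) -> None:
    """Write a Volume as an MRC2014 map (mode 2, float32)."""
    if np.isnan(volume.data).any():
        raise ValueError("refusing to serialize a volume containing NaN")
    path = str(path)
    if not overwrite:
        import os

        if os.path.exists(path):
            raise FileExistsError(path)
    nx, ny, nz = volume.shape_xyz
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(volume.data.T))  # (nx, ny, nz)
    m.grid.unit_cell = gemmi.UnitCell(
        nx * volume.voxel_size, ny * volume.voxel_size, nz * volume.voxel_size,
        90.0, 90.0, 90.0,
    )
    m.grid.spacegroup = gemmi.SpaceGroup("P1")
    m.update_ccp4_header()
    for word, value in zip((50, 51, 52), volume.origin):
        m.set_header_float(word, float(value))
    m.write_ccp4_map(path)


# ---------------------------------------------------------------------------
# STAR / TSV particle tables
#
# The STAR dialect written here is a single data block with one loop of
# named columns, the lingua franca of subtomogram-averaging metadata.
# It is intentionally small and is cross-checked in the test suite
# against gemmi's independent STAR parser.

_STAR_BLOCK = "particles"

_INT_COLUMNS = {"doublet_number", "registry_class", "half_set"}
_FLOAT_COLUMNS = set(POSITION_COLUMNS + EULER_COLUMNS + ["score"])


def _coerce_types(df: pd.DataFrame) -> pd.DataFrame:
    for col in df.columns:
        if col in _FLOAT_COLUMNS:
            df[col] = pd.to_numeric(df[col], errors="raise").astype(float)
        elif col in _INT_COLUMNS:
            s = df[col].mask(df[col].astype(str).isin(["", "NA", "<NA>", "nan"]))
            df[col] = pd.array(pd.to_numeric(s, errors="coerce"), dtype="Int64")
    if all(c in df.columns for c in EULER_COLUMNS):
        df[EULER_COLUMNS] = normalize_angles(df[EULER_COLUMNS].to_numpy(dtype=float))
    return df


def _format_cell(value) -> str:
    if value is pd.NA or (isinstance(value, float) and math.isnan(value)):
        return "<NA>"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_particles(table: pd.DataFrame, path) -> None:
    """Write a particle table as STAR (``.star``) or TSV (anything else)."""
    validate_particles(table)
    path = str(path)
    if path.endswith(".star"):
        lines = [f"data_{_STAR_BLOCK}", "", "loop_"]
        lines += [f"_{col} #{i + 1}" for i, col in enumerate(table.columns)]
        for _, row in table.iterrows():
            lines.append("\t".join(_format_cell(v) for v in row))
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        table.to_csv(path, sep="\t", index=False, na_rep="<NA>")


def _parse_star(path: str) -> pd.DataFrame:
    columns: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line or line.startswith("#") or line.startswith("data_"):
                continue
            if line == "loop_":
                in_loop = True
                columns, rows = [], []
                continue
            if in_loop and line.startswith("_"):
                columns.append(line.split()[0].lstrip("_"))
                continue
            if in_loop and columns:
                values = line.split()
                if len(values) != len(columns):
                    raise ValueError(
                        f"STAR row has {len(values)} fields, expected {len(columns)}"
                    )
                rows.append(values)
    if not columns:
        raise ValueError(f"no data loop found in STAR file: {path}")
    return pd.DataFrame(rows, columns=columns)


def read_particles(path) -> pd.DataFrame:
    """Read a STAR or TSV particle table; validates mandatory columns."""
    path = str(path)
    if path.endswith(".star"):
        df = _parse_star(path)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str, na_values=["<NA>"], keep_default_na=False)
    df = _coerce_types(df)
    return validate_particles(df)
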