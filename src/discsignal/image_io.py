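"""Volumetric image and label-map I/O with a fixed anatomical axis convention.

All downstream geometry assumes the canonical axis order

* axis 0 — sagittal slice direction (left–right),
* axis 1 — anterior → posterior, increasing index moves posterior,
* axis 2 — superior → inferior, increasing index moves caudally,

which in NIfTI orientation codes is ``("R", "P", "I")``.  Files are
reoriented on load using their affine, so images written by scanners or
segmentation tools in any orthogonal orientation are accepted.  Intensities
are never rescaled here.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

logger = logging.getLogger("discsignal")

CANONICAL_AXCODES = ("R", "P", "I")
AXIS_NAMES = ("sagittal", "anterior-posterior", "superior-inferior")

#: Disc levels from the first thoracic to the lumbosacral junction, in
#: cranio-caudal order.  ``L5-S`` (a common shorthand) is normalized to
#: ``L5-S1``.
DISC_LEVELS: tuple[str, ...] = tuple(
    [f"T{i}-T{i + 1}" for i in range(1, 12)]
    + ["T12-L1"]
    + [f"L{i}-L{i + 1}" for i in range(1, 5)]
    + ["L5-S1"]
)

CSF_LABEL = 99

#: Default label schema: background 0, discs 1..17 cranio-caudal, CSF 99.
#: Segmentation tools use varying conventions, so the schema is data, not
#: code; this default matches the phantom generator.
DEFAULT_LABEL_SCHEMA: dict[int, str] = {
    0: "background",
    **{i + 1: level for i, level in enumerate(DISC_LEVELS)},
    CSF_LABEL: "csf",
}

GROUPS = ("climber", "control")

MANIFEST_COLUMNS = ("subject_id", "group", "image_path", "labelmap_path")


def normalize_level_name(name: str) -> str:
    """Map shorthand disc-level names onto the canonical scheme."""
    name = name.strip()
    return "L5-S1" if name == "L5-S" else name


@dataclass(frozen=True)
class Volume:
    """A 3D intensity grid in canonical (sagittal, AP, SI) orientation.

    ``data`` holds raw scanner units; ``spacing`` is the per-axis voxel
    size in mm.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    axes: tuple[str, str, str] = AXIS_NAMES

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"Volume requires 3D data, got {self.data.ndim}D")
        if min(self.data.shape) < 1:
            raise ValueError(f"degenerate volume shape {self.data.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass(frozen=True)
class LabelMap:
    """An integer grid on the same lattice as a :class:`Volume`.

    Every nonzero code present in ``data`` must appear in ``label_schema``.
    """

    data: np.ndarray
    label_schema: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_LABEL_SCHEMA))
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.data.ndim != 3:
            raise ValueError(f"LabelMap requires 3D data, got {self.data.ndim}D")
        if not np.issubdtype(self.data.dtype, np.integer):
            raise ValueError(f"LabelMap data must be integer, got dtype {self.data.dtype}")
        present = set(np.unique(self.data).tolist()) - {0}
        unknown = sorted(present - set(self.label_schema))
        if unknown:
            raise ValueError(f"label codes not in schema: {unknown}")

    def labels_present(self) -> list[int]:
        return sorted(set(np.unique(self.data).tolist()) - {0})

    def level_name(self, code: int) -> str:
        return self.label_schema[code]

    def disc_codes(self) -> list[int]:
        """Codes whose schema name is a disc level, cranio-caudal order."""
        order = {lvl: i for i, lvl in enumerate(DISC_LEVELS)}
        codes = [c for c, n in self.label_schema.items() if normalize_level_name(n) in order]
        return sorted(codes, key=lambda c: order[normalize_level_name(self.label_schema[c])])

    def mask(self, code: int) -> np.ndarray:
        return self.data == code


def _canonical_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    """Affine whose axis codes are ("R", "P", "I")."""
    return np.diag([spacing[0], -spacing[1], -spacing[2], 1.0])


def _load_canonical(path: str | os.PathLike) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume, got shape {data.shape}")
    affine = img.affine
    if affine is None or not np.all(np.isfinite(affine)) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError(f"{path}: missing or ambiguous orientation metadata (degenerate affine)")
    ornt = nib.orientations.io_orientation(affine)
    if np.any(np.isnan(ornt)):
        raise ValueError(f"{path}: ambiguous orientation metadata (oblique affine)")
    target = nib.orientations.axcodes2ornt(CANONICAL_AXCODES)
    transform = nib.orientations.ornt_transform(ornt, target)
    data = nib.orientations.apply_orientation(data, transform)
    zooms = np.asarray(img.header.get_zooms()[:3], dtype=float)
    perm = transform[:, 0].astype(int)
    spacing = tuple(float(zooms[perm[i]]) for i in range(3))
    return data, spacing


def load_volume(path: str | os.PathLike) -> Volume:
    """Load a NIfTI intensity volume and reorient it to canonical axes."""
    data, spacing = _load_canonical(path)
    return Volume(np.asarray(data, dtype=np.float64), spacing)


def save_volume(volume: Volume, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(np.asarray(volume.data, dtype=np.float64), _canonical_affine(volume.spacing))
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def load_labelmap(
    path: str | os.PathLike, label_schema: dict[int, str] | None = None
) -> LabelMap:
    """Load an integer label map; codes must be covered by the schema."""
    data, spacing = _load_canonical(path)
    arr = np.asarray(data)
    if not np.issubdtype(arr.dtype, np.integer):
        rounded = np.rint(arr)
        if not np.allclose(arr, rounded, atol=1e-6):
            raise ValueError(f"{path}: label map contains non-integer values")
        arr = rounded.astype(np.int32)
    schema = dict(DEFAULT_LABEL_SCHEMA) if label_schema is None else dict(label_schema)
    return LabelMap(arr.astype(np.int32), schema, spacing)


def save_labelmap(labelmap: LabelMap, path: str | os.PathLike) -> None:
    img = nib.Nifti1Image(
        np.asarray(labelmap.data, dtype=np.int16), _canonical_affine(labelmap.spacing)
    )
    img.header.set_zooms(labelmap.spacing)
    nib.save(img, str(path))


def validate_pair(volume: Volume, labelmap: LabelMap) -> tuple[Volume, LabelMap]:
    """Check that an intensity volume and a label map share a lattice."""
    if volume.shape != labelmap.data.shape:
        raise ValueError(
            f"shape mismatch: volume {volume.shape} vs labelmap {labelmap.data.shape}"
        )
    vs, ls = np.asarray(volume.spacing), np.asarray(labelmap.spacing)
    if not np.allclose(vs, ls, rtol=1e-3):
        raise ValueError(f"spacing mismatch: volume {tuple(vs)} vs labelmap {tuple(ls)}")
    return volume, labelmap


def load_manifest(path: str | os.PathLike) -> pd.DataFrame:
    """Read and validate a subject manifest CSV.

    Columns: subject_id, group (climber/control), image_path, labelmap_path.
    Relative paths are resolved against the manifest's directory.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: manifest missing columns {missing}")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"{path}: duplicate subject ids {dups}")
    bad = sorted(set(df["group"]) - set(GROUPS))
    if bad:
        raise ValueError(f"{path}: unknown groups {bad}; expected {GROUPS}")
    base = path.parent
    for col in ("image_path", "labelmap_path"):
        df[col] = [str(p) if os.path.isabs(p) else str(base / p) for p in df[col]]
    return df.reset_index(drop=True)


def save_manifest(df: pd.DataFrame, path: str | os.PathLike) -> None:
    df.to_csv(path, index=False)
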