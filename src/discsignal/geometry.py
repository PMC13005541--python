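"""Midsagittal slice selection and anterior–posterior disc subregioning.

A disc occupying E sagittal slices contributes its 3 (E odd) or 4 (E even)
central slices.  Within each selected slice the disc mask is split into
``n_bins`` equal-width bins along an anterior–posterior axis — either the
in-slice principal axis of the mask (default; discs at the thoracolumbar
junction are inclined) or the image AP axis.  Bin 1 is anterior, bin
``n_bins`` posterior.  Intervals are half-open [lo, hi) with the last bin
closed, so every masked voxel lands in exactly one bin.

A fine partition (25 bins) nests exactly inside the coarse one (5 bins):
bin edges are the fractions k/n of the projection range, and 5j/25 == j/5
holds bitwise in IEEE arithmetic, so grouping fine bins in runs of five
reproduces the coarse assignment voxel for voxel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .image_io import LabelMap

logger = logging.getLogger("discsignal")

AXIS_MODES = ("principal", "image")


class DiscNotFoundError(ValueError):
    pass


class InsufficientExtentError(ValueError):
    """Disc spans fewer than 3 sagittal slices and is excluded."""


@dataclass(frozen=True)
class SliceSelection:
    disc_label: int
    slice_indices: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.slice_indices)
        if not 3 <= n <= 4:
            raise ValueError(f"slice selection must contain 3 or 4 slices, got {n}")


@dataclass(frozen=True)
class SubregionPartition:
    """Per-voxel AP bin assignment for one disc.

    ``voxels`` is an (N, 3) integer array of canonical voxel indices and
    ``bins`` the matching 1-based bin index (1 anterior .. n_bins
    posterior).  ``axis_definition`` records, per slice, the unit (AP, SI)
    axis actually used, for reproducibility.
    """

    disc_label: int
    n_bins: int
    voxels: np.ndarray
    bins: np.ndarray
    axis_definition: dict[int, tuple[float, float]]
    mode: str

    def __post_init__(self) -> None:
        if self.voxels.shape[0] != self.bins.shape[0]:
            raise ValueError("voxels and bins length mismatch")
        if self.bins.size and not (1 <= self.bins.min() and self.bins.max() <= self.n_bins):
            raise ValueError("bin index outside 1..n_bins")

    @property
    def n_voxels(self) -> int:
        return int(self.voxels.shape[0])

    def bin_counts(self) -> np.ndarray:
        """Voxel count per bin, length n_bins (bin 1 first)."""
        return np.bincount(self.bins, minlength=self.n_bins + 1)[1:]


def select_midsagittal_slices(labelmap: LabelMap, disc_label: int) -> SliceSelection:
    """Pick the 3 or 4 central sagittal slices of a disc.

    E = number of sagittal slices containing the disc.  E odd: the three
    slices centred on the voxel-count-weighted centre slice (ties to the
    lower index), window clamped inside the extent.  E even: the central
    four slices of the extent.  E < 3 excludes the disc.
    """
    counts = np.count_nonzero(labelmap.data == disc_label, axis=(1, 2))
    present = np.nonzero(counts)[0]
    if present.size == 0:
        raise DiscNotFoundError(f"disc not found: label {disc_label}")
    if present.size < 3:
        raise InsufficientExtentError(
            f"insufficient sagittal extent for label {disc_label}: "
            f"{present.size} slice(s)"
        )
    e = present.size
    if e == 3 or e == 4:
        chosen = present
    elif e % 2 == 1:
        c = counts[present].astype(float)
        com = float(np.sum(present * c) / np.sum(c))
        # nearest present slice; np.argmin takes the first (lower) on ties
        pos = int(np.argmin(np.abs(present - com)))
        pos = min(max(pos, 1), e - 2)
        chosen = present[pos - 1 : pos + 2]
    else:
        half = e // 2
        chosen = present[half - 2 : half + 2]
    return SliceSelection(disc_label, tuple(int(i) for i in chosen))


def compute_ap_axis(
    labelmap: LabelMap, disc_label: int, slice_index: int, mode: str = "principal"
) -> np.ndarray:
    """Unit AP axis of a disc within one sagittal slice, as an (AP, SI) vector.

    ``principal``: first principal direction of the in-slice voxel scatter
    (mm coordinates), sign-fixed so the AP component is positive.
    ``image``: the image AP axis, (1, 0).  Degenerate masks (< 3 voxels or
    collinear) fall back to the image axis with a warning.
    """
    if mode not in AXIS_MODES:
        raise ValueError(f"unknown axis mode {mode!r}; expected one of {AXIS_MODES}")
    ap, si = np.nonzero(labelmap.data[slice_index] == disc_label)
    if ap.size == 0:
        raise DiscNotFoundError(
            f"disc label {disc_label} empty in slice {slice_index}"
        )
    if mode == "image":
        return np.array([1.0, 0.0])
    coords = np.column_stack([ap * labelmap.spacing[1], si * labelmap.spacing[2]])
    if coords.shape[0] < 3:
        logger.warning(
            "label %d slice %d: degenerate mask (%d voxels), using image axis",
            disc_label, slice_index, coords.shape[0],
        )
        return np.array([1.0, 0.0])
    cov = np.cov(coords.T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[-1] <= 0 or evals[-1] < 1e-12 * max(1.0, abs(evals[0])):
        logger.warning(
            "label %d slice %d: collinear mask, using image axis", disc_label, slice_index
        )
        return np.array([1.0, 0.0])
    axis = evecs[:, -1]
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis
    return axis / np.linalg.norm(axis)


def _bin_edges(lo: float, hi: float, n_bins: int) -> np.ndarray:
    # fractions k/n make fine (25) and coarse (5) edges bitwise-nested
    return lo + (hi - lo) * (np.arange(1, n_bins) / n_bins)


def _assign_bins(proj: np.ndarray, n_bins: int) -> np.ndarray:
    lo, hi = float(proj.min()), float(proj.max())
    if hi == lo:
        # zero AP extent: place everything in the central bin
        return np.full(proj.shape, (n_bins + 1) // 2, dtype=np.int32)
    edges = _bin_edges(lo, hi, n_bins)
    return np.searchsorted(edges, proj, side="right").astype(np.int32) + 1


def partition_disc(
    labelmap: LabelMap,
    selection: SliceSelection,
    n_bins: int,
    mode: str = "principal",
    pooled: bool = False,
) -> SubregionPartition:
    """Partition a disc's selected-slice voxels into AP bins.

    Per slice (default) or pooled over slices, voxel centres are projected
    onto the AP axis; the projection range is split into ``n_bins``
    equal-width half-open intervals (last closed).  Slices with fewer
    voxels than ``n_bins`` are skipped for the fine partition.
    """
    if n_bins not in (5, 25):
        raise ValueError(f"n_bins must be 5 or 25, got {n_bins}")
    if mode not in AXIS_MODES:
        raise ValueError(f"unknown axis mode {mode!r}; expected one of {AXIS_MODES}")
    spacing = labelmap.spacing
    vox_list, bin_list = [], []
    axis_definition: dict[int, tuple[float, float]] = {}

    slice_data: list[tuple[int, np.ndarray, np.ndarray]] = []
    for s in selection.slice_indices:
        ap, si = np.nonzero(labelmap.data[s] == selection.disc_label)
        if ap.size == 0:
            logger.warning(
                "label %d: empty mask in selected slice %d, skipping",
                selection.disc_label, s,
            )
            continue
        if ap.size < n_bins:
            logger.warning(
                "label %d slice %d: %d voxels < %d bins, slice skipped",
                selection.disc_label, s, ap.size, n_bins,
            )
            continue
        slice_data.append((s, ap, si))

    if pooled and slice_data:
        all_coords = np.concatenate(
            [np.column_stack([ap * spacing[1], si * spacing[2]]) for _, ap, si in slice_data]
        )
        if mode == "principal" and all_coords.shape[0] >= 3:
            cov = np.cov(all_coords.T)
            evals, evecs = np.linalg.eigh(cov)
            axis = evecs[:, -1]
            if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
                axis = -axis
        else:
            axis = np.array([1.0, 0.0])
        proj_all = all_coords @ axis
        bins_all = _assign_bins(proj_all, n_bins)
        offset = 0
        for s, ap, si in slice_data:
            axis_definition[s] = (float(axis[0]), float(axis[1]))
            vox = np.column_stack([np.full(ap.shape, s), ap, si]).astype(np.int32)
            vox_list.append(vox)
            bin_list.append(bins_all[offset : offset + ap.size])
            offset += ap.size
    else:
        for s, ap, si in slice_data:
            axis = compute_ap_axis(labelmap, selection.disc_label, s, mode)
            axis_definition[s] = (float(axis[0]), float(axis[1]))
            proj = ap * spacing[1] * axis[0] + si * spacing[2] * axis[1]
            bins = _assign_bins(proj, n_bins)
            vox = np.column_stack([np.full(ap.shape, s), ap, si]).astype(np.int32)
            vox_list.append(vox)
            bin_list.append(bins)

    if vox_list:
        voxels = np.concatenate(vox_list)
        bins = np.concatenate(bin_list)
    else:
        voxels = np.empty((0, 3), dtype=np.int32)
        bins = np.empty((0,), dtype=np.int32)
    return SubregionPartition(
        selection.disc_label, n_bins, voxels, bins, axis_definition, mode
    )


def coarsen_partition(fine: SubregionPartition) -> SubregionPartition:
    """Group a 25-bin partition into 5 bins: fine bin b → ceil(b/5)."""
    if fine.n_bins != 25:
        raise ValueError(f"coarsen_partition expects 25 bins, got {fine.n_bins}")
    coarse_bins = ((fine.bins - 1) // 5 + 1).astype(np.int32)
    return SubregionPartition(
        fine.disc_label, 5, fine.voxels, coarse_bins, dict(fine.axis_definition), fine.mode
    )


def partition_to_overlay(partitions: list[SubregionPartition], shape: tuple[int, ...]) -> np.ndarray:
    """Integer QC overlay: per-disc bin codes on a zero background."""
    out = np.zeros(shape, dtype=np.int16)
    for p in partitions:
        out[p.voxels[:, 0], p.voxels[:, 1], p.voxels[:, 2]] = p.bins
    return out


def partition_counts_frame(partitions: list[SubregionPartition]) -> pd.DataFrame:
    """Tidy per-bin voxel counts for QC export."""
    rows = []
    for p in partitions:
        counts = p.bin_counts()
        for b in range(1, p.n_bins + 1):
            rows.append((p.disc_label, p.n_bins, b, int(counts[b - 1])))
    return pd.DataFrame(rows, columns=["disc_label", "n_bins", "bin", "n_voxels"])
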