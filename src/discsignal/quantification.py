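"""CSF normalization and per-disc / per-subregion signal statistics.

Intensities are divided by the mean raw signal over all CSF-labelled voxels
of the same image, which removes the arbitrary scanner scaling and makes
subjects comparable (CSF mean ≡ 1 after normalization).  Per disc, the mean
and population SD of the normalized signal are computed for the whole
selected midsagittal region and for every AP subregion at both
granularities; group-level profiles summarize subjects by the median and
interquartile range per fine bin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .geometry import SubregionPartition, coarsen_partition
from .image_io import CSF_LABEL, LabelMap, Volume, normalize_level_name

logger = logging.getLogger("discsignal")

LONG_TABLE_COLUMNS = ("subject_id", "group", "disc", "subregion", "mean_signal", "sd", "n_voxels")


@dataclass(frozen=True)
class NormalizedVolume:
    """Intensity grid divided by the image's mean CSF signal."""

    data: np.ndarray
    csf_mean: float
    csf_voxel_count: int

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape


@dataclass(frozen=True)
class DiscProfile:
    """Normalized signal statistics for one subject × disc level.

    ``per_subregion`` maps granularity (5 or 25) to a DataFrame with
    columns bin, mean, sd, n_voxels; empty bins carry count 0 and NaN mean.
    """

    subject_id: str
    disc_label: int
    level: str
    whole_region_mean: float
    whole_region_sd: float
    n_voxels: int
    per_subregion: dict[int, pd.DataFrame] = field(default_factory=dict)


@dataclass(frozen=True)
class GroupProfile:
    """Median (IQR) across subjects of per-bin subject means, one group × disc."""

    group: str
    level: str
    n_bins: int
    median: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    n_subjects: int


def normalize_to_csf(
    volume: Volume, labelmap: LabelMap, csf_label: int = CSF_LABEL
) -> NormalizedVolume:
    """Divide every voxel by the mean raw intensity over the CSF mask."""
    csf = labelmap.data == csf_label
    n = int(np.count_nonzero(csf))
    if n == 0:
        raise ValueError(f"no CSF label ({csf_label}) in label map")
    mu = float(volume.data[csf].mean())
    if mu <= 0:
        raise ValueError(f"CSF mean is non-positive ({mu})")
    return NormalizedVolume(volume.data / mu, mu, n)


def _bin_stats(values: np.ndarray, bins: np.ndarray, n_bins: int) -> pd.DataFrame:
    counts = np.bincount(bins, minlength=n_bins + 1)[1:].astype(np.int64)
    sums = np.bincount(bins, weights=values, minlength=n_bins + 1)[1:]
    sq = np.bincount(bins, weights=values**2, minlength=n_bins + 1)[1:]
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(counts > 0, sq / np.maximum(counts, 1) - means**2, np.nan)
    sds = np.sqrt(np.maximum(var, 0.0))
    return pd.DataFrame(
        {
            "bin": np.arange(1, n_bins + 1),
            "mean": means,
            "sd": np.where(counts > 0, sds, np.nan),
            "n_voxels": counts,
        }
    )


def disc_signal_stats(
    normalized: NormalizedVolume,
    partition: SubregionPartition,
    subject_id: str = "",
    level: str = "",
) -> DiscProfile:
    """Mean and population SD per AP bin and over the whole selected region.

    Given a 25-bin partition, 5-bin statistics are derived from the nested
    coarse assignment so fine and coarse granularities describe the same
    voxel set.
    """
    if partition.voxels.size and (
        partition.voxels[:, 0].max() >= normalized.shape[0]
        or partition.voxels[:, 1].max() >= normalized.shape[1]
        or partition.voxels[:, 2].max() >= normalized.shape[2]
    ):
        raise ValueError("partition voxel indices outside the normalized volume grid")
    vox = partition.voxels
    values = normalized.data[vox[:, 0], vox[:, 1], vox[:, 2]]
    per: dict[int, pd.DataFrame] = {
        partition.n_bins: _bin_stats(values, partition.bins, partition.n_bins)
    }
    if partition.n_bins == 25:
        coarse = coarsen_partition(partition)
        per[5] = _bin_stats(values, coarse.bins, 5)
    whole_mean = float(values.mean()) if values.size else float("nan")
    whole_sd = float(values.std()) if values.size else float("nan")
    return DiscProfile(
        subject_id=subject_id,
        disc_label=partition.disc_label,
        level=normalize_level_name(level) if level else str(partition.disc_label),
        whole_region_mean=whole_mean,
        whole_region_sd=whole_sd,
        n_voxels=int(values.size),
        per_subregion=per,
    )


def _group_of(manifest: pd.DataFrame) -> dict[str, str]:
    return dict(zip(manifest["subject_id"], manifest["group"]))


def aggregate_group_profiles(
    profiles: list[DiscProfile], manifest: pd.DataFrame, n_bins: int = 25
) -> list[GroupProfile]:
    """Median and IQR across subjects of per-bin subject means.

    Subjects missing a disc level (or with an empty bin) are excluded from
    that level/bin only; empty bins are never imputed.
    """
    groups = _group_of(manifest)
    if not groups:
        raise ValueError("manifest has no subjects")
    tbl: dict[tuple[str, str], list[np.ndarray]] = {}
    for p in profiles:
        if n_bins not in p.per_subregion:
            continue
        g = groups.get(p.subject_id)
        if g is None:
            raise ValueError(f"subject {p.subject_id!r} not in manifest")
        tbl.setdefault((g, p.level), []).append(p.per_subregion[n_bins]["mean"].to_numpy())
    present_groups = {g for g, _ in tbl}
    for g in sorted(set(groups.values())):
        if g not in present_groups:
            raise ValueError(f"no subjects with profiles in group {g!r}")
    out = []
    for (g, level), rows in sorted(tbl.items()):
        arr = np.vstack(rows)
        out.append(
            GroupProfile(
                group=g,
                level=level,
                n_bins=n_bins,
                median=np.nanmedian(arr, axis=0),
                q25=np.nanpercentile(arr, 25, axis=0),
                q75=np.nanpercentile(arr, 75, axis=0),
                n_subjects=arr.shape[0],
            )
        )
    return out


def group_profiles_frame(profiles: list[GroupProfile]) -> pd.DataFrame:
    rows = []
    for gp in profiles:
        for b in range(gp.n_bins):
            rows.append(
                (gp.group, gp.level, b + 1, gp.median[b], gp.q25[b], gp.q75[b], gp.n_subjects)
            )
    return pd.DataFrame(
        rows, columns=["group", "disc", "bin", "median", "q25", "q75", "n_subjects"]
    )


def build_long_table(
    profiles: list[DiscProfile], manifest: pd.DataFrame, n_bins: int | str = 5
) -> pd.DataFrame:
    """Tidy (subject, group, disc, subregion, mean_signal) observations.

    ``n_bins`` ∈ {5, 25} selects subregion granularity; ``"all"`` emits the
    per-disc whole-region variant with subregion = "all".
    """
    if not profiles:
        raise ValueError("no disc profiles supplied")
    groups = _group_of(manifest)
    rows = []
    for p in profiles:
        g = groups.get(p.subject_id)
        if g is None:
            raise ValueError(f"subject {p.subject_id!r} not in manifest")
        if n_bins == "all":
            rows.append(
                (p.subject_id, g, p.level, "all", p.whole_region_mean, p.whole_region_sd, p.n_voxels)
            )
        else:
            if n_bins not in p.per_subregion:
                raise ValueError(f"profile for {p.subject_id}/{p.level} lacks {n_bins}-bin stats")
            for rec in p.per_subregion[n_bins].itertuples(index=False):
                rows.append((p.subject_id, g, p.level, str(rec.bin), rec.mean, rec.sd, rec.n_voxels))
    df = pd.DataFrame(rows, columns=list(LONG_TABLE_COLUMNS))
    dup = df.duplicated(subset=["subject_id", "disc", "subregion"])
    if dup.any():
        keys = df.loc[dup, ["subject_id", "disc", "subregion"]].values.tolist()
        raise ValueError(f"duplicate (subject, disc, subregion) rows: {keys[:5]}")
    return df
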