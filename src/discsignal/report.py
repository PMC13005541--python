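"""Publication-style outputs: profile plots, forest plots, contrast tables.

Plots are QC/visualization artifacts; every numeric result is also written
as CSV, and each output file carries a JSON metadata sidecar (config hash,
software version, geometry and df options) sufficient to reproduce it.
Forest-plot significance marks are derived from the confidence interval
excluding zero — the same criterion as the p-value, never a separate path.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .image_io import DISC_LEVELS

_GROUP_STYLE = {"climber": ("tab:blue", "--"), "control": ("tab:orange", "-")}


def _config_hash(metadata: dict) -> str:
    blob = json.dumps(metadata, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_sidecar(path: str | Path, metadata: dict) -> Path:
    from . import __version__

    meta = dict(metadata)
    meta["software_version"] = __version__
    meta["config_hash"] = _config_hash(metadata)
    side = Path(str(path) + ".meta.json")
    side.write_text(json.dumps(meta, indent=2, sort_keys=True, default=str))
    return side


def write_table(df: pd.DataFrame, path: str | Path, metadata: dict | None = None) -> Path:
    path = Path(path)
    df.to_csv(path, index=False)
    write_sidecar(path, metadata or {})
    return path


def contrast_table(contrasts: pd.DataFrame) -> pd.DataFrame:
    """Round a contrast frame into the published table layout."""
    out = contrasts.copy()
    out["significant"] = (out["ci_low"] > 0) | (out["ci_high"] < 0)
    for c in ("lsmean_climbers", "se_climbers", "lsmean_controls", "se_controls",
              "difference", "ci_low", "ci_high"):
        out[c] = out[c].round(4)
    return out


def _disc_sort_key(levels: pd.Series) -> pd.Series:
    order = {lvl: i for i, lvl in enumerate(DISC_LEVELS)}
    return levels.map(lambda v: order.get(v, len(order)))


def profile_plot(group_profiles: pd.DataFrame, path: str | Path) -> Path:
    """Per-disc AP signal profiles: median curve with IQR band per group.

    One panel per disc level; dashed vertical lines mark the coarse
    5-subregion boundaries within the 25 fine bins.
    """
    levels = sorted(group_profiles["disc"].unique(), key=lambda v: _disc_sort_key(pd.Series([v]))[0])
    ncol = 4
    nrow = int(np.ceil(len(levels) / ncol))
    fig, axes = plt.subplots(nrow, ncol, figsize=(3.2 * ncol, 2.4 * nrow), sharex=True)
    axes = np.atleast_2d(axes)
    for i, level in enumerate(levels):
        ax = axes[i // ncol][i % ncol]
        sub = group_profiles[group_profiles["disc"] == level]
        for grp, gdf in sub.groupby("group"):
            color, ls = _GROUP_STYLE.get(grp, ("gray", "-"))
            gdf = gdf.sort_values("bin")
            ax.plot(gdf["bin"], gdf["median"], ls, color=color, label=grp, lw=1.2)
            ax.fill_between(gdf["bin"], gdf["q25"], gdf["q75"], color=color, alpha=0.2, lw=0)
        for edge in (5.5, 10.5, 15.5, 20.5):
            ax.axvline(edge, color="0.8", ls="--", lw=0.6)
        ax.set_title(level, fontsize=8)
        ax.tick_params(labelsize=7)
    for j in range(len(levels), nrow * ncol):
        axes[j // ncol][j % ncol].set_visible(False)
    handles, labels = axes[0][0].get_legend_handles_labels()
    fig.legend(handles, labels, loc="lower right", fontsize=8)
    fig.supxlabel("anterior → posterior fine subregion", fontsize=9)
    fig.supylabel("normalized T2 signal (CSF = 1)", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)


def forest_plot(contrasts: pd.DataFrame, path: str | Path, title: str = "") -> Path:
    """Forest plot of control − climber differences with 95% CI whiskers.

    Filled markers: CI excludes zero (significant); open markers: not.
    """
    df = contrasts.copy()
    df["order"] = _disc_sort_key(df["disc"])
    df = df.sort_values(["subregion", "order"], kind="stable").reset_index(drop=True)
    multi = df["subregion"].nunique() > 1
    labels = [
        f"{r.disc} [{r.subregion}]" if multi else r.disc for r in df.itertuples(index=False)
    ]
    y = np.arange(len(df))[::-1]
    sig = (df["ci_low"] > 0) | (df["ci_high"] < 0)
    fig_h = max(2.5, 0.22 * len(df) + 1.2)
    fig, ax = plt.subplots(figsize=(6, fig_h))
    ax.axvline(0.0, color="0.4", lw=1)
    ax.hlines(y, df["ci_low"], df["ci_high"], color="0.2", lw=1)
    ax.plot(df.loc[sig, "difference"], y[sig.to_numpy()], "o", color="0.1", ms=4)
    ax.plot(df.loc[~sig, "difference"], y[(~sig).to_numpy()], "o", mfc="white", mec="0.1", ms=4)
    ax.set_yticks(y)
    ax.set_yticklabels(labels, fontsize=7)
    ax.set_xlabel("difference in normalized signal mean (control − climber)", fontsize=8)
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return Path(path)
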