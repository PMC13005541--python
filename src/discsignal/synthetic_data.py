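"""Synthetic sagittal spine phantoms with known ground truth.

A phantom emulates a 12-slice sagittal T2-weighted acquisition covering
T1–S1: 17 intervertebral discs drawn as tilted ellipses in the (AP, SI)
plane (tilt increasing caudally), a bright cerebrospinal-fluid stripe
posterior to the column, vertebral bodies between the discs, and Rician
noise on the final magnitude image.  Disc tissue follows an
annulus-baseline-plus-nucleus-bump intensity profile along the disc's
major axis; the bump peaks centrally in lumbar discs and more posteriorly
in thoracic discs.  Subject-level random intercepts, per-bin residual
texture, and a configurable control − climber signal loss over selected
(disc, bin) cells give simulated cohorts exactly the statistical structure
the mixed model assumes, with a closed-form truth table for every bin.

All randomness flows through ``numpy.random.default_rng`` seeded
explicitly, so identical (config, seed) pairs yield bit-identical output.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import integrate

from .image_io import (
    DISC_LEVELS,
    LabelMap,
    Volume,
    save_labelmap,
    save_manifest,
    save_volume,
)
from .reference import default_group_effect

logger = logging.getLogger("discsignal")

TRUTH_COLUMNS = ("subject_id", "group", "disc", "bin", "expected_mean", "delta")


@dataclass(frozen=True)
class DiscSpec:
    """Geometry and nucleus profile of one disc level (mm, degrees)."""

    level: str
    ap_center: float
    si_center: float
    ap_half_width: float
    si_half_height: float
    tilt_deg: float
    nucleus_peak: float  # peak position as fraction of the AP extent


def default_disc_specs(
    shape: tuple[int, int, int], spacing: tuple[float, float, float]
) -> tuple[DiscSpec, ...]:
    """17 disc levels, growing and tilting caudally.

    Thoracic nucleus peaks sit posteriorly (fraction 0.62), thoracolumbar
    and lumbar peaks centrally (0.52), reproducing the posterior shift of
    the nucleus in the thoracic spine.
    """
    si_mm = shape[2] * spacing[2]
    margin = 18.0 * si_mm / 320.0
    centers = np.linspace(margin, si_mm - margin, len(DISC_LEVELS))
    half_w = np.linspace(14.0, 22.0, len(DISC_LEVELS))
    half_h = np.linspace(2.6, 4.6, len(DISC_LEVELS))
    tilt = np.linspace(0.0, 15.0, len(DISC_LEVELS))
    ap_center = 40.0 * shape[1] * spacing[1] / 96.0
    specs = []
    for i, level in enumerate(DISC_LEVELS):
        peak = 0.62 if level.startswith("T") and level != "T12-L1" else 0.52
        specs.append(
            DiscSpec(level, ap_center, float(centers[i]), float(half_w[i]),
                     float(half_h[i]), float(tilt[i]), peak)
        )
    return tuple(specs)


@dataclass(frozen=True)
class PhantomConfig:
    """Full description of the phantom and cohort-generating process.

    Intensities are arbitrary scanner units; after CSF normalization the
    annulus sits near 0.14 and the nucleus peak near 0.45, matching
    healthy-disc profiles.  ``noise_sigma`` is the Gaussian channel SD of
    the Rician noise (default gives nucleus SNR ≈ 20); ``sigma_b`` and
    ``sigma_e`` are the subject-intercept and residual-texture SDs on the
    normalized scale.  ``group_effect`` maps disc level → {coarse bin: Δ}
    subtracted from climbers (default: the reference thoracolumbar
    template, nucleus bins 2–4 of T10–L4).
    """

    shape: tuple[int, int, int] = (12, 96, 320)
    spacing: tuple[float, float, float] = (3.0, 1.0, 1.0)
    csf_intensity: float = 1000.0
    annulus_intensity: float = 140.0
    nucleus_amplitude: float = 330.0
    nucleus_width: float = 0.20
    vertebra_intensity: float = 260.0
    background_intensity: float = 40.0
    csf_ap_range: tuple[float, float] = (68.0, 76.0)
    noise_sigma: float = 23.0
    sigma_b: float = 0.03
    sigma_e: float = 0.02
    group_effect: dict[str, dict[int, float]] = field(default_factory=default_group_effect)
    n_climbers: int = 15
    n_controls: int = 15
    seed: int = 0
    discs: tuple[DiscSpec, ...] = ()

    def __post_init__(self) -> None:
        if not self.discs:
            object.__setattr__(self, "discs", default_disc_specs(self.shape, self.spacing))
        for name in ("csf_intensity", "annulus_intensity", "nucleus_amplitude",
                     "vertebra_intensity", "background_intensity"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.noise_sigma < 0 or self.sigma_b < 0 or self.sigma_e < 0:
            raise ValueError("noise and variance parameters must be non-negative")
        if self.n_climbers < 1 or self.n_controls < 1:
            raise ValueError("need at least one subject per group")
        for d in self.discs:
            if not 0.0 < d.nucleus_peak < 1.0:
                raise ValueError(f"{d.level}: nucleus peak must be in (0, 1)")
        self._validate_geometry()

    def _validate_geometry(self) -> None:
        ap_mm = self.shape[1] * self.spacing[1]
        si_mm = self.shape[2] * self.spacing[2]
        for d in self.discs:
            th = math.radians(d.tilt_deg)
            ap_ext = math.hypot(d.ap_half_width * math.cos(th), d.si_half_height * math.sin(th))
            si_ext = math.hypot(d.ap_half_width * math.sin(th), d.si_half_height * math.cos(th))
            if d.ap_center - ap_ext < 0 or d.ap_center + ap_ext > ap_mm:
                raise ValueError(f"geometry overflow at {d.level}: disc exceeds AP grid extent")
            if d.si_center - si_ext < 0 or d.si_center + si_ext > si_mm:
                raise ValueError(f"geometry overflow at {d.level}: disc exceeds SI grid extent")
            if d.ap_center + ap_ext >= self.csf_ap_range[0]:
                raise ValueError(f"geometry overflow at {d.level}: disc reaches the CSF canal")
        if self.csf_ap_range[1] > ap_mm:
            raise ValueError("CSF canal outside the AP grid extent")

    def disc(self, level: str) -> DiscSpec:
        for d in self.discs:
            if d.level == level:
                return d
        raise KeyError(f"unknown disc level {level!r}")


def _profile(config: PhantomConfig, spec: DiscSpec, t: np.ndarray) -> np.ndarray:
    """Raw tissue intensity along the AP fraction t of a disc."""
    return config.annulus_intensity + config.nucleus_amplitude * np.exp(
        -((t - spec.nucleus_peak) ** 2) / (2.0 * config.nucleus_width**2)
    )


def _fine_delta(config: PhantomConfig, level: str) -> np.ndarray:
    """Δ per fine bin (length 25) for climbers at one level."""
    out = np.zeros(25)
    for coarse, delta in config.group_effect.get(level, {}).items():
        out[(coarse - 1) * 5 : coarse * 5] = delta
    return out


def generate_phantom(
    config: PhantomConfig, subject_seed: int, group: str = "control", subject_id: str = ""
) -> tuple[Volume, LabelMap, pd.DataFrame]:
    """Render one subject's image, label map and per-bin truth table.

    Deterministic given (config, subject_seed, group).  The truth table
    lists, per disc × fine bin, the noise-free expected normalized mean
    including the subject intercept, bin texture and (for climbers) the
    injected Δ.
    """
    if group not in ("climber", "control"):
        raise ValueError(f"group must be climber or control, got {group!r}")
    rng = np.random.default_rng(subject_seed)
    nx, ny, nz = config.shape
    sy, sz = config.spacing[1], config.spacing[2]
    img2d = np.full((ny, nz), config.background_intensity)
    lab2d = np.zeros((ny, nz), dtype=np.int32)

    ap_mm = (np.arange(ny) * sy)[:, None]
    si_mm = (np.arange(nz) * sz)[None, :]

    # vertebral column band (behind the discs, anterior of the canal)
    v_lo = min(d.ap_center - d.ap_half_width for d in config.discs)
    v_hi = max(d.ap_center + d.ap_half_width for d in config.discs)
    vert = (ap_mm >= v_lo) & (ap_mm < v_hi) & (si_mm >= 6.0) & (si_mm < nz * sz - 6.0)
    img2d[np.broadcast_to(vert, img2d.shape)] = config.vertebra_intensity

    csf = (ap_mm >= config.csf_ap_range[0]) & (ap_mm < config.csf_ap_range[1])
    csf = np.broadcast_to(csf, img2d.shape)
    img2d[csf] = config.csf_intensity
    lab2d[csf] = 99

    b = rng.normal(0.0, config.sigma_b) if config.sigma_b > 0 else 0.0
    truth_rows = []
    for code, spec in enumerate(config.discs, start=1):
        e = rng.normal(0.0, config.sigma_e, size=25) if config.sigma_e > 0 else np.zeros(25)
        delta = _fine_delta(config, spec.level) if group == "climber" else np.zeros(25)
        th = math.radians(spec.tilt_deg)
        dap = ap_mm - spec.ap_center
        dsi = si_mm - spec.si_center
        u = dap * math.cos(th) + dsi * math.sin(th)
        v = -dap * math.sin(th) + dsi * math.cos(th)
        mask = (u / spec.ap_half_width) ** 2 + (v / spec.si_half_height) ** 2 <= 1.0
        t = (u[mask] + spec.ap_half_width) / (2.0 * spec.ap_half_width)
        fine = np.clip(np.floor(t * 25).astype(int), 0, 24)
        vals = _profile(config, spec, t) + (b + e[fine] - delta[fine]) * config.csf_intensity
        img2d[mask] = np.maximum(vals, 0.0)
        lab2d[mask] = code
        cf = closed_form_bin_means(config, spec.level)
        for k in range(25):
            truth_rows.append(
                (subject_id, group, spec.level, k + 1, cf[k] + b + e[k] - delta[k], delta[k])
            )

    img = np.broadcast_to(img2d, (nx, ny, nz)).copy()
    lab = np.broadcast_to(lab2d, (nx, ny, nz)).copy()
    if config.noise_sigma > 0:
        s = config.noise_sigma
        img = np.hypot(img + rng.normal(0.0, s, img.shape), rng.normal(0.0, s, img.shape))
    volume = Volume(img, config.spacing)
    labelmap = LabelMap(lab, spacing=config.spacing)
    truth = pd.DataFrame(truth_rows, columns=list(TRUTH_COLUMNS))
    return volume, labelmap, truth


def closed_form_bin_means(config: PhantomConfig, level: str, n_bins: int = 25) -> np.ndarray:
    """Analytic expected normalized mean per AP bin of a noise-free disc.

    The bin mean is the chord-weighted average of the intensity profile
    over the bin's AP fraction interval: weight h(t) = √(t(1−t)) (elliptic
    chord), normalized by the CSF intensity.
    """
    spec = config.disc(level)

    def h(t):
        return np.sqrt(np.maximum(t * (1.0 - t), 0.0))

    out = np.empty(n_bins)
    for k in range(n_bins):
        lo, hi = k / n_bins, (k + 1) / n_bins
        num, _ = integrate.quad(lambda t: _profile(config, spec, np.asarray(t)) * h(t), lo, hi)
        den, _ = integrate.quad(h, lo, hi)
        out[k] = num / den / config.csf_intensity
    return out


def rician_mean(nu: float, sigma: float) -> float:
    """E[√((ν+X)² + Y²)] with X, Y ~ N(0, σ²), by numerical integration.

    The noise-floor bias of MR magnitude images; used as an oracle for the
    noisy phantom's expected bin means.
    """
    if sigma == 0:
        return float(nu)
    upper = nu + 12 * sigma

    def integrand(m):
        # Rice pdf via logs to avoid overflow in i0
        z = m * nu / sigma**2
        log_i0 = np.log(np.i0(z)) if z < 700 else z - 0.5 * np.log(2 * np.pi * z)
        return m * np.exp(np.log(m / sigma**2) - (m**2 + nu**2) / (2 * sigma**2) + log_i0)

    val, _ = integrate.quad(integrand, 0.0, upper, limit=200)
    return float(val)


def simulate_cohort(
    config: PhantomConfig, out_dir: str | Path
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Write a full image cohort: NIfTI pairs, manifest CSV, truth CSV.

    The master ``config.seed`` drives per-subject seeds, so the whole
    cohort is reproducible from the config alone.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    subjects = [("climber", f"climber{i + 1:02d}") for i in range(config.n_climbers)]
    subjects += [("control", f"control{i + 1:02d}") for i in range(config.n_controls)]
    seeds = rng.integers(0, 2**31 - 1, size=len(subjects))
    manifest_rows, truths = [], []
    for (group, sid), seed in zip(subjects, seeds):
        vol, lab, truth = generate_phantom(config, int(seed), group, subject_id=sid)
        img_path = out_dir / f"{sid}_t2.nii.gz"
        lab_path = out_dir / f"{sid}_labels.nii.gz"
        try:
            save_volume(vol, img_path)
            save_labelmap(lab, lab_path)
        except OSError as exc:
            raise OSError(f"failed writing phantom for {sid} under {out_dir}: {exc}") from exc
        manifest_rows.append((sid, group, img_path.name, lab_path.name))
        truths.append(truth)
    manifest = pd.DataFrame(
        manifest_rows, columns=["subject_id", "group", "image_path", "labelmap_path"]
    )
    truth = pd.concat(truths, ignore_index=True)
    save_manifest(manifest, out_dir / "manifest.csv")
    truth.to_csv(out_dir / "truth.csv", index=False)
    # resolve paths for the returned frame, as load_manifest would
    manifest = manifest.assign(
        image_path=[str(out_dir / p) for p in manifest["image_path"]],
        labelmap_path=[str(out_dir / p) for p in manifest["labelmap_path"]],
    )
    return manifest, truth


def simulate_signal_table(
    rng: np.random.Generator,
    n_per_group: int = 15,
    disc_levels: tuple[str, ...] = DISC_LEVELS,
    subregions: tuple[str, ...] = ("all",),
    baseline: float = 0.35,
    sigma_b: float = 0.03,
    sigma_e: float = 0.02,
    effect: dict[tuple[str, str], float] | None = None,
) -> pd.DataFrame:
    """Draw a tidy long table directly from the mixed model's assumptions.

    y = baseline + b_subject + ε − Δ(disc, subregion)·[climber], with
    b ~ N(0, σ_b²) and ε ~ N(0, σ_e²) iid.  This is the fast,
    image-free cohort generator used for calibration and power studies of
    the stats module.
    """
    effect = effect or {}
    rows = []
    for group, n in (("climber", n_per_group), ("control", n_per_group)):
        for s in range(n):
            sid = f"{group}{s + 1:02d}"
            b = rng.normal(0.0, sigma_b)
            eps = rng.normal(0.0, sigma_e, size=(len(disc_levels), len(subregions)))
            for i, disc in enumerate(disc_levels):
                for j, sub in enumerate(subregions):
                    y = baseline + b + eps[i, j]
                    if group == "climber":
                        y -= effect.get((disc, str(sub)), 0.0)
                    rows.append((sid, group, disc, str(sub), y))
    return pd.DataFrame(rows, columns=["subject_id", "group", "disc", "subregion", "mean_signal"])
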