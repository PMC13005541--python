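"""Mixed-model group comparison of disc signal means.

The model for a subregion (or whole-disc) table is the Gaussian linear
mixed model

    mean_signal ~ group + disc + group:disc + (1 | subject)

fitted by REML.  The random subject intercept with iid residuals induces a
compound-symmetry within-subject covariance (constant variance
σ_b² + σ_e², constant non-negative intra-subject correlation
σ_b² / (σ_b² + σ_e²)).  Sliced comparisons evaluate the control − climber
contrast within each disc level on the least-squares-mean scale, with
two-sided 95% confidence limits.

Degrees of freedom use a Satterthwaite approximation computed from the
REML profile likelihood: for a contrast l the variance C(θ) = l'(X'V⁻¹X)⁻¹l
is differentiated (numerically) with respect to θ = (σ_b², σ_e²), and
ν = 2 C² / (g' A g) with A the inverse observed REML information.  In
balanced complete designs this coincides with classical (and
Kenward–Roger) degrees of freedom; ``df_method="kenward_roger"`` is
accepted and served by the same approximation, which is recorded in the
output.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import patsy
from scipy import stats as sps
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

from .image_io import DISC_LEVELS, GROUPS

logger = logging.getLogger("discsignal")

DF_METHODS = ("satterthwaite", "kenward_roger", "residual")

FORMULA = "mean_signal ~ C(group) * C(disc)"


@dataclass(frozen=True)
class ModelSpec:
    """Specification of the group × disc mixed model."""

    response: str = "mean_signal"
    df_method: str = "satterthwaite"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.df_method not in DF_METHODS:
            raise ValueError(f"df_method must be one of {DF_METHODS}, got {self.df_method!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


@dataclass(frozen=True)
class ContrastResult:
    """Sliced group comparison at one disc level (and subregion)."""

    disc: str
    subregion: str
    lsmean_climbers: float
    se_climbers: float
    lsmean_controls: float
    se_controls: float
    difference: float  # control − climber; positive = controls higher
    ci_low: float
    ci_high: float
    p_value: float
    df: float
    df_method: str


class _RemlParts:
    """Per-subject sufficient statistics for the random-intercept model.

    With V_i = σ_e² I + σ_b² J per subject, Woodbury gives
    V_i⁻¹ = (I − c_i J)/σ_e² with c_i = σ_b²/(σ_e² + n_i σ_b²), so all
    quantities reduce to X'X, X'y, y'y and per-subject row/response sums.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray, subject_codes: np.ndarray):
        self.X, self.y = X, y
        self.n_obs, self.p = X.shape
        n_subj = int(subject_codes.max()) + 1
        self.S = np.zeros((n_subj, self.p))  # per-subject column sums of X
        np.add.at(self.S, subject_codes, X)
        self.t = np.bincount(subject_codes, weights=y, minlength=n_subj)
        self.n_i = np.bincount(subject_codes, minlength=n_subj).astype(float)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.rank = int(np.linalg.matrix_rank(X))

    def _pieces(self, sb2: float, se2: float):
        c = sb2 / (se2 + self.n_i * sb2)
        xtvx = (self.XtX - (self.S * c[:, None]).T @ self.S) / se2
        xtvy = (self.Xty - self.S.T @ (c * self.t)) / se2
        ytvy = (self.yty - float(c @ self.t**2)) / se2
        return xtvx, xtvy, ytvy

    def gls(self, sb2: float, se2: float) -> tuple[np.ndarray, np.ndarray]:
        """GLS fixed effects and their covariance at variance components θ."""
        xtvx, xtvy, _ = self._pieces(sb2, se2)
        cov = np.linalg.pinv(xtvx)
        return cov @ xtvy, cov

    def contrast_var(self, l: np.ndarray, sb2: float, se2: float) -> float:
        xtvx, _, _ = self._pieces(sb2, se2)
        return float(l @ np.linalg.pinv(xtvx) @ l)

    def reml_loglike(self, sb2: float, se2: float) -> float:
        xtvx, xtvy, ytvy = self._pieces(sb2, se2)
        logdet_v = float(np.sum((self.n_i - 1) * np.log(se2) + np.log(se2 + self.n_i * sb2)))
        sign, logdet_x = np.linalg.slogdet(xtvx)
        beta = np.linalg.pinv(xtvx) @ xtvy
        ypy = ytvy - float(beta @ xtvy)
        return -0.5 * (logdet_v + logdet_x + ypy)


@dataclass
class MixedModelFit:
    """Fitted group × disc mixed model plus everything contrasts need."""

    spec: ModelSpec
    data: pd.DataFrame
    design_info: object
    beta: np.ndarray
    sigma_b2: float
    sigma_e2: float
    converged: bool
    parts: _RemlParts
    disc_levels: tuple[str, ...]
    group_levels: tuple[str, ...]
    n_obs: int
    result: object = field(repr=False, default=None)

    def design_row(self, group: str, disc: str) -> np.ndarray:
        new = pd.DataFrame({"group": [group], "disc": [disc]})
        return np.asarray(patsy.dmatrix(self.design_info, new))[0]


def _ordered_disc_levels(values: pd.Series) -> list[str]:
    present = list(dict.fromkeys(values))
    order = {lvl: i for i, lvl in enumerate(DISC_LEVELS)}
    if all(v in order for v in present):
        return sorted(present, key=order.__getitem__)
    return sorted(present)


def fit_mixed_model(long_table: pd.DataFrame, spec: ModelSpec | None = None) -> MixedModelFit:
    """Fit the group × disc random-intercept model by REML.

    Rows with missing ``mean_signal`` (empty subregions) are dropped.
    Requires both groups, ≥2 subjects per group and ≥2 disc levels.
    """
    spec = spec or ModelSpec()
    required = {"subject_id", "group", "disc", spec.response}
    missing = required - set(long_table.columns)
    if missing:
        raise ValueError(f"long table missing columns {sorted(missing)}")
    df = long_table.dropna(subset=[spec.response]).copy()
    if len(df) < len(long_table):
        logger.warning("dropped %d rows with missing response", len(long_table) - len(df))
    if spec.response != "mean_signal":
        df = df.rename(columns={spec.response: "mean_signal"})

    glv = sorted(set(df["group"]))
    if len(glv) < 2:
        raise ValueError(f"group factor has a single level: {glv}; need both of {GROUPS}")
    for g in glv:
        nsub = df.loc[df["group"] == g, "subject_id"].nunique()
        if nsub < 2:
            raise ValueError(f"group {g!r} has {nsub} subject(s); need at least 2")
    disc_levels = _ordered_disc_levels(df["disc"])
    if len(disc_levels) < 2:
        raise ValueError(f"need at least 2 disc levels, got {disc_levels}")
    df["disc"] = pd.Categorical(df["disc"], categories=disc_levels, ordered=True)
    cells = set(zip(df["group"].astype(str), df["disc"].astype(str)))
    for d in disc_levels:
        for g in glv:
            if (g, d) not in cells:
                raise ValueError(
                    f"contrast not estimable at disc {d}: no data for group {g!r}"
                )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore", UserWarning)
        model = smf.mixedlm(FORMULA, df, groups=df["subject_id"])
        try:
            result = model.fit(reml=True, method="bfgs")
        except np.linalg.LinAlgError:  # pragma: no cover - optimizer path dependent
            result = None
        if result is None or not result.converged:  # pragma: no cover
            result = model.fit(reml=True)
    if not result.converged:
        raise RuntimeError(
            "mixed model failed to converge; optimizer history: "
            f"{getattr(result, 'hist', None)}"
        )
    sigma_b2 = float(np.asarray(result.cov_re)[0, 0])
    sigma_e2 = float(result.scale)
    if sigma_b2 <= 1e-12 * max(sigma_e2, 1e-300):
        logger.warning("subject variance component estimated at zero (boundary)")

    design_info = result.model.data.design_info
    X = np.asarray(result.model.exog, dtype=float)
    y = np.asarray(result.model.endog, dtype=float)
    codes = pd.Categorical(df["subject_id"]).codes.astype(int)
    parts = _RemlParts(X, y, codes)
    beta = np.asarray(result.fe_params, dtype=float)

    return MixedModelFit(
        spec=spec,
        data=df,
        design_info=design_info,
        beta=beta,
        sigma_b2=sigma_b2,
        sigma_e2=sigma_e2,
        converged=bool(result.converged),
        parts=parts,
        disc_levels=tuple(disc_levels),
        group_levels=tuple(glv),
        n_obs=len(df),
        result=result,
    )


class _SatterthwaiteWorkspace:
    """Per-fit cache for Satterthwaite df: the observed REML information
    and the GLS covariance at perturbed variance components are the same
    for every contrast, so they are computed once per fitted model."""

    def __init__(self, fit: MixedModelFit):
        parts, sb2, se2 = fit.parts, fit.sigma_b2, fit.sigma_e2
        self.resid_df = float(max(parts.n_obs - parts.rank, 1))
        self.boundary = sb2 <= 1e-10 * se2
        theta = np.array([se2] if self.boundary else [sb2, se2])
        k = theta.size

        def full(th):
            return (0.0, th[0]) if self.boundary else (th[0], th[1])

        def cov_at(th):
            xtvx, _, _ = parts._pieces(*full(th))
            return np.linalg.pinv(xtvx)

        def ll(th):
            return parts.reml_loglike(*full(th))

        self.cov0 = cov_at(theta)
        h = theta * 1e-4
        self.h = h
        self.cov_plus, self.cov_minus = [], []
        for j in range(k):
            e = np.zeros(k)
            e[j] = h[j]
            self.cov_plus.append(cov_at(theta + e))
            self.cov_minus.append(cov_at(theta - e))
        hs = theta * 1e-3
        H = np.zeros((k, k))
        f0 = ll(theta)
        for j in range(k):
            e = np.zeros(k)
            e[j] = hs[j]
            H[j, j] = (ll(theta + e) - 2 * f0 + ll(theta - e)) / hs[j] ** 2
        for j in range(k):
            for m in range(j + 1, k):
                ej, em = np.zeros(k), np.zeros(k)
                ej[j], em[m] = hs[j], hs[m]
                H[j, m] = H[m, j] = (
                    ll(theta + ej + em) - ll(theta + ej - em)
                    - ll(theta - ej + em) + ll(theta - ej - em)
                ) / (4 * hs[j] * hs[m])
        info = -H
        self.A = None
        if np.all(np.isfinite(info)) and np.linalg.eigvalsh(info).min() > 0:
            self.A = np.linalg.inv(info)
        else:
            logger.warning("REML information not positive definite; using residual df")

    def df(self, l: np.ndarray) -> float:
        if self.A is None:
            return self.resid_df
        k = len(self.h)
        grad = np.array(
            [
                (l @ self.cov_plus[j] @ l - l @ self.cov_minus[j] @ l) / (2 * self.h[j])
                for j in range(k)
            ]
        )
        denom = float(grad @ self.A @ grad)
        C = float(l @ self.cov0 @ l)
        if denom <= 0 or not np.isfinite(denom):
            return self.resid_df
        return float(np.clip(2.0 * C**2 / denom, 1.0, self.resid_df))


def _satterthwaite_df(fit: MixedModelFit, l: np.ndarray) -> float:
    ws = getattr(fit, "_satt_ws", None)
    if ws is None:
        ws = _SatterthwaiteWorkspace(fit)
        fit._satt_ws = ws
    return ws.df(l)


def _df_for(fit: MixedModelFit, l: np.ndarray) -> tuple[float, str]:
    method = fit.spec.df_method
    if method == "residual":
        return float(max(fit.parts.n_obs - fit.parts.rank, 1)), "residual"
    nu = _satterthwaite_df(fit, l)
    # kenward_roger is served by the same small-sample approximation; the
    # two coincide for balanced complete designs (see methods note)
    label = "satterthwaite" if method == "satterthwaite" else "kenward_roger~satterthwaite"
    return nu, label


def sliced_contrasts(fit: MixedModelFit, subregion: str = "all") -> list[ContrastResult]:
    """Per-disc LS means by group and the control − climber difference.

    LS means are model cell means at each (group, disc); their SEs and the
    difference SE come from the GLS covariance at the REML variance
    components, so the CI and p-value are coherent (p < α ⇔ CI excludes 0).
    """
    observed = set(zip(fit.data["group"].astype(str), fit.data["disc"].astype(str)))
    out = []
    crit_q = 1.0 - fit.spec.alpha / 2.0
    for disc in fit.disc_levels:
        for g in fit.group_levels:
            if (g, disc) not in observed:
                raise ValueError(f"contrast not estimable at disc {disc}: no data for group {g!r}")
        row_cl = fit.design_row("climber", disc)
        row_co = fit.design_row("control", disc)
        l = row_co - row_cl
        ls_cl = float(row_cl @ fit.beta)
        ls_co = float(row_co @ fit.beta)
        se_cl = float(np.sqrt(fit.parts.contrast_var(row_cl, fit.sigma_b2, fit.sigma_e2)))
        se_co = float(np.sqrt(fit.parts.contrast_var(row_co, fit.sigma_b2, fit.sigma_e2)))
        diff = ls_co - ls_cl
        se = float(np.sqrt(fit.parts.contrast_var(l, fit.sigma_b2, fit.sigma_e2)))
        if se <= 0 or not np.isfinite(se):
            raise ValueError(f"degenerate contrast at disc {disc}: SE={se}")
        df, label = _df_for(fit, l)
        tcrit = float(sps.t.ppf(crit_q, df))
        tval = diff / se
        p = float(2.0 * sps.t.sf(abs(tval), df))
        out.append(
            ContrastResult(
                disc=disc,
                subregion=subregion,
                lsmean_climbers=ls_cl,
                se_climbers=se_cl,
                lsmean_controls=ls_co,
                se_controls=se_co,
                difference=diff,
                ci_low=diff - tcrit * se,
                ci_high=diff + tcrit * se,
                p_value=p,
                df=df,
                df_method=label,
            )
        )
    return out


def contrasts_to_frame(results: list[ContrastResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def run_per_subregion(long_table: pd.DataFrame, spec: ModelSpec | None = None) -> pd.DataFrame:
    """One model fit per subregion; Table-2-shaped contrast output.

    Failures in a subregion are logged and isolated; remaining subregions
    are still produced.
    """
    spec = spec or ModelSpec()
    if "subregion" not in long_table.columns:
        raise ValueError("long table has no 'subregion' column")
    subs = list(dict.fromkeys(long_table["subregion"].astype(str)))
    subs.sort(key=lambda s: (0, int(s)) if s.isdigit() else (1, s))
    frames = []
    for sub in subs:
        sdf = long_table[long_table["subregion"].astype(str) == sub]
        try:
            fit = fit_mixed_model(sdf, spec)
            frames.append(contrasts_to_frame(sliced_contrasts(fit, subregion=sub)))
        except Exception as exc:  # isolate per-subregion failures
            logger.error("subregion %s failed: %s", sub, exc)
    if not frames:
        raise ValueError("all subregion fits failed")
    return pd.concat(frames, ignore_index=True)
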