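"""Mixed-model analysis of ARE-luciferase reporter screens.

Wells are normalised to same-plate empty-vector baselines, the log2 fold
changes are fitted to a linear mixed model with fixed condition, cell-line
and condition x cell-line effects and a random intercept per plate
(estimated by REML), contrasts are tested with Satterthwaite-approximated
degrees of freedom, p-values are Bonferroni-corrected, and each partner is
classified by its pattern of effects across wild-type, NRF2-null and
derepressed (NRF2-T80K / KEAP1-null) cell lines.

The REML fit is profiled: for a single random intercept the criterion is a
one-dimensional function of the variance ratio ``lambda = sigma_plate^2 /
sigma_resid^2``; fixed effects and the residual variance have closed forms
given lambda, so the optimiser only searches that one axis.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "LmmFit",
    "ContrastResult",
    "PartnerClassification",
    "normalise_luciferase",
    "build_design",
    "fit_reporter_lmm",
    "satterthwaite_contrast",
    "adjust_bonferroni",
    "partner_contrast_table",
    "classify_partner_effect",
]

DEREPRESSED_LINES = ("NRF2_T80K_T80K", "NRF2_T80K_null", "KEAP1_KO")
NRF2_NULL_LINES = ("NRF2_KO_1", "NRF2_KO_2")


# ---------------------------------------------------------------------------
# Normalisation
# ---------------------------------------------------------------------------


def normalise_luciferase(
    obs: pd.DataFrame,
    baseline_condition: str = "empty_vector",
    fl_col: str = "fl",
    rl_col: str = "rl",
) -> pd.DataFrame:
    """Per-well firefly/Renilla ratios as log2 fold change over baseline.

    The baseline of a well is the geometric mean of the same-plate,
    same-cell-line empty-vector ratios.  Plates lacking an empty-vector
    baseline for a cell line are excluded with a warning.  Returns a copy
    with a ``log2_fc`` column; baseline wells are retained (their mean
    log2_fc is 0 per plate/cell-line by construction).
    """
    required = {"plate", "cell_line", "condition", fl_col, rl_col}
    missing = required - set(obs.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    df = obs.copy()
    if np.any(df[fl_col] <= 0) or np.any(df[rl_col] <= 0):
        raise ValueError("luminescences must be positive before ratio computation")
    df["_log2_ratio"] = np.log2(df[fl_col] / df[rl_col])
    base = (
        df[df["condition"] == baseline_condition]
        .groupby(["plate", "cell_line"])["_log2_ratio"]
        .mean()
        .rename("_baseline")
    )
    df = df.join(base, on=["plate", "cell_line"])
    dropped = df["_baseline"].isna()
    if dropped.any():
        bad = sorted(df.loc[dropped, ["plate", "cell_line"]].apply(tuple, axis=1).unique())
        warnings.warn(
            f"excluding {int(dropped.sum())} wells lacking an empty-vector baseline: {bad}",
            stacklevel=2,
        )
        df = df[~dropped]
    df["log2_fc"] = df["_log2_ratio"] - df["_baseline"]
    return df.drop(columns=["_log2_ratio", "_baseline"])


# ---------------------------------------------------------------------------
# Design matrix
# ---------------------------------------------------------------------------


@dataclass
class Design:
    X: np.ndarray
    y: np.ndarray
    groups: np.ndarray  # integer plate index per row
    columns: list[str]
    group_labels: list[str]


def build_design(
    data: pd.DataFrame,
    response: str = "log2_ratio",
    reference_condition: str = "empty_vector",
    reference_cell_line: str = "WT",
    interaction: bool = True,
) -> Design:
    """Treatment-coded fixed-effects design with plate grouping.

    Columns: intercept, ``condition[x]`` for each non-reference condition,
    ``cell_line[l]`` for each non-reference line, and (optionally) their
    interactions.  Empty levels are dropped; a rank-deficient design raises
    with the aliased columns listed.
    """
    df = data.reset_index(drop=True)
    conds = [c for c in pd.unique(df["condition"]) if c != reference_condition]
    lines = [l for l in pd.unique(df["cell_line"]) if l != reference_cell_line]
    cols: dict[str, np.ndarray] = {"intercept": np.ones(len(df))}
    for c in sorted(conds):
        cols[f"condition[{c}]"] = (df["condition"] == c).to_numpy(float)
    for l in sorted(lines):
        cols[f"cell_line[{l}]"] = (df["cell_line"] == l).to_numpy(float)
    if interaction:
        for c in sorted(conds):
            for l in sorted(lines):
                col = cols[f"condition[{c}]"] * cols[f"cell_line[{l}]"]
                if col.any():
                    cols[f"condition[{c}]:cell_line[{l}]"] = col
    names = list(cols)
    X = np.column_stack([cols[k] for k in names])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify aliased columns by pivoted QR
        from scipy.linalg import qr as _qr

        _, _, piv = _qr(X, pivoting=True, mode="economic")
        aliased = [names[i] for i in piv[rank:]]
        raise ValueError(f"design is rank deficient; aliased terms: {aliased}")
    labels = sorted(pd.unique(df["plate"]))
    idx = {p: i for i, p in enumerate(labels)}
    groups = df["plate"].map(idx).to_numpy(int)
    return Design(X=X, y=df[response].to_numpy(float), groups=groups,
                  columns=names, group_labels=labels)


# ---------------------------------------------------------------------------
# REML random-intercept fit
# ---------------------------------------------------------------------------


@dataclass
class LmmFit:
    """REML fit of ``y = X beta + Z b + e`` with one intercept per plate."""

    params: pd.Series
    se: pd.Series
    cov_params: pd.DataFrame
    sigma_plate2: float
    sigma_resid2: float
    loglik: float
    n: int
    p: int
    design: Design = field(repr=False)

    @property
    def columns(self) -> list[str]:
        return list(self.params.index)


def _group_blocks(groups: np.ndarray) -> list[np.ndarray]:
    order = np.argsort(groups, kind="stable")
    blocks = []
    for g in np.unique(groups):
        blocks.append(np.nonzero(groups == g)[0])
    del order
    return blocks


def _profiled_reml(lam: float, X: np.ndarray, y: np.ndarray,
                   blocks: list[np.ndarray]) -> tuple[float, np.ndarray, np.ndarray, float]:
    """REML log-likelihood profiled over beta and sigma^2 at variance ratio
    lambda; returns (loglik, beta, XtViX_inv, sigma2_hat)."""
    n, p = X.shape
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet_v = 0.0
    for idx in blocks:
        Xi = X[idx]
        yi = y[idx]
        ni = len(idx)
        shrink = lam / (1.0 + lam * ni)
        sx = Xi.sum(axis=0)
        sy = yi.sum()
        xtvx += Xi.T @ Xi - shrink * np.outer(sx, sx)
        xtvy += Xi.T @ yi - shrink * sx * sy
        ytvy += yi @ yi - shrink * sy * sy
        logdet_v += math.log1p(lam * ni)
    xtvx_inv = np.linalg.inv(xtvx)
    beta = xtvx_inv @ xtvy
    rss = ytvy - beta @ xtvy  # r' V^-1 r at the GLS solution
    sigma2 = rss / (n - p)
    sign, logdet_xtvx = np.linalg.slogdet(xtvx)
    if sign <= 0:
        return -np.inf, beta, xtvx_inv, sigma2
    ll = -0.5 * (
        (n - p) * math.log(2.0 * math.pi)
        + (n - p) * math.log(sigma2)
        + logdet_v
        + logdet_xtvx
        + (n - p)
    )
    return ll, beta, xtvx_inv, sigma2


def reml_loglik(sigma_plate2: float, sigma_resid2: float, X: np.ndarray,
                y: np.ndarray, groups: np.ndarray) -> float:
    """Unprofiled REML log-likelihood at variance components
    (sigma_plate^2, sigma_resid^2); used for Satterthwaite derivatives."""
    n, p = X.shape
    blocks = _group_blocks(groups)
    s2, sb2 = float(sigma_resid2), float(sigma_plate2)
    if s2 <= 0:
        return -np.inf
    lam = sb2 / s2
    xtvx = np.zeros((p, p))
    xtvy = np.zeros(p)
    ytvy = 0.0
    logdet_v = 0.0
    for idx in blocks:
        Xi = X[idx]
        yi = y[idx]
        ni = len(idx)
        shrink = lam / (1.0 + lam * ni)
        sx = Xi.sum(axis=0)
        sy = yi.sum()
        xtvx += Xi.T @ Xi - shrink * np.outer(sx, sx)
        xtvy += Xi.T @ yi - shrink * sx * sy
        ytvy += yi @ yi - shrink * sy * sy
        logdet_v += math.log1p(lam * ni)
    beta = np.linalg.solve(xtvx, xtvy)
    rss = ytvy - beta @ xtvy
    sign, logdet_xtvx = np.linalg.slogdet(xtvx / s2)
    if sign <= 0:
        return -np.inf
    return -0.5 * (
        (n - p) * math.log(2.0 * math.pi)
        + n * math.log(s2)
        + logdet_v
        + logdet_xtvx
        + rss / s2
    )


def fit_reporter_lmm(
    data: pd.DataFrame,
    response: str = "log2_ratio",
    reference_condition: str = "empty_vector",
    reference_cell_line: str = "WT",
    interaction: bool = True,
    design: Design | None = None,
) -> LmmFit:
    """REML fit of the random-intercept mixed model.

    The criterion is maximised by bounded scalar optimisation over
    ``log(lambda)`` with the boundary ``lambda = 0`` (ordinary least squares)
    checked explicitly, so a truly-zero plate variance is estimated as zero
    and the fixed effects then coincide with OLS.
    """
    if design is None:
        design = build_design(data, response=response,
                              reference_condition=reference_condition,
                              reference_cell_line=reference_cell_line,
                              interaction=interaction)
    X, y, groups = design.X, design.y, design.groups
    n, p = X.shape
    if len(np.unique(groups)) < 2:
        raise ValueError("need >= 2 plates for a plate random effect")
    blocks = _group_blocks(groups)

    def neg(u: float) -> float:
        return -_profiled_reml(math.exp(u), X, y, blocks)[0]

    res = optimize.minimize_scalar(neg, bounds=(-18.0, 12.0), method="bounded",
                                   options={"xatol": 1e-10})
    ll_hat, _, _, _ = _profiled_reml(math.exp(res.x), X, y, blocks)
    ll0, _, _, _ = _profiled_reml(0.0, X, y, blocks)
    lam = math.exp(res.x) if ll_hat > ll0 else 0.0
    # a ratio at the lower search bound is numerically zero plate variance
    if lam > 0 and res.x <= -17.5:
        lam = 0.0
    ll, beta, xtvx_inv, sigma2 = _profiled_reml(lam, X, y, blocks)
    cov = sigma2 * xtvx_inv
    se = np.sqrt(np.diag(cov))
    return LmmFit(
        params=pd.Series(beta, index=design.columns),
        se=pd.Series(se, index=design.columns),
        cov_params=pd.DataFrame(cov, index=design.columns, columns=design.columns),
        sigma_plate2=lam * sigma2,
        sigma_resid2=sigma2,
        loglik=ll,
        n=n,
        p=p,
        design=design,
    )


# ---------------------------------------------------------------------------
# Satterthwaite contrasts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContrastResult:
    estimate: float
    se: float
    t: float
    df: float
    p: float


def _contrast_variance(theta: np.ndarray, c: np.ndarray, X: np.ndarray,
                       groups: np.ndarray) -> float:
    """c' Cov(beta_hat; theta) c with theta = (sigma_plate^2, sigma_resid^2)."""
    sb2, s2 = float(theta[0]), float(theta[1])
    lam = max(sb2, 0.0) / s2
    p = X.shape[1]
    xtvx = np.zeros((p, p))
    for idx in _group_blocks(groups):
        Xi = X[idx]
        ni = len(idx)
        shrink = lam / (1.0 + lam * ni)
        sx = Xi.sum(axis=0)
        xtvx += Xi.T @ Xi - shrink * np.outer(sx, sx)
    cov = s2 * np.linalg.inv(xtvx)
    return float(c @ cov @ c)


def satterthwaite_contrast(fit: LmmFit, contrast: Sequence[float] | Mapping[str, float]) -> ContrastResult:
    """t-test of a fixed-effect contrast with Satterthwaite df.

    ``df = 2 (c'Vc)^2 / Var(c'Vc)`` where the variance of the estimated
    contrast variance comes from the delta method: the gradient of
    ``c'V(theta)c`` in the variance components (central differences, step
    1e-6 per component scale) and the inverse observed information of the
    REML log-likelihood.  In the classical limit of zero plate variance the
    residual df of the fixed-effects model is returned.
    """
    if isinstance(contrast, Mapping):
        c = np.zeros(fit.p)
        for name, v in contrast.items():
            c[fit.columns.index(name)] = v
    else:
        c = np.asarray(contrast, dtype=float)
    if c.shape != (fit.p,):
        raise ValueError(f"contrast must have length {fit.p}")
    if not np.any(c):
        raise ValueError("contrast must be non-zero")
    est = float(c @ fit.params.to_numpy())
    var = float(c @ fit.cov_params.to_numpy() @ c)
    se = math.sqrt(var)
    t = est / se
    X, y, groups = fit.design.X, fit.design.y, fit.design.groups
    resid_df = fit.n - fit.p
    if fit.sigma_plate2 <= 1e-10 * fit.sigma_resid2:
        df = float(resid_df)
    else:
        theta = np.array([fit.sigma_plate2, fit.sigma_resid2])
        steps = 1e-6 * np.maximum(theta, 1e-12)
        grad = np.zeros(2)
        for j in range(2):
            e = np.zeros(2)
            e[j] = steps[j]
            grad[j] = (
                _contrast_variance(theta + e, c, X, groups)
                - _contrast_variance(theta - e, c, X, groups)
            ) / (2 * steps[j])
        # observed information of the REML criterion in theta
        hsteps = 1e-4 * np.maximum(theta, 1e-10)
        H = np.zeros((2, 2))
        f0 = reml_loglik(theta[0], theta[1], X, y, groups)
        for j in range(2):
            for k in range(j, 2):
                ej = np.zeros(2); ej[j] = hsteps[j]
                ek = np.zeros(2); ek[k] = hsteps[k]
                if j == k:
                    fp = reml_loglik(*(theta + ej), X, y, groups)
                    fm = reml_loglik(*(theta - ej), X, y, groups)
                    H[j, j] = (fp - 2 * f0 + fm) / hsteps[j] ** 2
                else:
                    fpp = reml_loglik(*(theta + ej + ek), X, y, groups)
                    fpm = reml_loglik(*(theta + ej - ek), X, y, groups)
                    fmp = reml_loglik(*(theta - ej + ek), X, y, groups)
                    fmm = reml_loglik(*(theta - ej - ek), X, y, groups)
                    H[j, k] = H[k, j] = (fpp - fpm - fmp + fmm) / (4 * hsteps[j] * hsteps[k])
        try:
            acov = np.linalg.inv(-H)
        except np.linalg.LinAlgError:
            acov = None
        if acov is None or np.any(np.diag(acov) < 0):
            df = float(resid_df)
        else:
            var_of_var = float(grad @ acov @ grad)
            df = 2.0 * var**2 / var_of_var if var_of_var > 0 else float(resid_df)
            df = float(np.clip(df, 1.0, resid_df))
    p = 2.0 * stats.t.sf(abs(t), df)
    return ContrastResult(estimate=est, se=se, t=float(t), df=df, p=float(p))


def adjust_bonferroni(pvals: Sequence[float]) -> np.ndarray:
    """Bonferroni correction: ``p_adj = min(1, m * p)``."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, len(p) * p)


# ---------------------------------------------------------------------------
# Partner classification
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PartnerClassification:
    partner: str
    classes: tuple[str, ...]
    supporting: tuple[str, ...] = ()


def partner_contrast_table(
    fit: LmmFit,
    condition: str,
    cell_lines: Sequence[str] = NRF2_NULL_LINES + DEREPRESSED_LINES,
) -> pd.DataFrame:
    """Contrast rows for one partner: its wild-type effect (condition main
    effect) and its condition x cell-line interaction in each edited line."""
    rows = []
    main = f"condition[{condition}]"
    if main not in fit.columns:
        raise KeyError(f"no fixed effect for condition {condition!r}")
    res = satterthwaite_contrast(fit, {main: 1.0})
    rows.append({"partner": condition, "cell_line": "WT", "term": "wt_effect",
                 "estimate": res.estimate, "se": res.se, "t": res.t,
                 "df": res.df, "p": res.p})
    for line in cell_lines:
        term = f"condition[{condition}]:cell_line[{line}]"
        if term not in fit.columns:
            continue
        res = satterthwaite_contrast(fit, {term: 1.0})
        rows.append({"partner": condition, "cell_line": line, "term": "interaction",
                     "estimate": res.estimate, "se": res.se, "t": res.t,
                     "df": res.df, "p": res.p})
    out = pd.DataFrame(rows)
    out["p_bonf"] = adjust_bonferroni(out["p"].to_numpy())
    return out


def classify_partner_effect(contrasts: pd.DataFrame, alpha: float = 0.05) -> PartnerClassification:
    """Classify one partner from its contrast table.

    Rules (labels are not mutually exclusive, except ``no_effect``):

    * significant wild-type effect -> ``activator`` (positive) or
      ``inhibitor`` (negative);
    * significant dampening (interaction opposing the wild-type effect) in
      *both* NRF2-null lines -> ``NRF2_dependent``;
    * no wild-type effect but a significant interaction in at least one
      derepressed (T80K or KEAP1-null) line -> ``derepression_dependent``;
    * otherwise ``no_effect``.

    Requires the wild-type row and an interaction row per edited cell line;
    anything missing yields ``insufficient_data``.
    """
    required = {"term", "cell_line", "estimate", "p_bonf"}
    if not required <= set(contrasts.columns):
        raise ValueError(f"contrast table needs columns {sorted(required)}")
    partner = str(contrasts["partner"].iloc[0]) if "partner" in contrasts else ""
    wt = contrasts[contrasts["term"] == "wt_effect"]
    inter = contrasts[contrasts["term"] == "interaction"].set_index("cell_line")
    needed_lines = set(NRF2_NULL_LINES) | set(DEREPRESSED_LINES)
    if len(wt) != 1 or not needed_lines <= set(inter.index):
        return PartnerClassification(partner=partner, classes=("insufficient_data",))
    wt_est = float(wt["estimate"].iloc[0])
    wt_sig = float(wt["p_bonf"].iloc[0]) < alpha
    classes: list[str] = []
    supporting: list[str] = []
    if wt_sig:
        classes.append("activator" if wt_est > 0 else "inhibitor")
        supporting.append("wt_effect")
    if wt_sig and wt_est != 0:
        dampened = all(
            float(inter.loc[l, "p_bonf"]) < alpha
            and np.sign(float(inter.loc[l, "estimate"])) == -np.sign(wt_est)
            for l in NRF2_NULL_LINES
        )
        if dampened:
            classes.append("NRF2_dependent")
            supporting.extend(NRF2_NULL_LINES)
    if not wt_sig:
        hits = [l for l in DEREPRESSED_LINES if float(inter.loc[l, "p_bonf"]) < alpha]
        if hits:
            classes.append("derepression_dependent")
            supporting.extend(hits)
    if not classes:
        classes = ["no_effect"]
    return PartnerClassification(partner=partner, classes=tuple(classes),
                                 supporting=tuple(supporting))
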