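"""Population comparison via random-intercept linear mixed models.

Model: ``value = population (fixed) + bird (random intercept) + residual``,
estimated by REML with the variance ratio profiled out and maximized by a
bounded 1-D search (the boundary ``var_bird = 0`` is handled explicitly).
The population effect is tested with a type-III F statistic; denominator
degrees of freedom use the Satterthwaite approximation by default, with a
containment rule available.  Estimated marginal means (cell-means coding,
so EMMs equal the fixed-effect coefficients) are reported per population.

The intraclass correlation coefficient comes from an intercepts-only fit
of the same model: ``icc = var_bird / (var_bird + var_resid)``.

Everything here is exact linear algebra on the per-group block structure
of ``V = sigma_e^2 I + sigma_b^2 Z Z'`` — no dense N x N matrices.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy import stats as sps

from .exceptions import ContractViolation

_GAMMA_MAX = 1.0e6
_BOUNDARY_TOL = 1.0e-10


@dataclass
class LMMResult:
    populations: list[str]
    fixed_effect_estimate: float  # contrast: second population minus first
    F: float
    df_num: int
    df_den: float
    p: float
    emm: dict[str, tuple[float, float]]  # population -> (mean, SE)
    var_bird: float
    var_resid: float
    reml_loglik: float
    boundary: bool  # var_bird estimated at the zero boundary
    df_method: str
    df_den_by_method: dict[str, float] = field(default_factory=dict)
    n_obs: int = 0
    n_birds: int = 0


@dataclass
class ICCResult:
    icc: Optional[float]
    var_bird: float
    var_resid: float
    boundary: bool = False
    n_birds: int = 0
    n_obs: int = 0
    reason: str = ""


class _BlockLMM:
    """Per-group sufficient statistics for V = I + gamma * Z Z'."""

    def __init__(self, y: np.ndarray, X: np.ndarray, groups: np.ndarray):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.labels, inv = np.unique(groups, return_inverse=True)
        self.q = len(self.labels)
        self.sizes = np.bincount(inv).astype(float)
        # group-level sums
        self.Xg = np.zeros((self.q, self.p))
        self.yg = np.zeros(self.q)
        np.add.at(self.Xg, inv, X)
        np.add.at(self.yg, inv, y)
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _pieces(self, gamma: float):
        w = gamma / (1.0 + gamma * self.sizes)  # shrinkage per group
        XtVX = self.XtX - (self.Xg * w[:, None]).T @ self.Xg
        XtVy = self.Xty - self.Xg.T @ (w * self.yg)
        ytVy = self.yty - float(w @ (self.yg ** 2))
        logdetV = float(np.sum(np.log1p(gamma * self.sizes)))
        return XtVX, XtVy, ytVy, logdetV

    def profile_neg2_reml(self, gamma: float) -> float:
        XtVX, XtVy, ytVy, logdetV = self._pieces(gamma)
        beta = np.linalg.solve(XtVX, XtVy)
        quad = ytVy - float(beta @ XtVy)
        dof = self.n - self.p
        sigma2 = max(quad / dof, 1e-300)  # guard exact-fit degenerate data
        sign, logdetXtVX = np.linalg.slogdet(XtVX)
        return (dof * np.log(2.0 * np.pi * sigma2) + logdetV + logdetXtVX
                + dof)

    def neg2_reml_at(self, var_bird: float, var_resid: float) -> float:
        """-2 REML log-likelihood at explicit variance components."""
        gamma = var_bird / var_resid
        XtVX, XtVy, ytVy, logdetV = self._pieces(gamma)
        beta = np.linalg.solve(XtVX, XtVy)
        quad = (ytVy - float(beta @ XtVy)) / var_resid
        sign, logdetXtVX = np.linalg.slogdet(XtVX)
        dof = self.n - self.p
        return (dof * np.log(2.0 * np.pi) + (self.n - self.p) * np.log(var_resid)
                + logdetV + logdetXtVX + quad)

    def fit(self):
        obj = self.profile_neg2_reml
        # bracket on log-gamma plus the explicit boundary
        grid = np.concatenate(([0.0], np.logspace(-6, 8, 57)))
        vals = [obj(g) for g in grid]
        k = int(np.argmin(vals))
        if k == 0:
            # check a fine probe near zero before declaring the boundary
            res = optimize.minimize_scalar(
                obj, bounds=(0.0, grid[1]), method="bounded",
                options={"xatol": 1e-12})
            gamma = res.x if res.fun < vals[0] - 1e-12 else 0.0
        else:
            lo = grid[k - 1]
            hi = grid[min(k + 1, len(grid) - 1)]
            res = optimize.minimize_scalar(
                obj, bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-12})
            gamma = float(res.x)
            if obj(0.0) <= obj(gamma):
                gamma = 0.0
        boundary = gamma <= _BOUNDARY_TOL
        if boundary:
            gamma = 0.0
        XtVX, XtVy, ytVy, _ = self._pieces(gamma)
        beta = np.linalg.solve(XtVX, XtVy)
        quad = ytVy - float(beta @ XtVy)
        sigma2 = quad / (self.n - self.p)
        cov_beta = sigma2 * np.linalg.inv(XtVX)
        neg2 = obj(gamma)
        return gamma, boundary, beta, cov_beta, sigma2, -0.5 * neg2


def _satterthwaite_df(block: _BlockLMM, L: np.ndarray, var_bird: float,
                      var_resid: float) -> float:
    """Satterthwaite denominator df for a single-row contrast L.

    ``f(theta) = L (X' V(theta)^-1 X)^-1 L'`` with ``theta = (var_bird,
    var_resid)``; df = 2 f^2 / (g' Cov(theta) g) with the gradient g taken
    numerically and Cov(theta) from the inverse observed REML information.
    """

    def f(theta):
        vb, ve = theta
        gamma = max(vb, 0.0) / ve
        XtVX, _, _, _ = block._pieces(gamma)
        C = ve * np.linalg.inv(XtVX)
        return float((L @ C @ L.T).item())

    theta = np.array([var_bird, var_resid])
    h = np.maximum(1e-6, 1e-3 * np.maximum(np.abs(theta), var_resid))
    grad = np.zeros(2)
    for i in range(2):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += h[i]
        tm[i] = max(tm[i] - h[i], 1e-12)
        grad[i] = (f(tp) - f(tm)) / (tp[i] - tm[i])

    def nll(theta_):
        vb = max(theta_[0], 0.0)
        ve = max(theta_[1], 1e-12)
        return 0.5 * block.neg2_reml_at(vb, ve)

    H = np.zeros((2, 2))
    for i in range(2):
        for j in range(2):
            e_i = np.zeros(2); e_i[i] = h[i]
            e_j = np.zeros(2); e_j[j] = h[j]
            H[i, j] = (
                nll(theta + e_i + e_j) - nll(theta + e_i - e_j)
                - nll(theta - e_i + e_j) + nll(theta - e_i - e_j)
            ) / (4.0 * h[i] * h[j])
    try:
        cov_theta = np.linalg.inv(H)
        denom = float(grad @ cov_theta @ grad)
        if denom <= 0:
            return float("nan")
        return 2.0 * f(theta) ** 2 / denom
    except np.linalg.LinAlgError:
        return float("nan")


def fit_lmm(data: pd.DataFrame, *, value_col: str = "value",
            bird_col: str = "bird_id", population_col: str = "population",
            df_method: str = "satterthwaite") -> LMMResult:
    """REML random-intercept fit with a fixed population effect.

    ``data`` needs columns for the measured value, bird identifier and
    population label.  Every bird must belong to exactly one population
    and at least two populations must be present.
    """
    df = data[[value_col, bird_col, population_col]].dropna()
    pops = sorted(df[population_col].unique())
    if len(pops) < 2:
        raise ContractViolation("need at least two populations to compare")
    bird_pop = df.groupby(bird_col)[population_col].nunique()
    if (bird_pop > 1).any():
        bad = bird_pop[bird_pop > 1].index.tolist()
        raise ContractViolation(f"bird(s) {bad} appear in more than one population")

    y = df[value_col].to_numpy(dtype=float)
    groups = df[bird_col].to_numpy()
    # cell-means coding: one column per population, so beta == EMM
    X = np.column_stack([
        (df[population_col] == pop).to_numpy(dtype=float) for pop in pops
    ])
    block = _BlockLMM(y, X, groups)
    gamma, boundary, beta, cov_beta, sigma2, loglik = block.fit()
    var_resid = sigma2
    var_bird = gamma * sigma2

    k = len(pops)
    # type-III test of population equality: all pairwise-to-first contrasts
    Lmat = np.zeros((k - 1, k))
    Lmat[:, 0] = -1.0
    for i in range(k - 1):
        Lmat[i, i + 1] = 1.0
    contrast = Lmat @ beta
    middle = Lmat @ cov_beta @ Lmat.T
    try:
        F = float(contrast @ np.linalg.solve(middle, contrast) / (k - 1))
    except np.linalg.LinAlgError:
        # exact-fit data: zero covariance; the contrast is either exactly
        # zero (no information) or infinitely well resolved
        F = float("nan") if np.allclose(contrast, 0.0) else float("inf")

    n_birds = block.q
    df_containment = float(max(n_birds - k, 1))
    if boundary:
        df_satt = float(block.n - k)
    else:
        df_satt = _satterthwaite_df(block, Lmat[0:1], var_bird, var_resid)
        if not np.isfinite(df_satt) or df_satt < 1.0:
            df_satt = df_containment
    by_method = {"satterthwaite": df_satt, "containment": df_containment,
                 "residual": float(block.n - k)}
    if df_method not in by_method:
        raise ContractViolation(f"unknown df_method {df_method!r}")
    df_den = by_method[df_method]
    p = float(sps.f.sf(F, k - 1, df_den))

    emm = {pop: (float(beta[i]), float(np.sqrt(cov_beta[i, i])))
           for i, pop in enumerate(pops)}
    return LMMResult(
        populations=pops,
        fixed_effect_estimate=float(beta[1] - beta[0]),
        F=F, df_num=k - 1, df_den=float(df_den), p=p,
        emm=emm, var_bird=float(var_bird), var_resid=float(var_resid),
        reml_loglik=float(loglik), boundary=bool(boundary),
        df_method=df_method, df_den_by_method=by_method,
        n_obs=block.n, n_birds=n_birds,
    )


def icc(data: pd.DataFrame, *, value_col: str = "value",
        bird_col: str = "bird_id") -> ICCResult:
    """Intraclass correlation from an intercepts-only random-bird fit."""
    df = data[[value_col, bird_col]].dropna()
    y = df[value_col].to_numpy(dtype=float)
    groups = df[bird_col].to_numpy()
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        return ICCResult(icc=None, var_bird=float("nan"), var_resid=float("nan"),
                         n_birds=len(labels), n_obs=len(y),
                         reason="fewer than two birds")
    if counts.max() < 2:
        return ICCResult(icc=None, var_bird=float("nan"), var_resid=float("nan"),
                         n_birds=len(labels), n_obs=len(y),
                         reason="no bird has repeated measurements")
    X = np.ones((len(y), 1))
    block = _BlockLMM(y, X, groups)
    gamma, boundary, beta, cov_beta, sigma2, loglik = block.fit()
    var_bird = gamma * sigma2
    total = var_bird + sigma2
    return ICCResult(icc=float(var_bird / total), var_bird=float(var_bird),
                     var_resid=float(sigma2), boundary=bool(boundary),
                     n_birds=len(labels), n_obs=len(y))


@dataclass
class ComparisonReport:
    pigments: pd.DataFrame
    droplets: pd.DataFrame
    alpha: float
    df_method: str


_PIGMENT_ORDER = ["LWS", "MWS", "SWS", "UVS", "rod"]
_DROPLET_ORDER = ["R", "Y", "C", "P"]


def _compare_types(df: pd.DataFrame, type_col: str, order: list[str], *,
                   alpha: float, df_method: str,
                   compute_icc: bool = True) -> pd.DataFrame:
    rows = []
    present = [t for t in order if t in set(df[type_col])]
    present += sorted(set(df[type_col]) - set(order))
    all_pops = sorted(df["population"].unique())
    for t in present:
        sub = df[df[type_col] == t]
        row: dict = {"type": t}
        for pop in all_pops:
            vals = sub.loc[sub["population"] == pop, "value"]
            row[f"n_{pop}"] = int(len(vals))
            row[f"mean_{pop}"] = float(vals.mean()) if len(vals) else float("nan")
            row[f"se_{pop}"] = (float(vals.std(ddof=1) / np.sqrt(len(vals)))
                                if len(vals) > 1 else float("nan"))
        pops_here = sorted(sub["population"].unique())
        if len(pops_here) >= 2 and sub["bird_id"].nunique() >= 2:
            try:
                res = fit_lmm(sub, df_method=df_method)
                row.update({
                    "estimate": res.fixed_effect_estimate, "F": res.F,
                    "df_num": res.df_num, "df_den": res.df_den, "p": res.p,
                    "significant": bool(res.p < alpha),
                    "var_bird": res.var_bird, "var_resid": res.var_resid,
                    "boundary": res.boundary,
                })
                for pop in pops_here:
                    m, se = res.emm[pop]
                    row[f"emm_{pop}"] = m
                    row[f"emm_se_{pop}"] = se
            except (ContractViolation, np.linalg.LinAlgError):
                row["significant"] = None
        else:
            row["significant"] = None
        if compute_icc:
            r = icc(sub)
            row["icc"] = r.icc if r.icc is not None else float("nan")
            row["icc_defined"] = r.icc is not None
        rows.append(row)
    return pd.DataFrame(rows)


def comparison_report(cell_results: pd.DataFrame,
                      droplet_results: Optional[pd.DataFrame] = None, *,
                      alpha: float = 0.05,
                      df_method: str = "satterthwaite") -> ComparisonReport:
    """Per-type population comparison tables.

    ``cell_results`` must carry columns (value, bird_id, population,
    pigment_class) for QC-passed cells only; ``droplet_results`` the same
    with droplet_type.  Types absent in a population get a row with the
    statistics left missing rather than fabricated.
    """
    pig = _compare_types(
        cell_results.rename(columns={"pigment_class": "type"}),
        "type", _PIGMENT_ORDER, alpha=alpha, df_method=df_method,
    ) if len(cell_results) else pd.DataFrame()
    if droplet_results is not None and len(droplet_results):
        drop = _compare_types(
            droplet_results.rename(columns={"droplet_type": "type"}),
            "type", _DROPLET_ORDER, alpha=alpha, df_method=df_method,
        )
    else:
        drop = pd.DataFrame()
    return ComparisonReport(pigments=pig, droplets=drop, alpha=alpha,
                            df_method=df_method)
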