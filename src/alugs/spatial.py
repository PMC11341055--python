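"""Single-trial spatial mixed models: BLUEs, variance components, H2.

Per condition and trait the model is

    y = X beta + Z_r u_r + Z_c u_c + Z_s u_s + e,

with genotype (families and checks) either fixed (to obtain BLUEs) or
random (to obtain sigma_G^2 and broad-sense heritability), iid random row
and column effects capturing discontinuous field variation, and an optional
smooth surface modeled as a tensor-product penalized spline on the (row,
col) coordinates. The spline uses a default 8x8 cubic B-spline basis with a
second-order difference penalty; its penalty null space (bilinear trends)
is carried as fixed covariates and the penalized part is folded into the
mixed model as an iid random effect via the spectral decomposition of the
penalty. Variance components are estimated by REML, profiling out the
residual variance and optimizing the deviance over log variance ratios
with a derivative-free simplex search.

Broad-sense heritability is computed from the genotype-random fit as
H2 = sigma_G^2 / (sigma_G^2 + sigma_eps^2); spatial components are
deliberately excluded from the denominator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.interpolate import BSpline

from .errors import ConvergenceError, DegenerateDataError

__all__ = [
    "TrialFit", "fit_single_trial", "estimate_h2", "compute_blues",
    "correlate_conditions",
]


@dataclass
class TrialFit:
    """Result of a single-trial mixed-model fit."""

    trait: str
    condition: str
    genotype_as: str
    effects: pd.Series            # BLUEs (fixed) or BLUPs (random) per entry
    se: pd.Series                 # standard errors (fixed-genotype fits)
    is_check: pd.Series           # per-entry check flag
    varcomps: Dict[str, float]    # row, col, smooth, genotype?, residual
    surface: pd.Series            # per-plot spatial effect (index = plot rows used)
    fitted: pd.Series             # per-plot fitted values
    intercept: float
    converged: bool
    trace: List[float] = field(repr=False, default_factory=list)
    n_plots: int = 0


# ----------------------------------------------------------------------
# design construction
# ----------------------------------------------------------------------

def _one_hot(values: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    levels, inv = np.unique(values, return_inverse=True)
    Z = np.zeros((len(values), len(levels)))
    Z[np.arange(len(values)), inv] = 1.0
    return Z, levels


def _bspline_basis(x: np.ndarray, n_basis: int, degree: int = 3) -> np.ndarray:
    """Equally spaced cubic B-spline design matrix with ``n_basis`` columns."""
    lo, hi = x.min(), x.max()
    if hi == lo:
        hi = lo + 1.0
    n_inner = n_basis - degree + 1
    inner = np.linspace(lo, hi, n_inner)
    dx = inner[1] - inner[0]
    knots = np.concatenate([inner[0] - dx * np.arange(degree, 0, -1), inner,
                            inner[-1] + dx * np.arange(1, degree + 1)])
    return BSpline.design_matrix(x, knots, degree).toarray()


def _difference_penalty(k: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def _tensor_spline(row: np.ndarray, col: np.ndarray, n_knots: Tuple[int, int]):
    """Penalized tensor-spline random design + its fixed (null-space) part.

    Returns (Z_s, X_poly): Z_s spans the penalized directions, scaled so the
    implied prior is iid; X_poly carries the unpenalized bilinear trend
    (r, c, r*c) — the constant lives in the genotype/intercept columns.
    """
    kr, kc = n_knots
    Br = _bspline_basis(row.astype(float), kr)
    Bc = _bspline_basis(col.astype(float), kc)
    B = np.einsum("ij,ik->ijk", Br, Bc).reshape(len(row), kr * kc)
    S = np.kron(_difference_penalty(kr), np.eye(kc)) + np.kron(np.eye(kr), _difference_penalty(kc))
    w, V = np.linalg.eigh(S)
    pos = w > 1e-8 * w.max()
    Zs = B @ (V[:, pos] / np.sqrt(w[pos]))
    r = (row - row.mean()) / max(np.ptp(row), 1.0)
    c = (col - col.mean()) / max(np.ptp(col), 1.0)
    X_poly = np.column_stack([r, c, r * c])
    return Zs, X_poly


# ----------------------------------------------------------------------
# REML engine
# ----------------------------------------------------------------------

def _reml_deviance(log_lam, y, X, ZZts):
    lam = np.exp(np.clip(log_lam, -30.0, 30.0))
    n, p = X.shape
    H = np.eye(n)
    for lam_i, ZZt in zip(lam, ZZts):
        H += lam_i * ZZt
    L = np.linalg.cholesky(H)
    A = np.linalg.solve(L, X)
    b = np.linalg.solve(L, y)
    AtA = A.T @ A
    beta = np.linalg.solve(AtA, A.T @ b)
    resid = b - A @ beta
    rss = float(resid @ resid)
    logdet_H = 2.0 * float(np.log(np.diag(L)).sum())
    sign, logdet_AtA = np.linalg.slogdet(AtA)
    if sign <= 0:
        raise DegenerateDataError("rank-deficient fixed-effect design (confounded genotypes?)")
    dev = logdet_H + logdet_AtA + (n - p) * np.log(max(rss, 1e-300))
    return dev, beta, rss, L


def _fit_mixed(y, X, Z_list, max_iter=200, tol=1e-6):
    """REML over variance ratios; returns beta, per-component BLUPs, variances."""
    n, p = X.shape
    ZZts = [Z @ Z.T for Z in Z_list]
    trace: List[float] = []

    if not Z_list:
        dev, beta, rss, L = _reml_deviance(np.array([]), y, X, [])
        lam_hat = np.array([])
        converged = True
    else:
        x0 = np.full(len(Z_list), -1.0)

        def obj(x):
            d = _reml_deviance(x, y, X, ZZts)[0]
            trace.append(d)
            return d

        f0 = obj(x0)
        res = optimize.minimize(
            obj, x0, method="Nelder-Mead",
            options={"maxiter": max_iter * len(Z_list), "xatol": 1e-4,
                     "fatol": tol * (1.0 + abs(f0)), "adaptive": True},
        )
        lam_hat = np.exp(np.clip(res.x, -30.0, 30.0))
        converged = bool(res.success)
        if not converged:
            raise ConvergenceError(
                f"REML did not converge in {res.nit} simplex iterations", trace=trace)
        dev, beta, rss, L = _reml_deviance(res.x, y, X, ZZts)

    sigma_e2 = rss / (n - p)
    # BLUPs: u_i = lambda_i Z_i' H^{-1} (y - X beta)
    resid_raw = y - X @ beta
    Hinv_resid = np.linalg.solve(L.T, np.linalg.solve(L, resid_raw)) if Z_list else resid_raw
    blups = [lam_i * Z.T @ Hinv_resid for lam_i, Z in zip(lam_hat, Z_list)]
    sigmas = [lam_i * sigma_e2 for lam_i in lam_hat]

    # SEs of fixed effects from sigma_e2 * (X' H^-1 X)^-1
    A = np.linalg.solve(L, X) if Z_list else X
    cov_beta = sigma_e2 * np.linalg.inv(A.T @ A)
    se_beta = np.sqrt(np.diag(cov_beta))
    return beta, se_beta, blups, sigmas, sigma_e2, converged, trace


# ----------------------------------------------------------------------
# public operations
# ----------------------------------------------------------------------

def fit_single_trial(
    plots: pd.DataFrame,
    trait: str,
    genotype_as: str = "fixed",
    smooth: str = "tensor_spline",
    condition: Optional[str] = None,
    include_rowcol: bool = True,
    n_knots: Tuple[int, int] = (8, 8),
    max_iter: int = 200,
    tol: float = 1e-6,
) -> TrialFit:
    """Fit the spatial mixed model to one condition's plot table.

    Parameters
    ----------
    plots : DataFrame
        Long-format plot records (condition, block, row, col, entry_id,
        is_check, trait columns). If more than one condition is present,
        ``condition`` must name the one to fit.
    genotype_as : {'fixed', 'random'}
        Fixed yields BLUEs (cell means); random yields BLUPs and sigma_G^2.
    smooth : {'none', 'tensor_spline'}
        Whether to include the smooth spatial surface.
    include_rowcol : bool
        Include the iid random row and column effects.
    """
    if genotype_as not in ("fixed", "random"):
        raise ValueError("genotype_as must be 'fixed' or 'random'")
    if smooth not in ("none", "tensor_spline"):
        raise ValueError("smooth must be 'none' or 'tensor_spline'")

    df = plots
    conds = df["condition"].unique()
    if condition is not None:
        df = df[df["condition"] == condition]
    elif len(conds) > 1:
        raise ValueError(f"plot table holds conditions {list(conds)}; pass condition=")
    else:
        condition = str(conds[0])
    df = df.dropna(subset=[trait])
    if df.empty:
        raise DegenerateDataError(f"no non-missing observations for trait {trait!r}")
    if df["row"].nunique() < 2 or df["col"].nunique() < 2:
        raise DegenerateDataError("need at least 2 rows and 2 columns")

    y = df[trait].to_numpy(dtype=float)
    n = len(y)
    row = df["row"].to_numpy()
    col = df["col"].to_numpy()

    G, entry_levels = _one_hot(df["entry_id"].to_numpy())
    check_flag = (
        df.drop_duplicates("entry_id").set_index("entry_id")["is_check"]
        .reindex(entry_levels).astype(bool)
    )

    X_parts, Z_list, comp_names = [], [], []
    if genotype_as == "fixed":
        X_parts.append(G)  # cell-means coding: one column per entry, no intercept
    else:
        X_parts.append(np.ones((n, 1)))
        Z_list.append(G)
        comp_names.append("genotype")
    if smooth == "tensor_spline":
        Zs, X_poly = _tensor_spline(row, col, n_knots)
        X_parts.append(X_poly)
        Z_list.append(Zs)
        comp_names.append("smooth")
    if include_rowcol:
        Zr, _ = _one_hot(row)
        Zc, _ = _one_hot(col)
        Z_list.extend([Zr, Zc])
        comp_names.extend(["row", "col"])

    X = np.hstack(X_parts)
    beta, se_beta, blups, sigmas, sigma_e2, converged, trace = _fit_mixed(
        y, X, Z_list, max_iter=max_iter, tol=tol)

    varcomps = {"residual": float(sigma_e2)}
    for name, s in zip(comp_names, sigmas):
        key = {"genotype": "genotype", "smooth": "smooth", "row": "row", "col": "col"}[name]
        varcomps[key] = float(s)
    varcomps.setdefault("row", 0.0)
    varcomps.setdefault("col", 0.0)
    varcomps.setdefault("smooth", 0.0)

    # assemble per-entry effects
    if genotype_as == "fixed":
        k = G.shape[1]
        effects = pd.Series(beta[:k], index=entry_levels, name="blue")
        se = pd.Series(se_beta[:k], index=entry_levels, name="se")
        intercept = 0.0  # cell means absorb the intercept
    else:
        u_g = blups[comp_names.index("genotype")]
        effects = pd.Series(u_g, index=entry_levels, name="blup")
        se = pd.Series(np.nan, index=entry_levels, name="se")
        intercept = float(beta[0])

    # spatial surface per plot: random row/col/smooth BLUPs + fixed bilinear trend
    surface = np.zeros(n)
    for name, Z, u in zip(comp_names, Z_list, blups):
        if name in ("smooth", "row", "col"):
            surface += Z @ u
    if smooth == "tensor_spline":
        poly_cols = slice(X_parts[0].shape[1], X_parts[0].shape[1] + 3)
        surface += X[:, poly_cols] @ beta[poly_cols]

    fitted = X @ beta
    for Z, u in zip(Z_list, blups):
        fitted = fitted + Z @ u

    return TrialFit(
        trait=trait, condition=condition, genotype_as=genotype_as,
        effects=effects, se=se, is_check=check_flag,
        varcomps=varcomps,
        surface=pd.Series(surface, index=df.index),
        fitted=pd.Series(fitted, index=df.index),
        intercept=intercept, converged=converged, trace=trace, n_plots=n,
    )


def estimate_h2(fit: TrialFit) -> float:
    """Broad-sense heritability H2 = sigma_G^2 / (sigma_G^2 + sigma_eps^2).

    Spatial variance components are excluded from the denominator by
    definition of the estimator.
    """
    if fit.genotype_as != "random":
        raise ValueError("H2 requires a genotype-random fit")
    sg = fit.varcomps.get("genotype", 0.0)
    se = fit.varcomps["residual"]
    if sg + se <= 0:
        raise DegenerateDataError("sigma_G^2 + sigma_eps^2 = 0; heritability undefined")
    return float(sg / (sg + se))


def compute_blues(
    plots: pd.DataFrame,
    traits,
    conditions=None,
    smooth: str = "tensor_spline",
    **fit_kwargs,
) -> pd.DataFrame:
    """Fixed-genotype fits for every trait x condition; long BLUE table.

    Returns columns entry_id, condition, trait, blue, se, is_check.
    """
    if conditions is None:
        conditions = list(plots["condition"].unique())
    rows = []
    for cond in conditions:
        for trait in traits:
            fit = fit_single_trial(plots, trait, genotype_as="fixed",
                                   smooth=smooth, condition=cond, **fit_kwargs)
            rows.append(pd.DataFrame({
                "entry_id": fit.effects.index,
                "condition": cond,
                "trait": trait,
                "blue": fit.effects.to_numpy(),
                "se": fit.se.to_numpy(),
                "is_check": fit.is_check.to_numpy(),
            }))
    return pd.concat(rows, ignore_index=True)


def correlate_conditions(
    blues: pd.DataFrame,
    trait: str,
    method: str = "spearman",
    conditions: Tuple[str, str] = ("ALU", "LIM"),
    include_checks: bool = False,
) -> Tuple[float, float]:
    """Correlation of entry BLUEs between the two conditions.

    Returns (coefficient, two-sided p-value). Checks are excluded by
    default: the correlation characterizes the selection population.
    """
    df = blues[blues["trait"] == trait]
    if not include_checks:
        df = df[~df["is_check"].astype(bool)]
    wide = df.pivot_table(index="entry_id", columns="condition", values="blue")
    wide = wide.dropna(subset=list(conditions))
    if len(wide) < 3:
        raise DegenerateDataError("need >= 3 entries present in both conditions")
    a = wide[conditions[0]].to_numpy()
    b = wide[conditions[1]].to_numpy()
    if a.std() == 0 or b.std() == 0:
        raise DegenerateDataError("zero variance in one condition; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(a, b)
    elif method == "spearman":
        r, p = stats.spearmanr(a, b)
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), float(p)
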