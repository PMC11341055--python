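"""Multi-environment GBLUP via Gibbs sampling over kernel random effects.

Four model structures are supported, all with one fixed intercept per
condition and a homogeneous residual:

* ``SM``  — single-environment GBLUP: main genetic effect with genomic
  kernel K plus a line intercept with identity kernel, in one condition;
* ``MM``  — multi-environment main-effect model: the same two effects
  shared across conditions (genetic effects constant across environments,
  i.e. no genotype-by-environment interaction);
* ``MDs`` — MM plus a single genotype-by-environment deviation effect:
  K-structured deviations per condition sharing one common variance;
* ``MDe`` — MM plus an environment-specific deviation per condition, each
  with its own variance.

Effects are sampled in the spectral basis of their kernels: writing
u = U b with K = U diag(d) U', the scalar coefficients b_j have
independent priors N(0, sigma^2 d_j) and conjugate normal full
conditionals, so one Gibbs sweep is a pass over scalar updates with
running-residual bookkeeping. Variances have scaled-inverse-chi-square
full conditionals; condition intercepts have normal full conditionals
under a flat prior. The inner loop is JIT-compiled with numba when
available.

The observation mask is free-form: lines may be phenotyped in one
condition and not the other (sparse testing); effects are line-indexed,
so predictions for unobserved cells come from the kernel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateDataError
from .qc import KinshipKernel

__all__ = [
    "StackedData", "EffectComponent", "ModelFit", "MODEL_TAGS",
    "build_components", "stack_blues", "fit_gibbs", "predict_gebv",
    "variance_proportions", "gebv_frame",
]

MODEL_TAGS = ("SM", "MM", "MDs", "MDe")

#: Default chain settings for a production fit.
DEFAULT_MCMC = {"burn_in": 5000, "n_iter": 70000, "thin": 5}


# ----------------------------------------------------------------------
# data containers
# ----------------------------------------------------------------------

@dataclass
class StackedData:
    """Response vector stacked over conditions with record metadata."""

    y: np.ndarray
    entries: np.ndarray      # entry id per record
    conditions: np.ndarray   # condition id per record
    line_ids: List[str]      # kernel index (every entry must appear here)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        self.entries = np.asarray(self.entries, dtype=object)
        self.conditions = np.asarray(self.conditions, dtype=object)
        if not (len(self.y) == len(self.entries) == len(self.conditions)):
            raise ConfigurationError("stacked data arrays must share length")
        pairs = list(zip(self.entries, self.conditions))
        if len(set(pairs)) != len(pairs):
            raise ConfigurationError("more than one record per entry x condition")
        known = set(self.line_ids)
        orphans = sorted({e for e in self.entries if e not in known})
        if orphans:
            raise ConfigurationError(f"entries absent from the kernel index: {orphans[:5]}")
        if np.std(self.y) == 0:
            raise DegenerateDataError("response has zero variance")

    @property
    def n_records(self) -> int:
        return len(self.y)

    def condition_levels(self) -> List[str]:
        seen = []
        for c in self.conditions:
            if c not in seen:
                seen.append(c)
        return seen


def stack_blues(
    blues: pd.DataFrame,
    trait: str,
    line_ids: Sequence[str],
    conditions: Optional[Sequence[str]] = None,
    exclude: Optional[Mapping[str, Sequence]] = None,
    include_checks: bool = False,
) -> StackedData:
    """Build a :class:`StackedData` from a long BLUE table.

    ``exclude`` maps a condition to entry ids whose records must be left
    out of the stack (the sparse-testing / cross-validation hold-out).
    """
    df = blues[blues["trait"] == trait]
    if not include_checks and "is_check" in df.columns:
        df = df[~df["is_check"].astype(bool)]
    if conditions is not None:
        df = df[df["condition"].isin(list(conditions))]
    df = df[df["entry_id"].isin(list(line_ids))]
    if exclude:
        for cond, ids in exclude.items():
            drop = df["condition"].eq(cond) & df["entry_id"].isin(list(ids))
            df = df[~drop]
    df = df.dropna(subset=["blue"])
    return StackedData(
        y=df["blue"].to_numpy(),
        entries=df["entry_id"].to_numpy(),
        conditions=df["condition"].to_numpy(),
        line_ids=list(line_ids),
    )


@dataclass
class EffectComponent:
    """One kernel-structured random effect in the linear predictor.

    ``kind='shared'`` means a single line-level effect applying to every
    record of the listed conditions (the main genetic effect g and the
    line intercept l). ``kind='deviation'`` means a separate line-level
    block per condition; all blocks share ``variance_group``, which is the
    component's own name for MDe-style environment-specific variances and
    a common label for the MDs-style single-variance deviation.
    """

    name: str
    kernel: Optional[np.ndarray]   # None = identity
    conditions: Tuple[str, ...]
    kind: str = "shared"
    variance_group: str = ""

    def __post_init__(self):
        if self.kind not in ("shared", "deviation"):
            raise ConfigurationError(f"unknown component kind {self.kind!r}")
        if not self.variance_group:
            self.variance_group = self.name


def build_components(
    model: str,
    kernel: KinshipKernel,
    conditions: Sequence[str],
) -> List[EffectComponent]:
    """Translate a model tag into its list of random-effect components."""
    conditions = tuple(conditions)
    K = kernel.matrix
    if model not in MODEL_TAGS:
        raise ConfigurationError(f"unknown model tag {model!r}; expected one of {MODEL_TAGS}")
    if model == "SM":
        if len(conditions) != 1:
            raise ConfigurationError("SM is a single-environment model; pass exactly 1 condition")
    else:
        if len(conditions) != 2:
            raise ConfigurationError(f"{model} requires exactly 2 conditions")

    comps = [
        EffectComponent("g", K, conditions, kind="shared"),
        EffectComponent("l", None, conditions, kind="shared"),
    ]
    if model == "MDs":
        comps.append(EffectComponent("ge", K, conditions, kind="deviation", variance_group="ge"))
    elif model == "MDe":
        for cond in conditions:
            comps.append(EffectComponent(f"dev_{cond}", K, (cond,), kind="deviation"))
    return comps


@dataclass
class ModelFit:
    """Posterior summaries of a fitted GBLUP model."""

    model: str
    line_ids: List[str]
    conditions: List[str]
    effects: Dict[str, pd.Series]          # 'g', 'l', 'ge@ALU', 'dev_ALU@ALU', ...
    effect_mcse: Dict[str, pd.Series]
    variances: Dict[str, Dict[str, float]]  # group -> {mean, sd}
    residual_variance: Dict[str, float]
    intercepts: Dict[str, float]
    n_samples: int
    settings: Dict[str, int]
    seed: int
    variance_samples: pd.DataFrame = field(repr=False, default=None)


# ----------------------------------------------------------------------
# sampler core (numba-accelerated scalar Gibbs in the spectral basis)
# ----------------------------------------------------------------------

def _gibbs_core(y, WT, wtw, col_d, col_group, cond_idx, n_cond,
                sigma2, fix_group, df0, s0, sigma_e2, fix_e, dfe0, se0,
                burn_in, n_iter, thin, seed):  # pragma: no cover - exercised via wrapper
    np.random.seed(seed)
    n = y.shape[0]
    ncol = WT.shape[0]
    ngroup = sigma2.shape[0]
    b = np.zeros(ncol)
    mu = np.zeros(n_cond)
    e = y.copy()
    n_per_cond = np.zeros(n_cond)
    for i in range(n):
        n_per_cond[cond_idx[i]] += 1.0

    n_keep = (n_iter - burn_in + thin - 1) // thin
    b_sum = np.zeros(ncol)
    b_sumsq = np.zeros(ncol)
    mu_sum = np.zeros(n_cond)
    var_samples = np.zeros((n_keep, ngroup))
    rese_samples = np.zeros(n_keep)
    kept = 0

    for it in range(n_iter):
        # condition intercepts, flat prior
        for c in range(n_cond):
            s = 0.0
            for i in range(n):
                if cond_idx[i] == c:
                    s += e[i] + mu[c]
            mean = s / n_per_cond[c]
            new = mean + np.sqrt(sigma_e2 / n_per_cond[c]) * np.random.standard_normal()
            delta = new - mu[c]
            for i in range(n):
                if cond_idx[i] == c:
                    e[i] -= delta
            mu[c] = new

        # spectral-basis effect coefficients
        for j in range(ncol):
            w = WT[j]
            rj = 0.0
            for i in range(n):
                rj += w[i] * e[i]
            rj += wtw[j] * b[j]
            prec = wtw[j] / sigma_e2 + 1.0 / (sigma2[col_group[j]] * col_d[j])
            var = 1.0 / prec
            bn = var * rj / sigma_e2 + np.sqrt(var) * np.random.standard_normal()
            diff = bn - b[j]
            if diff != 0.0:
                for i in range(n):
                    e[i] -= w[i] * diff
            b[j] = bn

        # variance components: scaled-inverse-chi-square full conditionals
        for g in range(ngroup):
            if fix_group[g] == 0:
                ss = 0.0
                m = 0.0
                for j in range(ncol):
                    if col_group[j] == g:
                        ss += b[j] * b[j] / col_d[j]
                        m += 1.0
                sigma2[g] = (df0 * s0[g] + ss) / np.random.chisquare(df0 + m)
        if fix_e == 0:
            sse = 0.0
            for i in range(n):
                sse += e[i] * e[i]
            sigma_e2 = (dfe0 * se0 + sse) / np.random.chisquare(dfe0 + n)

        if it >= burn_in and (it - burn_in) % thin == 0:
            for j in range(ncol):
                b_sum[j] += b[j]
                b_sumsq[j] += b[j] * b[j]
            for c in range(n_cond):
                mu_sum[c] += mu[c]
            for g in range(ngroup):
                var_samples[kept, g] = sigma2[g]
            rese_samples[kept] = sigma_e2
            kept += 1

    return b_sum, b_sumsq, mu_sum, var_samples, rese_samples, kept


try:  # JIT-compile the sweep when numba is available
    from numba import njit

    _gibbs_core_jit = njit(cache=True, fastmath=False)(_gibbs_core)
except ImportError:  # pragma: no cover
    _gibbs_core_jit = _gibbs_core


# ----------------------------------------------------------------------

_EIG_TOL = 1e-10


def _spectral(kernel: Optional[np.ndarray], n: int):
    """Eigenbasis (U, d) of a kernel, trimming null directions."""
    if kernel is None:
        return np.eye(n), np.ones(n)
    w, U = np.linalg.eigh(kernel)
    keep = w > _EIG_TOL * max(w.max(), 1.0)
    if keep.sum() == 0:
        raise ConfigurationError("kernel has no positive eigenvalues")
    if w.min() < -1e-8 * max(w.max(), 1.0):
        raise ConfigurationError("kernel is not PSD")
    return U[:, keep], w[keep]


def fit_gibbs(
    data: StackedData,
    components: Sequence[EffectComponent],
    burn_in: int = DEFAULT_MCMC["burn_in"],
    n_iter: int = DEFAULT_MCMC["n_iter"],
    thin: int = DEFAULT_MCMC["thin"],
    seed: int = 0,
    prior_df: float = 5.0,
    fix_variances: Optional[Mapping[str, float]] = None,
    fix_residual: Optional[float] = None,
    model: str = "custom",
) -> ModelFit:
    """Run the Gibbs sampler and return posterior summaries.

    Priors: every variance gets a scaled-inverse-chi-square prior with
    ``prior_df`` degrees of freedom and scale chosen so the prior mode is
    an equal split of the phenotypic variance across all components plus
    the residual. ``fix_variances`` pins named variance groups (no update;
    useful for oracle checks and nesting degeneracies), ``fix_residual``
    pins the residual variance.
    """
    if n_iter <= burn_in:
        raise ConfigurationError("n_iter must exceed burn_in")
    if thin < 1:
        raise ConfigurationError("thin must be >= 1")
    fix_variances = dict(fix_variances or {})

    line_ids = data.line_ids
    n_lines = len(line_ids)
    line_pos = {lid: i for i, lid in enumerate(line_ids)}
    rec_line = np.array([line_pos[e] for e in data.entries])
    cond_levels = data.condition_levels()
    cond_pos = {c: i for i, c in enumerate(cond_levels)}
    cond_idx = np.array([cond_pos[c] for c in data.conditions], dtype=np.int64)
    n = data.n_records

    # assemble spectral design blocks
    blocks = []  # (label, component, U, d, group)
    groups: List[str] = []
    eig_cache: Dict[int, tuple] = {}
    for comp in components:
        key = id(comp.kernel) if comp.kernel is not None else -1
        if key not in eig_cache:
            eig_cache[key] = _spectral(comp.kernel, n_lines)
        U, d = eig_cache[key]
        if comp.variance_group not in groups:
            groups.append(comp.variance_group)
        if comp.kind == "shared":
            blocks.append((comp.name, comp, U, d, comp.variance_group))
        else:
            for cond in comp.conditions:
                blocks.append((f"{comp.name}@{cond}", comp, U, d, comp.variance_group))

    WT_parts, col_d_parts, col_group_parts = [], [], []
    block_slices = {}
    offset = 0
    for label, comp, U, d, group in blocks:
        if "@" in label:
            applies = data.conditions == label.split("@", 1)[1]
        else:
            applies = np.isin(data.conditions, comp.conditions)
        M = np.zeros((n, n_lines))
        rows = np.flatnonzero(applies)
        M[rows, rec_line[rows]] = 1.0
        W = M @ U
        WT_parts.append(np.ascontiguousarray(W.T))
        col_d_parts.append(d)
        col_group_parts.append(np.full(len(d), groups.index(group), dtype=np.int64))
        block_slices[label] = (slice(offset, offset + len(d)), U)
        offset += len(d)

    WT = np.vstack(WT_parts)
    wtw = (WT ** 2).sum(axis=1)
    col_d = np.concatenate(col_d_parts)
    col_group = np.concatenate(col_group_parts)
    ngroup = len(groups)

    # priors: equal split of phenotypic variance over components + residual
    vary = float(np.var(data.y, ddof=1))
    mode = vary / (ngroup + 1)
    s0_scalar = mode * (prior_df + 2.0) / prior_df
    s0 = np.full(ngroup, s0_scalar)
    sigma2 = np.full(ngroup, mode)
    fix_group = np.zeros(ngroup, dtype=np.int64)
    for gname, val in fix_variances.items():
        if gname not in groups:
            raise ConfigurationError(f"cannot fix unknown variance group {gname!r}")
        gi = groups.index(gname)
        sigma2[gi] = float(val)
        fix_group[gi] = 1
    if fix_residual is not None:
        sigma_e2, fix_e = float(fix_residual), 1
    else:
        sigma_e2, fix_e = mode, 0
    # a variance pinned at (or near) zero would make the scalar full
    # conditionals singular; clamp to a tiny floor instead
    sigma2 = np.maximum(sigma2, 1e-12 * max(vary, 1.0))

    b_sum, b_sumsq, mu_sum, var_samples, rese_samples, kept = _gibbs_core_jit(
        data.y, WT, wtw, col_d.astype(float), col_group, cond_idx, len(cond_levels),
        sigma2.copy(), fix_group, float(prior_df), s0, sigma_e2, fix_e,
        float(prior_df), s0_scalar, int(burn_in), int(n_iter), int(thin), int(seed),
    )

    b_mean = b_sum / kept
    b_var = np.maximum(b_sumsq / kept - b_mean ** 2, 0.0)
    effects, effect_mcse = {}, {}
    for label, (sl, U) in block_slices.items():
        u_mean = U @ b_mean[sl]
        u_mcse = np.sqrt((U ** 2) @ b_var[sl] / kept)
        effects[label] = pd.Series(u_mean, index=line_ids)
        effect_mcse[label] = pd.Series(u_mcse, index=line_ids)

    variances = {
        g: {"mean": float(var_samples[:, i].mean()), "sd": float(var_samples[:, i].std(ddof=1))
            if kept > 1 else 0.0}
        for i, g in enumerate(groups)
    }
    var_df = pd.DataFrame(var_samples, columns=groups)
    var_df["residual"] = rese_samples

    return ModelFit(
        model=model,
        line_ids=list(line_ids),
        conditions=cond_levels,
        effects=effects,
        effect_mcse=effect_mcse,
        variances=variances,
        residual_variance={"mean": float(rese_samples.mean()),
                           "sd": float(rese_samples.std(ddof=1)) if kept > 1 else 0.0},
        intercepts={c: float(mu_sum[i] / kept) for c, i in cond_pos.items()},
        n_samples=int(kept),
        settings={"burn_in": burn_in, "n_iter": n_iter, "thin": thin},
        seed=seed,
        variance_samples=var_df,
    )


def fit_model(
    model: str,
    blues: pd.DataFrame,
    kernel: KinshipKernel,
    trait: str,
    conditions: Sequence[str],
    exclude: Optional[Mapping[str, Sequence]] = None,
    **mcmc,
) -> ModelFit:
    """Convenience: stack BLUEs, build the model's components, and sample."""
    data = stack_blues(blues, trait, kernel.line_ids, conditions=conditions, exclude=exclude)
    comps = build_components(model, kernel, conditions)
    return fit_gibbs(data, comps, model=model, **mcmc)


# ----------------------------------------------------------------------

def predict_gebv(
    fit: ModelFit,
    entries: Sequence[str],
    condition: str,
    include_line_intercept: bool = True,
) -> pd.Series:
    """Genomic estimated breeding values for ``entries`` in ``condition``.

    GEBV = posterior mean of g + l + any deviation block applicable to the
    condition; the condition intercept is excluded (predictive ability is
    correlation-based, so a common shift is immaterial). The line intercept
    l is genetic by construction and included by default; pass
    ``include_line_intercept=False`` for the kernel-only alternative.
    """
    missing = [e for e in entries if e not in fit.effects["g"].index]
    if missing:
        raise KeyError(f"entries not in the fitted kernel index: {missing[:5]}")
    gebv = fit.effects["g"].reindex(entries).copy()
    if include_line_intercept and "l" in fit.effects:
        gebv = gebv + fit.effects["l"].reindex(entries)
    for label, eff in fit.effects.items():
        if "@" in label and label.split("@", 1)[1] == condition:
            gebv = gebv + eff.reindex(entries)
    gebv.name = f"gebv_{condition}"
    return gebv


def predict_value(fit: ModelFit, entries: Sequence[str], condition: str,
                  **kwargs) -> pd.Series:
    """Predicted trait values on the observation scale.

    Condition intercept plus GEBV — what the ratio-based stability index
    needs (a centered GEBV has no meaningful denominator).
    """
    out = fit.intercepts[condition] + predict_gebv(fit, entries, condition, **kwargs)
    out.name = f"pred_{condition}"
    return out


def gebv_frame(fit: ModelFit, trait: str, **kwargs) -> pd.DataFrame:
    """Long GEBV table (entry_id, condition, trait, gebv) for all conditions."""
    rows = []
    for cond in fit.conditions:
        g = predict_gebv(fit, fit.line_ids, cond, **kwargs)
        rows.append(pd.DataFrame({
            "entry_id": fit.line_ids, "condition": cond, "trait": trait,
            "gebv": g.to_numpy(),
        }))
    return pd.concat(rows, ignore_index=True)


def variance_proportions(fit: ModelFit) -> pd.Series:
    """Per-component share of total explained variance (sums to 1).

    Components are the residual plus each variance group (g, l, and the
    interaction deviations when present), as posterior means.
    """
    parts = {"residual": fit.residual_variance["mean"]}
    for g, v in fit.variances.items():
        parts[g] = v["mean"]
    total = sum(parts.values())
    if total <= 0:
        raise DegenerateDataError("total variance is zero")
    return pd.Series({k: v / total for k, v in parts.items()})
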