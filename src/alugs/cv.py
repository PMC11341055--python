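"""Sparse-testing cross-validation of the genomic prediction models.

Two scenarios are implemented, both targeting prediction in the stress
condition (ALU by default):

* ``single_env`` — k-1 folds of the target condition train an SM model;
  the held-out fold's records in that condition are predicted;
* ``multi_env``  — the training set is the whole population phenotyped in
  the secondary condition (LIM) plus k-1 folds phenotyped in the target;
  the held-out fold's target-condition records are predicted. The
  secondary-condition records of test entries *do* enter training: that is
  the sparse-testing design.

Predictive ability (PA) is the Pearson correlation between GEBVs and the
held-out BLUEs. A leakage audit asserts on every fold that no held-out
target-condition record reached the training stack. Models are compared
with one-way ANOVA plus Tukey's HSD and a compact letter display.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigurationError, DegenerateDataError, LeakageError
from .gblup import build_components, fit_gibbs, predict_gebv, stack_blues
from .qc import KinshipKernel

__all__ = [
    "FoldPlan", "CVResult", "make_folds", "run_cv", "predictive_ability",
    "compare_models",
]

#: Shortened default chain for desk-scale cross-validation runs; pass the
#: production settings explicitly for a full-length analysis.
CV_MCMC = {"burn_in": 500, "n_iter": 5000, "thin": 5}


@dataclass
class FoldPlan:
    """Entry-to-fold assignment for each repetition."""

    k: int
    repetitions: int
    assignment: Dict[int, pd.Series]  # rep -> Series(entry_id -> fold in 0..k-1)
    seed: int

    def fold_entries(self, rep: int, fold: int) -> List[str]:
        a = self.assignment[rep]
        return list(a.index[a == fold])


def make_folds(entries: Sequence[str], k: int, repetitions: int, seed: int) -> FoldPlan:
    """Uniformly random balanced partitions, deterministic per seed.

    Fold sizes differ by at most one (remainder entries spread one per
    fold).
    """
    entries = list(entries)
    n = len(entries)
    if k < 2:
        raise ConfigurationError("k must be >= 2")
    if k > n:
        raise ConfigurationError(f"k={k} exceeds the number of entries ({n})")
    rng = np.random.default_rng(seed)
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    labels = np.repeat(np.arange(k), sizes)
    assignment = {}
    for rep in range(repetitions):
        perm = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        folds[perm] = labels
        assignment[rep] = pd.Series(folds, index=entries)
    return FoldPlan(k=k, repetitions=repetitions, assignment=assignment, seed=seed)


@dataclass
class CVResult:
    """Fold-level predictive abilities plus optional raw predictions."""

    records: pd.DataFrame  # trait, model, scenario, rep, fold, pa
    predictions: Optional[pd.DataFrame] = field(repr=False, default=None)

    def summary(self) -> pd.DataFrame:
        """Mean and SD per trait x model.

        ``sd_folds`` pools all k x repetitions fold values; ``sd_reps`` is
        the SD of the repetition means.
        """
        rows = []
        for (trait, model), grp in self.records.groupby(["trait", "model"], sort=False):
            pa = grp["pa"].dropna()
            rep_means = grp.dropna(subset=["pa"]).groupby("rep")["pa"].mean()
            rows.append({
                "trait": trait, "model": model,
                "mean_pa": pa.mean(),
                "sd_folds": pa.std(ddof=1),
                "sd_reps": rep_means.std(ddof=1),
                "n_folds": len(pa),
            })
        return pd.DataFrame(rows)


def predictive_ability(gebv: Sequence[float], blues: Sequence[float]) -> float:
    """Pearson correlation between predicted and observed values."""
    g = np.asarray(gebv, dtype=float)
    b = np.asarray(blues, dtype=float)
    if len(g) != len(b) or len(g) < 3:
        raise DegenerateDataError("need >= 3 paired values")
    if g.std() == 0 or b.std() == 0:
        raise DegenerateDataError("zero variance; predictive ability undefined")
    return float(stats.pearsonr(g, b)[0])


def _chain_seed(seed: int, rep: int, fold: int, model_index: int) -> int:
    return int((seed * 1_000_003 + rep * 10_007 + fold * 101 + model_index) % (2**31 - 1))


def run_cv(
    blues: pd.DataFrame,
    kernel: KinshipKernel,
    trait: str,
    scenario: str,
    models: Sequence[str],
    plan: FoldPlan,
    mcmc: Optional[Mapping[str, int]] = None,
    target: str = "ALU",
    secondary: str = "LIM",
    keep_predictions: bool = False,
) -> CVResult:
    """Run the requested CV scenario for each model over every rep x fold."""
    if scenario not in ("single_env", "multi_env"):
        raise ConfigurationError("scenario must be 'single_env' or 'multi_env'")
    for m in models:
        if scenario == "single_env" and m != "SM":
            raise ConfigurationError(f"model {m} is not a single-environment model")
        if scenario == "multi_env" and m == "SM":
            raise ConfigurationError("SM cannot be used in the multi-environment scenario")
    mcmc = dict(CV_MCMC if mcmc is None else mcmc)

    fam = blues[~blues["is_check"].astype(bool)] if "is_check" in blues.columns else blues
    target_blues = (
        fam[(fam["trait"] == trait) & (fam["condition"] == target)]
        .set_index("entry_id")["blue"]
    )

    rows, preds = [], []
    for rep in range(plan.repetitions):
        for fold in range(plan.k):
            test_ids = [e for e in plan.fold_entries(rep, fold) if e in target_blues.index]
            conditions = (target,) if scenario == "single_env" else (target, secondary)
            data = stack_blues(
                blues, trait, kernel.line_ids, conditions=conditions,
                exclude={target: test_ids},
            )
            # leakage audit: no held-out target record may be in training
            leaked = [(e, c) for e, c in zip(data.entries, data.conditions)
                      if c == target and e in set(test_ids)]
            if leaked:
                raise LeakageError(f"validation records leaked into training: {leaked[:5]}")

            for mi, model in enumerate(models):
                comps = build_components(model, kernel, conditions)
                fit = fit_gibbs(
                    data, comps, model=model,
                    seed=_chain_seed(plan.seed, rep, fold, mi), **mcmc,
                )
                gebv = predict_gebv(fit, test_ids, target)
                obs = target_blues.reindex(test_ids)
                try:
                    pa = predictive_ability(gebv.to_numpy(), obs.to_numpy())
                except DegenerateDataError:
                    warnings.warn(
                        f"degenerate predictions in rep {rep} fold {fold} ({model}); PA recorded as missing")
                    pa = np.nan
                rows.append({"trait": trait, "model": model, "scenario": scenario,
                             "rep": rep, "fold": fold, "pa": pa})
                if keep_predictions:
                    preds.append(pd.DataFrame({
                        "trait": trait, "model": model, "scenario": scenario,
                        "rep": rep, "fold": fold, "entry_id": test_ids,
                        "gebv": gebv.to_numpy(),
                        # on the observation scale: needed by ratio indices
                        "value": gebv.to_numpy() + fit.intercepts[target],
                        "observed": obs.to_numpy(),
                    }))

    return CVResult(
        records=pd.DataFrame(rows),
        predictions=pd.concat(preds, ignore_index=True) if preds else None,
    )


# ----------------------------------------------------------------------
# model comparison
# ----------------------------------------------------------------------

def _compact_letters(models: List[str], means: Mapping[str, float],
                     ns_pairs: set) -> Dict[str, str]:
    """Compact letter display from the set of not-significant pairs.

    Maximal cliques of mutually non-different models each receive one
    letter; a model's display is the sorted union of its letters. Feasible
    by subset enumeration for the handful of models compared here.
    """
    order = sorted(models, key=lambda m: -means[m])
    cliques = []
    for r in range(len(order), 0, -1):
        for subset in itertools.combinations(order, r):
            if all((a, b) in ns_pairs or (b, a) in ns_pairs or a == b
                   for a, b in itertools.combinations(subset, 2)):
                s = set(subset)
                if not any(s <= c for c in cliques):
                    cliques.append(s)
    cliques.sort(key=lambda c: -max(means[m] for m in c))
    letters = {m: "" for m in models}
    for i, clique in enumerate(cliques):
        ch = chr(ord("a") + i)
        for m in clique:
            letters[m] += ch
    return {m: "".join(sorted(v)) for m, v in letters.items()}


def compare_models(cv: CVResult, trait: str, alpha: float = 0.05) -> pd.DataFrame:
    """ANOVA + Tukey HSD across models on fold x repetition PA values.

    Returns one row per model with its mean PA and compact-letter group;
    models sharing no letter differ significantly at ``alpha``.
    """
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    df = cv.records[(cv.records["trait"] == trait)].dropna(subset=["pa"])
    models = list(df["model"].unique())
    if len(models) < 2:
        raise ConfigurationError("need at least 2 models to compare")
    groups = {m: df.loc[df["model"] == m, "pa"].to_numpy() for m in models}
    if any(len(v) < 2 for v in groups.values()):
        raise ConfigurationError("each model needs >= 2 PA records")
    f_stat, p_value = stats.f_oneway(*groups.values())

    means = {m: float(v.mean()) for m, v in groups.items()}
    if all(np.allclose(groups[a], groups[b])
           for a, b in itertools.combinations(models, 2)):
        # identical vectors: Tukey is degenerate, everything shares a letter
        ns_pairs = set(itertools.combinations(models, 2))
    else:
        tuk = pairwise_tukeyhsd(df["pa"].to_numpy(), df["model"].to_numpy(), alpha=alpha)
        res = pd.DataFrame(tuk.summary().data[1:], columns=tuk.summary().data[0])
        ns_pairs = {(r["group1"], r["group2"]) for _, r in res.iterrows() if not r["reject"]}
    letters = _compact_letters(models, means, ns_pairs)

    out = pd.DataFrame({
        "model": models,
        "mean_pa": [means[m] for m in models],
        "letters": [letters[m] for m in models],
    }).sort_values("mean_pa", ascending=False).reset_index(drop=True)
    out.attrs["anova_F"] = float(f_stat)
    out.attrs["anova_p"] = float(p_value)
    return out
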