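"""Stability and multi-trait selection indices.

* ``iYLD`` — percent yield change from the limed control to the
  aluminum-toxic condition; positive = tolerant. ``e_iYLD`` is the same
  ratio computed from predicted (rather than observed) yields.
* Smith–Hazel index — coefficients beta = P^{-1} G w, with P the empirical
  covariance of the phenotypic values, G that of the genetic values, and w
  the economic weights. Two flavors are built here: a genomic index (GSi)
  scored on multi-environment GEBVs for the stress condition, and a
  phenotypic index (PSi) scored on control-condition BLUEs augmented with
  iYLD as a fifth trait.
* top-fraction selection and per-trait selection differentials
  S = mean(selected) - mean(population), positive for improvement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from ._util import round_half_up
from .errors import ConfigurationError, DegenerateDataError

__all__ = [
    "GSI_WEIGHTS", "PSI_WEIGHTS", "SelectionResult",
    "compute_iyld", "compute_e_iyld", "solve_index", "build_gsi", "build_psi",
    "select_top", "selection_differential", "bi_condition_top", "blues_wide",
]

#: Economic weights for the four agronomic traits (program defaults):
#: ignore flowering, penalize height, maximize yield, improve grain zinc.
GSI_WEIGHTS = {"FL": 0.0, "PH": -0.2, "YLD": 1.0, "ZN": 0.8}
#: The phenotypic index adds the yield-stability index at weight 0.5.
PSI_WEIGHTS = {**GSI_WEIGHTS, "iYLD": 0.5}


@dataclass
class SelectionResult:
    """Solved index coefficients, per-family scores and the selected set."""

    name: str
    weights: Dict[str, float]
    beta: pd.Series
    scores: pd.Series
    selected: List[str]
    differentials: Optional[pd.Series] = field(default=None)

    @property
    def n_selected(self) -> int:
        return len(self.selected)


# ----------------------------------------------------------------------
# stability index
# ----------------------------------------------------------------------

def compute_iyld(blues: pd.DataFrame, conditions=("ALU", "LIM"),
                 include_checks: bool = False,
                 on_nonpositive: str = "raise") -> pd.Series:
    """Yield-stability index per family, in percent.

    iYLD = (YLD_stress - YLD_control) / YLD_control * 100, from the BLUE
    table. The ratio is meaningless for a family whose control yield is
    non-positive: ``on_nonpositive='raise'`` errors (the contract default),
    ``'drop'`` excludes those families with a warning.
    """
    if on_nonpositive not in ("raise", "drop"):
        raise ValueError("on_nonpositive must be 'raise' or 'drop'")
    df = blues[blues["trait"] == "YLD"]
    if not include_checks and "is_check" in df.columns:
        df = df[~df["is_check"].astype(bool)]
    wide = df.pivot_table(index="entry_id", columns="condition", values="blue")
    wide = wide.dropna(subset=list(conditions))
    stress, control = conditions
    bad = wide.index[wide[control] <= 0]
    if len(bad):
        if on_nonpositive == "raise":
            raise DegenerateDataError(
                f"iYLD undefined for families with non-positive {control} yield: {list(bad)[:5]}")
        warnings.warn(f"iYLD undefined for {len(bad)} families with non-positive "
                      f"{control} yield; excluded: {list(bad)[:5]}")
        wide = wide.drop(index=bad)
    iyld = (wide[stress] - wide[control]) / wide[control] * 100.0
    iyld.name = "iYLD"
    return iyld


def compute_e_iyld(pred_stress: pd.Series, pred_control: pd.Series) -> pd.Series:
    """Stability index from predicted yields (same formula as iYLD).

    Inputs must be on the yield scale (condition intercept included), not
    centered GEBVs; otherwise the ratio's denominator is meaningless.
    """
    common = pred_stress.index.intersection(pred_control.index)
    s = pred_stress.reindex(common).astype(float)
    c = pred_control.reindex(common).astype(float)
    bad = common[c <= 0]
    if len(bad):
        raise DegenerateDataError(
            f"e_iYLD undefined for families with non-positive predicted control yield: {list(bad)[:5]}")
    out = (s - c) / c * 100.0
    out.name = "e_iYLD"
    return out


# ----------------------------------------------------------------------
# Smith–Hazel machinery
# ----------------------------------------------------------------------

def solve_index(P: np.ndarray, G: np.ndarray, w: Sequence[float],
                max_condition: float = 1e10) -> np.ndarray:
    """Index coefficients solving P beta = G w (no explicit inverse)."""
    P = np.asarray(P, dtype=float)
    G = np.asarray(G, dtype=float)
    w = np.asarray(w, dtype=float)
    k = len(w)
    if P.shape != (k, k) or G.shape != (k, k):
        raise ConfigurationError("P, G and w dimensions do not match")
    if not np.allclose(P, P.T, atol=1e-8) or not np.allclose(G, G.T, atol=1e-8):
        raise ConfigurationError("P and G must be symmetric")
    if not np.all(np.isfinite(w)):
        raise ConfigurationError("weights must be finite")
    eigvals = np.linalg.eigvalsh(P)
    if eigvals.min() <= 0 or eigvals.max() / eigvals.min() > max_condition:
        raise ConfigurationError(
            "P is singular or ill-conditioned; consider a ridge on the phenotypic covariance")
    return np.linalg.solve(P, G @ w)


def blues_wide(blues: pd.DataFrame, condition: str, traits: Sequence[str],
               include_checks: bool = False) -> pd.DataFrame:
    """Family x trait matrix of BLUEs for one condition."""
    df = blues[blues["condition"] == condition]
    if not include_checks and "is_check" in df.columns:
        df = df[~df["is_check"].astype(bool)]
    wide = df.pivot_table(index="entry_id", columns="trait", values="blue")
    return wide.reindex(columns=list(traits))


def _index_result(name, phen, gen, weights, score_on, fraction):
    traits = list(weights)
    missing_cols = [t for t in traits if t not in phen.columns or t not in gen.columns]
    if missing_cols:
        raise ConfigurationError(f"missing trait columns for index: {missing_cols}")
    phen = phen[traits]
    gen = gen[traits]
    common = phen.dropna().index.intersection(gen.dropna().index)
    dropped = sorted(set(phen.index).union(gen.index) - set(common))
    if dropped:
        warnings.warn(f"{len(dropped)} families lack a trait value and are excluded: {dropped[:5]}")
    phen, gen = phen.loc[common], gen.loc[common]
    P = np.cov(phen.to_numpy(), rowvar=False, ddof=1)
    G = np.cov(gen.to_numpy(), rowvar=False, ddof=1)
    w = np.array([weights[t] for t in traits])
    beta = pd.Series(solve_index(P, G, w), index=traits, name="beta")
    basis = gen if score_on == "genetic" else phen
    scores = pd.Series(basis.to_numpy() @ beta.to_numpy(), index=common,
                       name=f"{name}_score")
    selected = select_top(scores, fraction)
    return SelectionResult(name=name, weights=dict(weights), beta=beta,
                           scores=scores, selected=selected)


def build_gsi(blues_alu: pd.DataFrame, gebv_mm: pd.DataFrame,
              weights: Mapping[str, float] = GSI_WEIGHTS,
              fraction: float = 0.10) -> SelectionResult:
    """Genomic Smith–Hazel index for the stress condition.

    P is the covariance of the stress-condition BLUEs, G that of the
    multi-environment (MM) GEBVs for the same traits; families are scored
    on their GEBVs. Both inputs are family x trait matrices.
    """
    return _index_result("GSi", blues_alu, gebv_mm, weights, "genetic", fraction)


def build_psi(blues_lim: pd.DataFrame, gebv_sm_lim: pd.DataFrame, iyld: pd.Series,
              weights: Mapping[str, float] = PSI_WEIGHTS,
              fraction: float = 0.10) -> SelectionResult:
    """Phenotypic Smith–Hazel index on control-condition BLUEs plus iYLD.

    iYLD enters both matrices as a fifth trait; its "genetic" column falls
    back to the observed index when no prediction is supplied (no SM model
    predicts iYLD here — its genomic signal is precisely what the pipeline
    shows to be weak). Families are scored on the phenotypic values.
    """
    phen = blues_lim.copy()
    phen["iYLD"] = iyld
    gen = gebv_sm_lim.copy()
    if "iYLD" not in gen.columns:
        gen["iYLD"] = iyld
    return _index_result("PSi", phen, gen, weights, "phenotypic", fraction)


# ----------------------------------------------------------------------
# selection
# ----------------------------------------------------------------------

def select_top(scores: pd.Series, fraction: float = 0.10) -> List[str]:
    """Ids of the top ``fraction`` of families by score.

    The count is round-half-up(fraction * n); ties (and the all-equal
    degenerate case) are broken by stable family-id order.
    """
    if not (0.0 < fraction < 1.0):
        raise ConfigurationError("fraction must be in (0, 1)")
    if not np.all(np.isfinite(scores.to_numpy(dtype=float))):
        raise ConfigurationError("scores must be finite")
    n_sel = round_half_up(fraction * len(scores))
    if scores.nunique() == 1:
        warnings.warn("all scores equal; selecting by family-id order")
    ranked = scores.to_frame("score").reset_index(names="entry_id")
    ranked = ranked.sort_values(["score", "entry_id"], ascending=[False, True],
                                kind="mergesort")
    return ranked["entry_id"].head(n_sel).tolist()


def selection_differential(selected: Sequence[str], trait_values: pd.DataFrame) -> pd.Series:
    """Per-trait S = mean(selected) - mean(population), in trait units."""
    selected = list(selected)
    missing = [s for s in selected if s not in trait_values.index]
    if missing:
        raise ConfigurationError(f"selected families missing from trait values: {missing[:5]}")
    S = trait_values.loc[selected].mean() - trait_values.mean()
    S.name = "S"
    return S


def bi_condition_top(blues: pd.DataFrame, fraction: float = 0.10,
                     trait: str = "YLD", conditions=("ALU", "LIM")) -> List[str]:
    """Families in the top ``fraction`` for ``trait`` in *both* conditions."""
    tops = []
    for cond in conditions:
        wide = blues_wide(blues, cond, [trait]).dropna()
        tops.append(set(select_top(wide[trait], fraction)))
    return sorted(set.intersection(*tops))
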