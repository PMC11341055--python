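"""Synthetic genotypes, genetic values and p-rep field trials.

This module generates data with the statistical structure the downstream
analysis assumes, so every stage of the pipeline can be exercised and
validated against known truth:

* biallelic SNP dosages for a panel of partially inbred S0 lines, with a
  tunable minor-allele-frequency spectrum and first-order (Markov) linkage
  disequilibrium along each chromosome;
* true genetic values for four traits (days to flowering FL, plant height
  PH, grain yield YLD, grain zinc ZN) in two soil conditions (ALU =
  aluminum-toxic acid soil, LIM = limed control), with a configurable
  cross-condition genetic correlation `rho_g` — the knob that creates
  genotype-by-environment interaction;
* plot-level phenotypes on a partially replicated (p-rep) layout of blocks
  with repeated checks, contaminated by row effects, column effects, a
  smooth spatial surface and iid residual noise, with residual variance set
  from the per-trait heritability budget.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from ._util import round_half_up, stage_rng
from .errors import ConfigurationError, LayoutError
from .genotypes import GenotypeMatrix

TRAITS = ("FL", "PH", "YLD", "ZN")
CONDITIONS = ("ALU", "LIM")

#: Default narrow-sense heritability per (trait, condition): moderate for
#: height, high for flowering, matching a well-run upland trial.
DEFAULT_H2 = {
    ("FL", "ALU"): 0.75, ("FL", "LIM"): 0.74,
    ("PH", "ALU"): 0.60, ("PH", "LIM"): 0.56,
    ("YLD", "ALU"): 0.65, ("YLD", "LIM"): 0.71,
    ("ZN", "ALU"): 0.70, ("ZN", "LIM"): 0.65,
}

#: Default condition means in trait units (days, cm, kg/ha, ppm).
DEFAULT_ENV_MEANS = {
    ("FL", "ALU"): 71.8, ("FL", "LIM"): 70.2,
    ("PH", "ALU"): 112.0, ("PH", "LIM"): 108.0,
    ("YLD", "ALU"): 2219.0, ("YLD", "LIM"): 1946.0,
    ("ZN", "ALU"): 20.6, ("ZN", "LIM"): 19.4,
}

#: Default genetic standard deviations in trait units, chosen so that the
#: implied phenotypic coefficients of variation are realistic for an upland
#: rice panel (a few percent for FL/PH, ~25-30% for YLD).
DEFAULT_GENETIC_SD = {"FL": 3.5, "PH": 7.0, "YLD": 500.0, "ZN": 2.0}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults emulate the real trial this pipeline targets: 334 S0 lines,
    ~10^4 SNPs on 12 chromosomes with MAF > 2.5% and slow LD decay, two
    soil conditions with cross-condition genetic correlation 0.6, and a
    p-rep layout of 36 blocks x 14 plots with 25% replication plus six
    checks replicated six times per condition.

    ``marker_share`` is the fraction of genetic variance tagged by the
    genotyped markers; the remainder is line-level polygenic variance
    invisible to the kinship kernel. The default 0.75 mirrors the split a
    main-effect GBLUP with a line intercept estimates on such panels
    (genomic vs residual-genetic variance roughly 3:1).

    ``spatial_sd``, ``row_sd`` and ``col_sd`` are expressed as fractions of
    each trait's residual standard deviation so a single scalar scales all
    four traits coherently.
    """

    n_lines: int = 334
    n_snps: int = 10_000
    n_chromosomes: int = 12
    marker_spacing_bp: int = 40_000
    maf_range: Tuple[float, float] = (0.025, 0.5)
    ld_rho: float = 0.9
    inbreeding_f: float = 0.1
    missing_rate: float = 0.0
    traits: Tuple[str, ...] = TRAITS
    conditions: Tuple[str, ...] = CONDITIONS
    h2: Mapping[Tuple[str, str], float] = field(default_factory=lambda: dict(DEFAULT_H2))
    marker_share: float = 0.75
    rho_g: float = 0.6
    env_means: Mapping[Tuple[str, str], float] = field(default_factory=lambda: dict(DEFAULT_ENV_MEANS))
    genetic_sd: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_GENETIC_SD))
    trait_corr: Optional[np.ndarray] = None
    spatial_sd: float = 0.5
    row_sd: float = 0.3
    col_sd: float = 0.3
    n_blocks: int = 36
    plots_per_block: int = 14
    prep_fraction: float = 0.25
    n_checks: int = 6
    check_reps: int = 6
    seed: int = 0

    def __post_init__(self):
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(f"maf_range must lie in (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigurationError(f"ld_rho must be in [0, 1), got {self.ld_rho}")
        if not (0.0 <= self.inbreeding_f <= 1.0):
            raise ConfigurationError("inbreeding_f must be in [0, 1]")
        if not (-1.0 <= self.rho_g <= 1.0):
            raise ConfigurationError(f"rho_g must be in [-1, 1], got {self.rho_g}")
        if not (0.0 <= self.prep_fraction <= 1.0):
            raise ConfigurationError("prep_fraction must be in [0, 1]")
        if not (0.0 < self.marker_share <= 1.0):
            raise ConfigurationError("marker_share must be in (0, 1]")
        if self.n_lines < 2 or self.n_snps < 2:
            raise ConfigurationError("need at least 2 lines and 2 SNPs")
        for key in itertools.product(self.traits, self.conditions):
            h2 = self.h2.get(key)
            if h2 is None or not (0.0 < h2 < 1.0):
                raise ConfigurationError(f"heritability for {key} must be strictly inside (0, 1)")
            if key not in self.env_means:
                raise ConfigurationError(f"env_means missing entry {key}")
        for t in self.traits:
            if t not in self.genetic_sd:
                raise ConfigurationError(f"genetic_sd missing trait {t}")
        if self.trait_corr is not None:
            T = np.asarray(self.trait_corr, dtype=float)
            k = len(self.traits)
            if T.shape != (k, k) or not np.allclose(T, T.T):
                raise ConfigurationError("trait_corr must be a symmetric traits x traits matrix")
        if self.required_plots() > self.capacity():
            raise LayoutError(
                f"layout capacity {self.capacity()} plots < required "
                f"{self.required_plots()} (entries + replicates + checks)"
            )

    def n_duplicated(self) -> int:
        """Number of test entries sown twice under the p-rep contract."""
        return round_half_up(self.prep_fraction * self.n_lines)

    def required_plots(self) -> int:
        return self.n_lines + self.n_duplicated() + self.n_checks * self.check_reps

    def capacity(self) -> int:
        return self.n_blocks * self.plots_per_block

    def residual_sd(self, trait: str, condition: str) -> float:
        """Residual SD implied by the heritability budget h2 = Vg/(Vg+Ve)."""
        h2 = self.h2[(trait, condition)]
        return float(self.genetic_sd[trait]) * np.sqrt((1.0 - h2) / h2)

    def line_ids(self) -> list:
        width = len(str(self.n_lines))
        return [f"L{i + 1:0{width}d}" for i in range(self.n_lines)]

    def check_ids(self) -> list:
        return [f"CHK{i + 1}" for i in range(self.n_checks)]


@dataclass
class SimulationTruth:
    """Ground truth backing a simulated dataset.

    ``true_bv`` holds line-level genetic values with a (trait, condition)
    column MultiIndex; ``marker_effects`` the per-SNP effects that generated
    them; ``check_bv`` the fixed genetic values of the repeated checks;
    ``true_varcomps`` the generating variance parameters; and
    ``true_spatial_surface`` (filled in by :func:`simulate_field_trial`) the
    per-plot spatial effect per trait.
    """

    true_bv: pd.DataFrame
    marker_effects: pd.DataFrame
    check_bv: pd.DataFrame
    true_varcomps: Dict[Tuple[str, str], Dict[str, float]]
    true_spatial_surface: Optional[pd.DataFrame] = None


# ----------------------------------------------------------------------
# Genotypes
# ----------------------------------------------------------------------

def _sample_gametes(rng, p: np.ndarray, n_gametes: int, ld_rho: float) -> np.ndarray:
    """First-order Markov chain of alleles along one chromosome.

    Conditional allele probabilities are chosen so each marker keeps its
    target frequency ``p[j]`` while adjacent markers correlate at ``ld_rho``
    (clipped where the joint distribution would be infeasible).
    """
    m = len(p)
    out = np.empty((n_gametes, m), dtype=np.int8)
    out[:, 0] = rng.random(n_gametes) < p[0]
    for j in range(1, m):
        prev = out[:, j - 1]
        sd_prev = np.sqrt(p[j - 1] * (1.0 - p[j - 1]))
        sd_cur = np.sqrt(p[j] * (1.0 - p[j]))
        cond = p[j] + ld_rho * (sd_cur / sd_prev) * (prev - p[j - 1])
        cond = np.clip(cond, 0.0, 1.0)
        out[:, j] = rng.random(n_gametes) < cond
    return out


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Draw a line x SNP dosage matrix with the configured MAF spectrum and LD.

    Alternate alleles are coded as the minor allele, so realized alternate
    frequencies sit inside ``maf_range`` up to sampling noise. Heterozygous
    calls are thinned to frequency 2p(1-p)(1-f) per marker to mimic partial
    inbreeding, and an optional uniform missingness rate masks calls.
    """
    config.validate()
    rng = stage_rng(config.seed, stage=1)
    lo, hi = config.maf_range

    # markers spread over chromosomes in contiguous, evenly spaced runs
    sizes = np.full(config.n_chromosomes, config.n_snps // config.n_chromosomes)
    sizes[: config.n_snps % config.n_chromosomes] += 1
    chrom_of = np.repeat(np.arange(config.n_chromosomes), sizes)

    # allele frequencies drift slowly along each chromosome (AR(1) copula at
    # the same mixing rate as the haplotype chain): linked loci have similar
    # frequencies, which keeps the marginal-preserving chain feasible while
    # the per-marker marginal stays exactly uniform on maf_range
    dosages = np.empty((config.n_lines, config.n_snps), dtype=float)
    p_all = np.empty(config.n_snps)
    start = 0
    for c, size in enumerate(sizes):
        if size == 0:
            continue
        z = np.empty(size)
        z[0] = rng.standard_normal()
        innov = rng.standard_normal(size)
        rho = config.ld_rho
        for j in range(1, size):
            z[j] = rho * z[j - 1] + np.sqrt(1.0 - rho ** 2) * innov[j]
        p = lo + (hi - lo) * stats.norm.cdf(z)
        p_all[start:start + size] = p
        gam = _sample_gametes(rng, p, 2 * config.n_lines, config.ld_rho)
        dosages[:, start:start + size] = gam[::2] + gam[1::2]
        start += size

    if config.inbreeding_f > 0:
        het = dosages == 1
        fix = het & (rng.random(dosages.shape) < config.inbreeding_f)
        dosages[fix] = 2.0 * (rng.random(dosages.shape) < 0.5)[fix]

    missing = np.zeros_like(dosages, dtype=bool)
    if config.missing_rate > 0:
        missing = rng.random(dosages.shape) < config.missing_rate

    pos = np.concatenate([
        (np.arange(size) + 1) * config.marker_spacing_bp for size in sizes if size > 0
    ])
    snp_map = pd.DataFrame({
        "chrom": [f"chr{c + 1}" for c in chrom_of],
        "pos": pos.astype(int),
        "ref": "A",
        "alt": "T",
    })
    return GenotypeMatrix(dosages=dosages, missing=missing,
                          line_ids=config.line_ids(), snp_map=snp_map)


# ----------------------------------------------------------------------
# True genetic values
# ----------------------------------------------------------------------

def _trait_condition_chol(config: SimulationConfig) -> np.ndarray:
    """Cholesky factor of the (trait x condition) effect correlation matrix.

    The covariance is a Kronecker product T (x) C where T is the genetic
    correlation across traits (identity by default) and C the 2x2
    cross-condition correlation with off-diagonal rho_g.
    """
    k = len(config.traits)
    T = np.eye(k) if config.trait_corr is None else np.asarray(config.trait_corr, dtype=float)
    ncond = len(config.conditions)
    C = np.full((ncond, ncond), config.rho_g, dtype=float)
    np.fill_diagonal(C, 1.0)
    cov = np.kron(T, C)
    # tolerate rho_g = +/-1 (singular C) via eigenvalue square root
    w, v = np.linalg.eigh(cov)
    w = np.clip(w, 0.0, None)
    return v * np.sqrt(w)


def simulate_true_effects(genotypes: GenotypeMatrix, config: SimulationConfig) -> SimulationTruth:
    """Draw marker effects and true genetic values per trait and condition.

    Effects for the two conditions are correlated at ``rho_g``; the
    marker-borne part of each true value is the centered dosage matrix
    times the effects. A line-level polygenic remainder with the same
    correlation structure carries the fraction ``1 - marker_share`` of the
    genetic variance — the "residual genetic variation" that genotyped
    markers do not tag in a real panel. Both parts are rescaled per
    (trait, condition) so the realized total genetic SD equals
    ``genetic_sd``; rescaling preserves all correlations.
    """
    if genotypes.has_missing:
        raise ConfigurationError("genotypes must be complete (imputed) before effect simulation")
    config.validate()
    rng = stage_rng(config.seed, stage=2)

    W = genotypes.dosages - genotypes.dosages.mean(axis=0, keepdims=True)
    keys = list(itertools.product(config.traits, config.conditions))
    L = _trait_condition_chol(config)
    z = rng.standard_normal((genotypes.n_snps, len(keys)))
    alpha = z @ L.T  # SNP x (trait, condition), unit scale

    g = W @ alpha
    sd = g.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    target = np.array([config.genetic_sd[t] for t, _ in keys])
    scale = target * np.sqrt(config.marker_share) / sd
    g = g * scale
    alpha = alpha * scale

    if config.marker_share < 1.0:
        delta = rng.standard_normal((genotypes.n_lines, len(keys))) @ L.T
        dsd = delta.std(axis=0, ddof=1)
        dsd[dsd == 0] = 1.0
        delta = delta * (target * np.sqrt(1.0 - config.marker_share) / dsd)
        g = g + delta
        # the two parts are independent but not exactly orthogonal in sample;
        # normalize the sum so the realized genetic SD is the target exactly
        tsd = g.std(axis=0, ddof=1)
        tsd[tsd == 0] = 1.0
        g = g * (target / tsd)
        alpha = alpha * (target / tsd)

    cols = pd.MultiIndex.from_tuples(keys, names=["trait", "condition"])
    snp_names = genotypes.snp_map["chrom"].astype(str) + "_" + genotypes.snp_map["pos"].astype(str)
    true_bv = pd.DataFrame(g, index=genotypes.line_ids, columns=cols)
    marker_effects = pd.DataFrame(alpha, index=snp_names, columns=cols)

    # checks: fixed genetic values drawn from the same covariance structure
    zc = rng.standard_normal((config.n_checks, len(keys))) @ L.T
    check_bv = pd.DataFrame(zc * target, index=config.check_ids(), columns=cols)

    varcomps = {}
    for (t, e) in keys:
        vg = float(config.genetic_sd[t]) ** 2
        ve = config.residual_sd(t, e) ** 2
        varcomps[(t, e)] = {"var_g": vg, "var_e": ve, "h2": vg / (vg + ve)}
    return SimulationTruth(true_bv=true_bv, marker_effects=marker_effects,
                           check_bv=check_bv, true_varcomps=varcomps)


# ----------------------------------------------------------------------
# Field trial
# ----------------------------------------------------------------------

def _smooth_surface(rng, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Random smooth bivariate polynomial over plot coordinates, unit SD.

    A cubic Chebyshev expansion with random coefficients; standardized so
    the caller can scale it to any target SD.
    """
    r = 2.0 * (rows - rows.min()) / max(rows.max() - rows.min(), 1) - 1.0
    c = 2.0 * (cols - cols.min()) / max(cols.max() - cols.min(), 1) - 1.0
    basis = []
    for i in range(4):
        for j in range(4):
            if i + j == 0 or i + j > 3:
                continue
            basis.append(np.polynomial.chebyshev.chebval(r, [0] * i + [1])
                         * np.polynomial.chebyshev.chebval(c, [0] * j + [1]))
    surf = np.array(basis).T @ rng.standard_normal(len(basis))
    sd = surf.std(ddof=1)
    return surf / sd if sd > 0 else surf


def simulate_field_trial(truth: SimulationTruth, config: SimulationConfig) -> pd.DataFrame:
    """Lay out and phenotype the p-rep trial in both conditions.

    Returns a long-format plot table with columns condition, block, row,
    col, entry_id, is_check and one column per trait. A ``prep_fraction``
    share of test entries appears twice, each check appears ``check_reps``
    times, and any remaining plots are padded with extra check replicates
    (round-robin) so the block grid is full. Row, column and smooth spatial
    effects plus iid residuals are added on top of the genetic values, with
    residual variance set from the heritability budget.

    Fills ``truth.true_spatial_surface`` with the per-plot spatial effect
    (row + column + smooth) per trait and condition.
    """
    config.validate()
    rng = stage_rng(config.seed, stage=3)
    entries = list(truth.true_bv.index)
    checks = list(truth.check_bv.index)
    if len(entries) != config.n_lines or len(checks) != config.n_checks:
        raise LayoutError("truth does not cover the configured entries/checks")

    capacity = config.capacity()
    required = config.required_plots()
    if required > capacity:
        raise LayoutError(f"need {required} plots but layout offers {capacity}")

    n_dup = config.n_duplicated()
    frames = []
    surface_frames = []
    for cond in config.conditions:
        dup = list(rng.choice(entries, size=n_dup, replace=False))
        plot_entries = (entries + dup
                        + [c for c in checks for _ in range(config.check_reps)])
        pad = capacity - len(plot_entries)
        plot_entries += [checks[i % len(checks)] for i in range(pad)]
        plot_entries = np.array(plot_entries, dtype=object)
        rng.shuffle(plot_entries)

        block = np.repeat(np.arange(1, config.n_blocks + 1), config.plots_per_block)
        row = np.tile(np.arange(1, config.plots_per_block + 1), config.n_blocks)
        col = block.copy()  # blocks laid out side by side as field columns

        df = pd.DataFrame({
            "condition": cond, "block": block, "row": row, "col": col,
            "entry_id": plot_entries,
            "is_check": np.isin(plot_entries, checks),
        })
        surf_unit = _smooth_surface(rng, row.astype(float), col.astype(float))
        row_levels = np.unique(row)
        col_levels = np.unique(col)
        surf_cols = {}
        for trait in config.traits:
            sd_e = config.residual_sd(trait, cond)
            row_eff = dict(zip(row_levels, rng.normal(0.0, config.row_sd * sd_e, len(row_levels))))
            col_eff = dict(zip(col_levels, rng.normal(0.0, config.col_sd * sd_e, len(col_levels))))
            spatial = (np.array([row_eff[r] for r in row])
                       + np.array([col_eff[c] for c in col])
                       + config.spatial_sd * sd_e * surf_unit)
            bv_map = pd.concat([truth.true_bv[(trait, cond)], truth.check_bv[(trait, cond)]])
            g = bv_map.reindex(plot_entries).to_numpy()
            resid = rng.normal(0.0, sd_e, capacity)
            df[trait] = config.env_means[(trait, cond)] + g + spatial + resid
            surf_cols[trait] = spatial
        frames.append(df)
        sdf = df[["condition", "block", "row", "col"]].copy()
        for trait, vals in surf_cols.items():
            sdf[trait] = vals
        surface_frames.append(sdf)

    truth.true_spatial_surface = pd.concat(surface_frames, ignore_index=True)
    return pd.concat(frames, ignore_index=True)


def simulate_dataset(config: SimulationConfig):
    """Convenience: genotypes -> truth -> plot table in one call."""
    geno = simulate_genotypes(config)
    if geno.has_missing:
        from .qc import impute_missing
        complete = impute_missing(geno, method="marker_mean")
    else:
        complete = geno
    truth = simulate_true_effects(complete, config)
    plots = simulate_field_trial(truth, config)
    return geno, truth, plots
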