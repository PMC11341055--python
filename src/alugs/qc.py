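"""SNP quality control, imputation, kinship and diversity summaries.

Filters follow the genotyping protocol of a GBS panel: per-call read depth,
per-site missingness, biallelic status and minor allele frequency, applied
sequentially in a fixed order (depth -> missingness -> biallelic -> MAF) so
the removal counts are deterministic and auditable. Thresholds are strict
inequalities exactly as conventionally printed: keep depth > 10,
missingness < 20%, MAF > 2.5%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Sequence

import numpy as np
import pandas as pd

from .errors import QCError
from .genotypes import GenotypeMatrix

FILTER_ORDER = ("depth", "missingness", "biallelic", "maf")


@dataclass
class SnpQCReport:
    """Per-filter removal counts and per-site/per-line QC summaries."""

    input_snps: int
    removed: Dict[str, int]
    surviving_snps: int
    site_maf: pd.Series = field(repr=False, default=None)
    line_missingness: pd.Series = field(repr=False, default=None)
    line_heterozygosity: pd.Series = field(repr=False, default=None)

    def __post_init__(self):
        total = sum(self.removed.values()) + self.surviving_snps
        if total != self.input_snps:
            raise QCError(
                f"QC bookkeeping broken: {self.removed} removed + "
                f"{self.surviving_snps} survivors != {self.input_snps} input SNPs"
            )

    def to_dict(self) -> dict:
        return {
            "input_snps": self.input_snps,
            "removed": dict(self.removed),
            "surviving_snps": self.surviving_snps,
        }


@dataclass
class KinshipKernel:
    """Line x line genomic relationship matrix (symmetric, numerically PSD)."""

    matrix: np.ndarray
    line_ids: Sequence[str]

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        self.line_ids = list(self.line_ids)
        n = len(self.line_ids)
        if self.matrix.shape != (n, n):
            raise QCError("kernel shape does not match line ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-10):
            raise QCError("kernel must be symmetric")
        if np.any(np.diag(self.matrix) <= 0):
            raise QCError("kernel diagonal must be strictly positive")
        w = np.linalg.eigvalsh(self.matrix)
        if w.min() < -1e-8 * max(w.max(), 1.0):
            raise QCError(f"kernel is not PSD (min eigenvalue {w.min():.3g})")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.line_ids, columns=self.line_ids)

    def reorder(self, ids: Sequence[str]) -> "KinshipKernel":
        pos = [self.line_ids.index(i) for i in ids]
        return KinshipKernel(self.matrix[np.ix_(pos, pos)], list(ids))


# ----------------------------------------------------------------------

def filter_snps(
    genotypes: GenotypeMatrix,
    max_missing: float = 0.2,
    min_depth: int = 10,
    min_maf: float = 0.025,
    biallelic_only: bool = True,
) -> tuple[GenotypeMatrix, SnpQCReport]:
    """Apply the sequential site filters and return survivors plus a report.

    Calls with depth <= ``min_depth`` are first set missing (depth is a
    per-call criterion), then sites are removed if missingness >=
    ``max_missing``, if multi-allelic (when ``biallelic_only``), or if
    MAF <= ``min_maf`` — all boundaries exclusive for survival, matching
    the printed "(<20%)", "(>10)", "(>2.5%)" conventions.
    """
    dosages = genotypes.dosages.copy()
    missing = genotypes.missing.copy()
    removed = {k: 0 for k in FILTER_ORDER}

    if genotypes.depth is not None:
        low = genotypes.depth <= min_depth
        missing |= low
        # depth never removes a whole site by itself here; sites that become
        # too sparse fall to the missingness filter, but we still report how
        # many sites lost every call to depth masking alone.
        all_masked = missing.all(axis=0) & ~genotypes.missing.all(axis=0)
        removed["depth"] = int(all_masked.sum())
        keep = ~all_masked
    else:
        keep = np.ones(genotypes.n_snps, dtype=bool)

    work = GenotypeMatrix(
        dosages=dosages[:, keep], missing=missing[:, keep],
        line_ids=genotypes.line_ids,
        snp_map=genotypes.snp_map.loc[keep].reset_index(drop=True),
    )

    miss_ok = work.site_missingness() < max_missing
    removed["missingness"] = int((~miss_ok).sum())
    work = work.take_snps(np.flatnonzero(miss_ok))

    if biallelic_only:
        bi = work.is_biallelic()
        removed["biallelic"] = int((~bi).sum())
        work = work.take_snps(np.flatnonzero(bi))

    maf_ok = work.maf() > min_maf
    removed["maf"] = int((~maf_ok).sum())
    work = work.take_snps(np.flatnonzero(maf_ok))

    if work.n_snps == 0:
        raise QCError("no markers pass QC")

    report = SnpQCReport(
        input_snps=genotypes.n_snps,
        removed=removed,
        surviving_snps=work.n_snps,
        site_maf=pd.Series(work.maf()),
        line_missingness=work.line_missingness(),
        line_heterozygosity=work.line_heterozygosity(),
    )
    return work, report


def impute_missing(genotypes: GenotypeMatrix, method: str = "marker_mean") -> GenotypeMatrix:
    """Fill missing calls per marker with the observed mean or mode.

    A deterministic single-site imputer: observed calls are never changed,
    and a marker with no observed call at all is an error.
    """
    if method not in ("marker_mean", "marker_mode"):
        raise ValueError(f"unknown imputation method {method!r}")
    if not genotypes.has_missing:
        return genotypes
    dosages = genotypes.dosages.copy()
    n_obs = (~genotypes.missing).sum(axis=0)
    if (n_obs == 0).any():
        j = int(np.flatnonzero(n_obs == 0)[0])
        name = f"{genotypes.snp_map['chrom'][j]}_{genotypes.snp_map['pos'][j]}"
        raise QCError(f"marker {name} has no observed calls; cannot impute")
    for j in np.flatnonzero(genotypes.missing.any(axis=0)):
        obs = dosages[~genotypes.missing[:, j], j]
        if method == "marker_mean":
            fill = obs.mean()
        else:
            vals, counts = np.unique(obs, return_counts=True)
            fill = vals[np.argmax(counts)]
        dosages[genotypes.missing[:, j], j] = fill
    return GenotypeMatrix(
        dosages=dosages, missing=np.zeros_like(genotypes.missing),
        line_ids=genotypes.line_ids, snp_map=genotypes.snp_map, depth=genotypes.depth,
    )


def compute_linear_kernel(genotypes: GenotypeMatrix, scaling: str = "vanraden") -> KinshipKernel:
    """Genomic relationship matrix from the linear kernel.

    With ``scaling='vanraden'`` (the field-standard choice behind "linear
    kernel"): K = W W' / c, where W is the dosage matrix centered by twice
    the panel allele frequency and c = sum_i 2 p_i (1 - p_i). The diagonal
    then averages ~1 for an outbred panel. ``scaling='correlation'``
    standardizes each marker to unit variance before forming W W' / m.
    """
    if genotypes.has_missing:
        raise QCError("kernel requires complete genotypes; impute first")
    p = genotypes.allele_freq()
    poly = (p > 0) & (p < 1)
    if poly.sum() < 2:
        raise QCError("need at least 2 polymorphic markers for a kernel")
    X = genotypes.dosages[:, poly]
    p = p[poly]
    if scaling == "vanraden":
        W = X - 2.0 * p
        c = float(np.sum(2.0 * p * (1.0 - p)))
        K = (W @ W.T) / c
    elif scaling == "correlation":
        W = (X - X.mean(axis=0)) / X.std(axis=0, ddof=0)
        K = (W @ W.T) / W.shape[1]
    else:
        raise ValueError(f"unknown kernel scaling {scaling!r}")
    # symmetrize against floating-point drift
    K = 0.5 * (K + K.T)
    return KinshipKernel(matrix=K, line_ids=genotypes.line_ids)


# ----------------------------------------------------------------------

def maf_spectrum(genotypes: GenotypeMatrix, n_bins: int = 20) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-SNP MAF values and a binned histogram over [0, 0.5]."""
    maf = genotypes.maf()
    counts, edges = np.histogram(maf[~np.isnan(maf)], bins=n_bins, range=(0.0, 0.5))
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    return maf, hist


def ld_decay(
    genotypes: GenotypeMatrix,
    max_dist_bp: int = 1_000_000,
    n_bins: int = 20,
    max_pairs_per_chrom: int = 200_000,
) -> pd.DataFrame:
    """Binned mean r^2 between marker pairs vs physical distance.

    r^2 is the squared Pearson correlation of dosages, computed within
    chromosomes only. Chromosomes carrying a single marker contribute
    nothing (a warning is emitted if no pair exists at all).
    """
    obs = genotypes.observed().filled(np.nan)
    dists, r2s = [], []
    for chrom, grp in genotypes.snp_map.groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        if len(idx) < 2:
            continue
        pos = grp["pos"].to_numpy()
        X = obs[:, idx]
        ii, jj = np.triu_indices(len(idx), k=1)
        d = pos[jj] - pos[ii]
        sel = d <= max_dist_bp
        ii, jj, d = ii[sel], jj[sel], d[sel]
        if len(ii) > max_pairs_per_chrom:
            pick = np.linspace(0, len(ii) - 1, max_pairs_per_chrom).astype(int)
            ii, jj, d = ii[pick], jj[pick], d[pick]
        if len(ii) == 0:
            continue
        Xc = X - np.nanmean(X, axis=0)
        Xc = np.where(np.isnan(Xc), 0.0, Xc)
        norms = np.sqrt((Xc ** 2).sum(axis=0))
        norms[norms == 0] = np.nan
        num = (Xc[:, ii] * Xc[:, jj]).sum(axis=0)
        r = num / (norms[ii] * norms[jj])
        dists.append(d)
        r2s.append(r ** 2)
    if not dists:
        warnings.warn("no within-chromosome marker pairs; LD decay is empty")
        return pd.DataFrame(columns=["dist_left", "dist_right", "mean_r2", "n_pairs"])
    d = np.concatenate(dists)
    r2 = np.concatenate(r2s)
    ok = ~np.isnan(r2)
    d, r2 = d[ok], r2[ok]
    edges = np.linspace(0, max_dist_bp, n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = which == b
        if sel.any():
            rows.append((edges[b], edges[b + 1], float(r2[sel].mean()), int(sel.sum())))
    return pd.DataFrame(rows, columns=["dist_left", "dist_right", "mean_r2", "n_pairs"])
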