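"""Line x SNP dosage matrices with marker maps.

The central genotype container is :class:`GenotypeMatrix`: an integer dosage
matrix (count of alternate alleles, 0/1/2) over S0 lines, a boolean missing
mask, an optional per-call read-depth matrix, and a marker map (chromosome,
position, alleles) kept sorted by chromosome then position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError

MAP_COLUMNS = ("chrom", "pos", "ref", "alt")


@dataclass
class GenotypeMatrix:
    """Dosage matrix of shape (n_lines, n_snps) plus marker metadata.

    Parameters
    ----------
    dosages : ndarray of float
        Allele-dosage calls in {0, 1, 2}; entries under ``missing`` are
        ignored (and conventionally set to -1 or nan). After imputation
        dosages may be fractional (marker-mean imputation).
    missing : ndarray of bool
        True where the call is missing.
    line_ids : sequence of str
        Unique line identifiers, one per row.
    snp_map : DataFrame
        One row per SNP with columns chrom, pos, ref, alt. Multi-allelic
        sites carry a comma-separated ``alt`` field.
    depth : ndarray of int, optional
        Per-call read depth (same shape as dosages).
    """

    dosages: np.ndarray
    missing: np.ndarray
    line_ids: Sequence[str]
    snp_map: pd.DataFrame
    depth: Optional[np.ndarray] = None
    _validated: bool = field(default=False, repr=False)

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.missing = np.asarray(self.missing, dtype=bool)
        self.line_ids = list(self.line_ids)
        if self.dosages.shape != self.missing.shape:
            raise ConfigurationError("dosages and missing mask shapes differ")
        if len(self.line_ids) != self.dosages.shape[0]:
            raise ConfigurationError("line_ids length does not match dosage rows")
        if len(set(self.line_ids)) != len(self.line_ids):
            raise ConfigurationError("line ids must be unique")
        if len(self.snp_map) != self.dosages.shape[1]:
            raise ConfigurationError("snp_map length does not match dosage columns")
        missing_cols = set(MAP_COLUMNS) - set(self.snp_map.columns)
        if missing_cols:
            raise ConfigurationError(f"snp_map lacks columns: {sorted(missing_cols)}")
        self.snp_map = self.snp_map.reset_index(drop=True)
        if (self.snp_map["pos"] < 0).any():
            raise ConfigurationError("marker positions must be non-negative")
        # map must be sorted by chromosome then position
        m = self.snp_map
        for _, grp in m.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ConfigurationError("marker map not sorted by position within chromosome")
        obs = self.dosages[~self.missing]
        if obs.size and not np.all(np.isin(np.round(obs, 6), [0.0, 1.0, 2.0]) | ((obs >= 0) & (obs <= 2))):
            raise ConfigurationError("dosages must lie in [0, 2]")
        self._validated = True

    # ------------------------------------------------------------------
    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool(self.missing.any())

    def observed(self) -> np.ma.MaskedArray:
        """Dosages as a masked array (mask = missing)."""
        return np.ma.MaskedArray(self.dosages, mask=self.missing)

    def is_biallelic(self) -> np.ndarray:
        """Boolean per SNP: exactly one alternate allele."""
        alt = self.snp_map["alt"].astype(str)
        return (~alt.str.contains(",")).to_numpy()

    # ------------------------------------------------------------------
    def allele_freq(self) -> np.ndarray:
        """Alternate-allele frequency per SNP from observed calls."""
        obs = self.observed()
        with np.errstate(invalid="ignore"):
            p = obs.mean(axis=0).filled(np.nan) / 2.0
        return np.asarray(p)

    def maf(self) -> np.ndarray:
        """Minor-allele frequency per SNP (in [0, 0.5])."""
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def site_missingness(self) -> np.ndarray:
        return self.missing.mean(axis=0)

    def line_missingness(self) -> pd.Series:
        return pd.Series(self.missing.mean(axis=1), index=self.line_ids)

    def line_heterozygosity(self) -> pd.Series:
        """Fraction of observed calls that are heterozygous, per line."""
        het = (self.dosages == 1) & ~self.missing
        n_obs = (~self.missing).sum(axis=1)
        with np.errstate(invalid="ignore"):
            frac = np.where(n_obs > 0, het.sum(axis=1) / n_obs, np.nan)
        return pd.Series(frac, index=self.line_ids)

    # ------------------------------------------------------------------
    def take_snps(self, idx: np.ndarray) -> "GenotypeMatrix":
        """Subset to SNP columns ``idx`` (boolean or integer index)."""
        idx = np.asarray(idx)
        return GenotypeMatrix(
            dosages=self.dosages[:, idx],
            missing=self.missing[:, idx],
            line_ids=self.line_ids,
            snp_map=self.snp_map.iloc[idx].reset_index(drop=True)
            if idx.dtype != bool
            else self.snp_map.loc[idx].reset_index(drop=True),
            depth=None if self.depth is None else self.depth[:, idx],
        )

    def take_lines(self, ids: Sequence[str]) -> "GenotypeMatrix":
        pos = [self.line_ids.index(i) for i in ids]
        return GenotypeMatrix(
            dosages=self.dosages[pos],
            missing=self.missing[pos],
            line_ids=list(ids),
            snp_map=self.snp_map,
            depth=None if self.depth is None else self.depth[pos],
        )

    def to_frame(self) -> pd.DataFrame:
        """Line x SNP dosage DataFrame (missing as NaN), SNPs named chrom_pos."""
        names = self.snp_map["chrom"].astype(str) + "_" + self.snp_map["pos"].astype(str)
        vals = self.dosages.copy()
        vals[self.missing] = np.nan
        return pd.DataFrame(vals, index=self.line_ids, columns=names)
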