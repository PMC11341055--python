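"""SNP filters, imputation, kinship kernel and diversity summaries."""

import numpy as np
import pandas as pd
import pytest

from alugs import (
    GenotypeMatrix, QCError, compute_linear_kernel, filter_snps, impute_missing,
    ld_decay, maf_spectrum, simulate_genotypes, SimulationConfig,
)


def _matrix(dosages, missing=None, alt=None, depth=None, chrom=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snp_map = pd.DataFrame({
        "chrom": chrom if chrom is not None else ["chr1"] * m,
        "pos": np.arange(1, m + 1) * 100,
        "ref": ["A"] * m,
        "alt": alt if alt is not None else ["T"] * m,
    })
    return GenotypeMatrix(
        dosages=dosages,
        missing=np.zeros_like(dosages, dtype=bool) if missing is None else np.asarray(missing, bool),
        line_ids=[f"L{i}" for i in range(n)],
        snp_map=snp_map,
        depth=depth,
    )


@pytest.fixture
def planted_fixture():
    """10 SNPs over 20 lines with exactly three constructed violations.

    SNP 0: 25% missing (>= the 20% ceiling); SNP 1: MAF exactly 0.025
    (one heterozygote in 40 alleles, not strictly above the threshold);
    SNP 2: triallelic. The remaining 7 are clean and common.
    """
    rng = np.random.default_rng(0)
    n = 20
    dosages = rng.integers(0, 3, size=(n, 10)).astype(float)
    missing = np.zeros((n, 10), dtype=bool)
    missing[:5, 0] = True                      # 25% missing
    dosages[:, 1] = 0.0
    dosages[0, 1] = 1.0                        # MAF = 1/40 = 0.025
    # guarantee the clean SNPs are common
    for j in range(3, 10):
        col = dosages[:, j]
        if min(col.sum(), 2 * n - col.sum()) / (2 * n) <= 0.1:
            dosages[:8, j] = 1.0
    alt = ["T"] * 10
    alt[2] = "T,G"                             # triallelic
    return _matrix(dosages, missing=missing, alt=alt)


class TestFilterSnps:
    def test_planted_violations_counted_per_filter(self, planted_fixture):
        out, report = filter_snps(planted_fixture)
        assert out.n_snps == 7
        assert report.removed == {"depth": 0, "missingness": 1, "biallelic": 1, "maf": 1}
        assert report.surviving_snps + sum(report.removed.values()) == 10

    def test_maf_boundary_is_strict(self):
        # MAF exactly 0.025 is NOT strictly above the threshold -> removed
        n = 20
        d = np.zeros((n, 2))
        d[0, 0] = 1.0          # MAF 0.025
        d[: n // 2, 1] = 2.0   # MAF 0.5
        with_boundary, report = filter_snps(_matrix(d))
        assert with_boundary.n_snps == 1
        assert report.removed["maf"] == 1

    def test_clean_input_passes_through(self):
        d = np.array([[0, 1, 2], [2, 1, 0], [1, 1, 1], [0, 2, 2]], dtype=float)
        out, report = filter_snps(_matrix(d))
        assert out.n_snps == 3
        assert sum(report.removed.values()) == 0
        assert np.array_equal(out.dosages, d)

    def test_low_depth_calls_masked_before_site_filters(self):
        d = np.ones((10, 2))
        depth = np.full((10, 2), 50)
        depth[:3, 0] = 5  # 30% of calls shallow -> site 0 trips missingness
        out, report = filter_snps(_matrix(d * np.array([1, 1]), depth=depth))
        assert report.removed["missingness"] == 1
        assert out.n_snps == 1

    def test_no_survivors_is_an_error(self):
        d = np.zeros((6, 2))  # monomorphic, MAF 0
        with pytest.raises(QCError, match="no markers pass"):
            filter_snps(_matrix(d))

    def test_filter_idempotence(self, planted_fixture):
        once, _ = filter_snps(planted_fixture)
        twice, report = filter_snps(once)
        assert twice.n_snps == once.n_snps
        assert sum(report.removed.values()) == 0


class TestImpute:
    def test_marker_mean(self):
        d = np.array([[0.0], [2.0], [0.0]])
        miss = np.array([[False], [False], [True]])
        out = impute_missing(_matrix(d, missing=miss), method="marker_mean")
        assert out.dosages[2, 0] == pytest.approx(1.0)
        assert not out.has_missing

    def test_marker_mode(self):
        d = np.array([[2.0], [2.0], [0.0], [0.0]])
        miss = np.array([[False], [False], [False], [True]])
        out = impute_missing(_matrix(d, missing=miss), method="marker_mode")
        assert out.dosages[3, 0] == 2.0

    def test_complete_matrix_unchanged(self):
        g = _matrix(np.array([[0.0, 1.0], [2.0, 1.0]]))
        assert impute_missing(g) is g

    def test_fully_missing_marker_named_in_error(self):
        d = np.zeros((3, 2))
        miss = np.zeros((3, 2), bool)
        miss[:, 1] = True
        with pytest.raises(QCError, match="chr1_200"):
            impute_missing(_matrix(d, missing=miss))


class TestKernel:
    def test_double_loop_oracle(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(5, 20)).astype(float)
        g = _matrix(d)
        K = compute_linear_kernel(g).matrix
        # independent elementwise computation
        p = d.mean(axis=0) / 2
        poly = (p > 0) & (p < 1)
        W = d[:, poly] - 2 * p[poly]
        c = float(np.sum(2 * p[poly] * (1 - p[poly])))
        expected = np.empty((5, 5))
        for i in range(5):
            for j in range(5):
                expected[i, j] = sum(W[i, k] * W[j, k] for k in range(W.shape[1])) / c
        assert np.allclose(K, expected, atol=1e-10)

    def test_duplicate_lines_share_rows(self):
        d = np.array([[0, 1, 2, 1], [0, 1, 2, 1], [2, 1, 0, 0]], dtype=float)
        K = compute_linear_kernel(_matrix(d)).matrix
        assert K[0, 1] == pytest.approx(K[0, 0])
        assert np.allclose(K[0], K[1])

    def test_symmetric_and_psd(self, tiny_data):
        geno, _, _ = tiny_data
        K = compute_linear_kernel(geno)
        assert np.allclose(K.matrix, K.matrix.T)
        assert np.linalg.eigvalsh(K.matrix).min() >= -1e-8
        assert np.mean(np.diag(K.matrix)) == pytest.approx(1.0, abs=0.35)

    def test_marker_duplication_equivariance(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(6, 10)).astype(float)
        K1 = compute_linear_kernel(_matrix(d)).matrix
        K2 = compute_linear_kernel(_matrix(np.hstack([d, d]))).matrix
        assert np.allclose(K1, K2)

    def test_monomorphic_only_errors(self):
        with pytest.raises(QCError):
            compute_linear_kernel(_matrix(np.full((4, 3), 2.0)))


class TestDiversity:
    def test_maf_hand_value(self):
        g = _matrix(np.array([[0.0], [0.0], [1.0], [2.0]]))
        assert g.maf()[0] == pytest.approx(3.0 / 8.0)
        maf, hist = maf_spectrum(g)
        assert hist["count"].sum() == 1

    def test_perfectly_correlated_pair_r2(self):
        d = np.array([[0, 0], [1, 1], [2, 2], [0, 0], [2, 2]], dtype=float)
        out = ld_decay(_matrix(d), max_dist_bp=1000, n_bins=1)
        assert out["mean_r2"].iloc[0] == pytest.approx(1.0)

    def test_independent_markers_null_r2(self):
        cfg = SimulationConfig(n_lines=200, n_snps=300, n_chromosomes=3, ld_rho=0.0,
                               n_blocks=24, plots_per_block=11, n_checks=3,
                               check_reps=3, seed=3)
        g = simulate_genotypes(cfg)
        out = ld_decay(g, max_dist_bp=10_000_000, n_bins=1)
        assert out["mean_r2"].iloc[0] == pytest.approx(1.0 / 200, abs=2.0 / 200)

    def test_single_marker_per_chrom_warns_empty(self):
        d = np.array([[0.0, 1.0], [1.0, 2.0], [2.0, 0.0]])
        g = _matrix(d, chrom=["chr1", "chr2"])
        with pytest.warns(UserWarning, match="no within-chromosome"):
            out = ld_decay(g)
        assert out.empty
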