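"""Synthetic-data generator: determinism, MAF/LD targets, layout contract."""

import numpy as np
import pandas as pd
import pytest

from alugs import (
    ConfigurationError, LayoutError, SimulationConfig, simulate_dataset,
    simulate_field_trial, simulate_genotypes, simulate_true_effects,
)


def _cfg(**kw):
    base = dict(n_lines=60, n_snps=120, n_chromosomes=4, n_blocks=8,
                plots_per_block=11, n_checks=3, check_reps=3, seed=1)
    base.update(kw)
    return SimulationConfig(**base)


class TestGenotypes:
    def test_determinism_bit_identical(self):
        a = simulate_genotypes(_cfg(seed=5))
        b = simulate_genotypes(_cfg(seed=5))
        assert np.array_equal(a.dosages, b.dosages)
        assert a.snp_map.equals(b.snp_map)
        c = simulate_genotypes(_cfg(seed=6))
        assert not np.array_equal(a.dosages, c.dosages)

    def test_dosages_integral_and_map_sorted(self):
        g = simulate_genotypes(_cfg())
        assert set(np.unique(g.dosages)) <= {0.0, 1.0, 2.0}
        for _, grp in g.snp_map.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing

    def test_point_maf_range_is_hit(self):
        # all target frequencies at 0.25: realized MAFs within binomial noise
        g = simulate_genotypes(_cfg(n_lines=400, n_snps=200, n_blocks=50,
                                    maf_range=(0.25, 0.25), inbreeding_f=0.0, seed=2))
        assert np.all(np.abs(g.maf() - 0.25) < 0.03 + 3 * np.sqrt(0.25 * 0.75 / 800))

    def test_independence_limit_r2(self):
        # ld_rho = 0: adjacent-marker r^2 has null expectation ~ 1/n_lines
        n = 334
        g = simulate_genotypes(_cfg(n_lines=n, n_snps=400, ld_rho=0.0, n_blocks=40, seed=3))
        d = g.dosages
        r2 = []
        for _, grp in g.snp_map.groupby("chrom"):
            idx = grp.index.to_numpy()
            for j in range(len(idx) - 1):
                r2.append(np.corrcoef(d[:, idx[j]], d[:, idx[j + 1]])[0, 1] ** 2)
        assert np.mean(r2) == pytest.approx(1.0 / n, abs=3.0 / n)

    def test_ld_chain_tracks_mixing_parameter(self):
        # adjacent dosage correlation approximately ld_rho (attenuated by
        # clipping + heterozygote thinning); and monotone in ld_rho
        means = {}
        for rho in (0.0, 0.5, 0.9):
            g = simulate_genotypes(_cfg(n_lines=300, n_snps=300, ld_rho=rho,
                                        inbreeding_f=0.0, n_blocks=36, seed=4))
            d = g.dosages
            rs = []
            for _, grp in g.snp_map.groupby("chrom"):
                idx = grp.index.to_numpy()
                rs.extend(np.corrcoef(d[:, idx[j]], d[:, idx[j + 1]])[0, 1]
                          for j in range(len(idx) - 1))
            means[rho] = np.mean(rs)
        assert means[0.0] < means[0.5] < means[0.9]
        assert means[0.9] == pytest.approx(0.9, abs=0.15)

    def test_inbreeding_thins_heterozygotes(self):
        f = 0.4
        g0 = simulate_genotypes(_cfg(n_lines=400, n_snps=300, n_blocks=50, inbreeding_f=0.0, seed=5))
        gf = simulate_genotypes(_cfg(n_lines=400, n_snps=300, n_blocks=50, inbreeding_f=f, seed=5))
        het0 = (g0.dosages == 1).mean()
        hetf = (gf.dosages == 1).mean()
        assert hetf == pytest.approx(het0 * (1 - f), rel=0.1)

    def test_missingness_mask(self):
        g = simulate_genotypes(_cfg(missing_rate=0.1, seed=6))
        assert g.missing.mean() == pytest.approx(0.1, abs=0.03)

    @pytest.mark.parametrize("bad", [
        dict(maf_range=(0.0, 0.5)), dict(maf_range=(0.1, 0.6)),
        dict(ld_rho=1.0), dict(rho_g=1.5), dict(marker_share=0.0),
        dict(h2={}),
    ])
    def test_infeasible_config_rejected(self, bad):
        with pytest.raises((ConfigurationError, LayoutError)):
            _cfg(**bad)


class TestTrueEffects:
    def test_rho_one_identical_values(self):
        cfg = _cfg(rho_g=1.0)
        truth = simulate_true_effects(simulate_genotypes(cfg), cfg)
        a = truth.true_bv[("YLD", "ALU")]
        b = truth.true_bv[("YLD", "LIM")]
        assert np.corrcoef(a, b)[0, 1] == pytest.approx(1.0, abs=1e-9)

    def test_rho_zero_null_correlation(self):
        cfg = _cfg(n_lines=1000, n_snps=200, rho_g=0.0, n_blocks=120, seed=8)
        truth = simulate_true_effects(simulate_genotypes(cfg), cfg)
        r = np.corrcoef(truth.true_bv[("YLD", "ALU")], truth.true_bv[("YLD", "LIM")])[0, 1]
        assert abs(r) < 0.1

    def test_rho_target_monte_carlo(self):
        rs = []
        for seed in range(20):
            cfg = _cfg(n_lines=334, n_snps=150, rho_g=0.6, n_blocks=42, seed=seed)
            truth = simulate_true_effects(simulate_genotypes(cfg), cfg)
            rs.append(np.corrcoef(truth.true_bv[("FL", "ALU")],
                                  truth.true_bv[("FL", "LIM")])[0, 1])
        assert np.mean(rs) == pytest.approx(0.6, abs=0.1)

    def test_genetic_sd_matches_target(self, tiny_cfg, tiny_data):
        _, truth, _ = tiny_data
        for trait in tiny_cfg.traits:
            sd = truth.true_bv[(trait, "ALU")].std(ddof=1)
            assert sd == pytest.approx(tiny_cfg.genetic_sd[trait], rel=1e-6)

    def test_trait_correlation_matrix(self):
        T = np.eye(4)
        T[0, 2] = T[2, 0] = -0.4  # FL vs YLD antagonism
        cfg = _cfg(n_lines=600, n_snps=200, trait_corr=T, n_blocks=72, seed=9)
        truth = simulate_true_effects(simulate_genotypes(cfg), cfg)
        r = np.corrcoef(truth.true_bv[("FL", "ALU")], truth.true_bv[("YLD", "ALU")])[0, 1]
        assert r == pytest.approx(-0.4, abs=0.12)


class TestFieldTrial:
    def test_prep_counts_and_layout_audit(self, tiny_cfg, tiny_data):
        _, _, plots = tiny_data
        n_dup = round(0.25 * tiny_cfg.n_lines)
        for cond, sub in plots.groupby("condition"):
            assert len(sub) == tiny_cfg.capacity()
            # unique plot coordinates
            assert not sub.duplicated(["block", "row", "col"]).any()
            counts = sub.loc[~sub.is_check, "entry_id"].value_counts()
            assert (counts == 2).sum() == n_dup
            assert set(counts.unique()) == {1, 2}
            check_counts = sub.loc[sub.is_check, "entry_id"].value_counts()
            assert check_counts.min() >= tiny_cfg.check_reps

    def test_default_scale_replication_count(self):
        cfg = SimulationConfig(n_lines=334, n_snps=10, seed=0)
        assert cfg.n_duplicated() == 84  # round(0.25 * 334) = round(83.5)
        assert cfg.capacity() == 36 * 14 == 504

    def test_capacity_violation_message(self):
        with pytest.raises(LayoutError, match="capacity"):
            _cfg(n_blocks=6)

    def test_noise_free_limit(self):
        cfg = _cfg(spatial_sd=0.0, row_sd=0.0, col_sd=0.0,
                   h2={(t, c): 1 - 1e-9 for t in ("FL", "PH", "YLD", "ZN")
                       for c in ("ALU", "LIM")})
        geno, truth, plots = simulate_dataset(cfg)
        sub = plots[(plots.condition == "ALU") & ~plots.is_check]
        expect = (truth.true_bv[("FL", "ALU")].reindex(sub.entry_id).to_numpy()
                  + cfg.env_means[("FL", "ALU")])
        assert np.allclose(sub["FL"].to_numpy(), expect, atol=1e-3)

    def test_heritability_bookkeeping(self):
        # var(bv) / var(phenotype) converges to h2 without spatial noise
        cfg = _cfg(n_lines=1000, n_snps=100, n_blocks=120, spatial_sd=0.0,
                   row_sd=0.0, col_sd=0.0, seed=11)
        _, truth, plots = simulate_dataset(cfg)
        sub = plots[(plots.condition == "ALU") & ~plots.is_check]
        sub = sub.drop_duplicates("entry_id")
        vg = truth.true_bv[("YLD", "ALU")].var(ddof=1)
        vp = sub["YLD"].var(ddof=1)
        assert vg / vp == pytest.approx(cfg.h2[("YLD", "ALU")], abs=0.05)

    def test_stage_determinism(self, tiny_cfg, tiny_data):
        geno, truth, plots = tiny_data
        geno2, truth2, plots2 = simulate_dataset(tiny_cfg)
        assert np.array_equal(geno.dosages, geno2.dosages)
        pd.testing.assert_frame_equal(truth.true_bv, truth2.true_bv)
        pd.testing.assert_frame_equal(plots, plots2)
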