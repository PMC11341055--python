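"""Gibbs-sampled GBLUP: component structure, oracle equivalence, predictions."""

import numpy as np
import pandas as pd
import pytest

from alugs import (
    ConfigurationError, DegenerateDataError, KinshipKernel, build_components,
    compute_linear_kernel, fit_gibbs, predict_gebv, stack_blues,
    variance_proportions,
)
from alugs.gblup import fit_model
from tests.conftest import make_blues

MC = dict(burn_in=300, n_iter=2300, thin=4)


@pytest.fixture(scope="module")
def kernel(tiny_data):
    geno, _, _ = tiny_data
    return compute_linear_kernel(geno)


@pytest.fixture(scope="module")
def blues(tiny_cfg, tiny_data):
    _, truth, _ = tiny_data
    return make_blues(truth, tiny_cfg, trait="YLD", noise_seed=1)


class TestBuildComponents:
    def test_component_counts_per_model(self, kernel):
        assert [c.name for c in build_components("SM", kernel, ["ALU"])] == ["g", "l"]
        assert [c.name for c in build_components("MM", kernel, ["ALU", "LIM"])] == ["g", "l"]
        mds = build_components("MDs", kernel, ["ALU", "LIM"])
        assert [c.name for c in mds] == ["g", "l", "ge"]
        assert mds[2].kind == "deviation" and mds[2].variance_group == "ge"
        mde = build_components("MDe", kernel, ["ALU", "LIM"])
        assert [c.name for c in mde] == ["g", "l", "dev_ALU", "dev_LIM"]
        assert len({c.variance_group for c in mde}) == 4

    def test_invalid_requests(self, kernel):
        with pytest.raises(ConfigurationError):
            build_components("XX", kernel, ["ALU"])
        with pytest.raises(ConfigurationError):
            build_components("SM", kernel, ["ALU", "LIM"])
        with pytest.raises(ConfigurationError):
            build_components("MDe", kernel, ["ALU"])


class TestStackedData:
    def test_duplicate_records_rejected(self, kernel):
        df = pd.DataFrame({
            "entry_id": ["L01", "L01"], "condition": ["ALU", "ALU"],
            "trait": "YLD", "blue": [1.0, 2.0], "is_check": False,
        })
        with pytest.raises(ConfigurationError, match="more than one record"):
            stack_blues(df, "YLD", kernel.line_ids)

    def test_exclusion_mask(self, blues, kernel):
        held = kernel.line_ids[:5]
        data = stack_blues(blues, "YLD", kernel.line_ids, exclude={"ALU": held})
        assert not any((e in held) and (c == "ALU")
                       for e, c in zip(data.entries, data.conditions))
        assert any((e in held) and (c == "LIM")
                   for e, c in zip(data.entries, data.conditions))


class TestSampler:
    def test_retained_sample_bookkeeping(self, blues, kernel):
        fit = fit_model("MM", blues, kernel, "YLD", ("ALU", "LIM"),
                        burn_in=100, n_iter=600, thin=5, seed=0)
        assert fit.n_samples == (600 - 100) // 5
        # the production default echoes the same arithmetic
        assert (70000 - 5000) // 5 == 13000

    def test_seeded_chains_reproducible(self, blues, kernel):
        f1 = fit_model("MM", blues, kernel, "YLD", ("ALU", "LIM"), seed=9, **MC)
        f2 = fit_model("MM", blues, kernel, "YLD", ("ALU", "LIM"), seed=9, **MC)
        pd.testing.assert_series_equal(f1.effects["g"], f2.effects["g"])
        assert f1.variances == f2.variances

    def test_fixed_variance_posterior_matches_gls_blup(self, tiny_cfg, tiny_data):
        geno, truth, _ = tiny_data
        K = compute_linear_kernel(geno)
        blues = make_blues(truth, tiny_cfg, noise_seed=3)
        data = stack_blues(blues, "YLD", K.line_ids)
        comps = build_components("MM", K, ("ALU", "LIM"))
        sg2, sl2, se2 = 2.0e5, 5.0e4, 1.3e5
        fit = fit_gibbs(data, comps, burn_in=500, n_iter=8500, thin=4, seed=2,
                        fix_variances={"g": sg2, "l": sl2}, fix_residual=se2)
        # direct mixed-model-equation solve
        n = len(K.line_ids)
        pos = {l: i for i, l in enumerate(K.line_ids)}
        nr = data.n_records
        X = np.zeros((nr, 2))
        X[np.arange(nr), [0 if c == "ALU" else 1 for c in data.conditions]] = 1.0
        M = np.zeros((nr, n))
        M[np.arange(nr), [pos[e] for e in data.entries]] = 1.0
        W = np.hstack([M, M])
        Ginv = np.block([
            [np.linalg.inv(K.matrix + 1e-10 * np.eye(n)) / sg2, np.zeros((n, n))],
            [np.zeros((n, n)), np.eye(n) / sl2]])
        A = np.block([[X.T @ X, X.T @ W], [W.T @ X, W.T @ W + se2 * Ginv]])
        sol = np.linalg.solve(A, np.concatenate([X.T @ data.y, W.T @ data.y]))
        u = sol[2:2 + n] + sol[2 + n:]
        est = (fit.effects["g"] + fit.effects["l"]).to_numpy()
        rel = np.sqrt(np.mean((est - u) ** 2)) / np.sqrt(np.mean(u ** 2))
        assert rel < 0.05

    def test_degenerate_response_rejected(self, kernel):
        df = pd.DataFrame({
            "entry_id": kernel.line_ids, "condition": "ALU", "trait": "YLD",
            "blue": 1.0, "is_check": False,
        })
        with pytest.raises(DegenerateDataError):
            stack_blues(df, "YLD", kernel.line_ids)

    def test_non_psd_kernel_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises((ConfigurationError, Exception)):
            KinshipKernel(matrix=bad, line_ids=["a", "b"])


class TestPredictions:
    def test_mm_gebv_identical_across_conditions(self, blues, kernel):
        fit = fit_model("MM", blues, kernel, "YLD", ("ALU", "LIM"), seed=1, **MC)
        a = predict_gebv(fit, kernel.line_ids, "ALU")
        b = predict_gebv(fit, kernel.line_ids, "LIM")
        assert np.allclose(a, b)

    def test_sparse_entry_predicted_through_kernel(self, blues, kernel):
        held = kernel.line_ids[:6]
        fit = fit_model("MDs", blues, kernel, "YLD", ("ALU", "LIM"),
                        exclude={"ALU": held}, seed=1, **MC)
        pred = predict_gebv(fit, held, "ALU")
        assert np.all(np.isfinite(pred))
        assert pred.std() > 0

    def test_unknown_entry_raises(self, blues, kernel):
        fit = fit_model("MM", blues, kernel, "YLD", ("ALU", "LIM"), seed=1, **MC)
        with pytest.raises(KeyError):
            predict_gebv(fit, ["nope"], "ALU")

    def test_ridge_limit_shrinks_to_zero(self):
        # identity kernel, line intercept off: plain ridge; as noise/signal
        # ratio explodes the posterior mean effects shrink toward zero
        rng = np.random.default_rng(0)
        ids = [f"L{i}" for i in range(30)]
        K = KinshipKernel(np.eye(30), ids)
        df = pd.DataFrame({"entry_id": ids, "condition": "ALU", "trait": "YLD",
                           "blue": rng.normal(0, 1, 30), "is_check": False})
        data = stack_blues(df, "YLD", ids)
        comps = build_components("SM", K, ("ALU",))
        norms = []
        for ratio in (1.0, 1e4):
            # long chain: under heavy shrinkage the posterior mean is tiny
            # relative to the posterior SD, so MC noise needs averaging down
            fit = fit_gibbs(data, comps, burn_in=300, n_iter=10300, thin=2, seed=4,
                            fix_variances={"g": 1.0, "l": 1e-10}, fix_residual=ratio)
            norms.append(float(np.abs(predict_gebv(fit, ids, "ALU",
                                                   include_line_intercept=False)).mean()))
        assert norms[1] < 0.1 * norms[0]

    def test_permutation_exchangeability(self, tiny_cfg, tiny_data):
        geno, truth, _ = tiny_data
        K = compute_linear_kernel(geno)
        blues = make_blues(truth, tiny_cfg, noise_seed=5)
        fit = fit_model("MM", blues, K, "YLD", ("ALU", "LIM"), seed=6, **MC)
        perm = list(reversed(K.line_ids))
        fitp = fit_model("MM", blues, K.reorder(perm), "YLD", ("ALU", "LIM"),
                         seed=6, **MC)
        a = predict_gebv(fit, K.line_ids, "ALU")
        b = predict_gebv(fitp, K.line_ids, "ALU")
        # same model, permuted parameterization: same posterior up to MC error
        assert np.corrcoef(a, b)[0, 1] > 0.98


class TestNestingAndVariances:
    def test_proportions_sum_to_one(self, blues, kernel):
        fit = fit_model("MDe", blues, kernel, "YLD", ("ALU", "LIM"), seed=2, **MC)
        props = variance_proportions(fit)
        assert props.sum() == pytest.approx(1.0, abs=1e-9)
        assert set(props.index) == {"residual", "g", "l", "dev_ALU", "dev_LIM"}

    def test_noise_only_data_gives_small_genetic_share(self, kernel):
        rng = np.random.default_rng(3)
        ids = kernel.line_ids
        df = pd.concat([
            pd.DataFrame({"entry_id": ids, "condition": c, "trait": "YLD",
                          "blue": rng.normal(0, 1, len(ids)), "is_check": False})
            for c in ("ALU", "LIM")], ignore_index=True)
        fit = fit_model("MM", df, kernel, "YLD", ("ALU", "LIM"), seed=3, **MC)
        assert variance_proportions(fit)["g"] < 0.25

    def test_mds_with_zero_deviation_matches_mm(self, blues, kernel):
        mm = fit_model("MM", blues, kernel, "YLD", ("ALU", "LIM"), seed=5, **MC)
        mds0 = fit_model("MDs", blues, kernel, "YLD", ("ALU", "LIM"), seed=5,
                         fix_variances={"ge": 1e-10}, **MC)
        a = predict_gebv(mm, kernel.line_ids, "ALU")
        b = predict_gebv(mds0, kernel.line_ids, "ALU")
        rel = np.sqrt(np.mean((a - b) ** 2)) / a.std()
        assert rel < 0.1

    def test_gxe_share_responds_to_simulated_interaction(self, tiny_cfg):
        from alugs import SimulationConfig, simulate_genotypes, simulate_true_effects
        import dataclasses

        shares = {}
        for rho in (0.2, 1.0):
            cfg = dataclasses.replace(tiny_cfg, rho_g=rho, seed=20)
            geno = simulate_genotypes(cfg)
            truth = simulate_true_effects(geno, cfg)
            K = compute_linear_kernel(geno)
            blues = make_blues(truth, cfg, noise_seed=21)
            fit = fit_model("MDs", blues, K, "YLD", ("ALU", "LIM"), seed=22, **MC)
            shares[rho] = variance_proportions(fit)["ge"]
        assert shares[0.2] > shares[1.0]
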