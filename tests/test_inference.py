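"""Restricted permutation, FDR, bootstrap alignment and cross-validation."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sleepcca import (
    BlockMatrix,
    ConfoundTable,
    SyntheticConfig,
    bh_fdr,
    bootstrap_loadings,
    build_blocks,
    compute_loadings,
    crossval_cca,
    fit_cca,
    generate_cohort,
    generate_phenotypes,
    orient_components,
    permutation_test,
    posthoc_associations,
    residualize,
)
from sleepcca.inference import (
    is_valid_permutation,
    match_components,
    sample_permutation,
)

from conftest import random_blocks


def _cohort_frame(families):
    """Tiny cohort from a list of (family_id, relatedness, size)."""
    rows = []
    for fid, cls, size in families:
        for _ in range(size):
            rows.append((f"S{len(rows)}", fid, cls, 30.0, 0, 15))
    return pd.DataFrame(
        rows,
        columns=["subject_id", "family_id", "relatedness", "age", "sex", "education"],
    )


class TestExchangeabilityBlocks:
    def test_brute_force_enumeration_of_valid_permutations(self):
        # 2 MZ pairs + 1 sibling pair: 2! pair swaps x 2^2 within-MZ flips
        # x 1 x 2 within-SIB flips = 16 valid permutations of 6 subjects
        cohort = _cohort_frame(
            [("f1", "MZ", 2), ("f2", "MZ", 2), ("f3", "SIB", 2)]
        )
        blocks = build_blocks(cohort)
        valid = [
            p
            for p in itertools.permutations(range(6))
            if is_valid_permutation(blocks, np.array(p))
        ]
        assert len(valid) == 16
        assert blocks.n_valid_permutations() == 16

    def test_sampled_permutations_always_valid(self):
        cohort = _cohort_frame(
            [("f1", "MZ", 2), ("f2", "MZ", 2), ("f3", "SIB", 2), ("f4", "SINGLETON", 1)]
        )
        blocks = build_blocks(cohort)
        rng = np.random.default_rng(0)
        seen = set()
        for _ in range(200):
            perm = sample_permutation(blocks, rng)
            assert is_valid_permutation(blocks, perm)
            seen.add(tuple(perm))
        # all 16 distinct block-valid permutations should appear
        assert len(seen) == 16

    def test_identity_always_valid(self):
        cohort = _cohort_frame([("f1", "DZ", 2), ("f2", "SINGLETON", 1)])
        blocks = build_blocks(cohort)
        assert is_valid_permutation(blocks, np.arange(3))

    def test_all_singletons_reduce_to_free_permutation(self):
        cohort = _cohort_frame([(f"f{i}", "SINGLETON", 1) for i in range(5)])
        blocks = build_blocks(cohort)
        import math

        assert blocks.n_valid_permutations() == math.factorial(5)

    def test_missing_family_id_becomes_singleton(self):
        cohort = _cohort_frame([("f1", "MZ", 2)])
        cohort.loc[2] = ["S2", None, "SINGLETON", 30.0, 0, 15]
        blocks = build_blocks(cohort)
        assert len(blocks.families) == 2


class TestPermutationTest:
    def test_strong_signal_attains_minimal_p(self):
        cfg = SyntheticConfig(n_subjects=770, n_bps_vars=30, seed=4)
        cohort = generate_cohort(cfg)
        X, Y, _ = generate_phenotypes(cfg, cohort)
        conf = ConfoundTable.from_cohort(cohort)
        Xr, Yr = residualize(X, conf), residualize(Y, conf)
        blocks = build_blocks(cohort)
        res = permutation_test(Xr, Yr, blocks, n_perm=1000, seed=0)
        assert res.p_values[0] == pytest.approx(1.0 / 1001.0)

    def test_observed_below_every_null_draw_gives_p_one(self, rng):
        # degenerate check through the formula: p = (1 + n_perm)/(1 + n_perm)
        X, Y = random_blocks(rng, n=120, p=3, q=4)
        cohort = _cohort_frame([(f"f{i}", "SINGLETON", 1) for i in range(120)])
        blocks = build_blocks(cohort)
        res = permutation_test(X, Y, blocks, n_perm=200, seed=1)
        worst = res.null_corrs[:, -1]
        k = res.observed_corrs.shape[0]
        if (worst >= res.observed_corrs[-1]).all():
            assert res.p_values[-1] == 1.0
        assert np.all(res.p_values > 0)

    def test_shortcut_equals_literal_refit(self, rng):
        X, Y = random_blocks(rng, n=60, p=3, q=4)
        cohort = _cohort_frame([(f"f{i}", "SINGLETON", 1) for i in range(60)])
        blocks = build_blocks(cohort)
        perm_rng = np.random.default_rng(7)
        perm = sample_permutation(blocks, perm_rng)
        refit = fit_cca(X, Y.with_values(Y.values[perm])).canonical_corrs
        res = permutation_test(X, Y, blocks, n_perm=100, seed=99)
        # reproduce the first sampled permutation with the same seed stream
        rng2 = np.random.default_rng(99)
        first_perm = sample_permutation(blocks, rng2)
        literal = fit_cca(X, Y.with_values(Y.values[first_perm])).canonical_corrs
        np.testing.assert_allclose(res.null_corrs[0], literal, atol=1e-10)

    def test_restricted_vs_free_permutation_differ_under_family_dependence(self):
        # correlated families + null cross-block signal: the free-permutation
        # null is too narrow, so it rejects more often than the restricted one
        rates = {"restricted": 0, "free": 0}
        n_rep = 40
        for rep in range(n_rep):
            # the family dependence must span the whole block (as many
            # zero-correlation latents as sleep variables, low noise) for the
            # canonical correlations to feel the alignment of families
            cfg = SyntheticConfig(
                n_subjects=120,
                n_sleep_vars=3,
                n_bps_vars=6,
                planted_corrs=(0.0, 0.0, 0.0),
                family_mix=(0.5, 0.5, 0, 0),
                within_family_rho=0.8,
                confound_scale=0.0,
                discretize_sleep=False,
                noise_sd=0.1,
                seed=1000 + rep,
            )
            cohort = generate_cohort(cfg)
            X, Y, _ = generate_phenotypes(cfg, cohort)
            blocks = build_blocks(cohort)
            for label, restrict in (("restricted", True), ("free", False)):
                res = permutation_test(
                    X, Y, blocks, n_perm=200, seed=rep, restrict=restrict
                )
                rates[label] += res.p_values[0] <= 0.05
        assert rates["free"] > rates["restricted"]

    def test_too_few_permutations_rejected(self, rng):
        X, Y = random_blocks(rng, n=30, p=2, q=2)
        with pytest.raises(ValueError):
            permutation_test(X, Y, None, n_perm=50)


class TestBHFDR:
    def test_hand_computed_step_up(self):
        q, mask = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04, 0.05]), 0.05)
        np.testing.assert_allclose(q, 0.05)
        assert mask.all()

    def test_all_ones(self):
        q, mask = bh_fdr(np.ones(4), 0.05)
        np.testing.assert_array_equal(q, 1.0)
        assert not mask.any()

    def test_single_p(self):
        q, mask = bh_fdr(np.array([0.03]), 0.05)
        assert q[0] == pytest.approx(0.03)
        assert mask[0]

    def test_empty(self):
        q, mask = bh_fdr(np.array([]))
        assert q.size == 0 and mask.size == 0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_and_statsmodels(self, seed):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(seed)
        p = rng.uniform(size=int(rng.integers(1, 40)))
        q, mask = bh_fdr(p, 0.05)
        # brute-force step-up oracle
        m = len(p)
        order = np.argsort(p)
        q_bf = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            running = min(running, m * p[order[rank - 1]] / rank)
            q_bf[order[rank - 1]] = running
        np.testing.assert_allclose(q, q_bf, atol=0)
        reject_sm, q_sm, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        np.testing.assert_allclose(q, q_sm, atol=1e-12)
        np.testing.assert_array_equal(mask, reject_sm)


class TestBootstrap:
    def _fitted(self, cfg_seed=8, n=250, q=12):
        cfg = SyntheticConfig(n_subjects=n, n_bps_vars=q, seed=cfg_seed)
        cohort = generate_cohort(cfg)
        X, Y, truth = generate_phenotypes(cfg, cohort)
        conf = ConfoundTable.from_cohort(cohort)
        Xr, Yr = residualize(X, conf), residualize(Y, conf)
        model = orient_components(compute_loadings(fit_cca(Xr, Yr), Xr, Yr))
        blocks = build_blocks(cohort)
        return Xr, Yr, model, blocks, truth

    def test_identity_resample_reproduces_loadings_after_alignment(self):
        Xr, Yr, model, _, _ = self._fitted()
        assign, signs = match_components(
            model.sleep_weights,
            model.bps_weights,
            model.sleep_weights.copy(),
            model.bps_weights.copy(),
        )
        np.testing.assert_array_equal(assign, np.arange(model.k))
        np.testing.assert_array_equal(signs, 1.0)

    def test_matching_is_injective_under_shuffle_and_flip(self, rng):
        Xr, Yr, model, _, _ = self._fitted()
        order = rng.permutation(model.k)
        flips = rng.choice([-1.0, 1.0], model.k)
        assign, signs = match_components(
            model.sleep_weights,
            model.bps_weights,
            model.sleep_weights[:, order] * flips,
            model.bps_weights[:, order] * flips,
        )
        # matching must invert the shuffle and recover the flips
        np.testing.assert_array_equal(order[assign], np.arange(model.k))
        np.testing.assert_array_equal(signs, flips[assign])

    def test_loading_sd_shrinks_with_sample_size(self):
        sds = {}
        for n in (120, 770):
            acc = []
            for seed in range(20):
                cfg = SyntheticConfig(
                    n_subjects=n, n_bps_vars=10, planted_corrs=(0.7,), seed=seed
                )
                cohort = generate_cohort(cfg)
                X, Y, _ = generate_phenotypes(cfg, cohort)
                conf = ConfoundTable.from_cohort(cohort)
                Xr, Yr = residualize(X, conf), residualize(Y, conf)
                model = orient_components(
                    compute_loadings(fit_cca(Xr, Yr), Xr, Yr)
                )
                blocks = build_blocks(cohort)
                res = bootstrap_loadings(
                    Xr, Yr, model, n_boot=25, seed=seed, blocks=blocks
                )
                acc.append(res.loading_sd[:, 0].mean())
            sds[n] = np.mean(acc)
        assert sds[770] < sds[120]

    def test_low_noise_planted_structure_gives_large_z(self):
        cfg = SyntheticConfig(
            n_subjects=300,
            n_bps_vars=8,
            planted_corrs=(0.95,),
            noise_sd=0.05,
            discretize_sleep=False,
            confound_scale=0.0,
            seed=3,
        )
        cohort = generate_cohort(cfg)
        X, Y, truth = generate_phenotypes(cfg, cohort)
        conf = ConfoundTable.from_cohort(cohort)
        Xr, Yr = residualize(X, conf), residualize(Y, conf)
        model = orient_components(compute_loadings(fit_cca(Xr, Yr), Xr, Yr))
        blocks = build_blocks(cohort)
        res = bootstrap_loadings(Xr, Yr, model, n_boot=60, seed=0, blocks=blocks)
        # variables with heavy true weights must be confidently nonzero
        heavy = np.argmax(np.abs(truth.true_sleep_weights[:, 0]))
        assert np.abs(res.loading_z[heavy, 0]) > 5
        assert res.significant[heavy, 0]


class TestCrossValidation:
    def test_degenerate_single_fold_reproduces_in_sample_corrs(self):
        cfg = SyntheticConfig(n_subjects=150, n_bps_vars=10, seed=6)
        cohort = generate_cohort(cfg)
        X, Y, _ = generate_phenotypes(cfg, cohort)
        conf = ConfoundTable.from_cohort(cohort)
        blocks = build_blocks(cohort)
        cv = crossval_cca(X, Y, conf, blocks, n_folds=1, seed=0, n_perm=100)
        Xr, Yr = residualize(X, conf), residualize(Y, conf)
        in_sample = fit_cca(Xr, Yr).canonical_corrs
        np.testing.assert_allclose(cv.mean_corrs, in_sample, atol=1e-10)

    def test_no_family_spans_two_folds(self):
        cfg = SyntheticConfig(n_subjects=300, n_bps_vars=12, seed=7)
        cohort = generate_cohort(cfg)
        X, Y, _ = generate_phenotypes(cfg, cohort)
        conf = ConfoundTable.from_cohort(cohort)
        blocks = build_blocks(cohort)
        cv = crossval_cca(X, Y, conf, blocks, n_folds=5, seed=1, n_perm=100)
        fold_of = cv.fold_assignments
        fam = cohort["family_id"]
        per_family_folds = fold_of.groupby(fam.values).nunique()
        assert (per_family_folds == 1).all()

    def test_null_data_generalizes_near_zero(self):
        cfg = SyntheticConfig(
            n_subjects=400,
            n_bps_vars=10,
            planted_corrs=(0.0,),
            confound_scale=0.0,
            seed=9,
        )
        cohort = generate_cohort(cfg)
        X, Y, _ = generate_phenotypes(cfg, cohort)
        conf = ConfoundTable.from_cohort(cohort)
        blocks = build_blocks(cohort)
        cv = crossval_cca(X, Y, conf, blocks, n_folds=5, seed=2, n_perm=100)
        assert abs(cv.mean_corrs[0]) < 0.15

    def test_fold_too_small_for_sleep_block_rejected(self):
        cfg = SyntheticConfig(n_subjects=40, n_bps_vars=10, seed=3)
        cohort = generate_cohort(cfg)
        X, Y, _ = generate_phenotypes(cfg, cohort)
        conf = ConfoundTable.from_cohort(cohort)
        blocks = build_blocks(cohort)
        with pytest.raises(ValueError, match="fewer folds"):
            crossval_cca(X, Y, conf, blocks, n_folds=8, seed=0, n_perm=100)


class TestPosthocAssociations:
    def test_covariate_identical_to_composite_correlates_perfectly(self, rng):
        comp = rng.standard_normal(100)
        table = posthoc_associations(
            comp[:, None], pd.DataFrame({"mirror": comp})
        )
        assert table.loc[0, "stat"] == pytest.approx(1.0)

    def test_two_group_t_squared_equals_anova_f(self, rng):
        comp = rng.standard_normal(80)
        group = np.repeat(["a", "b"], 40)
        t_row = posthoc_associations(
            comp[:, None], pd.DataFrame({"g": group})
        )
        t = t_row.loc[0, "stat"]
        f, _ = stats.f_oneway(comp[group == "a"], comp[group == "b"])
        assert t**2 == pytest.approx(f, abs=1e-10)

    def test_small_category_skipped_with_reason(self, rng):
        comp = rng.standard_normal(30)
        group = np.array(["big"] * 26 + ["tiny"] * 4)
        table = posthoc_associations(comp[:, None], pd.DataFrame({"g": group}))
        assert table.loc[0, "test"] == "skipped"
        assert "tiny" in table.loc[0, "note"]

    def test_fdr_applied_across_all_computed_tests(self, rng):
        comp = rng.standard_normal((60, 2))
        covs = pd.DataFrame(
            {
                "cont": rng.standard_normal(60),
                "bin": np.repeat([0, 1], 30).astype(str),
            }
        )
        table = posthoc_associations(comp, covs)
        computed = table[table["p"].notna()]
        assert computed["q"].notna().all()
        assert (computed["q"] >= computed["p"] - 1e-12).all()
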