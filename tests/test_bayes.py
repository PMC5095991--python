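"""Sampler correctness: closed-form conjugate/ridge oracles under fixed
variances, reduction of the multi-trait model to independent chains under a
fixed diagonal covariance, chain reproducibility and exchangeability, and
the variance-partition bookkeeping."""

import numpy as np
import pandas as pd
import pytest

import seqblup as sb
from _toys import make_toy_dataset, make_toy_phenos, ridge_oracle

WB = sb.parse_scenario("WB-50K")
WBQ = sb.parse_scenario("WB-50K+MBQTL4")
MT = sb.parse_scenario("MT-50K")
MTQ = sb.parse_scenario("MT-50K+MBQTL4")


def _toy_model(n=150, p=60, n_qtl=6, seed=17, breeds=("X",), h2=0.5):
    rng = np.random.default_rng(seed)
    G = rng.binomial(2, rng.uniform(0.1, 0.9, p), (n, p)).astype(np.float32)
    breed_of = np.repeat(breeds, n // len(breeds))
    on_array = np.ones(p, bool)
    on_array[:n_qtl] = False
    ds = make_toy_dataset(G, np.arange(1, p + 1) * 50_000, breed_of, on_array=on_array)
    eff = rng.standard_normal(p) * np.sqrt(h2 / p)
    y = G.astype(float) @ eff + rng.standard_normal(n) * np.sqrt(1 - h2)
    phenos = make_toy_phenos(ds, y - y.mean())
    comps = sb.MarkerComponents(
        list(ds.markers["variant_id"][n_qtl:]), list(ds.markers["variant_id"][:n_qtl]), WBQ
    )
    designs = sb.build_design(ds, comps, ds.animals["animal_id"])
    return ds, phenos, comps, designs


class TestBuildDesign:
    def test_dimensions_and_cell_lookup(self):
        ds, phenos, comps, designs = _toy_model()
        assert designs.Z_array.shape[1] == len(comps.array_component)
        assert designs.Z_qtl.shape[1] == len(comps.qtl_component)
        # row of Z equals the dosage row of the source dataset (columns are
        # centered on the training mean, so add it back)
        aid = designs.animal_ids[7]
        row = np.flatnonzero((ds.animals["animal_id"] == aid).to_numpy())[0]
        expected = ds.dosage_for(comps.array_component, [row])[0]
        assert np.allclose(designs.Z_array[7] + designs.array_means, expected, atol=1e-12)

    def test_empty_qtl_component_zero_columns(self):
        ds, phenos, comps, _ = _toy_model()
        comps0 = sb.MarkerComponents(comps.array_component, [], WB)
        d = sb.build_design(ds, comps0, ds.animals["animal_id"])
        assert d.Z_qtl.shape == (len(ds.animals), 0)

    def test_missing_variant_named_in_error(self):
        ds, phenos, comps, _ = _toy_model()
        bad = sb.MarkerComponents(comps.array_component + ["ghost"], [], WB)
        with pytest.raises(KeyError, match="ghost"):
            sb.build_design(ds, bad, ds.animals["animal_id"])


class TestSingleTraitSampler:
    def test_fixed_variances_match_ridge_oracle(self):
        ds, phenos, comps, _ = _toy_model(n=120, p=80, n_qtl=0)
        comps1 = sb.MarkerComponents(list(ds.markers["variant_id"]), [], WB)
        designs = sb.build_design(ds, comps1, ds.animals["animal_id"])
        s2a, s2e = 0.01, 0.5
        summ = sb.gibbs_single_trait(
            designs, phenos, WB, sb.MCMCConfig(30000, 3000, seed=1),
            fixed_variances={"sigma2_array": s2a, "sigma2_e": s2e},
        )
        y = phenos.table.set_index("animal_id").loc[designs.animal_ids, "drp"].to_numpy()
        gebv_ref, _ = ridge_oracle(designs.Z_array, y, s2e / s2a)
        assert np.max(np.abs(summ.gebv.to_numpy() - gebv_ref)) < 0.01 * y.std()

    def test_single_marker_conjugate_posterior_moments(self):
        g = np.array([0.0, 1.0, 2.0, 1.0], dtype=np.float32)
        ds = make_toy_dataset(g[:, None], [1000], ["X"] * 4)
        y = np.array([-0.5, 0.2, 1.0, 0.4])
        phenos = make_toy_phenos(ds, y)
        comps = sb.MarkerComponents(list(ds.markers["variant_id"]), [], WB)
        designs = sb.build_design(ds, comps, ds.animals["animal_id"])
        s2a, s2e = 0.4, 0.3
        summ = sb.gibbs_single_trait(
            designs, phenos, WB, sb.MCMCConfig(60000, 5000, seed=2),
            fixed_variances={"sigma2_array": s2a, "sigma2_e": s2e},
        )
        # analytic joint posterior of (mu, a): N((X'X + D)^-1 X'y, s2e (X'X+D)^-1)
        X = np.column_stack([np.ones(4), g.astype(float)])
        D = np.diag([0.0, s2e / s2a])
        cov = s2e * np.linalg.inv(X.T @ X + D)
        mean = np.linalg.inv(X.T @ X + D) @ (X.T @ y)
        assert summ.effect_means_array[0] == pytest.approx(mean[1], abs=4 * np.sqrt(cov[1, 1] / 1000))

    def test_null_data_gives_null_effects(self):
        ds, phenos, comps, designs = _toy_model(n=80, p=30, n_qtl=5)
        null = make_toy_phenos(ds, np.zeros(80))
        summ = sb.gibbs_single_trait(designs, null, WBQ, sb.MCMCConfig(500, 100, seed=3))
        assert np.max(np.abs(summ.effect_means_array)) < 1e-4
        assert np.max(np.abs(summ.gebv.to_numpy())) < 1e-3

    def test_same_seed_identical_permuted_animals_identical(self):
        ds, phenos, comps, designs = _toy_model(n=90, p=40)
        cfg = sb.MCMCConfig(400, 100, seed=4)
        s1 = sb.gibbs_single_trait(designs, phenos, WBQ, cfg)
        s2 = sb.gibbs_single_trait(designs, phenos, WBQ, cfg)
        assert np.array_equal(s1.gebv.to_numpy(), s2.gebv.to_numpy())
        assert np.array_equal(s1.var_Za_chain, s2.var_Za_chain)
        # permuted animal list -> same design -> identical chain
        rng = np.random.default_rng(5)
        perm = rng.permutation(ds.animals["animal_id"].to_numpy())
        designs_p = sb.build_design(ds, comps, perm)
        s3 = sb.gibbs_single_trait(designs_p, phenos, WBQ, cfg)
        assert np.array_equal(s1.gebv.to_numpy(), s3.gebv.to_numpy())

    def test_independent_seeds_agree_on_gebv(self):
        ds, phenos, comps, designs = _toy_model(n=150, p=60)
        a = sb.gibbs_single_trait(designs, phenos, WBQ, sb.MCMCConfig(6000, 1000, seed=6))
        b = sb.gibbs_single_trait(designs, phenos, WBQ, sb.MCMCConfig(6000, 1000, seed=7))
        assert np.corrcoef(a.gebv, b.gebv)[0, 1] > 0.999

    def test_variance_partition_on_standardized_drp(self, two_breed_data, two_breed_split):
        config, dataset, arch, phenos = two_breed_data
        base = sb.filter_base_panel(dataset)
        comps = sb.MarkerComponents(base, arch.qtl_variant_ids, WBQ)
        train = two_breed_split.training_ids["A"]
        designs = sb.build_design(dataset, comps, train)
        summ = sb.gibbs_single_trait(designs, phenos.subset(train), WBQ,
                                     sb.MCMCConfig(3000, 600, seed=8))
        total = summ.var_Za_chain.mean() + summ.var_Zq_chain.mean() + summ.chains["sigma2_e"].mean()
        y = phenos.subset(train).for_breed("A")["drp"].to_numpy()
        assert total == pytest.approx(np.var(y), abs=0.15)

    def test_divergence_raises_with_state(self):
        ds, phenos, comps, designs = _toy_model(n=50, p=10)
        bad = make_toy_phenos(ds, np.full(50, np.nan))
        with pytest.raises((sb.bayes.GibbsDivergenceError, KeyError, ValueError)):
            sb.gibbs_single_trait(designs, bad, WBQ, sb.MCMCConfig(200, 50, seed=9))


class TestMultiTraitSampler:
    def _duplicated_breeds(self, n=200, p=40, seed=19):
        rng = np.random.default_rng(seed)
        G1 = rng.binomial(2, rng.uniform(0.2, 0.8, p), (n, p)).astype(np.float32)
        G = np.vstack([G1, G1])  # breed B is a copy of breed A
        breed_of = ["A"] * n + ["B"] * n
        ds = make_toy_dataset(G, np.arange(1, p + 1) * 100_000, breed_of)
        eff = rng.standard_normal(p) * np.sqrt(0.5 / p)
        y1 = G1.astype(float) @ eff + rng.standard_normal(n) * 0.7
        y = np.concatenate([y1, y1])
        phenos = make_toy_phenos(ds, y - y.mean())
        comps = sb.MarkerComponents(list(ds.markers["variant_id"]), [], MT)
        designs = sb.build_design(ds, comps, ds.animals["animal_id"])
        return ds, phenos, comps, designs

    def test_identical_data_gives_correlation_near_one(self):
        ds, phenos, comps, designs = self._duplicated_breeds()
        summ = sb.gibbs_multi_trait(designs, phenos, MT, sb.MCMCConfig(1500, 300, seed=10))
        assert summ.chains["corr_array_A_B"].mean() > 0.95

    def test_covariance_draws_are_spd_and_correlations_bounded(self):
        ds, phenos, comps, designs = self._duplicated_breeds(n=100, p=20)
        summ = sb.gibbs_multi_trait(designs, phenos, MT, sb.MCMCConfig(600, 100, seed=11))
        for mats in (summ.chains["sigma_array"],):
            eig = np.linalg.eigvalsh(mats)
            assert np.all(eig > 0)
        corr = summ.chains["corr_array_A_B"]
        assert np.all(np.abs(corr) <= 1.0 + 1e-12)

    def test_fixed_diagonal_covariance_reduces_to_single_trait(self):
        ds, phenos, comps, designs = _toy_model(n=200, p=50, n_qtl=0, breeds=("A", "B"), seed=20)
        comps = sb.MarkerComponents(list(ds.markers["variant_id"]), [], MT)
        designs = sb.build_design(ds, comps, ds.animals["animal_id"])
        s2a, s2e = 0.02, 0.6
        summ = sb.gibbs_multi_trait(
            designs, phenos, MT, sb.MCMCConfig(12000, 2000, seed=12),
            fixed_covariances={"array": np.eye(2) * s2a, "sigma2_e": np.array([s2e, s2e])},
        )
        # with a diagonal covariance the breeds decouple: compare each block
        # against its own ridge solution
        tab = phenos.table.set_index("animal_id")
        for j, breed in enumerate(designs.breed_names):
            s, t = designs.breed_starts[j], designs.breed_starts[j + 1]
            y = tab.loc[designs.animal_ids[s:t], "drp"].to_numpy()
            gebv_ref, _ = ridge_oracle(np.asarray(designs.Z_array[s:t]), y, s2e / s2a)
            assert np.max(np.abs(summ.gebv.to_numpy()[s:t] - gebv_ref)) < 0.03 * y.std()


class TestGebvAndSummaries:
    def test_zero_effects_give_zero_gebv(self):
        ds, phenos, comps, designs = _toy_model(n=40, p=10)
        summ = sb.gibbs_single_trait(designs, make_toy_phenos(ds, np.zeros(40)), WBQ,
                                     sb.MCMCConfig(200, 50, seed=13))
        gebv = sb.compute_gebv(ds, summ, list(designs.animal_ids[:5]))
        assert np.max(np.abs(gebv)) < 1e-3

    def test_compute_gebv_consistent_with_training_gebv(self):
        ds, phenos, comps, designs = _toy_model(n=60, p=20)
        summ = sb.gibbs_single_trait(designs, phenos, WBQ, sb.MCMCConfig(300, 100, seed=14))
        again = sb.compute_gebv(ds, summ, list(designs.animal_ids))
        assert np.allclose(again.to_numpy(), summ.gebv.to_numpy(), atol=1e-10)

    def test_gebv_linear_in_effect_means(self):
        ds, phenos, comps, designs = _toy_model(n=60, p=20)
        summ = sb.gibbs_single_trait(designs, phenos, WBQ, sb.MCMCConfig(300, 100, seed=15))
        doubled = sb.PosteriorSummary(**{**summ.__dict__})
        doubled.effect_means_array = 2 * summ.effect_means_array
        doubled.effect_means_qtl = 2 * summ.effect_means_qtl
        g1 = sb.compute_gebv(ds, summ, list(designs.animal_ids))
        g2 = sb.compute_gebv(ds, doubled, list(designs.animal_ids))
        assert np.allclose(g2.to_numpy(), 2 * g1.to_numpy(), atol=1e-10)

    def test_single_draw_var_za_identity(self):
        ds, phenos, comps, designs = _toy_model(n=50, p=15)
        summ = sb.gibbs_single_trait(designs, phenos, WBQ, sb.MCMCConfig(2, 1, seed=16))
        # one stored draw: effect means ARE that draw, so var(Z a) must match
        za = designs.Z_array @ summ.effect_means_array
        assert summ.var_Za_chain.shape == (1,)
        assert summ.var_Za_chain[0] == pytest.approx(float(np.var(za)), rel=1e-8)

    def test_summarize_posterior_arithmetic(self):
        ds, phenos, comps, designs = _toy_model(n=40, p=10)
        summ = sb.gibbs_single_trait(designs, phenos, WBQ, sb.MCMCConfig(200, 50, seed=17))
        summ.var_Za_chain = np.array([0.1, 0.2, 0.3])
        summ.var_Zq_chain = np.array([0.0, 0.0, 0.0])
        summ.chains["sigma2_e"] = np.array([1.0, 1.0, 1.0])
        rep = sb.summarize_posterior(summ).set_index("quantity")
        assert rep.at["sigma2_50K", "mean"] == pytest.approx(0.2)
        assert rep.at["sigma2_50K", "sd"] == pytest.approx(np.std([0.1, 0.2, 0.3], ddof=1))
        assert rep.at["sigma2_e", "sd"] == 0.0

    def test_chain_length_bookkeeping(self):
        ds, phenos, comps, designs = _toy_model(n=40, p=10)
        cfg = sb.MCMCConfig(500, 100, seed=18, store_every=4)
        summ = sb.gibbs_single_trait(designs, phenos, WBQ, cfg)
        assert summ.n_stored == (500 - 100) // 4
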