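"""The synthetic generator must deliver the statistical structure the
downstream analysis assumes: target allele-frequency divergence, distance-
decaying LD that is weaker across breeds than within, breed-correlated QTL
effects, half-sib family covariance and DRP at the target reliability."""

import numpy as np
import pandas as pd
import pytest

import seqblup as sb
from seqblup.simdata import make_marker_map


def _one_breed(n, fst=0.0, fam=10, **kw):
    return sb.BreedSpec("X", n, 0, fst, fam, **kw)


class TestBreedFrequencies:
    def test_zero_fst_returns_ancestral_exactly(self):
        p = np.linspace(0.01, 0.99, 50)
        out = sb.simulate_breed_frequencies(p, [_one_breed(10, fst=0.0)], seed=1)
        assert np.array_equal(out[0], p)

    def test_variance_matches_balding_nichols(self):
        # Beta(p(1-F)/F, (1-p)(1-F)/F) has variance F p (1-p)
        p = np.full(10_000, 0.5)
        out = sb.simulate_breed_frequencies(p, [_one_breed(10, fst=0.1)], seed=2)
        assert np.var(out[0]) == pytest.approx(0.1 * 0.25, rel=0.1)
        assert np.mean(out[0]) == pytest.approx(0.5, abs=0.01)

    def test_fixed_alleles_stay_fixed(self):
        p = np.array([0.0, 1.0, 0.5])
        out = sb.simulate_breed_frequencies(p, [_one_breed(10, fst=0.2)], seed=3)
        assert out[0, 0] == 0.0
        assert out[0, 1] == 1.0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            sb.simulate_breed_frequencies([0.5, 1.5], [_one_breed(10)], seed=1)
        with pytest.raises(ValueError):
            sb.simulate_breed_frequencies([np.nan], [_one_breed(10)], seed=1)


class TestGenotypes:
    def test_fixed_allele_gives_dosage_two(self):
        breeds = [_one_breed(30)]
        mm = make_marker_map(5, 10.0, seed=0)
        freqs = np.array([[1.0, 0.0, 0.5, 0.5, 0.5]])
        ds = sb.simulate_genotypes(freqs, mm, 0.1, breeds, seed=4)
        assert np.all(ds.dosages[:, 0] == 2.0)
        assert np.all(ds.dosages[:, 1] == 0.0)

    def test_mean_dosage_matches_binomial(self):
        n = 5000
        breeds = [_one_breed(n, fst=0.0, fam=20)]
        mm = make_marker_map(40, 50.0, seed=1)
        p = np.linspace(0.1, 0.9, 40)
        ds = sb.simulate_genotypes(p[None, :], mm, 0.05, breeds, seed=5)
        mean = ds.dosages.mean(axis=0)
        # maternal alleles are n fresh draws; paternal alleles descend from
        # 2 * n_sires founder haplotypes, which dominates the sampling error
        n_sires = ds.animals["sire_id"].nunique()
        se = np.sqrt(p * (1 - p) * (1.0 / n + 1.0 / (2 * n_sires)))
        assert np.all(np.abs(mean - 2 * p) < 4 * se)

    def test_dosage_bounds_and_seed_reproducibility(self):
        breeds = [_one_breed(50, fst=0.05)]
        mm = make_marker_map(100, 20.0, seed=2)
        freqs = np.random.default_rng(0).uniform(0.05, 0.95, (1, 100))
        ds1 = sb.simulate_genotypes(freqs, mm, 0.1, breeds, seed=6)
        ds2 = sb.simulate_genotypes(freqs, mm, 0.1, breeds, seed=6)
        assert ds1.dosages.min() >= 0 and ds1.dosages.max() <= 2
        assert np.array_equal(ds1.dosages, ds2.dosages)
        # realized MAF column is consistent with dosages
        f = ds1.dosages.mean(axis=0) / 2
        assert np.allclose(ds1.markers["maf"], np.minimum(f, 1 - f), atol=1e-6)

    def test_within_breed_ld_exceeds_across_breed(self):
        breeds = [
            sb.BreedSpec("P", 300, 0, 0.01, 15),
            sb.BreedSpec("Q", 300, 0, 0.25, 15),
        ]
        mm = make_marker_map(1500, 60.0, seed=3)
        anc = np.random.default_rng(1).uniform(0.1, 0.9, 1500)
        freqs = sb.simulate_breed_frequencies(anc, breeds, seed=7)
        ds = sb.simulate_genotypes(freqs, mm, 0.05, breeds, seed=8)

        def adjacent_r2(G):
            G = G - G.mean(axis=0)
            s = G.std(axis=0)
            ok = (s[:-1] > 0) & (s[1:] > 0)
            r = np.einsum("ij,ij->j", G[:, :-1], G[:, 1:]) / (G.shape[0] * s[:-1] * s[1:])
            return float(np.mean(r[ok] ** 2))

        P = ds.dosages[ds.breed_rows("P")].astype(float)
        Q = ds.dosages[ds.breed_rows("Q")].astype(float)
        pooled = np.vstack([P - P.mean(axis=0), Q - Q.mean(axis=0)])
        r2_pooled = adjacent_r2(pooled)
        assert adjacent_r2(P) > r2_pooled
        assert adjacent_r2(Q) > r2_pooled

    def test_rejects_empty_map_and_bad_ld(self):
        with pytest.raises(ValueError):
            sb.simulate_genotypes(np.zeros((1, 0)), pd.DataFrame(columns=["chromosome", "position_bp"]),
                                  0.1, [_one_breed(5)], seed=1)
        mm = make_marker_map(3, 1.0, seed=0)
        with pytest.raises(ValueError):
            sb.simulate_genotypes(np.full((1, 3), 0.5), mm, 1.0, [_one_breed(5)], seed=1)


@pytest.fixture(scope="module")
def arch_dataset():
    breeds = [sb.BreedSpec("A", 60, 0, 0.02, 10), sb.BreedSpec("B", 60, 0, 0.10, 10)]
    cfg = sb.SimulationConfig(breeds=breeds, n_markers=3000, n_qtl=0, chrom_length_mb=150.0)
    ds, _, _ = sb.simulate_dataset(cfg, seed=21)
    return ds


class TestArchitecture:
    def test_identity_correlation_gives_independent_effects(self, arch_dataset):
        arch = sb.simulate_architecture(arch_dataset, 2000, np.eye(2), 0.5, seed=9)
        r = np.corrcoef(arch.effects_per_breed.T)[0, 1]
        assert abs(r) < 0.05

    def test_target_correlation_recovered(self, arch_dataset):
        corr = np.array([[1.0, 0.8], [0.8, 1.0]])
        arch = sb.simulate_architecture(arch_dataset, 2000, corr, 0.5, seed=10)
        r = np.corrcoef(arch.effects_per_breed.T)[0, 1]
        assert r == pytest.approx(0.8, abs=0.05)

    def test_qtl_variance_fraction_realized(self, arch_dataset):
        arch = sb.simulate_architecture(arch_dataset, 100, np.eye(2), 0.3, seed=11)
        idx = arch_dataset.marker_indices(arch.qtl_variant_ids)
        rows = arch_dataset.breed_rows("A")
        g = arch_dataset.dosages[np.ix_(rows, idx)].astype(float)
        assert np.var(g @ arch.effects_per_breed[:, 0]) == pytest.approx(0.3, rel=1e-6)
        assert arch.polygenic_variance == pytest.approx(0.7)

    def test_zero_qtl_gives_empty_effects(self, arch_dataset):
        arch = sb.simulate_architecture(arch_dataset, 0, np.eye(2), 0.0, seed=12)
        assert arch.effects_per_breed.shape == (0, 2)
        phenos = sb.simulate_phenotypes(arch_dataset, arch, 0.9, seed=13)
        assert len(phenos.table) == len(arch_dataset.animals)

    def test_qtl_are_off_array(self, arch_dataset):
        arch = sb.simulate_architecture(arch_dataset, 50, np.eye(2), 0.3, seed=14)
        meta = arch_dataset.markers.set_index("variant_id")
        assert not meta.loc[arch.qtl_variant_ids, "on_array"].any()

    def test_rejects_non_psd_matrix(self, arch_dataset):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError):
            sb.simulate_architecture(arch_dataset, 10, bad, 0.3, seed=15)


class TestPhenotypes:
    def test_reliability_one_gives_standardized_tbv(self, arch_dataset):
        arch = sb.simulate_architecture(arch_dataset, 50, np.eye(2), 0.4, seed=16)
        phenos = sb.simulate_phenotypes(arch_dataset, arch, 1.0, seed=17)
        for b in ("A", "B"):
            sub = phenos.for_breed(b)
            z = (sub["tbv"] - sub["tbv"].mean()) / sub["tbv"].std(ddof=0)
            assert np.allclose(sub["drp"], z, atol=1e-10)

    def test_target_reliability_recovered(self):
        breeds = [_one_breed(5000, fst=0.02, fam=10)]
        cfg = sb.SimulationConfig(breeds=breeds, n_markers=200, n_qtl=20)
        ds, arch, phenos = sb.simulate_dataset(cfg, seed=22)
        sub = phenos.table
        r2 = np.corrcoef(sub["tbv"], sub["drp"])[0, 1] ** 2
        assert r2 == pytest.approx(0.9, abs=0.02)
        # standardization within breed
        assert sub["drp"].mean() == pytest.approx(0.0, abs=1e-9)
        assert sub["drp"].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_half_sib_tbv_covariance_quarter_of_additive_variance(self):
        # 500 paternal half-sib families; between-sire variance ~ V_A / 4
        breeds = [_one_breed(2500, fst=0.01, fam=5)]
        cfg = sb.SimulationConfig(breeds=breeds, n_markers=300, n_qtl=30)
        ds, arch, phenos = sb.simulate_dataset(cfg, seed=23)
        tab = phenos.table
        grp = tab.groupby("sire_id")["tbv"]
        k = grp.size().to_numpy()
        means, var_a = grp.mean().to_numpy(), tab["tbv"].var()
        within = grp.var(ddof=1).to_numpy()
        msw = np.average(within, weights=k - 1)
        between = np.var(means, ddof=1) - msw / k.mean()
        assert between == pytest.approx(0.25 * var_a, abs=0.05)

    def test_rejects_zero_reliability(self, arch_dataset):
        arch = sb.simulate_architecture(arch_dataset, 10, np.eye(2), 0.3, seed=18)
        with pytest.raises(ValueError):
            sb.simulate_phenotypes(arch_dataset, arch, 0.0, seed=19)


@pytest.fixture(scope="module")
def written(tmp_path_factory):
    breeds = [
        sb.BreedSpec("A", 25, 5, 0.02, 6, holstein_like=True),
        sb.BreedSpec("B", 20, 0, 0.10, 6),  # empty validation partition
    ]
    cfg = sb.SimulationConfig(breeds=breeds, n_markers=60, n_qtl=5, chrom_length_mb=10.0)
    ds, arch, phenos = sb.simulate_dataset(cfg, seed=31)
    prefix = tmp_path_factory.mktemp("io") / "toy"
    paths = sb.write_dataset(ds, phenos, prefix)
    back_ds, back_ph = sb.read_dataset(prefix)
    return ds, phenos, back_ds, back_ph, paths


class TestRoundTrip:
    def test_marker_metadata_identical(self, written):
        ds, _, back_ds, _, _ = written
        for col in ("variant_id", "chromosome", "position_bp", "on_array"):
            assert list(ds.markers[col]) == list(back_ds.markers[col])
        assert np.allclose(ds.markers["info_score"], back_ds.markers["info_score"], atol=1e-6)

    def test_dosages_within_print_precision(self, written):
        ds, _, back_ds, _, _ = written
        assert np.max(np.abs(ds.dosages - back_ds.dosages)) <= 2e-3

    def test_phenotypes_and_animals_round_trip(self, written):
        _, phenos, back_ds, back_ph, _ = written
        a = phenos.table.set_index("animal_id").sort_index()
        b = back_ph.table.set_index("animal_id").sort_index()
        assert np.allclose(a["drp"], b["drp"])
        assert list(a["sire_id"]) == list(b["sire_id"])
        assert [s.name for s in back_ds.breeds] == ["A", "B"]

    def test_pheno_file_header(self, written):
        *_, paths = written
        header = paths["phenotypes"].read_text().splitlines()[0].split("\t")
        assert header == ["animal_id", "breed", "sire_id", "age_rank", "drp", "drp_reliability", "trait"]

    def test_mismatched_animals_rejected(self, written, tmp_path):
        ds, phenos, *_ = written
        bad = phenos.subset(phenos.table["animal_id"].iloc[:10])
        with pytest.raises(ValueError):
            sb.write_dataset(ds, bad, tmp_path / "bad")
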