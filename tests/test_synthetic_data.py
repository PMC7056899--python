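import numpy as np
import pytest
from scipy import stats

from panelgp.kinship import build_grm
from panelgp.reml_gblup import MixedModelSpec, design_matrix, fit_reml, solve_gblup
from panelgp.synthetic_data import (GeneticMap, PRESETS, SimConfig, drop_gamete,
                                    make_families, preset_config, simulate_dataset,
                                    simulate_founders, simulate_trait, split_total)

from conftest import small_config


class TestFounders:
    def test_degenerate_maf_interval(self):
        cfg = small_config(n_families=100, n_snps=1000, maf_range=(0.5, 0.5), n_qtl=50)
        ds = simulate_founders(cfg)
        assert ds.n_individuals == 200
        p = ds.dosages.mean(axis=0) / 2
        # binomial sampling over 400 haplotypes: SD(p_hat) = 0.025, so 99% of
        # SNPs fall within 2.58 sigma = 0.065 of the forced frequency
        assert np.mean(np.abs(p - 0.5) < 0.065) > 0.98
        assert abs(p.mean() - 0.5) < 0.005

    def test_deterministic(self):
        cfg = small_config(seed=11)
        a = simulate_founders(cfg)
        b = simulate_founders(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)
        assert a.markers.equals(b.markers)

    def test_frequencies_uniform_on_range(self):
        """Per-SNP frequencies match a direct uniform draw (two-sample KS, a=0.01)."""
        cfg = small_config(n_families=500, n_snps=5000, maf_range=(0.05, 0.5))
        ds = simulate_founders(cfg)
        p_hat = ds.dosages.mean(axis=0) / 2
        oracle = np.random.default_rng(123).uniform(0.05, 0.5, 5000)
        assert stats.ks_2samp(p_hat, oracle).pvalue > 0.01

    def test_invalid_maf_range(self):
        with pytest.raises(ValueError, match="maf_range"):
            small_config(maf_range=(0.0, 0.5))


class TestDropGamete:
    def _one_chrom(self, m, length_bp, cm_per_mb):
        import pandas as pd
        markers = pd.DataFrame({
            "snp_id": [f"s{j}" for j in range(m)], "chrom": ["1"] * m,
            "pos": np.linspace(1, length_bp, m).astype(int),
            "a1": ["A"] * m, "a2": ["G"] * m,
        })
        return markers, GeneticMap(markers, cm_per_mb)

    def test_zero_recombination_copies_one_strand(self):
        _, gmap = self._one_chrom(50, 10**8, cm_per_mb=0.0)
        rng = np.random.default_rng(0)
        parent = np.vstack([np.zeros(50, dtype=np.int8), np.ones(50, dtype=np.int8)])
        picks = [drop_gamete(parent, gmap, rng) for _ in range(400)]
        sums = {p.sum() for p in picks}
        assert sums <= {0, 50}  # always an intact strand
        frac_one = np.mean([p.sum() == 50 for p in picks])
        assert 0.4 < frac_one < 0.6

    def test_crossover_count_matches_map_length(self):
        """100 cM chromosome: mean observed crossovers ~ 1.0 over 10,000 gametes."""
        _, gmap = self._one_chrom(1000, 10**8, cm_per_mb=1.0)  # 100 cM
        rng = np.random.default_rng(1)
        parent = np.vstack([np.zeros(1000, dtype=np.int8), np.ones(1000, dtype=np.int8)])
        switches = [(np.diff(drop_gamete(parent, gmap, rng)) != 0).sum()
                    for _ in range(10_000)]
        assert np.mean(switches) == pytest.approx(1.0, abs=0.05)

    def test_haldane_recombinant_fraction_at_50cm(self):
        """Two loci 50 cM apart: recombinant fraction ~ (1 - e^-1)/2 ~ 0.316."""
        _, gmap = self._one_chrom(2, 5 * 10**7, cm_per_mb=1.0)  # 50 cM span
        rng = np.random.default_rng(2)
        parent = np.array([[0, 0], [1, 1]], dtype=np.int8)
        rec = np.array([tuple(drop_gamete(parent, gmap, rng)) for _ in range(10_000)])
        frac = np.mean(rec[:, 0] != rec[:, 1])
        assert frac == pytest.approx((1 - np.exp(-1)) / 2, abs=0.015)

    def test_unsorted_map_rejected(self):
        import pandas as pd
        markers = pd.DataFrame({
            "snp_id": ["a", "b"], "chrom": ["1", "1"], "pos": [100, 50],
            "a1": ["A", "A"], "a2": ["G", "G"],
        })
        with pytest.raises(ValueError, match="sorted"):
            GeneticMap(markers, 1.0)


class TestMakeFamilies:
    @pytest.mark.parametrize(
        "preset, families, individuals",
        [("carp", 195, 1211), ("oyster", 23, 718),
         ("salmon", 85, 1481), ("seabream", 73, 741)],
    )
    def test_preset_family_and_sample_counts(self, preset, families, individuals):
        cfg = preset_config(preset)
        assert cfg.n_families == families
        assert cfg.n_offspring == individuals

    def test_mendelian_consistency(self):
        cfg = small_config(n_families=25, offspring_per_family=6, n_snps=400, seed=5)
        offspring = make_families(cfg)
        founders = simulate_founders(cfg)  # same seed -> same founder genotypes
        fdos = founders.dosages
        assert set(np.unique(offspring.dosages)) <= {0.0, 1.0, 2.0}
        sire_idx = founders.samples["iid"].reset_index(drop=True)
        lookup = {iid: k for k, iid in enumerate(sire_idx)}
        for i in range(offspring.n_individuals):
            s = fdos[lookup[offspring.samples.loc[i, "sire"]]]
            d = fdos[lookup[offspring.samples.loc[i, "dam"]]]
            o = offspring.dosages[i]
            lo = (s == 2).astype(int) + (d == 2).astype(int)
            hi = (s > 0).astype(int) + (d > 0).astype(int)
            assert np.all(o >= lo) and np.all(o <= hi)

    def test_deterministic(self):
        cfg = small_config(seed=9, n_families=10, offspring_per_family=4, n_snps=200)
        a = make_families(cfg)
        b = make_families(cfg)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_split_total_spreads_remainder(self):
        assert split_total(1211, 195)[:41] == [7] * 41
        assert sum(split_total(1211, 195)) == 1211


class TestSimulateTrait:
    def test_zero_heritability_independent_of_genotype(self):
        cfg = small_config(n_families=125, offspring_per_family=8, h2_true=0.0, seed=3)
        ds, ph, truth = simulate_dataset(cfg)
        y = ph.trait("trait").to_numpy()
        assert truth.realized_h2 == 0.0
        assert np.all(truth.true_breeding_values == 0)
        cors = [abs(np.corrcoef(ds.dosages[:, j], y)[0, 1]) for j in range(0, 1000, 97)]
        assert np.mean(cors) < 0.05

    def test_deterministic(self):
        cfg = small_config(seed=21, n_families=10, offspring_per_family=4, n_snps=300,
                           n_qtl=50)
        _, ph1, t1 = simulate_dataset(cfg)
        _, ph2, t2 = simulate_dataset(cfg)
        assert ph1.data.equals(ph2.data)
        np.testing.assert_array_equal(t1.true_breeding_values, t2.true_breeding_values)

    def test_censored_days_are_integers_in_range(self):
        cfg = preset_config("oyster", seed=2)
        _, ph, _ = simulate_dataset(cfg)
        y = ph.trait("days_to_death").to_numpy()
        assert np.all(y == np.round(y))
        assert y.min() >= 1 and y.max() <= 8

    def test_oyster_heritability_recovered_on_full_panel(self):
        """Preset day-censored trait: mean REML h2 over 10 seeds within 0.10 of 0.49."""
        ests = []
        for s in range(10):
            cfg = preset_config("oyster", seed=s)
            ds, ph, _ = simulate_dataset(cfg)
            spec = MixedModelSpec(cfg.trait_name, ("tank",))
            y, X, obs = design_matrix(ph, spec, ds.individual_ids)
            G = build_grm(ds)
            ests.append(fit_reml(y, X, G.matrix[np.ix_(obs, obs)]).h2)
        assert np.mean(ests) == pytest.approx(0.49, abs=0.10)

    def test_fixed_effect_contrast_recovered(self):
        """2-level factor with a 0.5 SD effect: GLS contrast 0.5 +/- 0.1 over 10 seeds."""
        recs = []
        for s in range(10):
            cfg = SimConfig(
                n_families=60, offspring_per_family=10, n_snps=800, n_chromosomes=5,
                chrom_lengths=tuple([1e8] * 5), h2_true=0.3, n_qtl=100,
                fixed_effects=(("tank", 2, (0.0, 0.5)),), seed=500 + s,
            )
            ds, ph, _ = simulate_dataset(cfg)
            spec = MixedModelSpec("trait", ("tank",))
            y, X, obs = design_matrix(ph, spec, ds.individual_ids)
            G = build_grm(ds).matrix
            vc = fit_reml(y, X, G[np.ix_(obs, obs)])
            recs.append(solve_gblup(obs, y, X, G, vc).fixed_effects[1])
        assert np.mean(recs) == pytest.approx(0.5, abs=0.1)

    def test_presets_enumerated(self):
        assert set(PRESETS) == {"salmon", "carp", "seabream", "oyster"}
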