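"""Generator contracts: Hardy-Weinberg genotypes, graded-response items,
factor standardisation and reproducibility."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtr

import phenofactor as pf
from phenofactor.exceptions import InvalidParameterError, InvalidSpecError


class TestGenotypes:
    def test_hwe_moments(self):
        n = 100_000
        g = pf.simulate_genotypes(n, maf=0.2, seed=1)
        # Binomial(2, 0.2): mean 0.4, variance 0.32
        se_mean = np.sqrt(0.32 / n)
        assert abs(g.values.mean() - 0.4) < 3 * se_mean
        assert abs(g.values.var() - 0.32) < 0.01
        assert g.call_rate == 1.0

    def test_hwe_symmetry_at_half(self):
        n = 100_000
        g = pf.simulate_genotypes(n, maf=0.5, seed=2)
        freqs = np.bincount(g.values.astype(int), minlength=3) / n
        for obs, exp in zip(freqs, (0.25, 0.5, 0.25)):
            assert abs(obs - exp) < 3 * np.sqrt(exp * (1 - exp) / n)

    @pytest.mark.parametrize("maf", [0.0, -0.1, 0.51, 1.0])
    def test_invalid_maf_rejected(self, maf):
        with pytest.raises(InvalidParameterError):
            pf.simulate_genotypes(4, maf=maf, seed=0)

    def test_empirical_maf_is_folded(self):
        g = pf.GenotypeVector(np.array([2.0, 2.0, 2.0, 1.0]))
        assert g.maf == pytest.approx(1 - 7 / 8)


class TestItemResponses:
    def test_null_model_category_frequencies(self):
        """With all loadings zero the items are discretised N(0,1) draws:
        category frequencies must match the Phi gaps of the thresholds."""
        pop = pf.make_default_population(n=50_000, maf=0.3)
        pop = dataclasses.replace(
            pop,
            lambda_g={k: 0.0 for k in pop.lambda_g},
            lambda_s={k: 0.0 for k in pop.lambda_s},
            thresholds={k: [-1.0, 0.0, 1.0] for k in pop.thresholds},
        )
        g = pf.simulate_genotypes(pop.n, pop.maf, seed=3)
        items = pf.simulate_item_responses(pop, g, seed=4)
        expected = np.diff(np.concatenate(([0], ndtr([-1.0, 0.0, 1.0]), [1])))
        col = items.data.iloc[:, 0].to_numpy()
        freqs = np.bincount(col.astype(int), minlength=4) / pop.n
        for obs, exp in zip(freqs, expected):
            assert abs(obs - exp) < 3 * np.sqrt(exp * (1 - exp) / pop.n)

    def test_no_snp_effect_gives_independence(self, default_pop):
        pop = dataclasses.replace(default_pop, n=20_000)
        g = pf.simulate_genotypes(pop.n, pop.maf, seed=5)
        items = pf.simulate_item_responses(pop, g, seed=6)
        gc = g.values - g.values.mean()
        for col in items.data.columns[:8]:
            r = np.corrcoef(gc, items.data[col])[0, 1]
            assert abs(r) < 3 / np.sqrt(pop.n)

    def test_snp_effect_reaches_target_factor(self, default_pop):
        """R2 = 0.05 on anxiety: squared correlation of g with the stored
        true anxiety factor scores recovers 0.05; other factors stay null."""
        n = 100_000
        pop = dataclasses.replace(default_pop, n=n,
                                  snp_effects={"anxiety": 0.05})
        g = pf.simulate_genotypes(n, pop.maf, seed=7)
        items = pf.simulate_item_responses(pop, g, seed=8)
        r_anx = np.corrcoef(g.values, items.factors["anxiety"])[0, 1]
        assert r_anx ** 2 == pytest.approx(0.05, abs=0.004)
        r_glob = np.corrcoef(g.values, items.factors["global"])[0, 1]
        assert abs(r_glob) < 3 / np.sqrt(n)
        # factors keep unit marginal variance
        assert items.factors["anxiety"].var() == pytest.approx(1.0, abs=0.02)

    def test_latent_response_variance_identity(self, default_pop):
        """Var(y*_j) = lambda' A lambda + 1 with A the factor covariance
        (identity here: no SNP effect)."""
        pop = dataclasses.replace(default_pop, n=100_000)
        g = pf.simulate_genotypes(pop.n, pop.maf, seed=9)
        items = pf.simulate_item_responses(pop, g, seed=10, keep_latent=True)
        for lab in pop.indicator_labels[:6]:
            expected = pop.lambda_g[lab] ** 2 + pop.lambda_s[lab] ** 2 + 1.0
            observed = items.latent[lab].var()
            assert observed == pytest.approx(expected, rel=0.03)

    def test_zero_specific_loadings_give_unidimensional_polychorics(self):
        """With specific loadings 0 the generator is a unidimensional
        graded-response model: polychorics equal the implied
        lambda_j*lambda_k rescaled to the correlation metric."""
        pop = pf.make_default_population(n=40_000, maf=0.3)
        pop = dataclasses.replace(
            pop, lambda_s={k: 0.0 for k in pop.lambda_s})
        g = pf.simulate_genotypes(pop.n, pop.maf, seed=11)
        items = pf.simulate_item_responses(pop, g, seed=12)
        labs = pop.indicator_labels
        for (a, b) in [(labs[0], labs[9]), (labs[3], labs[20])]:
            la, lb = pop.lambda_g[a], pop.lambda_g[b]
            implied = la * lb / np.sqrt((la ** 2 + 1) * (lb ** 2 + 1))
            rho, avar = pf.polychoric_corr(items.data[a], items.data[b])
            assert rho == pytest.approx(implied, abs=3 * np.sqrt(avar) + 0.005)

    def test_seed_determinism(self, default_pop):
        g = pf.simulate_genotypes(500, 0.3, seed=13)
        pop = dataclasses.replace(default_pop, n=500)
        a = pf.simulate_item_responses(pop, g, seed=14)
        b = pf.simulate_item_responses(pop, g, seed=14)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_missingness_flag(self, default_pop):
        pop = dataclasses.replace(default_pop, n=4000)
        g = pf.simulate_genotypes(pop.n, pop.maf, seed=15)
        items = pf.simulate_item_responses(pop, g, seed=16, missing_rate=0.1)
        frac = items.data.isna().to_numpy().mean()
        assert frac == pytest.approx(0.1, abs=0.01)
        assert items.complete_mask().sum() < pop.n

    def test_genotype_length_mismatch_rejected(self, default_pop):
        g = pf.simulate_genotypes(10, 0.3, seed=0)
        with pytest.raises(InvalidSpecError):
            pf.simulate_item_responses(default_pop, g, seed=0)


class TestPopulationSpec:
    def test_default_structure(self):
        spec = pf.make_default_population(n=1337, maf=0.3)
        assert spec.p == 26
        sizes = {d: sum(1 for v in spec.dim_map.values() if v == d)
                 for d in pf.DIMENSIONS}
        assert sizes == {"somatic": 6, "social": 7, "anxiety": 6,
                         "depression": 7}
        assert sum(sizes.values()) == 26
        ncat = spec.n_categories()
        composites = [k for k, v in ncat.items() if v == 7]
        assert sorted(composites) == ["headaches_comp", "sleep_problems_comp"]
        assert all(v == 4 for k, v in ncat.items() if k not in composites)
        # partition: every indicator in exactly one dimension
        assert set(spec.dim_map) == set(spec.indicator_labels)

    def test_yaml_roundtrip_lossless(self, tmp_path):
        spec = pf.make_default_population(n=77, maf=0.12,
                                          snp_effects={"somatic": 0.03})
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        back = pf.PopulationSpec.from_yaml(path)
        assert back == spec

    def test_nonincreasing_thresholds_rejected(self):
        spec = pf.make_default_population(n=100, maf=0.3)
        bad = dict(spec.thresholds)
        bad[spec.indicator_labels[0]] = [0.5, 0.5, 1.0]
        with pytest.raises(InvalidSpecError):
            dataclasses.replace(spec, thresholds=bad)

    def test_excessive_r2_rejected(self):
        with pytest.raises(InvalidSpecError):
            pf.make_default_population(n=100, maf=0.3,
                                       snp_effects={"anxiety": 1.0})
        # effects summing past 1 across SNPs are caught at simulation time
        pop = pf.make_default_population(n=100, maf=0.3)
        snps = [{"snp_id": f"s{i}", "maf": 0.3,
                 "effects": {"anxiety": 0.6}} for i in range(2)]
        with pytest.raises(InvalidSpecError):
            pf.simulate_cohort(pop, snps, seed=1)

    def test_csv_roundtrip(self, tmp_path, default_pop):
        pop = dataclasses.replace(default_pop, n=60)
        g = pf.simulate_genotypes(60, 0.3, seed=17)
        items = pf.simulate_item_responses(pop, g, seed=18, missing_rate=0.05)
        path = tmp_path / "items.csv"
        items.to_csv(path)
        back = pf.ItemResponseMatrix.from_csv(path)
        pd.testing.assert_frame_equal(back.data, items.data)
        assert back.dim_map == items.dim_map
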