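"""Generator contracts: determinism, planted structure, closed-form recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitoscreen import (
    CohortParams,
    DoseResponseParams,
    generate_cohort,
    generate_combination,
    generate_dose_response,
    generate_fingerprints,
    generate_kinome_profile,
    s_score,
    tanimoto,
)
from mitoscreen.synergy import median_effect_fit, combination_index


def small_cohort_params(**kw):
    defaults = dict(n_patients=80, n_genes=200, n_signature_genes=20, seed=11)
    defaults.update(kw)
    return CohortParams(**defaults)


class TestGenerateCohort:
    def test_same_seed_bit_identical(self):
        a = generate_cohort(small_cohort_params())
        b = generate_cohort(small_cohort_params())
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(a.survival, b.survival)
        assert a.truth.signature_genes == b.truth.signature_genes

    def test_different_seed_differs(self):
        a = generate_cohort(small_cohort_params(seed=1))
        b = generate_cohort(small_cohort_params(seed=2))
        assert not a.values.equals(b.values)

    def test_no_shared_factor_means_no_correlation(self):
        cohort = generate_cohort(
            small_cohort_params(n_patients=500, factor_loading=0.0, tumor_shift=0.0)
        )
        tumor = cohort.tumor_matrix()
        anchor = tumor.loc["GSG2"]
        rs = [
            stats.pearsonr(anchor, tumor.loc[g]).statistic
            for g in cohort.truth.signature_genes
        ]
        assert abs(np.mean(rs)) < 0.1

    def test_shared_factor_matches_closed_form_correlation(self):
        # two variables sharing one unit-loading factor with noise sd sigma
        # have correlation L^2 / (L^2 + sigma^2)
        loading, sigma = 1.0, 0.5
        expected = loading**2 / (loading**2 + sigma**2)
        cohort = generate_cohort(
            small_cohort_params(
                n_patients=500, factor_loading=loading, noise_sd=sigma, seed=5
            )
        )
        tumor = cohort.tumor_matrix()
        anchor = tumor.loc["GSG2"]
        rs = [
            stats.spearmanr(anchor, tumor.loc[g]).statistic
            for g in cohort.truth.signature_genes
        ]
        assert np.mean(rs) == pytest.approx(expected, abs=0.1)

    def test_pairing_and_survival_invariants(self):
        cohort = generate_cohort(small_cohort_params(censor_rate=0.5))
        assert (cohort.survival["time"] > 0).all()
        assert set(cohort.survival["event"].unique()) <= {0, 1}
        for nrm, tum in cohort.pairing.items():
            assert cohort.condition[nrm] == "normal"
            assert cohort.condition[tum] == "tumor"
            assert cohort.sample_patient[nrm] == cohort.sample_patient[tum]

    @pytest.mark.parametrize(
        "kw", [dict(n_signature_genes=200), dict(noise_sd=0.0), dict(censor_rate=1.5)]
    )
    def test_invalid_params_rejected(self, kw):
        with pytest.raises(ValueError):
            small_cohort_params(**kw)


class TestGenerateKinome:
    def test_planted_hit_count_drives_s_score(self):
        profile = generate_kinome_profile(403, 0, 17, threshold=10, seed=1)
        score = s_score(profile, 10)
        assert (score.n_hits, score.n_tested) == (17, 403)

    def test_extremes(self):
        none = generate_kinome_profile(50, 0, 0, threshold=10, seed=2)
        assert s_score(none, 10).value == 0.0
        all_hits = generate_kinome_profile(50, 0, 50, threshold=10, seed=3)
        assert s_score(all_hits, 10).value == 1.0

    def test_mutants_flagged_and_excluded(self):
        profile = generate_kinome_profile(100, 30, 10, threshold=10, seed=4)
        assert sum(e.is_mutant for e in profile.entries) == 30
        assert s_score(profile, 10).n_tested == 70

    def test_too_many_hits_rejected(self):
        with pytest.raises(ValueError):
            generate_kinome_profile(100, 50, 60, threshold=10, seed=5)

    def test_determinism(self):
        a = generate_kinome_profile(100, 10, 5, seed=6)
        b = generate_kinome_profile(100, 10, 5, seed=6)
        assert a.entries == b.entries


class TestGenerateDoseResponse:
    @pytest.mark.parametrize(
        "m, dm, dose, expected",
        [
            (2.0, 10.0, 10.0, 0.5),   # fa(Dm) = 0.5 by definition
            (1.0, 1.0, 3.0, 0.75),    # 3 / (1 + 3)
            (2.0, 10.0, 5.0, 0.2),    # 0.25 / 1.25
        ],
    )
    def test_noiseless_median_effect_values(self, m, dm, dose, expected):
        dr = generate_dose_response(
            DoseResponseParams("d", m=m, dm=dm, doses=(dose,), noise_sd=0.0)
        )
        assert dr.data["fa"].iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_noiseless_exactly_invertible(self):
        dr = generate_dose_response(
            DoseResponseParams("d", m=1.7, dm=3.3, doses=(0.5, 1, 2, 4, 8, 16))
        )
        fit = median_effect_fit(dr)
        assert fit.m == pytest.approx(1.7, rel=1e-10)
        assert fit.dm == pytest.approx(3.3, rel=1e-10)

    def test_nonpositive_dose_rejected(self):
        with pytest.raises(ValueError):
            DoseResponseParams("d", m=1, dm=1, doses=(1.0, -2.0))

    def test_determinism_with_noise(self):
        kw = dict(drug="d", m=1.0, dm=1.0, doses=(1.0, 2.0), noise_sd=0.3, seed=9)
        a = generate_dose_response(DoseResponseParams(**kw))
        b = generate_dose_response(DoseResponseParams(**kw))
        pd.testing.assert_frame_equal(a.data, b.data)


class TestGenerateCombination:
    @pytest.mark.parametrize("alpha", [0.25, 0.5, 1.0, 2.0])
    def test_planted_alpha_equals_ci_at_every_point(self, alpha):
        p1 = DoseResponseParams("a", m=1.3, dm=5.0, doses=(1, 2, 4, 8, 16, 32))
        p2 = DoseResponseParams("b", m=0.8, dm=0.7, doses=(0.1, 0.3, 1, 3, 9, 27))
        combo = generate_combination(
            p1, p2, combo_alpha=alpha, ratio=(3, 1), doses=[0.5, 1, 2, 4, 8]
        )
        fit1 = median_effect_fit(generate_dose_response(p1))
        fit2 = median_effect_fit(generate_dose_response(p2))
        for r in combo.data.itertuples():
            assert r.flag == ""
            ci = combination_index(r.dose1, r.dose2, r.fa, fit1, fit2)
            assert ci == pytest.approx(alpha, abs=1e-6)

    def test_rejects_bad_alpha(self):
        p = DoseResponseParams("a", m=1, dm=1, doses=(1,))
        with pytest.raises(ValueError):
            generate_combination(p, p, combo_alpha=0.0, doses=[1.0])


class TestGenerateFingerprints:
    def test_full_overlap_gives_identical_family_members(self):
        fps = generate_fingerprints(20, 1024, family_overlap=1.0, seed=1, n_families=4)
        fam0 = [fp for fp in fps if fp.id.startswith("F0_")]
        assert len(fam0) == 5
        for fp in fam0[1:]:
            assert tanimoto(fam0[0], fp) == 1.0

    def test_cross_family_tanimoto_zero(self):
        fps = generate_fingerprints(20, 1024, family_overlap=0.5, seed=2, n_families=4)
        a = next(fp for fp in fps if fp.id.startswith("F0_"))
        b = next(fp for fp in fps if fp.id.startswith("F1_"))
        assert tanimoto(a, b) == 0.0

    def test_within_family_mean_matches_monte_carlo_oracle(self):
        overlap, n_bits, n_fam, density = 0.5, 1024, 2, 0.5
        # Monte-Carlo oracle: simulate the generative model for bit pairs
        # directly (core bits shared, private bits independent) at 1e5 pairs.
        rng = np.random.default_rng(123)
        block = n_bits // n_fam
        core_p = density * overlap
        private_p = (density - core_p) / (1.0 - core_p)
        n_pairs = 100_000
        core = rng.random((n_pairs, block)) < core_p
        pa = core | (rng.random((n_pairs, block)) < private_p)
        pb = core | (rng.random((n_pairs, block)) < private_p)
        inter = (pa & pb).sum(axis=1)
        union = (pa | pb).sum(axis=1)
        expected = float(np.mean(inter[union > 0] / union[union > 0]))

        fps = generate_fingerprints(50, n_bits, overlap, seed=3, n_families=n_fam)
        fam0 = [fp for fp in fps if fp.id.startswith("F0_")]
        sims = [
            tanimoto(fam0[i], fam0[j])
            for i in range(len(fam0))
            for j in range(i + 1, len(fam0))
        ]
        assert np.mean(sims) == pytest.approx(expected, abs=0.05)

    def test_determinism_and_bounds(self):
        a = generate_fingerprints(10, 64, 0.3, seed=4)
        b = generate_fingerprints(10, 64, 0.3, seed=4)
        assert [fp.bits for fp in a] == [fp.bits for fp in b]
        with pytest.raises(ValueError):
            generate_fingerprints(10, 64, 1.5, seed=4)
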