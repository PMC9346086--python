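"""Per-locus equilibria, genome loads, and the closed-form ratio family."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from unguardedx import (
    DominanceSummary,
    LoadResult,
    LociCollection,
    LocusParams,
    ModelDomainError,
    WeakSelectionWarning,
    equilibrium_frequency,
    genome_loads_exact,
    locus_component_means,
    percent_conventions,
    ratio_baseline,
    ratio_no_dosage_comp,
    ratio_sex_limited,
    ratio_sexdiff,
    ratio_simplified,
)


class TestEquilibriumFrequency:
    @pytest.mark.parametrize(
        "kwargs, expected",
        [
            (dict(mu_f=0.0, mu_m=0.0, s_f=0.02, s_m=0.02, h=0.25), 0.0),
            (dict(mu_f=1e-6, mu_m=1e-6, s_f=0.02, s_m=0.02, h=0.25), 1e-4),
            (dict(mu_f=1e-6, mu_m=1e-6, s_f=0.0, s_m=0.02, h=0.25), 1.5e-4),
        ],
    )
    def test_closed_form(self, kwargs, expected):
        assert equilibrium_frequency(LocusParams(**kwargs)) == pytest.approx(expected)

    def test_neutral_locus_raises_with_locus_name(self):
        locus = LocusParams(
            mu_f=1e-6, mu_m=1e-6, s_f=0.0, s_m=0.0, h=0.25, locus_id="neutral1"
        )
        with pytest.raises(ModelDomainError, match="neutral1"):
            equilibrium_frequency(locus)

    def test_weak_selection_warns(self):
        # mutation pressure 3e-3 vs selection 3e-2: guard factor exceeded
        locus = LocusParams(mu_f=1e-3, mu_m=1e-3, s_f=0.02, s_m=0.02, h=0.25)
        with pytest.warns(WeakSelectionWarning):
            equilibrium_frequency(locus)

    def test_strong_selection_silent(self, reference_locus, recwarn):
        equilibrium_frequency(reference_locus)
        assert not any(
            isinstance(w.message, WeakSelectionWarning) for w in recwarn.list
        )


class TestLocusParamsValidation:
    @pytest.mark.parametrize(
        "field, value",
        [("mu_f", -1e-9), ("mu_f", 1.0), ("s_f", 1.5), ("h", -0.1), ("alpha_m", 2.0)],
    )
    def test_out_of_domain_rejected(self, field, value):
        kwargs = dict(mu_f=1e-6, mu_m=1e-6, s_f=0.02, s_m=0.02, h=0.25)
        kwargs[field] = value
        with pytest.raises(ModelDomainError):
            LocusParams(**kwargs)


class TestLocusComponentMeans:
    def test_zero_frequency_is_loadless(self, reference_locus):
        assert locus_component_means(reference_locus, 0.0) == (1.0, 1.0)

    def test_fully_recessive_invisible_in_females(self):
        locus = LocusParams(mu_f=1e-6, mu_m=1e-6, s_f=0.02, s_m=0.02, h=0.0)
        w_f, w_m = locus_component_means(locus, 0.3)
        assert w_f == 1.0
        assert w_m < 1.0

    def test_linearized_values(self):
        locus = LocusParams(
            mu_f=1e-6, mu_m=1e-6, s_f=0.02, s_m=0.02, h=0.25, alpha_f=0.3, alpha_m=0.3
        )
        w_f, w_m = locus_component_means(locus, 1e-4)
        assert w_f == pytest.approx(1.0 - 3e-7)
        assert w_m == pytest.approx(1.0 - 6e-7)

    def test_nonpositive_factor_is_error(self):
        locus = LocusParams(mu_f=0.0, mu_m=0.0, s_f=1.0, s_m=1.0, h=0.5)
        with pytest.raises(ModelDomainError, match="non-positive"):
            locus_component_means(locus, 1.0)


class TestGenomeLoadsExact:
    def test_no_mutation_no_effect(self):
        locus = LocusParams(mu_f=0.0, mu_m=0.0, s_f=0.02, s_m=0.02, h=0.25)
        res = genome_loads_exact(LociCollection.from_loci([locus]))
        assert res.ratio == pytest.approx(1.0)

    def test_identical_loci_match_simplified_exactly(self, identical_loci):
        """n identical equal-sex loci at h = 0.25 collapse algebraically to
        exp(n*mu*alpha) and to the mean-parameter formula with U = n*mu."""
        res = genome_loads_exact(identical_loci)
        n, mu, alpha = 100, 1e-6, 0.3
        assert res.ratio == pytest.approx(math.exp(n * mu * alpha), rel=1e-12)
        assert res.ratio == pytest.approx(
            ratio_simplified(n * mu, 0.25, alpha), rel=1e-12
        )

    def test_distributed_h_matches_taylor(self, distributed_loci):
        """Exact sum over 10^4 loci with spread dominance agrees with the
        second-order formula using the sample moments of h."""
        res = genome_loads_exact(distributed_loci)
        s = distributed_loci.summary()
        approx = ratio_baseline(
            s["U_linked"], DominanceSummary(s["h_bar"], s["var_h"]), s["alpha_f_bar"]
        )
        rel_log_err = abs(math.log(approx) - math.log(res.ratio)) / abs(
            math.log(res.ratio)
        )
        assert rel_log_err < 1e-3

    def test_empty_collection_rejected(self):
        with pytest.raises(ModelDomainError):
            LociCollection(())


class TestRatioFormulas:
    def test_drosophila_headline(self):
        assert ratio_simplified(0.1, 0.25, 0.3) == pytest.approx(1.0305, abs=5e-5)
        assert round(ratio_simplified(0.1, 0.25, 0.3), 2) == 1.03

    def test_additive_mutations_no_effect(self):
        assert ratio_simplified(0.2, 0.5, 0.3) == pytest.approx(1.0)

    @pytest.mark.parametrize("U", [0.05, 0.1, 0.5])
    def test_fully_recessive_upper_limit(self, U):
        assert ratio_simplified(U, 0.0, 1.0) == pytest.approx(math.exp(3 * U))

    def test_taylor_value(self):
        # 3*U*alpha = 0.09; bracket = (1-2h)/(1+2h) + 8*var/(1+2h)^3
        expected = math.exp(0.09 * (1.0 / 3.0 + 0.08 / 3.375))
        assert ratio_baseline(0.1, DominanceSummary(0.25, 0.01), 0.3) == pytest.approx(
            expected
        )
        assert expected == pytest.approx(1.032655, abs=5e-6)

    @given(
        U=st.floats(0.0, 1.0),
        h=st.floats(0.0, 0.5),
        alpha=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_taylor_reduces_to_simplified_at_zero_variance(self, U, h, alpha):
        assert ratio_baseline(U, DominanceSummary(h, 0.0), alpha) == ratio_simplified(
            U, h, alpha
        )

    @given(
        U=st.floats(0.0, 1.0),
        h=st.floats(0.0, 0.5),
        alpha=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_sexdiff_reduces_to_simplified_at_beta_one(self, U, h, alpha):
        assert ratio_sexdiff(U, h, alpha, 1.0) == ratio_simplified(U, h, alpha)

    def test_sexdiff_headline(self):
        assert ratio_sexdiff(0.1, 0.25, 0.1, 1.5) == pytest.approx(
            math.exp(0.0075)
        )
        assert round(ratio_sexdiff(0.1, 0.25, 0.1, 1.5), 4) == 1.0075

    def test_sexdiff_zw_bird(self):
        # ZW orientation: selection 1.5x stronger in the homogametic (male)
        # sex, so the het/hom ratio passed in is 1/1.5
        r = ratio_sexdiff(0.132, 0.25, 0.3, 1.0 / 1.5)
        assert r == pytest.approx(math.exp(0.0594 / (1.0 / 1.5 + 0.5)), rel=1e-12)
        assert 100 * (r - 1) == pytest.approx(5.2, abs=0.05)

    @pytest.mark.parametrize("beta", [1.1, 1.5, 3.0])
    def test_stronger_het_selection_dampens(self, beta):
        base = math.log(ratio_simplified(0.1, 0.25, 0.3))
        damped = math.log(ratio_sexdiff(0.1, 0.25, 0.3, beta))
        assert damped < base

    def test_nonpositive_beta_rejected(self):
        with pytest.raises(ModelDomainError):
            ratio_sexdiff(0.1, 0.25, 0.3, 0.0)

    def test_monotone_in_h_U_alpha(self):
        hs = np.linspace(0.0, 0.5, 26)
        ratios = [ratio_simplified(0.1, h, 0.3) for h in hs]
        assert all(a > b for a, b in zip(ratios, ratios[1:]))
        Us = np.linspace(0.0, 1.0, 11)
        assert all(
            ratio_simplified(u1, 0.25, 0.3) < ratio_simplified(u2, 0.25, 0.3)
            for u1, u2 in zip(Us, Us[1:])
        )
        alphas = np.linspace(0.0, 1.0, 11)
        assert all(
            ratio_simplified(0.1, 0.25, a1) < ratio_simplified(0.1, 0.25, a2)
            for a1, a2 in zip(alphas, alphas[1:])
        )

    def test_dominant_mean_warns(self):
        with pytest.warns(UserWarning, match="dominant"):
            r = ratio_simplified(0.1, 0.7, 0.3)
        assert r < 1.0


class TestSexLimited:
    def test_equal_alphas_abolish_effect(self):
        assert ratio_sex_limited(0.1, 0.3, 0.3).ratio == pytest.approx(1.0)

    def test_component_means_and_ratio(self):
        res = ratio_sex_limited(0.1, 0.1, 0.3)
        assert res.w_hom == pytest.approx(math.exp(-0.015))
        assert res.w_het == pytest.approx(math.exp(-0.045))
        assert res.ratio == pytest.approx(math.exp(0.03))

    def test_reversed_when_female_component_larger(self):
        assert ratio_sex_limited(0.1, 0.3, 0.1).ratio < 1.0


class TestNoDosageComp:
    @given(
        U=st.floats(0.0, 0.5),
        h=st.floats(0.0, 0.5),
        alpha=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_full_compensation_recovers_baseline(self, U, h, alpha):
        assert ratio_no_dosage_comp(U, h, alpha, 1.0) == ratio_simplified(U, h, alpha)

    @pytest.mark.parametrize("k", [0.3, 0.5, 0.9])
    def test_fully_recessive_undamped(self, k):
        assert ratio_no_dosage_comp(0.1, 0.0, 1.0, k) == pytest.approx(
            math.exp(0.3)
        )

    @pytest.mark.parametrize("k", [0.2, 0.5, 0.99])
    @pytest.mark.parametrize("h", [0.05, 0.25, 0.45])
    def test_damping_and_sign_threshold(self, k, h):
        damped = ratio_no_dosage_comp(0.1, h, 0.3, k)
        assert damped < ratio_simplified(0.1, h, 0.3)
        assert (damped > 1.0) == (h < k / 2.0)

    def test_k_domain(self):
        for k in (0.0, -0.5, 1.5):
            with pytest.raises(ModelDomainError):
                ratio_no_dosage_comp(0.1, 0.25, 0.3, k)


class TestLoadResultAndConventions:
    def test_percent_conventions(self):
        pct = percent_conventions(1.052233)
        assert pct["excess"] == pytest.approx(5.2233, abs=1e-4)
        assert pct["deficit"] == pytest.approx(100 * (1 - 1 / 1.052233))
        assert pct["log_pct"] == pytest.approx(100 * math.log(1.052233))

    def test_result_serialization_roundtrip(self):
        import json

        res = LoadResult(w_hom=0.99, w_het=0.96)
        payload = json.loads(res.to_json())
        assert payload["ratio"] == pytest.approx(0.99 / 0.96)
        assert set(payload["conventions"]) == {
            "pct_excess",
            "pct_deficit",
            "pct_log",
        }

    def test_invalid_survival_factors_rejected(self):
        with pytest.raises(ModelDomainError):
            LoadResult(w_hom=0.0, w_het=0.9)
        with pytest.raises(ModelDomainError):
            LoadResult(w_hom=0.9, w_het=1.2)


class TestLociCsvRoundTrip:
    def test_roundtrip(self, tmp_path, identical_loci):
        path = tmp_path / "loci.csv"
        identical_loci.to_csv(path)
        back = LociCollection.from_csv(path)
        assert back.n_X == identical_loci.n_X
        assert back.arrays()["h"] == pytest.approx(identical_loci.arrays()["h"])

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("locus_id,mu_f\nL0,1e-6\n")
        with pytest.raises(ModelDomainError, match="missing columns"):
            LociCollection.from_csv(path)


class TestDominanceSummary:
    def test_variance_bound_enforced(self):
        with pytest.raises(ModelDomainError):
            DominanceSummary(0.25, 0.25)  # max possible var is 0.1875
        DominanceSummary(0.25, 0.18)  # within the bound
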