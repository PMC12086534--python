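import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from h2oflux import (
    ElementalFormula,
    ExchangeableHydrogenEstimator,
    LabelingParameters,
    MID,
    analyte_enrichment,
    build_correction_matrix,
    correct_mid,
    estimate_f_mixture,
    estimate_n,
    forward_observed_mid,
    fractional_synthesis,
    natural_mid,
    new_pool_amount,
    truncation_bias_factor,
)
from h2oflux.labeling import SevereTruncationWarning

from oracles import enumeration_forward_mid

PALMITATE = ElementalFormula.from_string("C16H31O2", exchangeable_h=22)


def _corrected_mids(formula, n, p, f_values, K=3):
    nat = natural_mid(formula, K)
    cm = build_correction_matrix(nat)
    out = []
    for f in f_values:
        obs = forward_observed_mid(
            LabelingParameters(p=p, n=n, f=f), formula, K, truncation_bound=1.0
        )
        out.append(correct_mid(obs.values, cm))
    return out


class TestForwardModel:
    def test_no_synthesis_is_natural_abundance(self):
        mid = forward_observed_mid(
            LabelingParameters(p=0.04, n=22, f=0.0), PALMITATE, K=3
        )
        nat = natural_mid(PALMITATE, K=3)
        assert np.allclose(mid.values, nat.values, atol=1e-15)

    def test_unlabeled_water_is_natural_abundance(self):
        mid = forward_observed_mid(
            LabelingParameters(p=0.0, n=22, f=0.5), PALMITATE, K=3
        )
        nat = natural_mid(PALMITATE, K=3)
        assert np.allclose(mid.values, nat.values, atol=1e-12)

    def test_matches_enumeration_oracle(self, patterns):
        counts = {"C": 5, "H": 12, "O": 1}
        formula = ElementalFormula(counts=counts, exchangeable_h=10)
        mid = forward_observed_mid(
            LabelingParameters(p=0.04, n=10, f=0.3), formula, K=3
        )
        expected = enumeration_forward_mid(counts, patterns, 3, f=0.3, p=0.04, n=10)
        assert np.allclose(mid.values, expected, atol=1e-10)

    def test_severe_truncation_warns(self):
        with pytest.warns(SevereTruncationWarning):
            forward_observed_mid(
                LabelingParameters(p=0.3, n=22, f=0.8), PALMITATE, K=3
            )

    def test_n_must_match_designated_exchangeable(self):
        with pytest.raises(ValueError, match="exchangeable"):
            forward_observed_mid(
                LabelingParameters(p=0.04, n=10, f=0.1), PALMITATE, K=3
            )

    @given(
        f=st.floats(min_value=0.01, max_value=0.6),
        p=st.sampled_from([0.02, 0.04, 0.05]),
    )
    def test_enrichment_linear_and_increasing(self, f, p):
        """Enrichment is linear in f (slope p*n minus truncation) and grows with p."""
        params = LabelingParameters(p=p, n=22, f=f)
        nat = natural_mid(PALMITATE, K=3)
        cm = build_correction_matrix(nat)

        def enr(fv, pv):
            obs = forward_observed_mid(
                LabelingParameters(p=pv, n=22, f=fv), PALMITATE, 3,
                truncation_bound=1.0,
            )
            # un-normalized label distribution: linearity holds pre-renormalization
            mix = np.linalg.solve(cm.matrix, obs.values)
            return float(np.arange(4) @ mix)

        e1 = enr(f, p)
        e2 = enr(f / 2, p)
        assert e1 == pytest.approx(2 * e2, rel=1e-9)
        assert enr(f, p * 1.1) > e1


class TestEnrichmentAndEq1:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([1, 0, 0, 0], 0.0),
            ([0, 0, 0, 1], 3.0),
            ([0.85, 0.10, 0.04, 0.01], 0.21),
        ],
    )
    def test_weighted_sum(self, values, expected):
        assert analyte_enrichment(MID.from_values(values)) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "enrichment,p,n,expected",
        [
            (0.0, 0.04, 22, 0.0),
            (0.88, 0.04, 22, 100.0),
            (0.088, 0.04, 22, 10.0),
        ],
    )
    def test_fractional_synthesis_formula(self, enrichment, p, n, expected):
        assert fractional_synthesis(enrichment, p, n) == pytest.approx(expected)

    def test_zero_water_enrichment_rejected(self):
        with pytest.raises(ValueError, match="water enrichment"):
            fractional_synthesis(0.1, 0.0, 22)

    @given(
        enrichment=st.floats(min_value=0, max_value=2.9),
        p=st.floats(min_value=0.005, max_value=0.08),
        n=st.integers(min_value=1, max_value=30),
    )
    def test_algebraic_inverse(self, enrichment, p, n):
        f = fractional_synthesis(enrichment, p, n)
        assert f * (p * n) / 100.0 == pytest.approx(enrichment, rel=1e-12, abs=1e-15)

    def test_truncation_bias_shrinks_monotonically_with_K(self):
        """The K-truncation bias of Eq.-1 f estimates vanishes as K grows."""
        biases = [1.0 - truncation_bias_factor(22, 0.05, K) for K in range(3, 9)]
        assert all(b2 < b1 for b1, b2 in zip(biases, biases[1:]))
        assert biases[-1] < 1e-4

    def test_mixture_estimator_is_truncation_robust(self):
        f, p, n = 0.25, 0.05, 22
        (corrected,) = _corrected_mids(PALMITATE, n, p, [f])
        assert estimate_f_mixture(corrected, p, n) == pytest.approx(100 * f, rel=1e-9)


class TestEstimateN:
    def test_noiseless_palmitate_roundtrip(self):
        mids = _corrected_mids(PALMITATE, 22, 0.04, [0.05, 0.1, 0.2])
        result = estimate_n(mids, p=0.04)
        assert result.n == 22
        assert not result.tie
        assert result.ratio_estimate == pytest.approx(22.0, abs=1e-6)

    def test_bernoulli_labeling_gives_one(self):
        formula = ElementalFormula.from_string("C2H4O", exchangeable_h=1)
        mids = _corrected_mids(formula, 1, 0.04, [0.3, 0.5])
        assert estimate_n(mids, p=0.04).n == 1

    def test_recovers_tcdca_assignment(self, panel):
        adef = panel["T-CDCA"]
        assert adef.n_exchangeable == 18
        mids = _corrected_mids(adef.formula, 18, 0.04, [0.1, 0.2])
        assert estimate_n(mids, p=0.04).n == 18

    def test_insufficient_labeling_rejected(self):
        with pytest.raises(ValueError, match="insufficient labeling"):
            estimate_n([MID.from_values([1.0, 0, 0, 0])], p=0.04)

    def test_flat_profile_reports_tie_and_smallest(self):
        # at K=1 every binomial size fits m0/m1 exactly: a genuine tie
        mids = [np.array([0.99, 0.01])]
        result = estimate_n(mids, p=0.04, candidates=range(1, 10))
        assert result.tie
        assert result.n == 1
        assert len(result.tied_candidates) > 1

    @pytest.mark.parametrize(
        "cv,max_miss,min_rate",
        [
            (0.01, 0, 0.95),  # exact recovery at tight instrument noise
            (0.05, 2, 0.90),  # within +/-2 at routine 5% CV
        ],
    )
    def test_noisy_recovery_rate(self, rng, cv, max_miss, min_rate):
        """Recovery of n from 8 pooled samples under multiplicative noise.

        The integer-exact rate is limited by the noise on the m2/m1 and
        m3/m1 ratios, which carry all the n information once alpha and beta
        are free; at 5% per-isotopologue CV that noise exceeds the unit
        spacing of the candidate grid, so exactness is only guaranteed at
        tighter CVs while 5% CV still localizes n to +/-2.
        """
        n_true, p, f = 22, 0.04, 0.15
        formula = ElementalFormula.from_string("C16H31O2", exchangeable_h=22)
        nat = natural_mid(formula, K=3)
        cm = build_correction_matrix(nat)
        obs = forward_observed_mid(
            LabelingParameters(p=p, n=n_true, f=f), formula, K=3
        )
        sigma = np.sqrt(np.log1p(cv**2))
        hits = 0
        reps = 40
        for _ in range(reps):
            mids = []
            for _ in range(8):
                noisy = obs.values * np.exp(rng.normal(-sigma**2 / 2, sigma, 4))
                mids.append(correct_mid(noisy, cm))
            hits += abs(estimate_n(mids, p=p).n - n_true) <= max_miss
        assert hits / reps >= min_rate

    def test_estimator_interface(self):
        mids = _corrected_mids(PALMITATE, 22, 0.04, [0.1, 0.2])
        est = ExchangeableHydrogenEstimator(p=0.04).fit(
            np.vstack([m.values for m in mids])
        )
        assert est.n_ == 22
        assert est.residual_profile_.shape == (40,)
        assert est.get_params()["p"] == 0.04


def test_labeling_result_validates_ranges():
    from h2oflux import LabelingResult

    mid = MID.from_values([0.9, 0.08, 0.015, 0.005])
    res = LabelingResult(
        sample_id="s1", analyte_id="T-CA", corrected_mid=mid,
        enrichment=analyte_enrichment(mid), p=0.04, n=14, f_percent=20.0,
    )
    assert res.enrichment <= mid.K
    with pytest.raises(ValueError):
        LabelingResult(
            sample_id="s1", analyte_id="T-CA", corrected_mid=mid,
            enrichment=5.0, p=0.04, n=14, f_percent=20.0,
        )
    with pytest.raises(ValueError):
        LabelingResult(
            sample_id="s1", analyte_id="T-CA", corrected_mid=mid,
            enrichment=0.1, p=0.04, n=14, f_percent=-1.0,
        )


class TestNewPoolAmount:
    @pytest.mark.parametrize(
        "f,pool,expected",
        [(0.0, 123.0, 0.0), (100.0, 52.79, 52.79), (25.0, 80.0, 20.0)],
    )
    def test_arithmetic(self, f, pool, expected):
        assert new_pool_amount(f, pool) == pytest.approx(expected)

    @given(
        f=st.floats(min_value=0, max_value=100),
        pool=st.floats(min_value=0, max_value=1e4),
        c=st.floats(min_value=0.1, max_value=10),
    )
    def test_bilinear_and_nonnegative(self, f, pool, c):
        base = new_pool_amount(f, pool)
        assert base >= 0
        assert new_pool_amount(f, c * pool) == pytest.approx(c * base, rel=1e-12)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            new_pool_amount(-1.0, 10.0)
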