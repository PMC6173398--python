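"""Fixed-effects / DerSimonian-Laird combiners and Cochran heterogeneity."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from statsmodels.stats.meta_analysis import combine_effects

from transmeta.meta import (
    StudyEstimate,
    cochran_heterogeneity,
    dersimonian_laird_meta,
    fixed_effects_meta,
)
from transmeta.published import (
    SOLID_ACTIVITY,
    STABILITY_ACTIVITY,
    study_estimates,
    trial_estimates,
)


def make(pairs):
    return [StudyEstimate(f"s{i}", b, s) for i, (b, s) in enumerate(pairs)]


class TestFixedEffects:
    def test_single_estimate_is_identity(self):
        r = fixed_effects_meta(make([(1.3, 0.4)]))
        assert r.beta == pytest.approx(1.3) and r.se == pytest.approx(0.4)

    def test_two_identical_estimates_halve_the_variance(self):
        r = fixed_effects_meta(make([(0.7, 0.2), (0.7, 0.2)]))
        assert r.beta == pytest.approx(0.7)
        assert r.se == pytest.approx(0.2 / np.sqrt(2))

    def test_matches_weighted_least_squares_oracle(self, rng):
        # brute-force oracle: minimize the weighted sum of squares numerically
        from scipy.optimize import minimize_scalar

        for _ in range(10):
            k = rng.integers(2, 8)
            betas = rng.normal(0, 2, k)
            ses = rng.uniform(0.1, 3, k)
            ests = [StudyEstimate(f"s{i}", b, s) for i, (b, s) in enumerate(zip(betas, ses))]
            r = fixed_effects_meta(ests)
            w = 1 / ses**2
            opt = minimize_scalar(
                lambda mu: np.sum(w * (betas - mu) ** 2),
                bounds=(betas.min() - 1, betas.max() + 1), method="bounded",
                options={"xatol": 1e-12},
            )
            assert r.beta == pytest.approx(opt.x, abs=1e-7)
            # curvature of the chi-square surface gives the combined variance
            h = 1e-5
            f = lambda mu: np.sum(w * (betas - mu) ** 2)
            curv = (f(opt.x + h) - 2 * f(opt.x) + f(opt.x - h)) / h**2
            assert r.se == pytest.approx(np.sqrt(2 / curv), rel=1e-4)

    def test_matches_statsmodels_combine_effects(self, rng):
        # draw clearly heterogeneous effects so the DL moment estimate is
        # positive: statsmodels' "chi2" variant does not truncate tau2 at 0,
        # so the two definitions only coincide there
        for _ in range(5):
            k = int(rng.integers(3, 9))
            betas = rng.normal(0, 5, k)
            var = rng.uniform(0.01, 0.5, k)
            ests = [StudyEstimate(f"s{i}", b, np.sqrt(v)) for i, (b, v) in enumerate(zip(betas, var))]
            mine = fixed_effects_meta(ests)
            ref = combine_effects(betas, var, method_re="chi2")  # chi2 = DL moment estimator
            assert ref.tau2 > 0
            frame = ref.summary_frame()
            assert mine.beta == pytest.approx(frame.loc["fixed effect", "eff"], abs=1e-10)
            assert mine.se == pytest.approx(frame.loc["fixed effect", "sd_eff"], abs=1e-10)
            dl = dersimonian_laird_meta(ests)
            assert dl.beta == pytest.approx(frame.loc["random effect", "eff"], abs=1e-10)
            assert dl.se == pytest.approx(frame.loc["random effect", "sd_eff"], abs=1e-10)
            assert dl.tau2 == pytest.approx(ref.tau2, abs=1e-10)

    def test_rejects_empty_and_bad_se(self):
        with pytest.raises(ValueError):
            fixed_effects_meta([])
        with pytest.raises(ValueError):
            StudyEstimate("s", 1.0, 0.0)


class TestHeterogeneity:
    def test_identical_effects_give_zero_q(self):
        q, df, het_p, i2 = cochran_heterogeneity(make([(1.0, 0.5), (1.0, 0.2), (1.0, 1.0)]))
        assert q == pytest.approx(0.0)
        assert i2 == 0.0
        assert het_p == pytest.approx(1.0)

    def test_needs_two_studies(self):
        with pytest.raises(ValueError):
            cochran_heterogeneity(make([(1.0, 0.5)]))


class TestPublishedCohortRows:
    """Combined rows of the published 27-trait screen, from printed inputs."""

    @pytest.mark.parametrize(
        "trait, beta, ulp",
        [
            ("lppla2_activity", 2.424, 0.001),
            ("lppla2_mass", 1.775, 0.001),
            ("homocysteine", -0.012, 0.001),
            ("dpa_epa", -0.016, 0.001),
        ],
    )
    def test_fixed_effects_betas(self, trait, beta, ulp):
        r = fixed_effects_meta(study_estimates(trait))
        assert abs(r.beta - beta) <= ulp

    def test_activity_meta_se(self):
        r = fixed_effects_meta(study_estimates("lppla2_activity"))
        assert abs(r.se - 0.744) <= 0.001

    def test_mass_heterogeneity(self):
        _, _, het_p, i2 = cochran_heterogeneity(study_estimates("lppla2_mass"))
        assert abs(i2 - 32.0) <= 0.1
        assert abs(het_p - 0.22) <= 0.01

    def test_activity_heterogeneity_floors_at_zero(self):
        _, _, het_p, i2 = cochran_heterogeneity(study_estimates("lppla2_activity"))
        assert i2 == 0.0
        assert abs(het_p - 0.50) <= 0.01


class TestDerSimonianLaird:
    def test_truncation_reduces_to_fixed_effects(self):
        ests = make([(1.0, 0.5), (1.05, 0.5), (0.95, 0.5)])  # Q < df
        fe, dl = fixed_effects_meta(ests), dersimonian_laird_meta(ests)
        assert dl.tau2 == 0.0
        assert dl.beta == pytest.approx(fe.beta, abs=1e-14)
        assert dl.se == pytest.approx(fe.se, abs=1e-14)

    def test_published_stability_strata(self):
        r = dersimonian_laird_meta(trial_estimates(STABILITY_ACTIVITY))
        assert abs(r.beta - 3.82) <= 0.01
        assert abs(r.se - 0.59) <= 0.01
        assert r.tau2 == 0.0  # heterogeneity truncates

    def test_published_solid_strata(self):
        r = dersimonian_laird_meta(trial_estimates(SOLID_ACTIVITY))
        # printed inputs are rounded; the published 2.209 recomputes as 2.207
        assert abs(r.beta - 2.209) <= 0.005
        assert abs(r.se - 1.16) <= 0.01
        assert abs(r.p - 5.68e-2) <= 1e-3
        assert r.tau2 > 0


@given(
    data=st.lists(
        st.tuples(
            st.floats(-50, 50),
            st.floats(0.05, 10),
        ),
        min_size=2,
        max_size=8,
    ),
    shift=st.floats(-20, 20),
)
@settings(deadline=None, derandomize=True, max_examples=60)
def test_meta_invariants(data, shift):
    """Location equivariance; FE/DL standard-error orderings."""
    ests = make(data)
    fe, dl = fixed_effects_meta(ests), dersimonian_laird_meta(ests)
    # FE is at least as precise as the best single study; DL never more so than FE
    assert fe.se <= min(e.se for e in ests) + 1e-12
    assert dl.se >= fe.se - 1e-12
    assert dl.tau2 >= 0.0
    assert 0.0 <= fe.i2 < 100.0
    shifted = make([(b + shift, s) for b, s in data])
    fe2, dl2 = fixed_effects_meta(shifted), dersimonian_laird_meta(shifted)
    assert fe2.beta == pytest.approx(fe.beta + shift, rel=1e-9, abs=1e-7)
    assert fe2.q == pytest.approx(fe.q, rel=1e-6, abs=1e-7)
    assert dl2.tau2 == pytest.approx(dl.tau2, rel=1e-6, abs=1e-7)


def test_adding_a_study_increases_precision(rng):
    ests = make([(0.2, 0.5), (0.1, 0.8)])
    grown = ests + [StudyEstimate("new", 0.3, 1.5)]
    assert fixed_effects_meta(grown).se < fixed_effects_meta(ests).se
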