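"""Unit and property tests for the FFPE propagator evaluation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from tfcdiff import (
    FractionalParams,
    PropagatorQuery,
    SeriesSettings,
    check_admissibility,
    derived_exponents,
    evaluate_propagator,
    gaussian_limit_propagator,
    laplace_oracle,
    msd,
    propagator_profile,
)
from tfcdiff.propagator import (
    SeriesConvergenceError,
    _f_values,
    propagator_mass,
    propagator_second_moment,
    series_f,
    series_terms,
)

SQRT_PI = math.sqrt(math.pi)


class TestFractionalParams:
    @pytest.mark.parametrize(
        "alpha, expected",
        [
            (1.0, (-0.5, 0.5)),
            (0.47, (-0.765, 0.235)),  # the clinical study's fitted exponent
            (1.999, (-0.0005, 0.9995)),
        ],
    )
    def test_derived_exponents(self, alpha, expected):
        beta, gamma = derived_exponents(FractionalParams(alpha, 1.0))
        assert beta == pytest.approx(expected[0], abs=1e-12)
        assert gamma == pytest.approx(expected[1], abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, -0.3, 2.0, 2.5, float("nan")])
    def test_alpha_outside_open_interval_rejected(self, alpha):
        with pytest.raises(ValueError):
            FractionalParams(alpha=alpha, k_alpha=1.0)

    @pytest.mark.parametrize("k", [0.0, -1.0])
    def test_nonpositive_diffusivity_rejected(self, k):
        with pytest.raises(ValueError):
            FractionalParams(alpha=0.5, k_alpha=k)

    @given(st.floats(0.01, 1.99))
    def test_exponent_relations(self, alpha):
        p = FractionalParams(alpha, 1.0)
        assert p.beta == p.gamma - 1.0
        assert p.hurst == p.gamma


class TestQuery:
    def test_time_must_be_positive(self):
        with pytest.raises(ValueError):
            PropagatorQuery(x=0.0, x0=0.0, t=0.0)

    def test_similarity_argument(self):
        q = PropagatorQuery(x=3.0, x0=1.0, t=1.0)
        p = FractionalParams(alpha=1.0, k_alpha=4.0)
        assert q.g(p) == pytest.approx(1.0)
        assert PropagatorQuery(x=1.0, x0=1.0, t=1.0).g(p) == 0.0


class TestSeries:
    @pytest.mark.parametrize(
        "t, g, expected",
        [
            # closed-form Gaussian reduction f = exp(-g^2/(4t)) / sqrt(pi t)
            (1.0, 0.0, 1.0 / SQRT_PI),
            (1.0, 1.0, math.exp(-0.25) / SQRT_PI),
            (4.0, 2.0, math.exp(-0.25) / (2.0 * SQRT_PI)),
        ],
    )
    def test_gaussian_reduction(self, t, g, expected):
        res = series_f(t, g, beta=-0.5, gamma=0.5)
        assert not res.fallback
        assert res.value == pytest.approx(expected, rel=1e-12)

    def test_subdiffusive_value_matches_laplace_inversion(self):
        # independent Talbot oracle at the study's exponent
        res = series_f(1.0, 1.0, beta=-0.765, gamma=0.235)
        oracle = laplace_oracle(
            PropagatorQuery(x=1.0, x0=0.0, t=1.0), FractionalParams(0.47, 1.0)
        ) * 2.0  # strip the 1/(2 sqrt K) prefactor, K = 1
        assert res.value == pytest.approx(oracle, rel=1e-6)

    def test_gamma_pole_terms_vanish_exactly(self):
        # at alpha = 1 the reciprocal-Gamma argument hits a pole for odd k
        terms = series_terms(1.0, 1.0, beta=-0.5, gamma=0.5, k_max=30)
        assert np.all(terms[1::2] == 0.0)
        assert np.any(terms[0::2] != 0.0)

    def test_invalid_exponent_pair_rejected(self):
        with pytest.raises(ValueError):
            series_f(1.0, 1.0, beta=-0.2, gamma=0.5)

    def test_out_of_regime_without_fallback_raises(self):
        with pytest.raises(SeriesConvergenceError) as err:
            _f_values(
                1.0,
                np.array([40.0]),
                -0.765,
                0.235,
                SeriesSettings(),
                allow_fallback=False,
            )
        assert err.value.last_term == math.inf

    def test_far_regime_uses_fallback_consistently(self):
        from tfcdiff.propagator import _talbot_mp

        settings = SeriesSettings()
        res_near = series_f(1.0, 4.99, -0.765, 0.235, settings)
        res_far = series_f(1.0, 5.01, -0.765, 0.235, settings)
        assert not res_near.fallback and res_far.fallback
        # both routes agree with the high-precision inversion at their point
        for res, g in ((res_near, 4.99), (res_far, 5.01)):
            ref = _talbot_mp(1.0, g, 0.235, -0.765, 32, 30)
            assert res.value == pytest.approx(ref, rel=1e-6)


class TestPropagator:
    def test_classical_peak_value(self, classical_params):
        q = PropagatorQuery(x=0.0, x0=0.0, t=1.0)
        assert evaluate_propagator(q, classical_params) == pytest.approx(
            1.0 / math.sqrt(4.0 * math.pi), rel=1e-12
        )

    @hsettings(max_examples=30, deadline=None)
    @given(
        d=st.floats(0.01, 30.0),
        alpha=st.sampled_from([0.47, 0.8, 1.0, 1.3]),
        t=st.floats(0.2, 5.0),
    )
    def test_symmetry_in_displacement(self, d, alpha, t):
        p = FractionalParams(alpha, 2.0)
        left = evaluate_propagator(PropagatorQuery(5.0 - d, 5.0, t), p)
        right = evaluate_propagator(PropagatorQuery(5.0 + d, 5.0, t), p)
        assert left == pytest.approx(right, abs=1e-12)

    def test_profile_matches_scalar_evaluation(self, subdiffusive_params):
        xs = np.linspace(-3, 3, 11)
        profile = propagator_profile(xs, 0.0, 1.0, subdiffusive_params)
        singles = [
            evaluate_propagator(PropagatorQuery(x, 0.0, 1.0), subdiffusive_params)
            for x in xs
        ]
        np.testing.assert_allclose(profile, singles, rtol=1e-12)


class TestGaussianOracle:
    def test_closed_form_values(self):
        q0 = PropagatorQuery(x=0.0, x0=0.0, t=1.0)
        q2 = PropagatorQuery(x=2.0, x0=0.0, t=1.0)
        peak = 1.0 / math.sqrt(4.0 * math.pi)
        assert gaussian_limit_propagator(q0, 1.0) == pytest.approx(peak, rel=1e-12)
        assert gaussian_limit_propagator(q2, 1.0) == pytest.approx(
            peak * math.exp(-1.0), rel=1e-12
        )

    def test_normalization_by_quadrature(self):
        from scipy import integrate

        total, _ = integrate.quad(
            lambda x: gaussian_limit_propagator(PropagatorQuery(x, 0.0, 0.7), 2.0),
            -50,
            50,
        )
        assert total == pytest.approx(1.0, abs=1e-10)


class TestLaplaceOracle:
    def test_matches_gaussian_at_classical_alpha(self, classical_params):
        q = PropagatorQuery(x=0.0, x0=0.0, t=1.0)
        assert laplace_oracle(q, classical_params) == pytest.approx(
            gaussian_limit_propagator(q, 1.0), abs=1e-8
        )

    def test_two_precision_regression_value(self):
        # frozen after two precisions (32/30 and 64/45) agreed to < 1e-8
        p = FractionalParams(alpha=0.5, k_alpha=1.0)
        q = PropagatorQuery(x=1.0, x0=0.0, t=1.0)
        lo = laplace_oracle(q, p, degree=32, dps=30)
        hi = laplace_oracle(q, p, degree=64, dps=45)
        assert abs(lo - hi) < 1e-8
        assert lo == pytest.approx(0.19166770828534177, abs=1e-9)

    def test_symmetric_in_displacement(self):
        p = FractionalParams(alpha=0.8, k_alpha=3.0)
        va = laplace_oracle(PropagatorQuery(2.5, 1.0, 2.0), p)
        vb = laplace_oracle(PropagatorQuery(-0.5, 1.0, 2.0), p)
        assert va == pytest.approx(vb, rel=1e-12)

    def test_degree_below_contract_rejected(self, classical_params):
        with pytest.raises(ValueError):
            laplace_oracle(
                PropagatorQuery(0.0, 0.0, 1.0), classical_params, degree=16
            )


class TestMsd:
    def test_classical_limit(self):
        assert msd(FractionalParams(1.0, 1.0), 2.0) == pytest.approx(4.0)

    @given(
        alpha=st.floats(0.1, 1.9),
        k=st.floats(0.1, 10.0),
        t=st.floats(0.1, 5.0),
    )
    def test_power_law_doubling(self, alpha, k, t):
        p = FractionalParams(alpha, k)
        assert msd(p, 2.0 * t) / msd(p, t) == pytest.approx(
            2.0 ** alpha, rel=1e-9
        )

    def test_subdiffusive_closed_form_vs_quadrature(self, subdiffusive_params):
        from scipy import special

        closed = msd(subdiffusive_params, 1.0)
        assert closed == pytest.approx(2.0 / special.gamma(1.47), rel=1e-12)
        numeric = propagator_second_moment(subdiffusive_params, 1.0)
        assert numeric == pytest.approx(closed, rel=1e-2)


class TestAdmissibility:
    def test_classical_pair_admissible(self, classical_params):
        report = check_admissibility(
            classical_params, np.linspace(-10, 10, 81), [0.5, 1.0, 5.0]
        )
        assert report.admissible
        assert report.nonneg_ok and report.normalized_ok and report.slot_mass_ok
        assert report.density_min >= -1e-9

    def test_out_of_range_alpha_rejected_before_evaluation(self):
        with pytest.raises(ValueError):
            check_admissibility(
                FractionalParams(2.4, 1.0), np.linspace(-5, 5, 11), [1.0]
            )

    def test_slot_masses_of_normalized_density_bounded_by_one(self):
        # a density may exceed 1 (narrow kernel) but slot masses may not
        p = FractionalParams(1.0, 0.001)
        report = check_admissibility(p, np.linspace(-1, 1, 41), [0.5])
        assert report.density_max > 1.0
        assert report.slot_mass_ok

    def test_report_serializes(self, classical_params):
        import json

        report = check_admissibility(
            classical_params, np.linspace(-5, 5, 21), [1.0]
        )
        payload = json.loads(report.to_json())
        assert payload["admissible"] is True
        assert len(payload["per_t"]) == 1

    def test_empty_grids_rejected(self, classical_params):
        with pytest.raises(ValueError):
            check_admissibility(classical_params, [], [1.0])
        with pytest.raises(ValueError):
            check_admissibility(classical_params, [0.0], [])


class TestNormalization:
    @pytest.mark.parametrize("alpha", [0.47, 0.8, 1.2])
    def test_total_mass_is_one(self, alpha):
        p = FractionalParams(alpha, 1.5)
        for t in (0.5, 2.0):
            assert propagator_mass(p, t) == pytest.approx(1.0, abs=1e-3)
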