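"""Oxygen-response functions, hypoxic mortalities, predation and derivatives."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from benthox.model_core import (
    ModelParameters,
    ModelState,
    ParameterError,
    SigmoidParams,
    arrhenius,
    default_sigmoid,
    macrobenthos_derivative,
    phytoplankton_derivative,
    predation_rate,
    unnormalized_sigmoid,
    z_function,
    z_prime,
    zoo_hypoxic_mortality,
    zooplankton_derivative,
)


class _Rec:
    def __init__(self, temperature=20.0, par=25.0, do_conc=6.0, poc=2.0, din=0.2):
        self.temperature = temperature
        self.par = par
        self.do_conc = do_conc
        self.poc = poc
        self.din = din


class TestZFunction:
    def test_anchored_at_half_and_quarter(self):
        assert z_function(1.5, 1.5, 1.0) == pytest.approx(0.5)
        assert z_function(1.0, 1.5, 1.0) == pytest.approx(0.25)

    def test_logistic_symmetry_gives_three_quarters(self):
        # reflecting do_qx through do_gx: k = ln3/(do_gx - do_qx) puts the
        # 75% point at 2*do_gx - do_qx
        do_gx, do_qx = 2.0, 1.2
        assert z_function(2 * do_gx - do_qx, do_gx, do_qx) == pytest.approx(0.75)

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ParameterError):
            z_function(1.0, 1.0, 1.5)

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        do=st.floats(0.0, 50.0),
        do_gx=st.floats(0.5, 5.0),
        gap=st.floats(0.05, 2.0),
    )
    def test_bounded_in_unit_interval(self, do, do_gx, gap):
        z = z_function(do, do_gx, do_gx - gap * 0.9)
        assert 0.0 <= z <= 1.0


class TestZPrime:
    def test_midpoint_at_log_a_over_b(self):
        p = SigmoidParams(a=50.0, b=2.0)
        assert z_prime(math.log(50.0) / 2.0, p) == pytest.approx(0.5)

    def test_saturates_to_one(self):
        p = SigmoidParams(a=100.0, b=3.0)
        assert z_prime(10.0, p) == pytest.approx(1.0, abs=1e-8)

    def test_hand_value(self):
        # 1 / (1 + 100 e^-6)
        p = SigmoidParams(a=100.0, b=3.0)
        assert z_prime(2.0, p) == pytest.approx(1.0 / (1.0 + 100.0 * math.exp(-6.0)))
        assert z_prime(2.0, p) == pytest.approx(0.8014, abs=5e-4)

    def test_negative_do_rejected(self):
        with pytest.raises(ValueError):
            z_prime(-0.1, SigmoidParams(a=2.0, b=1.0))

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(
        a=st.floats(1e-3, 1e9),
        b=st.floats(1e-3, 50.0),
        do1=st.floats(0.0, 30.0),
        do2=st.floats(0.0, 30.0),
    )
    def test_monotone_and_bounded(self, a, b, do1, do2):
        p = SigmoidParams(a=a, b=b)
        lo, hi = sorted((do1, do2))
        z_lo, z_hi = z_prime(lo, p), z_prime(hi, p)
        assert 0.0 < z_lo <= z_hi <= 1.0


class TestUnnormalizedSigmoid:
    def test_hand_value(self):
        p = SigmoidParams(a=100.0, b=3.0, c=5.0)
        assert unnormalized_sigmoid(2.0, p) == pytest.approx(4.007, abs=5e-3)

    def test_value_at_zero_do(self):
        p = SigmoidParams(a=100.0, b=3.0, c=5.0)
        assert unnormalized_sigmoid(0.0, p) == pytest.approx(5.0 / 101.0)

    def test_ratio_to_normalized_is_amplitude(self):
        p = SigmoidParams(a=50.0, b=2.0, c=4.2)
        rng = np.random.default_rng(0)
        do = rng.uniform(0.0, 10.0, 1000)
        np.testing.assert_allclose(
            unnormalized_sigmoid(do, p) / z_prime(do, p), p.c, rtol=1e-14
        )


class TestZooHypoxicMortality:
    def test_zero_above_threshold(self, params):
        mz, doref = zoo_hypoxic_mortality(2.0, params)
        assert mz == 0.0 and doref == 2.0
        assert zoo_hypoxic_mortality(6.0, params)[0] == 0.0

    def test_maximal_at_anoxia(self, params):
        mz, doref = zoo_hypoxic_mortality(0.0, params)
        assert mz == pytest.approx(params.mzero_z)
        assert doref == 0.0

    def test_linear_halfway(self):
        p = ModelParameters(mzero_z=0.2, docrit_z=2.0)
        assert zoo_hypoxic_mortality(1.0, p)[0] == pytest.approx(0.1)

    def test_continuous_at_threshold(self, params):
        eps = 1e-9
        below = zoo_hypoxic_mortality(params.docrit_z - eps, params)[0]
        at = zoo_hypoxic_mortality(params.docrit_z, params)[0]
        assert below == pytest.approx(at, abs=1e-8)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(do1=st.floats(0.0, 2.0), do2=st.floats(0.0, 2.0))
    def test_monotone_decreasing_below_threshold(self, params, do1, do2):
        lo, hi = sorted((do1, do2))
        assert (
            zoo_hypoxic_mortality(lo, params)[0]
            >= zoo_hypoxic_mortality(hi, params)[0]
        )


class TestArrhenius:
    def test_unity_at_reference(self):
        assert arrhenius(20.0, 1.07, 20.0) == pytest.approx(1.0)
        assert arrhenius(35.0, 1.0, 20.0) == pytest.approx(1.0)

    def test_hand_power(self):
        assert arrhenius(30.0, 1.07, 20.0) == pytest.approx(1.07**10)
        assert arrhenius(30.0, 1.07, 20.0) == pytest.approx(1.9672, abs=1e-4)


class TestPredationRate:
    def test_half_saturation(self, params):
        full = params.beta_hat * arrhenius(25.0, params.theta_pred, params.t_ref)
        assert predation_rate(25.0, params.kdo, params) == pytest.approx(full / 2)

    def test_zero_at_anoxia(self, params):
        assert predation_rate(25.0, 0.0, params) == 0.0

    def test_hand_value(self):
        # theta chosen so the temperature multiplier is exactly 2
        p = ModelParameters(beta_hat=0.01, kdo=1.0, theta_pred=2.0, t_ref=20.0)
        assert predation_rate(21.0, 3.0, p) == pytest.approx(0.015)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(
        t1=st.floats(0.0, 35.0), t2=st.floats(0.0, 35.0),
        do1=st.floats(0.0, 15.0), do2=st.floats(0.0, 15.0),
    )
    def test_monotone_in_temperature_and_do(self, params, t1, t2, do1, do2):
        t_lo, t_hi = sorted((t1, t2))
        do_lo, do_hi = sorted((do1, do2))
        assert predation_rate(t_lo, do_lo, params) <= predation_rate(t_hi, do_hi, params)


class TestDerivatives:
    @pytest.mark.parametrize("which", ["P", "M", "B"])
    def test_no_spontaneous_generation(self, params, sigmoid, which):
        state = ModelState(
            P=0.0 if which == "P" else 0.5,
            M=0.0 if which == "M" else 0.2,
            B=0.0 if which == "B" else 2.0,
        )
        rec = _Rec()
        fn = {
            "P": phytoplankton_derivative,
            "M": zooplankton_derivative,
            "B": macrobenthos_derivative,
        }[which]
        d, _ = fn(state, rec, params, sigmoid)
        assert d == 0.0

    def test_phytoplankton_hand_balance(self, sigmoid):
        # engineer G = 0.5 exactly: saturating light/DIN, theta 1 at t_ref
        p = ModelParameters(
            pbm=0.5, resp_p=0.1, wa=0.1, phtl=0.05, theta_p=1.0,
            light_k=1e-12, kdin=1e-12,
        )
        state = ModelState(P=1.0, M=1.0, B=1.0)
        d, diag = phytoplankton_derivative(state, _Rec(), p, sigmoid)
        assert diag.PR == pytest.approx(0.05)
        assert d == pytest.approx((0.5 - 0.1 - 0.1) * 1.0 - 0.05)

    def test_zooplankton_balance_point(self, sigmoid):
        # Gz = 0.3 via saturating prey, losses tuned so dM/dt = 0
        p = ModelParameters(gz_max=0.3, kp_graze=1e-12, bmz=0.1, mzero_z=0.4,
                            phtlz=0.0, theta_z=1.0)
        state = ModelState(P=1.0, M=1.0, B=1.0)
        rec = _Rec(do_conc=1.0)  # Mz = 0.4*(1 - 1/2) = 0.2
        d, diag = zooplankton_derivative(state, rec, p, sigmoid)
        assert diag.Mz == pytest.approx(0.2)
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_zooplankton_mortality_off_under_normoxia(self, params, sigmoid):
        state = ModelState(P=0.5, M=0.3, B=2.0)
        _, diag = zooplankton_derivative(state, _Rec(do_conc=4.0), params, sigmoid)
        assert diag.Mz == 0.0

    def test_macrobenthos_pure_losses(self):
        # gains off (i0 = 0); back out rates so that at DO = 1, B = 2:
        # r*Z = 0.05, beta*B = 0.01, m = 0.04  =>  dB/dt = -0.1 * 2 = -0.2
        sig = SigmoidParams(a=1.5, b=1.0)
        do = 1.0
        zp = 1.0 / (1.0 + 1.5 * math.exp(-1.0))
        defaults = ModelParameters()
        z = float(z_function(do, defaults.do_gx, defaults.do_qx))
        p = ModelParameters(
            i0=0.0,
            resp_b=0.05 / z,
            beta_hat=0.01 / (2.0 * do / (defaults.kdo + do)),
            mzero_b=0.04 / (1.0 - zp),
            theta_pred=1.0, theta_b=1.0,
        )
        state = ModelState(P=0.0, M=0.0, B=2.0)
        d, diag = macrobenthos_derivative(state, _Rec(do_conc=do), p, sig)
        assert diag.m == pytest.approx(0.04)
        assert diag.beta * state.B == pytest.approx(0.01)
        assert d == pytest.approx(-(0.05 + 0.01 + 0.04) * 2.0)

    def test_macrobenthos_mortality_vanishes_at_high_do(self, params, sigmoid):
        state = ModelState(P=0.5, M=0.2, B=2.0)
        _, diag = macrobenthos_derivative(state, _Rec(do_conc=10.0), params, sigmoid)
        assert diag.m == pytest.approx(0.0, abs=1e-6)
        assert diag.Zprime == pytest.approx(1.0, abs=1e-6)


class TestParameterValidation:
    def test_invalid_values_rejected(self):
        with pytest.raises(ParameterError):
            ModelParameters(alpha=0.0)
        with pytest.raises(ParameterError):
            ModelParameters(do_gx=1.0, do_qx=1.5)
        with pytest.raises(ParameterError):
            ModelParameters(pbm=-0.1)

    def test_config_round_trip(self, tmp_path, params):
        path = tmp_path / "params.cfg"
        params.to_file(path)
        assert ModelParameters.from_file(path) == params

    def test_unknown_key_rejected(self, tmp_path):
        path = tmp_path / "bad.cfg"
        path.write_text("not_a_parameter = 1.0\n")
        with pytest.raises(ParameterError):
            ModelParameters.from_file(path)

    def test_with_scaled(self, params):
        assert params.with_scaled("alpha", 1.2).alpha == pytest.approx(1.2 * params.alpha)
        with pytest.raises(ParameterError):
            params.with_scaled("nope", 1.2)
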