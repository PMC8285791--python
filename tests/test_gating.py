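"""Gate kinetics: Boltzmann steady states, tau blends, closed-form relaxation,
and window profiles, including property tests over random gate specs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tburst.gating import (
    ACTIVATION,
    INACTIVATION,
    GateSpec,
    relax_gate_closed_form,
    steady_state,
    time_constant,
    window_profile,
)


def make_gate(polarity=ACTIVATION, v_half=-50.0, slope=6.0, tau_depol=2.0,
              tau_hyper=20.0, tau_v_mid=-60.0, tau_slope=8.0, exponent=1):
    return GateSpec(v_half=v_half, slope=slope, polarity=polarity,
                    tau_depol=tau_depol, tau_hyper=tau_hyper,
                    tau_v_mid=tau_v_mid, tau_slope=tau_slope, exponent=exponent)


gate_specs = st.builds(
    make_gate,
    polarity=st.sampled_from([ACTIVATION, INACTIVATION]),
    v_half=st.floats(-90, -20),
    slope=st.floats(1, 15),
    tau_depol=st.floats(0.2, 300),
    tau_hyper=st.floats(0.2, 300),
    tau_v_mid=st.floats(-90, -20),
    tau_slope=st.floats(1, 15),
    exponent=st.integers(1, 4),
)


class TestSteadyState:
    def test_midpoint_is_half(self):
        for pol in (ACTIVATION, INACTIVATION):
            g = make_gate(polarity=pol)
            assert steady_state(g, g.v_half) == pytest.approx(0.5)

    def test_one_slope_above_midpoint(self):
        g = make_gate(polarity=ACTIVATION)
        expected = 1.0 / (1.0 + math.exp(-1.0))
        assert steady_state(g, g.v_half + g.slope) == pytest.approx(expected, abs=1e-12)

    def test_inactivation_saturates_to_one_when_hyperpolarized(self):
        g = make_gate(polarity=INACTIVATION)
        assert steady_state(g, g.v_half - 40 * g.slope) == pytest.approx(1.0, abs=1e-9)

    def test_rejects_nonfinite_voltage(self):
        g = make_gate()
        with pytest.raises(ValueError):
            steady_state(g, math.nan)
        with pytest.raises(ValueError):
            steady_state(g, math.inf)

    def test_gate_spec_rejects_nonpositive_slope(self):
        with pytest.raises(ValueError):
            make_gate(slope=0.0)
        with pytest.raises(ValueError):
            make_gate(slope=-3.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(gate=gate_specs)
    def test_bounded_and_monotone_with_polarity(self, gate):
        v = np.linspace(-150, 60, 301)
        x = steady_state(gate, v)
        assert np.all((x >= 0) & (x <= 1))
        dx = np.diff(x)
        if gate.polarity == ACTIVATION:
            assert np.all(dx >= 0)
        else:
            assert np.all(dx <= 0)


class TestTimeConstant:
    def test_blend_midpoint_is_average(self):
        g = make_gate(tau_depol=4.0, tau_hyper=30.0)
        assert time_constant(g, g.tau_v_mid) == pytest.approx((4.0 + 30.0) / 2)

    def test_saturates_to_hyper_limit(self):
        g = make_gate(tau_depol=4.0, tau_hyper=30.0)
        tau = time_constant(g, g.tau_v_mid - 40 * g.tau_slope)
        assert tau == pytest.approx(30.0, rel=1e-6)

    def test_degenerate_blend_is_constant(self):
        g = make_gate(tau_depol=5.0, tau_hyper=5.0)
        for v in (-120.0, -60.0, 0.0, 40.0):
            assert time_constant(g, v) == pytest.approx(5.0)

    def test_rejects_nonpositive_taus(self):
        with pytest.raises(ValueError):
            make_gate(tau_depol=0.0)
        with pytest.raises(ValueError):
            make_gate(tau_hyper=-1.0)
        with pytest.raises(ValueError):
            make_gate(tau_slope=0.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(gate=gate_specs)
    def test_never_leaves_limiting_band(self, gate):
        v = np.linspace(-150, 60, 301)
        tau = time_constant(gate, v)
        lo = min(gate.tau_depol, gate.tau_hyper)
        hi = max(gate.tau_depol, gate.tau_hyper)
        assert np.all(tau >= lo - 1e-12)
        assert np.all(tau <= hi + 1e-12)


class TestClosedFormRelaxation:
    def test_initial_condition(self):
        g = make_gate()
        assert relax_gate_closed_form(g, -60.0, 0.37, 0.0) == pytest.approx(0.37)

    def test_equilibrium_at_long_times(self):
        g = make_gate()
        tau = time_constant(g, -60.0)
        x = relax_gate_closed_form(g, -60.0, 0.0, 50 * tau)
        assert x == pytest.approx(steady_state(g, -60.0), abs=1e-9)

    def test_one_time_constant_from_zero(self):
        g = make_gate()
        tau = time_constant(g, -60.0)
        x_inf = steady_state(g, -60.0)
        x = relax_gate_closed_form(g, -60.0, 0.0, tau)
        assert x == pytest.approx(x_inf * (1 - math.exp(-1)), abs=1e-12)

    def test_rejects_bad_inputs(self):
        g = make_gate()
        with pytest.raises(ValueError):
            relax_gate_closed_form(g, -60.0, 0.5, -1.0)
        with pytest.raises(ValueError):
            relax_gate_closed_form(g, -60.0, 1.5, 1.0)


class TestWindowProfile:
    def test_nonoverlapping_curves_have_negligible_window(self):
        act = make_gate(polarity=ACTIVATION, v_half=-40.0)
        inact = make_gate(polarity=INACTIVATION, v_half=-140.0)
        prof = window_profile(act, inact, np.linspace(-150, 20, 500))
        assert prof.peak < 1e-3

    def test_symmetric_complementary_sigmoids_peak_quarter_at_midpoint(self):
        v0 = -55.0
        act = make_gate(polarity=ACTIVATION, v_half=v0, slope=7.0, exponent=1)
        inact = make_gate(polarity=INACTIVATION, v_half=v0, slope=7.0)
        prof = window_profile(act, inact, np.linspace(-120, 20, 1401))
        assert prof.peak == pytest.approx(0.25, abs=1e-6)
        assert prof.peak_voltage == pytest.approx(v0, abs=0.11)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(act=gate_specs, inact=gate_specs)
    def test_peak_matches_dense_brute_force(self, act, inact):
        """Coarse-grid peak/argmax agree with a 0.01 mV brute-force search."""
        act = make_gate(polarity=ACTIVATION, v_half=act.v_half, slope=act.slope,
                        exponent=act.exponent)
        inact = make_gate(polarity=INACTIVATION, v_half=inact.v_half,
                          slope=inact.slope)
        grid = np.linspace(-120, 0, 1201)  # 0.1 mV
        prof = window_profile(act, inact, grid)
        # independent brute force via direct formula on a 0.01 mV grid
        dense = np.arange(-120, 0.0001, 0.01)
        s_act = 1.0 / (1.0 + np.exp(-(dense - act.v_half) / act.slope))
        s_inact = 1.0 / (1.0 + np.exp((dense - inact.v_half) / inact.slope))
        w = s_act ** act.exponent * s_inact
        assert prof.peak == pytest.approx(float(w.max()), abs=1e-4)
        assert prof.peak_voltage == pytest.approx(float(dense[np.argmax(w)]), abs=0.2)

    def test_peak_invariant_under_grid_refinement(self):
        act = make_gate(polarity=ACTIVATION, v_half=-50.0, exponent=2)
        inact = make_gate(polarity=INACTIVATION, v_half=-72.0)
        coarse = window_profile(act, inact, np.arange(-120, 0.01, 0.1))
        fine = window_profile(act, inact, np.arange(-120, 0.001, 0.01))
        assert coarse.peak == pytest.approx(fine.peak, abs=1e-4)

    def test_rejects_bad_grids(self):
        act = make_gate(polarity=ACTIVATION)
        inact = make_gate(polarity=INACTIVATION)
        with pytest.raises(ValueError):
            window_profile(act, inact, np.array([]))
        with pytest.raises(ValueError):
            window_profile(act, inact, np.array([-60.0, -50.0]))
        with pytest.raises(ValueError):
            window_profile(act, inact, np.array([-50.0, -60.0, -40.0]))
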