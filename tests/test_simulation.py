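"""Integrator contracts: exactness limits, determinism, protocol handling."""

import numpy as np
import pytest

from tburst.gating import ACTIVATION, INACTIVATION, GateSpec, relax_gate_closed_form
from tburst.model import CaTParams, Channel, NeuronParams, default_neuron
from tburst.simulate import (
    Protocol,
    Segment,
    integrate,
    settle_to_rhythm,
)
from tburst.spikes import f_i_curve


def capacitor_neuron(cat=None):
    return NeuronParams(
        c_m=1.0,
        na=Channel(0.0, 55.0),
        k=Channel(0.0, -90.0),
        leak=Channel(0.0, -65.0),
        cat=cat,
    )


def gate_carrier(act, inact):
    """Zero-conductance neuron whose only gates are a CaT pair (for clamping)."""
    cat = CaTParams("carrier", "21C", 0.0, 120.0, act, inact)
    return capacitor_neuron(cat)


class TestExactLimits:
    @pytest.mark.parametrize("method", ["exponential-euler", "rk4"])
    def test_capacitor_charges_linearly(self, method):
        p = capacitor_neuron()
        prot = Protocol(segments=(Segment(1.0, 100.0),), dt=0.02, v_init=-65.0)
        tr = integrate(p, prot, method=method)
        assert tr.v[-1] - tr.v[0] == pytest.approx(100.0, abs=1e-9)
        # linear throughout
        assert np.allclose(tr.v, -65.0 + tr.t, atol=1e-9)

    def test_charge_balance_machine_precision_expeuler(self):
        p = capacitor_neuron()
        prot = Protocol(segments=(Segment(0.37, 50.0),), dt=0.02, v_init=-60.0)
        tr = integrate(p, prot)
        assert tr.v[-1] - tr.v[0] == pytest.approx(0.37 * 50.0, abs=1e-11)

    @pytest.mark.parametrize("method", ["exponential-euler", "rk4"])
    def test_clamped_gates_match_closed_form(self, method):
        """Voltage-clamped gate trajectories vs the analytic relaxation."""
        act = GateSpec(-50.0, 6.0, ACTIVATION, 1.5, 6.0, -45.0, 8.0, 2)
        inact = GateSpec(-75.0, 6.0, INACTIVATION, 25.0, 60.0, -70.0, 6.0, 1)
        p = gate_carrier(act, inact)
        v_clamp = -62.0
        x0_m, x0_h = 0.1, 0.9
        init = np.array([v_clamp, x0_m, x0_h])
        prot = Protocol(
            segments=(Segment(0.0, 50.0, v_clamp=v_clamp),), dt=0.01, init=init
        )
        tr = integrate(p, prot, method=method)
        for name, x0 in (("cat_m", x0_m), ("cat_h", x0_h)):
            spec = act if name == "cat_m" else inact
            expected = relax_gate_closed_form(spec, v_clamp, x0, tr.t)
            assert np.max(np.abs(tr.gates[name] - expected)) < 1e-6

    def test_gate_guard_never_fires_on_healthy_run(self):
        p = default_neuron()
        res = settle_to_rhythm(p, 3.0)
        prot = Protocol(segments=(Segment(3.0, 200.0),), dt=0.02, init=res.state)
        tr = integrate(p, prot)
        assert tr.n_clamp_events == 0
        for arr in tr.gates.values():
            assert np.all((arr >= 0) & (arr <= 1))


class TestProtocolHandling:
    def test_segment_boundaries_are_exact_cumulative_durations(self):
        prot = Protocol(
            segments=(Segment(3.0, 200.0), Segment(-5.0, 70.0), Segment(3.0, 130.0)),
            dt=0.02,
        )
        assert np.array_equal(prot.boundaries(), np.array([200.0, 270.0, 400.0]))
        p = capacitor_neuron()
        tr = integrate(p, prot)
        assert np.array_equal(tr.segment_boundaries, prot.boundaries())
        # applied current switches right after the boundary sample
        i_before = tr.i_app[np.searchsorted(tr.t, 200.0) - 1]
        i_after = tr.i_app[np.searchsorted(tr.t, 200.0) + 1]
        assert i_before == 3.0
        assert i_after == -5.0

    def test_rejects_invalid_protocols(self):
        with pytest.raises(ValueError):
            Protocol(segments=())
        with pytest.raises(ValueError):
            Protocol(segments=(Segment(1.0, 0.0),))
        with pytest.raises(ValueError):
            Protocol(segments=(Segment(1.0, 10.0),), dt=0.1)
        with pytest.raises(ValueError):
            Protocol(segments=(Segment(1.0, 10.0),), dt=0.02, sample_interval=0.05)
        with pytest.raises(ValueError):
            Protocol(segments=(Segment(1.0, 10.0),), init="bogus")

    def test_rejects_unknown_method(self):
        p = capacitor_neuron()
        prot = Protocol(segments=(Segment(1.0, 10.0),))
        with pytest.raises(ValueError):
            integrate(p, prot, method="euler")

    def test_sampling_interval_subsamples_grid(self):
        p = capacitor_neuron()
        prot = Protocol(segments=(Segment(1.0, 10.0),), dt=0.02, sample_interval=0.1)
        tr = integrate(p, prot)
        assert tr.t[1] - tr.t[0] == pytest.approx(0.1)
        assert len(tr.t) == 101


class TestDeterminismAndRhythm:
    def test_settle_is_bit_deterministic(self, baseline):
        a = settle_to_rhythm(baseline, 3.0)
        b = settle_to_rhythm(baseline, 3.0)
        assert a.status == b.status == "rhythmic"
        assert np.array_equal(a.state, b.state)
        assert a.frequency == b.frequency

    def test_settle_converges_at_hold_current(self, baseline):
        res = settle_to_rhythm(baseline, 3.0)
        assert res.rhythmic
        assert res.isi_cv < 0.01
        assert res.frequency > 0

    def test_far_subthreshold_current_reports_quiescent(self, baseline):
        res = settle_to_rhythm(baseline, 0.2, max_time=1000.0)
        assert res.status == "quiescent"
        assert res.frequency == 0.0

    def test_cat_with_zero_conductance_is_bit_identical_to_no_cat(self, baseline):
        from tburst.model import make_zero_cat

        p0 = baseline
        p1 = default_neuron(make_zero_cat())
        prot0 = Protocol(segments=(Segment(3.0, 300.0),), dt=0.02, v_init=-65.0)
        tr0 = integrate(p0, prot0)
        tr1 = integrate(p1, prot0)
        assert np.array_equal(tr0.v, tr1.v)
        for name in tr0.gates:
            assert np.array_equal(tr0.gates[name], tr1.gates[name])
        assert np.all(tr1.i_cat == 0.0)

    def test_settle_init_starts_protocol_in_established_rhythm(self, baseline):
        prot = Protocol(segments=(Segment(3.0, 100.0),), dt=0.02, init="settle")
        tr = integrate(baseline, prot)
        from tburst.spikes import detect_spikes

        train = detect_spikes(tr)
        # rhythm is already established: spikes from the start at ~40 Hz
        assert len(train) >= 3
        assert train.times[0] < 40.0

    def test_settle_init_rejected_for_voltage_clamp_segment(self, baseline):
        prot = Protocol(segments=(Segment(0.0, 10.0, v_clamp=-60.0),), init="settle")
        with pytest.raises(ValueError):
            integrate(baseline, prot)

    def test_baseline_f_i_curve_is_nondecreasing(self, baseline):
        fi = f_i_curve(baseline, [2.8, 3.0, 5.0, 8.0, 10.0])
        assert (fi["status"] == "rhythmic").all()
        freqs = fi["frequency_hz"].to_numpy()
        assert np.all(np.diff(freqs) >= 0)
        assert freqs[0] > 0
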