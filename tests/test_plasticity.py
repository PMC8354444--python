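"""Dopamine-gated plasticity rule: unit, oracle and property tests."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mbmeta import plasticity
from mbmeta.circuit import CircuitState, initial_state
from mbmeta.params import CircuitParameters
from mbmeta.plasticity import PlasticityConfig, pairing_curve, \
    plasticity_step, update_traces


def _tiny(n_mbon=1, n_dan=1):
    return CircuitParameters(n_mbon=n_mbon, n_dan=n_dan, n_fbn=1, n_kc=1)


def _blank_state(params, w=0.0):
    return CircuitState(
        r=np.zeros(params.n_total),
        w=np.full((params.n_mbon, params.n_kc), w),
        W_kc_mbon=np.full((params.n_mbon, params.n_kc), w),
        trace_kc=np.zeros(params.n_kc),
        trace_dan=np.zeros(params.n_dan))


def _run_pulses(cfg, params, state, kc_fn, dan_fn, t_end):
    """Drive plasticity_step/update_traces with scripted pulse trains."""
    n = int(round(t_end / cfg.dt))
    for k in range(n):
        t = k * cfg.dt
        kc = np.atleast_1d(np.asarray(kc_fn(t), dtype=float))
        dan = np.atleast_1d(np.asarray(dan_fn(t), dtype=float))
        state = plasticity_step(cfg, params, state, kc, dan)
        state = update_traces(cfg, state, kc, dan)
    return state


class TestTraces:
    def test_step_response_monotone_to_one(self):
        cfg = PlasticityConfig(dt=0.1)
        p = _tiny()
        s = _blank_state(p)
        prev = 0.0
        for _ in range(200):
            s = update_traces(cfg, s, np.ones(1), np.zeros(1))
            assert s.trace_kc[0] >= prev
            prev = s.trace_kc[0]
        assert abs(s.trace_kc[0] - 1.0) < 1e-6
        assert s.trace_dan[0] == 0.0

    def test_pulse_peak_matches_closed_form(self):
        cfg = PlasticityConfig(tau_elig_kc=1.5, dt=0.01)
        p = _tiny()
        s = _blank_state(p)
        for k in range(int(2.0 / cfg.dt)):
            s = update_traces(cfg, s, np.ones(1), np.zeros(1))
        expected = 1.0 - np.exp(-2.0 / cfg.tau_elig_kc)
        assert abs(s.trace_kc[0] - expected) < 0.01

    def test_rejects_negative_rates(self):
        cfg = PlasticityConfig()
        s = _blank_state(_tiny())
        with pytest.raises(ValueError):
            update_traces(cfg, s, np.array([-1.0]), np.zeros(1))


class TestPlasticityStep:
    def test_silent_network_no_change(self):
        cfg = PlasticityConfig()
        p = _tiny()
        s = _blank_state(p, w=0.02)
        s2 = plasticity_step(cfg, p, s, np.zeros(1), np.zeros(1))
        assert np.array_equal(s2.w, s.w)
        assert np.array_equal(s2.W_kc_mbon, s.W_kc_mbon)

    def test_dan_alone_potentiates_only_its_compartment(self):
        """Dopamine without KC activity potentiates (beta > 0), locally."""
        p = _tiny(n_mbon=2, n_dan=2)
        p.beta = np.array([0.05, 0.05])
        cfg = PlasticityConfig(dt=0.1)
        s = _blank_state(p, w=0.01)
        dan = lambda t: [1.0 if 1.0 <= t < 3.0 else 0.0, 0.0]
        s = _run_pulses(cfg, p, s, lambda t: [0.0], dan, 10.0)
        assert s.w[0, 0] > 0.01          # driven compartment potentiated
        assert s.w[1, 0] == 0.01         # other compartment untouched

    @pytest.mark.parametrize("kc_first,expected_sign", [(True, -1), (False, 1)])
    def test_pairing_order_sets_sign(self, kc_first, expected_sign):
        """KC-before-DAN pairings depress; DAN-before-KC potentiate."""
        p = _tiny()
        cfg = PlasticityConfig(clip=False, dt=0.01)
        first = lambda t: 1.0 if 0.0 <= t < 2.0 else 0.0
        second = lambda t: 1.0 if 3.0 <= t < 5.0 else 0.0
        kc_fn, dan_fn = (first, second) if kc_first else (second, first)
        s = _run_pulses(cfg, p, _blank_state(p), kc_fn, dan_fn, 12.0)
        assert np.sign(s.w[0, 0]) == expected_sign

    def test_simultaneous_pulses_match_closed_form(self):
        """Square-pulse pairing at lag 0 with unequal trace constants has a
        piecewise-exponential closed form for the integrated dw."""
        tk, td, A, d = 1.0, 2.0, 1.0, 2.0
        p = _tiny()
        cfg = PlasticityConfig(tau_elig_kc=tk, tau_elig_dan=td, clip=False,
                               dt=0.01)
        pulse = lambda t: A if 0.0 <= t < d else 0.0
        s = _run_pulses(cfg, p, _blank_state(p), pulse, pulse, d + 0.1)
        # integral of A^2[(1-e^(-t/td)) - (1-e^(-t/tk))] over the pulse
        expected = A ** 2 * (tk * (1 - np.exp(-d / tk))
                             - td * (1 - np.exp(-d / td)))
        assert abs(s.w[0, 0] - expected) / abs(expected) < 0.02

    def test_effective_weight_relaxes_with_tau_w(self):
        """After a step change of w, W decays toward w with tau_W = 5 s."""
        p = _tiny()
        cfg = PlasticityConfig(dt=0.01)
        s = _blank_state(p)
        s.W_kc_mbon[:] = 0.05
        t_end = 5.0
        s = _run_pulses(cfg, p, s, lambda t: 0.0, lambda t: 0.0, t_end)
        assert abs(s.W_kc_mbon[0, 0] - 0.05 * np.exp(-t_end / 5.0)) < 5e-4


class TestPairingCurve:
    cfg = PlasticityConfig()
    lags = np.array([-8.0, -4.0, -1.0, 1.0, 4.0, 8.0, -30.0, 30.0])

    def test_biphasic_and_vanishing(self):
        dw = pairing_curve(self.cfg, self.lags, dt=0.05)
        assert np.all(dw[self.lags > 0] < 0)    # forward pairing: depression
        assert np.all(dw[self.lags < 0] > 0)    # backward pairing: potentiation
        peak = np.abs(dw).max()
        far = np.abs(dw[np.abs(self.lags) >= 30.0])
        assert np.all(far < 0.01 * peak)

    def test_window_scales_with_trace_constant(self):
        """Doubling the eligibility time constants doubles the e-folding
        lag of the depression lobe's tail (within 10%): beyond pulse
        overlap the curve decays as exp(-lag/tau)."""
        def tail_tau(tau):
            lags = np.array([6.0, 6.0 + tau])
            dw = pairing_curve(PlasticityConfig(tau_elig_kc=tau,
                                                tau_elig_dan=tau),
                               lags, dt=0.02)
            return tau / np.log(abs(dw[0]) / abs(dw[1]))

        assert abs(tail_tau(1.0) - 1.0) < 0.1
        assert abs(tail_tau(2.0) / tail_tau(1.0) - 2.0) < 0.2

    def test_antisymmetry_under_train_swap(self):
        """Swapping the KC and DAN pulse trains negates the integrated dw
        for matched trace constants (beta = 0)."""
        dw_fwd = pairing_curve(self.cfg, np.array([2.5]), dt=0.02)
        dw_bwd = pairing_curve(self.cfg, np.array([-2.5]), dt=0.02)
        assert abs(dw_fwd[0] + dw_bwd[0]) < 1e-10


@settings(max_examples=15, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_weights_bounded_for_arbitrary_rates(seed):
    """With clipping on, w and W stay inside [0, w_max] for any inputs."""
    rng = np.random.default_rng(seed)
    p = _tiny(n_mbon=2, n_dan=2)
    cfg = PlasticityConfig(dt=0.5)
    s = initial_state(p)
    for _ in range(60):
        kc = rng.uniform(0, 5, p.n_kc)
        dan = rng.uniform(0, 5, p.n_dan)
        s = plasticity_step(cfg, p, s, kc, dan)
        s = update_traces(cfg, s, kc, dan)
        assert np.all(s.w >= 0.0) and np.all(s.w <= cfg.w_max + 1e-12)
        assert np.all(s.W_kc_mbon >= 0.0)
        assert np.all(s.W_kc_mbon <= cfg.w_max + 1e-12)


def test_compartment_locality_with_block_map():
    """With a 2-compartment block map, DAN drive mapped to compartment 0
    never moves weights of compartment-1 MBONs."""
    p = CircuitParameters(n_mbon=4, n_dan=4, n_fbn=2, n_kc=3,
                          mbon_compartment=np.array([0, 0, 1, 1]),
                          dan_compartment=np.array([0, 0, 1, 1]))
    cfg = PlasticityConfig(dt=0.1)
    s = _blank_state(p, w=0.02)
    kc = lambda t: np.full(3, 1.0 if 0 <= t < 2 else 0.0)
    dan = lambda t: np.array([1.0, 1.0, 0.0, 0.0]) * (1.0 if 1 <= t < 3 else 0.0)
    s = _run_pulses(cfg, p, s, kc, dan, 8.0)
    assert np.any(s.w[:2] != 0.02)
    assert np.all(s.w[2:] == 0.02)
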