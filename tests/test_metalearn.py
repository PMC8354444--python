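"""Meta-learning machinery: losses, initialization, unroll/BPTT, training
plumbing and the error metric."""

import numpy as np
import pytest

import mbmeta
from mbmeta import circuit, plasticity
from mbmeta.metalearn import (LossConfig, TaskMix, TrainConfig,
                              evaluate_error_rate, initialize_parameters,
                              loss_and_grads, train, trial_loss, unroll)
from mbmeta.params import dan_mbon_mask, recurrence_mask
from mbmeta.plasticity import PlasticityConfig
from mbmeta.tasks import make_conditioning_trial, render_trial


class TestTrialLoss:
    def test_perfect_tracking_zero_loss(self):
        cfg = LossConfig()
        T = 40
        out = {"readout": np.ones((T, 1)), "r_dan": np.full((T, 20), 0.1)}
        tgt = {"readout": np.ones((T, 1))}
        assert trial_loss(cfg, out, tgt) == 0.0

    def test_dan_penalty_closed_form(self):
        """Constant DAN rate 0.2 across 20 DANs with lambda = 0.1 adds
        0.1 * 20 * (0.1)^2 = 0.02 to the loss."""
        cfg = LossConfig()
        T = 7
        out = {"readout": np.zeros((T, 1)), "r_dan": np.full((T, 20), 0.2)}
        tgt = {"readout": np.zeros((T, 1))}
        assert trial_loss(cfg, out, tgt) == pytest.approx(0.02)

    def test_navigation_loss_is_squared_distance(self):
        cfg = LossConfig(loss_kind="navigation")
        out = {"final_position": np.array([1.0, 2.0])}
        assert trial_loss(cfg, out, {"position": np.array([1.0, 2.0])}) == 0.0
        assert trial_loss(cfg, out, {"position": np.array([0.0, 0.0])}) == \
            pytest.approx(5.0)

    def test_engine_loss_matches_reference_formula(self, tiny_params, rng):
        """The batched engine computes the same per-trial loss as the
        plain formula applied to its recorded outputs."""
        opts = mbmeta.ConditioningOptions(n_kc=tiny_params.n_kc)
        tr = make_conditioning_trial("first_order", rng, opts)
        rt = render_trial(tr, tiny_params.n_kc)
        cfg = LossConfig()
        loss, parts, grads, rec = loss_and_grads(
            tiny_params, rt.kc[:, None], rt.ext[:, None], rt.resets,
            rt.target[:, None], loss_cfg=cfg, dtype=np.float64)
        out = {"readout": rec.readout[:, 0],
               "r_dan": rec.r[1:, 0, tiny_params.dan_slice]}
        ref = trial_loss(cfg, out, {"readout": rt.target})
        assert loss == pytest.approx(ref, rel=1e-10)


class TestInitialization:
    def test_variances_keyed_to_presynaptic_type(self):
        rng = np.random.default_rng(0)
        draws = [initialize_parameters(rng) for _ in range(40)]
        W = np.stack([p.W_recur for p in draws])
        mask = np.stack([dan_mbon_mask(p) for p in draws])
        from_mbon = W[:, :, :20][mask[:, :, :20]]
        from_dan = W[:, :, 20:40][mask[:, :, 20:40]]
        from_fbn = W[:, :, 40:][mask[:, :, 40:]]
        assert from_mbon.var() == pytest.approx(1 / 40, rel=0.05)
        assert from_dan.var() == pytest.approx(1 / 40, rel=0.05)
        assert from_fbn.var() == pytest.approx(1 / 120, rel=0.05)
        ro = np.stack([p.W_readout for p in draws])
        assert ro.var() == pytest.approx(1 / 20, rel=0.2)
        ex = np.stack([p.W_ext for p in draws])
        assert ex.var() == pytest.approx(1.0, rel=0.1)

    def test_structural_zeros_and_biases(self):
        p = initialize_parameters(np.random.default_rng(1))
        assert np.all(p.W_recur[p.mbon_slice, p.dan_slice] == 0.0)
        assert np.all(p.b == 0.1)

    def test_feedforward_mask_leaves_no_loops(self):
        p = initialize_parameters(np.random.default_rng(2),
                                  recurrence="feedforward")
        m = recurrence_mask(p, "feedforward")
        assert np.all(p.W_recur[~m] == 0.0)
        # FBNs feed DANs and MBONs but receive nothing: no cycles
        assert np.any(p.W_recur[p.dan_slice, p.fbn_slice] != 0.0)
        assert np.all(p.W_recur[p.fbn_slice, :] == 0.0)
        assert np.all(p.W_recur[:, p.mbon_slice] == 0.0)
        assert np.all(p.W_recur[:, p.dan_slice] == 0.0)


class TestUnroll:
    def test_matches_reference_simulator(self, tiny_params, rng):
        """The batched numba engine reproduces the step-by-step reference
        operations (circuit.step + plasticity ops) exactly."""
        p = tiny_params
        opts = mbmeta.ConditioningOptions(n_kc=p.n_kc)
        tr = make_conditioning_trial("extinction", rng, opts)
        rt = render_trial(tr, p.n_kc)
        pcfg = PlasticityConfig(w_max=p.w_max, dt=p.dt)
        state = circuit.initial_state(p)
        for n in range(rt.n_steps):
            if rt.resets[n]:
                state = circuit.reset_rates(p, state)
            state = circuit.step(p, state, rt.kc[n], rt.ext[n])
            dan = state.r[p.dan_slice]
            state = plasticity.plasticity_step(pcfg, p, state, rt.kc[n], dan)
            state = plasticity.update_traces(pcfg, state, rt.kc[n], dan)
        res = unroll(p, tr)
        assert np.allclose(res.rates[-1], state.r, atol=1e-10)
        assert np.allclose(res.final_state.w, state.w, atol=1e-12)
        assert np.allclose(res.final_state.W_kc_mbon, state.W_kc_mbon,
                           atol=1e-12)
        assert np.allclose(res.final_state.trace_dan, state.trace_dan,
                           atol=1e-12)

    def test_plasticity_off_freezes_weights(self, tiny_params, rng):
        opts = mbmeta.ConditioningOptions(n_kc=tiny_params.n_kc)
        tr = make_conditioning_trial("first_order", rng, opts)
        res = unroll(tiny_params, tr, plasticity_on=False)
        assert np.all(res.final_state.W_kc_mbon == tiny_params.w_max)
        assert np.all(res.final_state.w == tiny_params.w_max)

    def test_bit_identical_repetition(self, tiny_params, rng):
        opts = mbmeta.ConditioningOptions(n_kc=tiny_params.n_kc)
        tr = make_conditioning_trial("second_order", rng, opts)
        a = unroll(tiny_params, tr)
        b = unroll(tiny_params, tr)
        assert np.array_equal(a.rates, b.rates)
        assert np.array_equal(a.readout, b.readout)


class TestGradients:
    def test_bptt_matches_finite_differences(self):
        """Analytic BPTT gradients through the full plastic unroll agree
        with central finite differences to better than 1%."""
        rng = np.random.default_rng(7)
        p = initialize_parameters(rng, n_mbon=4, n_dan=4, n_fbn=8, n_kc=12)
        p.W_recur *= 0.5
        opts = mbmeta.ConditioningOptions(n_kc=12)
        tr = make_conditioning_trial("first_order", rng, opts)
        rt = render_trial(tr, 12)
        kc, ext, tg = rt.kc[:, None], rt.ext[:, None], rt.target[:, None]
        cfg = LossConfig()

        def loss_fn():
            l, _, g, _ = loss_and_grads(p, kc, ext, rt.resets, tg,
                                        loss_cfg=cfg, dtype=np.float64)
            return l, g

        _, grads = loss_fn()
        eps = 1e-5
        mask = dan_mbon_mask(p)
        checked = 0
        rs = np.random.default_rng(0)
        for name in ("W_recur", "b", "W_ext", "W_readout"):
            arr = getattr(p, name)
            for _ in range(4):
                ix = tuple(rs.integers(0, s) for s in arr.shape)
                if name == "W_recur" and not mask[ix]:
                    continue
                old = arr[ix]
                arr[ix] = old + eps
                lp, _ = loss_fn()
                arr[ix] = old - eps
                lm, _ = loss_fn()
                arr[ix] = old
                fd = (lp - lm) / (2 * eps)
                an = grads[name][ix]
                if max(abs(fd), abs(an)) < 1e-8:
                    continue
                assert abs(fd - an) / max(abs(fd), abs(an)) < 0.01, \
                    f"{name}{ix}: fd={fd} analytic={an}"
                checked += 1
        assert checked >= 8


class TestTraining:
    def test_zero_learning_rate_leaves_parameters(self):
        mix = TaskMix(kind="conditioning")
        cfg = TrainConfig(batch_size=2, n_epochs=3, learning_rate=0.0,
                          n_mbon=4, n_dan=4, n_fbn=8, n_kc=20)
        rec = train(mix, cfg, seed=3)
        fresh = train(mix, TrainConfig(batch_size=2, n_epochs=1,
                                       learning_rate=0.0, n_mbon=4, n_dan=4,
                                       n_fbn=8, n_kc=20), seed=3)
        assert np.array_equal(rec.params.W_recur, fresh.params.W_recur)
        assert np.array_equal(rec.params.b, fresh.params.b)

    def test_training_is_deterministic_given_seed(self):
        mix = TaskMix(kind="conditioning")
        cfg = TrainConfig(batch_size=2, n_epochs=4, n_mbon=4, n_dan=4,
                          n_fbn=8, n_kc=20)
        a = train(mix, cfg, seed=5)
        b = train(mix, cfg, seed=5)
        assert np.array_equal(a.loss_history, b.loss_history)
        assert np.array_equal(a.params.W_recur, b.params.W_recur)

    def test_feedforward_mode_keeps_mask_through_training(self):
        mix = TaskMix(kind="conditioning")
        cfg = TrainConfig(batch_size=2, n_epochs=4, recurrence="feedforward",
                          n_mbon=4, n_dan=4, n_fbn=8, n_kc=20)
        rec = train(mix, cfg, seed=6)
        m = recurrence_mask(rec.params, "feedforward")
        assert np.all(rec.params.W_recur[~m] == 0.0)
        assert np.any(rec.params.W_recur[m] != 0.0)

    def test_continual_carryover_fraction_schedule(self):
        mix = TaskMix(kind="continual")
        cfg = TrainConfig(batch_size=2, n_epochs=6, carryover_anneal_epochs=4,
                          n_mbon=4, n_dan=4, n_fbn=8, n_kc=20)
        rec = train(mix, cfg, seed=7)
        chi = rec.schedules["carryover_fraction"]
        assert chi[0] == 0.0 and chi[-1] == 1.0
        assert np.all(np.diff(chi) >= 0.0)
        assert rec.params.beta is not None
        assert np.all(rec.params.beta >= 0.0)


class TestErrorMetric:
    def test_silent_readout_counts_target_trials(self):
        """With W_readout = 0 the readout is identically 0: every trial
        whose target is nonzero errors, and none of the unreinforced
        (CS-) trials do."""
        p = initialize_parameters(np.random.default_rng(0), n_mbon=4,
                                  n_dan=4, n_fbn=8, n_kc=20)
        p.W_readout[:] = 0.0
        res = evaluate_error_rate(p, "first_order", 20, rng=1)
        assert res["error_rate"] == 1.0
        res = evaluate_error_rate(p, "cs_minus", 20, rng=1)
        assert res["error_rate"] == 0.0

    def test_empty_evaluation_flagged(self, tiny_params):
        res = evaluate_error_rate(tiny_params, "first_order", 0, rng=1)
        assert np.isnan(res["error_rate"])

    def test_untrained_network_fails_first_order(self, default_params):
        res = evaluate_error_rate(default_params, "first_order", 20, rng=2)
        assert res["error_rate"] > 0.5
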