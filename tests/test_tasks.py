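"""Trial-generator tests: odor codes, paradigm schedules, targets,
rendering."""

import numpy as np
import pytest

from mbmeta import tasks
from mbmeta.tasks import (ConditioningOptions, Trial, encode_odor,
                          make_conditioning_trial, make_continual_sequence,
                          make_nonplastic_env_trial, make_state_trial,
                          make_training_trial, render_trial)


@pytest.fixture
def opts():
    return ConditioningOptions(n_kc=200)


class TestEncodeOdor:
    def test_exact_sparsity(self, rng):
        pat = encode_odor(200, 0.1, rng)
        assert pat.sum() == 20 and set(np.unique(pat)) <= {0.0, 1.0}

    def test_deterministic_given_seed(self):
        a = encode_odor(100, 0.1, np.random.default_rng(5))
        b = encode_odor(100, 0.1, np.random.default_rng(5))
        assert np.array_equal(a, b)

    def test_mean_overlap_matches_hypergeometric(self, rng):
        """Two independent 10% codes on 200 KCs share 2 cells on average."""
        overlaps = [encode_odor(200, 0.1, rng) @ encode_odor(200, 0.1, rng)
                    for _ in range(3000)]
        assert abs(np.mean(overlaps) - 2.0) < 0.15

    def test_rejects_degenerate_sparsity(self, rng):
        with pytest.raises(ValueError):
            encode_odor(4, 0.05, rng)


class TestConditioningTrials:
    def test_onsets_within_stated_window(self, rng, opts):
        for _ in range(200):
            tr = make_conditioning_trial("first_order", rng, opts)
            for iv in tr.intervals:
                for ev in iv.events:
                    if ev.kind == "CS":
                        assert 5.0 <= ev.onset <= 15.0

    def test_us_omission_zeroes_targets(self, rng, opts):
        tr = make_conditioning_trial("first_order", rng, opts, omission="us")
        rt = render_trial(tr, 200)
        assert np.all(rt.target == 0.0)
        assert np.all(rt.ext == 0.0)

    def test_extinction_target_partially_reduced(self, rng, opts):
        tr = make_conditioning_trial("extinction", rng, opts)
        rt = render_trial(tr, 200)
        mid = np.abs(rt.target[(rt.t >= 30) & (rt.t < 60), 0]).max()
        test = np.abs(rt.target[rt.test_mask, 0]).max()
        assert mid == 1.0
        assert test == pytest.approx(opts.extinction_residual * 1.0)

    def test_extinction_middle_omission_is_first_order(self, rng, opts):
        tr = make_conditioning_trial("extinction", rng, opts,
                                     omission="middle")
        rt = render_trial(tr, 200)
        assert np.abs(rt.target[rt.test_mask, 0]).max() == 1.0
        assert np.all(rt.kc[(rt.t >= 30) & (rt.t < 60)] == 0.0)

    def test_second_order_transfers_valence(self, rng, opts):
        tr = make_conditioning_trial("second_order", rng, opts)
        sign = tr.meta["us_sign"]
        rt = render_trial(tr, 200)
        assert np.abs(rt.target[rt.test_mask, 0]).max() == 1.0
        assert np.sign(rt.target[rt.test_mask, 0]).max() == np.sign(sign) or \
            np.sign(rt.target[rt.test_mask, 0]).min() == np.sign(sign)
        # two distinct odors in play
        assert len(tr.kc_patterns) == 2

    def test_training_mixture_draws_both_families(self, rng, opts):
        paradigms = {make_training_trial(rng, opts).paradigm
                     for _ in range(50)}
        assert paradigms == {"extinction", "second_order"}

    def test_novelty_marks_first_presentation_only(self, rng, opts):
        tr = make_conditioning_trial("first_order", rng, opts)
        rt = render_trial(tr, 200, include_novelty=True)
        cs_steps = rt.kc.sum(axis=1) > 0
        first_window = rt.t < 30.0
        assert np.all(rt.target[cs_steps & first_window, 1] == 1.0)
        assert np.all(rt.target[cs_steps & ~first_window, 1] == 0.0)


class TestContinual:
    def test_presentation_counts_poisson_mean_two(self, opts):
        rng = np.random.default_rng(0)
        counts = []
        for _ in range(400):
            tr = make_continual_sequence(rng, opts)
            counts.extend(tr.meta["counts"])
        assert abs(np.mean(counts) - 2.0) < 0.1

    def test_cs_minus_targets_zero_and_plus_follow_pairings(self, opts):
        rng = np.random.default_rng(1)
        for _ in range(50):
            tr = make_continual_sequence(rng, opts)
            events = sorted(((on, ev) for on, ev in tr.absolute_events()),
                            key=lambda p: p[0])
            last = {}
            for on, ev in events:
                if ev.kind == "CS":
                    if ev.odor_id >= opts.n_cs_plus:
                        assert ev.target_valence == 0.0
                    else:
                        assert ev.target_valence == last.get(ev.odor_id, 0.0)
                elif ev.kind == "US":
                    # US follows the immediately preceding CS+
                    cs_events = [e for o, e in events
                                 if e.kind == "CS" and o < on]
                    last[cs_events[-1].odor_id] = ev.valence

    def test_no_overlapping_stimulus_windows(self, opts):
        rng = np.random.default_rng(2)
        for _ in range(30):
            tr = make_continual_sequence(rng, opts)
            spans = sorted((on, on + ev.duration)
                           for on, ev in tr.absolute_events())
            for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
                assert a1 <= b0 + 1e-9


class TestStateTrials:
    def test_gap_distribution(self, opts):
        rng = np.random.default_rng(3)
        gaps = []
        for _ in range(300):
            tr = make_state_trial(rng, opts)
            times = [0.0] + [t for t, _ in tr.meta["transitions"]]
            gaps.extend(np.diff(times))
        gaps = np.asarray(gaps)
        assert gaps.min() >= 10.0
        assert abs(gaps.mean() - 20.0) < 1.0

    def test_target_state_one_hot_and_pulses_sparse(self, rng, opts):
        tr = make_state_trial(rng, opts)
        rt = render_trial(tr, 200)
        assert rt.target_state is not None
        assert np.all(rt.target_state.sum(axis=1) == 1.0)
        pulse_channels = rt.ext[:, 2:]
        active = pulse_channels.sum(axis=0)
        # each pulse spans 2 s = 4 steps on one channel
        assert pulse_channels.max() == 1.0
        n_pulses = len(tr.meta["transitions"])
        assert pulse_channels.sum() == pytest.approx(4 * n_pulses)

    def test_probe_trial_placement(self, opts):
        rng = np.random.default_rng(4)
        tr = make_state_trial(rng, opts, probe=True)
        t2, s2 = tr.meta["transitions"][1]
        cs = [ev for _, ev in tr.absolute_events() if ev.kind == "CS"]
        onsets = sorted(ev.onset for ev in cs)
        assert onsets[0] == pytest.approx(t2 - 8.0)
        assert tr.meta["probe_state"] == s2


class TestNonplasticEnv:
    def test_probe_identity_split_and_targets(self, opts):
        rng = np.random.default_rng(5)
        bank = [encode_odor(200, 0.1, rng) for _ in range(6)]
        same = []
        for _ in range(600):
            tr = make_nonplastic_env_trial(bank, rng, opts)
            same.append(tr.meta["probe_is_cs"])
            rt = render_trial(tr, 200)
            probe_target = rt.target[rt.test_mask, 0]
            if tr.meta["probe_is_cs"]:
                assert np.abs(probe_target).max() == 1.0
            else:
                assert np.all(probe_target == 0.0)
        assert abs(np.mean(same) - 0.5) < 0.07

    def test_fixed_timing(self, rng, opts):
        bank = [encode_odor(200, 0.1, rng) for _ in range(3)]
        tr = make_nonplastic_env_trial(bank, rng, opts)
        cs_onsets = sorted(ev.onset for _, ev in tr.absolute_events()
                           if ev.kind == "CS")
        assert cs_onsets == [5.0, 15.0]


class TestRendering:
    def test_deterministic_and_json_round_trip(self, rng, opts):
        tr = make_conditioning_trial("second_order", rng, opts)
        r1 = render_trial(tr, 200)
        r2 = render_trial(Trial.from_json(tr.to_json()), 200)
        for name in ("kc", "ext", "target", "resets", "test_mask"):
            assert np.array_equal(getattr(r1, name), getattr(r2, name))

    def test_resets_at_interval_boundaries(self, rng, opts):
        tr = make_conditioning_trial("extinction", rng, opts)
        rt = render_trial(tr, 200)
        assert list(np.flatnonzero(rt.resets)) == [0, 60, 120]

    def test_batch_requires_same_structure(self, rng, opts):
        a = make_conditioning_trial("first_order", rng, opts)
        b = make_conditioning_trial("extinction", rng, opts)
        with pytest.raises(ValueError):
            tasks.render_batch([a, b], 200)
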