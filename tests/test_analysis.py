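"""Population-analysis tests on planted synthetic constructions."""

import numpy as np
import pytest

from mbmeta import analysis as ana
from mbmeta.analysis import ResponseTensor


def _tensor(act, dt=0.5):
    return ResponseTensor(activity=np.asarray(act, dtype=float), dt=dt)


class TestClustering:
    def test_identical_neurons_merge_first(self, rng):
        base = rng.uniform(0, 1, (1, 30, 2))
        act = np.concatenate([base, base, rng.uniform(0, 1, (2, 30, 2))])
        res = ana.cluster_dan_responses(_tensor(act))
        assert set(res["linkage"][0, :2].astype(int)) == {0, 1}
        assert res["linkage"][0, 2] == 0.0

    def test_planted_two_group_split(self, rng):
        """US+ vs US- tuned groups separated far beyond noise are
        recovered by the top split."""
        t = np.linspace(0, 1, 40)
        a = np.sin(2 * np.pi * t) * 5
        b = -a
        act = np.stack([a + rng.normal(0, .1, 40) for _ in range(4)]
                       + [b + rng.normal(0, .1, 40) for _ in range(4)])
        res = ana.cluster_dan_responses(_tensor(act[:, :, None]))
        from scipy.cluster.hierarchy import fcluster
        groups = fcluster(res["linkage"], 2, criterion="maxclust")
        assert len(set(groups[:4])) == 1
        assert len(set(groups[4:])) == 1
        assert groups[0] != groups[4]

    def test_permutation_consistency(self, rng):
        """Relabeling neurons permutes the dendrogram consistently: the
        cophenetic distances between the same neuron pairs are unchanged."""
        from scipy.cluster.hierarchy import cophenet
        from scipy.spatial.distance import squareform
        act = rng.uniform(0, 1, (5, 20, 3))
        perm = np.array([3, 0, 4, 1, 2])
        d1 = squareform(cophenet(ana.cluster_dan_responses(
            _tensor(act))["linkage"]))
        d2 = squareform(cophenet(ana.cluster_dan_responses(
            _tensor(act[perm]))["linkage"]))
        assert np.allclose(d1[np.ix_(perm, perm)], d2)


class TestPCA:
    def test_rank_one_activity(self, rng):
        time_course = rng.normal(size=60)
        loadings = rng.normal(size=6)
        act = np.einsum("n,t->nt", loadings, time_course).reshape(6, 60, 1)
        res = ana.pca_dan_responses(_tensor(act), n_components=3)
        assert res["variance_ratio"][0] > 0.999

    def test_planted_prediction_error_mode(self, rng):
        """A dominant mode loading US+ and omission responses with
        opposite signs is recovered as PC1 up to sign."""
        n, T = 8, 50
        mode = rng.normal(size=n)
        mode /= np.linalg.norm(mode)
        us = np.zeros(T); us[10:14] = 3.0
        om = np.zeros(T); om[30:34] = -3.0
        act = (np.einsum("n,t->nt", mode, us + om)
               + rng.normal(0, 0.05, (n, T)))
        res = ana.pca_dan_responses(_tensor(act[:, :, None]), n_components=2)
        c = res["components"][0]
        assert abs(np.dot(c, mode)) > 0.99
        proj = res["projections"][0, :, 0]
        assert np.sign(proj[10:14].mean()) != np.sign(proj[30:34].mean())

    def test_variance_fractions_monotone(self, rng):
        act = rng.normal(size=(6, 40, 3))
        res = ana.pca_dan_responses(_tensor(act), n_components=5)
        vr = res["variance_ratio"]
        assert vr.sum() <= 1.0 + 1e-9
        assert np.all(np.diff(vr) <= 1e-12)


class TestResponseCorrelation:
    def test_identical_and_orthogonal(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = ana.response_correlation_matrix(np.stack([a, a]))
        assert res["corr"][0, 1] == pytest.approx(1.0)
        b = np.array([1.0, -1.0, 1.0, -1.0])
        c = np.array([1.0, 1.0, -1.0, -1.0])
        res = ana.response_correlation_matrix(np.stack([b, c]))
        assert res["corr"][0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_planted_blocks_visible(self, rng):
        protos = [rng.normal(size=12) * 3 for _ in range(3)]
        resp, groups = [], []
        for g in range(3):
            for _ in range(5):
                resp.append(protos[g] + rng.normal(0, 0.5, 12))
                groups.append(g)
        res = ana.response_correlation_matrix(np.stack(resp),
                                              np.array(groups))
        corr, grp = res["corr"], res["grouping"]
        same = grp[:, None] == grp[None, :]
        off = ~np.eye(15, dtype=bool)
        assert corr[same & off].mean() > corr[~same].mean()

    def test_degenerate_rows_flagged(self):
        resp = np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0]])
        res = ana.response_correlation_matrix(resp)
        assert res["degenerate"][0]
        assert np.isnan(res["corr"][0, 1])


class TestWeightSummary:
    def test_point_masses(self):
        res = ana.weight_summary(np.full((5, 6), 0.05))
        assert res["mean"] == 1.0
        assert res["hist"][-1] > 0 and res["hist"][:-1].sum() == 0
        res = ana.weight_summary(np.zeros((5, 6)))
        assert res["mean"] == 0.0

    def test_uniform_moment(self, rng):
        W = rng.uniform(0, 0.05, size=20000)
        res = ana.weight_summary(W)
        assert res["mean"] == pytest.approx(0.5, abs=0.02)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            ana.weight_summary(np.array([0.06]))


class TestXcorr:
    def test_zero_velocity(self, rng):
        res = ana.dan_velocity_xcorr(rng.uniform(0, 1, (3, 50)),
                                     np.zeros(50), max_lag=5)
        assert np.all(res["xcorr"] == 0.0)

    def test_autocorrelation_peaks_at_zero(self, rng):
        x = rng.normal(size=400)
        res = ana.dan_velocity_xcorr(x[None], x, max_lag=10)
        assert np.argmax(res["xcorr"][0]) == 10  # lag 0

    def test_shift_moves_peak(self, rng):
        x = rng.normal(size=400)
        k = 4
        u = np.roll(x, -k)  # u(t) = x(t + k)
        res = ana.dan_velocity_xcorr(x[None], u, max_lag=10)
        lags = res["lags_s"]
        # E[x(t) u(t + tau)] peaks where t + tau - k aligns: tau = -k... the
        # peak of E[d(t)u(t+tau)] sits at tau = -k steps
        assert lags[np.argmax(res["xcorr"][0])] == pytest.approx(-k * 0.5)

    def test_rejects_short_series(self, rng):
        with pytest.raises(ValueError):
            ana.dan_velocity_xcorr(np.ones((1, 5)), np.ones(5), max_lag=8)


class TestValenceVsUS:
    def test_untrained_symmetric_network_uncorrelated(self):
        """Across fresh initializations the readout-weight / US-tuning
        correlation has no systematic sign."""
        import mbmeta
        corrs = []
        for seed in range(8):
            p = mbmeta.initialize_parameters(np.random.default_rng(seed),
                                             n_mbon=8, n_dan=8, n_fbn=16,
                                             n_kc=20)
            p.W_recur *= 0.3
            corrs.append(ana.valence_vs_us_response(p)["correlation"])
        assert abs(np.mean(corrs)) < 0.5

    def test_planted_anticorrelation_recovered(self, rng):
        """Synthetic per-compartment pairs with correlation -0.9 are
        recovered by the same Pearson machinery."""
        from scipy.stats import pearsonr
        n = 200
        x = rng.normal(size=n)
        y = -0.9 * x + np.sqrt(1 - 0.81) * rng.normal(size=n)
        r, _ = pearsonr(x, y)
        assert r == pytest.approx(-0.9, abs=0.06)
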