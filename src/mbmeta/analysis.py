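"""Population analyses of simulated activity.

Pure functions of recorded activity: hierarchical clustering and PCA of
dopamine-neuron responses, MBON response-correlation structure, synaptic
weight-distribution summaries, DAN-velocity cross-correlations during
navigation, and the relation between compartment readout weights and DAN
US-valence tuning.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import pearsonr
from sklearn.decomposition import PCA

from .metalearn.engine import forward_batch
from .params import CircuitParameters
from .tasks import Trial, render_batch

__all__ = [
    "ResponseTensor",
    "record_responses",
    "cluster_dan_responses",
    "pca_dan_responses",
    "response_correlation_matrix",
    "weight_summary",
    "dan_velocity_xcorr",
    "valence_vs_us_response",
]


@dataclass
class ResponseTensor:
    """Recorded activity: neurons x timesteps x trials plus per-trial
    metadata."""

    activity: np.ndarray                 # (n_neurons, T, n_trials)
    labels: list = field(default_factory=list)
    dt: float = 0.5

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.activity)):
            raise ValueError("activity must be finite")
        if self.labels and len(self.labels) != self.activity.shape[2]:
            raise ValueError("labels must align with trials")

    def save(self, path) -> None:
        """Write the tensor (and JSON-encoded labels) to an .npz archive."""
        import json

        np.savez(path, activity=self.activity, dt=self.dt,
                 labels=json.dumps(self.labels))

    @classmethod
    def load(cls, path) -> "ResponseTensor":
        import json

        with np.load(path, allow_pickle=False) as arc:
            return cls(activity=arc["activity"], dt=float(arc["dt"]),
                       labels=json.loads(str(arc["labels"])))


def record_responses(params: CircuitParameters, trials: list[Trial],
                     population: str = "dan", plasticity_on: bool = True,
                     pcfg=None) -> ResponseTensor:
    """Simulate trials and collect one population's rate histories."""
    kc, ext, _, _, resets, _ = render_batch(
        trials, params.n_kc, params.dt,
        include_novelty=params.d_readout == 2)
    rec = forward_batch(params, kc, ext, resets, plasticity_on=plasticity_on,
                        pcfg=pcfg, dtype=np.float64)
    sl = {"mbon": params.mbon_slice, "dan": params.dan_slice,
          "fbn": params.fbn_slice, "all": slice(None)}[population]
    act = np.transpose(rec.r[1:, :, sl], (2, 0, 1))
    labels = [{"paradigm": tr.paradigm, **tr.meta} for tr in trials]
    return ResponseTensor(activity=np.ascontiguousarray(act), labels=labels,
                          dt=params.dt)


def cluster_dan_responses(tensor: ResponseTensor,
                          method: str = "average") -> dict:
    """Agglomerative clustering of neurons on the Euclidean distance
    between their concatenated rate vectors; returns the dendrogram
    (scipy linkage matrix) and the leaf order for heatmap display."""
    n = tensor.activity.shape[0]
    if n < 2:
        raise ValueError("need at least two neurons to cluster")
    X = tensor.activity.reshape(n, -1)
    Z = linkage(X, method=method, metric="euclidean")
    return {"order": leaves_list(Z), "linkage": Z}


def pca_dan_responses(tensor: ResponseTensor, n_components: int = 5) -> dict:
    """PCA of population activity, mean-centered per neuron (no variance
    scaling: rates share units).

    Returns the components (n_components x n_neurons), the per-trial time
    courses of their projections (n_components x T x n_trials) and the
    explained-variance fractions.
    """
    n, T, R = tensor.activity.shape
    if T * R < n_components:
        raise ValueError("not enough samples for the requested components")
    X = tensor.activity.reshape(n, -1).T          # samples x neurons
    pca = PCA(n_components=n_components)
    proj = pca.fit_transform(X)                   # samples x comps
    return {"components": pca.components_,
            "projections": proj.T.reshape(n_components, T, R),
            "variance_ratio": pca.explained_variance_ratio_,
            "mean": pca.mean_}


def response_correlation_matrix(responses: np.ndarray,
                                grouping: np.ndarray | None = None) -> dict:
    """Pearson correlations between time-averaged MBON response vectors.

    ``responses``: (n_stimuli, n_mbon).  ``grouping`` orders the rows (for
    the state task: the state transition following each stimulus's first
    presentation), exposing block structure.  Zero-variance rows yield
    NaN entries and are flagged.
    """
    responses = np.asarray(responses, dtype=float)
    if responses.shape[0] < 2:
        raise ValueError("need at least two stimuli")
    order = (np.argsort(grouping, kind="stable") if grouping is not None
             else np.arange(responses.shape[0]))
    R = responses[order]
    sd = R.std(axis=1)
    degenerate = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(R)
    corr[degenerate, :] = np.nan
    corr[:, degenerate] = np.nan
    return {"corr": corr, "order": order, "degenerate": degenerate,
            "grouping": None if grouping is None else
            np.asarray(grouping)[order]}


def weight_summary(W_kc_mbon: np.ndarray, w_max: float = 0.05,
                   bins: int = 20) -> dict:
    """Histogram (density over W/w_max in [0, 1]) and moments of the
    KC->MBON weights."""
    wn = np.asarray(W_kc_mbon, dtype=float).ravel() / w_max
    if wn.min() < -1e-9 or wn.max() > 1 + 1e-9:
        raise ValueError("weights outside [0, w_max]")
    hist, edges = np.histogram(np.clip(wn, 0.0, 1.0), bins=bins,
                               range=(0.0, 1.0), density=True)
    return {"hist": hist, "edges": edges, "mean": float(wn.mean()),
            "std": float(wn.std())}


def dan_velocity_xcorr(dan_activity: np.ndarray, velocity: np.ndarray,
                       max_lag: int, dt: float = 0.5) -> dict:
    """Lagged product expectation E[d(t) u(t + lag)] per dopamine neuron.

    Positive lags mean the velocity follows the dopamine activity.
    """
    dan = np.atleast_2d(np.asarray(dan_activity, dtype=float))
    u = np.asarray(velocity, dtype=float)
    T = u.size
    if dan.shape[1] != T:
        raise ValueError("series must be aligned")
    if max_lag >= T:
        raise ValueError("series shorter than max_lag")
    lags = np.arange(-max_lag, max_lag + 1)
    xc = np.empty((dan.shape[0], lags.size))
    for i, k in enumerate(lags):
        if k >= 0:
            xc[:, i] = (dan[:, :T - k] * u[k:]).mean(axis=1) if k else \
                (dan * u).mean(axis=1)
        else:
            xc[:, i] = (dan[:, -k:] * u[:T + k]).mean(axis=1)
    return {"lags_s": lags * dt, "xcorr": xc}


def valence_vs_us_response(params: CircuitParameters,
                           rng: np.random.Generator | int = 0,
                           us_onset: float = 10.0, us_duration: float = 2.0,
                           interval: float = 30.0, amplitude: float = 1.0,
                           pcfg=None) -> dict:
    """Per-compartment (readout weight, US+ - US- DAN response) pairs.

    Presents an isolated positive-valence and an isolated negative-valence
    US (no CS) and measures each DAN's mean evoked rate during the pulse
    relative to its pre-US baseline.  In trained conditioning networks the
    compartment readout weight anticorrelates with this valence
    difference (learning by depression: punishment-reporting compartments
    carry reward-tuned dopamine).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    dt = params.dt
    T = int(round(interval / dt))
    t = np.arange(T) * dt
    kc = np.zeros((T, 2, params.n_kc))
    ext = np.zeros((T, 2, params.d_ext))
    sel = (t >= us_onset) & (t < us_onset + us_duration)
    ext[sel, 0, 0] = amplitude
    ext[sel, 1, 1] = amplitude
    resets = np.zeros(T, dtype=bool)
    resets[0] = True
    rec = forward_batch(params, kc, ext, resets, plasticity_on=True,
                        pcfg=pcfg, dtype=np.float64)
    r_dan = rec.r[1:, :, params.dan_slice]
    base = (t < us_onset)
    resp = r_dan[sel].mean(axis=0) - r_dan[base].mean(axis=0)  # (2, n_dan)
    diff_per_dan = resp[0] - resp[1]

    n_c = params.n_compartments
    dan_diff = np.array([diff_per_dan[params.dan_compartment == c].mean()
                         for c in range(n_c)])
    readout_w = np.array([params.W_readout[0,
                                           params.mbon_compartment == c].sum()
                          for c in range(n_c)])
    r, p = pearsonr(readout_w, dan_diff)
    return {"readout_weight": readout_w, "us_response_diff": dan_diff,
            "correlation": float(r), "p_value": float(p)}
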