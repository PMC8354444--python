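"""The two-phase meta-learning procedure.

Phase one ("optimization", standing in for evolution and development):
circuit parameters are updated by RMSprop on batched task losses, with
gradients propagated through the full unrolled plastic dynamics.  Phase
two: parameters are frozen and the network is evaluated on fresh trials
where the only learning is the dopamine-gated plasticity itself
(:mod:`mbmeta.metalearn.evaluate`).

Task-specific schedules follow the study conditions: probability-1/2
CS/US omissions in the conditioning mixture; the continual-learning
weight-carryover anneal (trial-initial weights mix the baseline w0 with
the previous trial's final weights, mixing fraction rising linearly to 1
over the first half of optimization); the navigation heading-spread
anneal (gamma from 0 to 0.5).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .. import navigation as nav
from ..params import CircuitParameters, recurrence_mask, save_parameters, \
    load_parameters
from ..plasticity import PlasticityConfig
from ..tasks import (ConditioningOptions, encode_odor, make_continual_sequence,
                     make_state_trial, make_nonplastic_env_trial,
                     make_training_trial, render_batch)
from .engine import Workspace, loss_and_grads, nav_loss_and_grads
from .initialization import initialize_parameters
from .losses import LossConfig
from .optimizer import RMSprop, clip_gradients

__all__ = ["TaskMix", "TrainConfig", "TrainRecord", "train"]

TASK_KINDS = ("conditioning", "continual", "state", "navigation", "nonplastic")


@dataclass
class TaskMix:
    """What the network is optimized for."""

    kind: str = "conditioning"
    paradigms: tuple[str, ...] = ("extinction", "second_order")
    options: ConditioningOptions = field(default_factory=ConditioningOptions)
    nav_options: nav.NavOptions = field(default_factory=nav.NavOptions)
    include_novelty: bool = False
    with_beta: bool = True          # continual learning only
    odor_bank_size: int = 10        # non-plastic comparison only

    def __post_init__(self) -> None:
        if self.kind not in TASK_KINDS:
            raise ValueError(f"kind must be one of {TASK_KINDS}")


@dataclass
class TrainConfig:
    batch_size: int = 30
    learning_rate: float = 1e-3
    n_epochs: int = 2000
    carryover_anneal_epochs: int | None = None   # default: n_epochs // 2
    gamma_final: float = 0.5
    rmsprop_alpha: float = 0.99
    rmsprop_eps: float = 1e-8
    # global gradient-norm clip; None disables.  Defaults to 10 for the
    # navigation task, whose closed-loop unroll occasionally produces
    # exploding gradients that would otherwise swamp RMSprop's
    # second-moment memory (see methods note); no clipping elsewhere.
    grad_clip_norm: float | None = None
    recurrence: str = "full"       # full | feedforward | zero
    plasticity_on: bool = True
    # float32 suffices for the open-loop tasks; the 400-step closed-loop
    # navigation backward pass can transiently exceed float32 range, so it
    # runs in float64 unless overridden (RMSprop keeps the resulting
    # updates bounded either way)
    dtype: str | None = None
    n_kc: int = 200
    n_mbon: int = 20
    n_dan: int = 20
    n_fbn: int = 60
    n_compartments: int | None = None
    tau: float = 1.0
    dt: float = 0.5
    w_max: float = 0.05
    plasticity: PlasticityConfig | None = None

    def __post_init__(self) -> None:
        if min(self.batch_size, self.n_epochs) <= 0 or self.learning_rate < 0:
            raise ValueError("batch_size, n_epochs must be positive and "
                             "learning_rate nonnegative")

    def resolved_plasticity(self) -> PlasticityConfig:
        if self.plasticity is not None:
            return self.plasticity
        return PlasticityConfig(w_max=self.w_max, dt=self.dt)

    def resolved_dtype(self, kind: str) -> np.dtype:
        if self.dtype is not None:
            return np.dtype(self.dtype)
        return np.dtype(np.float64 if kind == "navigation" else np.float32)

    def resolved_grad_clip(self, kind: str) -> float | None:
        if self.grad_clip_norm is not None:
            return self.grad_clip_norm
        return 10.0 if kind == "navigation" else None


@dataclass
class TrainRecord:
    """Outcome of one optimization run."""

    loss_history: np.ndarray
    parts_history: dict[str, np.ndarray]
    params: CircuitParameters
    task: TaskMix
    config: TrainConfig
    loss_config: LossConfig
    seed: int
    schedules: dict[str, np.ndarray] = field(default_factory=dict)
    diverged: bool = False
    W_kc_mbon: np.ndarray | None = None   # trained weights, non-plastic nets
    extras: dict = field(default_factory=dict)

    def save(self, directory: str | Path) -> None:
        """Write parameters (array archive + JSON sidecar), the loss curve
        as CSV, and the resolved configuration."""
        import pandas as pd

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_parameters(self.params, directory / "params")
        n = self.loss_history.size
        cols = {"epoch": np.arange(n), "loss": self.loss_history}
        for key, val in {**self.parts_history, **self.schedules}.items():
            col = np.full(n, np.nan)
            col[:min(n, len(val))] = np.asarray(val)[:n]
            cols[key] = col
        pd.DataFrame(cols).to_csv(directory / "loss_history.csv", index=False)
        if self.W_kc_mbon is not None:
            np.savez(directory / "kc_mbon_weights.npz", W_kc_mbon=self.W_kc_mbon)
        meta = {"seed": self.seed, "diverged": self.diverged,
                "task": _to_jsonable(asdict(self.task)),
                "config": _to_jsonable(asdict(self.config)),
                "loss_config": _to_jsonable(asdict(self.loss_config))}
        (directory / "record.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "TrainRecord":
        import pandas as pd

        directory = Path(directory)
        meta = json.loads((directory / "record.json").read_text())
        hist = pd.read_csv(directory / "loss_history.csv")
        task_d = meta["task"]
        task = TaskMix(kind=task_d["kind"],
                       paradigms=tuple(task_d["paradigms"]),
                       options=ConditioningOptions(**task_d["options"]),
                       nav_options=nav.NavOptions(**task_d["nav_options"]),
                       include_novelty=task_d["include_novelty"],
                       with_beta=task_d["with_beta"],
                       odor_bank_size=task_d["odor_bank_size"])
        cfg_d = dict(meta["config"])
        pcfg = cfg_d.pop("plasticity")
        config = TrainConfig(**cfg_d,
                             plasticity=None if pcfg is None
                             else PlasticityConfig(**pcfg))
        W = None
        if (directory / "kc_mbon_weights.npz").exists():
            with np.load(directory / "kc_mbon_weights.npz") as arc:
                W = arc["W_kc_mbon"]
        parts = {c: hist[c].to_numpy() for c in hist.columns
                 if c not in ("epoch", "loss")}
        return cls(loss_history=hist["loss"].to_numpy(), parts_history=parts,
                   params=load_parameters(directory / "params"), task=task,
                   config=config, loss_config=LossConfig(**meta["loss_config"]),
                   seed=meta["seed"], diverged=meta["diverged"], W_kc_mbon=W)


def _to_jsonable(obj):
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _trainables(params: CircuitParameters) -> dict[str, np.ndarray]:
    d = {"W_recur": params.W_recur, "b": params.b,
         "W_ext": params.W_ext, "W_readout": params.W_readout}
    if params.W_state is not None:
        d["W_state"] = params.W_state
    if params.beta is not None:
        d["beta"] = params.beta
    if params.W_u is not None:
        d["W_u"] = params.W_u
        d["W_omega"] = params.W_omega
        d["_b_u"] = np.array([params.b_u])
        d["_b_omega"] = np.array([params.b_omega])
    return d


def train(task_mix: TaskMix, train_config: TrainConfig | None = None,
          loss_config: LossConfig | None = None, seed: int = 0) -> TrainRecord:
    """Run the optimization phase for a task mixture.

    Deterministic given ``seed``: one seed sequence fans out to independent
    generators for parameter initialization and trial sampling, so
    ablations that share a seed also share their trial streams.
    """
    cfg = train_config or TrainConfig()
    mix = task_mix
    if loss_config is None:
        kind_map = {"conditioning": "valence", "nonplastic": "valence",
                    "continual": "valence", "state": "valence+state",
                    "navigation": "navigation"}
        loss_config = LossConfig(loss_kind=kind_map[mix.kind])
        if mix.include_novelty:
            loss_config.loss_kind = "valence+novelty"
    ss = np.random.SeedSequence(seed)
    rng_init, rng_trials = (np.random.default_rng(s) for s in ss.spawn(2))

    if mix.kind == "navigation":
        return _train_navigation(mix, cfg, loss_config, rng_init, rng_trials,
                                 seed)
    return _train_windowed(mix, cfg, loss_config, rng_init, rng_trials, seed)


def _init_for(mix: TaskMix, cfg: TrainConfig,
              rng: np.random.Generator) -> CircuitParameters:
    d_ext = {"conditioning": 2, "nonplastic": 2, "continual": 2,
             "state": 2 + mix.options.n_states, "navigation": 6}[mix.kind]
    return initialize_parameters(
        rng, n_mbon=cfg.n_mbon, n_dan=cfg.n_dan, n_fbn=cfg.n_fbn,
        n_kc=cfg.n_kc, d_ext=d_ext,
        d_readout=2 if mix.include_novelty else 1,
        with_state=mix.kind == "state",
        with_velocity=mix.kind == "navigation",
        with_beta=mix.kind == "continual" and mix.with_beta,
        n_compartments=cfg.n_compartments, tau=cfg.tau, dt=cfg.dt,
        w_max=cfg.w_max, recurrence=cfg.recurrence)


def _train_windowed(mix, cfg, loss_cfg, rng_init, rng_trials, seed):
    """Conditioning / continual / state / non-plastic training (open-loop
    trials rendered up front each epoch)."""
    opts = mix.options
    opts.n_kc = cfg.n_kc
    params = _init_for(mix, cfg, rng_init)
    mask = recurrence_mask(params, cfg.recurrence)
    pcfg = cfg.resolved_plasticity()
    dtype = cfg.resolved_dtype(mix.kind)
    B = cfg.batch_size
    M, K = params.n_mbon, params.n_kc

    nonplastic = mix.kind == "nonplastic"
    plasticity_on = cfg.plasticity_on and not nonplastic
    bank = None
    Wkc = None
    if nonplastic:
        bank = [encode_odor(cfg.n_kc, opts.sparsity, rng_init)
                for _ in range(mix.odor_bank_size)]
        Wkc = rng_init.normal(0.0, np.sqrt(1.0 / (2 * cfg.n_kc)), size=(M, K))

    trainables = _trainables(params)
    if nonplastic:
        trainables["W_kc_mbon"] = Wkc
    opt = RMSprop(trainables, lr=cfg.learning_rate, alpha=cfg.rmsprop_alpha,
                  eps=cfg.rmsprop_eps)

    continual = mix.kind == "continual"
    anneal = cfg.carryover_anneal_epochs or max(1, cfg.n_epochs // 2)
    chain_w = np.full((B, M, K), cfg.w_max)
    chain_W = np.full((B, M, K), cfg.w_max)

    losses = np.zeros(cfg.n_epochs)
    parts_hist: dict[str, list[float]] = {}
    chi_hist = np.zeros(cfg.n_epochs)
    diverged = False
    ws = Workspace()

    for epoch in range(cfg.n_epochs):
        if mix.kind in ("conditioning",):
            trials = [make_training_trial(rng_trials, opts, mix.paradigms)
                      for _ in range(B)]
        elif continual:
            trials = [make_continual_sequence(rng_trials, opts)
                      for _ in range(B)]
        elif mix.kind == "state":
            trials = [make_state_trial(rng_trials, opts) for _ in range(B)]
        else:
            trials = [make_nonplastic_env_trial(bank, rng_trials, opts)
                      for _ in range(B)]
        kc, ext, target, tstate, resets, _ = render_batch(
            trials, cfg.n_kc, cfg.dt, include_novelty=mix.include_novelty,
            n_states=opts.n_states, ws=ws, dtype=dtype)

        w0 = W0 = None
        if continual:
            chi = min(1.0, epoch / anneal)
            chi_hist[epoch] = chi
            w0 = (1.0 - chi) * cfg.w_max + chi * chain_w
            W0 = (1.0 - chi) * cfg.w_max + chi * chain_W
        if nonplastic:
            W0 = np.broadcast_to(Wkc, (B, M, K))

        loss, parts, grads, rec = loss_and_grads(
            params, kc, ext, resets, target,
            tstate if mix.kind == "state" else None,
            loss_cfg=loss_cfg, plasticity_on=plasticity_on, pcfg=pcfg,
            w0=w0, W0=W0, nonplastic_train=nonplastic, dtype=dtype, ws=ws)

        if not np.isfinite(loss):
            diverged = True
            losses[epoch:] = np.nan
            break
        if continual:
            chain_w = rec.w[-1].astype(float)
            chain_W = rec.W_kc_mbon[-1].astype(float)

        grads["W_recur"] = grads["W_recur"] * mask
        if params.W_u is not None:
            grads["_b_u"] = np.array([grads.pop("b_u", 0.0)])
            grads["_b_omega"] = np.array([grads.pop("b_omega", 0.0)])
        if cfg.resolved_grad_clip(mix.kind) is not None:
            clip_gradients(grads, cfg.resolved_grad_clip(mix.kind))
        opt.step(grads)
        params.W_recur *= mask
        if params.beta is not None:
            np.maximum(params.beta, 0.0, out=params.beta)
        losses[epoch] = loss
        for k, v in parts.items():
            parts_hist.setdefault(k, []).append(v)

    rec_out = TrainRecord(
        loss_history=losses,
        parts_history={k: np.asarray(v) for k, v in parts_hist.items()},
        params=params, task=mix, config=cfg, loss_config=loss_cfg, seed=seed,
        schedules={"carryover_fraction": chi_hist} if continual else {},
        diverged=diverged, W_kc_mbon=Wkc.copy() if nonplastic else None)
    if continual:
        rec_out.extras["chain_w"] = chain_w
        rec_out.extras["chain_W"] = chain_W
    if nonplastic:
        rec_out.extras["bank"] = bank
    return rec_out


def _train_navigation(mix, cfg, loss_cfg, rng_init, rng_trials, seed):
    opts = mix.nav_options
    params = _init_for(mix, cfg, rng_init)
    mask = recurrence_mask(params, cfg.recurrence)
    pcfg = cfg.resolved_plasticity()
    dtype = cfg.resolved_dtype("navigation")
    B = cfg.batch_size
    Tn = int(round(opts.nav_duration / cfg.dt))

    trainables = _trainables(params)
    opt = RMSprop(trainables, lr=cfg.learning_rate, alpha=cfg.rmsprop_alpha,
                  eps=cfg.rmsprop_eps)

    losses = np.zeros(cfg.n_epochs)
    gamma_hist = np.zeros(cfg.n_epochs)
    dist_hist = np.full(cfg.n_epochs, np.nan)
    clip = cfg.resolved_grad_clip("navigation")
    from .initialization import velocity_readout_mask
    vel_mask = velocity_readout_mask(params)
    # the closed loop is only marginally stable: keep the best parameters
    # (lowest batch-mean final distance over the second half of the
    # anneal) so a late exploding epoch cannot erase a converged solution
    best_dist = np.inf
    best_params = None
    best_epoch = -1
    diverged = False
    consecutive_failures = 0
    ws = Workspace()
    for epoch in range(cfg.n_epochs):
        gamma = cfg.gamma_final * (epoch / max(1, cfg.n_epochs - 1))
        gamma_hist[epoch] = gamma
        src, pat, theta0 = nav.sample_trial_batch(
            rng_trials, B, n_kc=cfg.n_kc, sparsity=mix.options.sparsity,
            gamma=gamma, options=opts)
        kc_cond, ext_cond = nav.render_conditioning_phase(pat, opts, cfg.dt)
        try:
            loss, grads, rec, dist = nav_loss_and_grads(
                params, kc_cond, ext_cond, Tn, src, theta0, pat=pat,
                plasticity_cond=cfg.plasticity_on,
                plasticity_nav=cfg.plasticity_on, pcfg=pcfg,
                half_height=opts.half_height, dtype=dtype, ws=ws)
        except FloatingPointError:
            # unroll left the representable range entirely: no usable
            # gradient this epoch; a long run of these means the
            # parameters themselves are unstable -> discard the seed
            losses[epoch] = np.nan
            consecutive_failures += 1
            if consecutive_failures > 25:
                diverged = True
                losses[epoch:] = np.nan
                break
            continue
        consecutive_failures = 0
        grads["W_recur"] = grads["W_recur"] * mask
        grads["W_u"] = grads["W_u"] * vel_mask
        grads["W_omega"] = grads["W_omega"] * vel_mask
        grads["_b_u"] = np.array([grads.pop("b_u")])
        grads["_b_omega"] = np.array([grads.pop("b_omega")])
        if clip is not None:
            clip_gradients(grads, clip)
        opt.step(grads)
        params.W_recur *= mask
        params.b_u = float(trainables["_b_u"][0])
        params.b_omega = float(trainables["_b_omega"][0])
        losses[epoch] = loss
        dist_hist[epoch] = float(dist.mean())
        if epoch >= cfg.n_epochs // 2 and dist_hist[epoch] < best_dist:
            best_dist = dist_hist[epoch]
            best_epoch = epoch
            best_params = params.copy()

    params.b_u = float(trainables["_b_u"][0])
    params.b_omega = float(trainables["_b_omega"][0])
    extras = {"final_params": params}
    if best_params is not None:
        params = best_params
    rec = TrainRecord(
        loss_history=losses,
        parts_history={"mean_final_distance": dist_hist},
        params=params, task=mix, config=cfg, loss_config=loss_cfg, seed=seed,
        schedules={"gamma": gamma_hist}, diverged=diverged, extras=extras)
    rec.extras["best_epoch"] = best_epoch
    return rec
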