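"""Task losses for the meta-learning outer loop.

The conditioning loss is a mean-squared error between the decoded valence
(and, when present, novelty or state readouts) and its target over every
timestep of a trial, plus a regularizer that penalizes dopamine activity
exceeding a baseline rate of 0.1:

    L = 1/T sum_t ||R(t) - R*(t)||^2
        + lambda/T sum_t sum_i [r_DAN_i(t) - 0.1]_+^2

The state task drops the DAN penalty (its whole point is state-dependent
dopamine fluctuations) and adds the squared error of the softmax state
decode.  The navigation loss is the squared Euclidean distance between the
agent's final position and the rewarded odor source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["LossConfig", "trial_loss"]

LOSS_KINDS = ("valence", "valence+novelty", "valence+state", "navigation")


@dataclass
class LossConfig:
    lambda_dan: float = 0.1
    dan_baseline: float = 0.1
    include_dan_penalty: bool = True
    loss_kind: str = "valence"

    def __post_init__(self) -> None:
        if self.lambda_dan < 0:
            raise ValueError("lambda_dan must be >= 0")
        if self.loss_kind not in LOSS_KINDS:
            raise ValueError(f"loss_kind must be one of {LOSS_KINDS}")
        if self.loss_kind == "valence+state":
            self.include_dan_penalty = False


def trial_loss(config: LossConfig, outputs: dict, targets: dict) -> float:
    """Loss of a single trial from recorded outputs.

    ``outputs`` carries time-aligned arrays: ``"readout"`` (T, d) and
    ``"r_dan"`` (T, n_dan); for the state task additionally
    ``"state_probs"`` (T, 3); for navigation only ``"final_position"``.
    ``targets`` carries ``"readout"``, ``"state"`` and/or ``"position"``.
    """
    if config.loss_kind == "navigation":
        err = np.asarray(outputs["final_position"], dtype=float) - \
            np.asarray(targets["position"], dtype=float)
        return float(err @ err)

    readout = np.atleast_2d(np.asarray(outputs["readout"], dtype=float).T).T
    target = np.atleast_2d(np.asarray(targets["readout"], dtype=float).T).T
    if readout.shape != target.shape:
        raise ValueError("readout and target shapes differ")
    T = readout.shape[0]
    loss = float(((readout - target) ** 2).sum() / T)

    if config.include_dan_penalty and config.lambda_dan > 0:
        r_dan = np.asarray(outputs["r_dan"], dtype=float)
        if r_dan.shape[0] != T:
            raise ValueError("r_dan not time-aligned with readout")
        pen = np.maximum(r_dan - config.dan_baseline, 0.0)
        loss += float(config.lambda_dan / T * (pen ** 2).sum())

    if config.loss_kind == "valence+state":
        probs = np.asarray(outputs["state_probs"], dtype=float)
        starget = np.asarray(targets["state"], dtype=float)
        if probs.shape != starget.shape:
            raise ValueError("state_probs and state target shapes differ")
        loss += float(((probs - starget) ** 2).sum() / T)
    return loss
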