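"""Synthetic observers and the adaptation experiment generator.

Trial tables are tidy pandas DataFrames with columns ``subject``,
``condition``, ``block``, ``set_size``, ``target``, ``nontargets``,
``response`` — angles in mapped radians internally (see
:mod:`ecwm.trialio` for the degree-based CSV format).

Two response backends are supported for the adaptation experiment: a
phenomenological one (a per-block contamination-mixture parameterization,
fast, used in recovery tests) and a mechanistic one (the neural encoder
with a per-block prior interpolating between the natural prior and the
adaptation distribution).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ecwm.mixture import MixtureParams
from ecwm.neural import PopulationConfig, simulate_trials
from ecwm.orientation import wrap_angle
from ecwm.priors import Prior
from ecwm.spa import SPAParams, sample_spa

TRIAL_COLUMNS = ["subject", "condition", "block", "set_size",
                 "target", "nontargets", "response"]


@dataclass(frozen=True)
class ExperimentDesign:
    """Block structure of the adaptation experiment."""

    n_blocks: int = 8
    trials_per_block: int = 72
    set_size: int = 4
    pre_blocks: tuple = (1,)
    adapt_blocks: tuple = (2, 3, 4, 5, 6, 7)
    post_blocks: tuple = (8,)

    def __post_init__(self):
        groups = (self.pre_blocks, self.adapt_blocks, self.post_blocks)
        all_blocks = [b for g in groups for b in g]
        if (sorted(all_blocks) != list(range(1, self.n_blocks + 1))):
            raise ValueError("pre/adapt/post blocks must partition 1..n_blocks")

    @property
    def total_trials(self):
        return self.n_blocks * self.trials_per_block


def _sample_mixture_responses(params: MixtureParams, targets, rng):
    """Responses under the contamination mixture (target + biased vM error)."""
    n = len(targets)
    mu = params.eta * np.sin(2.0 * targets)
    err = mu + rng.vonmises(0.0, params.kappa, size=n)
    guess = rng.random(n) >= params.lam
    if np.any(guess):
        err[guess] = rng.uniform(-np.pi, np.pi, size=guess.sum())
    return wrap_angle(targets + err)


def _responses_for(model, targets, N, rng):
    if isinstance(model, MixtureParams):
        return _sample_mixture_responses(model, targets, rng)
    if isinstance(model, SPAParams):
        return sample_spa(model, targets, N, rng=rng)
    if isinstance(model, PopulationConfig):
        _, resp = simulate_trials(model, targets, N, reps=1,
                                  seed=rng.integers(2**63))
        return resp
    raise TypeError(f"unsupported response model: {type(model).__name__}")


def gen_observer(model, set_sizes, trials_per_size: int, seed=None,
                 subject: str = "synthetic", target_values=None) -> pd.DataFrame:
    """Synthetic observer: uniform targets, responses from a generative model.

    Parameters
    ----------
    model : PopulationConfig or SPAParams
        Generative response model.
    set_sizes : sequence of int
        Set sizes to simulate (e.g. (1, 2, 4, 8)).
    trials_per_size : int
        Trials per set size.
    target_values : array-like, optional
        When given, targets are drawn uniformly from this discrete set
        (e.g. the fitting grid's stimulus bin centers, which avoids
        discretization mismatch in parameter-recovery studies) instead of
        the continuous uniform distribution.

    Returns
    -------
    pandas.DataFrame in the shared trial-table layout.
    """
    if trials_per_size < 1:
        raise ValueError("trials_per_size must be >= 1")
    rng = np.random.default_rng(seed)
    frames = []
    for N in set_sizes:
        if target_values is not None:
            targets = rng.choice(np.asarray(target_values, dtype=float),
                                 size=trials_per_size)
        else:
            targets = rng.uniform(-np.pi, np.pi, size=trials_per_size)
        nontargets = [rng.uniform(-np.pi, np.pi, size=N - 1) for _ in
                      range(trials_per_size)]
        responses = _responses_for(model, targets, N, rng)
        frames.append(pd.DataFrame({
            "subject": subject,
            "condition": "none",
            "block": 0,
            "set_size": int(N),
            "target": targets,
            "nontargets": nontargets,
            "response": responses,
        }))
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


_NONTARGET_PRIORS = {
    "incongruent": "adapt_oblique",
    "congruent": "adapt_cardinal",
}


def gen_adaptation_experiment(design: ExperimentDesign, condition: str,
                              response_model, seed=None,
                              subject: str = "synthetic") -> pd.DataFrame:
    """Full synthetic adaptation experiment for one subject.

    Targets are uniform in every block.  Nontargets are uniform in the
    pre/post blocks and drawn from the condition's bimodal distribution
    (incongruent: density proportional to 2-|cos|, peaks at the obliques;
    congruent: 2-|sin|, peaks at the cardinals) during adaptation blocks.

    Parameters
    ----------
    condition : {"incongruent", "congruent"}
    response_model
        Either a single model (MixtureParams / SPAParams /
        PopulationConfig) used in every block, or a dict mapping block
        index -> model (a per-block schedule).
    """
    if condition not in _NONTARGET_PRIORS:
        raise ValueError(f"unknown condition: {condition!r}")
    rng = np.random.default_rng(seed)
    adapt_prior = Prior(_NONTARGET_PRIORS[condition])
    uniform = Prior("uniform")
    frames = []
    for block in range(1, design.n_blocks + 1):
        n = design.trials_per_block
        N = design.set_size
        targets = rng.uniform(-np.pi, np.pi, size=n)
        nt_prior = adapt_prior if block in design.adapt_blocks else uniform
        nontargets = [nt_prior.sample(N - 1, rng=rng) for _ in range(n)]
        model = (response_model[block] if isinstance(response_model, dict)
                 else response_model)
        responses = _responses_for(model, targets, N, rng)
        frames.append(pd.DataFrame({
            "subject": subject,
            "condition": condition,
            "block": block,
            "set_size": N,
            "target": targets,
            "nontargets": nontargets,
            "response": responses,
        }))
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def linear_eta_schedule(design: ExperimentDesign, eta_start: float,
                        eta_end: float, kappa: float = 8.0,
                        lam: float = 0.9) -> dict:
    """Per-block mixture schedule: pre-block bias ``eta_start``, linear
    decay to ``eta_end`` over the adaptation blocks, held thereafter."""
    adapt = sorted(design.adapt_blocks)
    etas = np.linspace(eta_start, eta_end, len(adapt))
    schedule = {}
    for b in range(1, design.n_blocks + 1):
        if b in design.pre_blocks:
            eta = eta_start
        elif b in design.post_blocks:
            eta = eta_end
        else:
            eta = float(etas[adapt.index(b)])
        schedule[b] = MixtureParams(kappa=kappa, eta=float(eta), lam=lam)
    return schedule
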