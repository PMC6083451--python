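"""Contamination mixture model for orientation-dependent response bias.

Recall errors within an experimental block are modeled as a mixture of a
von Mises component whose mean shifts with target orientation,
``mu(theta) = eta * sin(2*theta)``, and a uniform contaminant:

    p(err | theta) = lam * VM(err; eta*sin(2*theta), kappa) + (1-lam)/(2*pi)

Positive ``eta`` means repulsion from the cardinal orientations.  This is a
statistical denoising device — no psychological interpretation is attached
to ``lam`` or ``kappa``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, i0e, logit

from ecwm.orientation import TWO_PI, circ_diff

#: default number of Nelder-Mead restarts
N_RESTARTS = 100

#: minimum trials per block accepted by fit_block
MIN_TRIALS = 20


@dataclass(frozen=True)
class MixtureParams:
    """kappa: von Mises concentration; eta: bias amplitude (radians,
    positive = repulsion from cardinals); lam: von Mises mixture weight."""

    kappa: float
    eta: float
    lam: float

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")


def error_density(params: MixtureParams, theta_target, delta):
    """Mixture density of recall error ``delta`` given target orientation."""
    theta_target = np.asarray(theta_target, dtype=float)
    delta = np.asarray(delta, dtype=float)
    mu = params.eta * np.sin(2.0 * theta_target)
    vm = np.exp(params.kappa * (np.cos(delta - mu) - 1.0)) / (
        TWO_PI * i0e(params.kappa)
    )
    return params.lam * vm + (1.0 - params.lam) / TWO_PI


def _negloglik(x, targets, deltas):
    """Negative log-likelihood on the unconstrained scale.

    x = [log kappa, eta, logit lam].
    """
    kappa = np.exp(x[0])
    if not np.isfinite(kappa) or kappa > 1e6:
        return np.inf
    eta = x[1]
    lam = expit(x[2])
    mu = eta * np.sin(2.0 * targets)
    log_vm = kappa * (np.cos(deltas - mu) - 1.0) - np.log(TWO_PI * i0e(kappa))
    # log(lam*vm + (1-lam)/2pi) computed stably via logaddexp
    with np.errstate(divide="ignore"):
        a = np.log(lam) + log_vm
        b = np.full_like(a, np.log1p(-lam) - np.log(TWO_PI)) if lam < 1.0 else None
    ll = a if b is None else np.logaddexp(a, b)
    total = ll.sum()
    return -total if np.isfinite(total) else np.inf


def fit_block(targets, responses, restarts: int = N_RESTARTS, seed=None,
              rng=None):
    """Fit the contamination mixture to one block of trials.

    Maximizes the summed log-density of recall errors via Nelder-Mead on
    transformed parameters (log kappa, eta, logit lam), restarted from
    ``restarts`` random starting points (kappa ~ U(0.5, 20),
    eta ~ U(-0.5, 0.5), lam ~ U(0.5, 1)).

    Parameters
    ----------
    targets, responses : array-like of float
        Per-trial target orientation and response, mapped radians.
    restarts : int
        Number of random restarts.
    seed, rng
        Seed or generator controlling the restart draws.

    Returns
    -------
    (MixtureParams, float)
        Best-fitting parameters and the maximized log-likelihood.
    """
    targets = np.atleast_1d(np.asarray(targets, dtype=float))
    responses = np.atleast_1d(np.asarray(responses, dtype=float))
    if targets.shape != responses.shape:
        raise ValueError("targets and responses must have the same length")
    if targets.size < MIN_TRIALS:
        raise ValueError(f"fit_block requires >= {MIN_TRIALS} trials")
    if rng is None:
        rng = np.random.default_rng(seed)

    deltas = circ_diff(responses, targets)
    best_val = np.inf
    best_x = None
    for _ in range(int(restarts)):
        x0 = np.array(
            [
                np.log(rng.uniform(0.5, 20.0)),
                rng.uniform(-0.5, 0.5),
                logit(rng.uniform(0.5, 1.0)),
            ]
        )
        res = minimize(
            _negloglik,
            x0,
            args=(targets, deltas),
            method="Nelder-Mead",
            options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 2000},
        )
        if np.isfinite(res.fun) and res.fun < best_val:
            best_val = res.fun
            best_x = res.x
    if best_x is None:
        raise RuntimeError("mixture likelihood non-finite at every start")
    params = MixtureParams(
        kappa=float(np.exp(best_x[0])),
        eta=float(best_x[1]),
        lam=float(expit(best_x[2])),
    )
    return params, -float(best_val)


def block_series(trials, restarts: int = N_RESTARTS, seed=None,
                 adapt_blocks=range(2, 8), pre_block=1, post_block=8):
    """Per-block mixture fits for one subject, plus summary contrasts.

    Parameters
    ----------
    trials : pandas.DataFrame
        Columns ``block``, ``target``, ``response`` (radians) for one
        subject.  Missing blocks are skipped with a warning.
    restarts, seed
        Passed to :func:`fit_block` (one derived seed per block).

    Returns
    -------
    dict with keys
        ``table`` : DataFrame (block, eta_hat, kappa_hat, lambda_hat,
        loglik, n_trials);
        ``contrast`` : eta_hat(post) - eta_hat(pre), or NaN if missing;
        ``slope`` : OLS slope of eta_hat on block index over the
        adaptation blocks, or NaN if fewer than 2 are present.
    """
    import warnings

    import pandas as pd

    rows = []
    blocks = sorted(set(int(b) for b in trials["block"].dropna().unique()))
    ss = np.random.SeedSequence(seed)
    child = dict(zip(blocks, ss.spawn(len(blocks))))
    for b in blocks:
        sub = trials[trials["block"] == b]
        params, ll = fit_block(
            sub["target"].to_numpy(),
            sub["response"].to_numpy(),
            restarts=restarts,
            rng=np.random.default_rng(child[b]),
        )
        rows.append(
            {
                "block": b,
                "eta_hat": params.eta,
                "kappa_hat": params.kappa,
                "lambda_hat": params.lam,
                "loglik": ll,
                "n_trials": len(sub),
            }
        )
    table = pd.DataFrame(rows)

    eta = dict(zip(table["block"], table["eta_hat"]))
    if pre_block in eta and post_block in eta:
        contrast = eta[post_block] - eta[pre_block]
    else:
        warnings.warn("pre or post block missing; contrast undefined")
        contrast = np.nan

    adapt = [b for b in adapt_blocks if b in eta]
    if len(adapt) >= 2:
        slope = float(np.polyfit(adapt, [eta[b] for b in adapt], 1)[0])
    else:
        warnings.warn("fewer than 2 adaptation blocks; slope undefined")
        slope = np.nan

    return {"table": table, "contrast": contrast, "slope": slope}
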