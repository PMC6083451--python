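"""Efficient-coding population encoder and Bayesian posterior-mean decoder.

A stimulus orientation is encoded by ``M`` von Mises tuning functions whose
preferred values are evenly spaced in the *warped* space: heterogeneity is
implemented as a remapping of the stimulus through the prior's CDF, so a
uniform prior recovers the homogeneous population exactly.  Divisive
normalization fixes the total expected spike count to ``gamma / N`` for set
size ``N``; spiking is independent Poisson over a unit decoding interval;
decoding computes the circular mean of the posterior over a grid, with the
prior reused as the Bayesian prior.

Tuning amplitudes are peak-1 (``exp(kappa*(cos(.) - 1))``): any common
prefactor cancels in the divisive normalization, so the gain enters only
through the ``gamma / N`` scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ecwm.orientation import TWO_PI, wrap_angle
from ecwm.priors import Prior

#: floor applied to rates inside logarithms (deep von Mises tails underflow)
RATE_FLOOR = 1e-12

#: resultant length below which a posterior is treated as directionless
_DEGENERATE_RESULTANT = 1e-12


@dataclass(frozen=True)
class PopulationConfig:
    """Configuration of the encoding population.

    Attributes
    ----------
    M : int
        Number of neurons (>= 2).
    kappa : float
        Basis tuning width: concentration of the homogeneous von Mises
        tuning functions before warping.
    gamma : float
        Total population gain: expected spikes per decoding interval at
        set size 1.
    prior : Prior
        Stimulus prior; drives both the tuning-curve warping and the
        Bayesian decoder.
    T : float
        Decoding interval; fixed to 1.
    """

    M: int = 100
    kappa: float = 2.0
    gamma: float = 50.0
    prior: Prior = field(default_factory=Prior)
    T: float = 1.0

    def __post_init__(self):
        if self.M < 2:
            raise ValueError("M must be >= 2")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.gamma <= 0:
            raise ValueError("gamma must be positive")
        if self.T != 1.0:
            raise ValueError("decoding interval T is fixed to 1")

    @property
    def preferred(self) -> np.ndarray:
        """Preferred values in warped space, evenly spaced over [-pi, pi)."""
        return -np.pi + TWO_PI * np.arange(self.M) / self.M


def tuning_rates(config: PopulationConfig, theta) -> np.ndarray:
    """Unnormalized (peak-1) tuning responses at stimulus ``theta``.

    Returns shape ``(M,)`` for scalar ``theta`` or ``(len(theta), M)`` for
    a vector of stimuli.  Entry ``i`` is
    ``exp(kappa * (cos(F(theta) - phi_i) - 1))`` with ``F`` the prior's
    warping map and ``phi_i`` the evenly spaced preferred values.
    """
    theta = np.asarray(theta, dtype=float)
    scalar = theta.ndim == 0
    warped = config.prior.warp(np.atleast_1d(theta))
    f = np.exp(
        config.kappa * (np.cos(warped[:, None] - config.preferred[None, :]) - 1.0)
    )
    return f[0] if scalar else f


def normalized_rates(config: PopulationConfig, theta, N: int) -> np.ndarray:
    """Post-normalization expected spike counts for set size ``N``.

    Divisive normalization is exact: each row sums to ``gamma / N``
    regardless of stimulus, prior, or tuning width.
    """
    if int(N) != N or N < 1:
        raise ValueError("set size N must be a positive integer")
    f = tuning_rates(config, theta)
    total = f.sum(axis=-1, keepdims=True)
    return (config.gamma / float(N)) * f / total


def sample_spikes(rates, seed=None, rng=None) -> np.ndarray:
    """Independent Poisson spike counts with the given mean rates."""
    if rng is None:
        rng = np.random.default_rng(seed)
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    return rng.poisson(rates)


def log_likelihood(config: PopulationConfig, spikes, theta_grid, N: int) -> np.ndarray:
    """Log-likelihood of each grid orientation given a spike pattern.

    Computes ``sum_i [n_i * ln r_i(theta) - r_i(theta)]`` (the ``ln n_i!``
    term is dropped — it does not vary with theta).  The ``sum_i r_i``
    term equals ``gamma / N`` for every theta by normalization and is kept
    for interpretability.

    ``spikes`` may be one pattern ``(M,)`` or a stack ``(n, M)``; the
    result has shape ``(len(theta_grid),)`` or ``(n, len(theta_grid))``.
    """
    theta_grid = np.atleast_1d(np.asarray(theta_grid, dtype=float))
    if theta_grid.size == 0:
        raise ValueError("theta_grid must be nonempty")
    spikes = np.asarray(spikes)
    single = spikes.ndim == 1
    counts = np.atleast_2d(spikes).astype(float)
    rates = normalized_rates(config, theta_grid, N)  # (G, M)
    log_rates = np.log(np.maximum(rates, RATE_FLOOR))
    ll = counts @ log_rates.T - config.gamma / float(N)
    return ll[0] if single else ll


def _posterior_circmean(log_post, theta_grid, rng):
    """Circular mean of posteriors given per-row log weights (unnormalized).

    Rows whose posterior resultant is numerically zero get a uniform random
    direction from ``rng``; returns (estimates, degenerate mask).
    """
    log_post = log_post - log_post.max(axis=1, keepdims=True)
    # zero negligible weights: exp of very negative values produces
    # subnormal floats that stall the BLAS matvec below
    w = np.where(log_post < -60.0, 0.0, np.exp(np.maximum(log_post, -60.0)))
    z = w @ np.exp(1j * theta_grid)
    norm = w.sum(axis=1)
    r = np.abs(z) / norm
    est = wrap_angle(np.angle(z))
    bad = r < _DEGENERATE_RESULTANT
    if np.any(bad):
        est[bad] = rng.uniform(-np.pi, np.pi, size=bad.sum())
    return est, bad


def decode(config: PopulationConfig, spikes, N: int = 1, n_grid: int = 100,
           seed=None, rng=None):
    """Posterior-mean estimate of the stimulus from a spike pattern.

    The posterior is proportional to ``exp(loglik(theta)) * prior(theta)``
    evaluated at ``n_grid`` evenly spaced orientations; the estimate is the
    direction of the posterior-weighted resultant (circular mean).  A
    directionless posterior (e.g. zero spikes under a uniform prior) yields
    a uniform random angle drawn from the decoder's RNG.

    Returns a float for a single pattern, an array for a stack.
    """
    if n_grid < 8:
        raise ValueError("n_grid must be >= 8")
    if rng is None:
        rng = np.random.default_rng(seed)
    spikes = np.asarray(spikes)
    single = spikes.ndim == 1
    counts = np.atleast_2d(spikes)

    theta_grid = np.linspace(-np.pi, np.pi, int(n_grid), endpoint=False)
    ll = log_likelihood(config, counts, theta_grid, N)
    if not np.all(np.isfinite(ll.max(axis=1))):
        raise ValueError("posterior is numerically degenerate (all -inf)")
    log_post = ll + np.log(np.maximum(config.prior.density(theta_grid), RATE_FLOOR))
    est, _ = _posterior_circmean(log_post, theta_grid, rng)
    return float(est[0]) if single else est


def simulate_trials(config: PopulationConfig, targets, N: int, reps: int = 1,
                    seed=None, n_grid: int = 100):
    """Simulate the encode -> spike -> decode pipeline.

    Each target is presented ``reps`` times; one seeded generator drives
    both spike sampling and degenerate-decode draws.

    Returns
    -------
    (targets_out, responses) : tuple of ndarray
        Flattened arrays of length ``len(targets) * reps``; row order is
        target-major (all reps of target 0, then target 1, ...).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    targets = np.atleast_1d(np.asarray(targets, dtype=float))
    rates = normalized_rates(config, targets, N)  # (K, M)
    mean = np.repeat(rates, reps, axis=0)
    counts = rng.poisson(mean)

    theta_grid = np.linspace(-np.pi, np.pi, int(n_grid), endpoint=False)
    log_rates = np.log(np.maximum(normalized_rates(config, theta_grid, N),
                                  RATE_FLOOR))
    log_prior = np.log(np.maximum(config.prior.density(theta_grid), RATE_FLOOR))
    ll = counts @ log_rates.T  # theta-independent terms dropped
    est, _ = _posterior_circmean(ll + log_prior, theta_grid, rng)
    return np.repeat(targets, reps), est
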