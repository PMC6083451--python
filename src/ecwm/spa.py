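"""Extended slots-plus-averaging model with stimulus-specific modulation.

``K`` fixed-precision slots are divided as evenly as possible among the
``N`` array items; items holding multiple slots average their copies, which
(in the high-concentration Gaussian approximation) adds concentrations.
When ``N > K`` some items get no slot and a probe of such an item produces
a uniform guess.  Stimulus-specific effects enter through two modulators:

* precision: ``kappa1(theta) = kappa1 * (1 - lam * |sin(theta)|)`` —
  maximal at cardinals, minimal at obliques;
* bias: ``mu(theta) = eta * sin(2*theta)`` — repulsive from the cardinals
  for positive ``eta``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import i0e

from ecwm.orientation import TWO_PI, wrap_angle

#: floor applied when precision modulation drives kappa1(theta) to zero
KAPPA_FLOOR = 1e-3


@dataclass(frozen=True)
class SPAParams:
    """Slots-plus-averaging parameters.

    K : slot count; kappa1 : single-slot concentration; eta : bias
    amplitude in [-1, 1]; lam : precision-modulation strength in [0, 1].
    """

    K: int
    kappa1: float
    eta: float = 0.0
    lam: float = 0.0

    def __post_init__(self):
        if int(self.K) != self.K or self.K < 1:
            raise ValueError("K must be a positive integer")
        if self.kappa1 <= 0:
            raise ValueError("kappa1 must be positive")
        if not -1.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [-1, 1]")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")


@dataclass(frozen=True)
class SlotAllocation:
    """Even-as-possible division of K slots among N items."""

    S_low: int
    S_high: int
    p_high: float
    guess_rate: float


def allocate(K: int, N: int) -> SlotAllocation:
    """Slot allocation for ``K`` slots and set size ``N``."""
    if K < 1 or N < 1:
        raise ValueError("K and N must be positive integers")
    s_low = K // N
    return SlotAllocation(
        S_low=s_low,
        S_high=s_low + 1,
        p_high=(K % N) / N,
        guess_rate=max(0.0, 1.0 - K / N),
    )


def kappa1_modulated(params: SPAParams, theta):
    """Orientation-dependent single-slot concentration, floored."""
    theta = np.asarray(theta, dtype=float)
    k = params.kappa1 * (1.0 - params.lam * np.abs(np.sin(theta)))
    return np.maximum(k, KAPPA_FLOOR)


def mu_bias(params: SPAParams, theta):
    """Orientation-dependent response bias ``eta * sin(2*theta)``."""
    return params.eta * np.sin(2.0 * np.asarray(theta, dtype=float))


def kappa_n(params: SPAParams, theta, N: int):
    """Effective concentration after slot averaging at set size ``N``.

    For ``N < K`` the weighted average over the S_low/S_high allocation
    collapses to ``(K / N) * kappa1(theta)``; for ``N >= K`` each stored
    item holds a single slot, ``kappa1(theta)``.
    """
    if N < 1:
        raise ValueError("N must be >= 1")
    k1 = kappa1_modulated(params, theta)
    if N < params.K:
        return (params.K / N) * k1
    return k1


def _vm_pdf(x, mu, kappa):
    """Von Mises density, exponentially scaled Bessel for stability."""
    return np.exp(kappa * (np.cos(x - mu) - 1.0)) / (TWO_PI * i0e(kappa))


def response_density(params: SPAParams, theta_target, N: int, theta_hat):
    """Probability density of response ``theta_hat`` to a given target.

    Mixture of a biased von Mises (stored item) and a uniform guess with
    weight ``guess_rate = max(0, 1 - K/N)``.
    """
    alloc = allocate(params.K, N)
    g = alloc.guess_rate
    theta_target = np.asarray(theta_target, dtype=float)
    theta_hat = np.asarray(theta_hat, dtype=float)
    mu = theta_target + mu_bias(params, theta_target)
    k = kappa_n(params, theta_target, N)
    return (1.0 - g) * _vm_pdf(theta_hat, mu, k) + g / TWO_PI


def sample_spa(params: SPAParams, targets, N: int, seed=None, rng=None):
    """Sample responses from the slots-plus-averaging mixture.

    Returns one response per target, wrapped into [-pi, pi).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    targets = np.atleast_1d(np.asarray(targets, dtype=float))
    alloc = allocate(params.K, N)
    n = targets.size
    mu = targets + mu_bias(params, targets)
    k = np.broadcast_to(kappa_n(params, targets, N), (n,))
    resp = mu + rng.vonmises(0.0, k)
    guess = rng.random(n) < alloc.guess_rate
    if np.any(guess):
        resp[guess] = rng.uniform(-np.pi, np.pi, size=guess.sum())
    return wrap_angle(resp)
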