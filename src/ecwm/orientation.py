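"""Circular coordinates, circular summary statistics, and kernel smoothing.

Orientation stimuli live on a half-circle of physical angles [-90, 90)
degrees, mapped onto the full circle [-pi, pi) radians by
``theta_rad = theta_deg * pi / 90``.  All internal computation uses mapped
radians; degrees appear only at the I/O boundary.

Bias is the (weighted) circular mean of recall error; precision is the
reciprocal of the squared circular standard deviation.  Curves of bias and
precision against target orientation are estimated at 50 evenly spaced
points with a von Mises kernel whose concentration is chosen so that the
kernel's circular SD equals the requested bandwidth ``h``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import i0e, i1e

TWO_PI = 2.0 * np.pi

#: number of evaluation points for smoothed bias/precision curves
N_EVAL_POINTS = 50

#: default kernel bandwidth (circular SD, radians) for bias curves
H_BIAS = 0.61
#: default kernel bandwidth (circular SD, radians) for precision curves
H_PRECISION = 0.23

#: floor on circular SD when all mass is concentrated at a point
_SD_FLOOR = 1e-6


def wrap_angle(theta):
    """Wrap angle(s) into [-pi, pi)."""
    return np.mod(np.asarray(theta, dtype=float) + np.pi, TWO_PI) - np.pi


def deg_to_rad(theta_deg):
    """Map stimulus degrees in [-90, 90) to circular radians in [-pi, pi)."""
    return wrap_angle(np.asarray(theta_deg, dtype=float) * np.pi / 90.0)


def rad_to_deg(theta_rad):
    """Map circular radians in [-pi, pi) back to stimulus degrees."""
    return wrap_angle(theta_rad) * 90.0 / np.pi


def circ_diff(a, b):
    """Signed circular difference ``a - b`` wrapped into [-pi, pi)."""
    return wrap_angle(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


@dataclass(frozen=True)
class CircularSummary:
    """Weighted circular mean/dispersion of a sample of angles.

    Attributes
    ----------
    mean : float
        Circular mean direction (radians in [-pi, pi)); the "bias".
    resultant_length : float
        Mean resultant length in [0, 1].
    circ_sd : float
        Circular standard deviation, ``sqrt(-2 ln R)``.
    precision : float
        ``1 / circ_sd**2``, capped when the sample is degenerate.
    n_effective : float
        Kish effective sample size of the weights.
    degenerate : bool
        True when the precision cap was applied (circ_sd below floor).
    """

    mean: float
    resultant_length: float
    circ_sd: float
    precision: float
    n_effective: float
    degenerate: bool = False


def circ_summary(errors, weights=None) -> CircularSummary:
    """Weighted circular mean, SD and precision of a set of angles.

    Parameters
    ----------
    errors : array-like of float
        Angles in radians (any real values; wrapped internally).
    weights : array-like of float, optional
        Nonnegative weights, at least one strictly positive.  Uniform
        weights are used if omitted.

    Raises
    ------
    ValueError
        If ``errors`` is empty, weights are negative, or all weights are 0.
    """
    errors = np.atleast_1d(np.asarray(errors, dtype=float))
    if errors.size == 0:
        raise ValueError("circ_summary requires at least one angle")
    if weights is None:
        weights = np.ones_like(errors)
    else:
        weights = np.atleast_1d(np.asarray(weights, dtype=float))
        if weights.shape != errors.shape:
            raise ValueError("weights must match errors in shape")
        if np.any(weights < 0):
            raise ValueError("weights must be nonnegative")
    wsum = weights.sum()
    if wsum <= 0:
        raise ValueError("at least one weight must be positive")

    z = np.sum(weights * np.exp(1j * errors)) / wsum
    mean = float(wrap_angle(np.angle(z)))
    r = float(min(abs(z), 1.0))
    if r <= 0.0:
        circ_sd = np.inf
    else:
        circ_sd = float(np.sqrt(-2.0 * np.log(r)))
    degenerate = circ_sd < _SD_FLOOR
    if degenerate:
        precision = 1.0 / _SD_FLOOR**2
    elif np.isinf(circ_sd):
        precision = 0.0
    else:
        precision = 1.0 / circ_sd**2
    n_eff = float(wsum**2 / np.sum(weights**2))
    return CircularSummary(
        mean=mean,
        resultant_length=r,
        circ_sd=circ_sd,
        precision=precision,
        n_effective=n_eff,
        degenerate=degenerate,
    )


def kappa_from_circular_sd(h: float) -> float:
    """Von Mises concentration whose circular SD equals ``h``.

    Solves ``I1(kappa)/I0(kappa) = exp(-h**2 / 2)`` numerically.
    """
    if h <= 0:
        raise ValueError("bandwidth h must be positive")
    target = np.exp(-0.5 * h * h)

    def f(k):
        return i1e(k) / i0e(k) - target

    lo, hi = 1e-8, 10.0
    if f(lo) >= 0:  # bandwidth so large the kernel is effectively uniform
        return lo
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e12:  # pragma: no cover - h effectively 0
            raise RuntimeError("failed to bracket kernel concentration")
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


@dataclass(frozen=True)
class SmoothedCurve:
    """Kernel-smoothed curve over the circular stimulus space.

    ``eval_points`` are 50 evenly spaced orientations in [-pi, pi);
    ``values`` holds the bias (radians) or precision (1/rad^2) at each
    point; ``n_effective`` the effective trial count entering each
    estimate; ``bandwidth`` the kernel circular SD used.
    """

    eval_points: np.ndarray
    values: np.ndarray
    bandwidth: float
    n_effective: np.ndarray

    def __post_init__(self):
        if len(self.eval_points) != len(self.values):
            raise ValueError("eval_points and values must have equal length")


def curve_eval_points(n: int = N_EVAL_POINTS) -> np.ndarray:
    """``n`` evenly spaced evaluation points over [-pi, pi)."""
    return np.linspace(-np.pi, np.pi, n, endpoint=False)


def smooth_curves(
    targets,
    errors,
    h_bias: float = H_BIAS,
    h_precision: float = H_PRECISION,
    n_points: int = N_EVAL_POINTS,
):
    """Kernel-smoothed bias and precision as functions of target orientation.

    At each of ``n_points`` evenly spaced orientations, trials are weighted
    by a von Mises kernel (circular SD ``h``) centred on the point and
    evaluated at each trial's target; bias is the weighted circular mean of
    the errors and precision comes from the weighted circular SD.  Kernel
    weights are renormalized at each evaluation point by the weighted-mean
    construction.

    Parameters
    ----------
    targets, errors : array-like of float
        Per-trial target orientation and recall error, radians.
    h_bias, h_precision : float
        Kernel circular SD for the bias and precision curves.
    n_points : int
        Number of evaluation points.

    Returns
    -------
    (SmoothedCurve, SmoothedCurve)
        Bias curve (radians) and precision curve (1/rad^2).
    """
    targets = np.atleast_1d(np.asarray(targets, dtype=float))
    errors = np.atleast_1d(np.asarray(errors, dtype=float))
    if targets.shape != errors.shape:
        raise ValueError("targets and errors must have the same length")
    if targets.size < 2:
        raise ValueError("smoothing requires at least 2 trials")

    points = curve_eval_points(n_points)

    def _curve(h, attr):
        kappa = kappa_from_circular_sd(h)
        # unnormalized von Mises kernel; circ_summary renormalizes
        w = np.exp(kappa * (np.cos(points[:, None] - targets[None, :]) - 1.0))
        vals = np.empty(n_points)
        neff = np.empty(n_points)
        for i in range(n_points):
            s = circ_summary(errors, w[i])
            vals[i] = getattr(s, attr)
            neff[i] = s.n_effective
        return SmoothedCurve(points, vals, h, neff)

    return _curve(h_bias, "mean"), _curve(h_precision, "precision")
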