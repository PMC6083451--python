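"""Normalized circular stimulus distributions and the CDF warping map.

Built-in priors on the mapped circular space [-pi, pi):

``uniform``
    Flat density 1/(2*pi).
``natural_cardinal``
    Density proportional to ``2 - |sin(theta)|``: bimodal with peaks at the
    cardinal orientations (theta = 0 and +/-pi, i.e. 0 and 90 degrees on the
    physical scale), approximating the distribution of orientations in
    natural scenes.
``adapt_cardinal``
    Alias of ``natural_cardinal`` (the congruent adaptation distribution).
``adapt_oblique``
    Density proportional to ``2 - |cos(theta)|``: peaks at the obliques
    (theta = +/-pi/2, i.e. +/-45 degrees), the incongruent adaptation
    distribution.
``custom``
    Arbitrary tabulated density, normalized and interpolated.

The warping map ``F(theta) = 2*pi*CDF(theta) - pi`` redistributes a
homogeneous population of tuning curves so that neural resources follow the
stimulus prior: more, and narrower, tuning functions where the prior is
dense.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import PchipInterpolator

from ecwm.orientation import TWO_PI, wrap_angle

_BUILTIN_KINDS = ("uniform", "natural_cardinal", "adapt_cardinal", "adapt_oblique")

# normalizer of 2 - |sin| (and 2 - |cos|) over [-pi, pi)
_BIMODAL_NORM = 4.0 * np.pi - 4.0

#: default tabulation resolution for custom priors / inverse CDF
DEFAULT_GRID = 4096


def _density_uniform(theta):
    return np.full_like(np.asarray(theta, dtype=float), 1.0 / TWO_PI)


def _density_cardinal(theta):
    theta = np.asarray(theta, dtype=float)
    return (2.0 - np.abs(np.sin(theta))) / _BIMODAL_NORM


def _density_oblique(theta):
    theta = np.asarray(theta, dtype=float)
    return (2.0 - np.abs(np.cos(theta))) / _BIMODAL_NORM


def _cdf_uniform(theta):
    theta = np.asarray(theta, dtype=float)
    return (theta + np.pi) / TWO_PI


def _cdf_cardinal(theta):
    # integral of |sin| from -pi to theta, piecewise in the sign of sin
    theta = np.asarray(theta, dtype=float)
    b = np.where(theta <= 0.0, np.cos(theta) + 1.0, 3.0 - np.cos(theta))
    return (2.0 * (theta + np.pi) - b) / _BIMODAL_NORM


def _cdf_oblique(theta):
    # integral of |cos| from -pi to theta; sign changes at +/- pi/2
    theta = np.asarray(theta, dtype=float)
    c = np.where(
        theta <= -np.pi / 2,
        -np.sin(theta),
        np.where(theta <= np.pi / 2, 2.0 + np.sin(theta), 4.0 - np.sin(theta)),
    )
    return (2.0 * (theta + np.pi) - c) / _BIMODAL_NORM


class Prior:
    """A normalized circular stimulus distribution on [-pi, pi).

    Parameters
    ----------
    kind : str
        One of ``uniform``, ``natural_cardinal``, ``adapt_cardinal``,
        ``adapt_oblique``, ``custom``.
    theta : array-like, optional
        Tabulation angles for ``custom`` priors (need not be sorted or
        normalized; must cover [-pi, pi)).
    density : array-like, optional
        Nonnegative density values matching ``theta`` for ``custom``.
    grid_resolution : int
        Number of tabulation points used for the inverse CDF (and, for
        ``custom`` priors, the density/CDF tables).

    Notes
    -----
    Built-in priors use closed-form densities and CDFs; ``custom`` priors
    tabulate on a dense grid with monotone (PCHIP) interpolation of the
    cumulative, which tolerates kinked densities.
    """

    def __init__(self, kind="uniform", theta=None, density=None,
                 grid_resolution=DEFAULT_GRID):
        if kind not in _BUILTIN_KINDS + ("custom",):
            raise ValueError(f"unknown prior kind: {kind!r}")
        self.kind = kind
        self.grid_resolution = int(grid_resolution)
        if self.grid_resolution < 16:
            raise ValueError("grid_resolution too small")

        if kind == "custom":
            if theta is None or density is None:
                raise ValueError("custom prior requires theta and density tables")
            theta = wrap_angle(np.asarray(theta, dtype=float))
            density = np.asarray(density, dtype=float)
            if theta.shape != density.shape or theta.size < 4:
                raise ValueError("theta/density tables invalid")
            if np.any(density < 0):
                raise ValueError("density must be nonnegative")
            order = np.argsort(theta)
            theta, density = theta[order], density[order]
            # resample periodically onto the dense internal grid
            grid = np.linspace(-np.pi, np.pi, self.grid_resolution + 1)
            ext_t = np.concatenate([theta - TWO_PI, theta, theta + TWO_PI])
            ext_d = np.tile(density, 3)
            dens = np.interp(grid, ext_t, ext_d)
            area = np.trapezoid(dens, grid)
            if area <= 0:
                raise ValueError("density integrates to zero")
            dens /= area
            self._grid = grid
            self._dens = dens
            cum = np.concatenate(
                [[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(grid))]
            )
            cum /= cum[-1]
            self._cum = cum
            self._cdf_interp = PchipInterpolator(grid, cum)
        else:
            self._grid = np.linspace(-np.pi, np.pi, self.grid_resolution + 1)
            self._dens = self._density_fn()(self._grid)
            self._cum = self._cdf_fn()(self._grid)

    def _density_fn(self):
        return {
            "uniform": _density_uniform,
            "natural_cardinal": _density_cardinal,
            "adapt_cardinal": _density_cardinal,
            "adapt_oblique": _density_oblique,
        }[self.kind]

    def _cdf_fn(self):
        return {
            "uniform": _cdf_uniform,
            "natural_cardinal": _cdf_cardinal,
            "adapt_cardinal": _cdf_cardinal,
            "adapt_oblique": _cdf_oblique,
        }[self.kind]

    # -- public surface ----------------------------------------------------

    def density(self, theta):
        """Probability density (1/radians) at ``theta`` (wrapped)."""
        theta = wrap_angle(theta)
        if self.kind == "custom":
            return np.interp(theta, self._grid, self._dens)
        return self._density_fn()(theta)

    def cdf(self, theta):
        """Cumulative distribution from -pi; cdf(-pi)=0, cdf(pi)=1.

        ``theta`` is clipped to [-pi, pi] (no wrapping: the CDF is a
        function on the fundamental interval, not a periodic one).
        """
        theta = np.clip(np.asarray(theta, dtype=float), -np.pi, np.pi)
        if self.kind == "custom":
            return np.clip(self._cdf_interp(theta), 0.0, 1.0)
        return np.clip(self._cdf_fn()(theta), 0.0, 1.0)

    def warp(self, theta):
        """Efficient-coding warping map ``F(theta) = 2*pi*cdf(theta) - pi``."""
        if self.kind == "uniform":
            # exact identity: guarantees the warped population reduces
            # bitwise to the homogeneous code
            return np.clip(np.asarray(theta, dtype=float), -np.pi, np.pi)
        return TWO_PI * self.cdf(theta) - np.pi

    def warp_inverse(self, x):
        """Inverse of :meth:`warp` via the tabulated quantile function."""
        u = (np.clip(np.asarray(x, dtype=float), -np.pi, np.pi) + np.pi) / TWO_PI
        return self._quantile(u)

    def _quantile(self, u):
        u = np.asarray(u, dtype=float)
        # _cum is monotone nondecreasing on the dense grid
        return np.interp(u, self._cum, self._grid)

    def sample(self, n, seed=None, rng=None):
        """Draw ``n`` angles by inverse-CDF sampling.

        Either a ``seed`` (int) or an existing ``numpy.random.Generator``
        may be supplied; the generator takes precedence.
        """
        if n < 1:
            raise ValueError("n must be >= 1")
        if rng is None:
            rng = np.random.default_rng(seed)
        u = rng.random(int(n))
        return wrap_angle(self._quantile(u))

    # -- serialization -----------------------------------------------------

    def to_config(self):
        """Small config block (round-trips through :meth:`from_config`)."""
        cfg = {"kind": self.kind, "grid_resolution": self.grid_resolution}
        if self.kind == "custom":
            cfg["theta_rad"] = self._grid.tolist()
            cfg["density"] = self._dens.tolist()
        return cfg

    @classmethod
    def from_config(cls, cfg):
        kind = cfg["kind"]
        if kind == "custom":
            return cls(
                kind,
                theta=cfg["theta_rad"],
                density=cfg["density"],
                grid_resolution=cfg.get("grid_resolution", DEFAULT_GRID),
            )
        return cls(kind, grid_resolution=cfg.get("grid_resolution", DEFAULT_GRID))

    def __repr__(self):
        return f"Prior(kind={self.kind!r})"
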