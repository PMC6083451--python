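"""Binned maximum-likelihood fitting of response models by grid search.

A model's predictions at one set size are summarized by a row-stochastic
J x Q stimulus-by-response matrix: J evenly spaced target orientations,
responses histogrammed into Q equal bins over [-pi, pi).  Observer trials
are binned the same way (targets to the nearest stimulus bin center) and
the summed log of the matrix entries is the fit criterion.  The neural
model's matrices are estimated by Monte Carlo simulation with common
random numbers across the parameter grid; the slots-plus-averaging model
admits exact bin probabilities (per-bin Gauss-Legendre quadrature of the
analytic mixture density), with a simulation path retained for strict
replication.  Models are compared by AIC = -2 lnL + 2P.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from ecwm.orientation import TWO_PI, circ_diff, wrap_angle
from ecwm.neural import PopulationConfig, simulate_trials
from ecwm.spa import SPAParams, allocate, kappa_n, mu_bias, response_density, sample_spa

#: default stimulus / response bin counts
J_BINS = 25
Q_BINS = 25

#: default Monte-Carlo responses per stimulus bin
DEFAULT_REPS = 10_000

#: pseudo-count added to each histogram cell before row normalization
PSEUDO_COUNT = 0.5

#: Gauss-Legendre nodes per response bin for analytic SPA probabilities
_GL_ORDER = 24


def stimulus_centers(J: int = J_BINS) -> np.ndarray:
    """J stimulus bin centers, evenly spaced and half-bin offset from -pi."""
    return -np.pi + (np.arange(J) + 0.5) * TWO_PI / J


def response_edges(Q: int = Q_BINS) -> np.ndarray:
    """Q+1 response bin edges spanning [-pi, pi]."""
    return np.linspace(-np.pi, np.pi, Q + 1)


def assign_stimulus_bin(targets, J: int = J_BINS) -> np.ndarray:
    """Index of the nearest stimulus bin center (circular distance)."""
    centers = stimulus_centers(J)
    d = np.abs(circ_diff(np.asarray(targets, dtype=float)[:, None], centers[None, :]))
    return np.argmin(d, axis=1)


def assign_response_bin(responses, Q: int = Q_BINS) -> np.ndarray:
    """Histogram bin index of each response."""
    r = wrap_angle(responses)
    q = np.floor((r + np.pi) / (TWO_PI / Q)).astype(int)
    return np.clip(q, 0, Q - 1)


@dataclass(frozen=True)
class ResponseMatrix:
    """Row-stochastic stimulus-by-response probability table for one set size."""

    probs: np.ndarray
    N: int
    J: int = J_BINS
    Q: int = Q_BINS

    def __post_init__(self):
        if self.probs.shape != (self.J, self.Q):
            raise ValueError("probs must have shape (J, Q)")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("rows must sum to 1")
        if np.any(self.probs <= 0):
            raise ValueError("entries must be positive after smoothing")


@dataclass(frozen=True)
class GridSpec:
    """Parameter grids for both model families.

    ``full`` grids follow the reference settings (neural: 100 x 100 over
    kappa 0.1..10 x gamma 1..100; SPA: K 1..10 x kappa1 0.1..10 x
    eta -1..1 x lam 0..1, all in 0.1 steps).  Reduced grids are allowed
    for testing and flagged via ``is_full = False``.
    """

    neural_kappa: np.ndarray
    neural_gamma: np.ndarray
    spa_K: np.ndarray
    spa_kappa1: np.ndarray
    spa_eta: np.ndarray
    spa_lam: np.ndarray
    is_full: bool = False

    @classmethod
    def full(cls):
        return cls(
            neural_kappa=np.round(np.arange(1, 101) * 0.1, 10),
            neural_gamma=np.arange(1, 101, dtype=float),
            spa_K=np.arange(1, 11),
            spa_kappa1=np.round(np.arange(1, 101) * 0.1, 10),
            spa_eta=np.round(np.arange(-10, 11) * 0.1, 10),
            spa_lam=np.round(np.arange(0, 11) * 0.1, 10),
            is_full=True,
        )

    @classmethod
    def coarse(cls):
        return cls(
            neural_kappa=np.round(np.linspace(0.5, 10.0, 20), 10),
            neural_gamma=np.round(np.linspace(5.0, 100.0, 20), 10),
            spa_K=np.arange(1, 11),
            spa_kappa1=np.round(np.arange(1, 11, dtype=float), 10),
            spa_eta=np.round(np.arange(-10, 11, 2) * 0.1, 10),
            spa_lam=np.round(np.arange(0, 11, 2) * 0.1, 10),
            is_full=False,
        )


@dataclass(frozen=True)
class FitResult:
    """Outcome of a grid search for one observer and one model family."""

    model_id: str
    params: dict
    loglik: float
    aic: float
    loglik_by_set_size: dict
    grid_meta: dict = field(default_factory=dict)
    seed: int | None = None

    N_PARAMS = {"neural": 2, "spa": 4}

    def to_dict(self):
        return {
            "model_id": self.model_id,
            "params": self.params,
            "loglik": self.loglik,
            "aic": self.aic,
            "loglik_by_set_size": {str(k): v for k, v in
                                   self.loglik_by_set_size.items()},
            "grid_meta": self.grid_meta,
            "seed": self.seed,
        }


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion, -2 lnL + 2P."""
    return -2.0 * loglik + 2.0 * n_params


# ---------------------------------------------------------------------------
# response matrices
# ---------------------------------------------------------------------------

def _histogram_matrix(targets_idx, responses, J, Q):
    counts = np.zeros((J, Q))
    q = assign_response_bin(responses, Q)
    np.add.at(counts, (targets_idx, q), 1.0)
    counts += PSEUDO_COUNT
    return counts / counts.sum(axis=1, keepdims=True)


def _spa_bin_probs(params: SPAParams, N: int, J: int, Q: int) -> np.ndarray:
    """Exact J x Q bin probabilities for the SPA mixture.

    Integrates the von Mises component over each response bin with
    Gauss-Legendre quadrature; the uniform guess component contributes
    ``guess_rate / Q`` per bin exactly.
    """
    centers = stimulus_centers(J)
    edges = response_edges(Q)
    g = allocate(params.K, N).guess_rate
    mu = centers + mu_bias(params, centers)  # (J,)
    kap = np.broadcast_to(kappa_n(params, centers, N), (J,))

    nodes, weights = np.polynomial.legendre.leggauss(_GL_ORDER)
    half = (edges[1] - edges[0]) / 2.0
    mid = (edges[:-1] + edges[1:]) / 2.0  # (Q,)
    x = mid[None, :, None] + half * nodes[None, None, :]  # (1, Q, G)

    from scipy.special import i0e

    z = np.exp(kap[:, None, None] * (np.cos(x - mu[:, None, None]) - 1.0))
    z /= TWO_PI * i0e(kap)[:, None, None]
    vm_probs = half * (z * weights[None, None, :]).sum(axis=2)  # (J, Q)
    probs = (1.0 - g) * vm_probs + g / Q
    return probs / probs.sum(axis=1, keepdims=True)


def build_response_matrix(model, N: int, J: int = J_BINS, Q: int = Q_BINS,
                          reps: int = DEFAULT_REPS, seed=None,
                          method: str = "auto", n_grid: int = 100) -> ResponseMatrix:
    """Stimulus-by-response matrix for one model at one set size.

    Parameters
    ----------
    model : PopulationConfig or SPAParams
        The generative model.
    method : {"auto", "simulate", "analytic"}
        ``analytic`` is exact and available for SPA models only; ``auto``
        picks analytic for SPA and simulation for the neural model.
    reps : int
        Monte-Carlo responses per stimulus bin for the simulation path.
    """
    is_spa = isinstance(model, SPAParams)
    if method == "auto":
        method = "analytic" if is_spa else "simulate"
    if method == "analytic":
        if not is_spa:
            raise ValueError("analytic matrices are available for SPA models only")
        probs = _spa_bin_probs(model, N, J, Q)
        return ResponseMatrix(probs=probs, N=N, J=J, Q=Q)

    if reps < 100:
        raise ValueError("reps must be >= 100")
    centers = stimulus_centers(J)
    if is_spa:
        rng = np.random.default_rng(seed)
        targets = np.repeat(centers, reps)
        responses = sample_spa(model, targets, N, rng=rng)
        idx = np.repeat(np.arange(J), reps)
    else:
        _, responses = simulate_trials(model, centers, N, reps=reps, seed=seed,
                                       n_grid=n_grid)
        idx = np.repeat(np.arange(J), reps)
    probs = _histogram_matrix(idx, responses, J, Q)
    return ResponseMatrix(probs=probs, N=N, J=J, Q=Q)


# ---------------------------------------------------------------------------
# binned likelihood
# ---------------------------------------------------------------------------

def trial_cell_counts(trials, J: int = J_BINS, Q: int = Q_BINS) -> dict:
    """Aggregate a trial table into per-set-size (J, Q) count matrices."""
    out = {}
    for N, sub in trials.groupby("set_size"):
        j = assign_stimulus_bin(sub["target"].to_numpy(), J)
        q = assign_response_bin(sub["response"].to_numpy(), Q)
        counts = np.zeros((J, Q))
        np.add.at(counts, (j, q), 1.0)
        out[int(N)] = counts
    return out


def bin_loglik(matrices: dict, trials) -> float:
    """Summed log-likelihood of a trial table under per-set-size matrices.

    Each trial's target is assigned to the nearest stimulus bin center and
    its response to its histogram bin; the contribution is the log of the
    corresponding matrix entry.
    """
    if len(trials) == 0:
        return 0.0
    total = 0.0
    for N, counts in trial_cell_counts(trials).items():
        if N not in matrices:
            raise KeyError(f"no response matrix for set size {N}")
        m = matrices[N]
        total += float(np.sum(counts * np.log(m.probs)))
    return total


def _loglik_from_counts(probs: np.ndarray, counts: np.ndarray) -> float:
    return float(np.sum(counts * np.log(probs)))


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

def fit_grid(model_family: str, trials, grid: GridSpec | None = None,
             seed=None, reps: int = DEFAULT_REPS, J: int = J_BINS,
             Q: int = Q_BINS, M: int = 100, prior=None,
             n_grid: int = 100, refine_reps: int | None = None,
             refine_top: int = 10, progress: bool = False) -> FitResult:
    """Maximum-likelihood grid search for one observer.

    Parameters
    ----------
    model_family : {"neural", "spa"}
    trials : pandas.DataFrame
        Columns ``set_size``, ``target``, ``response`` (radians).
    grid : GridSpec
        Defaults to :meth:`GridSpec.coarse`.
    seed : int
        Controls the Monte-Carlo noise of the neural path.  The same spike
        stream (common random numbers) is reused at every grid point, so
        refitting with the same seed reproduces the identical result.
    reps : int
        Simulated responses per stimulus bin (neural path).
    M, prior
        Population size and stimulus prior for the neural model
        (default ``natural_cardinal``).
    refine_reps : int, optional
        Two-stage neural search: after the full-grid pass at ``reps``,
        re-evaluate the ``refine_top`` best grid points at this higher
        rep count (fresh CRN stream) and take the refined argmax.  Cuts
        the Monte-Carlo noise of the winner at a fraction of the cost of
        running the whole grid at high reps.

    Returns
    -------
    FitResult
    """
    if len(trials) == 0:
        raise ValueError("trials must be nonempty")
    if grid is None:
        grid = GridSpec.coarse()
    cell_counts = trial_cell_counts(trials, J, Q)
    set_sizes = sorted(cell_counts)
    grid_meta = {"is_full": bool(grid.is_full), "J": J, "Q": Q}

    if model_family == "neural":
        from ecwm.priors import Prior

        if prior is None:
            prior = Prior("natural_cardinal")
        # one sub-seed per set size, identical across grid points (CRN);
        # the refinement stage gets its own independent streams
        ss = np.random.SeedSequence(seed)
        children = ss.spawn(2 * len(set_sizes))
        sub_seeds = dict(zip(set_sizes, children[:len(set_sizes)]))
        refine_seeds = dict(zip(set_sizes, children[len(set_sizes):]))

        def _eval(kappa, gamma, n_reps, seeds):
            config = PopulationConfig(M=M, kappa=float(kappa),
                                      gamma=float(gamma), prior=prior)
            by_n = {}
            for N in set_sizes:
                m = build_response_matrix(
                    config, N, J, Q, reps=n_reps,
                    seed=np.random.default_rng(seeds[N]),
                    method="simulate", n_grid=n_grid)
                by_n[N] = _loglik_from_counts(m.probs, cell_counts[N])
            return by_n

        results = []
        for kappa, gamma in itertools.product(grid.neural_kappa,
                                              grid.neural_gamma):
            by_n = _eval(kappa, gamma, reps, sub_seeds)
            results.append((sum(by_n.values()), float(kappa), float(gamma),
                            by_n))
        results.sort(key=lambda t: -t[0])

        if refine_reps is not None and refine_reps > reps:
            refined = []
            for _, kappa, gamma, _ in results[:refine_top]:
                by_n = _eval(kappa, gamma, refine_reps, refine_seeds)
                refined.append((sum(by_n.values()), kappa, gamma, by_n))
            refined.sort(key=lambda t: -t[0])
            results = refined
            grid_meta["refine_reps"] = int(refine_reps)
            grid_meta["refine_top"] = int(refine_top)

        ll, kappa, gamma, by_n = results[0]
        params = {"kappa": kappa, "gamma": gamma}
        grid_meta["shape"] = [len(grid.neural_kappa), len(grid.neural_gamma)]
        return FitResult("neural", params, ll, aic(ll, 2), by_n, grid_meta,
                         seed=seed)

    if model_family == "spa":
        best = (-np.inf, None, None)
        for K in grid.spa_K:
            for kappa1, eta, lam in itertools.product(
                    grid.spa_kappa1, grid.spa_eta, grid.spa_lam):
                params = SPAParams(K=int(K), kappa1=float(kappa1),
                                   eta=float(eta), lam=float(lam))
                by_n = {}
                for N in set_sizes:
                    probs = _spa_bin_probs(params, N, J, Q)
                    by_n[N] = _loglik_from_counts(probs, cell_counts[N])
                ll = sum(by_n.values())
                if ll > best[0]:
                    best = (ll, params, by_n)
        ll, params, by_n = best
        grid_meta["shape"] = [len(grid.spa_K), len(grid.spa_kappa1),
                              len(grid.spa_eta), len(grid.spa_lam)]
        return FitResult(
            "spa",
            {"K": params.K, "kappa1": params.kappa1, "eta": params.eta,
             "lam": params.lam},
            ll, aic(ll, 4), by_n, grid_meta, seed=seed)

    raise ValueError(f"unknown model family: {model_family!r}")


def compare(fits_by_observer: dict) -> dict:
    """AIC comparison across observers.

    Parameters
    ----------
    fits_by_observer : dict
        Maps observer id -> dict with keys ``neural`` and ``spa`` holding
        :class:`FitResult` objects.

    Returns
    -------
    dict with ``per_observer`` (list of dicts with ``delta_aic`` =
    AIC_neural - AIC_spa; negative favors the neural model),
    ``summed_delta_aic`` and preferred-model counts.
    """
    rows = []
    for obs, fits in fits_by_observer.items():
        if "neural" not in fits or "spa" not in fits:
            raise ValueError(f"observer {obs!r} needs both model fits")
        d = fits["neural"].aic - fits["spa"].aic
        rows.append({
            "subject": obs,
            "aic_neural": fits["neural"].aic,
            "aic_spa": fits["spa"].aic,
            "delta_aic": d,
        })
    total = sum(r["delta_aic"] for r in rows)
    n_neural = sum(1 for r in rows if r["delta_aic"] < 0)
    return {
        "per_observer": rows,
        "summed_delta_aic": total,
        "n_prefer_neural": n_neural,
        "n_prefer_spa": len(rows) - n_neural,
    }


# ---------------------------------------------------------------------------
# model-prediction curves
# ---------------------------------------------------------------------------

def prediction_curves(model, N: int, samples_per_target: int,
                      n_points: int = 100, reps: int = DEFAULT_REPS,
                      resamples: int = 500, seed=None, n_grid: int = 100):
    """Resampled bias and precision curves predicted by a fitted model.

    Simulates ``reps`` responses at each of ``n_points`` evenly spaced
    targets, then repeatedly subsamples ``samples_per_target`` responses
    (matching the empirical responses-per-binned-target count), computes
    the circular mean and precision at each point, and averages over
    ``resamples`` repetitions.

    Returns
    -------
    dict with ``points``, ``bias`` and ``precision`` arrays (length
    ``n_points``).
    """
    if samples_per_target < 2:
        raise ValueError("samples_per_target must be >= 2")
    rng = np.random.default_rng(seed)
    points = np.linspace(-np.pi, np.pi, n_points, endpoint=False)
    if isinstance(model, SPAParams):
        targets = np.repeat(points, reps)
        responses = sample_spa(model, targets, N, rng=rng)
    else:
        _, responses = simulate_trials(
            model, points, N, reps=reps,
            seed=rng.integers(2**63), n_grid=n_grid)
    errors = circ_diff(responses, np.repeat(points, reps)).reshape(n_points, reps)

    m = min(samples_per_target, reps)
    bias = np.zeros(n_points)
    precision = np.zeros(n_points)
    for i in range(n_points):
        if m >= reps:
            # subsample covers the full simulation: resampling is a no-op
            idx = np.tile(np.arange(reps), (resamples, 1))
        else:
            idx = rng.integers(0, reps, size=(resamples, m))
        z = np.exp(1j * errors[i][idx]).mean(axis=1)
        means = np.angle(z)
        r = np.clip(np.abs(z), 1e-12, 1.0 - 1e-15)
        prec = 1.0 / (-2.0 * np.log(r))
        bias[i] = np.angle(np.exp(1j * means).mean())
        precision[i] = prec.mean()
    return {"points": points, "bias": bias, "precision": precision}
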