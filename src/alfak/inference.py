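"""Karyotype fitness landscape inference from longitudinal count data.

The pipeline estimates a local fitness landscape in four stages:

1. **Frequent-clone fitness** — karyotypes observed at least ``min_obs`` times
   across all passages form the frequent set S. Their fitness is governed by
   the continuous-time replicator equation

       dx_i/dt = x_i [ f_i - sum_j x_j f_j ],

   whose closed-form solution x_i(t) = x_i(0) exp(f_i t) / Z(t) makes the
   log-frequency trajectories linear in time up to a shared offset. Stage 1
   solves the count-weighted log-linear least-squares problem this implies
   (a convex program), and stage 2 refines the estimates by maximizing the
   multinomial likelihood of the observed counts under the replicator
   solution. Only fitness *differences* are identified; a growth-offset
   correction pins the absolute scale.

2. **Neighbor fitness** — karyotypes one missegregation from S are too rare
   for direct estimation. Their frequency obeys an influx-growth balance

       dx_i/dt ≈ sum_{j in S} P(a_i | a_j) f_j x_j(t)  +  f_i x_i(t),

   where P is the per-division missegregation kernel and f_j x_j the parental
   division flux. Each neighbor fitness is fit by bounded scalar maximization
   of a binomial observation likelihood plus a normal prior
   N(f_i - f_j | mu_delta, sigma_delta^2) over its distance-1 frequent
   parents. Observing *no* cells of a neighbor is informative: it caps the
   fitness consistent with the influx it must have received.

3. **Kriging interpolation** — frequent and neighbor estimates anchor a
   Gaussian-process (Matern, nu = 1.5) regression over raw copy-number
   vectors, which supplies fitness for every karyotype within ``radius``
   missegregations of S (the charted region).

4. **Internal consistency (CV score)** — each frequent anchor is left out in
   turn, the GP is refit on the remainder and the held-out fitness predicted;
   CV score = 1 - SSE/SST is a leave-one-out predictive R^2 (max 1.0,
   unbounded below). Positive scores indicate a landscape that explains its
   own training anchors better than their mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import binom, norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern

from .karyotype import charted_region, manhattan_distance, one_step_neighbors
from .missegregation import MissegregationModel, transition_probability


# --------------------------------------------------------------------------
# containers


@dataclass
class LongitudinalCounts:
    """Per-passage karyotype counts at strictly increasing times (days)."""

    times: np.ndarray
    tables: list  # list of dict karyotype -> count, parallel to times

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) != len(self.tables):
            raise ValueError("times and tables must have equal length")
        if len(self.times) >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("passage times must be strictly increasing")
        clean = []
        for tab in self.tables:
            d = {}
            for k, c in tab.items():
                if c < 0:
                    raise ValueError(f"negative count for karyotype {k}")
                if c > 0:
                    d[tuple(k)] = int(c)
            clean.append(d)
        self.tables = clean

    @property
    def n_passages(self) -> int:
        return len(self.times)

    @property
    def totals(self) -> np.ndarray:
        return np.array([sum(t.values()) for t in self.tables], dtype=float)

    def karyotypes(self) -> set:
        out = set()
        for tab in self.tables:
            out.update(tab)
        return out

    def total_count(self, k) -> int:
        k = tuple(k)
        return sum(tab.get(k, 0) for tab in self.tables)

    def count_matrix(self, karyotypes: Sequence) -> np.ndarray:
        """(n_passages, len(karyotypes)) matrix of observed counts."""
        return np.array(
            [[tab.get(tuple(k), 0) for k in karyotypes] for tab in self.tables],
            dtype=float,
        )

    @classmethod
    def from_records(cls, records) -> "LongitudinalCounts":
        """Build from a list of ABM :class:`~alfak.abm.PassageRecord`."""
        return cls(
            times=[r.time for r in records],
            tables=[dict(r.sample) for r in records],
        )


@dataclass
class InferenceConfig:
    """Tunable parameters of the inference pipeline.

    min_obs
        Total-count threshold defining the frequent set S.
    p
        Missegregation probability per copy per division assumed during
        neighbor-flux inference (default 7.5e-4, a literature-scale average;
        inferred fitness slopes are coupled to this value).
    mu_delta, sigma_delta
        Mean and SD (1/day) of the normal prior on neighbor-minus-parent
        fitness differences.
    nugget
        Observation-noise variance added to the GP diagonal.
    radius
        Charted-region radius in missegregations (default 2).
    baseline_growth
        Net growth rate (1/day) assigned to the abundance-weighted mean
        fitness at the first passage by the growth-offset correction.
    """

    min_obs: int = 10
    p: float = 0.00075
    mu_delta: float = 0.0
    sigma_delta: float = 0.1
    kernel_nu: float = 1.5
    nugget: float = 1e-3
    radius: int = 2
    n_boot: int = 200
    baseline_growth: float = 0.5

    def __post_init__(self):
        if self.min_obs < 1:
            raise ValueError("min_obs must be >= 1")
        if self.sigma_delta <= 0:
            raise ValueError("sigma_delta must be > 0")
        if self.radius < 1:
            raise ValueError("radius must be >= 1")


@dataclass
class FrequentFit:
    """Replicator-based fitness estimates for the frequent set S."""

    karyotypes: list
    fitness: np.ndarray  # aligned with karyotypes
    x0: np.ndarray  # initial frequencies on the S-simplex
    t0: float
    converged: bool
    loglik: float

    def as_dict(self) -> dict:
        return {k: float(f) for k, f in zip(self.karyotypes, self.fitness)}


class KrigingModel:
    """Thin wrapper over a Matern-kernel Gaussian process regression.

    Inputs are raw 22-D copy-number vectors with a single isotropic
    length-scale fit by marginal-likelihood maximization (unless frozen).
    """

    def __init__(
        self,
        X: np.ndarray,
        y: np.ndarray,
        nugget=1e-3,
        nu: float = 1.5,
        length_scale: float = 3.0,
        optimize: bool = True,
    ):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if len(X) < 3:
            raise ValueError("kriging requires at least 3 anchors")
        if len(np.unique(X, axis=0)) < 3:
            raise ValueError("degenerate anchors: fewer than 3 distinct karyotypes")
        # the length-scale floor of 1.0 reflects the integer lattice: anchor
        # pairs are never closer than one missegregation; the fitted constant
        # factor (signal variance) lets long length scales represent smooth
        # large-scale trends
        kernel = ConstantKernel(1.0, (1e-3, 1e4)) * Matern(
            length_scale=length_scale, length_scale_bounds=(1.0, 1e3), nu=nu
        )
        alpha = np.maximum(np.asarray(nugget, dtype=float), 1e-10)
        # normalize_y rescales targets to unit variance, so express the
        # observation-noise variance relative to the anchor variance
        yvar = float(np.var(y))
        if yvar > 0:
            alpha = alpha / yvar
        if alpha.ndim == 0:
            alpha = float(alpha)
        self._alpha = alpha
        self.gp = GaussianProcessRegressor(
            kernel=kernel,
            alpha=alpha,
            normalize_y=True,
            optimizer="fmin_l_bfgs_b" if optimize else None,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            self.gp.fit(X, y)

    @property
    def length_scale(self) -> float:
        return float(self.gp.kernel_.k2.length_scale)

    def predict(self, karyotypes) -> tuple:
        """Return (mean, sd) arrays of fitness predictions."""
        X = np.asarray([tuple(k) for k in karyotypes], dtype=float)
        mean, sd = self.gp.predict(X, return_std=True)
        return mean, sd


@dataclass
class FittedLandscape:
    """Output of the full pipeline: anchors, GP, LUT and CV score."""

    frequent: dict  # karyotype -> fitness (absolute, 1/day)
    neighbors: dict  # karyotype -> fitness
    gp: Optional[KrigingModel]
    lut: dict  # karyotype -> fitness over the charted region
    source: dict  # karyotype -> {"frequent","neighbor","interpolated"}
    cv_score: float
    config: InferenceConfig
    lut_sd: dict = field(default_factory=dict)
    frequent_ci: Optional[dict] = None

    def fitness(self, k) -> Optional[float]:
        return self.lut.get(tuple(k))

    def as_lut(self, out_of_table: str = "lethal"):
        from .abm import LUTLandscape

        return LUTLandscape(table=dict(self.lut), out_of_table=out_of_table)


# --------------------------------------------------------------------------
# stage 1 + 2: frequent-clone fitness


def identify_frequent_clones(counts: LongitudinalCounts, min_obs: int) -> list:
    """Karyotypes whose summed count across passages is >= min_obs.

    Returned sorted by total count (descending, karyotype as tie-break) so
    downstream stages are deterministic.
    """
    totals = {k: counts.total_count(k) for k in counts.karyotypes()}
    S = [k for k, c in totals.items() if c >= min_obs]
    if not S:
        raise ValueError(
            f"no karyotype reaches min_obs={min_obs}; lower the threshold"
        )
    return sorted(S, key=lambda k: (-totals[k], k))


def replicator_solution(
    f: np.ndarray, x0: np.ndarray, times: np.ndarray, t0: float = 0.0
) -> np.ndarray:
    """Closed-form replicator frequencies x_i(t) at the requested times.

    x_i(t) = x_i(0) exp(f_i (t - t0)) / sum_j x_j(0) exp(f_j (t - t0));
    the result rows lie on the simplex to machine precision.
    """
    f = np.asarray(f, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if abs(x0.sum() - 1.0) > 1e-8 or np.any(x0 < -1e-12):
        raise ValueError("x0 must lie on the probability simplex")
    dt = times - t0
    # shift by the max exponent for numerical stability
    expo = np.outer(dt, f)
    expo -= expo.max(axis=1, keepdims=True)
    w = x0[None, :] * np.exp(expo)
    return w / w.sum(axis=1, keepdims=True)


def _stage1_weighted_lsq(counts, S, times):
    """Count-weighted log-linear least squares (the convex stage-1 problem).

    Under the replicator solution, log x_i(t) - log x_i(t0) =
    f_i (t - t0) - c(t) with a clone-independent offset c(t). Observed
    frequencies (with a +0.5 continuity correction for zeros) give a linear
    model in (f, c); counts serve as weights. The count-weighted mean of f is
    pinned to zero as the identifiability gauge.
    """
    C = counts.count_matrix(S)  # (T, m)
    T, m = C.shape
    xhat = (C + 0.5) / (C + 0.5).sum(axis=1, keepdims=True)
    dlog = np.log(xhat) - np.log(xhat[0])[None, :]
    rows = []
    rhs = []
    wts = []
    for t in range(1, T):
        dt = times[t] - times[0]
        for i in range(m):
            row = np.zeros(m + T - 1)
            row[i] = dt
            row[m + t - 1] = -1.0  # shared offset c_t
            rows.append(row)
            rhs.append(dlog[t, i])
            wts.append(C[t, i] + 0.5)
    A = np.asarray(rows)
    b = np.asarray(rhs)
    w = np.sqrt(np.asarray(wts))
    sol, *_ = np.linalg.lstsq(A * w[:, None], b * w, rcond=None)
    f = sol[:m]
    weights = C.sum(axis=0) + 0.5
    f = f - np.average(f, weights=weights)
    return f


def fit_frequent_fitness(
    counts: LongitudinalCounts, S: Sequence, config: InferenceConfig
) -> FrequentFit:
    """Two-stage replicator fit of frequent-clone fitness.

    Returns fitness on the gauge where the count-weighted mean is zero
    (apply :func:`growth_offset_correction` for absolute values). Initial
    frequencies are the (continuity-corrected) observed frequencies at the
    first passage.
    """
    S = list(S)
    if len(S) < 2:
        raise ValueError("need at least 2 frequent clones to fit fitness")
    if counts.n_passages < 2:
        raise ValueError("need at least 2 passages to fit fitness")
    times = counts.times
    C = counts.count_matrix(S)
    weights = C.sum(axis=0) + 0.5
    m = len(S)
    f1 = _stage1_weighted_lsq(counts, S, times)

    # stage 2: joint multinomial ML over fitness and initial frequencies
    # (clones can enter the frequent set mid-experiment, so the maximum-
    # likelihood x0 may be far below the first observed frequency).
    x0_init = (C[0] + 0.5) / (C[0] + 0.5).sum()

    dt = times - times[0]
    N_t = C.sum(axis=1)

    def unpack(theta):
        f = np.concatenate([[0.0], theta[: m - 1]])
        b = np.concatenate([[0.0], theta[m - 1 :]])
        b = b - b.max()
        x0 = np.exp(b)
        x0 /= x0.sum()
        return f, x0

    def nll_grad(theta):
        f, x0 = unpack(theta)
        x = replicator_solution(f, x0, times, t0=times[0])
        val = -np.sum(C * np.log(np.clip(x, 1e-300, None)))
        # d ll / d f_j = sum_t dt_t (C_tj - N_t x_tj); d ll / d b_j drops dt
        resid = C - N_t[:, None] * x
        g_f = -(dt[:, None] * resid).sum(axis=0)
        g_b = -resid.sum(axis=0)
        return val, np.concatenate([g_f[1:], g_b[1:]])

    init = np.concatenate(
        [(f1 - f1[0])[1:], (np.log(x0_init) - np.log(x0_init[0]))[1:]]
    )
    res = minimize(nll_grad, init, method="L-BFGS-B", jac=True,
                   options={"maxiter": 2000, "ftol": 1e-13, "gtol": 1e-9})
    converged = bool(res.success)
    if not converged:
        warnings.warn(
            "multinomial refinement did not converge; "
            "returning stage-1 least-squares estimates",
            RuntimeWarning,
        )
        f, x0 = f1, x0_init
        ll = -nll_grad(init)[0]
    else:
        f, x0 = unpack(res.x)
        ll = -res.fun
    f = f - np.average(f, weights=weights)
    return FrequentFit(
        karyotypes=S,
        fitness=f,
        x0=x0,
        t0=float(times[0]),
        converged=converged,
        loglik=float(ll),
    )


def growth_offset_correction(
    relative_f: Mapping, counts: LongitudinalCounts, baseline: float = 0.5
) -> dict:
    """Shift all fitness values so that the abundance-weighted mean fitness
    at the first passage equals ``baseline`` (1/day). Pairwise differences
    are untouched — only the unidentifiable absolute scale is pinned."""
    ks = list(relative_f)
    f = np.array([relative_f[k] for k in ks], dtype=float)
    w = np.array([counts.tables[0].get(tuple(k), 0) for k in ks], dtype=float)
    if w.sum() == 0:
        w = np.ones_like(f)
    shift = baseline - np.average(f, weights=w)
    return {k: float(v + shift) for k, v in zip(ks, f)}


# --------------------------------------------------------------------------
# stage 2b: neighbor fitness via mutational flux


def _parent_trajectories(frequent: Mapping, x0: Mapping, grid: np.ndarray):
    ks = list(frequent)
    f = np.array([frequent[k] for k in ks])
    x0v = np.array([x0[k] for k in ks])
    x0v = x0v / x0v.sum()
    X = replicator_solution(f, x0v, grid, t0=grid[0])
    return ks, f, X


def fit_neighbor_fitness(
    counts: LongitudinalCounts,
    frequent: Mapping,
    config: InferenceConfig,
    grid_size: int = 201,
    x0: Optional[Mapping] = None,
) -> dict:
    """Fitness of every viable one-step neighbor of the frequent set.

    For each neighbor the linear influx ODE

        dx_i/dt = sum_j P(i|j) f_j x_j(t) + (f_i - phibar(t)) x_i

    is integrated on a time grid with an integrating factor; the dilution
    term -phibar(t) x_i (mean population fitness from the fitted replicator
    solution) keeps neighbor *frequencies* consistent with the growing
    population. The candidate fitness maximizes the binomial likelihood of
    the neighbor's observed counts plus the normal prior against each
    distance-1 frequent parent. Neighbors lacking a distance-1 frequent
    parent are skipped (cannot occur for true one-step neighbors, kept as a
    guard).
    """
    if config.p <= 0:
        raise ValueError("neighbor inference requires p > 0")
    S = list(frequent)
    model = MissegregationModel(p=config.p)
    times = counts.times
    grid = np.linspace(times[0], times[-1], grid_size)
    if x0 is None:
        x0 = {k: counts.tables[0].get(tuple(k), 0) + 0.5 for k in S}
    ks, fS, X = _parent_trajectories(frequent, x0, grid)
    totals = counts.totals

    neighbors = set()
    for s in S:
        neighbors |= one_step_neighbors(s, allow_zero=False)
    neighbors -= set(map(tuple, S))

    # mean population fitness along the grid and its running integral
    phibar = X @ fS
    t_rel = grid - grid[0]
    Phi = np.concatenate(
        [[0.0], np.cumsum(0.5 * (phibar[1:] + phibar[:-1]) * np.diff(t_rel))]
    )

    result = {}
    t_idx = np.searchsorted(grid, times)
    t_idx = np.clip(t_idx, 0, grid_size - 1)
    div_rate = np.clip(fS, 0.0, None)
    for nb in sorted(neighbors):
        P = np.array([transition_probability(s, nb, model) for s in ks])
        flux = X @ (P * div_rate)  # influx per unit time along the grid
        adj = [j for j, s in enumerate(ks) if manhattan_distance(s, nb) == 1]
        if not adj:
            continue
        c_obs = np.array([tab.get(nb, 0) for tab in counts.tables], dtype=float)
        x_init = c_obs[0] / totals[0]
        f_adj = fS[adj]
        lo = float(f_adj.min() + config.mu_delta - 6.0 * config.sigma_delta)
        hi = float(f_adj.max() + config.mu_delta + 6.0 * config.sigma_delta)

        def neg_logpost(fi):
            x = _integrate_influx(t_rel, flux, fi, Phi, x_init)
            xt = np.clip(x[t_idx], 1e-12, 1.0 - 1e-12)
            ll = binom.logpmf(c_obs, totals, xt).sum()
            lp = norm.logpdf(
                fi - f_adj, loc=config.mu_delta, scale=config.sigma_delta
            ).sum()
            return -(ll + lp)

        res = minimize_scalar(neg_logpost, bounds=(lo, hi), method="bounded")
        result[nb] = float(res.x)
    return result


def _integrate_influx(t_rel, flux, f, Phi, x_init):
    """Solve dx/dt = flux(t) + (f - phibar(t)) x by integrating factor.

    ``Phi`` is the running integral of phibar; a(t) = f*t - Phi(t) gives
    x(t) = e^{a(t)} [x0 + int_0^t e^{-a(s)} flux(s) ds] (trapezoid rule).
    """
    a = f * t_rel - Phi
    damp = np.exp(-a) * flux
    cum = np.concatenate(
        [[0.0], np.cumsum(0.5 * (damp[1:] + damp[:-1]) * np.diff(t_rel))]
    )
    return np.exp(a) * (x_init + cum)


# --------------------------------------------------------------------------
# stage 3 + 4: kriging and cross-validation


def _anchor_noise(ks, config, noise: Optional[Mapping]) -> np.ndarray:
    if noise is None:
        return np.full(len(ks), config.nugget)
    return np.array([noise.get(k, config.nugget) for k in ks], dtype=float)


def fit_kriging(
    anchors: Mapping, config: InferenceConfig, noise: Optional[Mapping] = None
) -> KrigingModel:
    """Fit the Matern-nu=1.5 GP to (karyotype, fitness) anchor pairs.

    ``noise`` optionally maps karyotypes to observation-noise variances
    (heteroscedastic kriging); anchors not listed get ``config.nugget``.
    """
    ks = sorted(anchors)
    X = np.array([tuple(k) for k in ks], dtype=float)
    y = np.array([anchors[k] for k in ks], dtype=float)
    return KrigingModel(
        X, y, nugget=_anchor_noise(ks, config, noise), nu=config.kernel_nu
    )


def cv_score(
    frequent: Mapping, neighbors: Mapping, config: InferenceConfig
) -> float:
    """Leave-one-out predictive R^2 over the frequent anchors.

    Each frequent anchor is held out in turn; the GP (hyperparameters frozen
    from the full fit) is refit on the remaining frequent + neighbor anchors
    and predicts the held-out fitness. Returns 1 - SSE/SST (max 1.0, may be
    negative); NaN with a warning when the anchor fitnesses have no variance.
    """
    fk = sorted(frequent)
    if len(fk) < 4:
        raise ValueError("cv_score requires at least 4 frequent anchors")
    y_freq = np.array([frequent[k] for k in fk])
    if np.var(y_freq) == 0:
        warnings.warn("zero variance among frequent anchors; CV undefined", RuntimeWarning)
        return float("nan")
    all_anchors = dict(neighbors)
    all_anchors.update(frequent)
    noise = {k: config.sigma_delta**2 for k in neighbors}
    full = fit_kriging(all_anchors, config, noise=noise)

    # closed-form leave-one-out at fixed hyperparameters: with
    # K = k(X, X) + diag(alpha) and a = K^{-1} (y - mu), the held-out
    # residual at training point i is a_i / (K^{-1})_{ii}.
    ak = sorted(all_anchors)
    X = np.array([tuple(a) for a in ak], dtype=float)
    y = np.array([all_anchors[a] for a in ak])
    K = full.gp.kernel_(X)
    K[np.diag_indices_from(K)] += full._alpha
    Kinv = np.linalg.inv(K)
    mu = y.mean()
    loo_resid = (Kinv @ (y - mu)) / np.diag(Kinv)
    resid = {k: r for k, r in zip(ak, loo_resid)}
    sse = float(sum(resid[k] ** 2 for k in fk))
    sst = float(np.sum((y_freq - y_freq.mean()) ** 2))
    return 1.0 - sse / sst


# --------------------------------------------------------------------------
# orchestration


def fit_landscape(
    counts: LongitudinalCounts, config: Optional[InferenceConfig] = None
) -> FittedLandscape:
    """Run the full pipeline: S -> fitness -> neighbors -> kriging -> LUT -> CV."""
    config = config or InferenceConfig()
    S = identify_frequent_clones(counts, config.min_obs)
    if len(S) < 2:
        raise ValueError(
            "[frequent] fewer than 2 frequent clones; lower min_obs"
        )
    try:
        freq_fit = fit_frequent_fitness(counts, S, config)
    except Exception as e:  # pragma: no cover - stage labeling
        raise RuntimeError(f"[frequent] {e}") from e
    frequent = growth_offset_correction(
        freq_fit.as_dict(), counts, baseline=config.baseline_growth
    )
    x0_map = dict(zip(freq_fit.karyotypes, freq_fit.x0))
    try:
        neighbors = fit_neighbor_fitness(counts, frequent, config, x0=x0_map)
    except Exception as e:
        raise RuntimeError(f"[neighbors] {e}") from e

    anchors = dict(neighbors)
    anchors.update(frequent)
    # neighbor anchors carry prior-scale uncertainty; frequent anchors are
    # directly estimated and get the (smaller) nugget
    noise = {k: config.sigma_delta**2 for k in neighbors}
    try:
        gp = fit_kriging(anchors, config, noise=noise)
    except Exception as e:
        raise RuntimeError(f"[kriging] {e}") from e

    region = charted_region(S, radius=config.radius)
    region_list = sorted(region)
    mean, sd = gp.predict(region_list)
    lut = {}
    source = {}
    lut_sd = {}
    for k, m, s in zip(region_list, mean, sd):
        if k in frequent:
            lut[k] = frequent[k]
            source[k] = "frequent"
        elif k in neighbors:
            lut[k] = neighbors[k]
            source[k] = "neighbor"
        else:
            lut[k] = float(m)
            source[k] = "interpolated"
        lut_sd[k] = float(s)

    if len(S) >= 4 and np.var([frequent[k] for k in S]) > 0:
        score = cv_score(frequent, neighbors, config)
    else:
        warnings.warn("too few frequent anchors for CV score", RuntimeWarning)
        score = float("nan")

    return FittedLandscape(
        frequent=frequent,
        neighbors=neighbors,
        gp=gp,
        lut=lut,
        source=source,
        cv_score=float(score),
        config=config,
        lut_sd=lut_sd,
    )


def bootstrap_fitness(
    counts: LongitudinalCounts,
    S: Sequence,
    config: InferenceConfig,
    n_boot: Optional[int] = None,
    seed: int = 0,
    level: float = 0.95,
) -> dict:
    """Percentile bootstrap CIs for frequent-clone fitness (gauge-fixed).

    Cells are resampled within each passage (multinomial at the observed
    frequencies), the stage-1 estimator is refit per replicate, and
    percentile intervals are taken on the gauge where the count-weighted mean
    fitness is zero — i.e. the intervals describe fitness *differences* from
    the population mean.
    """
    n_boot = n_boot if n_boot is not None else config.n_boot
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    S = list(S)
    all_k = sorted(counts.karyotypes())
    Cfull = counts.count_matrix(all_k)
    totals = Cfull.sum(axis=1).astype(int)
    boots = np.empty((n_boot, len(S)))
    for b in range(n_boot):
        tabs = []
        for t in range(counts.n_passages):
            draw = rng.multinomial(totals[t], Cfull[t] / Cfull[t].sum())
            tabs.append({k: int(c) for k, c in zip(all_k, draw) if c > 0})
        bc = LongitudinalCounts(times=counts.times, tables=tabs)
        boots[b] = _stage1_weighted_lsq(bc, S, bc.times)
    alpha = (1.0 - level) / 2.0
    lo = np.quantile(boots, alpha, axis=0)
    hi = np.quantile(boots, 1.0 - alpha, axis=0)
    return {k: (float(l), float(h)) for k, l, h in zip(S, lo, hi)}
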