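"""Downstream analyses on fitted karyotype fitness landscapes.

Covers: per-karyotype mutational fitness-effect (delta-f) profiles and their
correlations; whole-genome-doubling classification and a fit-level permutation
Kolmogorov-Smirnov comparison; features and a logistic model for predicting
which not-yet-observed karyotypes will emerge; non-overlapping trajectory
sampling on lineage graphs; and quasispecies steady-state screens that ask how
the missegregation rate reshapes which karyotype dominates at mutation-
selection balance (the error-threshold phenomenon).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import statsmodels.api as sm
from scipy import stats

from .karyotype import N_AUTOSOMES, manhattan_distance
from .missegregation import kernel_matrix


# --------------------------------------------------------------------------
# delta-f profiles


@dataclass
class DeltaFProfile:
    """The 44 one-missegregation-step fitness effects of a karyotype.

    ``effects[2*c]`` is the loss of chromosome c+1, ``effects[2*c + 1]`` the
    gain; entries whose move would create a zero-copy (nonviable) state or
    leave the landscape's look-up table are NaN with ``viable`` False.
    """

    karyotype: tuple
    effects: np.ndarray  # length 44, ordered loss chr1, gain chr1, ...
    viable: np.ndarray  # length 44 bools


def _lut_of(landscape) -> dict:
    if isinstance(landscape, dict):
        return landscape
    if hasattr(landscape, "lut"):  # FittedLandscape / LoadedLandscape
        return landscape.lut
    return landscape.table  # LUTLandscape


def delta_f_profile(k, landscape) -> DeltaFProfile:
    """delta_f = f(neighbor) - f(k) for each of the 44 single-chromosome moves."""
    lut = _lut_of(landscape)
    k = tuple(int(c) for c in k)
    if k not in lut:
        raise KeyError(f"karyotype {k} absent from the landscape LUT")
    f0 = lut[k]
    effects = np.full(2 * N_AUTOSOMES, np.nan)
    viable = np.zeros(2 * N_AUTOSOMES, dtype=bool)
    for c in range(N_AUTOSOMES):
        for j, step in enumerate((-1, +1)):
            nb = k[:c] + (k[c] + step,) + k[c + 1 :]
            idx = 2 * c + j
            if nb[c] <= 0:
                continue  # loss into a zero-copy state: nonviable
            if nb in lut:
                effects[idx] = lut[nb] - f0
                viable[idx] = True
    return DeltaFProfile(karyotype=k, effects=effects, viable=viable)


def profile_correlation(p1: DeltaFProfile, p2: DeltaFProfile) -> tuple:
    """(Pearson r, Fisher z = atanh(r)) over jointly viable profile entries."""
    mask = p1.viable & p2.viable & np.isfinite(p1.effects) & np.isfinite(p2.effects)
    if mask.sum() < 3:
        raise ValueError("need at least 3 jointly viable profile entries")
    a, b = p1.effects[mask], p2.effects[mask]
    if np.std(a) == 0 or np.std(b) == 0:
        warnings.warn("zero variance in a delta-f profile", RuntimeWarning)
        return float("nan"), float("nan")
    r = float(np.corrcoef(a, b)[0, 1])
    z = float(np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15)))
    return r, z


# --------------------------------------------------------------------------
# whole-genome doubling


def wgd_classify(k) -> str:
    """``"WGD+"`` iff the modal chromosome copy number is >= 3 (ties -> smaller)."""
    vals = np.asarray(k, dtype=int)
    modal = int(np.argmax(np.bincount(vals)))
    return "WGD+" if modal >= 3 else "WGD-"


@dataclass
class PermutationKSResult:
    statistic: float
    p_value: float
    n_perm: int
    seed: int


def permutation_ks_test(
    values: Sequence[float],
    labels: Sequence[str],
    n_perm: int = 10_000,
    seed: int = 0,
) -> PermutationKSResult:
    """Fit-level permutation KS test between two labeled groups.

    ``values`` are per-landscape-fit summaries (e.g. the mean delta-f of a
    fit's WGD+ karyotypes) and ``labels`` the corresponding group labels.
    The KS statistic between the two groups' value distributions is compared
    against ``n_perm`` permutations of the labels among fits:
    p = (1 + #{KS* >= KS_obs}) / (n_perm + 1).
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("exactly two labels required")
    g0 = values[labels == groups[0]]
    g1 = values[labels == groups[1]]
    if len(g0) < 2 or len(g1) < 2:
        raise ValueError("need >= 2 fits per label")
    obs = stats.ks_2samp(g0, g1, method="asymp").statistic
    rng = np.random.default_rng(seed)
    n0 = len(g0)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(len(values))
        s = stats.ks_2samp(values[perm[:n0]], values[perm[n0:]], method="asymp").statistic
        if s >= obs - 1e-15:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return PermutationKSResult(
        statistic=float(obs), p_value=float(p), n_perm=n_perm, seed=seed
    )


# --------------------------------------------------------------------------
# novel karyotype emergence


@dataclass
class EmergenceFeatures:
    """Predictors for one candidate karyotype in Theta \\ zeta.

    ``f`` is the landscape fitness estimate; ``d[i-1]`` the fraction of the
    currently observed population exactly i missegregations away (i = 1..5);
    ``emerged`` whether the karyotype appears in the future sample.
    """

    karyotype: tuple
    f: float
    d: np.ndarray  # length 5
    emerged: bool


def emergence_features(
    theta: Mapping,
    zeta: Mapping,
    psi: set,
    weighting: str = "cell",
) -> list:
    """Features for every candidate karyotype not yet observed.

    theta: karyotype -> fitness over the fitted landscape; zeta: karyotype ->
    frequency in the latest sample; psi: karyotypes present in the future
    sample. ``weighting="cell"`` computes d_i as the abundance-weighted
    fraction of the zeta population at distance i; ``"clone"`` weights every
    observed karyotype equally.
    """
    if weighting not in ("cell", "clone"):
        raise ValueError("weighting must be 'cell' or 'clone'")
    zeta = {tuple(k): v for k, v in zeta.items()}
    psi = {tuple(k) for k in psi}
    zk = sorted(zeta)
    if weighting == "cell":
        w = np.array([zeta[k] for k in zk], dtype=float)
    else:
        w = np.ones(len(zk))
    w = w / w.sum()
    out = []
    for k in sorted(set(map(tuple, theta)) - set(zk)):
        d = np.zeros(5)
        for kz, wz in zip(zk, w):
            dist = manhattan_distance(k, kz)
            if 1 <= dist <= 5:
                d[dist - 1] += wz
        out.append(
            EmergenceFeatures(
                karyotype=k, f=float(theta[k]), d=d, emerged=k in psi
            )
        )
    return out


@dataclass
class EmergenceModel:
    """Logistic model logit P(emerge) = b0 + bf*f + sum_i bi*d_i."""

    coefficients: dict  # {"const","f","d1".."d5"} -> estimate
    z_values: dict
    p_values: dict
    separation: bool
    n: int


def fit_emergence_model(features: Sequence[EmergenceFeatures]) -> EmergenceModel:
    """Maximum-likelihood logistic regression with Wald z tests per predictor."""
    if not features:
        raise ValueError("no features supplied")
    y = np.array([int(ft.emerged) for ft in features])
    if y.min() == y.max():
        raise ValueError("labels are degenerate: both outcomes must occur")
    X = np.column_stack(
        [[ft.f for ft in features]] + [[ft.d[i] for ft in features] for i in range(5)]
    )
    X = sm.add_constant(X, has_constant="add")
    names = ["const", "f", "d1", "d2", "d3", "d4", "d5"]
    separation = False
    params = bse = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                separation = True
            bse = np.asarray(res.bse)
            params = np.asarray(res.params)
        except Exception:
            params = bse = None
            separation = True
        if params is None or not np.all(np.isfinite(params)):
            # (near-)separated data: fall back to a weakly ridge-penalized
            # fit; Wald statistics are unreliable here and flagged
            separation = True
            try:
                res = sm.Logit(y, X).fit_regularized(
                    disp=0, alpha=0.1, maxiter=500
                )
                params = np.asarray(res.params)
            except Exception:
                params = np.full(X.shape[1], np.nan)
            bse = np.full_like(params, np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = params / bse
    p = 2 * stats.norm.sf(np.abs(z))
    if np.any(np.abs(params) > 50) or np.any(~np.isfinite(bse)):
        separation = True
    if separation:
        warnings.warn(
            "possible separation: coefficients may be unbounded", RuntimeWarning
        )
    return EmergenceModel(
        coefficients=dict(zip(names, map(float, params))),
        z_values=dict(zip(names, map(float, z))),
        p_values=dict(zip(names, map(float, p))),
        separation=separation,
        n=len(y),
    )


# --------------------------------------------------------------------------
# lineage trajectories


def sample_nonoverlapping_trajectories(
    lineage_graph: nx.DiGraph, seed: int = 0, min_length: int = 2
) -> list:
    """Random maximal set of node-disjoint root-to-node passage trajectories.

    Candidate trajectories are all directed paths starting at a root (a node
    with no predecessors) with at least ``min_length`` passages; a shuffled
    greedy pass keeps each candidate whose nodes are disjoint from all kept
    ones, yielding a random maximal packing. Different seeds give different
    packings.
    """
    if not nx.is_directed_acyclic_graph(lineage_graph):
        raise ValueError("lineage graph must be acyclic")
    rng = np.random.default_rng(seed)
    roots = [n for n in lineage_graph.nodes if lineage_graph.in_degree(n) == 0]
    candidates = []
    for root in roots:
        stack = [(root, (root,))]
        while stack:
            node, path = stack.pop()
            if len(path) >= min_length:
                candidates.append(path)
            for succ in lineage_graph.successors(node):
                stack.append((succ, path + (succ,)))
    order = rng.permutation(len(candidates))
    used: set = set()
    kept = []
    for idx in order:
        path = candidates[idx]
        if used.isdisjoint(path):
            kept.append(path)
            used.update(path)
    return kept


# --------------------------------------------------------------------------
# steady states across missegregation rates


def build_transition_matrix(
    landscape,
    p: float,
    dt: float = 1.0,
    states: Optional[Sequence] = None,
    mutation_only: bool = False,
) -> tuple:
    """Growth-weighted missegregation operator over the charted region.

    The per-division kernel restricted to the charted states is column-
    renormalized (flux to states outside the region is discarded — the
    "approximate" part of the construction), then each column j is weighted
    by the parent growth factor exp(f_j * dt). One application propagates a
    population vector through dt days of growth and missegregation; the
    leading eigenvector is the quasispecies steady state.

    With ``mutation_only=True`` the column-stochastic renormalized kernel is
    returned instead (columns sum to 1 exactly).

    Returns (matrix, states) with states sorted for determinism.
    """
    lut = _lut_of(landscape)
    if not lut:
        raise ValueError("landscape LUT is empty")
    if p < 0:
        raise ValueError("p must be >= 0")
    states = sorted(lut) if states is None else [tuple(k) for k in states]
    S = np.asarray(states, dtype=int)
    max_copy = int(S.max())
    K = kernel_matrix(max_copy, max_copy, p)
    n = len(states)
    P = np.ones((n, n))
    for c in range(N_AUTOSOMES):
        col = S[:, c]
        P *= K[np.ix_(col, col)].T  # (child, parent)
    colsum = P.sum(axis=0)
    P = P / colsum[None, :]
    if mutation_only:
        return P, states
    f = np.array([lut[k] for k in states])
    A = P * np.exp(f * dt)[None, :]
    return A, states


def steady_state(
    matrix: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100_000,
) -> np.ndarray:
    """Leading eigenvector of a non-negative operator by power iteration.

    Normalized to sum 1 at every iteration; converged when successive
    iterates differ by less than ``tol`` in L1. Power iteration is run from
    two different initializations and a warning is raised if they disagree
    (a reducible operator, e.g. the identity, has no unique steady state).
    """
    A = np.asarray(matrix, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("matrix must be square")
    n = A.shape[0]

    def _power(x):
        x = x / x.sum()
        for _ in range(max_iter):
            y = A @ x
            s = y.sum()
            if s <= 0:
                raise RuntimeError("operator annihilated the population vector")
            y /= s
            if np.abs(y - x).sum() < tol:
                return y
            x = y
        raise RuntimeError(f"power iteration did not converge in {max_iter} steps")

    x1 = _power(np.ones(n))
    rng = np.random.default_rng(0)
    x2 = _power(rng.random(n) + 1e-3)
    if np.abs(x1 - x2).sum() > 1e-6:
        warnings.warn(
            "steady state depends on initialization (reducible operator)",
            RuntimeWarning,
        )
    return x1


@dataclass
class SteadyStateResult:
    """Per-rate steady states, dominant karyotypes and switch distances."""

    rates: np.ndarray
    states: list
    distributions: list  # per-rate frequency vectors over `states`
    dominants: list  # per-rate argmax karyotype
    distances: list  # Manhattan distance of each dominant to the lowest-rate one

    def distribution_dict(self, i: int) -> dict:
        return {k: float(v) for k, v in zip(self.states, self.distributions[i])}


def dominance_screen(
    landscape, rates: Sequence[float], dt: float = 1.0
) -> SteadyStateResult:
    """Steady-state dominant karyotype across a screen of missegregation rates.

    For each rate the quasispecies steady state over the charted region is
    computed and its most frequent karyotype recorded, together with the
    Manhattan distance to the dominant at the lowest screened rate. A
    distance > 0 at some rate is an error-threshold-style dominance switch.
    """
    rates = np.asarray(sorted(rates), dtype=float)
    if len(rates) < 2:
        raise ValueError("need at least 2 rates to screen")
    dists = []
    doms = []
    distributions = []
    states = None
    for r in rates:
        A, states = build_transition_matrix(landscape, p=r, dt=dt, states=states)
        ss = steady_state(A)
        distributions.append(ss)
        doms.append(states[int(np.argmax(ss))])
    ref = doms[0]
    dists = [manhattan_distance(ref, d) for d in doms]
    return SteadyStateResult(
        rates=rates,
        states=states,
        distributions=distributions,
        dominants=doms,
        distances=dists,
    )


def assign_rate_response_groups(
    screen: SteadyStateResult,
    top_n: int = 400,
    threshold: float = 0.2,
    method: str = "pearson",
) -> dict:
    """Label karyotypes by how their steady-state abundance tracks the rate.

    Among the ``top_n`` karyotypes most abundant at any screened rate,
    correlation of frequency with missegregation rate assigns group "x"
    (negative — these dominate at low rates) or "y" (positive — favored by
    high rates); |r| < ``threshold`` stays unassigned (None).
    """
    if len(screen.rates) < 3:
        raise ValueError("need at least 3 rates for correlation grouping")
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    F = np.asarray(screen.distributions)  # (n_rates, n_states)
    top = np.argsort(-F.max(axis=0))[:top_n]
    out = {}
    for idx in top:
        freq = F[:, idx]
        if np.std(freq) == 0:
            out[screen.states[idx]] = None
            continue
        if method == "pearson":
            r = float(np.corrcoef(freq, screen.rates)[0, 1])
        else:
            r = float(stats.spearmanr(freq, screen.rates).statistic)
        if abs(r) < threshold:
            out[screen.states[idx]] = None
        else:
            out[screen.states[idx]] = "x" if r < 0 else "y"
    return out
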