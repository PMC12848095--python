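"""Forecasting future karyotype distributions and scoring predictions.

A fitted landscape is turned into a forecast by running the agent-based model
in look-up-table mode from the last observed population. Predictions are
scored with the metrics used throughout the package:

- **angle metric** — the angle (degrees) between predicted and observed
  changes in the population-mean karyotype; 0 deg means identical direction
  of evolution, 90 deg is orthogonal (the null median in 22-D), 180 deg is
  opposite.
- **Monte Carlo angle null** — per-unit median angles are summarized by the
  median-of-medians statistic T and compared against matched-size draws of
  angles between independent random unit vectors in 22-D.
- **Wasserstein-1 distance** — exact discrete optimal transport between two
  karyotype distributions with a Euclidean (or Manhattan) ground metric.
- **overlap coefficient** — sum of elementwise minimum frequencies.
- **no-evolution baseline** — the last observed distribution itself; a useful
  forecast must beat it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .abm import LUTLandscape, SimConfig, run_simulation
from .karyotype import N_AUTOSOMES


def _validate_dist(dist: dict, tol: float = 1e-9) -> dict:
    if not dist:
        raise ValueError("distribution must be non-empty")
    total = float(sum(dist.values()))
    if any(v < -tol for v in dist.values()):
        raise ValueError("frequencies must be non-negative")
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"frequencies must sum to 1 (got {total})")
    return {tuple(k): v / total for k, v in dist.items() if v > 0}


def distribution_from_counts(counts: dict) -> dict:
    """Normalize a karyotype -> count table to relative frequencies."""
    total = float(sum(counts.values()))
    if total <= 0:
        raise ValueError("counts must have positive total")
    return {tuple(k): c / total for k, c in counts.items() if c > 0}


def mean_karyotype(dist: dict) -> np.ndarray:
    """Frequency-weighted mean copy number per chromosome (22-vector)."""
    dist = _validate_dist(dist)
    out = np.zeros(N_AUTOSOMES)
    for k, w in dist.items():
        out += w * np.asarray(k, dtype=float)
    return out


def angle_metric(v_ref: np.ndarray, v_test: np.ndarray) -> float:
    """Angle in degrees between two population-change vectors.

    Returns NaN for a zero vector (no direction), e.g. for the no-evolution
    baseline's change vector.
    """
    v1 = np.asarray(v_ref, dtype=float)
    v2 = np.asarray(v_test, dtype=float)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 == 0 or n2 == 0:
        return float("nan")
    c = np.clip(np.dot(v1, v2) / (n1 * n2), -1.0, 1.0)
    return float(np.degrees(np.arccos(c)))


@dataclass
class AngleNullResult:
    """Median-of-medians angle statistic and its Monte Carlo p-value."""

    T_obs: float
    p_value: float
    n_iter: int
    seed: int
    alternative: str
    null_T: np.ndarray


def _null_angles(rng: np.random.Generator, n: int, dims: int) -> np.ndarray:
    u = rng.normal(size=(n, dims))
    v = rng.normal(size=(n, dims))
    c = np.einsum("ij,ij->i", u, v) / (
        np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1)
    )
    return np.degrees(np.arccos(np.clip(c, -1.0, 1.0)))


def angle_null_test(
    per_unit_angles: Sequence[Sequence[float]],
    alternative: str = "one-sided",
    n_iter: int = 10_000,
    seed: int = 0,
    dims: int = N_AUTOSOMES,
) -> AngleNullResult:
    """Monte Carlo test of directional alignment against the random null.

    The statistic T is the median of per-unit median angles. Under the null,
    matched-size angle sets are drawn between independent standard-Gaussian
    unit vectors in ``dims`` dimensions; the one-sided p-value is the
    proportion of null statistics T* <= T (small angles = alignment), the
    two-sided p-value doubles the smaller tail.
    """
    units = [np.asarray(u, dtype=float) for u in per_unit_angles]
    if not units or any(len(u) == 0 for u in units):
        raise ValueError("each unit must contribute at least one angle")
    if alternative not in ("one-sided", "two-sided"):
        raise ValueError("alternative must be 'one-sided' or 'two-sided'")
    T_obs = float(np.median([np.median(u) for u in units]))
    sizes = [len(u) for u in units]
    rng = np.random.default_rng(seed)
    total = sum(sizes)
    splits = np.cumsum(sizes)[:-1]
    null_T = np.empty(n_iter)
    for it in range(n_iter):
        draws = _null_angles(rng, total, dims)
        meds = [np.median(chunk) for chunk in np.split(draws, splits)]
        null_T[it] = np.median(meds)
    lower = float(np.mean(null_T <= T_obs))
    if alternative == "one-sided":
        p = lower
    else:
        upper = float(np.mean(null_T >= T_obs))
        p = min(1.0, 2.0 * min(lower, upper))
    return AngleNullResult(
        T_obs=T_obs,
        p_value=p,
        n_iter=n_iter,
        seed=seed,
        alternative=alternative,
        null_T=null_T,
    )


def wasserstein_distance(d1: dict, d2: dict, metric: str = "euclidean") -> float:
    """Exact discrete Wasserstein-1 distance between two distributions.

    Solved as the optimal-transport linear program with ground metric
    ``euclidean`` (default) or ``manhattan`` on the integer copy-number
    vectors. Symmetric; zero iff the distributions coincide.
    """
    d1 = _validate_dist(d1)
    d2 = _validate_dist(d2)
    if d1 == d2:
        return 0.0
    k1 = sorted(d1)
    k2 = sorted(d2)
    a = np.array([d1[k] for k in k1])
    b = np.array([d2[k] for k in k2])
    X1 = np.asarray(k1, dtype=float)
    X2 = np.asarray(k2, dtype=float)
    diff = X1[:, None, :] - X2[None, :, :]
    if metric == "euclidean":
        C = np.sqrt((diff**2).sum(axis=2))
    elif metric == "manhattan":
        C = np.abs(diff).sum(axis=2)
    else:
        raise ValueError("metric must be 'euclidean' or 'manhattan'")
    n, m = C.shape
    if n == 1:
        return float(C[0] @ b)
    if m == 1:
        return float(a @ C[:, 0])
    # transport plan P >= 0 with row sums a and column sums b
    row_idx = np.repeat(np.arange(n), m)
    col_idx = np.tile(np.arange(m), n) + n
    var_idx = np.arange(n * m)
    A_eq = sparse.coo_matrix(
        (
            np.ones(2 * n * m),
            (np.concatenate([row_idx, col_idx]), np.concatenate([var_idx, var_idx])),
        ),
        shape=(n + m, n * m),
    ).tocsr()
    b_eq = np.concatenate([a, b])
    res = linprog(
        C.ravel(), A_eq=A_eq[:-1], b_eq=b_eq[:-1], bounds=(0, None), method="highs"
    )
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"optimal transport LP failed: {res.message}")
    return float(res.fun)


def no_evolution_baseline(last: dict) -> dict:
    """The static baseline forecast: the last observed state, unchanged."""
    return dict(_validate_dist(last))


def overlap_coefficient(d1: dict, d2: dict) -> float:
    """Abundance overlap sum_k min(d1(k), d2(k)) in [0, 1]."""
    d1 = _validate_dist(d1)
    d2 = _validate_dist(d2)
    return float(sum(min(v, d2.get(k, 0.0)) for k, v in d1.items()))


def forecast(
    landscape,
    start: dict,
    horizon_days: float,
    n_replicates: int = 10,
    seed: int = 0,
    p: float = 0.00075,
    n_cells: int = 1_000,
    dt: float = 0.1,
    N_max: int = 10_000,
    out_of_table: str = "lethal",
) -> dict:
    """Replicate-averaged ABM forecast of the karyotype distribution.

    The population is seeded with ``n_cells`` cells multinomially allocated
    to the starting distribution and evolved for ``horizon_days`` on the
    landscape's fitness look-up table (serial passaging at ``N_max`` keeps
    the run bounded without biasing frequencies). The returned distribution
    averages final-population frequencies over replicates.
    """
    start = _validate_dist(start)
    if horizon_days < 0:
        raise ValueError("horizon must be >= 0")
    if horizon_days == 0:
        return dict(start)
    if isinstance(landscape, dict):
        lut = LUTLandscape(table=landscape, out_of_table=out_of_table)
    elif isinstance(landscape, LUTLandscape):
        lut = landscape
    else:  # FittedLandscape
        lut = landscape.as_lut(out_of_table)
    rng = np.random.default_rng(seed)
    ks = sorted(start)
    freqs = np.array([start[k] for k in ks])
    acc: dict = {}
    n_alive = 0
    for _ in range(n_replicates):
        draw = rng.multinomial(n_cells, freqs)
        init = {k: int(c) for k, c in zip(ks, draw) if c > 0}
        cfg = SimConfig(
            p=p,
            N_max=N_max,
            n_seed=max(1, N_max // 10),
            dt=dt,
            t_end=horizon_days,
            init_counts=init,
            sample_size=1,
            sample_times=[],
            seed=int(rng.integers(2**31 - 1)),
        )
        result = run_simulation(cfg, lut)
        if result.extinct or result.final_state.total == 0:
            continue
        n_alive += 1
        for k, v in result.final_state.frequencies().items():
            acc[k] = acc.get(k, 0.0) + v
    if n_alive == 0:
        raise RuntimeError("population went extinct in every forecast replicate")
    return {k: v / n_alive for k, v in acc.items()}


def beat_baseline_fraction(records: Sequence[tuple]) -> float:
    """Fraction of (prediction_metric, baseline_metric) pairs where the
    prediction is strictly better (smaller); ties do not count as wins."""
    if not records:
        raise ValueError("records must be non-empty")
    wins = sum(1 for pred, base in records if pred < base)
    return wins / len(records)
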