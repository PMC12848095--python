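"""Chromosome missegregation transition kernel.

Model: during one division, each of the ``n`` copies of a chromosome
missegregates independently with probability ``p``; a missegregating copy's
sister chromatids co-segregate, ending up together in one daughter cell chosen
uniformly. A daughter therefore receives

    n_daughter = n - m + 2 g,        m ~ Binomial(n, p),  g ~ Binomial(m, 1/2),

where ``m`` counts missegregating copies and ``g`` those resolving toward this
daughter. The kernel is symmetric about ``n`` (gains and losses are equally
likely) and the two daughters of one division are complementary
(n_daughter1 + n_daughter2 = 2n). Chromosomes missegregate independently, so
the whole-karyotype transition probability is a product over the 22 autosomes.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.stats import binom

from .karyotype import N_AUTOSOMES


@dataclass(frozen=True)
class MissegregationModel:
    """Per-copy missegregation probability and zero-copy viability policy."""

    p: float
    allow_zero_copies: bool = False

    def __post_init__(self):
        if not (0.0 <= self.p <= 0.5):
            raise ValueError(f"missegregation probability p={self.p} outside [0, 0.5]")


@lru_cache(maxsize=4096)
def _daughter_kernel_cached(n: int, p: float) -> tuple:
    probs = np.zeros(2 * n + 1)
    if n == 0:
        probs[0] = 1.0
        return tuple(probs)
    m_vals = np.arange(n + 1)
    pm = binom.pmf(m_vals, n, p)
    for m in range(n + 1):
        if pm[m] == 0.0:
            continue
        g_vals = np.arange(m + 1)
        pg = binom.pmf(g_vals, m, 0.5)
        for g in range(m + 1):
            probs[n - m + 2 * g] += pm[m] * pg[g]
    return tuple(probs)


def per_chromosome_daughter_kernel(n: int, p: float) -> np.ndarray:
    """Distribution of one daughter's copy number given a parent with ``n``.

    Returns an array of length ``2n + 1``; entry ``d`` is the probability the
    daughter inherits ``d`` copies. Sums to 1 exactly (before any viability
    truncation, which is a population-level policy, not part of the kernel).
    """
    if n < 0:
        raise ValueError("parent copy number must be >= 0")
    if not (0.0 <= p <= 0.5):
        raise ValueError(f"missegregation probability p={p} outside [0, 0.5]")
    return np.array(_daughter_kernel_cached(int(n), float(p)))


def transition_probability(
    parent: Sequence[int], child: Sequence[int], model: MissegregationModel
) -> float:
    """P(child karyotype | parent karyotype) for a single daughter cell.

    Product over the 22 autosomes of the per-chromosome daughter kernel. For
    ``p = 0`` this is 1 iff child == parent. Note this is a per-division
    probability; converting to per-unit-time flux requires multiplying by the
    parent's division rate.
    """
    if len(parent) != N_AUTOSOMES or len(child) != N_AUTOSOMES:
        raise ValueError(f"karyotypes must have length {N_AUTOSOMES}")
    prob = 1.0
    for pc, cc in zip(parent, child):
        pc, cc = int(pc), int(cc)
        if cc > 2 * pc:
            return 0.0
        kernel = _daughter_kernel_cached(pc, model.p)
        prob *= kernel[cc]
        if prob == 0.0:
            return 0.0
    return prob


def kernel_matrix(max_parent: int, max_child: int, p: float) -> np.ndarray:
    """Per-chromosome kernel as a (max_parent+1, max_child+1) lookup table.

    ``K[n, d]`` = P(daughter has d copies | parent has n); entries with
    d > 2n are zero. Used to vectorize whole-karyotype transition matrices.
    """
    K = np.zeros((max_parent + 1, max_child + 1))
    for n in range(max_parent + 1):
        kern = per_chromosome_daughter_kernel(n, p)
        hi = min(len(kern), max_child + 1)
        K[n, :hi] = kern[:hi]
    return K


def transition_matrix(states: Sequence, p: float) -> np.ndarray:
    """Dense per-division transition matrix over an explicit state list.

    Entry (i, j) is P(child = states[i] | parent = states[j]) under the
    per-copy missegregation model; columns need not sum to 1 because children
    outside ``states`` are not represented.
    """
    S = np.asarray([tuple(k) for k in states], dtype=int)
    if S.ndim != 2 or S.shape[1] != N_AUTOSOMES:
        raise ValueError("states must be karyotypes of length 22")
    max_copy = int(S.max())
    K = kernel_matrix(max_copy, max_copy, p)
    n = len(states)
    P = np.ones((n, n))
    for c in range(N_AUTOSOMES):
        col = S[:, c]
        # M[j, i] = K[parent copy, child copy]; transpose to child-major
        P *= K[np.ix_(col, col)].T
    return P
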