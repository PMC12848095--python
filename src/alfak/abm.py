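"""Agent-based model of an evolving, missegregating cell population.

Cells carry integer karyotypes and divide at a karyotype-specific net growth
rate (fitness, 1/day) looked up from either a ground-truth GRF landscape or a
fitted look-up table (LUT). Time advances in discrete steps of ``dt`` days
using binomial thinning: a karyotype with count n and fitness f >= 0 produces
Binomial(n, f*dt) divisions per step; negative fitness acts as a death rate,
Binomial(n, |f|*dt) deaths. Each division replaces the parent with two
daughters whose karyotypes are drawn from the per-copy missegregation kernel
(the two daughters are complementary). Daughters that lose all copies of any
autosome die immediately, as do daughters falling outside a LUT with the
``lethal`` out-of-table policy.

Serial passaging emulates cell culture: whenever the population reaches
capacity ``N_max`` it is multinomially down-sampled to ``n_seed`` cells, and a
multinomial sample of ``sample_size`` cells (the simulated single-cell
sequencing measurement) is recorded just before the bottleneck.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from .karyotype import DIPLOID, N_AUTOSOMES, is_viable, manhattan_distance


@dataclass
class LUTLandscape:
    """Fitness look-up table over an explicit set of karyotypes.

    out_of_table policy (total: every queried karyotype resolves):

    - ``"lethal"``: karyotypes outside the table are nonviable (fitness None);
      consistent with charted-region truncation.
    - ``"min_fitness"``: assigned the minimum tabulated fitness.
    - ``"nearest_anchor"``: assigned the fitness of the nearest tabulated
      karyotype by Manhattan distance (ties broken by karyotype order).
    """

    table: dict
    out_of_table: str = "lethal"

    def __post_init__(self):
        if self.out_of_table not in ("lethal", "min_fitness", "nearest_anchor"):
            raise ValueError(f"unknown out_of_table policy: {self.out_of_table}")
        self.table = {tuple(k): float(v) for k, v in self.table.items()}
        for v in self.table.values():
            if not np.isfinite(v):
                raise ValueError("LUT fitness values must be finite")
        self._min = min(self.table.values()) if self.table else None

    def fitness(self, k) -> Optional[float]:
        """Fitness of ``k``; None signals a nonviable (lethal) state."""
        k = tuple(k)
        v = self.table.get(k)
        if v is not None:
            return v
        if self.out_of_table == "lethal":
            return None
        if self.out_of_table == "min_fitness":
            return self._min
        nearest = min(
            self.table, key=lambda a: (manhattan_distance(a, k), a)
        )
        return self.table[nearest]


@dataclass
class SimConfig:
    """Parameters of one ABM run (times in days, fitness in 1/day)."""

    p: float = 0.00075
    N_max: int = 10_000
    n_seed: int = 1_000
    dt: float = 0.1
    t_end: float = 100.0
    founder: tuple = DIPLOID
    init_counts: Optional[dict] = None  # overrides founder when given
    sample_size: int = 500
    sample_times: Optional[Sequence[float]] = None  # None -> sample at passages
    max_passages: Optional[int] = None
    seed: int = 0
    record_full: bool = False

    def __post_init__(self):
        if not (0.0 <= self.p <= 0.5):
            raise ValueError("p must lie in [0, 0.5]")
        if not (0 < self.n_seed <= self.N_max):
            raise ValueError("need 0 < n_seed <= N_max")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.sample_size <= 0:
            raise ValueError("sample_size must be > 0")


@dataclass
class PopulationState:
    """Karyotype -> cell count map at simulation time ``t`` (days)."""

    counts: dict
    t: float = 0.0

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def frequencies(self) -> dict:
        tot = self.total
        return {k: c / tot for k, c in self.counts.items()}


@dataclass
class PassageRecord:
    """One observation: sampling time, sampled counts and population size."""

    time: float
    sample: dict
    population_size: int
    full: Optional[dict] = None


@dataclass
class SimResult:
    records: list
    final_state: PopulationState
    extinct: bool
    passage_times: list
    config: SimConfig


_MISSING = object()


class _FitnessCache:
    """Memoized fitness lookup; None marks nonviable states."""

    def __init__(self, landscape):
        self._landscape = landscape
        self._cache = {}

    def __call__(self, k) -> Optional[float]:
        v = self._cache.get(k, _MISSING)
        if v is _MISSING:
            if not is_viable(k):
                v = None
            else:
                v = self._landscape.fitness(k)
            self._cache[k] = v
        return v


def _conditional_m_pmf(C: int, p: float) -> np.ndarray:
    """pmf of total missegregating copies M ~ Bin(C, p) given M >= 1."""
    from scipy.stats import binom as _binom

    m = np.arange(1, C + 1)
    pmf = _binom.pmf(m, C, p)
    s = pmf.sum()
    if s <= 0:  # p == 0 edge; never reached because q_ms == 0 then
        pmf = np.zeros(C)
        pmf[0] = 1.0
        return pmf
    return pmf / s


def step_population(
    state: PopulationState,
    config: SimConfig,
    landscape,
    rng: Optional[np.random.Generator] = None,
    _fitness=None,
    _mcache=None,
) -> PopulationState:
    """Advance the population by one time step of ``config.dt`` days.

    Pure given an explicit ``rng``; ``run_simulation`` threads one generator
    through all steps so runs are bit-reproducible from ``config.seed``.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fitness = _fitness if _fitness is not None else _FitnessCache(landscape)
    mcache = _mcache if _mcache is not None else {}
    dt, p = config.dt, config.p

    karyos = list(state.counts.keys())
    n = np.array([state.counts[k] for k in karyos], dtype=np.int64)
    f = np.array(
        [np.nan if fitness(k) is None else fitness(k) for k in karyos]
    )
    viable = ~np.isnan(f)
    fv = np.where(viable, f, 0.0)
    if np.any(np.abs(fv) * dt >= 1.0):
        bad = np.abs(fv) * dt >= 1.0
        raise ValueError(
            f"|fitness|*dt >= 1 for {int(bad.sum())} karyotype(s) "
            f"(max |f|={np.abs(fv).max():.3g}); reduce dt"
        )

    new_counts: dict = {}
    divisions = np.where(viable & (fv >= 0), rng.binomial(n, np.clip(fv, 0, None) * dt), 0)
    deaths = np.where(viable & (fv < 0), rng.binomial(n, np.clip(-fv, 0, None) * dt), 0)

    # probability a division involves no missegregating copy anywhere
    C_tot = np.array([sum(k) for k in karyos], dtype=np.int64)
    q_triv = (1.0 - p) ** C_tot
    n_triv = rng.binomial(divisions, q_triv)

    base = np.where(viable, n - deaths - divisions + 2 * n_triv, 0)
    for k, b in zip(karyos, base):
        if b > 0:
            new_counts[k] = new_counts.get(k, 0) + int(b)

    # handle the (rare) divisions with at least one missegregation one by one
    n_ms = divisions - n_triv
    for idx in np.nonzero(n_ms)[0]:
        k = karyos[idx]
        C = int(C_tot[idx])
        pmf = mcache.get(C)
        if pmf is None:
            pmf = _conditional_m_pmf(C, p)
            mcache[C] = pmf
        copies = np.array(k, dtype=np.int64)
        for _ in range(int(n_ms[idx])):
            M = int(rng.choice(len(pmf), p=pmf)) + 1
            m_per_chrom = rng.multivariate_hypergeometric(copies, M)
            g = rng.binomial(m_per_chrom, 0.5)
            delta = 2 * g - m_per_chrom
            d1 = tuple(int(c) for c in copies + delta)
            d2 = tuple(int(c) for c in copies - delta)
            for d in (d1, d2):
                if fitness(d) is not None:
                    new_counts[d] = new_counts.get(d, 0) + 1

    return PopulationState(counts=new_counts, t=state.t + dt)


def sample_counts(state: PopulationState, n: int, rng_or_seed=0) -> dict:
    """Multinomial sample of ``n`` cells from the current population.

    Sampling is with replacement from the population frequencies (a
    multinomial draw), emulating dissociation and sequencing of a random
    cell aliquot.
    """
    if n <= 0:
        raise ValueError("sample size must be > 0")
    if state.total == 0:
        raise ValueError("cannot sample from an empty population")
    rng = (
        rng_or_seed
        if isinstance(rng_or_seed, np.random.Generator)
        else np.random.default_rng(rng_or_seed)
    )
    karyos = list(state.counts.keys())
    counts = np.array([state.counts[k] for k in karyos], dtype=float)
    draw = rng.multinomial(n, counts / counts.sum())
    return {k: int(c) for k, c in zip(karyos, draw) if c > 0}


def run_simulation(config: SimConfig, landscape) -> SimResult:
    """Run the ABM with serial passaging and scheduled sampling.

    When ``sample_times`` is None (default) an observation is recorded at
    t = 0 and at every passage event (just before the bottleneck), emulating
    sequencing at each serial transfer. When explicit ``sample_times`` are
    given, observations occur at the first step crossing each time instead.
    """
    rng = np.random.default_rng(config.seed)
    fitness = _FitnessCache(landscape)
    mcache: dict = {}

    if config.init_counts is not None:
        counts = {tuple(k): int(v) for k, v in config.init_counts.items() if v > 0}
    else:
        counts = {tuple(config.founder): config.n_seed}
    state = PopulationState(counts=counts, t=0.0)

    records: list = []
    passage_times: list = []
    sample_at_passages = config.sample_times is None
    pending_times = sorted(config.sample_times) if config.sample_times else []

    def record(st: PopulationState):
        samp = sample_counts(st, config.sample_size, rng)
        records.append(
            PassageRecord(
                time=st.t,
                sample=samp,
                population_size=st.total,
                full=dict(st.counts) if config.record_full else None,
            )
        )

    if sample_at_passages:
        record(state)
    extinct = False
    while state.t < config.t_end - 1e-9:
        state = step_population(
            state, config, landscape, rng, _fitness=fitness, _mcache=mcache
        )
        if state.total == 0:
            extinct = True
            break
        while pending_times and state.t >= pending_times[0] - 1e-9:
            record(state)
            pending_times.pop(0)
        if state.total >= config.N_max:
            if sample_at_passages:
                record(state)
            passage_times.append(state.t)
            reseeded = sample_counts(state, config.n_seed, rng)
            state = PopulationState(counts=reseeded, t=state.t)
            if (
                config.max_passages is not None
                and len(passage_times) >= config.max_passages
            ):
                break
    return SimResult(
        records=records,
        final_state=state,
        extinct=extinct,
        passage_times=passage_times,
        config=config,
    )
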