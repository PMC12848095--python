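# Methods

This note documents the models implemented in `alfak`, the parameter choices
that matter, what the synthetic data generator does and does not emulate, and
the numerical decisions taken where the design was genuinely open.

## Karyotype space and the missegregation kernel

A karyotype is the ordered vector of integer copy numbers of the 22 human
autosomes; sex chromosomes and sub-chromosomal structure are out of scope.
States with a zero copy number are nonviable by default (a cell that has lost
every copy of an autosome dies); this is configurable where it matters.

One mitotic missegregation moves both sister chromatids of one chromosome
copy into the same daughter, changing that daughter's copy number by +1 and
its sibling's by −1 — so missegregation distance equals Manhattan (L1)
distance on the copy-number lattice, and each karyotype has 44 one-step
neighbors (a gain and a loss per autosome).

The transition kernel assumes each of the `n` copies of a chromosome
missegregates independently with per-copy probability `p` per division, and
each missegregating copy resolves toward a uniformly chosen daughter:

    n_daughter = n − m + 2g,   m ~ Binomial(n, p),   g ~ Binomial(m, 1/2).

The kernel is symmetric about `n` (gains and losses equally likely), the two
daughters of one division are complementary, and chromosomes are
independent, so the whole-karyotype kernel is the 22-fold product. The exact
convolution is computed once per (n, p) and cached; a brute-force per-copy
Monte Carlo simulator in the test-suite is the independent oracle for it.

`p` defaults to 7.5 × 10⁻⁴ per copy per division, a literature-scale average
for chromosomally unstable lines. The slope of the inferred landscape is
mathematically coupled to the assumed `p` (a larger assumed mutational
supply explains the same neighbor frequencies with lower neighbor fitness),
so `p` is a first-class configuration field, not a constant.

## Ground-truth landscapes (GRF)

Synthetic benchmarks need landscapes with controllable ruggedness. We
synthesize Gaussian random fields by random plane-wave superposition:

    f(k) = offset + (amplitude/√n_basis) Σ_j sin(2π⟨k, u_j⟩/λ + φ_j),

with u_j uniform unit directions in 22-D and phases φ_j ~ U(0, 2π). The
wavelength λ is Euclidean in copy-number space; fitness decorrelates over
roughly λ. Pointwise the field is asymptotically Gaussian with variance
amplitude²/2. Defaults: n_basis = 64, amplitude = 0.3/day, and the offset
calibrated per landscape so the diploid founder has fitness 1.0/day — the
division-per-day scale of immortalized mammary epithelial culture. The
smooth and rugged benchmark scenarios use λ = 1.6 and λ = 0.4; across this
range the fitness correlation between distance-1 neighbors spans roughly
0.7 down to ~0. Covariance-matrix sampling over an enumerated neighborhood
would give the same marginals at far higher cost and was rejected.

## Agent-based model

Cells carry karyotypes; fitness is the net growth rate. Time advances by
binomial thinning with step dt (default 0.1 day): a karyotype with count n
and fitness f ≥ 0 draws Binomial(n, f·dt) divisions; f < 0 instead draws
deaths at rate |f|. Each division replaces the parent with two complementary
daughters drawn from the missegregation kernel; zero-copy daughters (and, in
look-up-table mode with the `lethal` policy, daughters outside the table)
die at birth. An exact-stochastic scheme was rejected for speed at the
10⁴–10⁵ cell scale; the thinning scheme's discretization bias in the growth
exponent is O(f·dt) ≈ 1–5% per e-fold at the defaults and cancels entirely
from relative frequencies when fitnesses are equal.

Serial passaging triggers on capacity: when the population reaches N_max
(default 10⁴) it is multinomially reseeded to n_seed (default N_max/10), and
a multinomial sample of `sample_size` cells (default 500) is recorded just
before the bottleneck — the simulated single-cell sequencing measurement.
Division counts, daughter draws and sampling all run through one seeded
generator, so runs are bit-reproducible from the config.

## Inference

**Stage 1 (initialization).** Under the replicator solution the
log-frequencies of the frequent clones are linear in time up to a shared
offset: log x_i(t) − log x_i(t₀) = f_i (t − t₀) − c(t). We solve the
count-weighted least-squares problem in (f, c) — a convex program — with a
+0.5 continuity correction on zero counts (stage 1 only), and fix the gauge
by subtracting the count-weighted mean of f.

**Stage 2 (refinement).** The multinomial likelihood of the observed counts
under the closed-form replicator solution is maximized jointly over the
fitness vector and the initial frequencies x(0) (softmax-parameterized),
with analytic gradients. Optimizing x(0) matters: clones that enter the
frequent set mid-experiment have maximum-likelihood initial frequencies far
below their first observed frequency, and freezing x(0) at the observed
value systematically compresses the inferred fitness spread. The frequent
threshold `min_obs` trades coverage against noise; for the benchmark
studies we set it to ~1% of all sampled cells, below which a clone's
growth-slope MLE is dominated by sampling noise rather than fitness.

**Growth offset.** Only fitness differences are identified. The offset
correction shifts all estimates so the abundance-weighted mean fitness at
the first passage equals a declared baseline (default 0.5/day). All
downstream comparisons use differences; the baseline only anchors plots and
absolute division rates in forecasts.

**Neighbors.** Each viable one-step neighbor of the frequent set obeys the
linear influx equation given in the README; the dilution term −φ̄(t)x_i
(mean population fitness from the fitted replicator solution) is essential —
without it neighbor *frequencies* would grow at absolute rather than
relative rates and the absence likelihood would bias every neighbor far
below its parents. The equation is solved by integrating factor on a
201-point time grid; the per-division kernel is converted to per-time flux
by the parental division rate max(f_j, 0). The scalar posterior in f_i
(binomial likelihood + normal priors against adjacent parents,
μ_δ = 0, σ_δ = 0.1/day by default) is maximized by bounded search within
±6σ_δ of the parent range. σ_δ encodes how strongly a single
missegregation is expected to move fitness; the test-suite includes a
sensitivity check and the prior dominates exactly as σ_δ → 0.

**Kriging.** Anchors (frequent + neighbor estimates) feed a GP over raw
22-D copy-number vectors with kernel σ² · Matérn(ν = 3/2) and a single
isotropic length-scale fit by marginal likelihood. Numerical choices: the
length-scale is floored at 1.0 lattice unit (anchor pairs are never closer
than one missegregation, so sub-unit length-scales are pure noise fitting);
the signal variance σ² is fitted so long length-scales can represent smooth
large-scale trends; anchor noise is heteroscedastic — frequent anchors get
the nugget (default 10⁻³), neighbor anchors get σ_δ², reflecting that
neighbor estimates are prior-dominated. Without the heteroscedastic noise
the hundreds of noisy neighbor anchors drag the length-scale to the floor
and destroy interpolation. The look-up table covers the charted region
(radius 2 of the frequent set); anchor states keep their direct estimates,
all others take the GP mean.

**CV score.** Leave-one-out predictive R² over the frequent anchors,
computed by the closed-form LOO identity at the full fit's frozen
hyperparameters (with K = k(X,X) + diag(α), the held-out residual at
anchor i is (K⁻¹(y−ȳ))_i / (K⁻¹)_ii) — identical to refitting per anchor
but one O(n³) solve. The score is 1.0 for perfectly interpolable anchors,
near zero-or-negative for noise (both calibrations are in the test-suite),
and NaN (flagged) when anchor fitnesses have no variance.

**Bootstrap.** Percentile CIs on frequent fitness come from multinomial
resampling of cells within each passage and stage-1 refits, on the gauge
where the count-weighted mean fitness is zero.

## Forecasting and metrics

Forecasts seed the ABM from the last observed distribution (n_cells
multinomially allocated), run it in look-up-table mode for the horizon, and
average final frequencies over replicates. Change vectors for the angle
metric are differences of frequency-weighted mean karyotypes between
timepoints (the vectorization is a declared choice; alternative embeddings
can be plugged in). The directional null draws angles between independent
standard-Gaussian unit vectors in 22-D, matches the observed per-unit
sample sizes, and uses the median-of-per-unit-medians statistic; its median
is 90° by symmetry. Wasserstein-1 distances are exact discrete optimal
transport (HiGHS linear programming) with Euclidean ground metric
(Manhattan selectable). "Beats baseline" means strictly smaller
Wasserstein distance to the realized sample than the no-evolution baseline
(the last observed distribution); ties do not count.

## Downstream analyses

Δf profiles order the 44 single-step effects as (loss chr1, gain chr1, …);
losses into zero-copy states are flagged nonviable. Profile similarity is
Pearson over jointly viable entries with Fisher-z transform. WGD+ means
modal copy number ≥ 3 (modal ties resolve toward the smaller copy number —
deterministic and conservative for WGD classification). The WGD comparison
collapses Δf to per-fit means before a permutation KS test (10⁴ label
permutations at the fit level) to avoid pseudo-replication; note the KS
statistic is discrete for small group sizes, which makes the permutation
p-values conservative (type-I error is controlled at, not above, the
nominal level).

Emergence features d_i are the abundance-weighted fraction of the currently
observed population exactly i missegregations from a candidate (i = 1..5;
clone-weighted variant selectable), and the emergence model is a standard
maximum-likelihood logistic regression with two-sided Wald z tests;
separated data are flagged and fall back to a lightly ridge-penalized fit
with no standard errors.

The steady-state screen builds the quasispecies generation operator
A = K̃ · diag(e^{f_j dt}) over the charted region, where K̃ is the
per-division kernel restricted to the region and column-renormalized (flux
leaving the region is discarded — the declared approximation), and takes
the leading eigenvector by power iteration (tolerance 10⁻¹⁰, two
initializations, disagreement flags reducibility). Growth-weighting by the
parent's factor is what lets fitness shape the steady state; at p → 0 the
operator tends to diag(e^{f dt}) and all mass concentrates on the fittest
state, while at high rates broad plateaus out-compete narrow peaks — the
error threshold. Rate-response groups correlate per-karyotype steady-state
frequency with rate (Pearson by default) among the top-400 karyotypes;
|r| below 0.2 stays unassigned.

## Synthetic study conditions

The bundled scenarios are the package's study conditions, fixed once:
smooth (λ = 1.6) and rugged (λ = 0.4) GRF landscapes, founder fitness
1.0/day, amplitude 0.3/day, p = 7.5 × 10⁻⁴, N_max = 10⁴, n_seed = 10³,
dt = 0.1 day, 500 cells sampled per passage, 8 training passages after the
initial sample, and a forecast horizon at the third passage past training
(≈ 5–7 days). The horizon choice matters: one passage at this cadence is
too short for evolution to rise above the sampling noise of two 500-cell
samples, making any forecast-vs-baseline comparison a coin flip; by three
passages genuine compositional change dominates. The replicate studies run
20 end-to-end replicates; statistical calibrations use 100–200 replicates.

What the generator emulates: clonal interference, mutation-limited neighbor
emergence, serial-transfer bottlenecks, and finite single-cell sampling.
What it does not: measurement error in copy-number calling (counts are
exact draws from the population), sub-chromosomal events, cell-cell
interactions, time-varying landscapes, and the slower passage cadence of
xenografts (our cultures double daily, so passages are ~2.4 days apart).
Passing tests therefore demonstrate correctness of the machinery and
recoverability under idealized sampling, not robustness to copy-number
calling noise.

## Known limitations

- Frequent-clone fitness for late-emerging clones is the dominant error
  source: their trajectories mix mutational influx (not modeled within the
  frequent set) with growth, and sampling noise in their first appearances
  propagates into the landscape.
- Absence-based neighbor estimates are upper bounds in spirit; deleterious
  effects are biased toward the prior mean.
- The steady-state operator's boundary truncation makes screens
  approximate near the charted-region edge; enlarging the radius checks
  sensitivity.
- The identifiable quantity is always a fitness *difference*; absolute
  rates inherit the declared growth baseline.
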