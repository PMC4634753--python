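# Methods

## The problem

Next-generation sequencing of a mixed, unlabeled sample (pooled viral or
bacterial DNA, say) yields short reads that cannot be assigned to
individual genomes. After alignment to a reference, the only reliable
observable is the *proportion of each nucleotide at each site*. When such
samples are collected serially from the same evolving population at known
times, those sitewise proportions still carry information about two
population-genetic parameters: the haploid effective population size N and
the per-site, per-generation mutation rate μ. `serialfreq` implements two
estimators of (N, μ) that consume nothing but per-timepoint site-frequency
tables, plus the serial coalescent simulator both estimators depend on.

## Diversity statistics

For site s, timepoint t and base proportions F(s, j, t):

    D_intra(s, t)       = 1 − Σ_j F(s, j, t)²
    D_inter(s, t1, t2)  = 1 − Σ_j F(s, j, t1) F(s, j, t2)

and the means over n sites give D_intra(t) and D_inter(t1, t2). With T
timepoints there are T intra and T(T−1)/2 inter means. Under a neutral,
constant-size coalescent E[D_intra] ≈ θ = kNμ (k = 2 for haploids, the
default here, matching the microbial setting) and
E[D_inter(t1, t2)] ≈ θ + μ·Δt for sampling times Δt generations apart.

Note that D_intra computed from plug-in proportions of m sequences is the
probability that two draws *with replacement* differ, i.e. (1 − 1/m) times
the mean pairwise difference. This small-m shrinkage is deliberate — it is
what the formulas above prescribe — and it is the reason the least-squares
slope overestimates μ at small m (a behaviour the acceptance study
reproduces).

## Least-squares estimation

Stack the T + T(T−1)/2 mean diversities into Y (intra rows first, then
inter pairs in span-major order AB, BC, AC) and encode the model in X:
the θ column(s) are indicators, the μ column(s) carry elapsed generations.
Then B = (X′X)⁻¹X′Y estimates (θ, μ) and N̂ = θ̂/(kμ̂). Three
parameterizations are supported: constant θ/constant μ; one θ per
timepoint (an inter pair carries the θ of its *earlier* timepoint); and
one μ per adjacent interval (a long pair decomposes into the sum of its
adjacent intervals). Ordinary (unweighted) least squares is used
throughout; no variance model for the diversities is attempted.

Estimates are reported untruncated: on noisy data μ̂ (or θ̂) can be
negative, in which case N̂ is undefined (NaN, with a warning) rather than
silently clamped — truncation would bias the bootstrap and the
simulation-study coverage.

Confidence intervals use a site bootstrap: each of the (default 1000)
pseudoreplicates draws one vector of n site indices with replacement and
applies it to *all* timepoints, preserving the sitewise pairing that
D_inter requires; percentile 2.5/97.5 bounds are reported. Replicates with
μ̂ ≤ 0 stay in the θ and μ CIs and are excluded (counted) from the N CI.

The per-dataset ratio N̂ = θ̂/(2μ̂) deserves a caveat: its sampling
distribution is heavy-tailed, because μ̂'s noise is dominated by
genealogical (drift) fluctuations that do not shrink with sequence length
under complete linkage, and datasets with μ̂ near zero produce arbitrarily
large ratios. Averages of N̂ over replicate studies are therefore
unstable; the median is far better behaved. The study driver reports the
plain mean (excluding undefined values) for comparability, but any real
analysis should prefer the ABC posterior or at least a robust summary.

## Serial coalescent simulator

Backward in time, lineages from the most recent sample coalesce at rate
C(l, 2)/N per generation (continuous-time Kingman approximation, N
haploid); older samples join the active set when their sampling age is
reached. Mutations follow Jukes–Cantor: per branch, per site, events are
Poisson with rate μ per generation, each replacing the current base with
one of the other three uniformly; the root sequence is uniform per site.
JC is the minimal model consistent with statistics built from raw
nucleotide proportions. For branches whose expected event count exceeds
the number of sites, the implementation samples each site's end state
directly from the exact JC transition probability instead of enumerating
events — the same law with the event count marginalized out, bounding the
cost of mutation-saturated branches (which arise when ABC proposes extreme
μ values).

One root seed spawns labeled substreams for genealogy and mutations, so
each component replays independently. Default fixture length is 1000
sites, chosen so that θ-level diversity (θ = 0.06 at the study parameters)
is estimable at the study's sample sizes.

Calibration properties verified by the test suite: E[TMRCA] = N for n = 2
(and agreement with msprime, an independent implementation, at n = 6);
mean intra diversity equal to the finite-site JC expectation
(3/4)·x/(1+x)·(1−1/m), x = 4θ/3, at θ ∈ {0.01, 0.06, 0.2}; and the
inter-minus-intra excess tracking (3/4)(1 − e^{−4μΔt/3}) ≈ μΔt.

## Summary statistics and learned sufficient statistics

The raw summary vector per dataset (schema fixed, length 3T + 6·T(T−1)/2):
intra/inter diversity means; their sitewise population variances (divisor
n); a per-timepoint chi-square distance between the spectrum of the
most-frequent-base proportion (20 bins of width 0.05; half-open bins, top
bin closed; the bottom five bins are structurally empty since the max
proportion is ≥ 0.25) and the uniform reference; and, per timepoint pair,
counts of four exclusive site categories (identical-fixed; fixed in one
and same base uniquely most frequent in the other; both polymorphic with
the same unique plurality base; everything else). Ties for most-frequent
mean there is no unique majority, so tied sites fall into the fourth
category. "Fixed" means proportion 1 within 1e−12.

ABC needs low-dimensional, near-sufficient statistics. Following the
regression approach: draw training parameters uniformly (raw scale) from a
box spanning 0.2× to 5× the LS point estimates (falling back to
N ∈ [10, 1e6], μ ∈ [1e−8, 1e−3] if the LS anchor is unusable, and
intersecting with the prior support); simulate one dataset per draw under
the observed design; regress log10 N and log10 μ on the summary vector by
OLS. The log targets are the natural choice for scale parameters on a
multiplicative region under a 1/N prior. Summary columns are z-scored
internally before solving (diversities are ~1e−2, category counts ~1e3)
and the exact collinearity among each pair's four category counts is
resolved by the minimum-norm solution; a tiny standardized ridge exists as
a numerical fallback only. The two fitted linear combinations are the
sufficient statistics S = (S_N, S_μ); a schema hash binds a model to its
summary layout. Default training size is 2000 simulations (the full-scale
protocol uses 100000; both are exposed).

## ABC-MCMC

Priors: P(N) ∝ 1/N made proper on [1, 1e7] (config-exposed bounds), μ
uniform on [0, 1]. Proposals: a joint ("block") Gaussian random walk on
(ln N, ln μ) — both parameters move at every iteration, since independent
updates mix poorly here. For this walk the proposal density ratio in raw
coordinates is q(ϕᵢ|ϕ*)/q(ϕ*|ϕᵢ) = (N*μ*)/(Nᵢμᵢ), which combines with the
priors into the modified Metropolis–Hastings ratio

    α = min{1, q(ϕᵢ|ϕ*) P(ϕ*) / (q(ϕ*|ϕᵢ) P(ϕᵢ))}.

Each iteration simulates a full dataset at the proposal (same T, Δt,
sample sizes and site count as the observed data), projects its summary
vector through the trained model and rejects outright if

    d(S*, S°) = Σ_j (S*_j − S°_j)² / max(|S°_j|, 1e−3)  >  ε .

The absolute-value floor guards the denominator because the projected
statistics live on the log10 scale and can be ≤ 0. With ε = ∞ every
proposal passes the gate and the chain targets exactly the prior — the
test suite uses this to validate the proposal/prior bookkeeping by a
Kolmogorov–Smirnov test (the simulation step is skipped in that case; the
simulated data would influence nothing). ε itself is not part of the
published description; the default "auto" rule sets it to the 0.05
quantile of the distances between the training-stage projections and the
observed statistics, reusing simulations already paid for.

Chain mechanics follow the published protocol: 1e6 iterations by default,
every 1000th state recorded, first 10% discarded as burn-in, three
independent chains. Proposal scales (default 0.5 on the natural-log scale)
adapt by ×0.7/×1.3 steps toward a 10–30% acceptance band during burn-in,
clamped to [0.02, 5.0] so that a stretch of rejections cannot freeze the
walk, and are frozen after burn-in. The initial state is the training draw
whose projection is closest to the observed statistics: a random start
(even one restricted to the training region) can sit outside the
ε-passing set, where every proposal is rejected and the chain never moves;
the best training draw is guaranteed to pass the gate because ε is a
quantile of those same distances, and the burn-in discard removes the
initialization bias. If fewer than 0.1% of the first 1e4 iterations
accept, the run aborts with guidance instead of looping uselessly.

A run is labeled converged when the post-burn-in ESS (initial-positive-
sequence autocorrelation estimator, summed over chains) exceeds 100 for
both parameters and the between/within-chain variance ratio is below 1.1;
non-convergence sets a flag (and excludes the dataset from coverage
tallies in the study driver, mirroring the published convention of
re-running or excluding non-converged datasets). Posterior summaries are
pooled post-burn-in samples of all chains. The 95% HPD is the shortest
contiguous interval: sort the samples, slide a window of ⌈0.95·n⌉, take
the narrowest (leftmost on ties) — the same convention as Tracer-style
trace analysis.

## Problem sizes used by the shipped tests and acceptance script

The published studies use 100 datasets per design, 100000 training
simulations and chains of 1e6 iterations. The shipped test suite runs the
two least-squares studies at full replication (100 datasets each; they are
cheap) and the ABC study at desk scale: 12 datasets at the 3-timepoint ×
40-sequence, Δ = 400 design, 2000 training simulations and two chains of
12000 iterations per dataset. The `replicate-study` CLI exposes the
full-scale settings. `scripts/acceptance.py` recomputes the two
least-squares study means (t2/t4 designs) at full 100-dataset replication.

## What the simulations do and do not show

The generator emulates the published study conditions exactly as stated:
constant population size, neutral evolution, complete linkage (one
genealogy per dataset), JC mutation, error-free sitewise frequencies
obtained from full-length haplotypes. Passing tests therefore demonstrate
correctness of the estimators under those assumptions — not robustness to
recombination, selection, population-size change, sequencing error,
alignment error or indels, none of which are modeled. Real NGS data also
yield unequal per-site depths, whereas simulated tallies have uniform
depth m; the SAM reader handles ragged depth, but its statistical effect
on the estimators is not studied here.

## Known limitations

- The mean of per-dataset N̂ ratios is heavy-tailed (see above); printed
  study means for N are reproducible only in distribution, not tightly.
- The ε threshold, proposal family and N-prior bounds are this package's
  own design choices; the original description leaves them unspecified.
- At desk-scale chain lengths the μ posterior is wider than at full scale,
  which inflates the raw-scale posterior mean of μ somewhat.
- Indels and ambiguity codes are excluded from tallies; there is no
  fifth-state extension.
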