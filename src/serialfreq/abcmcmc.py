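"""ABC-MCMC sampler for (N, μ) with semi-automatic sufficient statistics.

Likelihood-free Metropolis–Hastings: at each iteration a new (N, μ) pair is
proposed by a Gaussian random walk on (log N, log μ) — both parameters
updated jointly, since independent updates mix poorly — a full dataset is
simulated under the serial coalescent at the proposal, its summary vector
is projected to the two learned sufficient statistics, and the proposal is
discarded outright if the distance

    d(S*, S°) = sum_j (S*_j - S°_j)^2 / g(S°_j),   g(x) = max(|x|, 1e-3)

to the observed statistics exceeds the threshold ε.  Proposals that pass
the gate are accepted with the modified Metropolis–Hastings probability

    α = min{1, q(ϕ_i | ϕ*) P(ϕ*) / (q(ϕ* | ϕ_i) P(ϕ_i))}

which involves the priors only — no likelihood.  Priors: P(N) ∝ 1/N on
[N_min, N_max] and μ uniform on [0, 1].  For the symmetric log-scale walk
the proposal density ratio is q(ϕ_i|ϕ*)/q(ϕ*|ϕ_i) = (N* μ*)/(N_i μ_i), so
with ε = ∞ the chain samples exactly from the (truncated) prior — a useful
validity check.

ε is not part of the published method description; by default it is set to
a low quantile of the distances between the training-stage projections and
the observed statistics ("auto" mode), re-using simulations already paid
for during sufficient-statistic training.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .coalsim import SimParams, simulate_frequency_matrices
from .sitefreq import SamplingDesign
from .suffstats import SufficientStatisticModel, project
from .summaries import SummaryVector, summary_vector

__all__ = [
    "AbcConfig",
    "McmcTrace",
    "HpdInterval",
    "ChainAbortError",
    "abc_distance",
    "propose_block",
    "acceptance_ratio",
    "auto_epsilon",
    "run_chain",
    "run_abc",
    "hpd",
    "effective_sample_size",
]

logger = logging.getLogger(__name__)

DISTANCE_FLOOR = 1e-3


class ChainAbortError(RuntimeError):
    """Raised when the chain cannot move (acceptance rate pathologically low)."""


@dataclass(frozen=True)
class AbcConfig:
    """Settings of one ABC-MCMC run.

    Defaults follow the published protocol: 10^6 iterations, every 1000th
    state recorded, first 10% discarded as burn-in, three independent
    chains.  Proposal scales are standard deviations of the Gaussian walk
    on (ln N, ln μ); during burn-in they adapt toward a 10–30% acceptance
    band and are frozen afterwards.
    """

    n_iterations: int = 1_000_000
    thin: int = 1000
    burnin_fraction: float = 0.1
    epsilon: float | str = "auto"  # numeric, or "auto" for training-quantile
    epsilon_auto_q: float = 0.05
    proposal_scale_logN: float = 0.5
    proposal_scale_logmu: float = 0.5
    adapt_proposals: bool = True
    n_prior_bounds: tuple[float, float] = (1.0, 1e7)
    seed: int = 0
    n_chains: int = 3
    min_acceptance_rate: float = 0.001
    acceptance_check_iter: int = 10_000

    def __post_init__(self) -> None:
        if not (0 <= self.burnin_fraction < 1):
            raise ValueError("burnin_fraction must be in [0, 1)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_prior_bounds[0] < 1:
            raise ValueError("N_min must be >= 1")
        if isinstance(self.epsilon, str):
            if self.epsilon != "auto":
                raise ValueError("epsilon must be a positive number or 'auto'")
        elif self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


@dataclass
class McmcTrace:
    """Thinned samples of one chain plus acceptance diagnostics."""

    iterations: np.ndarray  # recorded iteration numbers (multiples of thin)
    N: np.ndarray
    mu: np.ndarray
    distance: np.ndarray  # distance of each recorded state's statistics
    accepted: np.ndarray  # whether a move was accepted at the recorded iteration
    acceptance_rate: float
    epsilon: float
    config: AbcConfig
    final_scales: tuple[float, float]
    converged: bool | None = None

    @property
    def n_samples(self) -> int:
        return self.N.size

    def post_burnin(self) -> "McmcTrace":
        cut = int(math.floor(self.config.burnin_fraction * self.n_samples))
        return replace(
            self,
            iterations=self.iterations[cut:],
            N=self.N[cut:],
            mu=self.mu[cut:],
            distance=self.distance[cut:],
            accepted=self.accepted[cut:],
        )


@dataclass(frozen=True)
class HpdInterval:
    """Shortest interval holding a given posterior mass, plus point summaries."""

    lower: float
    upper: float
    mass: float
    mean: float
    median: float

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def abc_distance(S_star: Sequence[float], S_obs: Sequence[float]) -> float:
    """Chi-square-style distance between statistic vectors.

    Denominators are guarded by g(x) = max(|x|, 1e-3) because the projected
    statistics live on the log10 scale and can be <= 0.
    """
    a = np.asarray(S_star, dtype=float)
    b = np.asarray(S_obs, dtype=float)
    if a.shape != b.shape:
        raise ValueError("statistic vectors must have equal length")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite statistic values")
    denom = np.maximum(np.abs(b), DISTANCE_FLOOR)
    return float(np.sum((a - b) ** 2 / denom))


def propose_block(
    state: tuple[float, float],
    scales: tuple[float, float],
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Joint symmetric Gaussian random-walk proposal on (ln N, ln μ)."""
    N, mu = state
    if scales[0] > 0:
        N = math.exp(math.log(N) + rng.normal(0.0, scales[0]))
    if scales[1] > 0:
        mu = math.exp(math.log(mu) + rng.normal(0.0, scales[1]))
    return N, mu


def _log_prior(N: float, mu: float, n_bounds: tuple[float, float]) -> float:
    if not (n_bounds[0] <= N <= n_bounds[1]) or not (0.0 < mu <= 1.0):
        return -math.inf
    # P(N) ∝ 1/N (normalization constant cancels in the ratio); μ ~ U[0,1]
    return -math.log(N)


def acceptance_ratio(
    current: tuple[float, float],
    proposal: tuple[float, float],
    n_prior_bounds: tuple[float, float],
    proposal_density_ratio: float | None = None,
) -> float:
    """Modified Metropolis–Hastings ratio min{1, q·P(ϕ*) / P(ϕ_i)}.

    ``proposal_density_ratio`` is q(ϕ_i|ϕ*)/q(ϕ*|ϕ_i); if omitted, the
    log-scale symmetric-walk value (N* μ*)/(N_i μ_i) is used.
    """
    lp_cur = _log_prior(*current, n_prior_bounds)
    lp_new = _log_prior(*proposal, n_prior_bounds)
    if lp_new == -math.inf:
        return 0.0
    if proposal_density_ratio is None:
        proposal_density_ratio = (proposal[0] * proposal[1]) / (
            current[0] * current[1]
        )
    log_alpha = math.log(proposal_density_ratio) + lp_new - lp_cur
    return min(1.0, math.exp(min(log_alpha, 0.0)))


def auto_epsilon(
    model: SufficientStatisticModel,
    S_obs: tuple[float, float],
    q: float = 0.05,
) -> float:
    """ε as the q-quantile of training-projection distances to S_obs."""
    d = np.array([abc_distance(p, S_obs) for p in model.train_projections])
    return float(np.quantile(d, q))


def _draw_initial(
    model: SufficientStatisticModel,
    S_obs: tuple[float, float],
    n_prior_bounds: tuple[float, float],
) -> tuple[float, float]:
    """Initial state: the training draw whose projection is closest to S_obs.

    Starting from a random point of the (possibly vast) training region can
    strand the chain outside the ε-passing set for arbitrarily long, since
    every proposal is rejected by the distance gate.  The training stage has
    already evaluated the whole region, and because ε is set from these same
    distances, the best training draw is guaranteed to pass the gate.  The
    burn-in discard removes any initialization bias.
    """
    d = np.array([abc_distance(p, S_obs) for p in model.train_projections])
    N, mu = model.train_params[int(np.argmin(d))]
    N = float(np.clip(N, *n_prior_bounds))
    return N, float(min(mu, 1.0))


def run_chain(
    observed_summary: SummaryVector,
    model: SufficientStatisticModel,
    design: SamplingDesign,
    n_per_timepoint: Sequence[int] | int,
    n_sites: int,
    config: AbcConfig,
    initial_state: tuple[float, float] | None = None,
) -> McmcTrace:
    """Run one ABC-MCMC chain and return its thinned trace.

    Each iteration proposes a block (N, μ) move, simulates a dataset at the
    proposal matching the observed design, projects its summary vector to
    the sufficient statistics, applies the ε distance gate and then the
    modified MH acceptance.  The chain starts at the training draw closest
    (in projected-statistic distance) to the observed data, which is
    guaranteed to pass the gate; burn-in removes the initialization bias.
    With ε = ∞ the simulation step is skipped (the gate always passes and
    the simulated data influence nothing else), so the chain samples the
    prior exactly at negligible cost.

    Aborts with guidance if fewer than ``min_acceptance_rate`` of the first
    ``acceptance_check_iter`` iterations are accepted.
    """
    rng = np.random.default_rng(config.seed)
    S_obs = project(observed_summary, model)
    if config.epsilon == "auto":
        epsilon = auto_epsilon(model, S_obs, config.epsilon_auto_q)
        logger.info("auto epsilon (q=%g): %g", config.epsilon_auto_q, epsilon)
    else:
        epsilon = float(config.epsilon)
    skip_simulation = math.isinf(epsilon)

    if isinstance(n_per_timepoint, int):
        n_per_timepoint = [n_per_timepoint] * design.n_timepoints

    def simulate_projection(N: float, mu: float) -> tuple[float, float]:
        params = SimParams.make(N=N, mu=mu, times=design.times,
                                n_per_timepoint=n_per_timepoint, n_sites=n_sites)
        mats = simulate_frequency_matrices(params, rng)
        return project(summary_vector(mats, design), model)

    state = initial_state if initial_state is not None else _draw_initial(
        model, S_obs, config.n_prior_bounds
    )
    current_distance = math.nan
    scales = [config.proposal_scale_logN, config.proposal_scale_logmu]
    burnin_iter = int(config.burnin_fraction * config.n_iterations)
    adapt_window = 500
    window_accepts = 0

    n_rec = config.n_iterations // config.thin
    rec_iter = np.empty(n_rec, dtype=np.int64)
    rec_N = np.empty(n_rec)
    rec_mu = np.empty(n_rec)
    rec_dist = np.empty(n_rec)
    rec_acc = np.zeros(n_rec, dtype=bool)
    n_accept = 0
    rec = 0

    for it in range(1, config.n_iterations + 1):
        proposal = propose_block(state, (scales[0], scales[1]), rng)
        accepted = False
        alpha = acceptance_ratio(state, proposal, config.n_prior_bounds)
        if alpha > 0.0:
            if skip_simulation:
                dist = math.nan
                passes = True
            else:
                S_star = simulate_projection(*proposal)
                dist = abc_distance(S_star, S_obs)
                passes = dist <= epsilon
            if passes and rng.uniform() < alpha:
                state = proposal
                current_distance = dist
                accepted = True
        if accepted:
            n_accept += 1
            window_accepts += 1
        if config.adapt_proposals and it <= burnin_iter and it % adapt_window == 0:
            rate = window_accepts / adapt_window
            if rate < 0.10:
                # floor prevents a freeze spiral when nothing is accepted
                scales[0] = max(scales[0] * 0.7, 0.02)
                scales[1] = max(scales[1] * 0.7, 0.02)
            elif rate > 0.30:
                scales[0] = min(scales[0] * 1.3, 5.0)
                scales[1] = min(scales[1] * 1.3, 5.0)
            window_accepts = 0
        if it == config.acceptance_check_iter and config.n_iterations > it:
            if n_accept / it < config.min_acceptance_rate:
                raise ChainAbortError(
                    f"acceptance rate {n_accept / it:.2%} over the first {it} "
                    "iterations is below the abort threshold; epsilon is likely "
                    "too small or the proposal scales too large — raise epsilon "
                    "(or epsilon_auto_q) or reduce the proposal scales"
                )
        if it % config.thin == 0:
            rec_iter[rec] = it
            rec_N[rec] = state[0]
            rec_mu[rec] = state[1]
            rec_dist[rec] = current_distance
            rec_acc[rec] = accepted
            rec += 1
    return McmcTrace(
        iterations=rec_iter, N=rec_N, mu=rec_mu, distance=rec_dist,
        accepted=rec_acc, acceptance_rate=n_accept / config.n_iterations,
        epsilon=epsilon, config=config, final_scales=(scales[0], scales[1]),
    )


def effective_sample_size(values: np.ndarray) -> float:
    """ESS from the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        return float(n)
    x = x - x.mean()
    var = x @ x / n
    if var == 0:
        return float(n)
    acf = np.correlate(x, x, mode="full")[n - 1:] / (n * var)
    tau = 1.0
    for lag in range(1, n):
        if acf[lag] <= 0:
            break
        tau += 2.0 * acf[lag]
    return float(n / tau)


def _variance_ratio(chains: list[np.ndarray]) -> float:
    """Ratio of between+within to within-chain variance (PSRF-like, squared)."""
    m = len(chains)
    n = min(c.size for c in chains)
    arr = np.stack([c[:n] for c in chains])
    means = arr.mean(axis=1)
    W = arr.var(axis=1, ddof=1).mean()
    B = n * means.var(ddof=1)
    if W == 0:
        return 1.0
    var_hat = (n - 1) / n * W + B / n
    return float(var_hat / W)


@dataclass
class AbcResult:
    """Pooled multi-chain ABC-MCMC output."""

    chains: list[McmcTrace]
    converged: bool
    ess_N: float
    ess_mu: float
    variance_ratio_N: float
    variance_ratio_mu: float
    pooled_N: np.ndarray
    pooled_mu: np.ndarray

    def hpd_N(self, mass: float = 0.95) -> HpdInterval:
        return hpd(self.pooled_N, mass)

    def hpd_mu(self, mass: float = 0.95) -> HpdInterval:
        return hpd(self.pooled_mu, mass)


def run_abc(
    observed_summary: SummaryVector,
    model: SufficientStatisticModel,
    design: SamplingDesign,
    n_per_timepoint: Sequence[int] | int,
    n_sites: int,
    config: AbcConfig,
) -> AbcResult:
    """Run ``config.n_chains`` independent chains and pool post-burn-in samples.

    A run is labeled converged when the post-burn-in ESS exceeds 100 for
    both parameters and the between/within-chain variance ratio is < 1.1
    for both; non-convergence sets the flag rather than failing silently.
    """
    chains: list[McmcTrace] = []
    seeds = np.random.SeedSequence(config.seed).generate_state(config.n_chains)
    for c in range(config.n_chains):
        cfg = replace(config, seed=int(seeds[c] % (2**31)))
        chains.append(
            run_chain(observed_summary, model, design, n_per_timepoint,
                      n_sites, cfg)
        )
    post = [t.post_burnin() for t in chains]
    logs_N = [np.log(t.N) for t in post]
    logs_mu = [np.log(t.mu) for t in post]
    pooled_N = np.concatenate([t.N for t in post])
    pooled_mu = np.concatenate([t.mu for t in post])
    ess_N = sum(effective_sample_size(x) for x in logs_N)
    ess_mu = sum(effective_sample_size(x) for x in logs_mu)
    vr_N = _variance_ratio(logs_N) if len(post) > 1 else 1.0
    vr_mu = _variance_ratio(logs_mu) if len(post) > 1 else 1.0
    converged = ess_N > 100 and ess_mu > 100 and vr_N < 1.1 and vr_mu < 1.1
    if not converged:
        logger.warning(
            "run not converged: ESS(N)=%.1f ESS(mu)=%.1f VR(N)=%.3f VR(mu)=%.3f",
            ess_N, ess_mu, vr_N, vr_mu,
        )
    for t in chains:
        t.converged = converged
    return AbcResult(
        chains=chains, converged=converged, ess_N=ess_N, ess_mu=ess_mu,
        variance_ratio_N=vr_N, variance_ratio_mu=vr_mu,
        pooled_N=pooled_N, pooled_mu=pooled_mu,
    )


def hpd(trace_values: np.ndarray, mass: float = 0.95) -> HpdInterval:
    """Shortest contiguous interval containing ``mass`` of the samples.

    Sorts the values, slides a window of ceil(mass * n) samples and picks
    the narrowest (leftmost on ties) — the convention used by MCMC trace
    analysis tools.
    """
    x = np.sort(np.asarray(trace_values, dtype=float))
    n = x.size
    if n < 100:
        raise ValueError(f"need >= 100 samples for an HPD, got {n}")
    m = math.ceil(mass * n)
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return HpdInterval(
        lower=float(x[i]), upper=float(x[i + m - 1]), mass=mass,
        mean=float(x.mean()), median=float(np.median(x)),
    )
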