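"""End-to-end pipelines: one-dataset full runs and the replicated simulation study.

``full_run`` chains the whole method on one dataset: least-squares point
estimates -> training region -> sufficient-statistic training -> ABC-MCMC ->
HPD report.  ``replicate_study`` drives the simulation study: simulate many
datasets at known (N, μ), estimate each with LS and/or ABC-MCMC, and tally
how often the 95% intervals cover the truth.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .abcmcmc import AbcConfig, AbcResult, run_abc
from .coalsim import SimParams, simulate_frequency_matrices
from .lsq import BootstrapResult, LsFit, LsModelSpec, bootstrap_ci, estimate
from .sitefreq import SamplingDesign, SiteFrequencyMatrix
from .suffstats import (
    SufficientStatisticModel,
    make_training_region,
    train_sufficient_statistics,
)
from .summaries import summary_vector

__all__ = ["RunConfig", "FullRunResult", "StudyReport", "full_run",
           "replicate_study", "StudySpec"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration for a full single-dataset run.

    Serializes to a flat-key YAML mapping; CLI flags override file values.
    """

    times: tuple[float, ...] = (0.0, 400.0, 800.0)
    n_per_timepoint: tuple[int, ...] = (40, 40, 40)
    n_sites: int = 1000
    theta_mode: str = "constant"
    mu_mode: str = "constant"
    k: float = 2.0
    bootstrap_replicates: int = 1000
    k_train: int = 2000
    abc_iterations: int = 1_000_000
    abc_thin: int = 1000
    abc_burnin_fraction: float = 0.1
    abc_epsilon: float | str = "auto"
    abc_epsilon_auto_q: float = 0.05
    abc_chains: int = 3
    n_prior_min: float = 1.0
    n_prior_max: float = 1e7
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["times"] = list(self.times)
        data["n_per_timepoint"] = list(self.n_per_timepoint)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        data["times"] = tuple(data["times"])
        data["n_per_timepoint"] = tuple(data["n_per_timepoint"])
        return cls(**data)

    @property
    def design(self) -> SamplingDesign:
        return SamplingDesign.from_times(self.times)

    @property
    def model_spec(self) -> LsModelSpec:
        return LsModelSpec(theta_mode=self.theta_mode, mu_mode=self.mu_mode,
                           k=self.k)

    def abc_config(self, seed: int) -> AbcConfig:
        return AbcConfig(
            n_iterations=self.abc_iterations,
            thin=self.abc_thin,
            burnin_fraction=self.abc_burnin_fraction,
            epsilon=self.abc_epsilon,
            epsilon_auto_q=self.abc_epsilon_auto_q,
            n_chains=self.abc_chains,
            n_prior_bounds=(self.n_prior_min, self.n_prior_max),
            seed=seed,
        )


@dataclass
class FullRunResult:
    """Everything one full pipeline run produced for one dataset."""

    ls: LsFit
    bootstrap: BootstrapResult | None
    model: SufficientStatisticModel
    abc: AbcResult

    def report_row(self) -> dict[str, float | bool]:
        hn = self.abc.hpd_N()
        hm = self.abc.hpd_mu()
        return {
            "ls_theta": next(iter(self.ls.theta.values())),
            "ls_mu": next(iter(self.ls.mu.values())),
            "ls_N": next(iter(self.ls.N_hat.values())),
            "abc_mean_N": hn.mean,
            "abc_median_N": hn.median,
            "abc_hpd_N_lower": hn.lower,
            "abc_hpd_N_upper": hn.upper,
            "abc_mean_mu": hm.mean,
            "abc_median_mu": hm.median,
            "abc_hpd_mu_lower": hm.lower,
            "abc_hpd_mu_upper": hm.upper,
            "converged": self.abc.converged,
            "epsilon": self.abc.chains[0].epsilon,
            "training_r2_N": self.model.r2_N,
            "training_r2_mu": self.model.r2_mu,
        }


def full_run(
    matrices: Sequence[SiteFrequencyMatrix],
    config: RunConfig,
    run_bootstrap: bool = False,
) -> FullRunResult:
    """LS -> training region -> sufficient statistics -> ABC-MCMC -> HPDs."""
    design = config.design
    ls = estimate(matrices, design, config.model_spec)
    logger.info("stage ls: theta=%s mu=%s N=%s", ls.theta, ls.mu, ls.N_hat)
    boot = None
    if run_bootstrap:
        boot = bootstrap_ci(matrices, design, config.model_spec,
                            n_replicates=config.bootstrap_replicates,
                            seed=config.seed)
    region = make_training_region(ls, (config.n_prior_min, config.n_prior_max))
    model = train_sufficient_statistics(
        region, design, config.n_per_timepoint, config.n_sites,
        k_train=config.k_train, seed=config.seed,
    )
    logger.info("stage train: R2(N)=%.3f R2(mu)=%.3f", model.r2_N, model.r2_mu)
    obs = summary_vector(matrices, design)
    abc = run_abc(obs, model, design, config.n_per_timepoint, config.n_sites,
                  config.abc_config(config.seed))
    logger.info(
        "stage abc: epsilon=%g acceptance=%s converged=%s",
        abc.chains[0].epsilon,
        [f"{t.acceptance_rate:.2%}" for t in abc.chains],
        abc.converged,
    )
    return FullRunResult(ls=ls, bootstrap=boot, model=model, abc=abc)


@dataclass(frozen=True)
class StudySpec:
    """One cell of the simulation-study grid."""

    N: float = 3000.0
    mu: float = 1e-5
    n_timepoints: int = 5
    n_per_timepoint: int = 40
    generations_between: float = 200.0
    n_sites: int = 1000
    n_replicates: int = 100
    run_abc: bool = False
    k_train: int = 500
    abc_iterations: int = 100_000
    abc_thin: int = 100
    abc_chains: int = 3

    @property
    def design(self) -> SamplingDesign:
        times = [i * self.generations_between for i in range(self.n_timepoints)]
        return SamplingDesign.from_times(times)


@dataclass
class StudyReport:
    """Per-replicate rows plus coverage tallies for one study cell."""

    spec: StudySpec
    rows: list[dict]
    seed: int

    @property
    def mean_ls_mu(self) -> float:
        return float(np.mean([r["ls_mu"] for r in self.rows])) if self.rows else float("nan")

    @property
    def mean_ls_N(self) -> float:
        vals = [r["ls_N"] for r in self.rows if np.isfinite(r["ls_N"])]
        return float(np.mean(vals)) if vals else float("nan")

    def coverage(self, key_lower: str, key_upper: str, truth: float) -> tuple[int, int]:
        """(number covering, number counted); non-converged rows excluded."""
        hit = tot = 0
        for r in self.rows:
            if key_lower not in r or not r.get("converged", True):
                continue
            tot += 1
            if r[key_lower] <= truth <= r[key_upper]:
                hit += 1
        return hit, tot


def replicate_study(spec: StudySpec, seed: int = 0,
                    progress: bool = False) -> StudyReport:
    """Simulate ``spec.n_replicates`` datasets at the true (N, μ) and estimate each.

    Always runs LS; optionally the full ABC pipeline per replicate.
    Per-replicate failures are recorded on the row, not fatal.
    """
    root = np.random.SeedSequence(seed)
    rep_seeds = root.generate_state(max(spec.n_replicates, 1))
    rows: list[dict] = []
    design = spec.design
    for r in range(spec.n_replicates):
        rep_seed = int(rep_seeds[r] % (2**31))
        row: dict = {"replicate": r, "seed": rep_seed,
                     "true_N": spec.N, "true_mu": spec.mu}
        try:
            params = SimParams.make(
                N=spec.N, mu=spec.mu, times=design.times,
                n_per_timepoint=spec.n_per_timepoint, n_sites=spec.n_sites,
                seed=rep_seed,
            )
            mats = simulate_frequency_matrices(params)
            if spec.run_abc:
                cfg = RunConfig(
                    times=design.times,
                    n_per_timepoint=tuple([spec.n_per_timepoint] * spec.n_timepoints),
                    n_sites=spec.n_sites,
                    k_train=spec.k_train,
                    abc_iterations=spec.abc_iterations,
                    abc_thin=spec.abc_thin,
                    abc_chains=spec.abc_chains,
                    seed=rep_seed,
                )
                res = full_run(mats, cfg)
                row.update(res.report_row())
            else:
                ls = estimate(mats, design)
                row.update({
                    "ls_theta": next(iter(ls.theta.values())),
                    "ls_mu": next(iter(ls.mu.values())),
                    "ls_N": next(iter(ls.N_hat.values())),
                })
        except Exception as exc:  # pragma: no cover - defensive
            logger.error("replicate %d failed: %s", r, exc)
            row["error"] = str(exc)
        rows.append(row)
        if progress:
            print(f"replicate {r + 1}/{spec.n_replicates} done", flush=True)
    return StudyReport(spec=spec, rows=rows, seed=seed)


def write_study_report(report: StudyReport, path: str | Path) -> None:
    """TSV with '#' metadata header and one row per replicate."""
    keys: list[str] = []
    for row in report.rows:
        for k in row:
            if k not in keys:
                keys.append(k)
    with open(path, "w") as fh:
        fh.write(f"# serialfreq {__version__} study report\n")
        fh.write(f"# seed={report.seed}\n")
        for f_ in dataclasses.fields(report.spec):
            fh.write(f"# spec.{f_.name}={getattr(report.spec, f_.name)}\n")
        fh.write("# " + "\t".join(keys) + "\n")

        def fmt(v) -> str:
            if isinstance(v, bool) or v is None:
                return str(v)
            if isinstance(v, (int, np.integer)):
                return str(int(v))
            if isinstance(v, (float, np.floating)):
                return f"{float(v):.17g}"
            return str(v)

        for row in report.rows:
            fh.write("\t".join(fmt(row.get(k, "")) for k in keys) + "\n")
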