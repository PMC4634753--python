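"""Semi-automatic sufficient statistics via regression on simulated training data.

Choosing good low-dimensional ABC statistics by hand is hard.  The
semi-automatic approach instead *learns* one statistic per parameter: draw
training parameter values from a region anchored at the least-squares point
estimates, simulate a dataset for each draw under the serial coalescent,
compute the raw summary vector, and regress the known parameter values on
the summaries by ordinary least squares.  Each fitted linear combination is
then used as a single-valued (nearly) sufficient statistic in the ABC-MCMC
distance.

The regression targets are log10(N) and log10(μ): both are scale
parameters spanning decades, the training region is multiplicative, and the
1/N prior is uniform in log N.  Projections (and ABC distances) therefore
live on the log10 scale for observed and simulated data alike.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .coalsim import SimParams, simulate_frequency_matrices
from .lsq import LsFit
from .sitefreq import SamplingDesign
import hashlib

from .summaries import SummaryVector, summary_schema, summary_vector

__all__ = [
    "TrainingRegion",
    "SufficientStatisticModel",
    "make_training_region",
    "train_sufficient_statistics",
    "project",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

# wide fallback box covering the plausible microbial range, used when the
# LS anchor is unusable (non-finite or non-positive estimates)
FALLBACK_N_BOUNDS = (10.0, 1e6)
FALLBACK_MU_BOUNDS = (1e-8, 1e-3)

REGION_LOWER_FACTOR = 0.2
REGION_UPPER_FACTOR = 5.0


@dataclass(frozen=True)
class TrainingRegion:
    """Uniform training box for (N, μ), intersected with the prior support."""

    n_bounds: tuple[float, float]
    mu_bounds: tuple[float, float]

    def __post_init__(self) -> None:
        for lo, hi in (self.n_bounds, self.mu_bounds):
            if not (0 < lo < hi):
                raise ValueError("region bounds must satisfy 0 < lower < upper")

    def sample(self, size: int, rng: np.random.Generator) -> np.ndarray:
        """(size, 2) array of (N, μ) draws, uniform on the raw scale."""
        N = rng.uniform(*self.n_bounds, size=size)
        mu = rng.uniform(*self.mu_bounds, size=size)
        return np.column_stack([N, mu])


def make_training_region(
    ls: LsFit,
    n_prior_bounds: tuple[float, float] = (1.0, 1e7),
    mu_prior_bounds: tuple[float, float] = (0.0, 1.0),
) -> TrainingRegion:
    """Training box (0.2x, 5x) around the LS point estimates of N and μ.

    Falls back to a wide fixed box (with a prominent warning) when an LS
    estimate is non-finite or non-positive.  Bounds are intersected with
    the prior support.
    """
    mu_hat = next(iter(ls.mu.values()))
    n_hat = next(iter(ls.N_hat.values()))
    if np.isfinite(mu_hat) and mu_hat > 0:
        mu_bounds = (REGION_LOWER_FACTOR * mu_hat, REGION_UPPER_FACTOR * mu_hat)
    else:
        logger.warning(
            "LS mu estimate %g unusable; falling back to mu region %s",
            mu_hat, FALLBACK_MU_BOUNDS,
        )
        mu_bounds = FALLBACK_MU_BOUNDS
    if np.isfinite(n_hat) and n_hat > 0:
        n_bounds = (REGION_LOWER_FACTOR * n_hat, REGION_UPPER_FACTOR * n_hat)
    else:
        logger.warning(
            "LS N estimate %g unusable; falling back to N region %s",
            n_hat, FALLBACK_N_BOUNDS,
        )
        n_bounds = FALLBACK_N_BOUNDS
    n_bounds = (max(n_bounds[0], n_prior_bounds[0]),
                min(n_bounds[1], n_prior_bounds[1]))
    mu_bounds = (max(mu_bounds[0], 1e-300 if mu_prior_bounds[0] == 0 else mu_prior_bounds[0]),
                 min(mu_bounds[1], mu_prior_bounds[1]))
    return TrainingRegion(n_bounds=n_bounds, mu_bounds=mu_bounds)


@dataclass
class SufficientStatisticModel:
    """Fitted per-parameter linear combinations of the summary vector.

    ``coef_*`` multiply the raw summary vector; predictions are on the
    log10 scale of each parameter.  The schema hash binds the model to one
    summary-vector layout.  Training projections are retained so that the
    ABC threshold ε can be set from the training-distance distribution
    without paying for new simulations.
    """

    schema: tuple[str, ...]
    schema_hash: str
    transform: str  # "log10"
    intercept_N: float
    coef_N: np.ndarray
    intercept_mu: float
    coef_mu: np.ndarray
    k_train: int
    r2_N: float
    r2_mu: float
    train_params: np.ndarray  # (k_train, 2) raw (N, mu) draws
    train_projections: np.ndarray  # (k_train, 2) fitted (S_N, S_mu)
    ridge_alpha: float = 0.0

    def predict(self, values: np.ndarray) -> tuple[float, float]:
        s_n = self.intercept_N + float(values @ self.coef_N)
        s_mu = self.intercept_mu + float(values @ self.coef_mu)
        return s_n, s_mu


def _fit_linear(S: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, float]:
    """Regress y on standardized summary columns; return raw-scale fit.

    Columns are z-scored before solving so that statistics on very
    different scales (diversities ~1e-2, category counts ~1e3) are treated
    evenly.  Exact collinearities (the four category counts of a pair sum
    to n_sites) are handled by the minimum-norm least-squares solution; a
    tiny standardized ridge is the fallback if the solve itself fails.
    Returns (intercept, coefficients, ridge_alpha) on the raw scale.
    """
    m = S.mean(axis=0)
    s = S.std(axis=0)
    s = np.where(s > 0, s, 1.0)
    Xs = (S - m) / s
    alpha = 0.0
    try:
        beta_s, *_ = np.linalg.lstsq(Xs, y - y.mean(), rcond=None)
    except np.linalg.LinAlgError:  # pragma: no cover - numerical corner
        alpha = 1e-6 * Xs.shape[0]
        logger.warning("least-squares solve failed; ridge fallback alpha=%g", alpha)
        p = Xs.shape[1]
        beta_s = np.linalg.solve(Xs.T @ Xs + alpha * np.eye(p), Xs.T @ (y - y.mean()))
    coef = beta_s / s
    intercept = float(y.mean() - m @ coef)
    return intercept, coef, alpha


def train_sufficient_statistics(
    region: TrainingRegion,
    design: SamplingDesign,
    n_per_timepoint: Sequence[int] | int,
    n_sites: int,
    k_train: int = 2000,
    seed: int = 0,
) -> SufficientStatisticModel:
    """Fit the per-parameter sufficient-statistic regressions.

    Draws ``k_train`` (N, μ) pairs uniformly from the region, simulates one
    dataset per draw matching the observed sampling design, computes each
    dataset's summary vector and regresses log10(N) and log10(μ) on the
    summaries.  Deterministic given ``seed``.
    """
    schema = summary_schema(design)
    schema_hash = hashlib.sha256("\t".join(schema).encode()).hexdigest()[:16]
    p = len(schema)
    if k_train < 10 * p:
        raise ValueError(
            f"k_train={k_train} too small: need >= 10 x {p} summary statistics"
        )
    rng = np.random.default_rng(seed)
    params = region.sample(k_train, rng)
    S = np.empty((k_train, p))
    for i, (N, mu) in enumerate(params):
        mats = simulate_frequency_matrices(
            SimParams.make(N=N, mu=mu, times=design.times,
                           n_per_timepoint=n_per_timepoint, n_sites=n_sites),
            rng,
        )
        S[i] = summary_vector(mats, design).values
    y_N = np.log10(params[:, 0])
    y_mu = np.log10(params[:, 1])
    int_N, coef_N, alpha_N = _fit_linear(S, y_N)
    int_mu, coef_mu, alpha_mu = _fit_linear(S, y_mu)

    def r2(y: np.ndarray, yhat: np.ndarray) -> float:
        resid = y - yhat
        return float(1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean())))

    pred_N = int_N + S @ coef_N
    pred_mu = int_mu + S @ coef_mu
    return SufficientStatisticModel(
        schema=schema,
        schema_hash=schema_hash,
        transform="log10",
        intercept_N=int_N,
        coef_N=coef_N,
        intercept_mu=int_mu,
        coef_mu=coef_mu,
        k_train=k_train,
        r2_N=r2(y_N, pred_N),
        r2_mu=r2(y_mu, pred_mu),
        train_params=params,
        train_projections=np.column_stack([pred_N, pred_mu]),
        ridge_alpha=max(alpha_N, alpha_mu),
    )


def save_model(model: SufficientStatisticModel, path) -> None:
    """Write a model as a self-describing TSV (schema hash, transform, coefficients,
    training draws and their fitted projections)."""
    with open(path, "w") as fh:
        fh.write("# serialfreq sufficient-statistic model\n")
        fh.write(f"# schema_hash={model.schema_hash}\n")
        fh.write(f"# transform={model.transform}\n")
        fh.write(f"# k_train={model.k_train}\n")
        fh.write(f"# r2_N={model.r2_N:.17g}\tr2_mu={model.r2_mu:.17g}\n")
        fh.write(f"# ridge_alpha={model.ridge_alpha:.17g}\n")
        fh.write(f"intercept\t-\t{model.intercept_N:.17g}\t{model.intercept_mu:.17g}\n")
        for name, cn, cm in zip(model.schema, model.coef_N, model.coef_mu):
            fh.write(f"coef\t{name}\t{cn:.17g}\t{cm:.17g}\n")
        for (N, mu), (sn, sm) in zip(model.train_params, model.train_projections):
            fh.write(f"train\t{N:.17g}\t{mu:.17g}\t{sn:.17g}\t{sm:.17g}\n")


def load_model(path) -> SufficientStatisticModel:
    """Read a model written by :func:`save_model`."""
    meta: dict[str, str] = {}
    schema: list[str] = []
    coef_N: list[float] = []
    coef_mu: list[float] = []
    intercepts = (0.0, 0.0)
    train_p: list[tuple[float, float]] = []
    train_s: list[tuple[float, float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].strip().split("\t"):
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        meta[k] = v
                continue
            parts = line.split("\t")
            if parts[0] == "intercept":
                intercepts = (float(parts[2]), float(parts[3]))
            elif parts[0] == "coef":
                schema.append(parts[1])
                coef_N.append(float(parts[2]))
                coef_mu.append(float(parts[3]))
            elif parts[0] == "train":
                train_p.append((float(parts[1]), float(parts[2])))
                train_s.append((float(parts[3]), float(parts[4])))
    return SufficientStatisticModel(
        schema=tuple(schema),
        schema_hash=meta["schema_hash"],
        transform=meta.get("transform", "log10"),
        intercept_N=intercepts[0],
        coef_N=np.array(coef_N),
        intercept_mu=intercepts[1],
        coef_mu=np.array(coef_mu),
        k_train=int(meta.get("k_train", len(train_p))),
        r2_N=float(meta.get("r2_N", "nan")),
        r2_mu=float(meta.get("r2_mu", "nan")),
        train_params=np.array(train_p),
        train_projections=np.array(train_s),
        ridge_alpha=float(meta.get("ridge_alpha", "0.0")),
    )


def project(
    summary: SummaryVector, model: SufficientStatisticModel
) -> tuple[float, float]:
    """Project a summary vector to its two sufficient statistics (S_N, S_mu)."""
    if summary.schema_hash != model.schema_hash:
        raise ValueError(
            "summary vector schema does not match the trained model "
            f"({summary.schema_hash} != {model.schema_hash})"
        )
    return model.predict(summary.values)
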