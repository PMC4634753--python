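"""Least-squares estimation of θ and μ from serial diversity statistics.

Under a constant-size neutral coalescent the mean intra-timepoint diversity
estimates θ = kNμ (k = 2 haploid) and the mean inter-timepoint diversity
between samples Δt generations apart estimates θ + μΔt.  Stacking the
T intra and T(T-1)/2 inter mean diversities into a response vector Y and
encoding how θ and μ enter each expectation in a design matrix X gives the
linear model Y = XB, solved by ordinary least squares B = (X'X)⁻¹X'Y.
The effective population size is then recovered as N = θ/(kμ).

Three parameterizations are supported: constant θ / constant μ (the
2-parameter model), one θ per timepoint with a shared μ (an inter pair
(a, b) carries the θ of its earlier timepoint a), and a constant θ with one
μ per adjacent interval (an inter pair decomposes into the sum of its
adjacent-interval contributions).

Confidence intervals come from a site bootstrap: each pseudoreplicate
resamples site indices with replacement — one index vector shared across
all timepoints so that sitewise inter-timepoint pairing is preserved —
re-tallies frequencies and refits; CIs are the empirical 2.5/97.5
percentiles of the replicate estimates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sitefreq import (
    DiversitySet,
    SamplingDesign,
    SiteFrequencyMatrix,
    mean_diversities,
)

__all__ = [
    "LsModelSpec",
    "LsFit",
    "BootstrapResult",
    "build_design",
    "ls_fit",
    "estimate",
    "bootstrap_ci",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LsModelSpec:
    """Which least-squares parameterization to fit.

    ``k`` is the ploidy proportionality constant in θ = kNμ; the default 2
    is the haploid value appropriate for viral or bacterial samples.
    """

    theta_mode: str = "constant"  # constant | per_timepoint
    mu_mode: str = "constant"  # constant | per_interval
    k: float = 2.0

    def __post_init__(self) -> None:
        if self.theta_mode not in ("constant", "per_timepoint"):
            raise ValueError(f"unknown theta_mode {self.theta_mode!r}")
        if self.mu_mode not in ("constant", "per_interval"):
            raise ValueError(f"unknown mu_mode {self.mu_mode!r}")
        if self.k <= 0:
            raise ValueError("k must be positive")

    def n_parameters(self, T: int) -> int:
        return (T if self.theta_mode == "per_timepoint" else 1) + (
            T - 1 if self.mu_mode == "per_interval" else 1
        )


@dataclass
class LsFit:
    """An ordinary least-squares fit of the diversity system."""

    B: np.ndarray
    col_labels: list[str]
    row_labels: list[str]
    X: np.ndarray
    Y: np.ndarray
    residuals: np.ndarray
    k: float
    theta: dict[str, float]
    mu: dict[str, float]
    N_hat: dict[str, float]  # NaN where mu_hat <= 0

    @property
    def fitted(self) -> np.ndarray:
        return self.X @ self.B


@dataclass
class BootstrapResult:
    """Site-bootstrap percentile confidence intervals for an LS fit."""

    n_replicates: int
    seed: int
    col_labels: list[str]
    replicate_B: np.ndarray  # (n_replicates, p)
    replicate_N: dict[str, np.ndarray]
    ci: dict[str, tuple[float, float]]  # per parameter label, 2.5/97.5 pct
    n_invalid_N: dict[str, int]  # replicates with mu_hat <= 0, excluded from N CI


def build_design(
    design: SamplingDesign, model_spec: LsModelSpec
) -> tuple[np.ndarray, list[str], list[str]]:
    """Design matrix X for the chosen parameterization.

    Rows: all intra diversities in timepoint order, then all inter
    diversities in span-major pair order (AB, BC, AC).  θ columns are 0/1
    indicators;
    μ columns carry elapsed generations (decomposed per adjacent interval
    when ``mu_mode='per_interval'``).
    """
    T = design.n_timepoints
    p = model_spec.n_parameters(T)
    n_rows = T + T * (T - 1) // 2
    if p > n_rows:
        raise ValueError(
            f"under-determined model: {p} parameters but only {n_rows} equations "
            f"for T={T} timepoints"
        )
    if model_spec.theta_mode == "per_timepoint":
        theta_cols = [f"theta_{lab}" for lab in design.labels]
    else:
        theta_cols = ["theta"]
    if model_spec.mu_mode == "per_interval":
        mu_cols = [
            f"mu_{design.labels[i]}{design.labels[i + 1]}" for i in range(T - 1)
        ]
    else:
        mu_cols = ["mu"]
    col_labels = theta_cols + mu_cols
    n_theta = len(theta_cols)

    rows = []
    row_labels = []
    for t, lab in enumerate(design.labels):
        row = np.zeros(p)
        row[t if n_theta > 1 else 0] = 1.0
        rows.append(row)
        row_labels.append(f"intra_{lab}")
    for a, b in design.pairs:
        row = np.zeros(p)
        # inter pair carries the θ of its earlier timepoint
        row[a if n_theta > 1 else 0] = 1.0
        if model_spec.mu_mode == "per_interval":
            for i in range(a, b):
                row[n_theta + i] = design.times[i + 1] - design.times[i]
        else:
            row[n_theta] = design.elapsed(a, b)
        rows.append(row)
        row_labels.append(f"inter_{design.labels[a]}{design.labels[b]}")
    X = np.array(rows)
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        raise ValueError(f"design matrix rank {rank} < {p} parameters")
    return X, row_labels, col_labels


def _n_hat_pairings(col_labels: list[str]) -> list[tuple[str, str, str]]:
    """(label, theta column, mu column) triples for N = θ/(kμ)."""
    theta_cols = [c for c in col_labels if c.startswith("theta")]
    mu_cols = [c for c in col_labels if c.startswith("mu")]
    if len(theta_cols) == 1 and len(mu_cols) == 1:
        return [("N", theta_cols[0], mu_cols[0])]
    if len(mu_cols) == 1:
        return [(f"N_{c.split('_', 1)[1]}", c, mu_cols[0]) for c in theta_cols]
    return [(f"N_{c.split('_', 1)[1]}", theta_cols[0], c) for c in mu_cols]


def ls_fit(
    Y: np.ndarray | DiversitySet,
    X: np.ndarray,
    k: float = 2.0,
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
    warn_invalid: bool = True,
) -> LsFit:
    """Solve Y = XB by ordinary least squares and derive N = θ/(kμ).

    Estimates may be negative on noisy data and are reported untruncated;
    pairings with μ̂ ≤ 0 yield NaN for N with a warning.
    """
    if isinstance(Y, DiversitySet):
        Y = Y.response_vector
    Y = np.asarray(Y, dtype=float)
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design matrix")
    B, *_ = np.linalg.lstsq(X, Y, rcond=None)
    cols = list(col_labels) if col_labels is not None else [f"b{i}" for i in range(p)]
    rows = list(row_labels) if row_labels is not None else [f"y{i}" for i in range(len(Y))]
    est = dict(zip(cols, B))
    theta = {c: float(est[c]) for c in cols if c.startswith("theta")}
    mu = {c: float(est[c]) for c in cols if c.startswith("mu")}
    N_hat = {}
    for label, tc, mc in _n_hat_pairings(cols):
        if est[mc] > 0:
            N_hat[label] = float(est[tc] / (k * est[mc]))
        else:
            if warn_invalid:
                logger.warning(
                    "mu estimate %s = %g is not positive; %s undefined",
                    mc, est[mc], label,
                )
            N_hat[label] = float("nan")
    return LsFit(
        B=B, col_labels=cols, row_labels=rows, X=X, Y=Y,
        residuals=Y - X @ B, k=k, theta=theta, mu=mu, N_hat=N_hat,
    )


def estimate(
    matrices: Sequence[SiteFrequencyMatrix],
    design: SamplingDesign,
    model_spec: LsModelSpec = LsModelSpec(),
) -> LsFit:
    """Convenience: diversities + design matrix + fit in one call."""
    div = mean_diversities(matrices, design)
    X, row_labels, col_labels = build_design(design, model_spec)
    return ls_fit(div, X, k=model_spec.k, row_labels=row_labels,
                  col_labels=col_labels)


def bootstrap_ci(
    matrices: Sequence[SiteFrequencyMatrix],
    design: SamplingDesign,
    model_spec: LsModelSpec = LsModelSpec(),
    n_replicates: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Site-bootstrap percentile CIs for all LS parameters.

    One resampled site-index vector per pseudoreplicate, shared across
    timepoints.  Replicates with μ̂ ≤ 0 are retained for the θ and μ CIs and
    excluded (with a count) from the N CIs.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = np.random.default_rng(seed)
    X, row_labels, col_labels = build_design(design, model_spec)
    pinv = np.linalg.pinv(X)
    n = matrices[0].n_sites
    freqs = np.stack([m.freqs for m in matrices])  # (T, n, 4)
    pairs = design.pairs
    T = design.n_timepoints

    rep_B = np.empty((n_replicates, X.shape[1]))
    for r in range(n_replicates):
        idx = rng.integers(0, n, size=n)
        f = freqs[:, idx, :]
        intra = 1.0 - np.einsum("tsj,tsj->ts", f, f).mean(axis=1)
        inter = np.array(
            [np.mean(1.0 - np.einsum("sj,sj->s", f[a], f[b])) for a, b in pairs]
        )
        Y = np.concatenate([intra, inter]) if pairs else intra[:T]
        rep_B[r] = pinv @ Y
    est = {c: rep_B[:, i] for i, c in enumerate(col_labels)}
    rep_N: dict[str, np.ndarray] = {}
    n_invalid: dict[str, int] = {}
    for label, tc, mc in _n_hat_pairings(col_labels):
        mu_vals = est[mc]
        valid = mu_vals > 0
        n_invalid[label] = int((~valid).sum())
        vals = np.full(n_replicates, np.nan)
        vals[valid] = est[tc][valid] / (model_spec.k * mu_vals[valid])
        rep_N[label] = vals
    ci: dict[str, tuple[float, float]] = {}
    for c in col_labels:
        lo, hi = np.percentile(est[c], [2.5, 97.5])
        ci[c] = (float(lo), float(hi))
    for label, vals in rep_N.items():
        ok = vals[np.isfinite(vals)]
        if ok.size >= 2:
            lo, hi = np.percentile(ok, [2.5, 97.5])
            ci[label] = (float(lo), float(hi))
        else:
            ci[label] = (float("nan"), float("nan"))
    return BootstrapResult(
        n_replicates=n_replicates, seed=seed, col_labels=col_labels,
        replicate_B=rep_B, replicate_N=rep_N, ci=ci, n_invalid_N=n_invalid,
    )
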