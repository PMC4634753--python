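"""Serial-sample constant-size coalescent simulator with per-site mutation.

Generates the heterochronous alignments both estimators are built for:
samples of sequences taken from the same constant-size haploid population at
several known times.  Looking backward in time, lineages from the most
recent sample coalesce as a Kingman coalescent at rate C(l,2)/N per
generation; older samples join the active lineage set when their sampling
time is reached.  Mutations are dropped on the resulting genealogy as a
Poisson process of rate μ per site per generation under the Jukes–Cantor
model (each event replaces the current base by one of the other three,
uniformly), with the root sequence uniform over A/C/G/T per site.

Units: times and branch lengths are in generations; N is the haploid
effective size, so the expected pairwise intra-sample diversity is
θ = 2Nμ per site (before finite-site saturation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sitefreq import NUCLEOTIDES, SamplingDesign, SiteFrequencyMatrix

__all__ = [
    "SimParams",
    "Genealogy",
    "SerialAlignment",
    "simulate_genealogy",
    "drop_mutations",
    "simulate",
    "simulate_frequency_matrices",
]


@dataclass(frozen=True)
class SimParams:
    """Parameters of one serial-coalescent simulation."""

    N: float
    mu: float
    design: SamplingDesign
    n_per_timepoint: tuple[int, ...]
    n_sites: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("N must be positive")
        if self.mu < 0:
            raise ValueError("mu must be non-negative")
        if len(self.n_per_timepoint) != self.design.n_timepoints:
            raise ValueError("one sample size per timepoint required")
        if any(k < 1 for k in self.n_per_timepoint):
            raise ValueError("sample sizes must be >= 1")
        if self.n_sites < 1:
            raise ValueError("n_sites must be >= 1")

    @classmethod
    def make(
        cls,
        N: float,
        mu: float,
        times: Sequence[float],
        n_per_timepoint: int | Sequence[int],
        n_sites: int = 1000,
        seed: int | None = None,
    ) -> "SimParams":
        design = SamplingDesign.from_times(times)
        if isinstance(n_per_timepoint, int):
            npt = tuple([n_per_timepoint] * design.n_timepoints)
        else:
            npt = tuple(int(k) for k in n_per_timepoint)
        return cls(N=float(N), mu=float(mu), design=design, n_per_timepoint=npt,
                   n_sites=int(n_sites), seed=seed)


@dataclass
class Genealogy:
    """Binary serial-coalescent tree.

    Nodes 0..n_tips-1 are tips; internal nodes are appended in coalescence
    order, so every parent has a larger id than its children and the root is
    the last node.  ``node_age`` is backward time in generations measured
    from the most recent sampling time.
    """

    parent: np.ndarray  # (2n-1,), parent id; root has -1
    node_age: np.ndarray  # (2n-1,), generations before the latest sample
    tip_timepoint: np.ndarray  # (n_tips,), timepoint index per tip

    @property
    def n_tips(self) -> int:
        return self.tip_timepoint.size

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def tmrca(self) -> float:
        return float(self.node_age[self.root])

    @property
    def total_branch_length(self) -> float:
        bl = self.node_age[self.parent[:-1]] - self.node_age[:-1]
        return float(bl.sum())


@dataclass
class SerialAlignment:
    """Per-timepoint haplotype alignments produced by one simulation."""

    design: SamplingDesign
    codes: list[np.ndarray]  # per timepoint, (n_seq, n_sites) int8 in 0..3
    genealogy: Genealogy | None = None

    @property
    def n_sites(self) -> int:
        return self.codes[0].shape[1]

    def sequences(self, timepoint_index: int) -> list[str]:
        """ACGT strings for one timepoint."""
        lut = np.frombuffer(NUCLEOTIDES.encode("ascii"), dtype=np.uint8)
        return [
            lut[row].tobytes().decode("ascii") for row in self.codes[timepoint_index]
        ]

    def frequency_matrices(self) -> list[SiteFrequencyMatrix]:
        return [
            _counts_matrix(codes, label)
            for codes, label in zip(self.codes, self.design.labels)
        ]


def _counts_matrix(codes: np.ndarray, label: str) -> SiteFrequencyMatrix:
    n_seq, n_sites = codes.shape
    # single bincount pass: site-major offsets 4*s + base
    idx = (codes.astype(np.int64) + 4 * np.arange(n_sites, dtype=np.int64)[None, :]).ravel()
    counts = np.bincount(idx, minlength=4 * n_sites).reshape(n_sites, 4).astype(float)
    return SiteFrequencyMatrix(timepoint=label, counts=counts,
                               depth=np.full(n_sites, float(n_seq)))


def simulate_genealogy(params: SimParams, rng: np.random.Generator | None = None) -> Genealogy:
    """Draw one serial-sample Kingman genealogy.

    Continuous-time approximation: with ``l`` active lineages the waiting
    time to the next coalescence is Exponential with rate l(l-1)/(2N) per
    generation; lineages sampled at older timepoints enter when backward
    time reaches their age.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    times = params.design.times
    t_max = times[-1]
    # tips grouped by timepoint, ages backward from the latest sample
    tip_tp = np.repeat(np.arange(params.design.n_timepoints),
                       params.n_per_timepoint)
    n_tips = tip_tp.size
    tip_age = np.array([t_max - times[tp] for tp in tip_tp])

    n_nodes = 2 * n_tips - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    node_age = np.zeros(n_nodes)
    node_age[:n_tips] = tip_age

    # pending tip groups sorted by age ascending (most recent first)
    order = np.argsort(tip_age, kind="stable")
    pending = list(order)
    active: list[int] = []
    t = 0.0
    next_id = n_tips

    # batched uniform stream: scalar Generator calls dominate otherwise
    buf = rng.random(8 * n_tips + 16)
    pos = 0

    def draw() -> float:
        nonlocal buf, pos
        if pos >= buf.size:
            buf = rng.random(buf.size)
            pos = 0
        u = buf[pos]
        pos += 1
        return u

    while pending or len(active) > 1:
        # admit tips whose age has been reached
        while pending and tip_age[pending[0]] <= t:
            active.append(int(pending.pop(0)))
        l = len(active)
        if l < 2:
            t = tip_age[pending[0]]
            continue
        rate = l * (l - 1) / (2.0 * params.N)
        wait = -math.log(1.0 - draw()) / rate
        if pending and t + wait > tip_age[pending[0]]:
            t = tip_age[pending[0]]
            continue
        t += wait
        # uniform unordered pair without replacement
        i = int(draw() * l)
        j = int(draw() * (l - 1))
        if j >= i:
            j += 1
        a, b = active[i], active[j]
        node_age[next_id] = t
        parent[a] = next_id
        parent[b] = next_id
        for idx in sorted((i, j), reverse=True):
            active.pop(idx)
        active.append(next_id)
        next_id += 1
    return Genealogy(parent=parent, node_age=node_age, tip_timepoint=tip_tp)


def drop_mutations(
    genealogy: Genealogy,
    mu: float,
    n_sites: int,
    rng: np.random.Generator | int | None = None,
    design: SamplingDesign | None = None,
) -> SerialAlignment:
    """Evolve sequences down a genealogy under Jukes–Cantor mutation.

    Per branch the number of mutation events across all sites is
    Poisson(μ · branch length · n_sites); each event hits a uniform site and
    replaces its current base with one of the other three uniformly.  The
    root sequence is uniform over A/C/G/T per site.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n_nodes = genealogy.n_nodes
    n_tips = genealogy.n_tips
    root = genealogy.root
    seqs: list[np.ndarray | None] = [None] * n_nodes
    seqs[root] = rng.integers(0, 4, size=n_sites, dtype=np.int8)
    # batch all branch draws (Poisson counts, hit sites, base shifts) upfront;
    # mutation-saturated branches (expected events > n_sites) are evolved via
    # the exact per-site JC transition probability instead — the end state
    # has the same law with the event count marginalized out, at O(n_sites)
    # cost instead of O(events)
    branch_len = genealogy.node_age[genealogy.parent[:-1]] - genealogy.node_age[:-1]
    lam = mu * n_sites * branch_len
    saturated = lam > n_sites
    n_events = np.where(saturated, 0, rng.poisson(np.where(saturated, 0.0, lam)))
    total = int(n_events.sum())
    sites = rng.integers(0, n_sites, size=total)
    shifts = rng.integers(1, 4, size=total)
    offsets = np.concatenate([[0], np.cumsum(n_events)])
    parent = genealogy.parent
    # parents always have larger ids, so a reverse sweep visits parent first;
    # mutation-free branches share the parent array (copy-on-write)
    for node in range(n_nodes - 2, -1, -1):
        if saturated[node]:
            seq = seqs[parent[node]].copy()
            p_diff = 0.75 * (1.0 - math.exp(-4.0 * mu * branch_len[node] / 3.0))
            hit = rng.random(n_sites) < p_diff
            k = int(hit.sum())
            seq[hit] = (seq[hit] + rng.integers(1, 4, size=k).astype(np.int8)) % 4
            seqs[node] = seq
            continue
        lo, hi = offsets[node], offsets[node + 1]
        if lo == hi:
            seqs[node] = seqs[parent[node]]
            continue
        seq = seqs[parent[node]].copy()
        # events applied one by one: repeated hits at a site must compound
        for k in range(lo, hi):
            s = sites[k]
            seq[s] = (seq[s] + shifts[k]) % 4
        seqs[node] = seq
    if design is None:
        T = int(genealogy.tip_timepoint.max()) + 1
        design = SamplingDesign.from_times(list(range(T)))
    codes = [
        np.array([seqs[i] for i in np.flatnonzero(genealogy.tip_timepoint == tp)])
        for tp in range(design.n_timepoints)
    ]
    return SerialAlignment(design=design, codes=codes, genealogy=genealogy)


def simulate(params: SimParams, rng: np.random.Generator | None = None) -> SerialAlignment:
    """One full simulation: genealogy plus mutated alignments.

    A root seed (``params.seed``) spawns independent, labeled substreams for
    the genealogy and the mutation process, so each component is
    independently replayable.
    """
    if rng is None:
        ss = np.random.SeedSequence(params.seed)
        gen_ss, mut_ss = ss.spawn(2)
        gen_rng = np.random.default_rng(gen_ss)
        mut_rng = np.random.default_rng(mut_ss)
    else:
        gen_rng = mut_rng = rng
    genealogy = simulate_genealogy(params, gen_rng)
    return drop_mutations(genealogy, params.mu, params.n_sites, mut_rng,
                          design=params.design)


def simulate_frequency_matrices(
    params: SimParams, rng: np.random.Generator | None = None
) -> list[SiteFrequencyMatrix]:
    """Simulate and tally directly into per-timepoint frequency matrices."""
    return simulate(params, rng).frequency_matrices()
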