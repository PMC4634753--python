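"""Sitewise nucleotide frequencies and diversity statistics for serial samples.

Serially sampled, mixed, anonymous sequence data are reduced to one table per
timepoint giving the proportion of A, C, G and T at every aligned site.  All
downstream estimators (least squares and ABC-MCMC) consume only these tables:
no haplotype reconstruction, no genealogy.

The two elementary statistics are the sitewise intra-timepoint diversity

    D_intra(s, t) = 1 - sum_j F(s, j, t)^2

(the probability two random draws at site ``s`` and time ``t`` differ) and
the inter-timepoint diversity

    D_inter(s, t1, t2) = 1 - sum_j F(s, j, t1) * F(s, j, t2)

between two sampling times.  Their means over sites feed the least-squares
system and the ABC summary vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

__all__ = [
    "NUCLEOTIDES",
    "SamplingDesign",
    "SiteFrequencyMatrix",
    "DiversitySet",
    "read_alignment_fasta",
    "read_aligned_reads_sam",
    "read_frequency_table",
    "write_frequency_table",
    "frequency_matrix_from_sequences",
    "intra_diversity_site",
    "inter_diversity_site",
    "mean_diversities",
    "drop_uncovered_sites",
]

logger = logging.getLogger(__name__)

NUCLEOTIDES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(NUCLEOTIDES)}

#: tolerance under which a proportion counts as exactly 1 ("fixed")
FIXED_TOL = 1e-12


@dataclass(frozen=True)
class SamplingDesign:
    """Ordered sampling timepoints with times in generations.

    ``times`` are forward-time sampling instants, strictly increasing.  With
    ``T`` timepoints the design yields ``T`` intra-timepoint diversities and
    ``T*(T-1)/2`` inter-timepoint diversities (ordered pairs a < b).
    """

    labels: tuple[str, ...]
    times: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.times):
            raise ValueError("labels and times must have equal length")
        if len(self.times) < 1:
            raise ValueError("need at least one timepoint")
        if any(t < 0 for t in self.times):
            raise ValueError("times must be non-negative")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate timepoint labels")

    @classmethod
    def from_times(cls, times: Sequence[float]) -> "SamplingDesign":
        labels = tuple(f"t{i}" for i in range(len(times)))
        return cls(labels=labels, times=tuple(float(t) for t in times))

    @property
    def n_timepoints(self) -> int:
        return len(self.times)

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """Ordered timepoint index pairs (a, b), a < b.

        Span-major order (all adjacent pairs first, then spans of two
        intervals, ...), matching the worked three-timepoint layout
        AB, BC, AC used in the least-squares system.
        """
        T = self.n_timepoints
        return [(a, a + s) for s in range(1, T) for a in range(T - s)]

    def elapsed(self, a: int, b: int) -> float:
        return self.times[b] - self.times[a]

    @property
    def intervals(self) -> list[float]:
        """Adjacent inter-timepoint intervals Δt, length T-1."""
        return [self.times[i + 1] - self.times[i] for i in range(self.n_timepoints - 1)]


@dataclass
class SiteFrequencyMatrix:
    """Per-site nucleotide counts and proportions for one timepoint.

    ``counts`` has shape (n_sites, 4) in A, C, G, T order; ``depth`` is the
    per-site number of unambiguous observations.  Proportions are
    counts/depth and sum to 1 at every site; sites with zero depth are not
    representable (drop them first with :func:`drop_uncovered_sites`).
    """

    timepoint: str
    counts: np.ndarray
    depth: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[1] != 4:
            raise ValueError("counts must have shape (n_sites, 4)")
        if self.depth is None:
            self.depth = self.counts.sum(axis=1)
        self.depth = np.asarray(self.depth)
        if np.any(self.depth <= 0):
            bad = int(np.flatnonzero(self.depth <= 0)[0])
            raise ValueError(
                f"site {bad + 1} at timepoint {self.timepoint!r} has zero usable "
                "observations; frequencies are undefined"
            )
        if np.any(self.counts < 0):
            raise ValueError("negative counts")

    @property
    def n_sites(self) -> int:
        return self.counts.shape[0]

    @property
    def freqs(self) -> np.ndarray:
        """(n_sites, 4) array of proportions; rows sum to 1."""
        cached = getattr(self, "_freqs", None)
        if cached is None:
            cached = self.counts / self.depth[:, None]
            object.__setattr__(self, "_freqs", cached)
        return cached


@dataclass
class DiversitySet:
    """All intra- and inter-timepoint diversities for one dataset.

    Mean values are arithmetic means of the per-site values.  Intra
    diversities live in [0, 0.75] (maximum at equifrequent A/C/G/T), inter
    diversities in [0, 1].
    """

    design: SamplingDesign
    per_site_intra: np.ndarray  # (T, n_sites)
    per_site_inter: np.ndarray  # (P, n_sites), pair order = design.pairs

    @property
    def intra(self) -> dict[str, float]:
        return {
            lab: float(m)
            for lab, m in zip(self.design.labels, self.per_site_intra.mean(axis=1))
        }

    @property
    def inter(self) -> dict[tuple[str, str], float]:
        means = self.per_site_inter.mean(axis=1)
        return {
            (self.design.labels[a], self.design.labels[b]): float(m)
            for (a, b), m in zip(self.design.pairs, means)
        }

    @property
    def response_vector(self) -> np.ndarray:
        """Flattened Y: intra means (timepoint order) then inter means (pair order)."""
        return np.concatenate(
            [self.per_site_intra.mean(axis=1), self.per_site_inter.mean(axis=1)]
        )


# ---------------------------------------------------------------------------
# readers / writers


def frequency_matrix_from_sequences(
    sequences: Iterable[str], timepoint: str
) -> SiteFrequencyMatrix:
    """Tally a list of equal-length aligned sequences into a frequency matrix.

    Characters outside A/C/G/T (case-insensitive) — gaps, Ns, IUPAC
    ambiguity codes — are excluded from that column's tally.
    """
    seqs = [s.upper() for s in sequences]
    if not seqs:
        raise ValueError("no sequences provided")
    n = len(seqs[0])
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8).reshape(
        len(seqs), n
    )
    counts = np.empty((n, 4), dtype=float)
    for j, base in enumerate(NUCLEOTIDES):
        counts[:, j] = (arr == ord(base)).sum(axis=0)
    depth = counts.sum(axis=1)
    if np.any(depth == 0):
        bad = int(np.flatnonzero(depth == 0)[0])
        raise ValueError(
            f"column {bad + 1} has no unambiguous bases at timepoint {timepoint!r}"
        )
    return SiteFrequencyMatrix(timepoint=timepoint, counts=counts, depth=depth)


def read_alignment_fasta(path: str | Path, timepoint: str) -> SiteFrequencyMatrix:
    """Tally a multi-FASTA alignment into a per-site frequency matrix.

    All records must have equal length.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    n = len(records[0].seq)
    for rec in records:
        if len(rec.seq) != n:
            raise ValueError(
                f"record {rec.id!r} in {path} has length {len(rec.seq)}, expected {n}"
            )
    return frequency_matrix_from_sequences((str(r.seq) for r in records), timepoint)


def read_aligned_reads_sam(
    path: str | Path,
    reference_length: int,
    timepoint: str,
    min_base_quality: int = 0,
) -> tuple[SiteFrequencyMatrix, np.ndarray]:
    """Tally aligned read bases per reference position from a SAM file.

    Uses mapped read orientation as stored; deletions and reference skips are
    ignored (no fifth state).  Returns the matrix for covered sites together
    with the 0-based indices of covered sites (positions with no coverage are
    excluded, with a warning).  Inputs are assumed error-corrected, hence
    ``min_base_quality`` defaults to 0.
    """
    import pysam

    counts = np.zeros((reference_length, 4), dtype=float)
    n_reads = 0
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for read in sam.fetch(until_eof=True):
            if read.is_unmapped or read.query_sequence is None:
                continue
            n_reads += 1
            quals = read.query_qualities
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if rpos >= reference_length:
                    continue
                if quals is not None and quals[qpos] < min_base_quality:
                    continue
                base = read.query_sequence[qpos].upper()
                j = _BASE_INDEX.get(base)
                if j is not None:
                    counts[rpos, j] += 1
    if n_reads == 0:
        raise ValueError(f"no mapped reads in {path}")
    depth = counts.sum(axis=1)
    covered = np.flatnonzero(depth > 0)
    if covered.size < reference_length:
        logger.warning(
            "%d of %d reference positions have no coverage in %s; excluded",
            reference_length - covered.size,
            reference_length,
            path,
        )
    matrix = SiteFrequencyMatrix(
        timepoint=timepoint, counts=counts[covered], depth=depth[covered]
    )
    return matrix, covered


_TABLE_COLUMNS = [
    "site",
    "count_A",
    "count_C",
    "count_G",
    "count_T",
    "depth",
    "freq_A",
    "freq_C",
    "freq_G",
    "freq_T",
]


def write_frequency_table(matrix: SiteFrequencyMatrix, path: str | Path) -> None:
    """Write a frequency matrix as TSV (1-based site index, '#' header)."""
    freqs = matrix.freqs
    with open(path, "w") as fh:
        fh.write(f"# timepoint={matrix.timepoint}\n")
        fh.write("# " + "\t".join(_TABLE_COLUMNS) + "\n")
        for s in range(matrix.n_sites):
            row = [str(s + 1)]
            row += [f"{c:.10g}" for c in matrix.counts[s]]
            row.append(f"{matrix.depth[s]:.10g}")
            row += [f"{f:.10g}" for f in freqs[s]]
            fh.write("\t".join(row) + "\n")


def read_frequency_table(path: str | Path, timepoint: str | None = None) -> SiteFrequencyMatrix:
    """Read a frequency-table TSV written by :func:`write_frequency_table`."""
    label = timepoint
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "timepoint=" in line and label is None:
                    label = line.split("timepoint=", 1)[1].strip()
                continue
            rows.append(line.split("\t"))
    if not rows:
        raise ValueError(f"no data rows in {path}")
    data = np.array([[float(x) for x in r] for r in rows])
    counts = data[:, 1:5]
    depth = data[:, 5]
    return SiteFrequencyMatrix(timepoint=label or "t?", counts=counts, depth=depth)


def drop_uncovered_sites(
    matrices: Sequence[SiteFrequencyMatrix],
    covered_indices: Sequence[np.ndarray],
    reference_length: int,
) -> list[SiteFrequencyMatrix]:
    """Restrict per-timepoint matrices to sites covered at *every* timepoint.

    Inter-timepoint diversities require matched sites, so a site with zero
    usable observations at any timepoint is dropped from all timepoints
    jointly; the dropped count is logged.
    """
    common = np.arange(reference_length)
    for idx in covered_indices:
        common = np.intersect1d(common, idx)
    dropped = reference_length - common.size
    if dropped:
        logger.warning("dropping %d sites uncovered at one or more timepoints", dropped)
    out = []
    for mat, idx in zip(matrices, covered_indices):
        lookup = {site: row for row, site in enumerate(idx)}
        rows = [lookup[s] for s in common]
        out.append(
            SiteFrequencyMatrix(
                timepoint=mat.timepoint,
                counts=mat.counts[rows],
                depth=mat.depth[rows],
            )
        )
    return out


# ---------------------------------------------------------------------------
# diversity statistics


def intra_diversity_site(freq_row: np.ndarray) -> float:
    """Sitewise intra-timepoint diversity, ``1 - sum_j F_j^2``."""
    f = np.asarray(freq_row, dtype=float)
    return float(1.0 - np.dot(f, f))


def inter_diversity_site(freq_row_t1: np.ndarray, freq_row_t2: np.ndarray) -> float:
    """Sitewise inter-timepoint diversity, ``1 - sum_j F_j(t1) F_j(t2)``."""
    f1 = np.asarray(freq_row_t1, dtype=float)
    f2 = np.asarray(freq_row_t2, dtype=float)
    return float(1.0 - np.dot(f1, f2))


def _per_site_intra(freqs: np.ndarray) -> np.ndarray:
    return 1.0 - np.einsum("sj,sj->s", freqs, freqs)


def _per_site_inter(f1: np.ndarray, f2: np.ndarray) -> np.ndarray:
    return 1.0 - np.einsum("sj,sj->s", f1, f2)


def mean_diversities(
    matrices: Sequence[SiteFrequencyMatrix], design: SamplingDesign
) -> DiversitySet:
    """All intra- and inter-timepoint diversities for matched matrices.

    ``matrices`` must be ordered as ``design.labels`` and share ``n_sites``.
    """
    if len(matrices) != design.n_timepoints:
        raise ValueError("one matrix per design timepoint required")
    n = matrices[0].n_sites
    for m in matrices:
        if m.n_sites != n:
            raise ValueError(
                f"mismatched n_sites: {m.timepoint!r} has {m.n_sites}, expected {n}"
            )
    freqs = [m.freqs for m in matrices]
    per_intra = np.stack([_per_site_intra(f) for f in freqs])
    pairs = design.pairs
    if pairs:
        per_inter = np.stack([_per_site_inter(freqs[a], freqs[b]) for a, b in pairs])
    else:
        per_inter = np.empty((0, n))
    return DiversitySet(design=design, per_site_intra=per_intra, per_site_inter=per_inter)
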