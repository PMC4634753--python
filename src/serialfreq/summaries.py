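"""Raw summary statistics for the sufficient-statistic regression.

The full vector computed from the per-timepoint frequency matrices,
in a fixed schema order:

1. mean intra-timepoint diversities (T entries) and mean inter-timepoint
   diversities (T(T-1)/2 entries);
2. population variances (divisor n) of the corresponding per-site
   diversities (T + T(T-1)/2 entries);
3. per-timepoint chi-square distances between the frequency spectrum of
   the most-frequent-nucleotide proportion (20 bins of width 0.05) and a
   uniform reference spectrum (T entries);
4. for every timepoint pair, the counts of sites in four mutually
   exclusive joint-pattern categories (4 × T(T-1)/2 entries):
   C1 both timepoints fixed for the same base; C2 fixed in one timepoint
   with the same base the unique most-frequent in the other (polymorphic)
   timepoint; C3 both polymorphic with the same unique most-frequent base;
   C4 everything else.

Every statistic is a function of the sitewise nucleotide proportions only,
so the vector is invariant under any relabeling of the four bases applied
consistently across timepoints.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .sitefreq import (
    FIXED_TOL,
    SamplingDesign,
    SiteFrequencyMatrix,
    mean_diversities,
)

__all__ = [
    "SummaryVector",
    "diversity_variances",
    "spectrum_distance",
    "chi_square_spectrum",
    "site_pattern_categories",
    "summary_schema",
    "summary_vector",
]

N_SPECTRUM_BINS = 20
_UNIFORM_REF = 1.0 / N_SPECTRUM_BINS  # 0.05


@dataclass
class SummaryVector:
    """Ordered summary statistics plus a schema naming each position."""

    values: np.ndarray
    schema: tuple[str, ...]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.schema):
            raise ValueError("schema length must equal vector length")

    @property
    def schema_hash(self) -> str:
        return hashlib.sha256("\t".join(self.schema).encode()).hexdigest()[:16]

    def __len__(self) -> int:
        return self.values.size


def diversity_variances(per_site_diversities: np.ndarray) -> float:
    """Population variance (divisor n) of sitewise diversities."""
    v = np.asarray(per_site_diversities, dtype=float)
    if v.size < 1:
        raise ValueError("need at least one per-site value")
    return float(np.mean((v - v.mean()) ** 2))


def _spectrum_bins(max_props: np.ndarray) -> np.ndarray:
    # half-open [0.05c, 0.05(c+1)) bins, top bin closed at 1.0; the small
    # epsilon keeps exact rational boundaries (count/depth) in the right bin
    b = np.floor(max_props * N_SPECTRUM_BINS + 1e-9).astype(int)
    return np.clip(b, 0, N_SPECTRUM_BINS - 1)


def spectrum_distance(fs: np.ndarray) -> float:
    """Chi-square distance of a relative frequency spectrum from uniform.

    ``sum_c (FS_c - 0.05)^2 / 0.05`` over the 20 categories; 0 for an
    exactly uniform spectrum, 19.0 when all mass falls in one bin.
    """
    fs = np.asarray(fs, dtype=float)
    if fs.size != N_SPECTRUM_BINS:
        raise ValueError(f"spectrum must have {N_SPECTRUM_BINS} categories")
    return float(np.sum((fs - _UNIFORM_REF) ** 2 / _UNIFORM_REF))


def chi_square_spectrum(matrix: SiteFrequencyMatrix) -> float:
    """Chi-square distance of the max-proportion spectrum from uniform.

    Bins the proportion of each site's most frequent nucleotide into 20
    categories of width 0.05, forms the relative frequency spectrum FS_t
    and compares it to the uniform reference via :func:`spectrum_distance`.
    The lowest five bins are structurally empty (the max proportion is at
    least 0.25) but are retained in the sum.
    """
    max_props = matrix.freqs.max(axis=1)
    bins = _spectrum_bins(max_props)
    fs = np.bincount(bins, minlength=N_SPECTRUM_BINS) / matrix.n_sites
    return spectrum_distance(fs)


def _majority_info(freqs: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(argmax, is_fixed, has_unique_argmax) per site."""
    mx = freqs.max(axis=1)
    arg = freqs.argmax(axis=1)
    fixed = mx >= 1.0 - FIXED_TOL
    unique = (freqs >= mx[:, None] - FIXED_TOL).sum(axis=1) == 1
    return arg, fixed, unique


def site_pattern_categories(
    matrix_t1: SiteFrequencyMatrix, matrix_t2: SiteFrequencyMatrix
) -> tuple[int, int, int, int]:
    """Counts of the four joint site-pattern categories for one pair.

    A tie for most-frequent base means there is no unique majority, so the
    site cannot satisfy C2/C3 and falls into C4.  Categories are mutually
    exclusive and exhaustive: the counts sum to n_sites.
    """
    if matrix_t1.n_sites != matrix_t2.n_sites:
        raise ValueError("matched n_sites required")
    f1, f2 = matrix_t1.freqs, matrix_t2.freqs
    a1, fix1, uniq1 = _majority_info(f1)
    a2, fix2, uniq2 = _majority_info(f2)
    same = a1 == a2
    c1 = fix1 & fix2 & same
    c2 = (fix1 & ~fix2 & uniq2 & same) | (fix2 & ~fix1 & uniq1 & same)
    c3 = ~fix1 & ~fix2 & uniq1 & uniq2 & same
    c4 = ~(c1 | c2 | c3)
    return int(c1.sum()), int(c2.sum()), int(c3.sum()), int(c4.sum())


def summary_schema(design: SamplingDesign) -> tuple[str, ...]:
    """Schema (entry names, in order) of the summary vector for a design."""
    labels = design.labels
    pair_names = [f"{labels[a]}{labels[b]}" for a, b in design.pairs]
    schema: list[str] = []
    schema += [f"mean_intra_{lab}" for lab in labels]
    schema += [f"mean_inter_{nm}" for nm in pair_names]
    schema += [f"var_intra_{lab}" for lab in labels]
    schema += [f"var_inter_{nm}" for nm in pair_names]
    schema += [f"chisq_spectrum_{lab}" for lab in labels]
    for nm in pair_names:
        schema += [f"cat{i}_{nm}" for i in range(1, 5)]
    return tuple(schema)


def summary_vector(
    matrices: Sequence[SiteFrequencyMatrix], design: SamplingDesign
) -> SummaryVector:
    """The full summary-statistic vector in fixed schema order."""
    T = design.n_timepoints
    if T < 2:
        raise ValueError("at least two timepoints required (inter statistics)")
    div = mean_diversities(matrices, design)
    pairs = design.pairs
    labels = design.labels
    pair_names = [f"{labels[a]}{labels[b]}" for a, b in pairs]

    values: list[float] = []
    schema: list[str] = []
    for lab, v in zip(labels, div.per_site_intra.mean(axis=1)):
        values.append(float(v))
        schema.append(f"mean_intra_{lab}")
    for name, v in zip(pair_names, div.per_site_inter.mean(axis=1)):
        values.append(float(v))
        schema.append(f"mean_inter_{name}")
    for lab, row in zip(labels, div.per_site_intra):
        values.append(diversity_variances(row))
        schema.append(f"var_intra_{lab}")
    for name, row in zip(pair_names, div.per_site_inter):
        values.append(diversity_variances(row))
        schema.append(f"var_inter_{name}")
    # majority info computed once per timepoint, shared by spectrum & categories
    info = [_majority_info(m.freqs) for m in matrices]
    maxprops = [m.freqs.max(axis=1) for m in matrices]
    n = matrices[0].n_sites
    for lab, mp in zip(labels, maxprops):
        bins = _spectrum_bins(mp)
        fs = np.bincount(bins, minlength=N_SPECTRUM_BINS) / n
        values.append(float(np.sum((fs - _UNIFORM_REF) ** 2 / _UNIFORM_REF)))
        schema.append(f"chisq_spectrum_{lab}")
    for (a, b), name in zip(pairs, pair_names):
        a1, fix1, uniq1 = info[a]
        a2, fix2, uniq2 = info[b]
        same = a1 == a2
        c1 = fix1 & fix2 & same
        c2 = (fix1 & ~fix2 & uniq2 & same) | (fix2 & ~fix1 & uniq1 & same)
        c3 = ~fix1 & ~fix2 & uniq1 & uniq2 & same
        cats = (int(c1.sum()), int(c2.sum()), int(c3.sum()),
                n - int(c1.sum()) - int(c2.sum()) - int(c3.sum()))
        for i, c in enumerate(cats, start=1):
            values.append(float(c))
            schema.append(f"cat{i}_{name}")
    return SummaryVector(values=np.array(values), schema=tuple(schema))
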