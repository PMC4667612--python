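"""Windowed estimation of Watterson's theta, pi, Tajima's D and folded SFS.

All estimators work from called genotypes (alt-allele dosages), not from
genotype likelihoods: per site, ``n`` is the number of called chromosomes
(2 x called genotypes) and ``k`` the alternate-allele count.  Per-site
scaling uses the genomic span of the window (``L``) rather than the number of
SNP records, so monomorphic sequence counts toward the denominator; a
callability override can replace the raw span.

Missing-data conventions: pi uses exact per-site (n, k); Watterson's theta
and Tajima's D need a single sample size per window and use n-bar, the mean
number of called chromosomes over the window's variant sites, rounded to the
nearest integer.  D is undefined (NaN) when a window has no segregating
sites and that missingness is propagated rather than coerced to 0.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import hypergeom

from palmscan.io import GenomicInterval, GenotypeMatrix, InputError

logger = logging.getLogger(__name__)


def harmonic(m: int) -> float:
    """a_m = sum_{i=1}^{m} 1/i (0 for m <= 0)."""
    return float(sum(1.0 / i for i in range(1, m + 1)))


def harmonic2(m: int) -> float:
    """b_m = sum_{i=1}^{m} 1/i^2."""
    return float(sum(1.0 / i**2 for i in range(1, m + 1)))


@dataclass
class WindowStat:
    """Diversity summary of one genomic window."""

    interval: GenomicInterval
    n_callable_sites: int  # L: genomic span used for per-site scaling
    S: int  # segregating sites
    mean_n: float  # mean called chromosomes over variant sites (0 if none)
    theta_w: float
    pi: float
    tajima_d: float  # NaN when S == 0

    @property
    def start(self) -> int:
        return self.interval.start


@dataclass
class SFS:
    """Folded (minor-allele) site-frequency spectrum.

    ``counts[i]`` is the (possibly fractional, after projection) number of
    sites with minor-allele count ``i``, for i = 1..floor(n/2).
    """

    counts: np.ndarray
    n: int
    site_class: str | None = None

    def classes(self) -> np.ndarray:
        return np.arange(1, len(self.counts) + 1)


def _site_nk(
    matrix: GenotypeMatrix, subset: list[str] | None, mask: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized per-site (n, k) over a sample subset (and site mask)."""
    idx = matrix.sample_indices(subset)
    calls = matrix.calls[idx]
    if mask is not None:
        calls = calls[:, mask]
    called = calls >= 0
    n = 2 * called.sum(axis=0)
    k = np.where(called, calls, 0).sum(axis=0)
    return n.astype(np.int64), k.astype(np.int64)


def site_components(
    matrix: GenotypeMatrix, sample_subset: list[str] | None, site: int
) -> tuple[int, int]:
    """(called chromosomes, alt-allele count) at one site; (0, 0) = uncallable."""
    if not (0 <= site < matrix.n_sites):
        raise InputError(f"site index {site} out of range")
    n, k = _site_nk(matrix, sample_subset, np.array([site]))
    return int(n[0]), int(k[0])


def _window_L(matrix: GenotypeMatrix, interval: GenomicInterval, L: int | None) -> int:
    if L is not None:
        return L
    return interval.span


def watterson_theta(
    matrix: GenotypeMatrix,
    subset: list[str] | None,
    interval: GenomicInterval,
    L: int | None = None,
) -> float:
    """Per-site Watterson estimate S / (a_{n-1} * L) for one window.

    ``n`` is the rounded mean number of called chromosomes over the window's
    variant sites.  Returns NaN when L = 0, and 0.0 for windows with no
    segregating sites.
    """
    return window_stat(matrix, subset, interval, L).theta_w


def nucleotide_diversity(
    matrix: GenotypeMatrix,
    subset: list[str] | None,
    interval: GenomicInterval,
    L: int | None = None,
) -> float:
    """Per-site mean pairwise diversity: (1/L) sum_sites 2k(n-k) / (n(n-1))."""
    return window_stat(matrix, subset, interval, L).pi


def tajimas_d(
    matrix: GenotypeMatrix,
    subset: list[str] | None,
    interval: GenomicInterval,
) -> float:
    """Tajima's D for one window (NaN when the window has no segregating site)."""
    return window_stat(matrix, subset, interval).tajima_d


def _tajima_constants(n: int) -> tuple[float, float]:
    """(e1, e2) of the D denominator for sample size n chromosomes."""
    if n < 2:
        raise InputError("Tajima's D needs n >= 2")
    a1 = harmonic(n - 1)
    a2 = harmonic2(n - 1)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return e1, e2


def tajima_d_from_counts(S: int, pi_total: float, n: int) -> float:
    """D from window totals: S segregating sites, total pairwise differences
    Pi = pi * L, and a fixed sample size n."""
    if S == 0:
        return math.nan
    e1, e2 = _tajima_constants(n)
    a1 = harmonic(n - 1)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:  # degenerate for n < 4, where the 1989 variance vanishes
        return math.nan
    return (pi_total - S / a1) / math.sqrt(var)


def window_stat(
    matrix: GenotypeMatrix,
    subset: list[str] | None,
    interval: GenomicInterval,
    L: int | None = None,
) -> WindowStat:
    """All window statistics in one pass (used by the per-stat wrappers)."""
    mask = matrix.site_mask(interval)
    n, k = _site_nk(matrix, subset, mask)
    return _stat_from_nk(interval, n, k, _window_L(matrix, interval, L))


def _stat_from_nk(
    interval: GenomicInterval, n: np.ndarray, k: np.ndarray, L: int
) -> WindowStat:
    usable = n >= 2
    n_skipped = int((~usable & (n > 0)).sum())
    if n_skipped:
        logger.debug("%s: skipped %d sites with n < 2", interval, n_skipped)
    n, k = n[usable], k[usable]
    seg = (k > 0) & (k < n)
    S = int(seg.sum())
    if L <= 0:
        return WindowStat(interval, 0, S, 0.0, math.nan, math.nan, math.nan)
    if len(n) == 0:
        return WindowStat(interval, L, 0, 0.0, 0.0, 0.0, math.nan)
    pi_total = float(
        (2.0 * k[seg] * (n[seg] - k[seg]) / (n[seg] * (n[seg] - 1.0))).sum()
    )
    mean_n = float(n.mean())
    n_bar = int(round(mean_n))
    theta_w = S / (harmonic(n_bar - 1) * L) if S else 0.0
    d = tajima_d_from_counts(S, pi_total, n_bar) if S else math.nan
    return WindowStat(interval, L, S, mean_n, theta_w, pi_total / L, d)


def window_scan(
    matrix: GenotypeMatrix,
    subset: list[str] | None,
    window_size: int,
    step: int | None = None,
    scaffold_lengths: dict[str, int] | None = None,
) -> list[WindowStat]:
    """Tile every scaffold from coordinate 0 and compute per-window statistics.

    Full windows start at multiples of ``step`` (default: non-overlapping,
    step = window_size); after the last full window, trailing partial windows
    are emitted with their true span until the scaffold end is covered.
    """
    step = window_size if step is None else step
    if not (1 <= step <= window_size):
        raise InputError("need window_size >= step >= 1")
    out: list[WindowStat] = []
    for scaf in matrix.scaffold_names():
        length = (
            scaffold_lengths[scaf]
            if scaffold_lengths and scaf in scaffold_lengths
            else matrix.scaffold_span(scaf)
        )
        on_scaf = matrix.scaffolds == scaf
        n_all, k_all = _site_nk(matrix, subset, on_scaf)
        pos = matrix.positions[on_scaf]
        order = np.argsort(pos)
        pos, n_all, k_all = pos[order], n_all[order], k_all[order]
        bounds: list[tuple[int, int]] = []
        start = 0
        while start + window_size <= length:
            bounds.append((start, start + window_size))
            start += step
        covered = bounds[-1][1] if bounds else 0
        if covered < length:
            # with step <= window_size one trailing partial covers the tail
            bounds.append((start, length))
        for lo_pos, hi_pos in bounds:
            lo, hi = np.searchsorted(pos, [lo_pos, hi_pos])
            out.append(
                _stat_from_nk(
                    GenomicInterval(scaf, lo_pos, hi_pos),
                    n_all[lo:hi],
                    k_all[lo:hi],
                    hi_pos - lo_pos,
                )
            )
    return out


def folded_sfs(
    matrix: GenotypeMatrix,
    subset: list[str] | None = None,
    site_class_filter: str | None = None,
    project_n: int | None = None,
) -> SFS:
    """Folded minor-allele SFS, optionally restricted to one effect class.

    Without projection, every site must have the same number of called
    chromosomes.  With ``project_n``, each site is down-sampled to ``project_n``
    chromosomes by the hypergeometric expectation; sites with fewer called
    chromosomes than the target raise an error.
    """
    mask = np.ones(matrix.n_sites, dtype=bool)
    if site_class_filter is not None:
        if matrix.effect_class is None:
            raise InputError("matrix has no effect_class annotation")
        mask = np.array(
            [e == site_class_filter for e in matrix.effect_class], dtype=bool
        )
    n, k = _site_nk(matrix, subset, mask)
    seg = (k > 0) & (k < n)
    n, k = n[seg], k[seg]
    if len(n) == 0:
        target = project_n if project_n else 0
        return SFS(np.zeros(max(target // 2, 0)), target or 0, site_class_filter)
    if project_n is None:
        if len(np.unique(n)) != 1:
            raise InputError(
                "sites have unequal call counts; pass project_n to downsample"
            )
        target = int(n[0])
        counts = np.zeros(target // 2)
        folded = np.minimum(k, target - k)
        for f in folded:
            counts[f - 1] += 1
        return SFS(counts, target, site_class_filter)
    target = int(project_n)
    if (n < target).any():
        raise InputError("project_n exceeds the call count at some sites")
    counts = np.zeros(target // 2)
    j = np.arange(target + 1)
    for ni, ki in zip(n, k):
        pmf = hypergeom.pmf(j, ni, ki, target)
        for jj in range(1, target):  # drop classes fixed after projection
            counts[min(jj, target - jj) - 1] += pmf[jj]
    return SFS(counts, target, site_class_filter)


def single_genome_theta(matrix: GenotypeMatrix, sample: str) -> float:
    """Per-site heterozygosity of one diploid: het calls / callable span.

    The callable span is the summed scaffold span of the matrix (declared
    scaffold lengths when available).  Under neutrality the expectation equals
    the per-site population mutation rate theta.
    """
    i = matrix.sample_index(sample)
    calls = matrix.calls[i]
    if (calls >= 0).sum() == 0:
        return math.nan
    span = sum(matrix.scaffold_span(s) for s in matrix.scaffold_names())
    if span == 0:
        return math.nan
    return float((calls == 1).sum()) / span
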