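"""Per-sample windowed heterozygosity, ROH detection and inbreeding F.

Window heterozygosity is the proportion of heterozygous genotypes among
called SNP genotypes in the window (a SNP-conditioned proportion, not a
per-bp rate).  Runs of homozygosity are maximal runs of windows with
near-zero heterozygosity spanning more than ``min_span`` bp, where "near
zero" is formalized as a threshold relative to the sample's median window
proportion.  The inbreeding coefficient is the moment estimator
F = 1 - H_obs / H_exp with expected heterozygosity from reference-panel
allele frequencies (the focal sample excluded).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from palmscan.io import GenomicInterval, GenotypeMatrix, InputError


@dataclass
class HetWindow:
    sample: str
    interval: GenomicInterval
    n_calls: int
    n_het: int

    @property
    def proportion(self) -> float:
        return self.n_het / self.n_calls if self.n_calls else math.nan


@dataclass
class ROHInterval:
    sample: str
    interval: GenomicInterval
    mean_het: float
    window_count: int

    @property
    def span(self) -> int:
        return self.interval.span


@dataclass
class InbreedingEstimate:
    sample: str
    f: float
    n_sites: int


def het_windows(
    matrix: GenotypeMatrix,
    sample: str,
    window_size: int = 20_000,
    scaffold_lengths: dict[str, int] | None = None,
) -> list[HetWindow]:
    """Non-overlapping windowed het counts for one sample.

    Scaffolds shorter than one full window are skipped; trailing partial
    windows on retained scaffolds are emitted so that window counts pool to
    the sample's global counts.
    """
    if window_size <= 0:
        raise InputError("window_size must be > 0")
    i = matrix.sample_index(sample)
    out: list[HetWindow] = []
    for scaf in matrix.scaffold_names():
        length = (
            scaffold_lengths[scaf]
            if scaffold_lengths and scaf in scaffold_lengths
            else matrix.scaffold_span(scaf)
        )
        if length < window_size:
            continue
        on_scaf = matrix.scaffolds == scaf
        pos = matrix.positions[on_scaf]
        calls = matrix.calls[i, on_scaf]
        order = np.argsort(pos)
        pos, calls = pos[order], calls[order]
        start = 0
        while start < length:
            end = min(start + window_size, length)
            lo, hi = np.searchsorted(pos, [start, end])
            window = calls[lo:hi]
            called = window >= 0
            out.append(
                HetWindow(
                    sample,
                    GenomicInterval(scaf, start, end),
                    n_calls=int(called.sum()),
                    n_het=int((window == 1).sum()),
                )
            )
            start = end
    return out


def default_epsilon(windows: list[HetWindow]) -> float:
    """'Near zero' threshold: 5% of the sample's median window proportion,
    floored at the equivalent of one het call per typical window."""
    props = [w.proportion for w in windows if w.n_calls > 0]
    calls = [w.n_calls for w in windows if w.n_calls > 0]
    if not props:
        raise InputError("no windows with calls")
    return max(0.05 * float(np.median(props)), 1.0 / float(np.median(calls)))


def detect_roh(
    windows: list[HetWindow],
    min_span: int = 500_000,
    epsilon: float | None = None,
    max_gap_windows: int = 1,
) -> list[ROHInterval]:
    """Runs of homozygosity from a sample's windowed het proportions.

    Maximal runs of windows with proportion <= epsilon, allowing up to
    ``max_gap_windows`` consecutive interrupting windows, reported iff the
    run spans more than ``min_span`` bp.
    """
    if not windows:
        return []
    eps = default_epsilon(windows) if epsilon is None else epsilon
    out: list[ROHInterval] = []
    by_scaf: dict[str, list[HetWindow]] = {}
    for w in windows:
        by_scaf.setdefault(w.interval.scaffold, []).append(w)
    for scaf in sorted(by_scaf):
        ws = sorted(by_scaf[scaf], key=lambda w: w.interval.start)
        low = [
            i
            for i, w in enumerate(ws)
            if w.n_calls > 0 and w.proportion <= eps
        ]
        run: list[int] = []
        for i in low + [None]:
            if run and (i is None or i - run[-1] - 1 > max_gap_windows):
                first, last = run[0], run[-1]
                iv = GenomicInterval(
                    scaf, ws[first].interval.start, ws[last].interval.end
                )
                if iv.span > min_span:
                    members = [w for w in ws[first : last + 1] if w.n_calls > 0]
                    mean_het = float(
                        np.sum([w.n_het for w in members])
                        / np.sum([w.n_calls for w in members])
                    )
                    out.append(
                        ROHInterval(
                            ws[first].sample, iv, mean_het, last - first + 1
                        )
                    )
                run = []
            if i is not None:
                run.append(i)
    return out


def inbreeding_f(
    matrix: GenotypeMatrix,
    sample: str,
    allele_freqs_source_subset: list[str] | None = None,
    maf_range: tuple[float, float] = (0.05, 0.95),
    min_sites: int = 100,
) -> InbreedingEstimate:
    """Moment inbreeding estimate F = 1 - H_obs / H_exp for one sample.

    Allele frequencies come from ``allele_freqs_source_subset`` (default: all
    samples) with the focal sample excluded; only sites with frequency inside
    ``maf_range`` and a called focal genotype are used, and at least
    ``min_sites`` such sites are required.
    """
    i = matrix.sample_index(sample)
    source = (
        matrix.sample_ids if allele_freqs_source_subset is None
        else list(allele_freqs_source_subset)
    )
    source = [s for s in source if s != sample]
    if not source:
        raise InputError("no reference samples for allele frequencies")
    idx = matrix.sample_indices(source)
    ref_calls = matrix.calls[idx]
    called = ref_calls >= 0
    n = 2 * called.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p_hat = np.where(called, ref_calls, 0).sum(axis=0) / np.where(n > 0, n, 1)
    focal = matrix.calls[i]
    use = (
        (n > 2)
        & (p_hat >= maf_range[0])
        & (p_hat <= maf_range[1])
        & (focal >= 0)
    )
    n_used = int(use.sum())
    if n_used < min_sites:
        raise InputError(
            f"only {n_used} usable sites (need >= {min_sites}) for {sample}"
        )
    h_exp = float((2.0 * p_hat[use] * (1.0 - p_hat[use])).sum())
    if h_exp == 0:
        raise InputError("zero expected heterozygosity")
    h_obs = float((focal[use] == 1).sum())
    return InbreedingEstimate(sample, 1.0 - h_obs / h_exp, n_used)


def het_density_summary(
    windows: list[HetWindow],
    bin_width: float = 0.005,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Histogram of window het proportions and a low-het-peak flag.

    Bins of fixed width cover [0, max proportion]; the flag is raised when
    the lowest bin's mass exceeds twice the median bin mass — the signature
    of the near-zero heterozygosity peak produced by inbreeding.
    """
    props = np.array([w.proportion for w in windows if w.n_calls > 0])
    if len(props) < 20:
        raise InputError("need >= 20 windows with calls")
    n_bins = max(1, int(math.ceil((props.max() + 1e-12) / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(props, bins=edges)
    if n_bins == 1:
        return counts, edges, True
    flag = counts[0] > 2.0 * float(np.median(counts))
    return counts, edges, bool(flag)
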