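"""Two-population diversity-ratio selective-sweep scan.

For each genomic window the scan forms x = log2(theta_W,pop1 / theta_W,pop2),
Z-transforms x against the genome-wide empirical distribution, and calls
outlier regions in each tail.  A window only seeds a region if a second
outlier window lies within ``pair_distance`` on the same scaffold (the
paired-window rule); qualifying windows are merged into maximal regions.
Windows where either population has theta = 0 or too few segregating sites
are excluded before standardization (the log-ratio is undefined or unstable
there); an optional pseudocount keeps them instead.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2_contingency

from palmscan.io import GenomicInterval, InputError
from palmscan.diversity import WindowStat

logger = logging.getLogger(__name__)


@dataclass
class SweepWindowScore:
    """Per-window log2 theta-ratio and its genome-wide Z-score."""

    interval: GenomicInterval
    theta_pop1: float
    theta_pop2: float
    log_ratio: float  # NaN when excluded
    z: float  # NaN when excluded
    excluded: bool = False
    reason: str | None = None


@dataclass
class SweepRegion:
    """A merged run of paired outlier windows; ``direction`` names the
    population that lost diversity."""

    interval: GenomicInterval
    direction: str  # "pop1" or "pop2"
    min_z: float  # most extreme |z| among member windows
    window_count: int
    mean_tajima_d: float = math.nan


def score_windows(
    windows_pop1: list[WindowStat],
    windows_pop2: list[WindowStat],
    min_S: int = 2,
    pseudo_theta: float = 0.0,
) -> list[SweepWindowScore]:
    """Log2 theta-ratio Z-scores over identically tiled window lists.

    Windows with theta = 0 or S < ``min_S`` in either population are excluded
    before standardization unless ``pseudo_theta`` > 0 is added to both
    estimates.  Standardization uses the population standard deviation
    (divisor n) of the scored windows; the opposite orientation is its exact
    sign flip.
    """
    if len(windows_pop1) != len(windows_pop2):
        raise InputError("window lists differ in length")
    scores: list[SweepWindowScore] = []
    for w1, w2 in zip(windows_pop1, windows_pop2):
        if w1.interval != w2.interval:
            raise InputError(
                f"window tilings differ: {w1.interval} vs {w2.interval}"
            )
        t1, t2 = w1.theta_w + pseudo_theta, w2.theta_w + pseudo_theta
        reason = None
        if not (t1 > 0 and t2 > 0):
            reason = "zero theta"
        elif min(w1.S, w2.S) < min_S:
            reason = f"S < {min_S}"
        if reason is not None and pseudo_theta <= 0:
            scores.append(
                SweepWindowScore(
                    w1.interval, w1.theta_w, w2.theta_w, math.nan, math.nan,
                    excluded=True, reason=reason,
                )
            )
        else:
            scores.append(
                SweepWindowScore(
                    w1.interval, w1.theta_w, w2.theta_w, math.log2(t1 / t2), math.nan
                )
            )
    x = np.array([s.log_ratio for s in scores if not s.excluded])
    if len(x) < 10:
        raise InputError(f"only {len(x)} scored windows; s.d. unstable")
    sd = float(x.std(ddof=0))
    mean = float(x.mean())
    if sd == 0:
        logger.warning("all log-ratios identical; setting every z to 0")
    for s in scores:
        if not s.excluded:
            s.z = 0.0 if sd == 0 else (s.log_ratio - mean) / sd
    return scores


def percent_reduction(theta_a: float, theta_b: float) -> float:
    """Percentage diversity reduction 100*(1 - theta_b/theta_a).

    Report rounded to the nearest integer percent.
    """
    if theta_a <= 0:
        raise InputError("theta_a must be > 0")
    return 100.0 * (1.0 - theta_b / theta_a)


def call_regions(
    scores: list[SweepWindowScore],
    z_threshold: float = 5.0,
    pair_distance: int = 10_000,
    tajima_by_window: dict[GenomicInterval, float] | None = None,
) -> list[SweepRegion]:
    """Tail-outlier sweep regions under the paired-window rule.

    In each orientation (sign flip of z), windows with z <= -z_threshold
    qualify only if another qualifying window starts within ``pair_distance``
    (start-to-start) on the same scaffold; qualifying windows are merged into
    maximal regions with start gaps <= pair_distance.  Direction "pop1" means
    population 1 lost diversity (negative z on the pop1/pop2 log-ratio).
    """
    regions: list[SweepRegion] = []
    scored = [s for s in scores if not s.excluded]
    for sign, direction in ((1.0, "pop1"), (-1.0, "pop2")):
        outliers = [s for s in scored if sign * s.z <= -z_threshold]
        by_scaf: dict[str, list[SweepWindowScore]] = {}
        for s in outliers:
            by_scaf.setdefault(s.interval.scaffold, []).append(s)
        for scaf, group in by_scaf.items():
            group.sort(key=lambda s: s.interval.start)
            starts = np.array([s.interval.start for s in group])
            paired = [
                s
                for i, s in enumerate(group)
                if ((np.abs(starts - starts[i]) <= pair_distance) & (starts != starts[i])).any()
            ]
            run: list[SweepWindowScore] = []
            for s in paired + [None]:
                if run and (
                    s is None
                    or s.interval.start - run[-1].interval.start > pair_distance
                ):
                    iv = GenomicInterval(
                        scaf, run[0].interval.start, run[-1].interval.end
                    )
                    d = math.nan
                    if tajima_by_window is not None:
                        ds = [
                            tajima_by_window[w.interval]
                            for w in run
                            if w.interval in tajima_by_window
                            and not math.isnan(tajima_by_window[w.interval])
                        ]
                        d = float(np.mean(ds)) if ds else math.nan
                    regions.append(
                        SweepRegion(
                            iv,
                            direction,
                            min_z=float(min(sign * w.z for w in run)),
                            window_count=len(run),
                            mean_tajima_d=d,
                        )
                    )
                    run = []
                if s is not None:
                    run.append(s)
    regions.sort(key=lambda r: (r.interval.scaffold, r.interval.start))
    return regions


def tajima_enrichment(
    scores: list[SweepWindowScore],
    tajima_by_window: dict[GenomicInterval, float],
    z_cut: float = 3.0,
) -> tuple[np.ndarray, float, float]:
    """Chi-square test for enrichment of negative Tajima's D in outlier windows.

    Builds the 2x2 table (outlier: z <= -z_cut vs non-outlier) x (D < 0 vs
    D >= 0) over scored windows with defined D, and applies Pearson's
    chi-square with df = 1 and no continuity correction.  Returns
    (table, statistic, p).
    """
    table = np.zeros((2, 2), dtype=np.int64)
    for s in scores:
        if s.excluded or s.interval not in tajima_by_window:
            continue
        d = tajima_by_window[s.interval]
        if math.isnan(d):
            continue
        row = 0 if s.z <= -z_cut else 1
        col = 0 if d < 0 else 1
        table[row, col] += 1
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise InputError("degenerate enrichment table (zero margin)")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected < 1).any():
        logger.warning("enrichment table has expected cell < 1; p unreliable")
    stat, p, _, _ = chi2_contingency(table, correction=False)
    return table, float(stat), float(p)


def hudson_fst(
    n1: np.ndarray, k1: np.ndarray, n2: np.ndarray, k2: np.ndarray
) -> float:
    """Plain Hudson-style FST over sites from per-population (n, k) arrays."""
    ok = (n1 >= 2) & (n2 >= 2)
    n1, k1, n2, k2 = n1[ok], k1[ok], n2[ok], k2[ok]
    p1, p2 = k1 / n1, k2 / n2
    num = (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
    den = p1 * (1 - p2) + p2 * (1 - p1)
    if den.sum() == 0:
        return math.nan
    return float(num.sum() / den.sum())
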