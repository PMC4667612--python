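"""Genotype-r2 linkage disequilibrium decay and contingency-table tests.

LD is the squared Pearson correlation of genotype dosage vectors over
pairwise-complete samples (genotype r2, the vcftools ``--geno-r2``
convention, not haplotype r2), restricted to same-scaffold pairs within a
physical window and to sites above a minor-allele-frequency floor.  The
decay curve bins pairwise r2 by distance; the "loss" summaries report the
smallest bin midpoint at which the mean r2 has fallen to (1 - f) of the
maximum bin mean.

The association tests are the plain Pearson chi-square (no continuity
correction) and a full-enumeration Fisher exact test for r x c tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln
from scipy.stats import chi2_contingency

from palmscan.io import GenotypeMatrix, InputError


@dataclass
class LDPair:
    site_i: int
    site_j: int
    distance: int
    r2: float


def ld_pairs(
    matrix: GenotypeMatrix,
    max_window_bp: int = 100_000,
    min_maf: float = 0.1,
) -> list[LDPair]:
    """All same-scaffold site pairs within ``max_window_bp`` with dosage r2.

    Sites with minor-allele frequency below ``min_maf`` (over called samples)
    are dropped first; pairs monomorphic over their pairwise-complete samples
    are skipped.
    """
    calls = matrix.calls.astype(float)
    calls[calls < 0] = np.nan
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(calls, axis=0) / 2.0
    maf = np.minimum(freq, 1 - freq)
    keep = np.flatnonzero(maf >= min_maf)
    out: list[LDPair] = []
    for scaf in matrix.scaffold_names():
        idx = keep[np.asarray(matrix.scaffolds[keep] == scaf)]
        idx = idx[np.argsort(matrix.positions[idx])]
        pos = matrix.positions[idx]
        for a in range(len(idx)):
            b_hi = np.searchsorted(pos, pos[a] + max_window_bp, side="right")
            for b in range(a + 1, b_hi):
                x, y = calls[:, idx[a]], calls[:, idx[b]]
                both = ~np.isnan(x) & ~np.isnan(y)
                if both.sum() < 2:
                    continue
                xv, yv = x[both], y[both]
                vx, vy = xv.var(), yv.var()
                if vx == 0 or vy == 0:
                    continue
                cov = ((xv - xv.mean()) * (yv - yv.mean())).mean()
                out.append(
                    LDPair(
                        int(idx[a]),
                        int(idx[b]),
                        int(pos[b] - pos[a]),
                        float(cov**2 / (vx * vy)),
                    )
                )
    return out


def ld_decay_curve(
    pairs: list[LDPair],
    bin_width_bp: int = 1000,
) -> tuple[pd.DataFrame, dict[float, float | None]]:
    """Mean r2 per distance bin plus loss-distance summaries.

    Returns a DataFrame (bin_mid, mean_r2, n_pairs; empty bins reported with
    NaN) and, for f in {0.5, 0.9}, the smallest bin midpoint at which
    mean r2 <= (1 - f) * max bin mean (None if never reached).
    """
    if not pairs:
        raise InputError("no LD pairs")
    dist = np.array([p.distance for p in pairs])
    r2 = np.array([p.r2 for p in pairs])
    n_bins = int(dist.max() // bin_width_bp) + 1
    bins = (dist // bin_width_bp).astype(int)
    mean = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=np.int64)
    for b in range(n_bins):
        sel = bins == b
        counts[b] = sel.sum()
        if counts[b]:
            mean[b] = r2[sel].mean()
    mids = (np.arange(n_bins) + 0.5) * bin_width_bp
    curve = pd.DataFrame({"bin_mid": mids, "mean_r2": mean, "n_pairs": counts})
    peak = np.nanmax(mean)
    summary: dict[float, float | None] = {}
    for f in (0.5, 0.9):
        threshold = (1.0 - f) * peak
        hit = np.flatnonzero(~np.isnan(mean) & (mean <= threshold + 1e-9 * peak))
        summary[f] = float(mids[hit[0]]) if len(hit) else None
    return curve, summary


def chisq_test(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square test of independence (no continuity correction)."""
    table = np.asarray(table)
    if table.ndim != 2 or min(table.shape) < 2:
        raise InputError("need at least a 2x2 table")
    if (table < 0).any():
        raise InputError("counts must be non-negative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise InputError("zero margin in contingency table")
    stat, p, dof, _ = chi2_contingency(table, correction=False)
    return float(stat), int(dof), float(p)


def _log_table_prob(table: np.ndarray, log_margin_const: float) -> float:
    return log_margin_const - gammaln(table + 1).sum()


def fisher_exact_rxc(table: np.ndarray, max_total: int = 500) -> float:
    """Exact Fisher test for an r x c table by full enumeration.

    The p-value is the total hypergeometric probability of all tables with
    the observed margins whose probability does not exceed that of the
    observed table.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2:
        raise InputError("table must be 2-dimensional")
    if (table < 0).any():
        raise InputError("counts must be non-negative")
    n = int(table.sum())
    if n > max_total:
        raise InputError(
            f"total count {n} exceeds enumeration bound {max_total}; "
            "use the chi-square test"
        )
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    log_margin_const = (
        gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)
    )
    logp_obs = _log_table_prob(table, log_margin_const)
    r, c = table.shape

    p_total = 0.0
    work = np.zeros((r, c), dtype=np.int64)

    def fill(row: int, col: int, row_left: np.ndarray, col_left: np.ndarray):
        nonlocal p_total
        if row == r - 1:
            # last row forced by column margins
            if (col_left >= 0).all():
                work[r - 1] = col_left
                logp = _log_table_prob(work, log_margin_const)
                if logp <= logp_obs + 1e-9:
                    p_total += math.exp(logp)
            return
        if col == c - 1:
            work[row, col] = row_left[row]
            new_col = col_left.copy()
            new_col[col] -= row_left[row]
            if new_col[col] >= 0:
                fill(row + 1, 0, row_left, new_col)
            return
        hi = min(row_left[row], col_left[col])
        for v in range(hi + 1):
            work[row, col] = v
            new_row = row_left.copy()
            new_row[row] -= v
            new_col = col_left.copy()
            new_col[col] -= v
            fill(row, col + 1, new_row, new_col)

    fill(0, 0, rows.copy(), cols.copy())
    return min(p_total, 1.0)


def enumerate_table_probs(table: np.ndarray) -> list[float]:
    """Probabilities of every table with the observed margins (test oracle)."""
    table = np.asarray(table, dtype=np.int64)
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    n = int(table.sum())
    log_margin_const = (
        gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)
    )
    r, c = table.shape
    probs: list[float] = []
    work = np.zeros((r, c), dtype=np.int64)

    def fill(row: int, col: int, row_left: np.ndarray, col_left: np.ndarray):
        if row == r - 1:
            if (col_left >= 0).all():
                work[r - 1] = col_left
                probs.append(math.exp(_log_table_prob(work, log_margin_const)))
            return
        if col == c - 1:
            work[row, col] = row_left[row]
            new_col = col_left.copy()
            new_col[col] -= row_left[row]
            if new_col[col] >= 0:
                fill(row + 1, 0, row_left, new_col)
            return
        hi = min(row_left[row], col_left[col])
        for v in range(hi + 1):
            work[row, col] = v
            new_row = row_left.copy()
            new_row[row] -= v
            new_col = col_left.copy()
            new_col[col] -= v
            fill(row, col + 1, new_row, new_col)

    fill(0, 0, rows.copy(), cols.copy())
    return probs


def reconstruct_counts(percentages: list[float], n: int) -> list[int]:
    """Integer class counts from printed percentages of a known total.

    Each percentage is rounded to the nearest count; the remainder (if the
    percentages do not sum to 100) goes to an implicit final class, so the
    returned counts always sum to ``n``.
    """
    counts = [round(p / 100.0 * n) for p in percentages]
    rest = n - sum(counts)
    if rest < 0:
        raise InputError("percentages overshoot the total")
    return counts + ([rest] if rest else [])


def truncated_residues(full_length: int, stop_position: int) -> int:
    """Residues lost to a premature stop: full protein length minus the
    position of the introduced stop codon."""
    if not (0 < stop_position <= full_length):
        raise InputError("stop position must lie within the protein")
    return full_length - stop_position
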