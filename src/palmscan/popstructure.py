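"""Genotype distances, neighbour-joining trees, PCA and Evanno delta-K.

The genetic distance between two diploids is the mean, over SNP sites called
in both, of the fraction of the four cross-sample allele pairings
(a,c), (a,d), (b,c), (b,d) that differ — equivalently the probability that
one allele drawn from each individual differs.  In dosage terms the per-site
contribution is ``(gx/2)(1 - gy/2) + (1 - gx/2)(gy/2)``.  Note that under
this definition a self-comparison is not zero at heterozygous sites (each
contributes 1/2); the diagonal of a DistanceMatrix is 0 by convention.

By default the divisor L is the number of SNP sites called in both samples
(pairwise-complete); ``global_L=True`` divides by the total SNP count
instead.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio

from palmscan.io import GenotypeMatrix, InputError

logger = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances in [0, 1] with per-pair site counts."""

    sample_ids: list[str]
    values: np.ndarray
    l_pair: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.values.shape != (n, n):
            raise InputError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise InputError("distance matrix not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


def _pair_distance(
    gx: np.ndarray, gy: np.ndarray, global_L: int | None = None
) -> tuple[float, int]:
    both = (gx >= 0) & (gy >= 0)
    L = int(both.sum())
    if L == 0:
        return float("nan"), 0
    ax = gx[both] / 2.0
    ay = gy[both] / 2.0
    total = float((ax * (1 - ay) + (1 - ax) * ay).sum())
    div = global_L if global_L is not None else L
    return total / div, L


def gronau_distance(
    matrix: GenotypeMatrix,
    sample_x: str,
    sample_y: str,
    global_L: bool = False,
) -> float:
    """Cross-pairing allele distance between two samples (see module docs)."""
    gx = matrix.calls[matrix.sample_index(sample_x)]
    gy = matrix.calls[matrix.sample_index(sample_y)]
    d, L = _pair_distance(gx, gy, matrix.n_sites if global_L else None)
    if L == 0:
        raise InputError(f"no sites called in both {sample_x} and {sample_y}")
    return d


def distance_matrix(
    matrix: GenotypeMatrix,
    subset: list[str] | None = None,
    global_L: bool = False,
) -> DistanceMatrix:
    """All-pairs cross-pairing distances (diagonal fixed to 0 by convention)."""
    ids = matrix.sample_ids if subset is None else list(subset)
    if len(ids) < 2:
        raise InputError("need >= 2 samples")
    idx = matrix.sample_indices(ids)
    n = len(ids)
    values = np.zeros((n, n))
    l_pair = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d, L = _pair_distance(
                matrix.calls[idx[i]],
                matrix.calls[idx[j]],
                matrix.n_sites if global_L else None,
            )
            values[i, j] = values[j, i] = d
            l_pair[i, j] = l_pair[j, i] = L
    return DistanceMatrix(ids, values, l_pair)


def neighbor_joining(dm: DistanceMatrix) -> skbio.TreeNode:
    """Saitou-Nei neighbour joining; returns an unrooted skbio TreeNode.

    The Q-criterion pair with the smallest value is joined each step, ties
    broken by the lowest (i, j) index pair; negative branch lengths are
    clamped to 0 (logged).
    """
    if not np.isfinite(dm.values).all():
        raise InputError("non-finite distances")
    n = len(dm.sample_ids)
    if n < 3:
        raise InputError("neighbour joining needs >= 3 samples")
    d = dm.values.astype(float).copy()
    labels: list[str] = [_quote(s) for s in dm.sample_ids]
    n_clamped = 0

    def _clamp(x: float) -> float:
        nonlocal n_clamped
        if x < 0:
            n_clamped += 1
            return 0.0
        return x

    while len(labels) > 3:
        m = len(labels)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # ties: lowest (i, j) pair in row-major order
        best = np.unravel_index(np.argmin(q), q.shape)
        i, j = min(best), max(best)
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = _clamp(li), _clamp(lj)
        new_label = f"({labels[i]}:{li:.10g},{labels[j]}:{lj:.10g})"
        d_new = (d[i] + d[j] - d[i, j]) / 2.0
        keep = [x for x in range(m) if x not in (i, j)]
        d = np.vstack([d[keep][:, keep], d_new[keep]])
        d = np.hstack([d, np.append(d_new[keep], 0.0)[:, None]])
        labels = [labels[x] for x in keep] + [new_label]
    # final 3-way join at an unresolved root
    (a, b, c) = range(3)
    la = _clamp((d[a, b] + d[a, c] - d[b, c]) / 2.0)
    lb = _clamp((d[a, b] + d[b, c] - d[a, c]) / 2.0)
    lc = _clamp((d[a, c] + d[b, c] - d[a, b]) / 2.0)
    newick = (
        f"({labels[a]}:{la:.10g},{labels[b]}:{lb:.10g},{labels[c]}:{lc:.10g});"
    )
    if n_clamped:
        logger.info("clamped %d negative branch lengths to 0", n_clamped)
    return skbio.TreeNode.read(_io.StringIO(newick))


def _quote(label: str) -> str:
    return label if label.replace("_", "").isalnum() else f"'{label}'"


def pca(
    matrix: GenotypeMatrix,
    subset: list[str] | None = None,
    n_components: int = 10,
) -> tuple[np.ndarray, np.ndarray]:
    """Standardized-genotype PCA.

    Dosages are centered by 2*p-hat and scaled by sqrt(2*p-hat*(1-p-hat));
    missing calls are imputed to the site mean and monomorphic sites dropped.
    Returns (coordinates, variance fractions) from the eigendecomposition of
    the sample covariance.
    """
    idx = matrix.sample_indices(subset)
    if len(idx) < 2:
        raise InputError("need >= 2 samples")
    g = matrix.calls[idx].astype(float)
    g[g < 0] = np.nan
    p_hat = np.nanmean(g, axis=0) / 2.0
    keep = (p_hat > 0) & (p_hat < 1)
    g = g[:, keep]
    p_hat = p_hat[keep]
    if g.shape[1] < n_components:
        raise InputError(
            f"{g.shape[1]} polymorphic sites < {n_components} components"
        )
    col_mean = 2.0 * p_hat
    inds = np.where(np.isnan(g))
    g[inds] = col_mean[inds[1]]
    x = (g - col_mean) / np.sqrt(2.0 * p_hat * (1.0 - p_hat))
    x -= x.mean(axis=0)  # sample covariance centering
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    var = s**2
    frac = var / var.sum()
    k = min(n_components, len(s))
    return u[:, :k] * s[:k], frac[:k]


def evanno_delta_k(likelihood_table: pd.DataFrame) -> pd.DataFrame:
    """Evanno delta-K from replicate clustering log-likelihoods.

    Input columns: ``K`` and ``lnL`` (one row per replicate).  Output is
    indexed by K with columns mean_lnL, sd_lnL, n_reps and delta_k, where
    delta_k(K) = |mean(K+1) - 2 mean(K) + mean(K-1)| / sd(K) (sample s.d.),
    defined only for interior K with positive s.d.
    """
    for col in ("K", "lnL"):
        if col not in likelihood_table.columns:
            raise InputError(f"likelihood table missing column {col!r}")
    grouped = likelihood_table.groupby("K")["lnL"]
    out = pd.DataFrame(
        {
            "mean_lnL": grouped.mean(),
            "sd_lnL": grouped.std(ddof=1),
            "n_reps": grouped.size(),
        }
    ).sort_index()
    ks = out.index.to_numpy()
    if len(ks) < 3 or not (np.diff(ks) == 1).all():
        raise InputError("need >= 3 consecutive K values")
    if (out["n_reps"] < 2).any():
        raise InputError("need >= 2 replicates per K")
    mean = out["mean_lnL"].to_numpy()
    delta = np.full(len(ks), np.nan)
    for i in range(1, len(ks) - 1):
        sd = out["sd_lnL"].iloc[i]
        if sd > 0:
            delta[i] = abs(mean[i + 1] - 2 * mean[i] + mean[i - 1]) / sd
    out["delta_k"] = delta
    return out


def best_k(evanno_table: pd.DataFrame) -> int:
    """argmax of delta_k over interior K."""
    if evanno_table["delta_k"].isna().all():
        raise InputError("no defined delta_k values")
    return int(evanno_table["delta_k"].idxmax())


def random_snp_subset(
    matrix: GenotypeMatrix, n_sites: int, seed: int
) -> GenotypeMatrix:
    """Uniform site subsample without replacement, genomic order preserved."""
    if n_sites > matrix.n_sites:
        raise InputError("n_sites exceeds the matrix size")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(matrix.n_sites, size=n_sites, replace=False))
    return matrix.take_sites(idx)
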