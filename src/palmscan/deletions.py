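"""Coverage-breadth gene presence/absence (homozygous deletion) calling.

A gene/sample cell's breadth is the fraction of the gene's positions covered
by at least one read.  Samples with mean depth below ``min_depth`` are
excluded entirely; a gene is callable only if at least one eligible sample
reaches ``breadth_present`` (mappability guard); within callable genes,
eligible samples with breadth strictly below ``breadth_del`` are called
deleted.  Boundary conventions follow the wording "fewer than 15%" (strict)
and "90% or more" (inclusive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from palmscan.io import InputError, SampleMetadata


@dataclass
class CoverageTable:
    """Gene x sample coverage-breadth fractions in [0, 1]."""

    breadth: pd.DataFrame  # index gene_id, columns sample ids

    def __post_init__(self) -> None:
        values = self.breadth.to_numpy(dtype=float)
        if np.isnan(values).any():
            raise InputError("coverage table contains missing values")
        if ((values < 0) | (values > 1)).any():
            raise InputError("coverage breadth values must lie in [0, 1]")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.breadth.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.breadth.columns)


@dataclass
class DeletionCall:
    gene_id: str
    deleted_samples: frozenset[str]
    cohort_frequency: float  # deleted / eligible samples


def call_deletions(
    table: CoverageTable,
    metadata: SampleMetadata,
    breadth_del: float = 0.15,
    breadth_present: float = 0.90,
    min_depth: float = 15.0,
) -> list[DeletionCall]:
    """Homozygous deletion calls under the breadth criterion (see module docs)."""
    eligible = [
        s
        for s in table.sample_ids
        if s in metadata.sample_ids and metadata.mean_depth(s) >= min_depth
    ]
    if not eligible:
        raise InputError(f"no samples with mean depth >= {min_depth}")
    sub = table.breadth[eligible]
    callable_genes = sub.max(axis=1) >= breadth_present
    out: list[DeletionCall] = []
    for gene in sub.index[callable_genes]:
        row = sub.loc[gene]
        deleted = frozenset(row.index[row < breadth_del])
        if deleted:
            out.append(DeletionCall(gene, deleted, len(deleted) / len(eligible)))
    return out


def deletion_frequency_spectrum(
    calls: list[DeletionCall], n_eligible: int
) -> dict[str, float]:
    """Fractions of gene-loss events by cohort frequency class.

    Classes: singleton (one carrier), low ((1 carrier, 20%]), and
    high (> 20% of eligible samples).
    """
    if not calls:
        raise InputError("no deletion calls")
    counts = np.array([len(c.deleted_samples) for c in calls])
    singleton = counts == 1
    high = (counts / n_eligible > 0.20) & ~singleton
    low = ~singleton & ~high
    total = len(calls)
    return {
        "n_genes": total,
        "singleton_fraction": singleton.sum() / total,
        "low_fraction": low.sum() / total,
        "high_fraction": high.sum() / total,
    }


def breadth_from_depth(
    depths: dict[str, dict[str, np.ndarray]],
) -> CoverageTable:
    """Coverage breadth from per-site depth arrays: fraction of positions
    with depth >= 1.  ``depths[gene][sample]`` is an integer array over the
    gene's positions."""
    genes = list(depths)
    if not genes:
        raise InputError("no genes")
    samples = list(depths[genes[0]])
    values = np.zeros((len(genes), len(samples)))
    for gi, gene in enumerate(genes):
        for si, sample in enumerate(samples):
            arr = np.asarray(depths[gene][sample])
            if arr.size == 0:
                raise InputError(f"empty depth array for {gene}/{sample}")
            if (arr < 0).any():
                raise InputError("depths must be non-negative")
            values[gi, si] = (arr >= 1).mean()
    return CoverageTable(
        pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)
    )
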