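"""Shared genotype/coordinate conventions and readers/writers for the standard formats.

Conventions
-----------
* Coordinates are 0-based half-open everywhere inside the package.  The only
  conversion happens at the VCF boundary: a VCF record at POS ``p`` (1-based)
  becomes internal site position ``p - 1`` and maps to the interval
  ``[p - 1, p)``.
* Genotypes are stored as alternate-allele dosage: 0, 1, 2, or :data:`MISSING`
  (``-1``).  Phase is discarded; half-missing genotypes are treated as missing.
* Only biallelic SNP records are retained; multiallelic or indel records are
  skipped with a logged count rather than decomposed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

EFFECT_CLASSES = (
    "synonymous",
    "nonsynonymous",
    "nonsense",
    "intergenic",
    "intron",
    "utr5",
    "utr3",
)


class InputError(ValueError):
    """Raised when an input file or argument violates a precondition."""


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval ``[start, end)`` on one scaffold."""

    scaffold: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise InputError(
                f"invalid interval {self.scaffold}:[{self.start}, {self.end})"
            )

    @property
    def span(self) -> int:
        return self.end - self.start

    def contains(self, scaffold: str, position: int) -> bool:
        return scaffold == self.scaffold and self.start <= position < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.scaffold == other.scaffold
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GenotypeMatrix:
    """Biallelic SNP genotypes for a panel of diploid samples.

    ``calls`` is an ``(n_samples, n_sites)`` int8 array of alternate-allele
    dosages with ``-1`` for missing.  Site positions are 0-based and strictly
    increasing within each scaffold.  ``scaffold_lengths``, when known, gives
    the callable span used to scale per-site statistics; otherwise the span is
    inferred from the last site on each scaffold.
    """

    sample_ids: list[str]
    scaffolds: np.ndarray
    positions: np.ndarray
    ref_allele: np.ndarray
    alt_allele: np.ndarray
    calls: np.ndarray
    effect_class: np.ndarray | None = None
    scaffold_lengths: dict[str, int] | None = None

    def __post_init__(self) -> None:
        self.scaffolds = np.asarray(self.scaffolds, dtype=object)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.sample_ids), len(self.positions)):
            raise InputError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.positions)} sites"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_sites(self) -> int:
        return len(self.positions)

    def validate(self) -> None:
        bad = (self.calls < -1) | (self.calls > 2)
        if bad.any():
            raise InputError("dosages must be in {0, 1, 2} or -1 (missing)")
        for scaf in pd.unique(self.scaffolds):
            pos = self.positions[self.scaffolds == scaf]
            if len(pos) > 1 and not (np.diff(pos) > 0).all():
                raise InputError(f"positions not strictly increasing on {scaf}")

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise InputError(f"unknown sample {sample_id!r}") from None

    def sample_indices(self, subset: list[str] | None) -> np.ndarray:
        if subset is None:
            return np.arange(self.n_samples)
        return np.array([self.sample_index(s) for s in subset], dtype=np.intp)

    def missing_fraction(self) -> np.ndarray:
        """Per-site fraction of missing calls."""
        return (self.calls == MISSING).mean(axis=0)

    def site_mask(self, interval: GenomicInterval) -> np.ndarray:
        return (
            (self.scaffolds == interval.scaffold)
            & (self.positions >= interval.start)
            & (self.positions < interval.end)
        )

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            sample_ids=list(self.sample_ids),
            scaffolds=self.scaffolds[index],
            positions=self.positions[index],
            ref_allele=self.ref_allele[index],
            alt_allele=self.alt_allele[index],
            calls=self.calls[:, index],
            effect_class=None if self.effect_class is None else self.effect_class[index],
            scaffold_lengths=self.scaffold_lengths,
        )

    def take_samples(self, subset: list[str]) -> "GenotypeMatrix":
        idx = self.sample_indices(subset)
        return GenotypeMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            scaffolds=self.scaffolds,
            positions=self.positions,
            ref_allele=self.ref_allele,
            alt_allele=self.alt_allele,
            calls=self.calls[idx],
            effect_class=self.effect_class,
            scaffold_lengths=self.scaffold_lengths,
        )

    def scaffold_span(self, scaffold: str) -> int:
        """Callable span of a scaffold: declared length, else last site + 1."""
        if self.scaffold_lengths and scaffold in self.scaffold_lengths:
            return self.scaffold_lengths[scaffold]
        pos = self.positions[self.scaffolds == scaffold]
        if len(pos) == 0:
            raise InputError(f"unknown scaffold {scaffold!r}")
        return int(pos.max()) + 1

    def scaffold_names(self) -> list[str]:
        if self.scaffold_lengths:
            return list(self.scaffold_lengths)
        return list(pd.unique(self.scaffolds))


@dataclass
class SampleMetadata:
    """Per-sample provenance: population label, mean depth and phenotypes.

    Backed by a DataFrame indexed by sample id with at least the columns
    ``population`` and ``mean_depth``; any further columns are phenotype
    labels (e.g. ``fruit_colour``, ``fruit_texture``).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("population", "mean_depth"):
            if col not in self.table.columns:
                raise InputError(f"metadata missing required column {col!r}")
        if self.table.index.has_duplicates:
            raise InputError("duplicate sample ids in metadata")
        if (self.table["mean_depth"] < 0).any():
            raise InputError("mean_depth must be >= 0")

    @classmethod
    def from_csv(cls, path: str | Path) -> "SampleMetadata":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index_label="sample_id")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def population(self, sample_id: str) -> str:
        return str(self.table.loc[sample_id, "population"])

    def mean_depth(self, sample_id: str) -> float:
        return float(self.table.loc[sample_id, "mean_depth"])

    def samples_in(self, population: str) -> list[str]:
        return list(self.table.index[self.table["population"] == population])

    def phenotype(self, sample_id: str, name: str):
        return self.table.loc[sample_id, name]

    def validate_against(self, matrix: GenotypeMatrix) -> None:
        missing = set(matrix.sample_ids) - set(self.table.index)
        if missing:
            raise InputError(f"samples absent from metadata: {sorted(missing)}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_BASES = frozenset("ACGT")


def read_vcf(path: str | Path, min_call_rate: float = 0.95) -> GenotypeMatrix:
    """Read biallelic SNP genotypes from a VCF v4.x file.

    Multiallelic and non-SNP records are skipped (counted in the log), phased
    separators are treated as unphased, half-missing genotypes as missing, and
    only records with call rate >= ``min_call_rate`` are retained (the default
    0.95 drops records with more than 5% missing genotypes).
    """
    from cyvcf2 import VCF

    path = Path(path)
    if not path.exists():
        raise InputError(f"no such VCF: {path}")
    try:
        vcf = VCF(str(path))
    except Exception as exc:  # cyvcf2 raises OSError on malformed headers
        raise InputError(f"cannot parse VCF {path}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise InputError(f"VCF {path} contains no samples")
    n = len(samples)

    scaffold_lengths = None
    try:
        scaffold_lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    except AttributeError:  # header without contig lines
        pass

    scaffolds, positions, refs, alts, rows, effects = [], [], [], [], [], []
    n_skipped = n_lowcall = 0
    any_effect = False
    try:
        for lineno, var in enumerate(vcf, start=1):
            if (
                len(var.ALT) != 1
                or var.REF not in _BASES
                or var.ALT[0] not in _BASES
            ):
                n_skipped += 1
                continue
            gts = var.genotypes  # [allele_a, allele_b, phased] per sample
            dosage = np.full(n, MISSING, dtype=np.int8)
            for i, gt in enumerate(gts):
                a, b = gt[0], gt[1]
                if a < 0 or b < 0:
                    continue
                dosage[i] = a + b
            call_rate = (dosage != MISSING).sum() / n
            if call_rate < min_call_rate:
                n_lowcall += 1
                continue
            scaffolds.append(var.CHROM)
            positions.append(var.POS - 1)  # to 0-based
            refs.append(var.REF)
            alts.append(var.ALT[0])
            rows.append(dosage)
            eff = var.INFO.get("EFFCLASS")
            effects.append(eff)
            any_effect = any_effect or eff is not None
    except Exception as exc:
        raise InputError(
            f"cannot parse VCF {path} near record {len(rows) + n_skipped + n_lowcall + 1}: {exc}"
        ) from exc

    if n_skipped:
        logger.info("%s: skipped %d non-biallelic-SNP records", path, n_skipped)
    if n_lowcall:
        logger.info(
            "%s: dropped %d records with call rate < %.3g",
            path,
            n_lowcall,
            min_call_rate,
        )

    calls = (
        np.array(rows, dtype=np.int8).T
        if rows
        else np.zeros((n, 0), dtype=np.int8)
    )
    matrix = GenotypeMatrix(
        sample_ids=samples,
        scaffolds=np.array(scaffolds, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref_allele=np.array(refs, dtype=object),
        alt_allele=np.array(alts, dtype=object),
        calls=calls,
        effect_class=np.array(effects, dtype=object) if any_effect else None,
        scaffold_lengths=scaffold_lengths,
    )
    matrix.validate()
    return matrix


_GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(matrix: GenotypeMatrix, path: str | Path) -> None:
    """Write a GenotypeMatrix as VCF v4.2 (unphased GT, missing as ``./.``)."""
    matrix.validate()
    order = np.lexsort((matrix.positions, matrix.scaffolds.astype(str)))
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=palmscan\n")
        if matrix.effect_class is not None:
            fh.write(
                '##INFO=<ID=EFFCLASS,Number=1,Type=String,Description="Site effect class">\n'
            )
        if matrix.scaffold_lengths:
            for name, length in matrix.scaffold_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(matrix.sample_ids)
            + "\n"
        )
        for j in order:
            info = "."
            if matrix.effect_class is not None and matrix.effect_class[j] is not None:
                info = f"EFFCLASS={matrix.effect_class[j]}"
            gts = "\t".join(_GT_STRINGS[int(d)] for d in matrix.calls[:, j])
            fh.write(
                f"{matrix.scaffolds[j]}\t{matrix.positions[j] + 1}\t.\t"
                f"{matrix.ref_allele[j]}\t{matrix.alt_allele[j]}\t.\tPASS\t"
                f"{info}\tGT\t{gts}\n"
            )


# ---------------------------------------------------------------------------
# Coverage tables, metadata, BED
# ---------------------------------------------------------------------------


def read_coverage_table(path: str | Path, metadata: SampleMetadata | None = None):
    """Read a tab-separated gene x sample coverage-breadth table.

    Header row holds sample ids, one row per gene; every value must lie in
    [0, 1].  If metadata is given, sample-set mismatches are logged as
    warnings (not errors).
    """
    from palmscan.deletions import CoverageTable

    df = pd.read_csv(path, sep="\t", index_col=0)
    table = CoverageTable(df)
    if metadata is not None:
        missing = set(metadata.sample_ids) - set(df.columns)
        extra = set(df.columns) - set(metadata.sample_ids)
        if missing:
            logger.warning("coverage table lacks samples: %s", sorted(missing))
        if extra:
            logger.warning("coverage table has unknown samples: %s", sorted(extra))
    return table


def write_coverage_table(table, path: str | Path) -> None:
    table.breadth.to_csv(path, sep="\t", index_label="gene_id")


def write_bed(
    intervals: list[GenomicInterval],
    path: str | Path,
    names: list[str] | None = None,
    scores: list[float] | None = None,
) -> None:
    """Write intervals as BED (0-based half-open), optionally with name/score."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.scaffold, str(iv.start), str(iv.end)]
            if names is not None or scores is not None:
                cols.append(names[i] if names is not None else ".")
            if scores is not None:
                cols.append(f"{scores[i]:g}")
            fh.write("\t".join(cols) + "\n")


def read_bed(path: str | Path):
    """Read a BED file; returns (intervals, extra columns as list of tuples)."""
    intervals, extras = [], []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            intervals.append(
                GenomicInterval(parts[0], int(parts[1]), int(parts[2]))
            )
            extras.append(tuple(parts[3:]))
    return intervals, extras
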