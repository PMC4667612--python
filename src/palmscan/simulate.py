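"""Synthetic genotype, coverage and truth data with known population structure.

The generator emulates the statistical structure of a two-population crop
resequencing panel (a North Africa vs Middle East analogue): a clean
population split, admixed individuals, a per-site scaled mutation rate near
0.01, planted low-diversity sweep windows, whole-locus identity-by-descent
inbreeding with long runs of homozygosity, and per-gene coverage breadth with
planted homozygous gene deletions.

The coalescent here is the standard n-sample Kingman coalescent with
infinite sites: exponential waiting times with rate k(k-1)/2 while k lineages
remain (time in units of 2N generations), and Poisson mutations at rate
theta*L/2 per unit branch length, so E[S] = theta * L * a_{n-1} and
E[pi] = theta per site.  Loci are independent (no intra-locus recombination);
linkage disequilibrium is produced by a separate discrete-generation
Wright-Fisher forward simulator with per-bp recombination.

Selective sweeps are modelled as a local reduction of effective theta: at
swept loci the swept population's haplotypes are drawn from an independent
coalescent with theta multiplied by the diversity-reduction factor, which
plants exactly the footprint the diversity-ratio scan consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from palmscan.io import (
    GenomicInterval,
    GenotypeMatrix,
    InputError,
    SampleMetadata,
)

SCAFFOLD = "S000001"

POP1 = "north_africa"
POP2 = "middle_east"
ADMIXED = "admixed"


@dataclass(frozen=True)
class SweepSpec:
    """A planted sweep: the named population loses diversity on the interval."""

    population: str
    interval: GenomicInterval
    factor: float  # effective theta multiplier, 0 < factor <= 1

    def __post_init__(self) -> None:
        if not (0 < self.factor <= 1):
            raise InputError("diversity_reduction_factor must be in (0, 1]")
        if self.population not in (POP1, POP2):
            raise InputError(f"unknown sweep population {self.population!r}")


@dataclass(frozen=True)
class WrightFisherParams:
    """Forward-simulation knobs: diploid N, generations, per-bp rates."""

    n_diploid: int = 50
    generations: int = 200
    seq_len: int = 5000
    mu_per_bp: float = 5e-5
    recomb_per_bp: float = 1e-4


@dataclass
class DeletionSpec:
    """Planted homozygous gene deletions for the coverage simulator.

    ``deleted`` maps gene id -> set of sample ids carrying the deletion.
    Non-deleted breadths are Uniform(present_range); deleted breadths are
    Uniform(deleted_range).
    """

    n_genes: int = 50
    deleted: dict[str, set[str]] = field(default_factory=dict)
    present_range: tuple[float, float] = (0.92, 1.0)
    deleted_range: tuple[float, float] = (0.0, 0.10)

    def __post_init__(self) -> None:
        for lo, hi in (self.present_range, self.deleted_range):
            if not (0 <= lo <= hi <= 1):
                raise InputError("breadth noise bounds must lie within [0, 1]")


@dataclass
class SimulationConfig:
    """Conditions for the two-population genotype simulation.

    ``theta_site`` defaults to 0.01, the per-site scale of the study system;
    ``split_time`` is in units of 2N generations (0 = panmictic) and, with the
    deme sizes, is an illustrative free knob.  ``admixture_fractions`` gives,
    per admixed sample, the probability that each of its lineages at a locus
    descends from population 1.  ``inbreeding_f`` gives per-sample
    probabilities of whole-locus identity by descent; ``roh_spec`` plants
    deterministic IBD tracts.
    """

    seed: int = 0
    n_pop1: int = 10
    n_pop2: int = 42
    theta_site: float = 0.01
    n_loci: int = 200
    locus_len: int = 1000
    split_time: float = 1.0
    admixture_fractions: list[float] = field(default_factory=list)
    sweep_spec: list[SweepSpec] = field(default_factory=list)
    inbreeding_f: dict[str, float] = field(default_factory=dict)
    roh_spec: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    wf_params: WrightFisherParams | None = None
    deletion_spec: DeletionSpec | None = None
    mean_depth: float = 20.8

    def __post_init__(self) -> None:
        if self.theta_site <= 0:
            raise InputError("theta_site must be > 0")
        if self.split_time < 0:
            raise InputError("split_time must be >= 0")
        if self.split_time > 0 and (self.n_pop1 < 2 or self.n_pop2 < 2):
            raise InputError("need >= 2 samples per population when split_time > 0")
        for a in self.admixture_fractions:
            if not (0 <= a <= 1):
                raise InputError("admixture fractions must be in [0, 1]")
        for f in self.inbreeding_f.values():
            if not (0 <= f <= 1):
                raise InputError("inbreeding_f values must be in [0, 1]")

    @property
    def sample_ids(self) -> list[str]:
        return (
            [f"NA{i + 1:03d}" for i in range(self.n_pop1)]
            + [f"ME{i + 1:03d}" for i in range(self.n_pop2)]
            + [f"AD{i + 1:03d}" for i in range(len(self.admixture_fractions))]
        )

    @property
    def populations(self) -> list[str]:
        return (
            [POP1] * self.n_pop1
            + [POP2] * self.n_pop2
            + [ADMIXED] * len(self.admixture_fractions)
        )

    @property
    def genome_length(self) -> int:
        return self.n_loci * self.locus_len


@dataclass
class SimTruth:
    """Ground truth emitted alongside simulated data; consumed only by tests."""

    sweeps: list[SweepSpec] = field(default_factory=list)
    roh: dict[str, list[GenomicInterval]] = field(default_factory=dict)
    f_true: dict[str, float] = field(default_factory=dict)
    deleted: set[tuple[str, str]] = field(default_factory=set)  # (gene, sample)
    theta_site: float = 0.0
    ancestry_fraction: dict[str, float] = field(default_factory=dict)
    ibd_loci: dict[str, list[int]] = field(default_factory=dict)
    n_loci: int = 0
    locus_len: int = 0


# ---------------------------------------------------------------------------
# Kingman coalescent with infinite sites
# ---------------------------------------------------------------------------


def _coalescent_tree(
    demes: np.ndarray, split_time: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate a (structured) coalescent genealogy.

    ``demes`` assigns each of the n leaf lineages to a deme; lineages coalesce
    only within demes until ``split_time`` (in 2N units), after which all
    demes merge into one ancestral pool.  Returns (parent, node_time) arrays
    over the 2n-1 nodes; leaves are nodes 0..n-1, the root has parent -1.
    """
    n = len(demes)
    if n < 2:
        raise InputError("need >= 2 lineages")
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    node_time = np.zeros(2 * n - 1)
    merged = split_time <= 0 or len(np.unique(demes)) == 1
    pools: dict[int, list[int]]
    if merged:
        pools = {0: list(range(n))}
    else:
        pools = {d: list(np.flatnonzero(demes == d)) for d in np.unique(demes)}
    t = 0.0
    nxt = n
    while sum(len(p) for p in pools.values()) > 1:
        rates = {d: len(p) * (len(p) - 1) / 2 for d, p in pools.items()}
        total = sum(rates.values())
        if total == 0:
            # isolated singleton lineages: nothing can happen before the merge
            t = split_time
            pools = {0: [x for p in pools.values() for x in p]}
            merged = True
            continue
        dt = rng.exponential(1.0 / total)
        if not merged and t + dt >= split_time:
            t = split_time
            pools = {0: [x for p in pools.values() for x in p]}
            merged = True
            continue
        t += dt
        u = rng.random() * total
        acc = 0.0
        for d, r in rates.items():
            acc += r
            if u <= acc:
                pool = pools[d]
                break
        i, j = rng.choice(len(pool), size=2, replace=False)
        a, b = pool[i], pool[j]
        parent[a] = parent[b] = nxt
        node_time[nxt] = t
        pool[:] = [x for x in pool if x not in (a, b)] + [nxt]
        nxt += 1
    return parent, node_time


def _leaves_under(parent: np.ndarray, n_leaves: int, node: int) -> np.ndarray:
    children: dict[int, list[int]] = {}
    for c, p in enumerate(parent):
        if p >= 0:
            children.setdefault(int(p), []).append(c)
    out = []
    stack = [node]
    while stack:
        v = stack.pop()
        if v < n_leaves:
            out.append(v)
        else:
            stack.extend(children.get(v, []))
    return np.array(sorted(out), dtype=np.intp)


def _mutate_tree(
    parent: np.ndarray,
    node_time: np.ndarray,
    n_leaves: int,
    theta_total: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Drop Poisson mutations on the genealogy; returns (n_leaves, S) 0/1 array."""
    has_parent = parent >= 0
    blen = np.zeros(len(parent))
    blen[has_parent] = node_time[parent[has_parent]] - node_time[has_parent]
    total = blen.sum()
    n_mut = rng.poisson(theta_total / 2.0 * total)
    if n_mut == 0:
        return np.zeros((n_leaves, 0), dtype=np.int8)
    branches = rng.choice(len(parent), size=n_mut, p=blen / total)
    haps = np.zeros((n_leaves, n_mut), dtype=np.int8)
    # memoise leaf sets: many mutations often land on the same branch
    cache: dict[int, np.ndarray] = {}
    for col, b in enumerate(branches):
        b = int(b)
        if b not in cache:
            cache[b] = _leaves_under(parent, n_leaves, b)
        haps[cache[b], col] = 1
    return haps


def simulate_coalescent_locus(
    n_chrom: int,
    theta_site: float,
    locus_len: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """One neutral panmictic infinite-sites locus.

    Returns ``(haplotypes, positions)``: an ``(n_chrom, S)`` 0/1 array and the
    sorted 0-based site positions (uniform on the locus, all distinct).  Every
    segregating site splits the sample into two non-empty allele classes.
    """
    if n_chrom < 2:
        raise InputError("n_chrom must be >= 2")
    if theta_site <= 0:
        raise InputError("theta_site must be > 0")
    parent, node_time = _coalescent_tree(np.zeros(n_chrom, dtype=np.int64), 0.0, rng)
    haps = _mutate_tree(parent, node_time, n_chrom, theta_site * locus_len, rng)
    s = haps.shape[1]
    if s > locus_len:
        raise InputError(
            f"locus of {locus_len} bp cannot hold {s} infinite-sites mutations; "
            "increase locus_len or reduce theta"
        )
    positions = np.sort(rng.choice(locus_len, size=s, replace=False))
    return haps, positions


def _simulate_locus_haplotypes(
    demes: np.ndarray,
    split_time: float,
    theta_total: float,
    rng: np.random.Generator,
) -> np.ndarray:
    parent, node_time = _coalescent_tree(demes, split_time, rng)
    return _mutate_tree(parent, node_time, len(demes), theta_total, rng)


def simulate_two_pop(
    config: SimulationConfig,
) -> tuple[GenotypeMatrix, SampleMetadata, SimTruth]:
    """Simulate the full two-population panel on one synthetic scaffold.

    Loci are laid end to end on scaffold ``S000001``.  Population-1 and
    population-2 lineages coalesce in separate demes until ``split_time``;
    each admixed lineage joins deme 1 with its sample's admixture fraction.
    Sweeps replace the swept population's haplotypes at overlapping loci with
    an independent coalescent at ``theta * factor``.  With probability
    ``inbreeding_f[sample]`` (or deterministically inside ``roh_spec``
    intervals) an individual's second haplotype is a whole-locus copy of its
    first.
    """
    rng = np.random.default_rng(config.seed)
    sample_ids = config.sample_ids
    pops = config.populations
    n_samples = len(sample_ids)
    n_chrom = 2 * n_samples
    chrom_sample = np.repeat(np.arange(n_samples), 2)

    # base deme per chromosome; admixed chroms re-drawn per locus
    base_deme = np.empty(n_chrom, dtype=np.int64)
    for s in range(n_samples):
        if pops[s] == POP1:
            base_deme[2 * s : 2 * s + 2] = 0
        elif pops[s] == POP2:
            base_deme[2 * s : 2 * s + 2] = 1
        else:
            base_deme[2 * s : 2 * s + 2] = -1  # drawn per locus
    admixed_idx = [i for i, p in enumerate(pops) if p == ADMIXED]
    alpha = dict(zip(admixed_idx, config.admixture_fractions))

    truth = SimTruth(
        sweeps=list(config.sweep_spec),
        roh={s: list(v) for s, v in config.roh_spec.items()},
        f_true={s: config.inbreeding_f.get(s, 0.0) for s in sample_ids},
        theta_site=config.theta_site,
        n_loci=config.n_loci,
        locus_len=config.locus_len,
        ibd_loci={s: [] for s in sample_ids},
    )
    pop1_draws = {s: 0 for s in admixed_idx}

    all_pos: list[np.ndarray] = []
    all_calls: list[np.ndarray] = []
    for locus in range(config.n_loci):
        start = locus * config.locus_len
        locus_iv = GenomicInterval(SCAFFOLD, start, start + config.locus_len)
        # sweep factors hitting this locus, by population
        factors = {POP1: 1.0, POP2: 1.0}
        for sw in config.sweep_spec:
            if sw.interval.overlaps(locus_iv):
                factors[sw.population] = min(factors[sw.population], sw.factor)

        demes = base_deme.copy()
        for s in admixed_idx:
            draws = rng.random(2) < alpha[s]
            demes[2 * s : 2 * s + 2] = np.where(draws, 0, 1)
            pop1_draws[s] += int(draws.sum())

        theta_total = config.theta_site * config.locus_len
        swept_pops = [p for p, f in factors.items() if f < 1.0]
        hap_blocks: list[tuple[np.ndarray, np.ndarray]] = []  # (chrom idx, haps)
        if not swept_pops:
            haps = _simulate_locus_haplotypes(
                demes, config.split_time, theta_total, rng
            )
            hap_blocks.append((np.arange(n_chrom), haps))
        else:
            swept_demes = {POP1: 0, POP2: 1}
            swept_set = {swept_demes[p] for p in swept_pops}
            rest = np.flatnonzero(~np.isin(demes, list(swept_set)))
            if len(rest) >= 2:
                hap_blocks.append(
                    (
                        rest,
                        _simulate_locus_haplotypes(
                            demes[rest], config.split_time, theta_total, rng
                        ),
                    )
                )
            elif len(rest) == 1:
                hap_blocks.append((rest, np.zeros((1, 0), dtype=np.int8)))
            for p in swept_pops:
                idx = np.flatnonzero(demes == swept_demes[p])
                if len(idx) < 2:
                    continue
                hap_blocks.append(
                    (
                        idx,
                        _simulate_locus_haplotypes(
                            np.zeros(len(idx), dtype=np.int64),
                            0.0,
                            theta_total * factors[p],
                            rng,
                        ),
                    )
                )

        s_total = sum(h.shape[1] for _, h in hap_blocks)
        if s_total > config.locus_len:
            raise InputError("locus too short for mutation count; increase locus_len")
        haplotypes = np.zeros((n_chrom, s_total), dtype=np.int8)
        col = 0
        for idx, h in hap_blocks:
            haplotypes[idx, col : col + h.shape[1]] = h
            col += h.shape[1]
        pos_local = np.sort(rng.choice(config.locus_len, size=s_total, replace=False))
        # columns were filled block-wise; shuffle so positions are exchangeable
        order = rng.permutation(s_total)
        haplotypes = haplotypes[:, order]

        # diploid genotypes with whole-locus IBD (inbreeding / planted ROH)
        g = haplotypes[0::2] + haplotypes[1::2]  # (n_samples, S)
        for s in range(n_samples):
            sid = sample_ids[s]
            in_roh = any(iv.overlaps(locus_iv) for iv in config.roh_spec.get(sid, []))
            f = config.inbreeding_f.get(sid, 0.0)
            if in_roh or (f > 0 and rng.random() < f):
                g[s] = 2 * haplotypes[2 * s]
                truth.ibd_loci[sid].append(locus)
        # drop sites monomorphic in the final genotypes
        k = g.sum(axis=0)
        seg = (k > 0) & (k < n_chrom)
        all_pos.append(start + pos_local[seg])
        all_calls.append(g[:, seg])

    for s in admixed_idx:
        truth.ancestry_fraction[sample_ids[s]] = pop1_draws[s] / (2 * config.n_loci)

    positions = np.concatenate(all_pos)
    calls = np.concatenate(all_calls, axis=1)
    n_sites = len(positions)
    ref = np.full(n_sites, "A", dtype=object)
    alt = np.full(n_sites, "T", dtype=object)
    matrix = GenotypeMatrix(
        sample_ids=sample_ids,
        scaffolds=np.full(n_sites, SCAFFOLD, dtype=object),
        positions=positions,
        ref_allele=ref,
        alt_allele=alt,
        calls=calls,
        scaffold_lengths={SCAFFOLD: config.genome_length},
    )
    matrix.validate()
    meta = SampleMetadata(
        pd.DataFrame(
            {"population": pops, "mean_depth": config.mean_depth},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return matrix, meta, truth


def diploid_matrix_from_loci(
    loci: list[tuple[np.ndarray, np.ndarray]],
    locus_len: int,
    scaffold: str = SCAFFOLD,
) -> GenotypeMatrix:
    """Assemble per-locus haplotypes into one diploid GenotypeMatrix.

    Consecutive haplotypes are paired into diploids; loci are laid end to end
    on one scaffold.  Dosage-based statistics (per-site n and k) are identical
    whether computed on the haplotypes or on the paired genotypes.
    """
    if not loci:
        raise InputError("no loci")
    n_chrom = loci[0][0].shape[0]
    if n_chrom % 2:
        raise InputError("need an even number of haplotypes to pair diploids")
    pos_out, call_out = [], []
    for i, (haps, pos) in enumerate(loci):
        g = haps[0::2] + haps[1::2]
        k = haps.sum(axis=0)
        seg = (k > 0) & (k < n_chrom)
        pos_out.append(i * locus_len + pos[seg])
        call_out.append(g[:, seg])
    positions = np.concatenate(pos_out)
    calls = np.concatenate(call_out, axis=1).astype(np.int8)
    n_sites = len(positions)
    return GenotypeMatrix(
        sample_ids=[f"S{i + 1:03d}" for i in range(n_chrom // 2)],
        scaffolds=np.full(n_sites, scaffold, dtype=object),
        positions=positions,
        ref_allele=np.full(n_sites, "A", dtype=object),
        alt_allele=np.full(n_sites, "T", dtype=object),
        calls=calls,
        scaffold_lengths={scaffold: len(loci) * locus_len},
    )


# ---------------------------------------------------------------------------
# Forward Wright-Fisher simulation (for LD decay)
# ---------------------------------------------------------------------------


def simulate_wright_fisher_ld(
    wf_params: WrightFisherParams,
    n_sample: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete-generation diploid Wright-Fisher with recombination and mutation.

    A population of 2N haplotypes over ``seq_len`` biallelic sites evolves for
    ``generations`` generations; each offspring haplotype is a recombinant
    gamete of a random parent (crossovers Poisson with mean
    ``recomb_per_bp * seq_len``), and mutations (Poisson with mean
    ``2N * seq_len * mu_per_bp`` per generation) flip single alleles.  Returns
    ``n_sample`` sampled haplotypes restricted to segregating sites, plus the
    site positions.
    """
    p = wf_params
    if p.n_diploid < 10:
        raise InputError("n_diploid must be >= 10")
    if p.generations <= 0:
        raise InputError("generations must be > 0")
    if n_sample > 2 * p.n_diploid:
        raise InputError("cannot sample more haplotypes than 2N")
    n_hap = 2 * p.n_diploid
    pop = np.zeros((n_hap, p.seq_len), dtype=np.int8)
    mean_mut = n_hap * p.seq_len * p.mu_per_bp
    mean_xo = p.recomb_per_bp * p.seq_len
    for _ in range(p.generations):
        parents = rng.integers(p.n_diploid, size=n_hap)
        which = rng.integers(2, size=n_hap)
        n_xo = rng.poisson(mean_xo, size=n_hap)
        new = pop[2 * parents + which].copy()
        for i in np.flatnonzero(n_xo):
            cuts = np.sort(rng.integers(1, p.seq_len, size=n_xo[i]))
            gamete = new[i]
            other = pop[2 * parents[i] + 1 - which[i]]
            use_other = False
            prev = 0
            for cut in list(cuts) + [p.seq_len]:
                if use_other:
                    gamete[prev:cut] = other[prev:cut]
                use_other = not use_other
                prev = cut
        pop = new
        n_mut = rng.poisson(mean_mut)
        if n_mut:
            rows = rng.integers(n_hap, size=n_mut)
            cols = rng.integers(p.seq_len, size=n_mut)
            pop[rows, cols] = 1 - pop[rows, cols]
    take = rng.choice(n_hap, size=n_sample, replace=False)
    sample = pop[take]
    freq = sample.mean(axis=0)
    seg = (freq > 0) & (freq < 1)
    return sample[:, seg], np.flatnonzero(seg).astype(np.int64)


# ---------------------------------------------------------------------------
# Coverage breadth (for the deletion caller)
# ---------------------------------------------------------------------------


def simulate_coverage(
    deletion_spec: DeletionSpec,
    samples: list[str],
    rng: np.random.Generator,
):
    """Per-gene per-sample coverage breadth with planted homozygous deletions.

    Non-deleted cells draw breadth from Uniform over ``present_range``
    (default (0.92, 1.0)); deleted cells from ``deleted_range`` (default
    (0, 0.10)).  Returns (CoverageTable, SimTruth with ``deleted`` pairs).
    """
    from palmscan.deletions import CoverageTable

    genes = [f"gene{i + 1:04d}" for i in range(deletion_spec.n_genes)]
    known = set(deletion_spec.deleted)
    unknown = known - set(genes)
    if unknown:
        raise InputError(f"deletion_spec names unknown genes: {sorted(unknown)}")
    lo_p, hi_p = deletion_spec.present_range
    lo_d, hi_d = deletion_spec.deleted_range
    values = rng.uniform(lo_p, hi_p, size=(len(genes), len(samples)))
    truth = SimTruth()
    for gi, gene in enumerate(genes):
        for sample in deletion_spec.deleted.get(gene, set()):
            si = samples.index(sample)
            values[gi, si] = rng.uniform(lo_d, hi_d)
            truth.deleted.add((gene, sample))
    table = CoverageTable(
        pd.DataFrame(values, index=pd.Index(genes, name="gene_id"), columns=samples)
    )
    return table, truth
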