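# palmscan

Post-variant-calling population genomics for resequenced crop panels, built
around the analyses used to characterise diversity and diversification in
date palm (*Phoenix dactylifera*) cultivars: windowed diversity statistics, a
two-population diversity-ratio selective-sweep scan, genotype-distance
neighbour-joining trees, heterozygosity/ROH/inbreeding profiling,
coverage-breadth gene presence/absence calling, LD decay, and
contingency-table genotype–phenotype association tests.  A built-in
coalescent / Wright–Fisher synthetic-data generator produces VCFs, coverage
tables and truth files with the same statistical structure, so every stage
is testable end-to-end with no external data.

It is aimed at population geneticists working with called genotypes (a VCF
with GT fields plus a sample-metadata table) downstream of read alignment
and SNP calling.

## The statistics at the core

For a window of genomic span *L* with *S* segregating sites and *n* called
chromosomes:

* **Watterson's estimator** θ̂_W = S / (a_{n−1} · L), with
  a_m = Σ_{i=1}^{m} 1/i.
* **Nucleotide diversity** π̂ = (1/L) Σ_sites 2k(n−k) / (n(n−1)), with per-site
  alternate-allele count *k*.
* **Tajima's D** = (Π − S/a₁) / √(e₁S + e₂S(S−1)) with the standard 1989
  constants, undefined when S = 0.
* **Sweep scan**: per 5-kb window, x = log₂(θ_W,pop1 / θ_W,pop2) is Z-scored
  against the genome-wide empirical distribution; windows with |Z| ≥ 5 call a
  region only when a second outlier window starts within 10 kb (both tails
  scanned, giving the direction of diversity loss).
* **Genotype distance** between diploids X and Y: the mean over SNP sites of
  the fraction of the four cross-sample allele pairings (a,c),(a,d),(b,c),(b,d)
  that differ; trees by Saitou–Nei neighbour joining.
* **Inbreeding** F̂ = 1 − H_obs / Σ 2p̂(1−p̂) over intermediate-frequency sites,
  with p̂ from a reference panel excluding the focal sample.
* **Gene loss**: a sample is called deleted for a gene when its coverage
  breadth is < 0.15 while some ≥15× sample reaches ≥ 0.90 (mappability guard).
* **LD**: genotype-dosage r² within 100 kb at MAF ≥ 0.1, binned in 1-kb
  distance classes.

## Worked example

Simulate a two-population panel with one planted sweep and scan it:

```python
from palmscan import (
    SimulationConfig, SweepSpec, GenomicInterval,
    simulate_two_pop, window_scan, score_windows, call_regions,
    percent_reduction, watterson_theta,
)

sweep_iv = GenomicInterval("S000001", 200_000, 220_000)
config = SimulationConfig(
    seed=3, n_pop1=10, n_pop2=10, n_loci=400, locus_len=2500,
    split_time=1.0,
    sweep_spec=[SweepSpec("middle_east", sweep_iv, 0.05)],
)
matrix, meta, truth = simulate_two_pop(config)

na = meta.samples_in("north_africa")
me = meta.samples_in("middle_east")
scores = score_windows(window_scan(matrix, na, 5000),
                       window_scan(matrix, me, 5000))
# genome-scale scans use z_threshold=5; at this 1-Mb toy scale the handful
# of swept windows themselves inflate the empirical s.d., so the demo uses 4
for r in call_regions(scores, z_threshold=4.0, pair_distance=10_000):
    print(r.interval.scaffold, r.interval.start, r.interval.end,
          r.direction, round(r.min_z, 2))

t_na = watterson_theta(matrix, na, sweep_iv)
t_me = watterson_theta(matrix, me, sweep_iv)
print(round(t_na, 5), round(t_me, 5), f"{percent_reduction(t_na, t_me):.0f}%")
```

prints (seed 3):

```
S000001 200000 220000 pop2 -7.26
0.00977 0.00038 96%
```

i.e. the scan recovers the planted 20-kb interval exactly, the direction
(population 2, the Middle-East analogue, lost diversity), and the ~96% local
diversity reduction produced by the planted factor of 0.05.

The same stages are available from the shell:

```bash
palmscan simulate --out demo --seed 3
palmscan sweep-scan --vcf demo/simulated.vcf --pop demo/metadata.csv \
    --window 5000 --z 5 --pair-dist 10000 --out regions.bed
palmscan assoc --table counts.csv --test chisq
palmscan run --out run1 --seed 3      # full pipeline with a JSON/markdown report
```

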