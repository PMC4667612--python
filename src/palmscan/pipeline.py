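"""End-to-end orchestration: simulate -> diversity -> sweep scan -> structure
-> ROH/inbreeding -> deletions -> LD -> association, with one config and one
seed.

Every stage writes its own re-loadable output file under the run directory
and contributes a section to a JSON + markdown report.  Given the same
config and seed the report is byte-identical across reruns.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from palmscan import diversity, hetroh, ldassoc, popstructure, sweep
from palmscan.deletions import call_deletions, deletion_frequency_spectrum
from palmscan.io import (
    GenomicInterval,
    InputError,
    SampleMetadata,
    read_coverage_table,
    read_vcf,
    write_bed,
    write_coverage_table,
    write_vcf,
)
from palmscan.simulate import (
    POP1,
    POP2,
    DeletionSpec,
    SimulationConfig,
    SweepSpec,
    WrightFisherParams,
    simulate_coverage,
    simulate_two_pop,
    simulate_wright_fisher_ld,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs; defaults follow the study's printed parameters."""

    seed: int = 0
    out_dir: str = "palmscan_run"
    # inputs; when vcf is None the synthetic generator provides the data
    vcf: str | None = None
    metadata: str | None = None
    coverage_table: str | None = None
    likelihood_table: str | None = None  # CSV with columns K, lnL
    sim: SimulationConfig | None = None
    # analysis parameters
    diversity_window: int = 10_000
    sweep_window: int = 5_000
    z_threshold: float = 5.0
    pair_distance: int = 10_000
    enrichment_z: float = 3.0
    min_S: int = 2
    het_window: int = 20_000
    roh_min_span: int = 500_000
    breadth_del: float = 0.15
    breadth_present: float = 0.90
    min_depth: float = 15.0
    ld_window_bp: int = 100_000
    min_maf: float = 0.1
    ld_bin_bp: int = 1000
    n_structure_snps: int = 25_000
    pop1: str = POP1
    pop2: str = POP2

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("sim", None)
        config = cls(**raw)
        if sim is not None:
            sweeps = [
                SweepSpec(
                    s["population"],
                    GenomicInterval(
                        s.get("scaffold", "S000001"), s["start"], s["end"]
                    ),
                    s["factor"],
                )
                for s in sim.pop("sweep_spec", [])
            ]
            roh = {
                sample: [
                    GenomicInterval(r.get("scaffold", "S000001"), r["start"], r["end"])
                    for r in ivs
                ]
                for sample, ivs in sim.pop("roh_spec", {}).items()
            }
            wf = sim.pop("wf_params", None)
            dele = sim.pop("deletion_spec", None)
            config.sim = SimulationConfig(
                sweep_spec=sweeps,
                roh_spec=roh,
                wf_params=WrightFisherParams(**wf) if wf else None,
                deletion_spec=(
                    DeletionSpec(
                        n_genes=dele["n_genes"],
                        deleted={g: set(v) for g, v in dele.get("deleted", {}).items()},
                    )
                    if dele
                    else None
                ),
                **sim,
            )
        return config


def _echo_thresholds(config: RunConfig) -> None:
    for f in dataclasses.fields(config):
        if f.name in ("sim",):
            continue
        logger.info("config %s = %r", f.name, getattr(config, f.name))


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the report dict (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _echo_thresholds(config)
    report: dict = {"seed": config.seed}
    stage = "inputs"
    try:
        truth = None
        if config.vcf is not None:
            matrix = read_vcf(config.vcf)
            if config.metadata is None:
                raise InputError("metadata CSV required with --vcf")
            meta = SampleMetadata.from_csv(config.metadata)
        else:
            sim = config.sim or SimulationConfig(seed=config.seed)
            matrix, meta, truth = simulate_two_pop(sim)
            write_vcf(matrix, out / "simulated.vcf")
            meta.to_csv(out / "metadata.csv")
            (out / "truth.json").write_text(
                json.dumps(
                    {
                        "theta_site": truth.theta_site,
                        "f_true": truth.f_true,
                        "sweeps": [
                            {
                                "population": s.population,
                                "start": s.interval.start,
                                "end": s.interval.end,
                                "factor": s.factor,
                            }
                            for s in truth.sweeps
                        ],
                    },
                    sort_keys=True,
                    indent=1,
                )
            )
        meta.validate_against(matrix)
        pop1 = meta.samples_in(config.pop1)
        pop2 = meta.samples_in(config.pop2)

        stage = "diversity"
        whole = [
            GenomicInterval(s, 0, matrix.scaffold_span(s))
            for s in matrix.scaffold_names()
        ]
        pooled = {}
        for name, subset in (("all", None), (config.pop1, pop1), (config.pop2, pop2)):
            if subset is not None and len(subset) < 2:
                continue
            stats = [diversity.window_stat(matrix, subset, iv) for iv in whole]
            L = sum(w.n_callable_sites for w in stats)
            S = sum(w.S for w in stats)
            n_bar = int(round(np.mean([w.mean_n for w in stats])))
            pooled[name] = {
                "theta_w": S / (diversity.harmonic(n_bar - 1) * L) if S else 0.0,
                "pi": float(
                    sum(w.pi * w.n_callable_sites for w in stats) / L
                ),
                "S": S,
                "L": L,
            }
        windows = diversity.window_scan(matrix, None, config.diversity_window)
        _write_windows(windows, out / "diversity_windows.tsv")
        report["diversity"] = pooled

        stage = "sweep_scan"
        if len(pop1) >= 2 and len(pop2) >= 2:
            w1 = diversity.window_scan(matrix, pop1, config.sweep_window)
            w2 = diversity.window_scan(matrix, pop2, config.sweep_window)
            scores = sweep.score_windows(w1, w2, min_S=config.min_S)
            d_by_window = {w.interval: w.tajima_d for w in w2}
            regions = sweep.call_regions(
                scores,
                config.z_threshold,
                config.pair_distance,
                tajima_by_window=d_by_window,
            )
            write_bed(
                [r.interval for r in regions],
                out / "sweep_regions.bed",
                names=[r.direction for r in regions],
                scores=[r.min_z for r in regions],
            )
            _write_scores(scores, d_by_window, out / "sweep_windows.tsv")
            try:
                _, chi2, p = sweep.tajima_enrichment(
                    scores, d_by_window, config.enrichment_z
                )
            except InputError:
                chi2 = p = math.nan
            report["sweep_scan"] = {
                "n_scored_windows": sum(not s.excluded for s in scores),
                "n_regions": len(regions),
                "regions": [
                    {
                        "scaffold": r.interval.scaffold,
                        "start": r.interval.start,
                        "end": r.interval.end,
                        "direction": r.direction,
                        "min_z": r.min_z,
                    }
                    for r in regions
                ],
                "tajima_enrichment_chi2": chi2,
                "tajima_enrichment_p": p,
            }

        stage = "population_structure"
        sub = matrix
        if matrix.n_sites > config.n_structure_snps:
            sub = popstructure.random_snp_subset(
                matrix, config.n_structure_snps, config.seed
            )
        dm = popstructure.distance_matrix(sub)
        dm.to_frame().to_csv(out / "distances.tsv", sep="\t")
        tree = popstructure.neighbor_joining(dm)
        tree.write(str(out / "tree.nwk"))
        coords, var_frac = popstructure.pca(
            sub, n_components=min(5, len(sub.sample_ids) - 1)
        )
        np.savetxt(out / "pca.tsv", coords, delimiter="\t")
        report["population_structure"] = {
            "n_snps_used": sub.n_sites,
            "pc_variance_fractions": [float(v) for v in var_frac],
        }
        if config.likelihood_table:
            import pandas as pd

            table = popstructure.evanno_delta_k(
                pd.read_csv(config.likelihood_table)
            )
            table.to_csv(out / "evanno.tsv", sep="\t")
            report["population_structure"]["best_k"] = popstructure.best_k(table)

        stage = "het_roh"
        roh_rows = []
        f_rows = []
        for sample in matrix.sample_ids:
            hw = hetroh.het_windows(matrix, sample, config.het_window)
            for r in hetroh.detect_roh(hw, min_span=config.roh_min_span):
                roh_rows.append(r)
            try:
                est = hetroh.inbreeding_f(matrix, sample)
                f_rows.append((sample, est.f, est.n_sites))
            except InputError:
                pass
        write_bed(
            [r.interval for r in roh_rows],
            out / "roh.bed",
            names=[r.sample for r in roh_rows],
        )
        with open(out / "inbreeding.tsv", "w") as fh:
            fh.write("sample\tF\tn_sites\n")
            for sample, f_val, n_sites in f_rows:
                fh.write(f"{sample}\t{f_val:.6g}\t{n_sites}\n")
        report["het_roh"] = {
            "n_roh": len(roh_rows),
            "inbreeding_f": {s: round(f_val, 6) for s, f_val, _ in f_rows},
        }

        stage = "deletions"
        cov = None
        if config.coverage_table:
            cov = read_coverage_table(config.coverage_table, meta)
        elif config.sim is not None and config.sim.deletion_spec is not None:
            rng = np.random.default_rng(config.seed + 1)
            cov, cov_truth = simulate_coverage(
                config.sim.deletion_spec, matrix.sample_ids, rng
            )
            write_coverage_table(cov, out / "coverage.tsv")
            if truth is not None:
                truth.deleted = cov_truth.deleted
        if cov is not None:
            calls = call_deletions(
                cov, meta, config.breadth_del, config.breadth_present, config.min_depth
            )
            eligible = [
                s
                for s in cov.sample_ids
                if s in meta.sample_ids and meta.mean_depth(s) >= config.min_depth
            ]
            spectrum = (
                deletion_frequency_spectrum(calls, len(eligible)) if calls else {}
            )
            with open(out / "deletions.tsv", "w") as fh:
                fh.write("gene_id\tcohort_frequency\tdeleted_samples\n")
                for c in calls:
                    fh.write(
                        f"{c.gene_id}\t{c.cohort_frequency:.6g}\t"
                        f"{','.join(sorted(c.deleted_samples))}\n"
                    )
            report["deletions"] = {
                "n_gene_loss_events": len(calls),
                "spectrum": spectrum,
            }

        stage = "ld"
        if config.sim is not None and config.sim.wf_params is not None:
            rng = np.random.default_rng(config.seed + 2)
            haps, pos = simulate_wright_fisher_ld(
                config.sim.wf_params, n_sample=40, rng=rng
            )
            from palmscan.io import GenotypeMatrix

            n_pairs = haps.shape[0] // 2
            g = haps[0 : 2 * n_pairs : 2] + haps[1 : 2 * n_pairs : 2]
            ld_matrix = GenotypeMatrix(
                sample_ids=[f"WF{i:03d}" for i in range(n_pairs)],
                scaffolds=np.full(len(pos), "wf_locus", dtype=object),
                positions=pos,
                ref_allele=np.full(len(pos), "A", dtype=object),
                alt_allele=np.full(len(pos), "T", dtype=object),
                calls=g.astype(np.int8),
            )
        else:
            ld_matrix = matrix
        pairs = ldassoc.ld_pairs(ld_matrix, config.ld_window_bp, config.min_maf)
        if pairs:
            curve, summary = ldassoc.ld_decay_curve(pairs, config.ld_bin_bp)
            curve.to_csv(out / "ld_decay.tsv", sep="\t", index=False)
            report["ld"] = {
                "n_pairs": len(pairs),
                "half_loss_distance_bp": summary[0.5],
                "ninety_loss_distance_bp": summary[0.9],
            }

        stage = "report"
        text = json.dumps(report, sort_keys=True, indent=1, allow_nan=True)
        (out / "report.json").write_text(text)
        (out / "report.md").write_text(_markdown_report(report))
    except Exception as exc:
        raise RuntimeError(
            f"pipeline failed at stage {stage!r}: {exc} "
            f"(partial outputs preserved in {out})"
        ) from exc
    return report


def _write_windows(windows, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tstart\tend\tL\tS\ttheta_w\tpi\ttajima_d\n")
        for w in windows:
            fh.write(
                f"{w.interval.scaffold}\t{w.interval.start}\t{w.interval.end}\t"
                f"{w.n_callable_sites}\t{w.S}\t{w.theta_w:.6g}\t{w.pi:.6g}\t"
                f"{w.tajima_d:.6g}\n"
            )


def _write_scores(scores, d_by_window, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("scaffold\tstart\tend\ttheta_pop1\ttheta_pop2\tx\tz\ttajima_d_pop2\n")
        for s in scores:
            d = d_by_window.get(s.interval, math.nan)
            fh.write(
                f"{s.interval.scaffold}\t{s.interval.start}\t{s.interval.end}\t"
                f"{s.theta_pop1:.6g}\t{s.theta_pop2:.6g}\t{s.log_ratio:.6g}\t"
                f"{s.z:.6g}\t{d:.6g}\n"
            )


def _markdown_report(report: dict) -> str:
    lines = ["# palmscan run report", ""]
    for section, content in sorted(report.items()):
        if section == "seed":
            lines.append(f"Seed: {content}")
            lines.append("")
            continue
        lines.append(f"## {section}")
        lines.append("")
        lines.append("```json")
        lines.append(json.dumps(content, sort_keys=True, indent=1))
        lines.append("```")
        lines.append("")
    return "\n".join(lines)
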