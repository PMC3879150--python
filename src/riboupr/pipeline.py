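"""Configured end-to-end runs: simulate -> count -> TE -> splice -> RLS.

A single YAML config is the only parameter entry point. Each run writes TSV
artifacts per stage, a plain-text report mirroring the study's summary
artifacts (regulated-set sizes, overlap tables, splicing fractions, lifespan
screen), and a manifest with the parameter hash, seeds and per-stage record
counts, so that record conservation can be audited from the manifest alone.
Outputs carry no timestamps: the same config and seed give a byte-identical
bundle.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .counting import count_features
from .datasets import HAC1_FOOTPRINT_FOLD, HAC1_SPLICED_PERCENT
from .lifespan import classify_longevity, survival_curve
from .models import CountTable, GeneModel, compute_rpkm
from .splicing import junction_spliced_fraction, spliced_fraction
from .synthetic import (
    LifespanDesign,
    RegulationDesign,
    generate_genome,
    genome_span,
    simulate_alignments,
    simulate_count_tables,
    simulate_lifespan_cohort,
)
from .translation import (
    build_expression_table,
    classify_regulation,
    cluster_te_changes,
    overlap_sets,
    regulated_set,
)

__version__ = "0.1.0"

STUDY_CONDITIONS = ("WT", "WT_TM", "alg12", "bst1")
# lifespan scenario: Table-style mean RLS per strain vs a shared control mean
STUDY_RLS_MEANS = {"WT": 26.4, "alg12": 30.7, "bst1": 33.8}

DEFAULT_THRESHOLDS = {
    "five_prime_trim": 100,
    "min_rpkm": 10.0,
    "log2_threshold": 0.6,
    "alpha": 0.05,
}
DEFAULT_SIMULATE = {
    "n_genes": 150,
    "replicates": 2,
    "depth": 20_000,
    "dispersion": 0.01,
    "cohort_size": 300,
    "read_length": 28,
    "homolog_pairs": 1,
    "length_range": [300, 1500],
}


class ConfigError(ValueError):
    """Raised when a pipeline config fails validation."""


@dataclass
class PipelineConfig:
    seed: int
    outdir: str
    thresholds: dict[str, float] = field(default_factory=dict)
    multimapper_policy: str = "discard"
    library_size_mode: str = "assigned"
    simulate: dict[str, Any] | None = None
    inputs: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        th = dict(DEFAULT_THRESHOLDS)
        th.update(self.thresholds or {})
        self.thresholds = th
        if self.simulate is not None:
            sim = dict(DEFAULT_SIMULATE)
            sim.update(self.simulate)
            self.simulate = sim
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        th = self.thresholds
        if th["five_prime_trim"] < 0:
            raise ConfigError("five_prime_trim must be >= 0")
        if th["min_rpkm"] < 0:
            raise ConfigError("min_rpkm must be >= 0")
        if th["log2_threshold"] < 0:
            raise ConfigError("log2_threshold must be >= 0")
        if not 0 < th["alpha"] < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.multimapper_policy not in ("discard", "keep"):
            raise ConfigError("multimapper_policy must be discard|keep")
        if self.library_size_mode not in ("assigned", "mapped"):
            raise ConfigError("library_size_mode must be assigned|mapped")
        if (self.simulate is None) == (self.inputs is None):
            raise ConfigError("config must declare exactly one of 'simulate' or 'inputs'")
        if self.inputs is not None:
            for key in ("genes",):
                if key in self.inputs and not Path(self.inputs[key]).exists():
                    raise ConfigError(f"input path does not exist: {self.inputs[key]}")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {"seed", "outdir", "thresholds", "multimapper_policy",
                 "library_size_mode", "simulate", "inputs"}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in data or "outdir" not in data:
            raise ConfigError("config must set 'seed' and 'outdir'")
        return cls(**data)

    def param_dict(self) -> dict[str, Any]:
        return {
            "seed": self.seed,
            "thresholds": self.thresholds,
            "multimapper_policy": self.multimapper_policy,
            "library_size_mode": self.library_size_mode,
            "simulate": self.simulate,
            "inputs": self.inputs,
        }

    def param_hash(self) -> str:
        blob = json.dumps(self.param_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _subseeds(seed: int, n: int) -> list[int]:
    """Derive n deterministic sub-seeds below 2^31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n)]


def study_design(
    genome: list[GeneModel],
    replicates: int = 2,
    depth: int = 20_000,
    dispersion: float = 0.01,
    seed: int = 0,
) -> RegulationDesign:
    """Expression design emulating the study's four conditions.

    Conditions: untreated wild type (reference), tunicamycin-treated wild
    type, alg12 and bst1 deletions. The first genome gene is the HAC1-like
    intron gene: abundant, transcriptionally flat, translationally induced
    per condition (TE fold changes mirroring the reported Hac1p induction).
    A slice of the remaining genes receives transcriptional and TE fold
    changes of 3x up/down per condition so every regulated set is non-empty.
    """
    design = RegulationDesign.random(
        genome,
        conditions=STUDY_CONDITIONS,
        reference="WT",
        replicates=replicates,
        depth=depth,
        dispersion=dispersion,
        seed=seed,
    )
    n = len(genome)
    hac1 = 0  # index of the intron gene
    design.baseline_abundance[hac1] = float(np.quantile(design.baseline_abundance, 0.9))
    for cond in STUDY_CONDITIONS[1:]:
        design.te_fold_change[cond][hac1] = HAC1_FOOTPRINT_FOLD[cond]
    # plant generic regulated genes: disjoint blocks after the intron/homolog genes
    block = max(2, n // 30)
    start = 5
    for i, cond in enumerate(STUDY_CONDITIONS[1:]):
        up_t = slice(start + 4 * i * block, start + (4 * i + 1) * block)
        dn_t = slice(start + (4 * i + 1) * block, start + (4 * i + 2) * block)
        up_te = slice(start + (4 * i + 2) * block, start + (4 * i + 3) * block)
        dn_te = slice(start + (4 * i + 3) * block, start + (4 * i + 4) * block)
        design.mrna_fold_change[cond][up_t] = 3.0
        design.mrna_fold_change[cond][dn_t] = 1 / 3.0
        design.te_fold_change[cond][up_te] = 3.0
        design.te_fold_change[cond][dn_te] = 1 / 3.0
    return design


@dataclass
class Manifest:
    version: str
    seed: int
    param_hash: str
    stages: list[dict[str, Any]] = field(default_factory=list)

    def add(self, name: str, **counts: Any) -> None:
        self.stages.append({"stage": name, **counts})

    def to_json(self) -> str:
        return json.dumps(
            {
                "version": self.version,
                "seed": self.seed,
                "param_hash": self.param_hash,
                "stages": self.stages,
            },
            indent=2,
            sort_keys=True,
        )


def run_pipeline(config: PipelineConfig) -> Manifest:
    """Execute the configured stages and write the report bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(version=__version__, seed=config.seed,
                        param_hash=config.param_hash())
    report: list[str] = ["riboupr pipeline report", "=" * 23, ""]
    th = config.thresholds
    trim = int(th["five_prime_trim"])

    try:
        if config.simulate is not None:
            genome, tables, cond_map, splice_tallies, cohort_pairs = _run_simulated(
                config, outdir, manifest
            )
            reference = "WT"
        else:
            genome, tables, cond_map, splice_tallies, cohort_pairs, reference = (
                _load_inputs(config, outdir, manifest)
            )
    except Exception as err:  # annotate the failing stage for the caller
        raise RuntimeError(f"pipeline stage 'prepare' failed: {err}") from err

    # --- te stage ------------------------------------------------------
    stage = "te"
    try:
        fp_rpkm = compute_rpkm(tables["footprint"])
        mrna_rpkm = compute_rpkm(tables["mrna"])
        expr = build_expression_table(
            fp_rpkm, mrna_rpkm, cond_map, reference, min_rpkm=th["min_rpkm"]
        )
        calls = classify_regulation(expr, log2_threshold=th["log2_threshold"])
        _write_expression(expr, calls, outdir)
        manifest.add(stage, genes=int(len(fp_rpkm)), calls=int(len(calls)))
        report.append("Regulated-set sizes (strict |log2 FC| > "
                      f"{th['log2_threshold']}):")
        contrasts = expr.contrast_conditions
        for axis in ("footprint", "mrna", "te"):
            for cond in contrasts:
                up = len(regulated_set(calls, axis, cond, "up"))
                dn = len(regulated_set(calls, axis, cond, "down"))
                report.append(f"  {axis:9s} {cond:8s} up={up:4d} down={dn:4d}")
        report.append("")
        report.append("Overlap of footprint-up sets between conditions:")
        for i, c1 in enumerate(contrasts):
            for c2 in contrasts[i + 1:]:
                a = regulated_set(calls, "footprint", c1, "up")
                b = regulated_set(calls, "footprint", c2, "up")
                na, nb, ni = overlap_sets(a, b)
                report.append(f"  {c1} ({na}) vs {c2} ({nb}): {ni} shared")
        report.append("")
        te_mat = expr.log2fc["te"]
        try:
            clust = cluster_te_changes(te_mat, min_abs_log2=th["log2_threshold"])
            _write_cluster(clust, te_mat, outdir)
            report.append(f"TE-change clustering: {len(clust.gene_ids)} genes clustered")
        except ValueError:
            report.append("TE-change clustering: fewer than 2 regulated genes, skipped")
        report.append("")
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    # --- splice stage --------------------------------------------------
    stage = "splice"
    try:
        if splice_tallies is not None:
            splice_tallies.to_csv(outdir / "splicing.tsv", sep="\t", index=False,
                                  lineterminator="\n")
            manifest.add(stage, samples=int(len(splice_tallies)))
            report.append("HAC1-style spliced fractions (% spliced):")
            for row in splice_tallies.itertuples(index=False):
                report.append(f"  {row.sample:14s} {row.fraction:6.1f}")
            report.append("")
        else:
            manifest.add(stage, samples=0)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    # --- rls stage -----------------------------------------------------
    stage = "rls"
    try:
        if cohort_pairs:
            screen, counts = classify_longevity(cohort_pairs, alpha=th["alpha"])
            screen.to_csv(outdir / "rls_screen.tsv", sep="\t", index=False,
                          lineterminator="\n")
            curves = []
            for mutant, control in cohort_pairs:
                for cohort in (mutant, control):
                    c = survival_curve(cohort)
                    c.insert(0, "strain", cohort.strain)
                    curves.append(c)
            pd.concat(curves, ignore_index=True).drop_duplicates().to_csv(
                outdir / "survival_curves.tsv", sep="\t", index=False,
                lineterminator="\n")
            manifest.add(stage, strains=int(len(screen)),
                         cells=int(sum(len(m) + len(c) for m, c in cohort_pairs)))
            report.append("Replicative-lifespan screen:")
            for row in screen.itertuples(index=False):
                report.append(
                    f"  {row.strain:8s} mean={row.mutant_mean:5.1f} vs "
                    f"{row.control_mean:5.1f}  change={row.pct_change:+6.1f}%  "
                    f"p={row.p_value:.4g}  {row.longevity_class}"
                )
            report.append(
                f"  summary: {counts['long-lived']} long-lived, "
                f"{counts['short-lived']} short-lived, {counts['unchanged']} unchanged"
            )
            report.append("")
        else:
            manifest.add(stage, strains=0)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err

    (outdir / "report.txt").write_text("\n".join(report) + "\n")
    (outdir / "manifest.json").write_text(manifest.to_json() + "\n")
    return manifest


def _run_simulated(config, outdir, manifest):
    sim = config.simulate
    th = config.thresholds
    trim = int(th["five_prime_trim"])
    seeds = _subseeds(config.seed, 64)

    genome = generate_genome(
        n_genes=int(sim["n_genes"]),
        length_range=tuple(sim["length_range"]),
        intron_gene_count=1,
        homolog_pair_count=int(sim["homolog_pairs"]),
        seed=seeds[0],
    )
    rio.write_gff3(genome, outdir / "genes.gff3")
    design = study_design(
        genome,
        replicates=int(sim["replicates"]),
        depth=int(sim["depth"]),
        dispersion=float(sim["dispersion"]),
        seed=seeds[1],
    )
    simulated = simulate_count_tables(genome, design, five_prime_trim=trim)
    simulated.truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False,
                           lineterminator="\n")
    manifest.add("simulate", genes=len(genome),
                 samples=len(simulated.condition_map),
                 footprint_reads=int(simulated.footprints.counts.to_numpy().sum()),
                 mrna_reads=int(simulated.mrna.counts.to_numpy().sum()))

    hac1 = genome[0]
    spliced_by_cond = {
        "WT": HAC1_SPLICED_PERCENT["WT"] / 100.0,
        "WT_TM": HAC1_SPLICED_PERCENT["WT_TM"] / 100.0,
        "alg12": HAC1_SPLICED_PERCENT["alg12"] / 100.0,
        "bst1": HAC1_SPLICED_PERCENT["bst1"] / 100.0,
    }

    # alignments + counting per axis and sample
    tables: dict[str, CountTable] = {}
    splice_rows = []
    k = 2
    total_records = 0
    counted = {}
    for axis, table in (("footprint", simulated.footprints), ("mrna", simulated.mrna)):
        aligned = {}
        for sample in table.sample_ids:
            cond = simulated.condition_map[sample]
            records = simulate_alignments(
                genome,
                table,
                sample=sample,
                read_length=int(sim["read_length"]),
                intron_spliced_fraction={hac1.gene_id: spliced_by_cond[cond]},
                five_prime_trim=trim,
                seed=seeds[k],
            )
            k += 1
            aligned[sample] = records
            total_records += len(records)
            if axis == "mrna":
                near = [r for r in records
                        if r.chrom == hac1.chrom and r.start <= hac1.end
                        and r.end >= hac1.start]
                tally = junction_spliced_fraction(near, hac1)
                splice_rows.append(
                    {"sample": sample, "spliced": tally.spliced,
                     "unspliced": tally.unspliced,
                     "uninformative": tally.uninformative,
                     "fraction": round(tally.fraction, 1)}
                )
        rio.write_sam(aligned[table.sample_ids[0]],
                      outdir / f"{axis}_{table.sample_ids[0]}.sam",
                      {genome[0].chrom: genome_span(genome)})
        result = count_features(
            aligned, genome, five_prime_trim=trim,
            multimapper_policy=config.multimapper_policy,
            library_size_mode=config.library_size_mode,
        )
        result.check_conservation()
        tables[axis] = result.table
        rio.write_count_table(result.table, outdir / f"{axis}_counts.tsv")
        result.unassigned.to_csv(outdir / f"{axis}_unassigned.tsv", sep="\t",
                                 lineterminator="\n")
        counted[axis] = int(result.table.counts.to_numpy().sum())
    manifest.add("count", records=total_records,
                 footprint_assigned=counted["footprint"],
                 mrna_assigned=counted["mrna"])

    splice_frame = pd.DataFrame(splice_rows)

    # lifespan cohorts
    n_cells = int(sim["cohort_size"])
    pairs = []
    for j, strain in enumerate(s for s in STUDY_RLS_MEANS if s != "WT"):
        mut = simulate_lifespan_cohort(LifespanDesign(
            strain=strain, cohort_size=n_cells, mean_rls=STUDY_RLS_MEANS[strain],
            seed=seeds[40 + 2 * j], control="WT"))
        ctrl = simulate_lifespan_cohort(LifespanDesign(
            strain="WT", cohort_size=n_cells, mean_rls=STUDY_RLS_MEANS["WT"],
            seed=seeds[41 + 2 * j]))
        pairs.append((mut, ctrl))
    rio.write_lifespan_tsv([c for p in pairs for c in p], outdir / "cohorts.tsv")

    return genome, tables, simulated.condition_map, splice_frame, pairs


def _load_inputs(config, outdir, manifest):
    inputs = config.inputs
    th = config.thresholds
    trim = int(th["five_prime_trim"])
    genome = None
    if "genes" in inputs:
        path = str(inputs["genes"])
        genome = rio.read_bed12(path) if path.endswith(".bed") else rio.read_gff3(path)

    tables = {}
    total = 0
    for axis in ("footprint", "mrna"):
        counts_key, aln_key = f"{axis}_counts", f"{axis}_alignments"
        if counts_key in inputs:
            tables[axis] = rio.read_count_table(inputs[counts_key])
        elif aln_key in inputs:
            if genome is None:
                raise ConfigError("alignment counting requires a 'genes' input")
            aligned = {}
            for sample, path in inputs[aln_key].items():
                path = str(path)
                recs = rio.read_sam(path) if path.endswith(".sam") else rio.read_alignment_tsv(path)
                aligned[sample] = recs
                total += len(recs)
            result = count_features(
                aligned, genome, five_prime_trim=trim,
                multimapper_policy=config.multimapper_policy,
                library_size_mode=config.library_size_mode,
            )
            tables[axis] = result.table
            rio.write_count_table(result.table, outdir / f"{axis}_counts.tsv")
            result.unassigned.to_csv(outdir / f"{axis}_unassigned.tsv", sep="\t",
                                     lineterminator="\n")
        else:
            raise ConfigError(f"inputs must provide {counts_key} or {aln_key}")
    manifest.add("count", records=total)

    cond_map = dict(inputs["condition_map"])
    reference = inputs.get("reference", "WT")

    splice_frame = None
    if "splicing_table" in inputs:
        df = rio.read_splicing_tsv(inputs["splicing_table"])
        splice_frame = pd.DataFrame(
            {
                "sample": df["sample"],
                "spliced": df["spliced_signal"],
                "unspliced": df["unspliced_signal"],
                "uninformative": 0,
                "fraction": [
                    round(spliced_fraction(s, u), 1)
                    for s, u in zip(df["spliced_signal"], df["unspliced_signal"])
                ],
            }
        )

    pairs = []
    if "cohorts" in inputs:
        cohorts = rio.read_lifespan_tsv(inputs["cohorts"])
        by_strain = {c.strain: c for c in cohorts}
        for c in cohorts:
            if c.control:
                if c.control not in by_strain:
                    raise ConfigError(f"missing control cohort {c.control!r}")
                pairs.append((c, by_strain[c.control]))

    return genome, tables, cond_map, splice_frame, pairs, reference


def _write_expression(expr, calls, outdir: Path) -> None:
    parts = []
    fp = expr.fp_mean.add_prefix("fp_mean_")
    mr = expr.mrna_mean.add_prefix("mrna_mean_")
    te = expr.te.add_prefix("te_")
    parts = pd.concat([fp, mr, te], axis=1)
    for axis in ("footprint", "mrna", "te"):
        parts = pd.concat(
            [parts, expr.log2fc[axis].add_prefix(f"log2fc_{axis}_")], axis=1
        )
    parts.index.name = "gene_id"
    parts.to_csv(outdir / "expression.tsv", sep="\t", lineterminator="\n")
    calls.to_csv(outdir / "regulation_calls.tsv", sep="\t", index=False,
                 lineterminator="\n")


def _write_cluster(clust, te_mat: pd.DataFrame, outdir: Path) -> None:
    # CDT-style layout: rows in leaf order
    ordered = te_mat.loc[clust.leaf_order]
    ordered.index.name = "gene_id"
    ordered.to_csv(outdir / "te_clustered.cdt", sep="\t", lineterminator="\n")
    with open(outdir / "te_merge_tree.txt", "w") as fh:
        fh.write("node\tleft\tright\tdistance\tsize\n")
        n = len(clust.gene_ids)
        for i, (a, b, d, size) in enumerate(clust.linkage):
            left = clust.gene_ids[int(a)] if a < n else f"node{int(a) - n}"
            right = clust.gene_ids[int(b)] if b < n else f"node{int(b) - n}"
            fh.write(f"node{i}\t{left}\t{right}\t{d:.6f}\t{int(size)}\n")
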