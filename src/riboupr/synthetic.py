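"""Synthetic genomes, count tables, alignments and lifespan cohorts.

The study's raw sequencing reads were never deposited, so every stage of the
pipeline is exercised against generated data with known ground truth. The
generative model mirrors the quantities the pipeline estimates:

* mRNA counts are negative-binomial around a depth-scaled latent abundance
  times a per-condition transcriptional fold change;
* footprint counts share the *same* latent transcriptional component and add
  a translation-efficiency (TE) factor times a per-condition TE fold change —
  so TE is the only translational degree of freedom, matching the
  footprint-rpkm / mRNA-rpkm definition of TE;
* replicates are independent draws;
* replicative-lifespan cohorts are discretised gamma division counts matched
  to a target mean and shape.

Ground truth (expected rpkm, true fold changes) is always returned next to
the data so downstream checks never have to re-infer the design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import AlignmentRecord, CountTable, GeneModel, effective_length
from .lifespan import LifespanCohort

DEFAULT_DISPERSION = 0.01  # NB dispersion; replicate correlations are near 1 in this assay
DEFAULT_DEPTH = 5_000_000
DEFAULT_READ_LENGTH = 28


# ---------------------------------------------------------------------------
# genome generation


def generate_genome(
    n_genes: int,
    length_range: tuple[int, int] = (300, 1800),
    intron_gene_count: int = 0,
    homolog_pair_count: int = 0,
    seed: int = 0,
    chrom: str = "chrS",
    intergenic_range: tuple[int, int] = (100, 400),
    intron_length_range: tuple[int, int] = (60, 252),
    chrom_length: int | None = None,
) -> list[GeneModel]:
    """Lay out non-overlapping genes on both strands of one synthetic chromosome.

    Lengths are spliced-CDS lengths, drawn as multiples of 3 within
    ``length_range``. The first ``intron_gene_count`` genes carry one intron
    interior to the CDS (placed past the 5' third so junction reads clear the
    5' trim zone); the first ``homolog_pair_count`` pairs after those share a
    homology-group tag so simulated reads from them can be multi-mappers.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    lo, hi = length_range
    if lo < 3:
        raise ValueError("gene lengths must be >= 3 nt")
    if intron_gene_count < 0 or homolog_pair_count < 0:
        raise ValueError("counts must be non-negative")
    if intron_gene_count + 2 * homolog_pair_count > n_genes:
        raise ValueError("intron and homolog designations exceed gene count")

    rng = np.random.default_rng(seed)
    codons_lo, codons_hi = lo // 3 + (lo % 3 > 0), hi // 3
    if codons_hi < codons_lo:
        raise ValueError(f"no multiple of 3 in length range {length_range}")

    genes: list[GeneModel] = []
    cursor = 1 + int(rng.integers(intergenic_range[0], intergenic_range[1] + 1))
    # leave room upstream so minus-strand reads never run off the left edge
    cursor += 100
    for i in range(n_genes):
        spliced_len = 3 * int(rng.integers(codons_lo, codons_hi + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        introns: tuple[tuple[int, int], ...] = ()
        span = spliced_len
        if i < intron_gene_count:
            ilen = int(rng.integers(intron_length_range[0], intron_length_range[1] + 1))
            # breakpoint in spliced coordinates, interior and past the 5' third
            frac = 0.35 + 0.4 * rng.random()
            brk = max(2, min(spliced_len - 1, int(spliced_len * frac)))
            if strand == "+":
                istart = cursor + brk
            else:
                istart = cursor + (spliced_len - brk)
            introns = ((istart, istart + ilen - 1),)
            span = spliced_len + ilen
        start, end = cursor, cursor + span - 1
        genes.append(
            GeneModel(
                gene_id=f"g{i:05d}",
                chrom=chrom,
                strand=strand,
                start=start,
                end=end,
                introns=introns,
            )
        )
        cursor = end + 1 + int(rng.integers(intergenic_range[0], intergenic_range[1] + 1))

    if chrom_length is not None and cursor + 100 > chrom_length:
        raise ValueError(
            f"cannot pack {n_genes} genes into chromosome of length {chrom_length}"
        )

    offset = intron_gene_count
    for p in range(homolog_pair_count):
        tag = f"hg{p:03d}"
        genes[offset + 2 * p].homology_group = tag
        genes[offset + 2 * p + 1].homology_group = tag
    return genes


def genome_span(genes: Sequence[GeneModel]) -> int:
    """Chromosome length needed to contain the genes plus a margin."""
    return max(g.end for g in genes) + 200


# ---------------------------------------------------------------------------
# expression design


@dataclass
class RegulationDesign:
    """Ground-truth expression design for paired footprint/mRNA simulation.

    Fold changes are per condition relative to the reference; the reference
    condition implicitly has fold change 1 on both axes. ``dispersion`` is the
    negative-binomial dispersion (variance = mu + dispersion * mu^2) shared by
    all genes and samples; ``depth`` is the expected per-sample library size.
    """

    gene_ids: tuple[str, ...]
    conditions: tuple[str, ...]
    reference: str
    replicates: int
    baseline_abundance: np.ndarray
    baseline_te: np.ndarray
    mrna_fold_change: dict[str, np.ndarray] = field(default_factory=dict)
    te_fold_change: dict[str, np.ndarray] = field(default_factory=dict)
    dispersion: float = DEFAULT_DISPERSION
    depth: int = DEFAULT_DEPTH
    seed: int = 0

    def __post_init__(self) -> None:
        self.gene_ids = tuple(self.gene_ids)
        self.conditions = tuple(self.conditions)
        n = len(self.gene_ids)
        self.baseline_abundance = np.asarray(self.baseline_abundance, dtype=float)
        self.baseline_te = np.asarray(self.baseline_te, dtype=float)
        if self.reference not in self.conditions:
            raise ValueError(f"reference {self.reference!r} not in conditions")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        for name, arr in (("abundance", self.baseline_abundance), ("TE", self.baseline_te)):
            if arr.shape != (n,):
                raise ValueError(f"baseline {name} must have one value per gene")
            if (arr <= 0).any():
                raise ValueError(f"baseline {name} must be strictly positive")
        for label, fcs in (("mRNA", self.mrna_fold_change), ("TE", self.te_fold_change)):
            for cond, arr in fcs.items():
                if cond not in self.conditions:
                    raise ValueError(f"{label} fold change for unknown condition {cond!r}")
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (n,) or (arr <= 0).any():
                    raise ValueError(
                        f"{label} fold changes for {cond!r} must be positive, one per gene"
                    )
                fcs[cond] = arr

    @classmethod
    def random(
        cls,
        genome: Sequence[GeneModel],
        conditions: Sequence[str] = ("WT", "mutant"),
        reference: str = "WT",
        replicates: int = 2,
        depth: int = DEFAULT_DEPTH,
        dispersion: float = DEFAULT_DISPERSION,
        abundance_sigma: float = 1.0,
        te_sigma: float = 0.25,
        seed: int = 0,
    ) -> "RegulationDesign":
        """Lognormal baselines, all fold changes 1; edit the fold-change
        arrays afterwards to plant regulated genes."""
        rng = np.random.default_rng(seed)
        n = len(genome)
        return cls(
            gene_ids=tuple(g.gene_id for g in genome),
            conditions=tuple(conditions),
            reference=reference,
            replicates=replicates,
            baseline_abundance=rng.lognormal(mean=3.0, sigma=abundance_sigma, size=n),
            baseline_te=rng.lognormal(mean=0.0, sigma=te_sigma, size=n),
            mrna_fold_change={c: np.ones(n) for c in conditions if c != reference},
            te_fold_change={c: np.ones(n) for c in conditions if c != reference},
            dispersion=dispersion,
            depth=depth,
            seed=seed,
        )

    def fold_changes(self, condition: str, axis: str) -> np.ndarray:
        table = self.mrna_fold_change if axis == "mrna" else self.te_fold_change
        if condition == self.reference or condition not in table:
            return np.ones(len(self.gene_ids))
        return table[condition]

    def sample_ids(self) -> list[str]:
        return [f"{c}_rep{r}" for c in self.conditions for r in range(1, self.replicates + 1)]


@dataclass
class SimulatedCounts:
    """Paired count tables with the generative truth used to produce them."""

    footprints: CountTable
    mrna: CountTable
    truth: pd.DataFrame
    condition_map: dict[str, str]


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, dispersion: float) -> np.ndarray:
    size = 1.0 / dispersion
    p = size / (size + mu)
    return rng.negative_binomial(size, p)


def expected_rpkm(design: RegulationDesign, lengths: np.ndarray, axis: str) -> pd.DataFrame:
    """Analytic expected rpkm per gene and condition (depth cancels)."""
    out = {}
    a = design.baseline_abundance
    for cond in design.conditions:
        w = a * design.fold_changes(cond, "mrna")
        if axis == "footprint":
            w = w * design.baseline_te * design.fold_changes(cond, "te")
        total = float((w * lengths).sum())
        out[cond] = 1e9 * w / total
    return pd.DataFrame(out, index=list(design.gene_ids))


def simulate_count_tables(
    genome: Sequence[GeneModel],
    design: RegulationDesign,
    five_prime_trim: int = 100,
) -> SimulatedCounts:
    """Draw paired footprint/mRNA count tables under the design.

    Expected count of gene g in a sample of condition c is
    depth * w_g / sum(w * L) * L_g with w = abundance * mRNA-FC (mRNA axis)
    or w = abundance * mRNA-FC * TE * TE-FC (footprint axis); counts are NB
    draws around that mean with the shared dispersion.
    """
    gene_order = [g.gene_id for g in genome]
    if list(design.gene_ids) != gene_order:
        raise ValueError("design gene ids must match the genome, in order")
    lengths = np.array(
        [effective_length(g, five_prime_trim)[0] for g in genome], dtype=float
    )
    rng = np.random.default_rng(design.seed)
    frames: dict[str, dict[str, np.ndarray]] = {"footprint": {}, "mrna": {}}
    condition_map: dict[str, str] = {}
    for cond in design.conditions:
        w_m = design.baseline_abundance * design.fold_changes(cond, "mrna")
        w_f = w_m * design.baseline_te * design.fold_changes(cond, "te")
        mu_m = design.depth * (w_m * lengths) / float((w_m * lengths).sum())
        mu_f = design.depth * (w_f * lengths) / float((w_f * lengths).sum())
        for rep in range(1, design.replicates + 1):
            sample = f"{cond}_rep{rep}"
            condition_map[sample] = cond
            frames["footprint"][sample] = _nb_draw(rng, mu_f, design.dispersion)
            frames["mrna"][sample] = _nb_draw(rng, mu_m, design.dispersion)

    tables = {}
    eff = pd.Series(lengths.astype(int), index=gene_order)
    flags = pd.Series(
        [effective_length(g, five_prime_trim)[1] for g in genome], index=gene_order
    )
    for axis in ("footprint", "mrna"):
        cf = pd.DataFrame(frames[axis], index=gene_order, dtype="int64")
        tables[axis] = CountTable(
            counts=cf,
            effective_lengths=eff,
            library_sizes=cf.sum(axis=0),
            short_gene=flags,
        )

    exp_m = expected_rpkm(design, lengths, "mrna")
    exp_f = expected_rpkm(design, lengths, "footprint")
    truth_rows = []
    for cond in design.conditions:
        truth_rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene_order,
                    "condition": cond,
                    "expected_mrna_rpkm": exp_m[cond].to_numpy(),
                    "expected_footprint_rpkm": exp_f[cond].to_numpy(),
                    "true_mrna_fc": design.fold_changes(cond, "mrna"),
                    "true_te_fc": design.fold_changes(cond, "te"),
                }
            )
        )
    truth = pd.concat(truth_rows, ignore_index=True)
    return SimulatedCounts(
        footprints=tables["footprint"],
        mrna=tables["mrna"],
        truth=truth,
        condition_map=condition_map,
    )


# ---------------------------------------------------------------------------
# alignment simulation


def simulate_alignments(
    genome: Sequence[GeneModel],
    counts: CountTable,
    sample: str | None = None,
    read_length: int = DEFAULT_READ_LENGTH,
    first100_fraction: float = 0.0,
    multimap_fraction: float = 0.0,
    intron_spliced_fraction: float | Mapping[str, float] = 1.0,
    five_prime_trim: int = 100,
    seed: int = 0,
) -> list[AlignmentRecord]:
    """Emit one AlignmentRecord per counted read for one sample.

    Reads are placed by their 5' end, uniform over the trimmed spliced CDS;
    ``first100_fraction`` of reads instead land in the 5' trim zone and
    ``multimap_fraction`` are flagged with 2 genomic hits (reads from
    homology-group genes always are). For intron genes each read derives from
    the spliced transcript with probability ``intron_spliced_fraction``
    (junction-spanning, split alignment) and otherwise from the unspliced
    precursor (contiguous, 5' end inside the intron).
    """
    if not 0.0 <= first100_fraction <= 1.0 or not 0.0 <= multimap_fraction <= 1.0:
        raise ValueError("fractions must lie in [0, 1]")
    shortest = min(g.spliced_length for g in genome)
    if read_length > shortest:
        raise ValueError(
            f"read_length {read_length} exceeds shortest spliced CDS ({shortest} nt)"
        )
    if sample is None:
        sample = counts.sample_ids[0]
    col = counts.counts[sample]
    rng = np.random.default_rng(seed)
    records: list[AlignmentRecord] = []
    serial = 0
    for gene in genome:
        n = int(col.get(gene.gene_id, 0))
        if n == 0:
            continue
        L = gene.spliced_length
        if L <= five_prime_trim + 1:
            raise ValueError(
                f"gene {gene.gene_id} spliced CDS ({L} nt) does not clear the "
                f"{five_prime_trim} nt 5' trim zone"
            )
        if isinstance(intron_spliced_fraction, Mapping):
            spl_frac = float(intron_spliced_fraction.get(gene.gene_id, 1.0))
        else:
            spl_frac = float(intron_spliced_fraction)
        junction_offset = None
        if gene.introns:
            if len(gene.introns) != 1:
                raise ValueError("alignment simulation supports at most one intron per gene")
            istart, iend = gene.introns[0]
            # spliced offset of the last 5'-exon base
            boundary = istart - 1 if gene.strand == "+" else iend + 1
            junction_offset = gene.spliced_offset(boundary)

        for _ in range(n):
            serial += 1
            rid = f"r{serial:08d}_{gene.gene_id}"
            hits = 2 if (gene.homology_group or rng.random() < multimap_fraction) else 1
            from_spliced = True
            if gene.introns and rng.random() >= spl_frac:
                from_spliced = False
            if not from_spliced:
                # unspliced precursor: contiguous genomic read, 5' end in the intron
                istart, iend = gene.introns[0]
                gpos = int(rng.integers(istart, iend + 1))
                start = gpos if gene.strand == "+" else max(1, gpos - read_length + 1)
                records.append(
                    AlignmentRecord(rid, gene.chrom, gene.strand, start, read_length, hits)
                )
                continue
            if gene.introns and junction_offset is not None:
                # junction-spanning: 5' offset drawn so the read crosses the splice site
                lo = max(1, junction_offset - read_length + 2)
                hi = junction_offset
                offset = int(rng.integers(lo, hi + 1))
            elif rng.random() < first100_fraction:
                offset = int(rng.integers(1, min(five_prime_trim, L) + 1))
            else:
                offset = int(rng.integers(five_prime_trim + 1, L + 1))
            records.append(
                _spliced_read(gene, offset, read_length, rid, hits)
            )
    return records


def _spliced_read(
    gene: GeneModel, offset: int, read_length: int, read_id: str, n_hits: int
) -> AlignmentRecord:
    """Build a (possibly split) genomic record for a transcript-coordinate read."""
    last = min(offset + read_length - 1, gene.spliced_length)  # clip at the 3' end
    positions = sorted(gene.genomic_position(o) for o in range(offset, last + 1))
    blocks: list[tuple[int, int]] = []
    run_start = prev = positions[0]
    for p in positions[1:]:
        if p == prev + 1:
            prev = p
            continue
        blocks.append((run_start, prev - run_start + 1))
        run_start = prev = p
    blocks.append((run_start, prev - run_start + 1))
    total = sum(l for _, l in blocks)
    return AlignmentRecord(
        read_id=read_id,
        chrom=gene.chrom,
        strand=gene.strand,
        start=blocks[0][0],
        length=total,
        n_hits=n_hits,
        blocks=tuple(blocks) if len(blocks) > 1 else None,
    )


# ---------------------------------------------------------------------------
# lifespan cohorts


@dataclass
class LifespanDesign:
    """Design for one simulated replicative-lifespan cohort.

    ``mean_rls`` is the target mean division count; ``shape`` the gamma shape
    (mean/sd ratio squared; 7 reproduces the ~26 +/- 10 division spread typical
    of wild-type BY4741 cohorts).
    """

    strain: str
    cohort_size: int
    mean_rls: float
    shape: float = 7.0
    seed: int = 0
    control: str | None = None

    def __post_init__(self) -> None:
        if self.cohort_size < 1:
            raise ValueError("cohort size must be >= 1")
        if self.mean_rls <= 0:
            raise ValueError("mean RLS must be positive")
        if self.shape <= 0:
            raise ValueError("shape must be positive")


def simulate_lifespan_cohort(design: LifespanDesign) -> LifespanCohort:
    """Draw division counts from a discretised gamma with the design mean."""
    rng = np.random.default_rng(design.seed)
    draws = rng.gamma(design.shape, design.mean_rls / design.shape, size=design.cohort_size)
    divisions = np.maximum(np.rint(draws), 0).astype(int)
    return LifespanCohort(
        strain=design.strain,
        divisions=tuple(int(d) for d in divisions),
        control=design.control,
    )
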