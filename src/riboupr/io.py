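"""Readers and writers for the standard formats the pipeline touches.

Gene models: GFF3 (canonical) and BED12. Alignments: SAM (split alignments
expressed with N-skips in the CIGAR, hit counts in the NH tag) or a simple
tab-delimited table (read_id, chrom, strand, start, length, n_hits[, cigar]);
the optional cigar column appears only when split reads are present, since
six columns cannot encode a junction-spanning alignment. Count tables,
cohorts and splicing tables are plain TSV via pandas.

Internal coordinates are 1-based inclusive; BED (0-based half-open) and pysam
(0-based) are converted at this boundary.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd
import pysam

from .lifespan import LifespanCohort
from .models import AlignmentRecord, CountTable, GeneModel

# ---------------------------------------------------------------------------
# gene models


def write_gff3(genes: Sequence[GeneModel], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.homology_group:
                attrs += f";homology_group={g.homology_group}"
            fh.write(
                f"{g.chrom}\triboupr\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for s, e in g.exon_intervals():
                fh.write(
                    f"{g.chrom}\triboupr\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\tParent={g.gene_id}\n"
                )


def read_gff3(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from GFF3: one ``gene`` feature per gene with child
    ``CDS`` parts; introns are the gaps between CDS parts."""
    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    genes = []
    for feat in db.features_of_type("gene"):
        cds = sorted(db.children(feat, featuretype="CDS"), key=lambda f: f.start)
        if cds:
            parts = [(c.start, c.end) for c in cds]
        else:
            parts = [(feat.start, feat.end)]
        introns = tuple(
            (parts[i][1] + 1, parts[i + 1][0] - 1) for i in range(len(parts) - 1)
        )
        hg = feat.attributes.get("homology_group", [None])[0]
        genes.append(
            GeneModel(
                gene_id=feat.id,
                chrom=feat.seqid,
                strand=feat.strand,
                start=parts[0][0],
                end=parts[-1][1],
                introns=introns,
                homology_group=hg,
            )
        )
    return genes


def read_bed12(path: str | os.PathLike) -> list[GeneModel]:
    """Read gene models from BED12; blocks become the spliced CDS parts."""
    cols = [
        "chrom", "chromStart", "chromEnd", "name", "score", "strand",
        "thickStart", "thickEnd", "itemRgb", "blockCount", "blockSizes",
        "blockStarts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    genes = []
    for row in df.itertuples(index=False):
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        starts = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        # BED is 0-based half-open; convert to 1-based inclusive
        parts = [
            (row.chromStart + s + 1, row.chromStart + s + sz)
            for s, sz in zip(starts, sizes)
        ]
        introns = tuple(
            (parts[i][1] + 1, parts[i + 1][0] - 1) for i in range(len(parts) - 1)
        )
        genes.append(
            GeneModel(
                gene_id=str(row.name),
                chrom=str(row.chrom),
                strand=str(row.strand),
                start=parts[0][0],
                end=parts[-1][1],
                introns=introns,
            )
        )
    return genes


# ---------------------------------------------------------------------------
# alignments

ALIGNMENT_COLUMNS = ("read_id", "chrom", "strand", "start", "length", "n_hits")


def _cigar_string(rec: AlignmentRecord) -> str:
    blocks = rec.block_list()
    parts = []
    for i, (s, l) in enumerate(blocks):
        parts.append(f"{l}M")
        if i + 1 < len(blocks):
            gap = blocks[i + 1][0] - (s + l)
            parts.append(f"{gap}N")
    return "".join(parts)


def write_alignment_tsv(records: Iterable[AlignmentRecord], path: str | os.PathLike) -> None:
    records = list(records)
    spliced = any(r.blocks is not None for r in records)
    cols = list(ALIGNMENT_COLUMNS) + (["cigar"] if spliced else [])
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in records:
            row = [r.read_id, r.chrom, r.strand, str(r.start), str(r.length), str(r.n_hits)]
            if spliced:
                row.append(_cigar_string(r))
            fh.write("\t".join(row) + "\n")


def _blocks_from_cigar(start: int, cigar: str) -> tuple[tuple[int, int], ...] | None:
    blocks: list[tuple[int, int]] = []
    pos, num = start, ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        n = int(num)
        num = ""
        if ch == "M":
            blocks.append((pos, n))
            pos += n
        elif ch in "ND":
            pos += n
        else:
            raise ValueError(f"unsupported CIGAR op {ch!r}")
    return tuple(blocks) if len(blocks) > 1 else None


def read_alignment_tsv(path: str | os.PathLike) -> list[AlignmentRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"alignment table missing columns: {missing}")
    records = []
    has_cigar = "cigar" in df.columns
    for row in df.itertuples(index=False):
        blocks = None
        if has_cigar and isinstance(row.cigar, str) and "N" in row.cigar:
            blocks = _blocks_from_cigar(int(row.start), row.cigar)
        records.append(
            AlignmentRecord(
                read_id=str(row.read_id),
                chrom=str(row.chrom),
                strand=str(row.strand),
                start=int(row.start),
                length=int(row.length),
                n_hits=int(row.n_hits),
                blocks=blocks,
            )
        )
    return records


def write_sam(
    records: Iterable[AlignmentRecord],
    path: str | os.PathLike,
    chrom_lengths: Mapping[str, int],
) -> None:
    """Write minimal SAM: mandatory columns plus the NH hit-count tag."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for chrom, length in chrom_lengths.items():
            fh.write(f"@SQ\tSN:{chrom}\tLN:{length}\n")
        for r in records:
            flag = 16 if r.strand == "-" else 0
            fh.write(
                f"{r.read_id}\t{flag}\t{r.chrom}\t{r.start}\t255\t{_cigar_string(r)}"
                f"\t*\t0\t0\t*\t*\tNH:i:{r.n_hits}\n"
            )


def read_sam(path: str | os.PathLike) -> list[AlignmentRecord]:
    records = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            blocks_0 = aln.get_blocks()  # 0-based half-open
            blocks = tuple((s + 1, e - s) for s, e in blocks_0)
            n_hits = aln.get_tag("NH") if aln.has_tag("NH") else 1
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    chrom=aln.reference_name,
                    strand="-" if aln.is_reverse else "+",
                    start=blocks[0][0],
                    length=sum(l for _, l in blocks),
                    n_hits=int(n_hits),
                    blocks=blocks if len(blocks) > 1 else None,
                )
            )
    return records


# ---------------------------------------------------------------------------
# tables


def write_count_table(table: CountTable, path: str | os.PathLike) -> None:
    out = table.counts.copy()
    out.insert(0, "effective_length", table.effective_lengths)
    out.index.name = "gene_id"
    with open(path, "w") as fh:
        fh.write("# library_sizes\t" + "\t".join(
            f"{s}={int(table.library_sizes[s])}" for s in table.sample_ids) + "\n")
        out.to_csv(fh, sep="\t", lineterminator="\n")


def read_count_table(path: str | os.PathLike) -> CountTable:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("# library_sizes"):
            raise ValueError("count table missing library-size header line")
        lib = {}
        for item in header.strip().split("\t")[1:]:
            k, v = item.split("=")
            lib[k] = int(v)
        df = pd.read_csv(fh, sep="\t", index_col="gene_id")
    lengths = df.pop("effective_length")
    return CountTable(
        counts=df,
        effective_lengths=lengths,
        library_sizes=pd.Series(lib).reindex(df.columns),
    )


def write_lifespan_tsv(cohorts: Sequence[LifespanCohort], path: str | os.PathLike) -> None:
    rows = []
    for c in cohorts:
        for i, d in enumerate(c.divisions):
            rows.append(
                (c.strain, f"{c.strain}_{i:05d}", d, c.control or "", c.mating_type or "")
            )
    pd.DataFrame(
        rows, columns=["strain", "cell_id", "divisions", "control_label", "mating_type"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_lifespan_tsv(path: str | os.PathLike) -> list[LifespanCohort]:
    df = pd.read_csv(path, sep="\t", dtype={"strain": str}, keep_default_na=False)
    cohorts = []
    for (strain, control, mt), grp in df.groupby(
        ["strain", "control_label", "mating_type"], sort=False
    ):
        cohorts.append(
            LifespanCohort(
                strain=strain,
                divisions=tuple(int(d) for d in grp["divisions"]),
                control=control or None,
                mating_type=mt or None,
            )
        )
    return cohorts


def read_splicing_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """TSV of (sample, spliced_signal, unspliced_signal)."""
    df = pd.read_csv(path, sep="\t")
    needed = {"sample", "spliced_signal", "unspliced_signal"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"splicing table missing columns: {sorted(missing)}")
    return df
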