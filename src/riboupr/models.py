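"""Core domain types: gene models, alignment records, count tables.

Coordinates are 1-based inclusive throughout (GFF3 convention). Conversion
from 0-based half-open systems (BED, pysam) happens at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

STRANDS = ("+", "-")


@dataclass
class GeneModel:
    """A gene's CDS on the genome, with optional introns.

    ``start``/``end`` delimit the genomic CDS *span* (introns included).
    ``introns`` are 1-based inclusive intervals strictly inside the span and
    pairwise disjoint; the spliced CDS is the span minus the introns.
    ``homology_group`` tags genes whose sequence is shared with another gene,
    so that simulated reads from them can be emitted as multi-mappers.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    introns: tuple[tuple[int, int], ...] = ()
    homology_group: str | None = None

    def __post_init__(self) -> None:
        self.introns = tuple(tuple(iv) for iv in self.introns)
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid CDS span [{self.start}, {self.end}]")
        prev_end = None
        for s, e in sorted(self.introns):
            if not (self.start < s <= e < self.end):
                raise ValueError(
                    f"intron [{s}, {e}] not strictly inside CDS span "
                    f"[{self.start}, {self.end}] of {self.gene_id}"
                )
            if prev_end is not None and s <= prev_end + 1:
                raise ValueError(f"introns of {self.gene_id} overlap or touch")
            prev_end = e
        if self.spliced_length < 1:
            raise ValueError(f"spliced CDS of {self.gene_id} shorter than 1 nt")

    @property
    def span_length(self) -> int:
        return self.end - self.start + 1

    @property
    def intron_length(self) -> int:
        return sum(e - s + 1 for s, e in self.introns)

    @property
    def spliced_length(self) -> int:
        return self.span_length - self.intron_length

    def exon_intervals(self) -> list[tuple[int, int]]:
        """Genomic intervals of the spliced CDS, left to right."""
        exons = []
        pos = self.start
        for s, e in sorted(self.introns):
            if pos <= s - 1:
                exons.append((pos, s - 1))
            pos = e + 1
        if pos <= self.end:
            exons.append((pos, self.end))
        return exons

    @cached_property
    def _exonic_positions(self) -> np.ndarray:
        parts = [np.arange(s, e + 1) for s, e in self.exon_intervals()]
        return np.concatenate(parts)

    def in_intron(self, pos: int) -> bool:
        return any(s <= pos <= e for s, e in self.introns)

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    def spliced_offset(self, pos: int) -> int | None:
        """1-based offset of a genomic position within the spliced CDS,
        counted from the biological 5' end; ``None`` if the position falls
        in an intron or outside the span."""
        if not self.contains(pos) or self.in_intron(pos):
            return None
        exonic = self._exonic_positions
        idx = int(np.searchsorted(exonic, pos))
        if self.strand == "+":
            return idx + 1
        return len(exonic) - idx

    def genomic_position(self, offset: int) -> int:
        """Genomic position of a 1-based spliced-CDS offset (5'-anchored)."""
        if not (1 <= offset <= self.spliced_length):
            raise ValueError(f"offset {offset} outside spliced CDS of {self.gene_id}")
        exonic = self._exonic_positions
        if self.strand == "+":
            return int(exonic[offset - 1])
        return int(exonic[len(exonic) - offset])


@dataclass
class AlignmentRecord:
    """One mapped read.

    ``start`` is the leftmost mapped genomic position; ``blocks`` lists
    (start, length) pairs for split (junction-spanning) alignments and is
    ``None`` for the common contiguous case. ``length`` is the total aligned
    length (sum of block lengths).
    """

    read_id: str
    chrom: str
    strand: str
    start: int
    length: int
    n_hits: int = 1
    blocks: tuple[tuple[int, int], ...] | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}")
        if self.start < 1:
            raise ValueError("position must be >= 1")
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.n_hits < 1:
            raise ValueError("hit count must be >= 1")
        if self.blocks is not None:
            self.blocks = tuple((int(s), int(l)) for s, l in self.blocks)
            if self.blocks[0][0] != self.start:
                raise ValueError("first block must start at the record start")
            if sum(l for _, l in self.blocks) != self.length:
                raise ValueError("block lengths must sum to record length")

    def block_list(self) -> tuple[tuple[int, int], ...]:
        if self.blocks is None:
            return ((self.start, self.length),)
        return self.blocks

    @property
    def end(self) -> int:
        """Rightmost aligned genomic position (1-based inclusive)."""
        s, l = self.block_list()[-1]
        return s + l - 1

    @property
    def five_prime(self) -> int:
        """Biological 5' end: leftmost position on +, rightmost on -."""
        return self.start if self.strand == "+" else self.end


@dataclass
class CountTable:
    """Genes x samples integer counts with library sizes and effective lengths.

    ``effective_lengths`` is the per-gene length that rpkm normalises by
    (spliced CDS minus the 5' trim, clamped at 1 nt); ``short_gene`` flags
    genes whose length was clamped.
    """

    counts: pd.DataFrame
    effective_lengths: pd.Series
    library_sizes: pd.Series
    short_gene: pd.Series | None = None

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        self.effective_lengths = self.effective_lengths.reindex(self.counts.index)
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if (self.effective_lengths < 1).any():
            raise ValueError("effective lengths must be >= 1")
        if self.short_gene is None:
            self.short_gene = pd.Series(False, index=self.counts.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def validate_library_sizes(self) -> None:
        """Check the default invariant: library size == column sum."""
        sums = self.counts.sum(axis=0)
        if not (self.library_sizes >= sums).all():
            raise ValueError("library sizes smaller than assigned-read totals")


def compute_rpkm(table: CountTable) -> pd.DataFrame:
    """Reads per kilobase of (effective) feature length per million reads.

    rpkm[g, s] = count[g, s] / (L_g / 1000) / (N_s / 1e6), where L_g is the
    gene's effective length and N_s the sample's library size.
    """
    if (table.library_sizes <= 0).any():
        bad = table.library_sizes[table.library_sizes <= 0].index.tolist()
        raise ValueError(f"library size must be positive; zero/negative for {bad}")
    kb = table.effective_lengths.to_numpy(dtype=float)[:, None] / 1e3
    millions = table.library_sizes.to_numpy(dtype=float)[None, :] / 1e6
    rpkm = table.counts.to_numpy(dtype=float) / kb / millions
    return pd.DataFrame(rpkm, index=table.counts.index, columns=table.counts.columns)


def effective_length(gene: GeneModel, five_prime_trim: int) -> tuple[int, bool]:
    """Spliced CDS length minus the 5' trim, clamped at 1 nt.

    Returns ``(length, clamped)``; clamped genes should be treated with
    caution downstream (the rpkm denominator is degenerate for them).
    """
    raw = gene.spliced_length - five_prime_trim
    if raw < 1:
        return 1, True
    return raw, False


def make_count_table(
    counts: pd.DataFrame,
    genes: Sequence[GeneModel] | Iterable[GeneModel],
    five_prime_trim: int = 100,
    library_sizes: pd.Series | None = None,
) -> CountTable:
    """Assemble a CountTable from a counts frame and gene models."""
    genes = list(genes)
    by_id = {g.gene_id: g for g in genes}
    missing = [g for g in counts.index if g not in by_id]
    if missing:
        raise ValueError(f"counts reference unknown genes: {missing[:5]}")
    lengths, flags = {}, {}
    for gid in counts.index:
        lengths[gid], flags[gid] = effective_length(by_id[gid], five_prime_trim)
    if library_sizes is None:
        library_sizes = counts.sum(axis=0)
    return CountTable(
        counts=counts,
        effective_lengths=pd.Series(lengths),
        library_sizes=library_sizes,
        short_gene=pd.Series(flags),
    )
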