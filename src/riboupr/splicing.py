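"""Spliced-fraction quantification for an intron-containing transcript.

Two routes to the same quantity — the percent of a transcript pool (HAC1-like)
present in the spliced form, the readout of Ire1p endonuclease activity:

* from band intensities (RT-PCR products resolved on a gel and quantified by
  densitometry): spliced / (spliced + unspliced) x 100;
* from junction-classified sequencing reads over the gene model: reads that
  span the splice junction with the intron absent are spliced evidence, reads
  whose 5' end lies in the intron or whose contiguous alignment crosses an
  exon-intron boundary are unspliced evidence, everything else is
  uninformative and excluded from the denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

from .models import AlignmentRecord, GeneModel


@dataclass
class SplicingMeasurement:
    """One sample's spliced/unspliced signal pair (intensities or counts)."""

    sample: str
    spliced: float
    unspliced: float

    def __post_init__(self) -> None:
        if self.spliced < 0 or self.unspliced < 0:
            raise ValueError("signals must be non-negative")

    @property
    def undefined(self) -> bool:
        return self.spliced + self.unspliced == 0

    @property
    def fraction(self) -> float:
        return spliced_fraction(self.spliced, self.unspliced)


def spliced_fraction(spliced: float, unspliced: float) -> float:
    """Percent spliced: 100 * spliced / (spliced + unspliced).

    NaN (the undefined flag) when both signals are zero. Invariant under
    rescaling both signals by any positive constant.
    """
    if spliced < 0 or unspliced < 0:
        raise ValueError("signals must be non-negative")
    total = spliced + unspliced
    if total == 0:
        return math.nan
    return 100.0 * spliced / total


@dataclass
class JunctionResult:
    """Read-level splicing tally for one intron-containing gene."""

    spliced: int
    unspliced: int
    uninformative: int

    @property
    def informative(self) -> int:
        return self.spliced + self.unspliced

    @property
    def fraction(self) -> float:
        """Percent spliced among informative reads; NaN if none."""
        if self.informative == 0:
            return math.nan
        return 100.0 * self.spliced / self.informative


def classify_read(record: AlignmentRecord, gene: GeneModel) -> str:
    """Classify one read as "spliced", "unspliced" or "uninformative"."""
    if len(gene.introns) != 1:
        raise ValueError(f"gene {gene.gene_id} must have exactly one intron")
    istart, iend = gene.introns[0]
    if record.chrom != gene.chrom or record.strand != gene.strand:
        return "uninformative"
    blocks = record.block_list()
    if len(blocks) >= 2:
        # spliced evidence only when a gap removes the intron exactly
        for (s1, l1), (s2, _) in zip(blocks, blocks[1:]):
            if s1 + l1 == istart and s2 == iend + 1:
                return "spliced"
        return "uninformative"
    s, l = blocks[0]
    e = s + l - 1
    if istart <= record.five_prime <= iend:
        return "unspliced"
    if s < istart <= e or s <= iend < e:
        # contiguous alignment running across an exon-intron boundary
        return "unspliced"
    return "uninformative"


def junction_spliced_fraction(
    alignments: Iterable[AlignmentRecord], gene: GeneModel
) -> JunctionResult:
    """Tally junction evidence over a gene with exactly one intron."""
    if len(gene.introns) != 1:
        raise ValueError(f"gene {gene.gene_id} must have exactly one intron")
    counts = {"spliced": 0, "unspliced": 0, "uninformative": 0}
    for rec in alignments:
        counts[classify_read(rec, gene)] += 1
    return JunctionResult(**counts)
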