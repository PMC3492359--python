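"""Mini-genome annotation model and positional category attribution.

The discovery pipeline attributes every genomic position to one of five
categories -- ncRNA, exon, intron, pseudogene/repeat, or intergenic --
mirroring how short-read coverage over an intermediate-size (70-500 nt)
transcriptome is partitioned.  Annotation intervals may overlap (a snoRNA
hosted in an intron, a repeat inside a gene); attribution resolves
overlaps with a fixed precedence order, ncRNA first by default.

Conventions
-----------
* Coordinates are 0-based half-open everywhere in this package.  The GFF3
  reader (1-based closed) converts at the boundary.
* Category attribution ignores strand: a position inside an annotation on
  either strand takes that annotation's category.  Strand matters only for
  the novelty filter and detection logic in :mod:`isncrna.transfrags`,
  which query the strand-aware masks kept here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

#: Annotation categories, highest attribution precedence first.
DEFAULT_PRECEDENCE: tuple[str, ...] = ("ncRNA", "exon", "intron", "pseudogene_repeat")

#: Category returned for positions covered by no annotation record.
INTERGENIC = "intergenic"

#: ncRNA class labels used throughout (detection tables, simulation).
NCRNA_CLASSES: tuple[str, ...] = (
    "snoRNA",
    "snRNA",
    "tRNA",
    "rRNA",
    "sbRNA",
    "scRNA",
    "SL2",
    "SmY",
    "uncharacterized_is_ncRNA",
    "21U-RNA",
    "miRNA",
)

#: Classes in the interrogated intermediate-size range; 21U-RNAs and
#: miRNAs fall below it and are reported separately, outside the total.
IS_NCRNA_CLASSES: tuple[str, ...] = NCRNA_CLASSES[:9]


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """Half-open genomic interval ``[start, end)`` on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty interval: [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval", same_strand: bool = False) -> bool:
        if self.chrom != other.chrom:
            return False
        if same_strand and self.strand != other.strand:
            return False
        return self.start < other.end and other.start < self.end

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(slots=True)
class AnnotationRecord:
    """One annotated feature: an ncRNA locus, exon, intron or repeat.

    ``ncrna_class`` is present exactly when ``category == "ncRNA"``.  The
    annotated transcription start site (TSS) is the strand-aware 5' end.
    """

    interval: GenomicInterval
    category: str
    locus_id: str
    ncrna_class: Optional[str] = None

    def __post_init__(self) -> None:
        if self.category == "ncRNA":
            if self.ncrna_class is None:
                raise ValueError(f"{self.locus_id}: ncRNA record needs ncrna_class")
        elif self.ncrna_class is not None:
            raise ValueError(f"{self.locus_id}: ncrna_class only valid for ncRNA records")

    @property
    def tss(self) -> int:
        """Annotated 5'-end position (strand-aware)."""
        iv = self.interval
        return iv.start if iv.strand == "+" else iv.end - 1


class AnnotatedGenome:
    """Interval catalogue over a set of chromosomes with fast attribution.

    Builds, lazily and per chromosome, an int8 array holding the
    highest-precedence category code at every base (0 = intergenic), plus
    strand-aware boolean masks for category subsets used by the novelty
    filter.

    Parameters
    ----------
    chrom_lengths:
        Mapping chromosome name -> length in bases.
    records:
        The annotation records; intervals must lie within bounds and
        ``locus_id`` must be unique.
    precedence:
        Category attribution order, highest first.  Overridable because
        the tie-break between overlapping annotation layers is a modelling
        choice, not a property of the data.
    """

    def __init__(
        self,
        chrom_lengths: Mapping[str, int],
        records: Iterable[AnnotationRecord] = (),
        precedence: Sequence[str] = DEFAULT_PRECEDENCE,
    ) -> None:
        self.chrom_lengths: dict[str, int] = {c: int(n) for c, n in chrom_lengths.items()}
        self.records: list[AnnotationRecord] = list(records)
        self.precedence: tuple[str, ...] = tuple(precedence)
        if set(self.precedence) != set(DEFAULT_PRECEDENCE):
            raise ValueError(f"precedence must permute {DEFAULT_PRECEDENCE}")
        seen: set[str] = set()
        for rec in self.records:
            iv = rec.interval
            if iv.chrom not in self.chrom_lengths:
                raise ValueError(f"{rec.locus_id}: unknown chromosome {iv.chrom!r}")
            if iv.end > self.chrom_lengths[iv.chrom]:
                raise ValueError(f"{rec.locus_id}: interval exceeds chromosome length")
            if rec.locus_id in seen:
                raise ValueError(f"duplicate locus_id {rec.locus_id!r}")
            seen.add(rec.locus_id)
        # code 0 = intergenic; precedence[0] gets the highest code
        self._code_of = {cat: len(self.precedence) - i for i, cat in enumerate(self.precedence)}
        self._cat_of = [INTERGENIC] + list(reversed(self.precedence))
        self._codes: dict[str, np.ndarray] = {}
        self._masks: dict[tuple, np.ndarray] = {}

    # -- indexes -----------------------------------------------------------

    def category_code(self, category: str) -> int:
        if category == INTERGENIC:
            return 0
        return self._code_of[category]

    def code_category(self, code: int) -> str:
        return self._cat_of[code]

    def category_array(self, chrom: str) -> np.ndarray:
        """Per-base highest-precedence category codes for one chromosome."""
        if chrom not in self.chrom_lengths:
            raise ValueError(f"unknown chromosome {chrom!r}")
        arr = self._codes.get(chrom)
        if arr is None:
            arr = np.zeros(self.chrom_lengths[chrom], dtype=np.int8)
            for rec in self.records:
                iv = rec.interval
                if iv.chrom != chrom:
                    continue
                code = self._code_of[rec.category]
                seg = arr[iv.start : iv.end]
                np.maximum(seg, code, out=seg)
            self._codes[chrom] = arr
        return arr

    def strand_mask(self, categories: Sequence[str], chrom: str, strand: str) -> np.ndarray:
        """Boolean per-base mask of positions covered, on ``strand``, by any
        record whose category is in ``categories``."""
        if chrom not in self.chrom_lengths:
            raise ValueError(f"unknown chromosome {chrom!r}")
        key = (tuple(sorted(categories)), chrom, strand)
        mask = self._masks.get(key)
        if mask is None:
            mask = np.zeros(self.chrom_lengths[chrom], dtype=bool)
            wanted = set(categories)
            for rec in self.records:
                iv = rec.interval
                if iv.chrom == chrom and iv.strand == strand and rec.category in wanted:
                    mask[iv.start : iv.end] = True
            self._masks[key] = mask
        return mask

    # -- record access -----------------------------------------------------

    def records_of(self, category: str) -> list[AnnotationRecord]:
        return [r for r in self.records if r.category == category]

    def ncrna_records(self, classes: Optional[Sequence[str]] = None) -> list[AnnotationRecord]:
        recs = self.records_of("ncRNA")
        if classes is None:
            return recs
        wanted = set(classes)
        return [r for r in recs if r.ncrna_class in wanted]


def classify_position(
    genome: AnnotatedGenome, chrom: str, pos: int, strand: Optional[str] = None
) -> str:
    """Category of one genomic position under the genome's precedence.

    ``strand`` is accepted for interface symmetry but ignored: attribution
    is strand-blind by design (see module docstring).
    """
    if chrom not in genome.chrom_lengths:
        raise ValueError(f"unknown chromosome {chrom!r}")
    if not 0 <= pos < genome.chrom_lengths[chrom]:
        raise ValueError(f"position {pos} outside {chrom} [0, {genome.chrom_lengths[chrom]})")
    return genome.code_category(int(genome.category_array(chrom)[pos]))


def classify_interval(genome: AnnotatedGenome, interval: GenomicInterval) -> str:
    """Highest-precedence category among the positions an interval covers."""
    if interval.chrom not in genome.chrom_lengths:
        raise ValueError(f"unknown chromosome {interval.chrom!r}")
    if interval.end > genome.chrom_lengths[interval.chrom]:
        raise ValueError("interval exceeds chromosome length")
    code = int(genome.category_array(interval.chrom)[interval.start : interval.end].max())
    return genome.code_category(code)
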