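"""Strand-specific fractional read coverage and genomic distributions.

Short 36-nt reads may map to several genomic loci; each placement of a
read contributes ``1 / n_hits`` to every base it covers, so the total
coverage mass contributed by one read equals its length regardless of how
many placements it has (conservation).  Coverage is kept per chromosome
and strand as a dense float vector -- the working genomes here are small
(megabases), which keeps this exact and simple.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple

import numpy as np

from .annotation import (
    INTERGENIC,
    AnnotatedGenome,
    GenomicInterval,
    classify_interval,
)


@dataclass(frozen=True, slots=True)
class AlignedRead:
    """One placement of an aligned read.

    A read mapping to ``n_hits`` loci appears as ``n_hits`` AlignedRead
    entries sharing the same ``n_hits`` value; each contributes a weight
    of ``1 / n_hits`` per covered base.
    """

    interval: GenomicInterval
    n_hits: int = 1
    sample_id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.n_hits < 1:
            raise ValueError(f"n_hits must be >= 1, got {self.n_hits}")

    @property
    def weight(self) -> float:
        return 1.0 / self.n_hits


class CoverageTrack:
    """Per-base fractional coverage for one sample, by chromosome and strand."""

    def __init__(self, chrom_lengths: Mapping[str, int], sample_id: Optional[str] = None):
        self.chrom_lengths = {c: int(n) for c, n in chrom_lengths.items()}
        self.sample_id = sample_id
        self._data: Dict[Tuple[str, str], np.ndarray] = {}

    def array(self, chrom: str, strand: str) -> np.ndarray:
        if chrom not in self.chrom_lengths:
            raise ValueError(f"unknown chromosome {chrom!r}")
        key = (chrom, strand)
        arr = self._data.get(key)
        if arr is None:
            arr = np.zeros(self.chrom_lengths[chrom], dtype=np.float64)
            self._data[key] = arr
        return arr

    def add_read(self, read: AlignedRead) -> None:
        iv = read.interval
        if iv.chrom not in self.chrom_lengths:
            raise ValueError(f"read on unknown chromosome {iv.chrom!r}")
        if iv.end > self.chrom_lengths[iv.chrom]:
            raise ValueError(f"read [{iv.start},{iv.end}) outside {iv.chrom}")
        self.array(iv.chrom, iv.strand)[iv.start : iv.end] += read.weight

    def total_mass(self) -> float:
        """Sum of coverage over all positions and strands."""
        return float(sum(arr.sum() for arr in self._data.values()))

    def covered_mask(self, chrom: str) -> np.ndarray:
        """Positions covered by at least one read on either strand."""
        mask = np.zeros(self.chrom_lengths[chrom], dtype=bool)
        for (c, _s), arr in self._data.items():
            if c == chrom:
                mask |= arr > 0
        return mask

    def iter_tracks(self) -> Iterable[Tuple[str, str, np.ndarray]]:
        """Yield ``(chrom, strand, vector)`` for materialised tracks, sorted."""
        for (chrom, strand) in sorted(self._data):
            yield chrom, strand, self._data[(chrom, strand)]

    def n_covered(self) -> int:
        return int(sum((arr > 0).sum() for arr in self._data.values()))


def build_coverage(
    reads: Iterable[AlignedRead],
    genome: AnnotatedGenome | Mapping[str, int],
    sample_id: Optional[str] = None,
) -> CoverageTrack:
    """Accumulate fractional coverage from read placements.

    Each placement adds ``1 / n_hits`` over its covered bases on its own
    strand, so total coverage mass equals the summed read lengths.
    """
    lengths = genome.chrom_lengths if isinstance(genome, AnnotatedGenome) else genome
    track = CoverageTrack(lengths, sample_id=sample_id)
    for read in reads:
        track.add_read(read)
    return track


def read_distribution(
    reads: Iterable[AlignedRead], genome: AnnotatedGenome
) -> Dict[str, float]:
    """Fractional share of read weight per annotation category.

    Each placement contributes ``1 / n_hits`` to the category of its
    interval (whole-placement attribution via :func:`classify_interval`);
    shares are normalised by total weight and sum to 1.
    """
    totals: Dict[str, float] = {}
    grand = 0.0
    for read in reads:
        cat = classify_interval(genome, read.interval)
        w = read.weight
        totals[cat] = totals.get(cat, 0.0) + w
        grand += w
    if grand == 0.0:
        raise ValueError("no reads supplied")
    return {cat: w / grand for cat, w in sorted(totals.items())}


def nucleotide_distribution(
    track: CoverageTrack, genome: AnnotatedGenome
) -> Dict[str, float]:
    """Share of covered genomic positions per category.

    A position counts once if covered on either strand; categories come
    from strand-blind positional attribution.  Raises if nothing is
    covered.
    """
    counts: Dict[str, float] = {}
    total = 0
    for chrom in track.chrom_lengths:
        mask = track.covered_mask(chrom)
        n = int(mask.sum())
        if n == 0:
            continue
        total += n
        codes = genome.category_array(chrom)[mask]
        for code in np.unique(codes):
            cat = genome.code_category(int(code))
            counts[cat] = counts.get(cat, 0.0) + int((codes == code).sum())
    if total == 0:
        raise ValueError("no covered positions")
    return {cat: c / total for cat, c in sorted(counts.items())}
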