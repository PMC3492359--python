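"""Transfrag calling, novelty filtering, detection rates and TSS profiling.

A *transfrag* (transcribed fragment) is a maximal run of consecutive
same-strand positions with coverage > 0.  Novel-transcript candidates are
transfrags that survive three filters, applied in order:

1. mean per-base coverage >= 6 (``rejected_low_coverage`` otherwise),
2. length >= 36 nt, one read length (``rejected_short``),
3. no same-strand overlap with an annotated ncRNA locus
   (``rejected_annotated``).

Retained candidates shorter than 70 nt -- the lower bound of the
intermediate-size class -- are extended downstream (strand-aware 3') to
70 nt for probe design; the pre-extension interval and coverage
statistics are kept so that filtering is idempotent.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .annotation import (
    IS_NCRNA_CLASSES,
    AnnotatedGenome,
    AnnotationRecord,
    GenomicInterval,
)
from .coverage import CoverageTrack

STATUS_NOVEL = "novel_retained"
STATUS_LOW = "rejected_low_coverage"
STATUS_SHORT = "rejected_short"
STATUS_ANNOTATED = "rejected_annotated"
STATUS_KNOWN = "known_overlap"


@dataclass(slots=True)
class Transfrag:
    """A called contiguous transcribed fragment.

    ``source_interval`` holds the pre-extension interval for transfrags
    that were 3'-extended; coverage statistics always refer to it.
    """

    interval: GenomicInterval
    mean_coverage: float
    max_coverage: float
    sample_ids: Tuple[str, ...] = ()
    status: Optional[str] = None
    source_interval: Optional[GenomicInterval] = None

    @property
    def length(self) -> int:
        return self.interval.length

    @property
    def core(self) -> GenomicInterval:
        """Interval the coverage statistics were measured on."""
        return self.source_interval if self.source_interval is not None else self.interval


def call_transfrags(track: CoverageTrack) -> List[Transfrag]:
    """Maximal coverage>0 runs per chromosome and strand, no filtering."""
    sample_ids = (track.sample_id,) if track.sample_id is not None else ()
    out: List[Transfrag] = []
    for chrom, strand, arr in track.iter_tracks():
        mask = arr > 0
        if not mask.any():
            continue
        padded = np.concatenate(([False], mask, [False]))
        diff = np.diff(padded.astype(np.int8))
        starts = np.flatnonzero(diff == 1)
        ends = np.flatnonzero(diff == -1)
        for s, e in zip(starts, ends):
            seg = arr[s:e]
            out.append(
                Transfrag(
                    interval=GenomicInterval(chrom, int(s), int(e), strand),
                    mean_coverage=float(seg.mean()),
                    max_coverage=float(seg.max()),
                    sample_ids=sample_ids,
                )
            )
    return out


def filter_novel(
    transfrags: Iterable[Transfrag],
    genome: AnnotatedGenome,
    *,
    min_coverage: float = 6.0,
    min_length: int = 36,
    extend_to: int = 70,
    coverage_stat: str = "mean",
    overlap_categories: Sequence[str] = ("ncRNA",),
) -> List[Transfrag]:
    """Apply the novelty filters; return new transfrags with status set.

    ``coverage_stat`` selects which aggregate the coverage cut-off is
    applied to (``"mean"`` by default, ``"max"`` available).  Overlap
    rejection is same-strand against the categories in
    ``overlap_categories`` -- annotated ncRNA loci only by default, so
    intronic, antisense and exon-overlapping transcripts survive.
    Idempotent: rerunning on its own output reproduces it.
    """
    if coverage_stat not in ("mean", "max"):
        raise ValueError(f"coverage_stat must be 'mean' or 'max', got {coverage_stat!r}")
    out: List[Transfrag] = []
    for tf in transfrags:
        cov = tf.mean_coverage if coverage_stat == "mean" else tf.max_coverage
        core = tf.core
        if cov < min_coverage:
            out.append(replace(tf, status=STATUS_LOW))
            continue
        if core.length < min_length:
            out.append(replace(tf, status=STATUS_SHORT))
            continue
        mask = genome.strand_mask(overlap_categories, core.chrom, core.strand)
        if mask[core.start : core.end].any():
            out.append(replace(tf, status=STATUS_ANNOTATED))
            continue
        iv = tf.interval
        src = tf.source_interval
        if core.length < extend_to:
            chrom_len = genome.chrom_lengths[core.chrom]
            if core.strand == "+":
                new_end = min(core.start + extend_to, chrom_len)
                iv = GenomicInterval(core.chrom, core.start, new_end, "+")
            else:
                new_start = max(core.end - extend_to, 0)
                iv = GenomicInterval(core.chrom, new_start, core.end, "-")
            src = core
        out.append(replace(tf, interval=iv, source_interval=src, status=STATUS_NOVEL))
    return out


def merge_novel(transfrags: Iterable[Transfrag]) -> List[Transfrag]:
    """Merge same-strand overlapping ``novel_retained`` transfrags across
    samples into single novel transcripts.

    The merged mean coverage is the length-weighted mean of the parts'
    means (an approximation adequate for bookkeeping); sample ids are
    unioned.
    """
    groups: Dict[Tuple[str, str], List[Transfrag]] = {}
    for tf in transfrags:
        if tf.status != STATUS_NOVEL:
            continue
        groups.setdefault((tf.interval.chrom, tf.interval.strand), []).append(tf)
    merged: List[Transfrag] = []
    for (chrom, strand), tfs in sorted(groups.items()):
        tfs.sort(key=lambda t: (t.interval.start, t.interval.end))
        cluster: List[Transfrag] = []
        cluster_end = -1
        for tf in tfs + [None]:  # type: ignore[list-item]
            if tf is not None and (not cluster or tf.interval.start < cluster_end):
                cluster.append(tf)
                cluster_end = max(cluster_end, tf.interval.end)
                continue
            if cluster:
                start = min(t.interval.start for t in cluster)
                end = max(t.interval.end for t in cluster)
                w = np.array([t.core.length for t in cluster], dtype=float)
                means = np.array([t.mean_coverage for t in cluster])
                samples = tuple(sorted({s for t in cluster for s in t.sample_ids}))
                merged.append(
                    Transfrag(
                        interval=GenomicInterval(chrom, start, end, strand),
                        mean_coverage=float((w * means).sum() / w.sum()),
                        max_coverage=float(max(t.max_coverage for t in cluster)),
                        sample_ids=samples,
                        status=STATUS_NOVEL,
                    )
                )
            if tf is not None:
                cluster = [tf]
                cluster_end = tf.interval.end
    return merged


@dataclass
class DetectionReport:
    """Per-class detection table for known ncRNA loci.

    ``frame`` has columns ``ncrna_class``, ``n_known``, ``n_detected``,
    ``rate_percent``; a summary row labelled ``all`` totals the
    intermediate-size classes.
    """

    frame: pd.DataFrame

    TOTAL_LABEL = "all"

    @staticmethod
    def compute_rate(n_known: int, n_detected: int) -> float:
        return round(100.0 * n_detected / n_known, 2)

    @classmethod
    def from_counts(
        cls, counts: Iterable[Tuple[str, int, int]]
    ) -> "DetectionReport":
        """Build a report from ``(class, n_known, n_detected)`` triples,
        computing the percentage for each row."""
        rows = []
        for name, known, detected in counts:
            if not 0 <= detected <= known:
                raise ValueError(f"{name}: detected {detected} outside [0, {known}]")
            rows.append((name, known, detected, cls.compute_rate(known, detected)))
        return cls(
            pd.DataFrame(rows, columns=["ncrna_class", "n_known", "n_detected", "rate_percent"])
        )

    def rate_of(self, ncrna_class: str) -> float:
        sel = self.frame.loc[self.frame["ncrna_class"] == ncrna_class, "rate_percent"]
        if sel.empty:
            raise KeyError(ncrna_class)
        return float(sel.iloc[0])


def detection_rate(
    transfrags: Iterable[Transfrag],
    genome: AnnotatedGenome,
    min_fraction_covered: float = 0.0,
    total_classes: Sequence[str] = IS_NCRNA_CLASSES,
) -> DetectionReport:
    """Fraction of known ncRNA loci overlapped by any transfrag.

    A locus counts as detected when a same-strand transfrag (from any
    sample) overlaps more than ``min_fraction_covered`` of its length
    (default: any overlap).  Classes with no known loci are omitted; a
    summary row over ``total_classes`` is appended.  Overlapping
    transfrags are additionally tagged ``known_overlap`` unless they
    already carry a status.
    """
    # transfrag occupancy masks per (chrom, strand)
    occupancy: Dict[Tuple[str, str], np.ndarray] = {}
    tf_list = list(transfrags)
    for tf in tf_list:
        iv = tf.interval
        key = (iv.chrom, iv.strand)
        mask = occupancy.get(key)
        if mask is None:
            mask = np.zeros(genome.chrom_lengths[iv.chrom], dtype=bool)
            occupancy[key] = mask
        mask[iv.start : iv.end] = True

    known: Dict[str, int] = {}
    detected: Dict[str, int] = {}
    for rec in genome.ncrna_records():
        cls_name = rec.ncrna_class
        known[cls_name] = known.get(cls_name, 0) + 1
        iv = rec.interval
        mask = occupancy.get((iv.chrom, iv.strand))
        if mask is None:
            continue
        overlap = int(mask[iv.start : iv.end].sum())
        if overlap > min_fraction_covered * iv.length:
            detected[cls_name] = detected.get(cls_name, 0) + 1

    for tf in tf_list:
        if tf.status is None:
            iv = tf.interval
            m = genome.strand_mask(("ncRNA",), iv.chrom, iv.strand)
            if m[iv.start : iv.end].any():
                tf.status = STATUS_KNOWN

    rows = []
    for cls_name in sorted(known):
        k, d = known[cls_name], detected.get(cls_name, 0)
        rows.append((cls_name, k, d, DetectionReport.compute_rate(k, d)))
    tot_k = sum(known[c] for c in known if c in set(total_classes))
    tot_d = sum(detected.get(c, 0) for c in known if c in set(total_classes))
    if tot_k > 0:
        rows.append(
            (DetectionReport.TOTAL_LABEL, tot_k, tot_d, DetectionReport.compute_rate(tot_k, tot_d))
        )
    return DetectionReport(
        pd.DataFrame(rows, columns=["ncrna_class", "n_known", "n_detected", "rate_percent"])
    )


@dataclass
class TssProfile:
    """Offsets of transfrag 5' termini from annotated TSSs.

    One row per known intermediate-size ncRNA locus that is overlapped by
    a sufficiently covered same-strand transfrag: ``offset`` is the
    strand-aware distance of the transfrag 5' end from the annotated TSS
    (negative = upstream), ``covered_at_tss`` says whether the transfrag
    spans the TSS itself.
    """

    frame: pd.DataFrame

    @property
    def covered_fraction(self) -> float:
        if self.frame.empty:
            raise ValueError("no loci in profile")
        return float(self.frame["covered_at_tss"].mean())

    def histogram(self, bin_width: int = 10) -> Tuple[np.ndarray, np.ndarray]:
        """Offset histogram ``(counts, bin_edges)`` at the given bin width."""
        off = self.frame["offset"].to_numpy()
        lo = int(np.floor(off.min() / bin_width) * bin_width)
        hi = int(np.ceil((off.max() + 1) / bin_width) * bin_width)
        edges = np.arange(lo, hi + bin_width, bin_width)
        counts, edges = np.histogram(off, bins=edges)
        return counts, edges

    def mode_offset(self, bin_width: int = 10) -> float:
        """Centre of the most populated offset bin (empirical mode)."""
        counts, edges = self.histogram(bin_width)
        i = int(np.argmax(counts))
        return float((edges[i] + edges[i + 1]) / 2.0)


def _five_prime(iv: GenomicInterval) -> int:
    return iv.start if iv.strand == "+" else iv.end - 1


def tss_profile(
    transfrags: Iterable[Transfrag],
    genome: AnnotatedGenome,
    coverage_min: float = 6.0,
    classes: Sequence[str] = IS_NCRNA_CLASSES,
) -> TssProfile:
    """Profile transfrag 5'-end offsets at known is-ncRNA TSSs.

    For each known locus with at least one overlapping same-strand
    transfrag of mean coverage >= ``coverage_min``, report the smallest
    (most 5') strand-aware offset and whether any qualifying transfrag
    spans the TSS.
    """
    by_key: Dict[Tuple[str, str], List[Transfrag]] = {}
    for tf in transfrags:
        if tf.mean_coverage >= coverage_min:
            by_key.setdefault((tf.interval.chrom, tf.interval.strand), []).append(tf)
    rows = []
    for rec in genome.ncrna_records(classes):
        iv = rec.interval
        hits = [
            tf
            for tf in by_key.get((iv.chrom, iv.strand), [])
            if tf.interval.overlaps(iv, same_strand=True)
        ]
        if not hits:
            continue
        tss = rec.tss
        sign = 1 if iv.strand == "+" else -1
        offset = min(sign * (_five_prime(tf.interval) - tss) for tf in hits)
        covered = any(tf.interval.start <= tss < tf.interval.end for tf in hits)
        rows.append((rec.locus_id, rec.ncrna_class, int(offset), bool(covered)))
    return TssProfile(
        pd.DataFrame(rows, columns=["locus_id", "ncrna_class", "offset", "covered_at_tss"])
    )
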