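"""Synthetic data generator for every stage of the pipeline.

Emulates, at desk scale and with full ground truth, the study design the
analysis assumes: a small annotated genome carrying the known ncRNA
classes in realistic relative proportions, planted novel intermediate-size
(70-500 nt) loci placed intergenic / intronic (either strand) /
exon-overlapping, 36-nt read sets for three sequencing conditions
(wild type, wild type after 100 J/m2 UV, repair-deficient mutant) with a
UV-induced subset of novel loci, fractionally weighted multi-mapped reads
via explicit decoy placements in repeats, four-array microarray
intensities with an intensity-dependent distortion on one array,
replicated qPCR Ct tables, and binomial dose-response survival counts.

Everything is driven by one :class:`numpy.random.Generator`; a fixed seed
fully determines all outputs.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .annotation import (
    IS_NCRNA_CLASSES,
    AnnotatedGenome,
    AnnotationRecord,
    GenomicInterval,
)
from .coverage import AlignedRead
from .expression import ExpressionMatrix, SeqExpression

SEQ_CONDITIONS = ("N2", "N2_UV", "xpa1")
ARRAY_CONDITIONS = ("N2", "N2_UV", "xpa1", "xpa1_UV")


# --------------------------------------------------------------------------
# configuration and ground truth
# --------------------------------------------------------------------------


def _default_class_counts() -> Dict[str, int]:
    # the known ncRNA inventory at one-fifth scale for the is-size classes,
    # plus small below-size classes (rarely captured by size selection).
    return {
        "snoRNA": 27,
        "snRNA": 20,
        "tRNA": 126,
        "rRNA": 4,
        "sbRNA": 2,
        "scRNA": 1,
        "SL2": 2,
        "SmY": 1,
        "uncharacterized_is_ncRNA": 12,
        "21U-RNA": 50,
        "miRNA": 20,
    }


def _default_class_lengths() -> Dict[str, Tuple[int, int]]:
    return {
        "snoRNA": (70, 150),
        "snRNA": (100, 200),
        "tRNA": (72, 90),
        "rRNA": (110, 160),
        "sbRNA": (60, 100),
        "scRNA": (90, 110),
        "SL2": (100, 120),
        "SmY": (70, 90),
        "uncharacterized_is_ncRNA": (70, 500),
        "21U-RNA": (21, 22),
        "miRNA": (55, 70),
    }


def _default_detect_prob() -> Dict[str, float]:
    # chance that a known locus is expressed in the sequenced size range;
    # mirrors the per-class detection behaviour of the real libraries,
    # where the below-size classes are largely missed
    return {
        "snoRNA": 0.93,
        "snRNA": 0.89,
        "tRNA": 0.94,
        "rRNA": 1.0,
        "sbRNA": 1.0,
        "scRNA": 1.0,
        "SL2": 1.0,
        "SmY": 1.0,
        "uncharacterized_is_ncRNA": 0.59,
        "21U-RNA": 0.01,
        "miRNA": 0.10,
    }


@dataclass
class SimulationConfig:
    """All knobs of the generator; the defaults are the study conditions."""

    # genome layout
    chrom_lengths: Dict[str, int] = field(
        default_factory=lambda: {"chrI": 1_000_000, "chrII": 1_000_000}
    )
    ncrna_class_counts: Dict[str, int] = field(default_factory=_default_class_counts)
    ncrna_class_lengths: Dict[str, Tuple[int, int]] = field(default_factory=_default_class_lengths)
    detect_prob: Dict[str, float] = field(default_factory=_default_detect_prob)
    n_coding_genes: int = 40
    exons_per_gene: Tuple[int, int] = (3, 8)
    exon_length: Tuple[int, int] = (100, 300)
    intron_length: Tuple[int, int] = (250, 800)
    n_repeats: int = 30
    repeat_length: Tuple[int, int] = (300, 1500)
    placement_margin: int = 150  # exceeds the 70-nt probe extension

    # novel loci
    n_novel_loci: int = 30
    novel_length: Tuple[int, int] = (70, 500)
    novel_placement: Dict[str, float] = field(
        default_factory=lambda: {"intergenic": 0.6, "intronic": 0.3, "exon_overlap": 0.1}
    )
    uv_responsive_fraction: float = 0.5
    uv_fold_range: Tuple[float, float] = (2.0, 4.0)
    n_known_responsive: int = 3

    # sequencing
    read_length: int = 36
    depth_scale: float = 1.0
    known_coverage_log2: Tuple[float, float] = (np.log2(40.0), 1.0)  # (mean, sd)
    novel_coverage_log2: Tuple[float, float] = (np.log2(18.0), 0.4)
    novel_coverage_min: float = 12.0
    exon_coverage: float = 2.0
    n_background_reads: int = 1500
    multi_map_fraction: float = 0.08
    tss_covered_fraction: float = 0.75
    tss_trim_range: Tuple[int, int] = (20, 60)
    tss_anchor_fraction: float = 0.2

    # microarray
    array_noise_sigma_log2: float = 0.15
    seq_noise_sigma_log2: float = 0.25
    distorted_array: Optional[str] = "xpa1_UV"
    distortion_coef: float = 0.1
    probe_baseline_log2: Tuple[float, float] = (4.0, 0.5)

    # qPCR
    n_qpcr_targets: int = 4
    ct_noise_sigma: float = 0.1
    ct_replicates: int = 3
    ct_target_baseline: float = 28.0
    ct_reference_baseline: float = 16.0

    # survival assay
    survival_doses: Tuple[float, ...] = (0.0, 50.0, 100.0, 150.0, 200.0)
    survival_d50: float = 120.0
    survival_slope: float = 30.0
    knockdown_d50_shifts: Tuple[float, ...] = (-35.0, -35.0, -15.0)
    survival_replicates: int = 3
    survival_animals: int = 60


@dataclass
class NovelTruth:
    interval: GenomicInterval
    placement: str
    base_coverage: float
    uv_fold: float
    responsive: bool


@dataclass
class KnownTruth:
    expressed: bool
    base_coverage: float
    tss_trim: int  # 0 = mature transcript starts at the annotated TSS
    uv_fold: float
    responsive: bool


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    known: Dict[str, KnownTruth] = field(default_factory=dict)
    novel: Dict[str, NovelTruth] = field(default_factory=dict)
    probe_responders: Dict[str, float] = field(default_factory=dict)  # probe -> fold
    ct_folds: Dict[str, Dict[str, float]] = field(default_factory=dict)
    survival_probs: Dict[str, Dict[float, float]] = field(default_factory=dict)

    def responsive_novel_ids(self) -> List[str]:
        return sorted(k for k, v in self.novel.items() if v.responsive)

    def to_json(self, path: Union[str, Path]) -> None:
        def enc(obj):
            if isinstance(obj, GenomicInterval):
                return {"chrom": obj.chrom, "start": obj.start, "end": obj.end, "strand": obj.strand}
            raise TypeError(type(obj))

        payload = {
            "known": {k: asdict(v) for k, v in self.known.items()},
            "novel": {k: asdict(v) for k, v in self.novel.items()},
            "probe_responders": self.probe_responders,
            "ct_folds": self.ct_folds,
            "survival_probs": self.survival_probs,
        }
        Path(path).write_text(json.dumps(payload, default=enc, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        known = {k: KnownTruth(**v) for k, v in raw["known"].items()}
        novel = {}
        for k, v in raw["novel"].items():
            v = dict(v)
            v["interval"] = GenomicInterval(**v["interval"])
            novel[k] = NovelTruth(**v)
        return cls(
            known=known,
            novel=novel,
            probe_responders=raw["probe_responders"],
            ct_folds=raw["ct_folds"],
            survival_probs={c: {float(d): p for d, p in m.items()} for c, m in raw["survival_probs"].items()},
        )


def condition_multiplier(condition: str, uv_fold: float, responsive: bool) -> float:
    return uv_fold if (responsive and condition.endswith("_UV")) else 1.0


# --------------------------------------------------------------------------
# genome simulation
# --------------------------------------------------------------------------


class _Allocator:
    """Carves non-overlapping intervals with margins out of free space."""

    def __init__(self, chrom_lengths: Dict[str, int], margin: int):
        self.margin = margin
        self.segments: List[Tuple[str, int, int]] = [
            (c, 0, n) for c, n in sorted(chrom_lengths.items())
        ]

    def allocate(self, length: int, rng: np.random.Generator) -> Tuple[str, int]:
        need = length + 2 * self.margin
        caps = np.array([e - s - need for (_c, s, e) in self.segments], dtype=float)
        ok = np.flatnonzero(caps >= 0)
        if ok.size == 0:
            raise ValueError("genome too small to place requested loci")
        w = caps[ok] + 1.0
        i = int(ok[rng.choice(ok.size, p=w / w.sum())])
        chrom, s, e = self.segments.pop(i)
        start = int(rng.integers(s + self.margin, e - self.margin - length + 1))
        self.segments.append((chrom, s, start))
        self.segments.append((chrom, start + length, e))
        self.segments.sort()
        return chrom, start


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator
) -> Tuple[AnnotatedGenome, GroundTruth]:
    """Build the annotated mini-genome and its expression ground truth.

    Features never overlap within a category; novel loci (ground truth
    only, never annotated) avoid annotated ncRNA loci on both strands so
    their novelty is unambiguous.
    """
    margin = config.placement_margin
    alloc = _Allocator(config.chrom_lengths, margin)
    records: List[AnnotationRecord] = []
    truth = GroundTruth()

    # coding genes with exon/intron structure
    free_introns: List[Tuple[GenomicInterval, str]] = []  # (interval, host strand)
    exon_sites: List[Tuple[GenomicInterval, GenomicInterval, str]] = []  # (exon, next intron, strand)
    for g in range(config.n_coding_genes):
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        ex_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, size=n_ex)
        in_lens = rng.integers(config.intron_length[0], config.intron_length[1] + 1, size=n_ex - 1)
        span = int(ex_lens.sum() + in_lens.sum())
        chrom, start = alloc.allocate(span, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        pos = start
        parts: List[Tuple[str, GenomicInterval]] = []
        for j in range(n_ex):
            ex_iv = GenomicInterval(chrom, pos, pos + int(ex_lens[j]), strand)
            records.append(AnnotationRecord(ex_iv, "exon", f"gene{g:03d}.exon{j}"))
            parts.append(("exon", ex_iv))
            pos += int(ex_lens[j])
            if j < n_ex - 1:
                in_iv = GenomicInterval(chrom, pos, pos + int(in_lens[j]), strand)
                records.append(AnnotationRecord(in_iv, "intron", f"gene{g:03d}.intron{j}"))
                parts.append(("intron", in_iv))
                free_introns.append((in_iv, strand))
                exon_sites.append((ex_iv, in_iv, strand))
                pos += int(in_lens[j])
    rng.shuffle(free_introns)
    rng.shuffle(exon_sites)
    used_introns: set = set()

    def take_intron(min_len: int) -> Optional[Tuple[GenomicInterval, str]]:
        for iv, s in free_introns:
            key = (iv.chrom, iv.start, iv.end)
            if key not in used_introns and iv.length >= min_len:
                used_introns.add(key)
                return iv, s
        return None

    # known ncRNA loci
    for cls_name in sorted(config.ncrna_class_counts):
        lo, hi = config.ncrna_class_lengths[cls_name]
        for k in range(config.ncrna_class_counts[cls_name]):
            length = int(rng.integers(lo, hi + 1))
            locus_id = f"{cls_name}_{k:04d}"
            intronic = cls_name == "snoRNA" and rng.random() < 0.5
            placed = False
            if intronic:
                got = take_intron(length + 40)
                if got is not None:
                    host, host_strand = got
                    off = int(rng.integers(host.start + 20, host.end - 20 - length + 1))
                    iv = GenomicInterval(host.chrom, off, off + length, host_strand)
                    placed = True
            if not placed:
                strand = "+" if rng.random() < 0.5 else "-"
                chrom, start = alloc.allocate(length, rng)
                iv = GenomicInterval(chrom, start, start + length, strand)
            records.append(AnnotationRecord(iv, "ncRNA", locus_id, ncrna_class=cls_name))
            expressed = bool(rng.random() < config.detect_prob.get(cls_name, 0.5))
            cov = float(2.0 ** rng.normal(*config.known_coverage_log2)) * config.depth_scale
            trim = 0
            if expressed and cls_name in IS_NCRNA_CLASSES and rng.random() > config.tss_covered_fraction:
                trim = int(rng.integers(config.tss_trim_range[0], config.tss_trim_range[1] + 1))
            truth.known[locus_id] = KnownTruth(
                expressed=expressed, base_coverage=cov, tss_trim=trim, uv_fold=1.0, responsive=False
            )

    # a few known is-ncRNAs respond to UV (the screen should find them too)
    expressed_is = [
        lid
        for lid, t in sorted(truth.known.items())
        if t.expressed and lid.split("_")[0] in IS_NCRNA_CLASSES and t.base_coverage >= 10
    ]
    for lid in list(rng.permutation(expressed_is))[: config.n_known_responsive]:
        truth.known[lid].responsive = True
        truth.known[lid].uv_fold = float(rng.uniform(*config.uv_fold_range))

    # repeats / pseudogene space
    for r in range(config.n_repeats):
        length = int(rng.integers(config.repeat_length[0], config.repeat_length[1] + 1))
        chrom, start = alloc.allocate(length, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        records.append(
            AnnotationRecord(
                GenomicInterval(chrom, start, start + length, strand),
                "pseudogene_repeat",
                f"repeat{r:03d}",
            )
        )

    # planted novel loci (ground truth only, not annotation records)
    kinds = list(config.novel_placement)
    probs = np.array([config.novel_placement[k] for k in kinds], dtype=float)
    probs /= probs.sum()
    for n in range(config.n_novel_loci):
        length = int(rng.integers(config.novel_length[0], config.novel_length[1] + 1))
        kind = kinds[int(rng.choice(len(kinds), p=probs))]
        iv: Optional[GenomicInterval] = None
        if kind == "intronic":
            got = take_intron(length + 40)
            if got is not None:
                host, _hs = got
                off = int(rng.integers(host.start + 20, host.end - 20 - length + 1))
                strand = "+" if rng.random() < 0.5 else "-"  # either strand of the intron
                iv = GenomicInterval(host.chrom, off, off + length, strand)
        elif kind == "exon_overlap":
            while exon_sites:
                ex_iv, in_iv, strand = exon_sites.pop()
                key = (in_iv.chrom, in_iv.start, in_iv.end)
                if key in used_introns:
                    continue
                max_in_exon = min(50, ex_iv.length - 1, length - 20)
                if max_in_exon < 20 or in_iv.length < (length - 20) + 20:
                    continue
                in_exon = int(rng.integers(20, max_in_exon + 1))
                start = ex_iv.end - in_exon
                if start + length > in_iv.end - 20:
                    continue
                used_introns.add(key)
                iv = GenomicInterval(ex_iv.chrom, start, start + length, strand)
                break
        if iv is None:  # intergenic, or fallback when no slot was free
            kind_eff = "intergenic"
            strand = "+" if rng.random() < 0.5 else "-"
            chrom, start = alloc.allocate(length, rng)
            iv = GenomicInterval(chrom, start, start + length, strand)
        else:
            kind_eff = kind
        cov = float(
            np.clip(2.0 ** rng.normal(*config.novel_coverage_log2), config.novel_coverage_min, 60.0)
        ) * config.depth_scale
        responsive = bool(rng.random() < config.uv_responsive_fraction)
        fold = float(rng.uniform(*config.uv_fold_range)) if responsive else 1.0
        truth.novel[f"novel_{n:04d}"] = NovelTruth(
            interval=iv, placement=kind_eff, base_coverage=cov, uv_fold=fold, responsive=responsive
        )

    genome = AnnotatedGenome(config.chrom_lengths, records)
    return genome, truth


# --------------------------------------------------------------------------
# read simulation
# --------------------------------------------------------------------------


def _locus_reads(
    iv: GenomicInterval,
    n: int,
    chrom_len: int,
    rng: np.random.Generator,
    read_len: int,
    anchor_frac: float,
    trim: int,
    sample_id: Optional[str],
) -> List[AlignedRead]:
    out: List[AlignedRead] = []
    if iv.strand == "+":
        five = iv.start + trim
        s_lo, s_hi = five, max(five, iv.end - read_len)
    else:
        e_eff = iv.end - trim
        s_anchor = max(0, e_eff - read_len)
        s_lo, s_hi = min(iv.start, s_anchor), s_anchor
    for _ in range(n):
        if rng.random() < anchor_frac:
            s = five if iv.strand == "+" else s_hi
        else:
            s = int(rng.integers(s_lo, s_hi + 1))
        s = max(0, min(s, chrom_len - read_len))
        out.append(
            AlignedRead(GenomicInterval(iv.chrom, s, s + read_len, iv.strand), 1, sample_id)
        )
    return out


def simulate_reads(
    genome: AnnotatedGenome,
    truth: GroundTruth,
    config: SimulationConfig,
    condition: str,
    rng: np.random.Generator,
) -> List[AlignedRead]:
    """Draw one condition's 36-nt read placements from the ground truth.

    Expected read counts per locus follow its (condition-scaled) target
    mean coverage; start positions are uniform within the locus with a
    small 5'-anchored fraction so that highly expressed transcripts reach
    their TSS.  A configured fraction of locus reads is multi-mapped,
    realised as explicit decoy placements inside repeat annotation with
    weight shared through ``n_hits``.
    """
    read_len = config.read_length
    repeats = [r.interval for r in genome.records_of("pseudogene_repeat")]
    reads: List[AlignedRead] = []

    def emit(iv: GenomicInterval, cov: float, trim: int, anchor: float) -> None:
        lam = cov * max(iv.length, read_len) / read_len
        n = int(rng.poisson(lam))
        if n == 0:
            return
        chrom_len = genome.chrom_lengths[iv.chrom]
        new = _locus_reads(iv, n, chrom_len, rng, read_len, anchor, trim, condition)
        if repeats and config.multi_map_fraction > 0:
            multi = rng.random(len(new)) < config.multi_map_fraction
            for i in np.flatnonzero(multi):
                n_hits = int(rng.integers(2, 4))
                prim = new[i]
                placements = [AlignedRead(prim.interval, n_hits, condition)]
                for _ in range(n_hits - 1):
                    rep = repeats[int(rng.integers(len(repeats)))]
                    s = int(rng.integers(rep.start, max(rep.start, rep.end - read_len) + 1))
                    strand = "+" if rng.random() < 0.5 else "-"
                    placements.append(
                        AlignedRead(
                            GenomicInterval(rep.chrom, s, s + read_len, strand), n_hits, condition
                        )
                    )
                new[i] = placements[0]
                new.extend(placements[1:])
        reads.extend(new)

    for lid, t in sorted(truth.known.items()):
        if not t.expressed:
            continue
        rec = next(r for r in genome.records if r.locus_id == lid)
        mult = condition_multiplier(condition, t.uv_fold, t.responsive)
        emit(rec.interval, t.base_coverage * mult, t.tss_trim, config.tss_anchor_fraction)

    for lid, t in sorted(truth.novel.items()):
        mult = condition_multiplier(condition, t.uv_fold, t.responsive)
        emit(t.interval, t.base_coverage * mult, 0, config.tss_anchor_fraction)

    # low-level mRNA background over exons (below the coverage cut-off)
    for rec in genome.records_of("exon"):
        emit(rec.interval, config.exon_coverage * config.depth_scale, 0, 0.0)

    # uniform background noise
    chroms = sorted(genome.chrom_lengths)
    lens = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    p = lens / lens.sum()
    for _ in range(config.n_background_reads):
        c = chroms[int(rng.choice(len(chroms), p=p))]
        s = int(rng.integers(0, genome.chrom_lengths[c] - read_len + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        reads.append(AlignedRead(GenomicInterval(c, s, s + read_len, strand), 1, condition))
    return reads


# --------------------------------------------------------------------------
# microarray / sequencing-proxy simulation
# --------------------------------------------------------------------------


def _probe_locus_truth(
    probe_iv: Optional[GenomicInterval], probe_id: str, truth: GroundTruth
) -> Tuple[float, bool]:
    """(uv_fold, responsive) of the locus a probe interrogates."""
    if probe_id in truth.known:
        t = truth.known[probe_id]
        return t.uv_fold, t.responsive
    if probe_iv is not None:
        best, best_ov = None, 0
        for t in truth.novel.values():
            if t.interval.strand != probe_iv.strand:
                continue
            ov = t.interval.overlap_length(probe_iv)
            if ov > best_ov:
                best, best_ov = t, ov
        if best is not None:
            return best.uv_fold, best.responsive
    return 1.0, False


def simulate_microarray(
    probes: Sequence[Tuple[str, Optional[GenomicInterval]]],
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    conditions: Sequence[str] = ARRAY_CONDITIONS,
) -> Tuple[ExpressionMatrix, SeqExpression]:
    """Log-normal intensities around the true per-condition expression.

    One array (``config.distorted_array``) receives an intensity-dependent
    log-scale distortion ``y -> (1 + c) * y`` to exercise rank-invariant
    normalization.  The returned sequencing proxy is derived from the same
    truth with independent noise, for the consistency criterion; probes on
    loci without sequencing expression get zero there.
    Fills ``truth.probe_responders``.
    """
    base_mu, base_sd = config.probe_baseline_log2
    rows_arr, rows_seq, index = [], [], []
    truth.probe_responders = {}
    for probe_id, iv in probes:
        fold, responsive = _probe_locus_truth(iv, probe_id, truth)
        if responsive:
            truth.probe_responders[probe_id] = fold
        if probe_id in truth.known:
            t = truth.known[probe_id]
            base = np.log2(max(t.base_coverage, 1.0)) + 4.0
            seq_expressed = t.expressed
            seq_base = np.log2(max(t.base_coverage, 1e-9))
        else:
            novel = None
            if iv is not None:
                for nt in truth.novel.values():
                    if nt.interval.strand == iv.strand and nt.interval.overlap_length(iv) > 0:
                        novel = nt
                        break
            if novel is not None:
                base = np.log2(novel.base_coverage) + 4.0
                seq_expressed, seq_base = True, np.log2(novel.base_coverage)
            else:
                base = rng.normal(base_mu, base_sd)
                seq_expressed, seq_base = False, 0.0
        arr_row, seq_row = [], []
        for cond in conditions:
            mult = condition_multiplier(cond, fold, responsive)
            y = base + np.log2(mult) + rng.normal(0.0, config.array_noise_sigma_log2)
            if cond == config.distorted_array:
                y = y * (1.0 + config.distortion_coef)
            arr_row.append(2.0 ** y)
            if cond in SEQ_CONDITIONS or cond in ("N2", "N2_UV"):
                if seq_expressed:
                    seq_row.append(
                        2.0 ** (seq_base + np.log2(mult) + rng.normal(0.0, config.seq_noise_sigma_log2))
                    )
                else:
                    seq_row.append(0.0)
        rows_arr.append(arr_row)
        rows_seq.append(seq_row)
        index.append(probe_id)
    seq_cols = [c for c in conditions if c in SEQ_CONDITIONS or c in ("N2", "N2_UV")]
    matrix = ExpressionMatrix(pd.DataFrame(rows_arr, index=index, columns=list(conditions)))
    seq = SeqExpression(pd.DataFrame(rows_seq, index=index, columns=seq_cols))
    return matrix, seq


def simulate_screen_matrix(
    rng: np.random.Generator,
    n_probes: int = 500,
    n_responders: int = 50,
    fold: float = 2.0,
    noise_sigma_log2: float = 0.15,
    seq_noise_sigma_log2: float = 0.25,
    up_fraction: float = 0.7,
    conditions: Sequence[str] = ARRAY_CONDITIONS,
) -> Tuple[ExpressionMatrix, SeqExpression, List[str]]:
    """Spike-in benchmark matrix: flat probes plus known UV responders.

    Responders change ``fold``-fold in both UV arrays (up or down); the
    sequencing proxy is concordant with independent noise.  Returns the
    raw matrix, the proxy and the responder probe ids.
    """
    ids = [f"p{i:04d}" for i in range(n_probes)]
    resp_idx = rng.choice(n_probes, size=n_responders, replace=False)
    responders = sorted(ids[i] for i in resp_idx)
    up = rng.random(n_probes) < up_fraction
    base = rng.normal(8.0, 1.5, size=n_probes)
    lfold = np.zeros(n_probes)
    lfold[resp_idx] = np.where(up[resp_idx], np.log2(fold), -np.log2(fold))
    arr = np.empty((n_probes, len(conditions)))
    for j, cond in enumerate(conditions):
        shift = lfold if cond.endswith("_UV") else 0.0
        arr[:, j] = 2.0 ** (base + shift + rng.normal(0.0, noise_sigma_log2, n_probes))
    seq_cols = ["N2", "N2_UV"]
    seq = np.empty((n_probes, 2))
    for j, cond in enumerate(seq_cols):
        shift = lfold if cond.endswith("_UV") else 0.0
        seq[:, j] = 2.0 ** (base + shift + rng.normal(0.0, seq_noise_sigma_log2, n_probes))
    return (
        ExpressionMatrix(pd.DataFrame(arr, index=ids, columns=list(conditions))),
        SeqExpression(pd.DataFrame(seq, index=ids, columns=seq_cols)),
        responders,
    )


# --------------------------------------------------------------------------
# qPCR and survival simulation
# --------------------------------------------------------------------------


def simulate_ct(
    truth: GroundTruth,
    config: SimulationConfig,
    rng: np.random.Generator,
    conditions: Sequence[str] = ARRAY_CONDITIONS,
    reference_id: str = "U6",
) -> pd.DataFrame:
    """Replicated Ct table for a few UV-responsive loci.

    Ct(target) = baseline - log2(relative expression) + Gaussian noise;
    the reference transcript is condition-independent.  True fold changes
    are recorded in ``truth.ct_folds``.
    """
    targets = truth.responsive_novel_ids()[: config.n_qpcr_targets]
    if len(targets) < config.n_qpcr_targets:
        targets += [
            lid for lid, t in sorted(truth.known.items()) if t.responsive
        ][: config.n_qpcr_targets - len(targets)]
    rows = []
    truth.ct_folds = {}
    for tid in targets:
        t = truth.novel[tid] if tid in truth.novel else truth.known[tid]
        truth.ct_folds[tid] = {}
        for cond in conditions:
            mult = condition_multiplier(cond, t.uv_fold, t.responsive)
            truth.ct_folds[tid][cond] = mult
            for rep in range(1, config.ct_replicates + 1):
                ct_t = config.ct_target_baseline - np.log2(mult) + rng.normal(0, config.ct_noise_sigma)
                ct_r = config.ct_reference_baseline + rng.normal(0, config.ct_noise_sigma)
                rows.append((tid, reference_id, cond, rep, float(ct_t), float(ct_r)))
    return pd.DataFrame(
        rows,
        columns=["target_id", "reference_id", "condition", "replicate", "ct_target", "ct_reference"],
    )


def logistic_survival(dose: float, d50: float, slope: float) -> float:
    return float(1.0 / (1.0 + np.exp((dose - d50) / slope)))


def simulate_survival(
    config: SimulationConfig,
    rng: np.random.Generator,
    knockdown_names: Optional[Sequence[str]] = None,
    record_truth: Optional[GroundTruth] = None,
) -> pd.DataFrame:
    """Binomial survival counts under a logistic dose-response.

    The control follows ``p(dose) = 1 / (1 + exp((dose - d50) / slope))``;
    each knockdown shifts ``d50`` by its configured amount (UV-sensitive
    knockdowns shift it down).  A shift of 0 simulates the null.
    """
    if knockdown_names is None:
        knockdown_names = [f"RNAi-kd{i+1}" for i in range(len(config.knockdown_d50_shifts))]
    if len(knockdown_names) != len(config.knockdown_d50_shifts):
        raise ValueError("knockdown names and d50 shifts differ in length")
    conds = [("RNAi-Empty", 0.0)] + list(zip(knockdown_names, config.knockdown_d50_shifts))
    rows = []
    probs: Dict[str, Dict[float, float]] = {}
    for name, shift in conds:
        probs[name] = {}
        for dose in config.survival_doses:
            p = logistic_survival(dose, config.survival_d50 + shift, config.survival_slope)
            probs[name][float(dose)] = p
            for rep in range(1, config.survival_replicates + 1):
                surv = int(rng.binomial(config.survival_animals, p))
                rows.append((name, float(dose), rep, surv, config.survival_animals - surv))
    if record_truth is not None:
        record_truth.survival_probs = probs
    return pd.DataFrame(
        rows, columns=["condition", "dose", "replicate", "n_survived", "n_arrested"]
    )
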