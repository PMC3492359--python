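"""Format readers and writers shared by all pipeline stages.

Internal coordinates are 0-based half-open; GFF3 (1-based closed) and
wiggle (1-based) are converted at these boundaries.  Every writer here
has a matching reader and round-trips its own output.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

import numpy as np
import pandas as pd
import pysam
from gffutils.iterators import DataIterator

from .annotation import (
    NCRNA_CLASSES,
    AnnotatedGenome,
    AnnotationRecord,
    GenomicInterval,
)
from .coverage import AlignedRead, CoverageTrack
from .transfrags import Transfrag

PathLike = Union[str, Path]


# -- aligned reads ---------------------------------------------------------


def read_sam_reads(path: PathLike, sample_id: Optional[str] = None) -> List[AlignedRead]:
    """Aligned reads from SAM; the NH tag supplies the hit count (default 1)."""
    out: List[AlignedRead] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped:
                continue
            n_hits = aln.get_tag("NH") if aln.has_tag("NH") else 1
            strand = "-" if aln.is_reverse else "+"
            iv = GenomicInterval(
                aln.reference_name, aln.reference_start, aln.reference_end, strand
            )
            out.append(AlignedRead(iv, int(n_hits), sample_id))
    return out


_READS_BED_COLS = ["chrom", "start", "end", "name", "score", "strand", "n_hits"]


def write_reads_bed(reads: Iterable[AlignedRead], path: PathLike) -> None:
    """BED6+1: the 7th column carries the hit count."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads):
            iv = r.interval
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\tread{i}\t0\t{iv.strand}\t{r.n_hits}\n"
            )


def read_reads_bed(path: PathLike, sample_id: Optional[str] = None) -> List[AlignedRead]:
    df = pd.read_csv(path, sep="\t", header=None, names=_READS_BED_COLS)
    return [
        AlignedRead(
            GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
            int(row.n_hits),
            sample_id,
        )
        for row in df.itertuples()
    ]


# -- wiggle ----------------------------------------------------------------


def write_wiggle(track: CoverageTrack, path: PathLike) -> None:
    """fixedStep (step 1) wiggle, one track line per strand, runs only."""
    with open(path, "w") as fh:
        last_strand = None
        for chrom, strand, arr in track.iter_tracks():
            if strand != last_strand:
                name = f"{track.sample_id or 'coverage'}|{strand}"
                fh.write(f'track type=wiggle_0 name="{name}"\n')
                last_strand = strand
            mask = arr > 0
            if not mask.any():
                continue
            padded = np.concatenate(([False], mask, [False]))
            diff = np.diff(padded.astype(np.int8))
            for s, e in zip(np.flatnonzero(diff == 1), np.flatnonzero(diff == -1)):
                fh.write(f"fixedStep chrom={chrom} start={s + 1} step=1\n")
                fh.write("".join(f"{v:.6g}\n" for v in arr[s:e]))


def read_wiggle(path: PathLike, chrom_lengths: Mapping[str, int]) -> CoverageTrack:
    track = CoverageTrack(chrom_lengths)
    strand = "+"
    arr: Optional[np.ndarray] = None
    pos = 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("track"):
                name = line.split('name="', 1)[1].rstrip('"')
                sample, strand = name.rsplit("|", 1)
                if track.sample_id is None:
                    track.sample_id = sample
            elif line.startswith("fixedStep"):
                fields = dict(kv.split("=") for kv in line.split()[1:])
                arr = track.array(fields["chrom"], strand)
                pos = int(fields["start"]) - 1
            else:
                assert arr is not None, "wiggle value before fixedStep header"
                arr[pos] = float(line)
                pos += 1
    return track


# -- annotation ------------------------------------------------------------

_GFF_TYPE_OF_CATEGORY = {"exon": "exon", "intron": "intron", "pseudogene_repeat": "repeat_region"}


def default_gff3_category_map() -> Dict[str, str]:
    """feature type -> category; ncRNA class names map to the ncRNA category."""
    m = {cls: "ncRNA" for cls in NCRNA_CLASSES}
    m.update(
        {
            "ncRNA": "ncRNA",
            "exon": "exon",
            "intron": "intron",
            "repeat_region": "pseudogene_repeat",
            "pseudogene": "pseudogene_repeat",
        }
    )
    return m


def write_annotation_gff3(genome: AnnotatedGenome, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom, n in sorted(genome.chrom_lengths.items()):
            fh.write(f"##sequence-region {chrom} 1 {n}\n")
        for rec in genome.records:
            iv = rec.interval
            ftype = rec.ncrna_class if rec.category == "ncRNA" else _GFF_TYPE_OF_CATEGORY[rec.category]
            attrs = f"ID={rec.locus_id}"
            fh.write(
                f"{iv.chrom}\tisncrna\t{ftype}\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )


def read_annotation_gff3(
    path: PathLike,
    category_map: Optional[Mapping[str, str]] = None,
    chrom_lengths: Optional[Mapping[str, int]] = None,
) -> AnnotatedGenome:
    """GFF3 -> AnnotatedGenome, converting to 0-based half-open.

    ``category_map`` maps feature types onto the four categories
    (unmapped types are skipped); chromosome lengths come from
    ``##sequence-region`` pragmas unless passed explicitly.
    """
    cmap = dict(category_map) if category_map is not None else default_gff3_category_map()
    it = DataIterator(str(path))
    features = list(it)
    lengths: Dict[str, int] = dict(chrom_lengths or {})
    for d in it.directives:
        if d.startswith("sequence-region"):
            _tag, chrom, _start, end = d.split()
            lengths.setdefault(chrom, int(end))
    if not lengths:
        raise ValueError("no chromosome lengths: supply chrom_lengths or ##sequence-region")
    records = []
    for f in features:
        if f.featuretype not in cmap:
            continue
        category = cmap[f.featuretype]
        ncrna_class = None
        if category == "ncRNA":
            if f.featuretype in NCRNA_CLASSES:
                ncrna_class = f.featuretype
            else:
                ncrna_class = f.attributes.get("ncrna_class", ["uncharacterized_is_ncRNA"])[0]
        locus_id = f.attributes.get("ID", [f"{f.seqid}:{f.start}-{f.end}"])[0]
        records.append(
            AnnotationRecord(
                GenomicInterval(f.seqid, f.start - 1, f.end, f.strand),
                category,
                locus_id,
                ncrna_class=ncrna_class,
            )
        )
    return AnnotatedGenome(lengths, records)


def write_annotation_bed(genome: AnnotatedGenome, path: PathLike) -> None:
    """BED6 with ``locus_id|category|ncrna_class`` in the name field."""
    with open(path, "w") as fh:
        for rec in genome.records:
            iv = rec.interval
            name = f"{rec.locus_id}|{rec.category}|{rec.ncrna_class or '.'}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_annotation_bed(path: PathLike, chrom_lengths: Mapping[str, int]) -> AnnotatedGenome:
    records = []
    with open(path) as fh:
        for line in fh:
            chrom, start, end, name, _score, strand = line.rstrip("\n").split("\t")
            locus_id, category, ncrna_class = name.split("|")
            records.append(
                AnnotationRecord(
                    GenomicInterval(chrom, int(start), int(end), strand),
                    category,
                    locus_id,
                    ncrna_class=None if ncrna_class == "." else ncrna_class,
                )
            )
    return AnnotatedGenome(chrom_lengths, records)


# -- transfrags ------------------------------------------------------------


def write_transfrags_bed(transfrags: Iterable[Transfrag], path: PathLike) -> None:
    """BED6 plus status, coverage statistics, samples and source interval."""
    with open(path, "w") as fh:
        for i, tf in enumerate(transfrags):
            iv = tf.interval
            src = tf.source_interval
            fh.write(
                "\t".join(
                    [
                        iv.chrom,
                        str(iv.start),
                        str(iv.end),
                        f"transfrag{i}",
                        "0",
                        iv.strand,
                        tf.status or ".",
                        f"{tf.mean_coverage:.6g}",
                        f"{tf.max_coverage:.6g}",
                        ",".join(tf.sample_ids) or ".",
                        f"{src.start}-{src.end}" if src is not None else ".",
                    ]
                )
                + "\n"
            )


def read_transfrags_bed(path: PathLike) -> List[Transfrag]:
    out: List[Transfrag] = []
    with open(path) as fh:
        for line in fh:
            (chrom, start, end, _name, _score, strand, status, mean_cov, max_cov, samples, src) = (
                line.rstrip("\n").split("\t")
            )
            iv = GenomicInterval(chrom, int(start), int(end), strand)
            src_iv = None
            if src != ".":
                s, e = src.split("-")
                src_iv = GenomicInterval(chrom, int(s), int(e), strand)
            out.append(
                Transfrag(
                    interval=iv,
                    mean_coverage=float(mean_cov),
                    max_coverage=float(max_cov),
                    sample_ids=tuple(samples.split(",")) if samples != "." else (),
                    status=None if status == "." else status,
                    source_interval=src_iv,
                )
            )
    return out
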