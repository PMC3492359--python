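import numpy as np
import pytest

from isncrna.annotation import AnnotatedGenome, AnnotationRecord, GenomicInterval
from isncrna.simulate import SimulationConfig


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def mini_genome():
    """Hand-built 1 kb + 0.5 kb genome with overlapping annotation layers.

    chrI: gene (exon [100,200) + intron [200,300) + exon [300,400)) on +,
    a snoRNA [240,290) inside the intron (+), an intergenic snRNA
    [500,560) on -, a repeat [600,700) on +.  chrII is empty.
    """
    records = [
        AnnotationRecord(GenomicInterval("chrI", 100, 200, "+"), "exon", "g1.e1"),
        AnnotationRecord(GenomicInterval("chrI", 200, 300, "+"), "intron", "g1.i1"),
        AnnotationRecord(GenomicInterval("chrI", 300, 400, "+"), "exon", "g1.e2"),
        AnnotationRecord(
            GenomicInterval("chrI", 240, 290, "+"), "ncRNA", "sno1", ncrna_class="snoRNA"
        ),
        AnnotationRecord(
            GenomicInterval("chrI", 500, 560, "-"), "ncRNA", "snr1", ncrna_class="snRNA"
        ),
        AnnotationRecord(GenomicInterval("chrI", 600, 700, "+"), "pseudogene_repeat", "rep1"),
    ]
    return AnnotatedGenome({"chrI": 1000, "chrII": 500}, records)


@pytest.fixture
def small_sim_config():
    """Scaled-down generator settings so simulation tests stay fast."""
    return SimulationConfig(
        chrom_lengths={"chrI": 300_000, "chrII": 200_000},
        ncrna_class_counts={
            "snoRNA": 8,
            "snRNA": 5,
            "tRNA": 20,
            "rRNA": 2,
            "sbRNA": 1,
            "scRNA": 1,
            "SL2": 1,
            "SmY": 1,
            "uncharacterized_is_ncRNA": 5,
            "21U-RNA": 10,
            "miRNA": 5,
        },
        n_coding_genes=12,
        n_repeats=8,
        n_novel_loci=12,
        n_background_reads=300,
    )


def brute_force_classify(records, precedence, pos):
    """Independent per-position classifier: scan every record."""
    cats = [
        rec.category
        for rec in records
        if rec.interval.start <= pos < rec.interval.end
    ]
    if not cats:
        return "intergenic"
    return min(cats, key=list(precedence).index)


def brute_force_runs(vector):
    """Independent run finder: linear scan accumulating coverage>0 runs."""
    runs = []
    start = None
    for i, v in enumerate(list(vector) + [0.0]):
        if v > 0 and start is None:
            start = i
        elif v <= 0 and start is not None:
            seg = vector[start:i]
            runs.append((start, i, float(np.mean(seg)), float(np.max(seg))))
            start = None
    return runs
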