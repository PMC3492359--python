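"""End-to-end orchestration: simulate or load inputs, discover novel
transcripts, screen for UV responders, quantify and test.

`run_pipeline` executes the stages in order -- coverage, transfrag
calling, novelty filtering, detection/TSS profiling, microarray
normalization (quantile and GRSN), the three-criterion screen and its
union, qPCR quantification, and survival statistics -- writing every
intermediate artifact when an output directory is given and returning a
JSON-serialisable run summary.  Any stage failure raises
:class:`PipelineError` labelled with the stage name; artifacts written by
earlier stages are retained.
"""

from __future__ import annotations

import dataclasses
import json
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import io as pio
from .annotation import IS_NCRNA_CLASSES, AnnotatedGenome, GenomicInterval
from .coverage import CoverageTrack, build_coverage, nucleotide_distribution, read_distribution
from .expression import ExpressionMatrix, SeqExpression
from .normalize import grsn_normalize, quantile_normalize
from .qpcr import ddct, relative_expression_frame
from .screen import (
    DEFAULT_PAIRS,
    candidates_frame,
    screen_candidates,
    union_candidates,
)
from .simulate import (
    SEQ_CONDITIONS,
    GroundTruth,
    SimulationConfig,
    simulate_ct,
    simulate_genome,
    simulate_microarray,
    simulate_reads,
    simulate_survival,
)
from .survival import paired_ttest, per_dose_tests, survival_curve
from .transfrags import (
    call_transfrags,
    detection_rate,
    filter_novel,
    merge_novel,
    tss_profile,
)


class PipelineError(RuntimeError):
    """A stage failed; the message is prefixed with the stage name."""


@contextmanager
def _stage(name: str):
    try:
        yield
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - deliberate re-labelling
        raise PipelineError(f"stage {name!r}: {exc}") from exc


@dataclass
class PipelineConfig:
    """All thresholds and paths of a run; unknown keys are rejected."""

    seed: int = 42
    out_dir: Optional[str] = None
    sim: SimulationConfig = field(default_factory=SimulationConfig)

    # discovery thresholds
    min_coverage: float = 6.0
    min_length: int = 36
    extend_to: int = 70
    coverage_stat: str = "mean"
    tss_coverage_min: float = 6.0

    # screening
    fc_threshold: float = 1.5
    cv_mode: str = "linear"
    grsn_invariant_fraction: float = 0.1
    pairs: Dict[str, Tuple[str, str]] = field(default_factory=lambda: dict(DEFAULT_PAIRS))
    consistency_strain: str = "N2"

    # quantification / survival
    calibrator_condition: str = "N2"
    survival_control: str = "RNAi-Empty"

    # optional external inputs (simulation fills whatever is absent)
    annotation_file: Optional[str] = None
    read_files: Dict[str, str] = field(default_factory=dict)
    matrix_file: Optional[str] = None
    seq_file: Optional[str] = None
    ct_file: Optional[str] = None
    survival_file: Optional[str] = None

    def __post_init__(self) -> None:
        for name in ("min_coverage", "min_length", "extend_to", "fc_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "sim" in data and isinstance(data["sim"], dict):
            sim_known = {f.name for f in dataclasses.fields(SimulationConfig)}
            sim_unknown = set(data["sim"]) - sim_known
            if sim_unknown:
                raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
            data["sim"] = SimulationConfig(**data["sim"])
        if "pairs" in data:
            data["pairs"] = {k: tuple(v) for k, v in data["pairs"].items()}
        return cls(**data)


def _load_reads(path: str, sample_id: str):
    if str(path).endswith(".sam"):
        return pio.read_sam_reads(path, sample_id)
    return pio.read_reads_bed(path, sample_id)


def _seq_expression_from_coverage(
    probes: List[Tuple[str, GenomicInterval]],
    tracks: Dict[str, CoverageTrack],
) -> SeqExpression:
    """RNA-Seq expression proxy: per-sample mean coverage over each probe."""
    rows = []
    conds = sorted(tracks)
    for _pid, iv in probes:
        row = []
        for c in conds:
            arr = tracks[c].array(iv.chrom, iv.strand)
            row.append(float(arr[iv.start : iv.end].mean()))
        rows.append(row)
    return SeqExpression(pd.DataFrame(rows, index=[p for p, _ in probes], columns=conds))


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; return the summary dict (also written as JSON)."""
    rng = np.random.default_rng(config.seed)
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": []}

    truth: Optional[GroundTruth] = None
    with _stage("genome"):
        if config.annotation_file:
            genome = pio.read_annotation_gff3(config.annotation_file)
        else:
            genome, truth = simulate_genome(config.sim, rng)
        summary["n_annotation_records"] = len(genome.records)
        summary["stages"].append("genome")
        if out:
            pio.write_annotation_gff3(genome, out / "annotation.gff3")

    with _stage("reads"):
        reads_by_cond = {}
        conditions = sorted(config.read_files) if config.read_files else list(SEQ_CONDITIONS)
        for cond in conditions:
            if config.read_files:
                reads_by_cond[cond] = _load_reads(config.read_files[cond], cond)
            else:
                reads_by_cond[cond] = simulate_reads(genome, truth, config.sim, cond, rng)
            if out and not config.read_files:
                pio.write_reads_bed(reads_by_cond[cond], out / f"reads_{cond}.bed")
        summary["n_reads"] = {c: len(r) for c, r in reads_by_cond.items()}
        summary["stages"].append("reads")

    with _stage("coverage"):
        tracks = {c: build_coverage(r, genome, sample_id=c) for c, r in reads_by_cond.items()}
        summary["coverage_mass"] = {c: t.total_mass() for c, t in tracks.items()}
        dist = {}
        for c in conditions:
            if reads_by_cond[c]:
                dist[c] = read_distribution(reads_by_cond[c], genome)
        summary["read_distribution"] = dist
        nt_dist = {}
        for c in conditions:
            if tracks[c].n_covered():
                nt_dist[c] = nucleotide_distribution(tracks[c], genome)
        summary["nucleotide_distribution"] = nt_dist
        summary["stages"].append("coverage")
        if out:
            for c, t in tracks.items():
                pio.write_wiggle(t, out / f"coverage_{c}.wig")

    with _stage("transfrags"):
        raw_by_cond = {c: call_transfrags(t) for c, t in tracks.items()}
        all_raw = [tf for tfs in raw_by_cond.values() for tf in tfs]
        summary["n_transfrags"] = {c: len(tfs) for c, tfs in raw_by_cond.items()}
        summary["stages"].append("transfrags")

    with _stage("detection"):
        report = detection_rate(all_raw, genome)
        summary["detection"] = report.frame.to_dict(orient="records")
        if out:
            report.frame.to_csv(out / "detection_report.tsv", sep="\t", index=False)
        summary["stages"].append("detection")

    with _stage("tss"):
        profile = tss_profile(all_raw, genome, coverage_min=config.tss_coverage_min)
        if not profile.frame.empty:
            summary["tss_covered_fraction"] = profile.covered_fraction
            summary["tss_n_loci"] = int(len(profile.frame))
            if out:
                profile.frame.to_csv(out / "tss_profile.tsv", sep="\t", index=False)
        summary["stages"].append("tss")

    with _stage("novelty-filter"):
        filtered_by_cond = {
            c: filter_novel(
                tfs,
                genome,
                min_coverage=config.min_coverage,
                min_length=config.min_length,
                extend_to=config.extend_to,
                coverage_stat=config.coverage_stat,
            )
            for c, tfs in raw_by_cond.items()
        }
        status_counts: Dict[str, int] = {}
        for tfs in filtered_by_cond.values():
            for tf in tfs:
                status_counts[tf.status] = status_counts.get(tf.status, 0) + 1
        novel = merge_novel(tf for tfs in filtered_by_cond.values() for tf in tfs)
        summary["filter_status_counts"] = status_counts
        summary["n_novel_transcripts"] = len(novel)
        summary["novel_by_strand"] = {
            s: sum(1 for tf in novel if tf.interval.strand == s) for s in "+-"
        }
        if out:
            pio.write_transfrags_bed(
                [tf for tfs in filtered_by_cond.values() for tf in tfs], out / "transfrags.bed"
            )
            pio.write_transfrags_bed(novel, out / "novel_transcripts.bed")
        summary["stages"].append("novelty-filter")

    with _stage("probes"):
        probes: List[Tuple[str, GenomicInterval]] = [
            (rec.locus_id, rec.interval) for rec in genome.ncrna_records(IS_NCRNA_CLASSES)
        ]
        probes += [(f"novelT{i:04d}", tf.interval) for i, tf in enumerate(novel)]
        summary["n_probes"] = len(probes)
        summary["stages"].append("probes")

    with _stage("microarray"):
        matrix = seq = None
        if config.matrix_file:
            matrix = ExpressionMatrix.from_tsv(config.matrix_file)
        elif truth is not None:
            matrix, _synthetic_seq = simulate_microarray(probes, truth, config.sim, rng)
        if config.seq_file:
            seq = SeqExpression.from_tsv(config.seq_file)
        else:
            seq = _seq_expression_from_coverage(probes, tracks)
        if out and matrix is not None:
            matrix.to_tsv(out / "microarray_raw.tsv")
            seq.to_tsv(out / "seq_expression.tsv")
        summary["stages"].append("microarray")

    candidates = []
    if matrix is not None:
        with _stage("screen"):
            em_q = quantile_normalize(matrix)
            em_g = grsn_normalize(matrix, invariant_fraction=config.grsn_invariant_fraction)
            rec_q = screen_candidates(
                em_q,
                seq,
                config.pairs,
                fc_threshold=config.fc_threshold,
                cv_mode=config.cv_mode,
                consistency_strain=config.consistency_strain,
                normalization_path="quantile",
            )
            rec_g = screen_candidates(
                em_g,
                seq,
                config.pairs,
                fc_threshold=config.fc_threshold,
                cv_mode=config.cv_mode,
                consistency_strain=config.consistency_strain,
                normalization_path="grsn",
            )
            candidates = union_candidates(rec_q, rec_g)
            n_q = sum(1 for r in rec_q if r.is_candidate)
            summary["n_candidates_quantile"] = n_q
            summary["n_candidates_grsn_extra"] = len(candidates) - n_q
            summary["n_candidates_union"] = len(candidates)
            summary["candidates"] = [c.probe_id for c in candidates]
            if out:
                candidates_frame(rec_q + rec_g).to_csv(out / "screen_records.tsv", sep="\t", index=False)
            summary["stages"].append("screen")

        if truth is not None:
            with _stage("recovery"):
                probe_iv = dict(probes)
                cand_ids = {c.probe_id for c in candidates}
                recovered = 0
                responsive = truth.responsive_novel_ids()
                for lid in responsive:
                    liv = truth.novel[lid].interval
                    hit = any(
                        probe_iv[pid].strand == liv.strand
                        and probe_iv[pid].overlap_length(liv) > 0
                        for pid in cand_ids
                        if pid in probe_iv
                    )
                    recovered += bool(hit)
                summary["n_responsive_novel_planted"] = len(responsive)
                summary["n_responsive_novel_recovered"] = recovered
                if responsive:
                    summary["responsive_novel_recall"] = recovered / len(responsive)
                summary["stages"].append("recovery")

    with _stage("qpcr"):
        ct = None
        if config.ct_file:
            ct = pd.read_csv(config.ct_file, sep="\t")
        elif truth is not None:
            ct = simulate_ct(truth, config.sim, rng)
        if ct is not None and not ct.empty:
            rel = ddct(ct, config.calibrator_condition)
            frame = relative_expression_frame(rel)
            summary["qpcr"] = frame.to_dict(orient="records")
            if out:
                ct.to_csv(out / "ct_table.tsv", sep="\t", index=False)
                frame.to_csv(out / "qpcr_report.tsv", sep="\t", index=False)
        summary["stages"].append("qpcr")

    with _stage("survival"):
        counts = None
        if config.survival_file:
            counts = pd.read_csv(config.survival_file, sep="\t")
        elif truth is not None:
            counts = simulate_survival(config.sim, rng, record_truth=truth)
        if counts is not None and not counts.empty:
            curve = survival_curve(counts)
            pvals = {}
            dose_pvals = {}
            for cond in curve.conditions():
                if cond == config.survival_control:
                    continue
                pvals[cond] = paired_ttest(curve, cond, config.survival_control)
                dose_pvals[cond] = per_dose_tests(curve, cond, config.survival_control)
            summary["survival_paired_p"] = pvals
            summary["survival_per_dose_p"] = dose_pvals
            if out:
                counts.to_csv(out / "survival_counts.tsv", sep="\t", index=False)
                curve.summary.to_csv(out / "survival_curve.tsv", sep="\t", index=False)
        summary["stages"].append("survival")

    if out:
        if truth is not None:
            truth.to_json(out / "ground_truth.json")
        (out / "summary.json").write_text(json.dumps(_jsonable(summary), indent=1))
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj
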