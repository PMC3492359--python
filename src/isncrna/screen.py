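"""Three-criterion screen for UV-responsive transcripts.

A probe becomes a candidate when, on a normalized matrix, all of:

(i)   its UV / untreated fold change is at least 1.5 in either direction
      in at least one strain pair,
(ii)  its coefficient of variation across all arrays exceeds the median
      CV of all probes, and
(iii) the direction of its UV response agrees between microarray and the
      sequencing expression proxy (wild-type pair by default; probes
      without sequencing signal fail).

The screen is run once under quantile and once under GRSN normalization;
the final candidate set is the union of the two paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .expression import STATE_RAW, ExpressionMatrix, SeqExpression

#: Default strain -> (untreated sample, UV sample) pairing: wild type and
#: the repair-deficient xpa-1 mutant, each before/after 100 J/m2 UV.
DEFAULT_PAIRS: Dict[str, Tuple[str, str]] = {
    "N2": ("N2", "N2_UV"),
    "xpa1": ("xpa1", "xpa1_UV"),
}

_FC_TOL = 1e-9  # protects the 'at least 1.5-fold' boundary from log round-trip error


@dataclass(slots=True)
class CandidateRecord:
    """Screening outcome for one probe under one normalization path."""

    probe_id: str
    fold_change_uv: Dict[str, float]  # strain -> linear UV/untreated ratio
    cv: float
    passed: Dict[str, bool]  # {'fc', 'cv', 'consistency'} -> bool
    normalization_path: str

    @property
    def is_candidate(self) -> bool:
        return all(self.passed.values())


def _check_pairs(sample_ids: Sequence[str], pairs: Mapping[str, Tuple[str, str]]) -> None:
    for strain, (unt, uv) in pairs.items():
        for s in (unt, uv):
            if s not in sample_ids:
                raise ValueError(f"pair for strain {strain!r} references missing sample {s!r}")


def screen_candidates(
    norm_matrix: ExpressionMatrix,
    seq_expr: SeqExpression,
    pairs: Mapping[str, Tuple[str, str]] = DEFAULT_PAIRS,
    *,
    fc_threshold: float = 1.5,
    cv_mode: str = "linear",
    consistency_strain: str = "N2",
    normalization_path: str = "quantile",
) -> List[CandidateRecord]:
    """Apply the fold-change / CV / consistency screen to every probe.

    ``norm_matrix`` must be normalized (log2 values).  CV is computed on
    the linear scale across all arrays by default (``cv_mode='log'``
    switches to log2 values).  The consistency direction is taken from
    ``consistency_strain``'s pair in both the array and sequencing data.
    """
    if norm_matrix.normalization_state == STATE_RAW:
        raise ValueError("screen requires a normalized matrix")
    if cv_mode not in ("linear", "log"):
        raise ValueError(f"cv_mode must be 'linear' or 'log', got {cv_mode!r}")
    if consistency_strain not in pairs:
        raise ValueError(f"consistency strain {consistency_strain!r} not in pairs")
    _check_pairs(norm_matrix.sample_ids, pairs)

    log_vals = norm_matrix.data
    lfc_thresh = math.log2(fc_threshold)

    lfc: Dict[str, pd.Series] = {}
    for strain, (unt, uv) in pairs.items():
        lfc[strain] = log_vals[uv] - log_vals[unt]
    fc_pass = pd.concat(
        [s.abs() >= lfc_thresh - _FC_TOL for s in lfc.values()], axis=1
    ).any(axis=1)

    scale = np.power(2.0, log_vals) if cv_mode == "linear" else log_vals
    cv = scale.std(axis=1, ddof=1) / scale.mean(axis=1)
    cv_pass = cv > cv.median()

    unt, uv = pairs[consistency_strain]
    arr_sign = np.sign(lfc[consistency_strain])
    seq_sign = pd.Series(0.0, index=log_vals.index)
    seq = seq_expr.data
    if unt in seq.columns and uv in seq.columns:
        common = log_vals.index.intersection(seq.index)
        eps = 1e-12
        s = np.sign(
            np.log2((seq.loc[common, uv] + eps) / (seq.loc[common, unt] + eps))
        )
        seq_sign.loc[common] = s
    cons_pass = (arr_sign == seq_sign) & (seq_sign != 0)

    out: List[CandidateRecord] = []
    for probe in log_vals.index:
        out.append(
            CandidateRecord(
                probe_id=probe,
                fold_change_uv={s: float(2.0 ** lfc[s].loc[probe]) for s in pairs},
                cv=float(cv.loc[probe]),
                passed={
                    "fc": bool(fc_pass.loc[probe]),
                    "cv": bool(cv_pass.loc[probe]),
                    "consistency": bool(cons_pass.loc[probe]),
                },
                normalization_path=normalization_path,
            )
        )
    return out


@dataclass(slots=True)
class UnionCandidate:
    probe_id: str
    paths: Tuple[str, ...]


def union_candidates(
    records_quantile: Iterable[CandidateRecord],
    records_grsn: Iterable[CandidateRecord],
) -> List[UnionCandidate]:
    """Union of the two normalization paths' candidate sets by probe id.

    Both screens must have been run on the same probe universe.
    """
    rq = list(records_quantile)
    rg = list(records_grsn)
    if {r.probe_id for r in rq} != {r.probe_id for r in rg}:
        raise ValueError("probe universes of the two screens differ")
    paths: Dict[str, List[str]] = {}
    for recs in (rq, rg):
        for r in recs:
            if r.is_candidate:
                paths.setdefault(r.probe_id, [])
                if r.normalization_path not in paths[r.probe_id]:
                    paths[r.probe_id].append(r.normalization_path)
    return [UnionCandidate(pid, tuple(p)) for pid, p in sorted(paths.items())]


def candidates_frame(records: Iterable[CandidateRecord]) -> pd.DataFrame:
    """Tabular per-criterion report for a screen run."""
    rows = []
    for r in records:
        row = {"probe_id": r.probe_id, "cv": r.cv, "path": r.normalization_path}
        for strain, fc in r.fold_change_uv.items():
            row[f"fc_{strain}"] = fc
        for crit, ok in r.passed.items():
            row[f"pass_{crit}"] = ok
        row["is_candidate"] = r.is_candidate
        rows.append(row)
    return pd.DataFrame(rows)
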