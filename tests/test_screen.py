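import math

import numpy as np
import pandas as pd
import pytest

from isncrna.expression import ExpressionMatrix, SeqExpression
from isncrna.normalize import quantile_normalize
from isncrna.screen import (
    DEFAULT_PAIRS,
    screen_candidates,
    union_candidates,
)
from isncrna.simulate import simulate_screen_matrix

SAMPLES = ["N2", "N2_UV", "xpa1", "xpa1_UV"]


def _norm_em(values, probes=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=probes, columns=SAMPLES),
        normalization_state="log2_quantile",
    )


def _seq(values, probes=None):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    return SeqExpression(pd.DataFrame(values, index=probes, columns=["N2", "N2_UV"]))


def test_flat_probe_fails_cv_criterion():
    lfc = math.log2(1.5)
    em = _norm_em([[5, 5, 5, 5], [5, 5 + 2 * lfc, 5, 5]])
    seq = _seq([[10, 10], [10, 30]])
    records = {r.probe_id: r for r in screen_candidates(em, seq)}
    assert records["p0"].cv == pytest.approx(0.0)
    assert not records["p0"].passed["cv"]
    assert not records["p0"].is_candidate


def test_exact_threshold_fold_change_is_a_candidate():
    """'At least 1.5-fold' includes the boundary itself."""
    lfc = math.log2(1.5)
    em = _norm_em([[5, 5 + lfc, 5, 5], [5, 5, 5, 5], [6, 6, 6, 6]])
    seq = _seq([[10, 20], [10, 10], [10, 10]])
    records = {r.probe_id: r for r in screen_candidates(em, seq)}
    assert records["p0"].passed["fc"]
    assert records["p0"].fold_change_uv["N2"] == pytest.approx(1.5)
    assert records["p0"].is_candidate


def test_downregulation_counts_too():
    lfc = math.log2(2.0)
    em = _norm_em([[5, 5 - lfc, 5, 5], [5, 5, 5, 5], [6, 6, 6, 6]])
    seq = _seq([[20, 5], [10, 10], [10, 10]])
    records = {r.probe_id: r for r in screen_candidates(em, seq)}
    assert records["p0"].is_candidate


def test_discordant_sequencing_direction_fails_consistency():
    lfc = math.log2(2.0)
    em = _norm_em([[5, 5 + lfc, 5, 5], [5, 5, 5, 5], [6, 6, 6, 6]])
    seq = _seq([[20, 5], [10, 10], [10, 10]])  # seq says down, array says up
    records = {r.probe_id: r for r in screen_candidates(em, seq)}
    assert not records["p0"].passed["consistency"]


def test_probe_absent_from_sequencing_fails_consistency():
    lfc = math.log2(2.0)
    em = _norm_em([[5, 5 + lfc, 5, 5], [5, 5, 5, 5], [6, 6, 6, 6]])
    seq = SeqExpression(pd.DataFrame([[10.0, 20.0]], index=["p1"], columns=["N2", "N2_UV"]))
    records = {r.probe_id: r for r in screen_candidates(em, seq)}
    assert not records["p0"].passed["consistency"]


def test_raising_threshold_never_grows_candidate_set(rng):
    em_raw, seq, _resp = simulate_screen_matrix(rng, n_probes=200, n_responders=20)
    em = quantile_normalize(em_raw)
    sets = []
    for fc in (1.2, 1.5, 2.0):
        recs = screen_candidates(em, seq, fc_threshold=fc)
        sets.append({r.probe_id for r in recs if r.is_candidate})
    assert sets[2] <= sets[1] <= sets[0]


def test_cv_criterion_splits_probes_in_half(rng):
    em_raw, seq, _resp = simulate_screen_matrix(rng, n_probes=101, n_responders=10)
    em = quantile_normalize(em_raw)
    recs = screen_candidates(em, seq)
    cvs = [r.cv for r in recs]
    assert len(set(cvs)) == len(cvs)  # all distinct in continuous noise
    n_above = sum(r.passed["cv"] for r in recs)
    assert n_above == 50  # (n - 1) / 2 for odd n


def test_spike_in_recovery(rng):
    hits, false = [], []
    for _ in range(3):
        em_raw, seq, responders = simulate_screen_matrix(rng)
        em = quantile_normalize(em_raw)
        cand = {r.probe_id for r in screen_candidates(em, seq) if r.is_candidate}
        hits.append(len(cand & set(responders)) / len(responders))
        false.append(len(cand - set(responders)))
    assert min(hits) >= 0.9
    assert max(false) <= 5


def test_config_errors(rng):
    em_raw, seq, _ = simulate_screen_matrix(rng, n_probes=50, n_responders=5)
    em = quantile_normalize(em_raw)
    with pytest.raises(ValueError, match="normalized"):
        screen_candidates(em_raw, seq)
    with pytest.raises(ValueError, match="missing sample"):
        screen_candidates(em, seq, pairs={"N2": ("N2", "nope")})
    with pytest.raises(ValueError, match="cv_mode"):
        screen_candidates(em, seq, cv_mode="weird")


class TestUnion:
    def _records(self, rng, n=30):
        em_raw, seq, _ = simulate_screen_matrix(rng, n_probes=n, n_responders=5)
        em = quantile_normalize(em_raw)
        return screen_candidates(em, seq, normalization_path="quantile")

    def test_disjoint_sets_add(self, rng):
        import copy

        recs = self._records(rng)
        ids = [r.probe_id for r in recs]
        # force disjoint candidate sets by editing the pass flags
        q = copy.deepcopy(recs)
        for r in q:
            r.passed = {k: r.probe_id in ids[:3] for k in r.passed}
        g = copy.deepcopy(recs)
        for r in g:
            r.normalization_path = "grsn"
            r.passed = {k: r.probe_id in ids[3:5] for k in r.passed}
        union = union_candidates(q, g)
        assert len(union) == 5
        paths = {u.probe_id: u.paths for u in union}
        assert paths[ids[0]] == ("quantile",)
        assert paths[ids[4]] == ("grsn",)

    def test_identical_and_empty_paths(self, rng):
        import copy

        recs = self._records(rng)
        union_same = union_candidates(recs, recs)
        assert {u.probe_id for u in union_same} == {
            r.probe_id for r in recs if r.is_candidate
        }
        empty = copy.deepcopy(recs)
        for r in empty:
            r.passed = {k: False for k in r.passed}
        union = union_candidates(recs, empty)
        assert {u.probe_id for u in union} == {r.probe_id for r in recs if r.is_candidate}

    def test_probe_universe_mismatch_rejected(self, rng):
        recs = self._records(rng)
        with pytest.raises(ValueError, match="universes"):
            union_candidates(recs, recs[:-1])
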