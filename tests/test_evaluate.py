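"""Evaluation layer: classification partition, matrices, TMB, Fisher test."""

import math

import numpy as np
import pytest
from scipy import stats

from simtk.evaluate import (
    ClassifiedCall,
    TP,
    caller_consideration_fraction,
    detection_matrix,
    fisher_exact,
    fn_causes,
    fp_rate_vs_expected_burden,
    match_calls,
    tmb_estimate,
    vaf_bias_report,
)
from simtk.naive_caller import CandidateCall
from simtk.truth_set import TruthRecord


def _call(pos, alt="A", alt_count=10, depth=100, filters=(), contig="chr1"):
    return CandidateCall(contig, pos, "C", alt, alt_count, depth, 0, depth, set(filters))


def _somatic(pos, alt="A", f=0.1, n_edited=5, contig="chr1"):
    return TruthRecord(
        contig, pos - 1, alt, "somatic_spike_in", 0,
        {"true_f": f, "n_edited": n_edited, "read_ids": [f"r{pos}i{j}" for j in range(n_edited)]},
    )


def test_empty_vcf_all_truth_are_fn():
    truth = [_somatic(10, n_edited=0), _somatic(20, n_edited=4)]
    classified = match_calls([], truth)
    assert [c.klass for c in classified] == ["no_alt_coverage", "not_emitted"]


def test_match_classification_partition():
    truth = [
        _somatic(10),  # TP
        _somatic(20),  # filtered
        _somatic(30, n_edited=0),  # no_alt_coverage
        _somatic(40),  # not_emitted
    ]
    damage = TruthRecord("chr1", 49, "T", "damage_artefact", None, {"channel": "A[C>T]A"})
    calls = [
        _call(10),
        _call(20, filters={"weak_evidence"}),
        _call(50, alt="T"),  # FP at the artefact site
        _call(60),  # FP with no truth: sequencing error
    ]
    classified = match_calls(calls, truth + [damage])
    by = {}
    for c in classified:
        by.setdefault(c.klass, 0)
        by[c.klass] += 1
    assert by == {
        "TP": 1,
        "filtered:weak_evidence": 1,
        "no_alt_coverage": 1,
        "not_emitted": 1,
        "FP_artefact": 1,
        "FP_error": 1,
    }
    # partition: |somatic truth| = TP + FN causes; |PASS| = TP + FP classes
    n_fn = sum(1 for c in classified if c.is_fn)
    assert len(truth) == by["TP"] + n_fn
    n_pass_calls = sum(1 for c in calls if c.passed)
    assert n_pass_calls == by["TP"] + by["FP_artefact"] + by["FP_error"]


def test_germline_fp_classification():
    germ = TruthRecord("chr1", 99, "G", "germline_snv", 0, {})
    classified = match_calls([_call(100, alt="G")], [germ])
    assert classified[0].klass == "FP_germline"


def test_misaligned_cause_priority():
    from simtk.truth_set import MisalignmentReport

    t = _somatic(20, n_edited=2)
    report = MisalignmentReport(set(t.metadata["read_ids"]), 10, 2, 0)
    classified = match_calls([], [t], misalignment=report)
    assert classified[0].klass == "misaligned"


def test_contig_mismatch_is_hard_error():
    with pytest.raises(ValueError, match="absent from truth"):
        match_calls([_call(10, contig="chrX")], [_somatic(10)])


def test_fn_cause_counts():
    truth = [_somatic(10, n_edited=0), _somatic(20), _somatic(30)]
    calls = [_call(20, filters={"weak_evidence", "min_alt_reads"})]
    counts = fn_causes(match_calls(calls, truth))
    assert counts == {"no_alt_coverage": 1, "filtered": 1, "not_emitted": 1}


# ---------------------------------------------------------------------------
# detection matrix


def test_detection_matrix_identity_when_all_detected():
    truth = [_somatic(10 * (i + 1), f=0.005 * i + 0.0026) for i in range(20)]
    calls = []
    classified = []
    for t in truth:
        c = _call(t.ref_pos + 1, alt_count=int(round(t.true_f * 100)), depth=100)
        classified.append(ClassifiedCall(TP, c, t))
    dm = detection_matrix(classified)
    assert dm.matrix.sum() == 20
    assert np.all(dm.burden[:20] == 1)
    assert np.nansum(dm.rates) == pytest.approx(20.0)
    # row sums conserve the per-bin burden
    assert np.array_equal(dm.matrix.sum(axis=1), dm.burden)


def test_detection_matrix_zero_pass():
    truth = [_somatic(10, f=0.12)]
    dm = detection_matrix(match_calls([], truth))
    assert dm.matrix[:, :-1].sum() == 0
    assert np.nansum(dm.rates) == 0.0


# ---------------------------------------------------------------------------
# TMB and burden arithmetic


def test_tmb_estimate_counts_pass_calls_above_threshold():
    classified = [
        ClassifiedCall(TP, _call(10, alt_count=6, depth=100), _somatic(10)),
        ClassifiedCall(TP, _call(20, alt_count=4, depth=100), _somatic(20)),
        ClassifiedCall("FP_error", _call(30, alt_count=9, depth=100), None),
    ]
    # two PASS calls at VAF >= 0.05 (0.06 and 0.09) on 2 Mb
    assert tmb_estimate(classified, 0.05, 2.0) == 1.0
    assert tmb_estimate([], 0.05, 2.0) == 0.0


def test_tmb_printed_arithmetic_645_on_76mb():
    classified = [
        ClassifiedCall(TP, _call(i + 1, alt_count=6, depth=100), _somatic(i + 1))
        for i in range(645)
    ]
    assert tmb_estimate(classified, 0.05, 76.0) == 8.49  # 645/76 to 2 dp


def test_fp_rate_vs_expected_burden_printed_values():
    assert fp_rate_vs_expected_burden(42, 2.7, 76.0) == (205, 20)
    assert fp_rate_vs_expected_burden(0, 2.7, 76.0) == (205, 0)
    expected, pct = fp_rate_vs_expected_burden(5, 0.0, 76.0)
    assert expected == 0 and pct is None


def test_caller_consideration_fraction():
    assert caller_consideration_fraction(11_283, 7_332_528) == 0.0015
    with pytest.raises(ValueError):
        caller_consideration_fraction(1, 0)


# ---------------------------------------------------------------------------
# VAF bias


def test_vaf_bias_unbiased_when_everything_passes():
    """Unconditional binomial mean: no detection threshold, no bias."""
    rng = np.random.default_rng(50)
    d, f0, n = 200, 0.035, 4000
    classified = [
        ClassifiedCall(TP, _call(i + 1, alt_count=int(x), depth=d), _somatic(i + 1, f=f0))
        for i, x in enumerate(rng.binomial(d, f0, n))
    ]
    rep = vaf_bias_report(classified, f0)
    se = math.sqrt(f0 * (1 - f0) / d / n)
    assert abs(rep["mean"] - f0) < 3 * se
    assert rep["n_pass"] == n


def test_vaf_bias_empty_report():
    rep = vaf_bias_report([ClassifiedCall("not_emitted", None, _somatic(10))], 0.035)
    assert rep["n_pass"] == 0 and rep["mean"] is None


# ---------------------------------------------------------------------------
# Fisher's exact test


def test_fisher_symmetric_table_shows_no_enrichment():
    # one-sided tail of a perfectly symmetric table: P(X >= observed)
    # includes the bulk of the hypergeometric mass, far from significance
    p = fisher_exact([[10, 10], [10, 10]])
    assert p > 0.5
    assert fisher_exact([[10, 10], [10, 10]], alternative="two-sided") == pytest.approx(1.0)


def test_fisher_printed_strand_table():
    p = fisher_exact([[4043, 126], [30, 12]])
    assert 4.5e-9 < p < 5.5e-9  # prints as 5e-09 to one significant figure


def test_fisher_zero_margin_convention():
    assert fisher_exact([[0, 0], [3, 4]]) == 1.0
    assert fisher_exact([[0, 5], [0, 2]]) == 1.0


def test_fisher_matches_exhaustive_enumeration():
    """Brute-force hypergeometric enumeration over all tables (margins <= 12)."""
    rng = np.random.default_rng(51)
    for _ in range(25):
        a, b, c, d = (int(x) for x in rng.integers(0, 7, 4))
        if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
            continue
        table = [[a, b], [c, d]]
        n, row1, col2 = a + b + c + d, a + b, b + d
        # one-sided (greater): tables with cell (1,1) >= observed d,
        # probability from the hypergeometric law with fixed margins
        p_brute = 0.0
        for dd in range(0, min(c + d, b + d) + 1):
            bb = col2 - dd
            aa = row1 - bb
            cc = n - row1 - dd
            if min(aa, bb, cc, dd) < 0:
                continue
            if dd >= d:
                p_brute += (
                    math.comb(row1, bb) * math.comb(n - row1, dd) / math.comb(n, col2)
                )
        assert fisher_exact(table) == pytest.approx(p_brute, rel=1e-9)
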