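"""Score a somatic caller's output against the comprehensive truth set.

Classification is a partition: every true somatic variant is exactly one
of TP or a false-negative cause (no alternate-read coverage, dropped
without a record, supporting reads misaligned, or filtered with a named
label), and every PASS call is exactly one of TP or a false-positive class
(sequencing error, damage artefact, germline).  On top of the
classification sit the summary analyses: per-semi-centile detection
matrix, filter attribution, inferred-VAF bias, tumour mutation burden and
the strand-evidence contingency of damage-artefact sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .naive_caller import CandidateCall, Pileup
from .spectrum import round_display, semi_centile_bins
from .truth_set import MisalignmentReport, TruthRecord

TP = "TP"
FP_ERROR = "FP_error"
FP_ARTEFACT = "FP_artefact"
FP_GERMLINE = "FP_germline"


@dataclass
class ClassifiedCall:
    """One classified event: a call, a truth record, or a matched pair."""

    klass: str  # TP, FP_*, or an FN cause ("no_alt_coverage", "not_emitted",
    # "misaligned", "filtered:<labels>")
    call: CandidateCall | None = None
    truth: TruthRecord | None = None

    @property
    def is_fn(self) -> bool:
        return self.klass not in (TP, FP_ERROR, FP_ARTEFACT, FP_GERMLINE)


def match_calls(
    calls: Sequence[CandidateCall],
    truth: Sequence[TruthRecord],
    tumour_pileup: Pileup | None = None,
    misalignment: MisalignmentReport | None = None,
) -> list[ClassifiedCall]:
    """Match calls to truth on (contig, pos, alt) and classify everything.

    False-negative cause priority: ``no_alt_coverage`` (zero alternate
    reads in the data) -> ``misaligned`` (alternate reads exist but all
    their supporting reads moved) -> ``filtered:<label>`` (record present,
    non-PASS) -> ``not_emitted`` (no record at all).
    """
    call_contigs = {c.contig for c in calls}
    truth_contigs = {t.contig for t in truth}
    if call_contigs and truth_contigs and not call_contigs <= truth_contigs:
        raise ValueError(
            f"VCF contigs {sorted(call_contigs - truth_contigs)} absent from truth"
        )
    by_key = {(c.contig, c.pos, c.alt): c for c in calls}
    somatic = [t for t in truth if t.source == "somatic_spike_in"]
    damage_keys = {
        (t.contig, t.ref_pos + 1, t.alt) for t in truth if t.source == "damage_artefact"
    }
    germ_keys = {
        (t.contig, t.ref_pos + 1, t.alt)
        for t in truth
        if t.source in ("germline_snv", "germline_indel")
    }
    germ_positions = {(k[0], k[1]) for k in germ_keys}
    out: list[ClassifiedCall] = []
    matched_tp_keys = set()
    for t in somatic:
        key = (t.contig, t.ref_pos + 1, t.alt)
        call = by_key.get(key)
        if call is not None and call.passed:
            out.append(ClassifiedCall(TP, call, t))
            matched_tp_keys.add(key)
            continue
        n_alt = t.metadata.get("n_edited", None)
        if tumour_pileup is not None:
            n_alt = tumour_pileup.base_count(t.contig, t.ref_pos, t.alt)
        if n_alt == 0:
            out.append(ClassifiedCall("no_alt_coverage", None, t))
        elif misalignment is not None and _all_support_misaligned(t, misalignment):
            out.append(ClassifiedCall("misaligned", None, t))
        elif call is not None:
            labels = ",".join(sorted(call.filters))
            out.append(ClassifiedCall(f"filtered:{labels}", call, t))
        else:
            out.append(ClassifiedCall("not_emitted", None, t))
    for call in calls:
        key = (call.contig, call.pos, call.alt)
        if not call.passed or key in matched_tp_keys:
            continue
        if key in damage_keys:
            out.append(ClassifiedCall(FP_ARTEFACT, call, None))
        elif key in germ_keys or (call.contig, call.pos) in germ_positions:
            out.append(ClassifiedCall(FP_GERMLINE, call, None))
        else:
            out.append(ClassifiedCall(FP_ERROR, call, None))
    return out


def _all_support_misaligned(t: TruthRecord, report: MisalignmentReport) -> bool:
    ids = t.metadata.get("read_ids", [])
    return bool(ids) and all(r in report.flagged_read_ids for r in ids)


@dataclass
class DetectionMatrix:
    """Detection per true-frequency semi-centile, with inferred-bin spread.

    ``matrix[i, j]`` counts variants with true frequency in semi-centile i
    detected with inferred frequency in semi-centile j; the last column is
    "not detected".  Row sums conserve the per-bin ground-truth burden.
    """

    matrix: np.ndarray  # (n_bins, n_bins + 1)
    burden: np.ndarray  # per true-bin totals
    rates: np.ndarray  # detected / burden per true bin (nan for empty bins)
    bins: list[tuple[float, float]]


def detection_matrix(classified: Sequence[ClassifiedCall], n_bins: int = 100) -> DetectionMatrix:
    bins = semi_centile_bins(n_bins)
    edges = np.linspace(0.0, 0.5, n_bins + 1)
    mat = np.zeros((n_bins, n_bins + 1), dtype=np.int64)
    for cc in classified:
        if cc.truth is None or cc.truth.true_f is None:
            continue
        i = min(int(np.searchsorted(edges, cc.truth.true_f, side="right")) - 1, n_bins - 1)
        i = max(i, 0)
        if cc.klass == TP:
            j = min(int(np.searchsorted(edges, cc.call.vaf, side="right")) - 1, n_bins - 1)
            j = max(j, 0)
            mat[i, j] += 1
        else:
            mat[i, n_bins] += 1
    burden = mat.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rates = np.where(burden > 0, mat[:, :n_bins].sum(axis=1) / np.maximum(burden, 1), np.nan)
    return DetectionMatrix(mat, burden, rates, bins)


def filter_attribution(classified: Sequence[ClassifiedCall]) -> dict[str, int]:
    """Count filtered false negatives by filter label."""
    counts: dict[str, int] = {}
    for cc in classified:
        if cc.is_fn and cc.klass.startswith("filtered:"):
            for label in cc.klass.split(":", 1)[1].split(","):
                counts[label] = counts.get(label, 0) + 1
    return counts


def fn_causes(classified: Sequence[ClassifiedCall]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for cc in classified:
        if cc.is_fn:
            key = "filtered" if cc.klass.startswith("filtered:") else cc.klass
            counts[key] = counts.get(key, 0) + 1
    return counts


def tmb_estimate(
    classified: Sequence[ClassifiedCall],
    threshold: float = 0.05,
    target_size_mb: float = 76.0,
) -> float:
    """Caller-facing TMB: PASS calls with inferred VAF >= threshold, per Mb."""
    if target_size_mb <= 0:
        raise ValueError("target size must be positive")
    n = sum(
        1
        for cc in classified
        if cc.call is not None and cc.call.passed and cc.call.vaf >= threshold
    )
    return round_display(n / target_size_mb, 2)


def vaf_bias_report(classified: Sequence[ClassifiedCall], f0: float) -> dict:
    """Inferred-VAF summary of PASS true positives against a point-mass truth."""
    vafs = np.array([cc.call.vaf for cc in classified if cc.klass == TP])
    if vafs.size == 0:
        return {"n_pass": 0, "mean": None, "median": None, "bias": None, "f0": f0}
    return {
        "n_pass": int(vafs.size),
        "mean": float(vafs.mean()),
        "median": float(np.median(vafs)),
        "bias": float(vafs.mean() - f0),
        "f0": f0,
    }


# ---------------------------------------------------------------------------
# strand-evidence analysis of damage-artefact sites


def strand_evidence_contingency(
    classified: Sequence[ClassifiedCall],
    truth: Sequence[TruthRecord],
    tumour_pileup: Pileup,
    calls: Sequence[CandidateCall] = (),
) -> np.ndarray:
    """2x2 table of artefact sites: rows TN vs FP, columns single vs both strand.

    Analysed sites are the damage-artefact truth sites that the caller
    emitted (any record): a site is a false positive if its call PASSed,
    a true negative if it was filtered.  A site has both-strand evidence
    when the alternate base is supported by reads of both fragment
    orientation classes.
    """
    by_key = {(c.contig, c.pos, c.alt): c for c in calls} if calls else {
        (cc.call.contig, cc.call.pos, cc.call.alt): cc.call
        for cc in classified
        if cc.call is not None
    }
    table = np.zeros((2, 2), dtype=np.int64)
    for t in truth:
        if t.source != "damage_artefact":
            continue
        call = by_key.get((t.contig, t.ref_pos + 1, t.alt))
        if call is None:
            continue  # never considered by the caller
        f1r2, f2r1 = tumour_pileup.orientation_counts(t.contig, t.ref_pos, t.alt)
        both = f1r2 > 0 and f2r1 > 0
        row = 1 if call.passed else 0  # FP row below TN row
        table[row, 1 if both else 0] += 1
    return table


def fisher_exact(table, alternative: str = "greater") -> float:
    """One-sided Fisher's exact test on a 2x2 strand-evidence table.

    With rows (TN, FP) and columns (single-strand, both-strand) the
    ``greater`` alternative tests enrichment of both-strand evidence among
    false positives.  All-zero margins give p = 1 by convention.  (For the
    archetypal table [[4043, 126], [30, 12]] the one- and two-sided values
    coincide to one significant figure; the lower tail mass is negligible.)
    """
    t = np.asarray(table, dtype=np.int64)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer cells")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative=alternative).pvalue)


def caller_consideration_fraction(n_considered: int, total_burden: int) -> float:
    """Fraction of a spiked burden the caller emitted any record for.

    Damage burdens are huge and mostly invisible to callers: only sites
    meeting the caller's emission threshold appear in the VCF at all (e.g.
    11 283 considered out of 7 332 528 spiked is 0.0015).  Displayed to 4
    decimals.
    """
    if total_burden <= 0:
        raise ValueError("total burden must be positive")
    return round_display(n_considered / total_burden, 4)


def fp_rate_vs_expected_burden(
    fp_count: int, median_tmb: float, target_size_mb: float
) -> tuple[int, float | None]:
    """Contextualise artefact false positives against an expected true burden.

    Returns (expected mutations, percentage): e.g. a median pan-cancer TMB
    of 2.7 mut/Mb on a 76 Mb target implies 205 expected true mutations, so
    42 artefact PASS calls amount to a 20% false-positive rate relative to
    that burden.  The companion quantity FP/(FP+TP) is reported separately
    by :func:`summarise` as ``precision_complement``.
    """
    if fp_count < 0 or median_tmb < 0 or target_size_mb < 0:
        raise ValueError("inputs must be non-negative")
    expected = int(round_display(median_tmb * target_size_mb, 0))
    if expected == 0:
        return 0, (0.0 if fp_count == 0 else None)
    return expected, round_display(100.0 * fp_count / expected, 0)


# ---------------------------------------------------------------------------
# report


@dataclass
class EvaluationReport:
    classified: list[ClassifiedCall]
    detection: DetectionMatrix
    filter_counts: dict[str, int]
    fn_cause_counts: dict[str, int]
    tmb: float
    vaf_summary: dict
    strand_table: np.ndarray | None = None
    fisher_p: float | None = None
    extras: dict = field(default_factory=dict)

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for cc in self.classified:
            key = cc.klass if not cc.klass.startswith("filtered:") else "filtered"
            counts[key] = counts.get(key, 0) + 1
        return counts

    def to_json(self, path=None) -> str:
        payload = {
            "class_counts": self.class_counts(),
            "fn_causes": self.fn_cause_counts,
            "filter_attribution": self.filter_counts,
            "tmb": self.tmb,
            "vaf_summary": self.vaf_summary,
            "detection_rates": [None if np.isnan(r) else float(r) for r in self.detection.rates],
            "strand_table": None if self.strand_table is None else self.strand_table.tolist(),
            "fisher_p": self.fisher_p,
            **self.extras,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def summarise(
    calls: Sequence[CandidateCall],
    truth: Sequence[TruthRecord],
    tumour_pileup: Pileup | None = None,
    misalignment: MisalignmentReport | None = None,
    *,
    target_size_mb: float,
    tmb_threshold: float = 0.05,
    point_mass_f0: float | None = None,
    n_bins: int = 100,
) -> EvaluationReport:
    """Full evaluation of one caller run against one truth set."""
    classified = match_calls(calls, truth, tumour_pileup, misalignment)
    det = detection_matrix(classified, n_bins)
    report = EvaluationReport(
        classified=classified,
        detection=det,
        filter_counts=filter_attribution(classified),
        fn_cause_counts=fn_causes(classified),
        tmb=tmb_estimate(classified, tmb_threshold, target_size_mb),
        vaf_summary=vaf_bias_report(classified, point_mass_f0) if point_mass_f0 else {},
    )
    n_tp = sum(1 for cc in classified if cc.klass == TP)
    n_fp = sum(1 for cc in classified if cc.klass in (FP_ERROR, FP_ARTEFACT, FP_GERMLINE))
    report.extras["n_tp"] = n_tp
    report.extras["n_fp"] = n_fp
    if n_tp + n_fp:
        report.extras["precision_complement"] = n_fp / (n_tp + n_fp)
    damage_truth = [t for t in truth if t.source == "damage_artefact"]
    if damage_truth:
        call_keys = {(c.contig, c.pos, c.alt) for c in calls}
        n_considered = sum(
            1 for t in damage_truth if (t.contig, t.ref_pos + 1, t.alt) in call_keys
        )
        report.extras["artefact_considered_fraction"] = caller_consideration_fraction(
            n_considered, len(damage_truth)
        )
        if tumour_pileup is not None:
            table = strand_evidence_contingency(classified, truth, tumour_pileup, calls)
            report.strand_table = table
            report.fisher_p = fisher_exact(table)
    return report


def plot_vaf_histogram(
    classified: Sequence[ClassifiedCall],
    path,
    true_frequencies=None,
    bins: int = 50,
) -> None:
    """Inferred-VAF histogram of PASS calls with the ground truth overlaid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    vafs = [cc.call.vaf for cc in classified if cc.klass == TP]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.hist(vafs, bins=bins, range=(0, 0.6), alpha=0.7, label="PASS calls (inferred VAF)")
    if true_frequencies is not None:
        ax.hist(
            list(true_frequencies), bins=bins, range=(0, 0.6), histtype="step",
            color="k", label="ground truth",
        )
    ax.set_xlabel("variant allele frequency")
    ax.set_ylabel("variants")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
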