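"""A minimal tumour-normal somatic SNV caller used as a test surrogate.

The caller scores each site by a one-sided binomial test of the alternate
count against the sequencing error rate and applies three filters modelled
on common somatic-caller behaviour: ``min_alt_reads`` (too few alternate
reads), ``weak_evidence`` (the binomial test does not reject),
``normal_artifact`` (alternate evidence in the matched normal) and
``clustered_events`` (too many candidates in a small window).  It is
deliberately simple — just enough statistical structure to exhibit the
detection-rate and conditional VAF-bias phenomena of real callers — and its
detection rule is exactly enumerable, which the tests exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pysam
from scipy import stats

from .phased_genome import PhasedGenome
from .read_sim import F1R2, SimFragment

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

FILTER_LABELS = ("weak_evidence", "normal_artifact", "min_alt_reads", "clustered_events")


@dataclass
class CallerParams:
    """Tunables of the naive caller.

    error_rate
        Assumed per-base miscall probability under the null (default 1e-3).
    alpha
        Significance level of the one-sided binomial test (default 0.01).
    min_alt
        Minimum alternate reads for a PASS-eligible call, k (default 3).
    min_emit
        Minimum alternate reads for a site to appear in the VCF at all
        (default 2); sites below this are dropped without record.
    normal_threshold
        Alternate reads of the same base in the normal at or above which
        ``normal_artifact`` is applied (default 2).
    cluster_window
        Candidates with more than two emitted candidates within this many
        bases are flagged ``clustered_events`` (default 100).
    """

    error_rate: float = 1e-3
    alpha: float = 0.01
    min_alt: int = 3
    min_emit: int = 2
    normal_threshold: int = 2
    cluster_window: int = 100


@dataclass
class CandidateCall:
    contig: str
    pos: int  # 1-based reference coordinate
    ref: str
    alt: str
    alt_count: int
    depth: int
    normal_alt: int
    normal_depth: int
    filters: set[str] = field(default_factory=set)

    @property
    def vaf(self) -> float:
        return self.alt_count / self.depth if self.depth else 0.0

    @property
    def passed(self) -> bool:
        return not self.filters


class Pileup:
    """Reference-space base counts, by base and fragment orientation."""

    def __init__(self, genome: PhasedGenome):
        self.genome = genome
        self.counts = {
            c: np.zeros((genome.contig_length(c), 4), dtype=np.int32) for c in genome.contigs
        }
        # [pos, base, orientation class (0=F1R2, 1=F2R1)]
        self.orient = {
            c: np.zeros((genome.contig_length(c), 4, 2), dtype=np.int32) for c in genome.contigs
        }

    def add_fragments(self, fragments: Sequence[SimFragment]) -> "Pileup":
        for frag in fragments:
            oi = 0 if frag.orientation == F1R2 else 1
            for read in frag.reads:
                hmap = self.genome.hap_to_ref_map[read.hap][read.contig][read.start : read.end]
                codes = _CODE[np.frombuffer(bytes(read.seq), dtype=np.uint8)]
                ok = (hmap >= 0) & (codes < 4)
                np.add.at(self.counts[read.contig], (hmap[ok], codes[ok]), 1)
                np.add.at(self.orient[read.contig], (hmap[ok], codes[ok], oi), 1)
        return self

    def depth(self, contig: str, ref_pos: int) -> int:
        return int(self.counts[contig][ref_pos].sum())

    def base_count(self, contig: str, ref_pos: int, base: str) -> int:
        return int(self.counts[contig][ref_pos, _CODE[ord(base)]])

    def orientation_counts(self, contig: str, ref_pos: int, base: str) -> tuple[int, int]:
        """(F1R2, F2R1) counts of a base at a site."""
        row = self.orient[contig][ref_pos, _CODE[ord(base)]]
        return int(row[0]), int(row[1])


def pileup_fragments(fragments: Sequence[SimFragment], genome: PhasedGenome) -> Pileup:
    return Pileup(genome).add_fragments(fragments)


def pass_threshold(depth: int, params: CallerParams) -> int:
    """Smallest alternate count that PASSes at this depth (clean normal).

    The caller's PASS rule for an unclustered site with no normal evidence
    reduces to ``alt >= t(depth)`` where t is this threshold: alt >= k and
    the one-sided binomial test rejects at alpha.  Exactly enumerable, so
    the detection probability and the conditional mean VAF of passed calls
    follow in closed form from the binomial distribution.
    """
    for x in range(params.min_alt, depth + 1):
        if stats.binom.sf(x - 1, depth, params.error_rate) < params.alpha:
            return x
    return depth + 1


def detection_probability(depth: int, f: float, params: CallerParams) -> float:
    """P(PASS) for a variant at true frequency f covered by ``depth`` reads."""
    t = pass_threshold(depth, params)
    return float(stats.binom.sf(t - 1, depth, f))


def conditional_mean_vaf(depth: int, f: float, params: CallerParams) -> float:
    """E[X/depth | X >= pass threshold] for X ~ Binomial(depth, f)."""
    t = pass_threshold(depth, params)
    x = np.arange(t, depth + 1)
    pmf = stats.binom.pmf(x, depth, f)
    total = pmf.sum()
    if total == 0:
        return float("nan")
    return float((x / depth) @ pmf / total)


def call_somatic(
    tumour: Pileup,
    normal: Pileup,
    params: CallerParams | None = None,
    target: Sequence[tuple[str, int, int]] | None = None,
) -> list[CandidateCall]:
    """Emit candidate somatic SNVs from matched tumour/normal pileups.

    A site is emitted when its best non-reference base has at least
    ``min_emit`` supporting reads; filters are then applied as described in
    :class:`CallerParams`.  PASS means no filters.  Zero-depth sites are
    never emitted.
    """
    params = params or CallerParams()
    genome = tumour.genome
    calls: list[CandidateCall] = []
    for contig in genome.contigs:
        counts = tumour.counts[contig]
        ref_codes = _CODE[np.frombuffer(genome.reference[contig].encode(), dtype=np.uint8)]
        alt_counts = counts.copy()
        pos_idx = np.arange(len(ref_codes))
        alt_counts[pos_idx, ref_codes] = 0
        best_alt = alt_counts.argmax(axis=1)
        best_count = alt_counts[pos_idx, best_alt]
        depth = counts.sum(axis=1)
        mask = best_count >= params.min_emit
        if target is not None:
            tmask = np.zeros(len(ref_codes), dtype=bool)
            for c, s, e in target:
                if c == contig:
                    tmask[s:e] = True
            mask &= tmask
        sites = np.nonzero(mask)[0]
        if sites.size == 0:
            continue
        pvals = stats.binom.sf(best_count[sites] - 1, depth[sites], params.error_rate)
        ncounts = normal.counts[contig]
        for p0, pval in zip(sites, pvals):
            alt_base = "ACGT"[best_alt[p0]]
            call = CandidateCall(
                contig=contig,
                pos=int(p0) + 1,
                ref="ACGT"[ref_codes[p0]],
                alt=alt_base,
                alt_count=int(best_count[p0]),
                depth=int(depth[p0]),
                normal_alt=int(ncounts[p0, best_alt[p0]]),
                normal_depth=int(ncounts[p0].sum()),
            )
            if call.alt_count < params.min_alt:
                call.filters.add("min_alt_reads")
            if pval >= params.alpha:
                call.filters.add("weak_evidence")
            if call.normal_alt >= params.normal_threshold:
                call.filters.add("normal_artifact")
            calls.append(call)
        # clustered_events over emitted candidates of this contig
        cpos = np.array([c.pos for c in calls if c.contig == contig])
        for call in calls:
            if call.contig != contig:
                continue
            near = np.count_nonzero(np.abs(cpos - call.pos) <= params.cluster_window)
            if near > 2:
                call.filters.add("clustered_events")
    return calls


# ---------------------------------------------------------------------------
# VCF I/O


def write_calls_vcf(
    calls: Sequence[CandidateCall], genome: PhasedGenome, path: str | Path
) -> None:
    header = pysam.VariantHeader()
    for label, desc in (
        ("weak_evidence", "Binomial test vs sequencing error not significant"),
        ("normal_artifact", "Alternate evidence in the matched normal"),
        ("min_alt_reads", "Fewer alternate reads than required"),
        ("clustered_events", "Too many candidates within the cluster window"),
    ):
        header.filters.add(label, None, None, desc)
    header.add_line('##INFO=<ID=DP,Number=1,Type=Integer,Description="Tumour depth">')
    header.add_line('##INFO=<ID=AC,Number=1,Type=Integer,Description="Tumour alt read count">')
    header.add_line('##INFO=<ID=AF,Number=1,Type=Float,Description="Inferred allele frequency">')
    header.add_line('##INFO=<ID=NAC,Number=1,Type=Integer,Description="Normal alt read count">')
    for contig in genome.contigs:
        header.contigs.add(contig, length=genome.contig_length(contig))
    order = {c: i for i, c in enumerate(genome.contigs)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in sorted(calls, key=lambda c: (order[c.contig], c.pos)):
            rec = out.new_record(
                contig=call.contig, start=call.pos - 1, alleles=(call.ref, call.alt)
            )
            rec.info["DP"] = call.depth
            rec.info["AC"] = call.alt_count
            rec.info["AF"] = call.vaf
            rec.info["NAC"] = call.normal_alt
            if call.filters:
                for f in sorted(call.filters):
                    rec.filter.add(f)
            else:
                rec.filter.add("PASS")
            out.write(rec)


def read_calls_vcf(path: str | Path) -> list[CandidateCall]:
    """Load any caller's VCF (FILTER column semantics) into CandidateCalls."""
    calls = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            filters = {f for f in rec.filter.keys() if f != "PASS"}
            depth = int(rec.info.get("DP", 0))
            ac = int(rec.info.get("AC", 0))
            if "AF" in rec.info and depth == 0:
                af = rec.info["AF"]
                af = float(af[0] if isinstance(af, tuple) else af)
            calls.append(
                CandidateCall(
                    rec.contig, rec.pos, rec.ref, rec.alts[0],
                    ac, depth, int(rec.info.get("NAC", 0)), 0, filters,
                )
            )
    return calls
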