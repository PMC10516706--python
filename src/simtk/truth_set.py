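"""The comprehensive truth set: every non-reference base has one source.

Attribution categories: germline SNV/indel (haplotype differs from the
reference by construction), somatic spike-in, DNA-damage artefact and
sequencing error.  On internally generated data the attribution must be a
partition — an unattributed mismatch is a truth leak and a hard failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import pysam

from .phased_genome import HAPLOTYPE_NAMES, PhasedGenome
from .read_sim import ErrorLog, SimFragment, SimRead, split_hap_contig_name

logger = logging.getLogger(__name__)

SOURCES = (
    "germline_snv",
    "germline_indel",
    "somatic_spike_in",
    "damage_artefact",
    "sequencing_error",
)

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
    _CODE[_b + 32] = _i


@dataclass
class TruthRecord:
    """One truth entry: a (position, alt) pair with its single source.

    ``ref_pos`` is 0-based reference coordinate.  ``metadata`` carries the
    per-source payload: ``true_f``/``n_overlapping``/``n_edited``/
    ``read_ids`` for somatic spike-ins, ``channel``/``orientation``/``vaf``
    for damage artefacts, ``read_id`` for per-read sequencing errors.
    A record with zero supporting reads is flagged ``unrepresented``.
    """

    contig: str
    ref_pos: int
    alt: str
    source: str
    hap: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.source not in SOURCES:
            raise ValueError(f"unknown truth source {self.source!r}")

    @property
    def unrepresented(self) -> bool:
        return self.metadata.get("n_edited", None) == 0

    @property
    def true_f(self) -> float | None:
        return self.metadata.get("true_f")


@dataclass
class MisalignmentReport:
    """Reads whose aligned position disagrees with their true-position tag."""

    flagged_read_ids: set
    n_reads: int
    n_flagged: int
    n_skipped: int  # reads without an XT tag
    per_variant: dict = field(default_factory=dict)  # (contig, ref_pos) -> count


def _germline_position_index(genome: PhasedGenome) -> dict[tuple[str, int], str]:
    """Map every reference position covered by a germline record to its kind."""
    idx: dict[tuple[str, int], str] = {}
    for v in genome.germline:
        kind = "germline_snv" if v.is_snv else "germline_indel"
        for p in range(v.pos - 1, v.pos - 1 + max(len(v.ref), 1)):
            idx[(v.contig, p)] = kind
    return idx


def _iter_reads(data) -> Iterable[SimRead]:
    for item in data:
        if isinstance(item, SimFragment):
            yield from item.reads
        else:
            yield item


def classify_mismatches(
    data: Sequence[SimFragment] | Sequence[SimRead] | str | Path,
    genome: PhasedGenome,
    truth: Sequence[TruthRecord],
    error_log: ErrorLog,
) -> tuple[dict[str, int], int, list]:
    """Attribute every read-base mismatch against the reference to a source.

    Returns ``(per-source totals, unattributed count, unattributed detail)``.
    Bases covering haplotype insertions (no reference image) are attributed
    ``germline_indel`` by construction.  The unattributed count must be 0 on
    internally generated data.
    """
    if isinstance(data, (str, Path)):
        from .read_sim import load_reads

        data = load_reads(data)

    germ_idx = _germline_position_index(genome)
    somatic_idx = {}
    damage_idx = {}
    for t in truth:
        if t.source == "somatic_spike_in":
            if t.metadata.get("mode") == "read_fraction":
                # read-fraction editing is haplotype-blind: match either
                somatic_idx[(t.contig, t.ref_pos, t.alt, 0)] = t
                somatic_idx[(t.contig, t.ref_pos, t.alt, 1)] = t
            else:
                somatic_idx[(t.contig, t.ref_pos, t.alt, t.hap)] = t
        elif t.source == "damage_artefact":
            damage_idx[(t.contig, t.ref_pos, t.alt)] = t

    ref_codes = {c: _CODE[np.frombuffer(s.encode(), dtype=np.uint8)] for c, s in genome.reference.items()}
    counts = {s: 0 for s in SOURCES}
    unattributed: list[tuple[str, str, int, str]] = []

    for read in _iter_reads(data):
        hmap = genome.hap_to_ref_map[read.hap][read.contig][read.start : read.end]
        codes = _CODE[np.frombuffer(bytes(read.seq), dtype=np.uint8)]
        inserted = hmap < 0
        for off in np.nonzero(inserted)[0]:
            # bases inside a haplotype insertion: germline indel by
            # construction unless the base call itself was an error
            if error_log.lookup(read.read_id, read.start + int(off)) is not None:
                counts["sequencing_error"] += 1
            else:
                counts["germline_indel"] += 1
        mapped = ~inserted
        rpos = hmap[mapped]
        mism = np.nonzero(ref_codes[read.contig][rpos] != codes[mapped])[0]
        if mism.size == 0:
            continue
        offsets = np.nonzero(mapped)[0][mism]
        hseq = genome.hap_seq[read.hap][read.contig]
        for off in offsets:
            hap_pos = read.start + int(off)
            ref_pos = int(hmap[off])
            obs = chr(read.seq[off])
            if error_log.lookup(read.read_id, hap_pos) is not None:
                counts["sequencing_error"] += 1
            elif (read.contig, ref_pos) in germ_idx and obs == hseq[hap_pos]:
                counts[germ_idx[(read.contig, ref_pos)]] += 1
            elif (read.contig, ref_pos, obs, read.hap) in somatic_idx:
                counts["somatic_spike_in"] += 1
            elif (read.contig, ref_pos, obs) in damage_idx:
                counts["damage_artefact"] += 1
            else:
                unattributed.append((read.read_id, read.contig, ref_pos, obs))
    return counts, len(unattributed), unattributed


# ---------------------------------------------------------------------------
# serialization


def write_truth(
    records: Sequence[TruthRecord],
    genome: PhasedGenome,
    vcf_path: str | Path,
    tsv_path: str | Path | None = None,
) -> None:
    """Write the truth set as a sorted VCF (sources in INFO) plus a TSV mirror.

    One record per (position, alt, source); duplicates are a hard error.
    INFO keys: SRC source, TF true frequency, CH signature channel, OR
    fragment-orientation class, HAP haplotype, NE edited-read count.
    """
    seen = set()
    for r in records:
        key = (r.contig, r.ref_pos, r.alt, r.source)
        if key in seen:
            raise ValueError(f"duplicate truth record {key}")
        seen.add(key)

    header = pysam.VariantHeader()
    header.add_line('##INFO=<ID=SRC,Number=1,Type=String,Description="Truth source category">')
    header.add_line('##INFO=<ID=TF,Number=1,Type=Float,Description="True allele frequency">')
    header.add_line('##INFO=<ID=CH,Number=1,Type=String,Description="Trinucleotide signature channel">')
    header.add_line('##INFO=<ID=OR,Number=1,Type=String,Description="Fragment orientation class">')
    header.add_line('##INFO=<ID=HAP,Number=1,Type=String,Description="Haplotype of origin">')
    header.add_line('##INFO=<ID=NE,Number=1,Type=Integer,Description="Number of edited reads">')
    for contig in genome.contigs:
        header.contigs.add(contig, length=genome.contig_length(contig))

    order = {c: i for i, c in enumerate(genome.contigs)}
    rows = []
    with pysam.VariantFile(str(vcf_path), "w", header=header) as out:
        for r in sorted(records, key=lambda r: (order[r.contig], r.ref_pos, r.alt, r.source)):
            rec = out.new_record(
                contig=r.contig,
                start=r.ref_pos,
                alleles=(genome.reference[r.contig][r.ref_pos], r.alt),
            )
            rec.info["SRC"] = r.source
            if r.true_f is not None:
                rec.info["TF"] = float(r.true_f)
            if "channel" in r.metadata:
                rec.info["CH"] = _encode_channel(r.metadata["channel"])
            if "orientation" in r.metadata:
                rec.info["OR"] = r.metadata["orientation"]
            if r.hap is not None:
                rec.info["HAP"] = HAPLOTYPE_NAMES[r.hap]
            if "n_edited" in r.metadata:
                rec.info["NE"] = int(r.metadata["n_edited"])
            out.write(rec)
            rows.append(
                {
                    "contig": r.contig,
                    "pos": r.ref_pos + 1,
                    "ref": genome.reference[r.contig][r.ref_pos],
                    "alt": r.alt,
                    "source": r.source,
                    "haplotype": HAPLOTYPE_NAMES[r.hap] if r.hap is not None else ".",
                    "true_f": r.true_f if r.true_f is not None else ".",
                    "channel": r.metadata.get("channel", "."),
                    "orientation": r.metadata.get("orientation", "."),
                    "n_edited": r.metadata.get("n_edited", "."),
                }
            )
    if tsv_path is not None:
        pd.DataFrame(rows).to_csv(tsv_path, sep="\t", index=False)


def _encode_channel(label: str) -> str:
    # VCF INFO strings may not contain '>'; store A[C>T]G as A.C.T.G
    return label.replace("[", ".").replace(">", ".").replace("]", ".")


def _decode_channel(enc: str) -> str:
    f5, ref, alt, f3 = enc.split(".")
    return f"{f5}[{ref}>{alt}]{f3}"


def read_truth(vcf_path: str | Path) -> list[TruthRecord]:
    """Round-trip loader for truth VCFs written by :func:`write_truth`."""
    out = []
    with pysam.VariantFile(str(vcf_path)) as vcf:
        for rec in vcf:
            meta: dict = {}
            if "TF" in rec.info:
                meta["true_f"] = float(rec.info["TF"])
            if "CH" in rec.info:
                meta["channel"] = _decode_channel(rec.info["CH"])
            if "OR" in rec.info:
                meta["orientation"] = rec.info["OR"]
            if "NE" in rec.info:
                meta["n_edited"] = int(rec.info["NE"])
            hap = None
            if "HAP" in rec.info:
                hap = HAPLOTYPE_NAMES.index(rec.info["HAP"])
            out.append(
                TruthRecord(rec.contig, rec.start, rec.alts[0], rec.info["SRC"], hap, meta)
            )
    return out


# ---------------------------------------------------------------------------
# post-realignment audit


def audit_alignment(
    bam: str | Path,
    genome: PhasedGenome | None = None,
    truth: Sequence[TruthRecord] | None = None,
) -> MisalignmentReport:
    """Flag reads whose aligned position differs from their XT tag.

    When ``genome`` is given and the BAM is in haplotype coordinates, the
    aligned start is lifted to reference space before the comparison, so
    the audit also works on BAMs that were realigned externally (where the
    position is already in reference space, pass ``genome=None``).
    """
    flagged = set()
    n_reads = n_skipped = 0
    spans: list[tuple[str, int, int, str]] = []
    with pysam.AlignmentFile(str(bam), check_sq=False) as fh:
        for a in fh:
            n_reads += 1
            if not a.has_tag("XT"):
                n_skipped += 1
                continue
            expected = int(a.get_tag("XT"))
            actual = a.reference_start
            contig = a.reference_name
            if genome is not None:
                contig, hap = split_hap_contig_name(a.reference_name)
                hmap = genome.hap_to_ref_map[hap][contig]
                seg = hmap[a.reference_start : a.reference_end or a.reference_start + 1]
                mapped = seg[seg >= 0]
                actual = int(mapped[0]) if mapped.size else -1
            if actual != expected:
                rid = f"{a.query_name}/{1 if a.is_read1 else 2}"
                flagged.add(rid)
                spans.append((contig, expected, expected + (a.query_length or 0), rid))
    per_variant: dict[tuple[str, int], int] = {}
    if truth is not None:
        for t in truth:
            n = sum(1 for c, s, e, _ in spans if c == t.contig and s <= t.ref_pos < e)
            if n:
                per_variant[(t.contig, t.ref_pos)] = n
    if n_skipped:
        logger.warning("alignment audit skipped %d reads without XT tags", n_skipped)
    return MisalignmentReport(flagged, n_reads, len(flagged), n_skipped, per_variant)
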