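"""Paired-end read simulation over a phased genome with a full error log.

Every fragment is one DNA molecule drawn from one haplotype.  Reads are
stored in forward-genome orientation (as SAM does); sequencing errors are
injected per cycle and every miscalled base is logged with its haplotype
and reference-lifted coordinate, so that downstream truth attribution can
account for literally every non-reference base.  Alignments are emitted in
haplotype-true coordinates (one SAM contig per haplotype) carrying tags for
haplotype of origin (``XH``), true reference-lifted start (``XT``) and
fragment orientation (``XO``).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .phased_genome import HAPLOTYPE_NAMES, PhasedGenome

logger = logging.getLogger(__name__)

F1R2 = "F1R2"  # first-in-pair sequenced off the forward genomic strand
F2R1 = "F2R1"

_BASES = b"ACGT"
_OTHER = {b: [x for x in _BASES if x != b] for b in _BASES}


@dataclass
class SimRead:
    """One read of a simulated fragment, in forward-genome orientation."""

    name: str
    contig: str
    hap: int
    start: int  # 0-based haplotype coordinate of leftmost aligned base
    seq: bytearray
    qual: np.ndarray  # uint8 Phred scores, genome orientation
    is_reverse: bool
    is_read1: bool

    @property
    def end(self) -> int:
        return self.start + len(self.seq)

    @property
    def read_id(self) -> str:
        return f"{self.name}/{1 if self.is_read1 else 2}"


@dataclass
class SimFragment:
    """A sequenced insert: two mates from one haplotype molecule."""

    name: str
    contig: str
    hap: int
    start: int  # haplotype coords, leftmost
    end: int
    orientation: str  # F1R2 or F2R1
    reads: tuple[SimRead, SimRead]

    def reads_covering(self, hap_pos: int) -> list[SimRead]:
        return [r for r in self.reads if r.start <= hap_pos < r.end]


@dataclass(frozen=True)
class ErrorEntry:
    read_id: str
    contig: str
    hap: int
    hap_pos: int
    ref_pos: int | None  # None when the errored base sits in an insertion
    true_base: str
    observed_base: str
    quality: int


@dataclass
class ErrorLog:
    """Complete record of simulated base-calling errors.

    One entry per miscalled base; spike-in editing removes entries whose
    base it overwrites, keeping the log in sync with the data.
    """

    entries: list[ErrorEntry] = field(default_factory=list)
    _index: dict[tuple[str, int], ErrorEntry] = field(default_factory=dict, repr=False)

    def add(self, entry: ErrorEntry) -> None:
        self.entries.append(entry)
        self._index[(entry.read_id, entry.hap_pos)] = entry

    def discard(self, read_id: str, hap_pos: int) -> None:
        entry = self._index.pop((read_id, hap_pos), None)
        if entry is not None:
            self.entries.remove(entry)

    def lookup(self, read_id: str, hap_pos: int) -> ErrorEntry | None:
        return self._index.get((read_id, hap_pos))

    def __len__(self) -> int:
        return len(self.entries)


def _as_rate_vector(error_rates, read_length: int) -> np.ndarray:
    rates = np.atleast_1d(np.asarray(error_rates, dtype=float))
    if rates.size == 1:
        rates = np.full(read_length, float(rates[0]))
    if rates.size != read_length:
        raise ValueError("per-cycle error-rate vector length must equal read length")
    if np.any((rates < 0) | (rates >= 1)):
        raise ValueError("error rates must lie in [0, 1)")
    return rates


def _phred(rates: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        q = np.where(rates > 0, -10.0 * np.log10(np.maximum(rates, 1e-10)), 42.0)
    return np.clip(np.rint(q), 2, 42).astype(np.uint8)


def _hap_interval(genome: PhasedGenome, hap: int, contig: str, start: int, end: int):
    """Lift a reference interval onto a haplotype (nearest mapped bounds)."""
    inv = genome.ref_to_hap_map[hap][contig]
    seg = inv[start:end]
    mapped = seg[seg >= 0]
    if mapped.size == 0:
        return None
    return int(mapped[0]), int(mapped[-1]) + 1


def simulate_fragments(
    genome: PhasedGenome,
    target: Sequence[tuple[str, int, int]],
    mean_depth: float,
    *,
    read_length: int = 100,
    insert_mean: float = 300.0,
    insert_sd: float = 30.0,
    error_rates: float | Sequence[float] = 1e-3,
    rng: np.random.Generator | int | None = None,
) -> tuple[list[SimFragment], ErrorLog]:
    """Draw fragments uniformly over the target to an expected mean depth.

    The target is given in reference coordinates and lifted per haplotype.
    Fragment counts are split evenly between the two haplotypes; the number
    of alternate-haplotype molecules sampled at any one site is therefore
    binomial, not fixed — depth is emergent, not exact.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = np.random.default_rng(rng)
    rates = _as_rate_vector(error_rates, read_length)
    quals = _phred(rates)

    fragments: list[SimFragment] = []
    error_log = ErrorLog()
    serial = 0
    for contig, rstart, rend in target:
        for hap in (0, 1):
            hiv = _hap_interval(genome, hap, contig, rstart, rend)
            if hiv is None:
                continue
            hstart, hend = hiv
            length = hend - hstart
            if length < read_length:
                logger.warning(
                    "target interval %s:%d-%d shorter than read length on %s; skipped",
                    contig, rstart, rend, HAPLOTYPE_NAMES[hap],
                )
                continue
            hseq = genome.hap_seq[hap][contig]
            span = max(1, length - int(insert_mean) + 1)
            n_frags = int(round(mean_depth * span / (2 * read_length) / 2))
            frag_lens = np.rint(rng.normal(insert_mean, insert_sd, n_frags)).astype(int)
            frag_lens = np.clip(frag_lens, read_length, length)
            starts = hstart + rng.integers(0, np.maximum(1, length - frag_lens + 1))
            forward = rng.random(n_frags) < 0.5
            for fl, fs, fwd in zip(frag_lens, starts, forward):
                serial += 1
                fragments.append(
                    _make_fragment(
                        f"sim{serial:08d}", genome, contig, hap, int(fs), int(fs + fl),
                        read_length, bool(fwd), hseq, rates, quals, rng, error_log,
                    )
                )
    return fragments, error_log


def _make_fragment(
    name, genome, contig, hap, fstart, fend, read_length,
    forward, hseq, rates, quals, rng, error_log,
) -> SimFragment:
    orientation = F1R2 if forward else F2R1
    left_is_read1 = forward
    reads = []
    for left in (True, False):
        rstart = fstart if left else fend - read_length
        is_read1 = left == left_is_read1
        is_reverse = not left  # right mate is sequenced off the reverse strand
        seq = bytearray(hseq[rstart : rstart + read_length], "ascii")
        qual = np.empty(read_length, dtype=np.uint8)
        # cycle c maps to genome offset c (forward) or L-1-c (reverse)
        offsets = np.arange(read_length) if not is_reverse else read_length - 1 - np.arange(read_length)
        qual[offsets] = quals
        read = SimRead(name, contig, hap, rstart, seq, qual, is_reverse, is_read1)
        err_cycles = np.nonzero(rng.random(read_length) < rates)[0]
        for cyc in err_cycles:
            off = int(offsets[cyc])
            true_base = chr(seq[off])
            obs = _OTHER[seq[off]][rng.integers(3)]
            seq[off] = obs
            hap_pos = rstart + off
            ref_pos = genome.hap_to_ref(hap, contig, hap_pos)
            error_log.add(
                ErrorEntry(
                    read.read_id, contig, hap, hap_pos, ref_pos,
                    true_base, chr(obs), int(quals[cyc]),
                )
            )
        reads.append(read)
    return SimFragment(name, contig, hap, fstart, fend, orientation, tuple(reads))


# ---------------------------------------------------------------------------
# SAM/BAM output in haplotype-true coordinates


def hap_contig_name(contig: str, hap: int) -> str:
    return f"{contig}_{HAPLOTYPE_NAMES[hap]}"


def split_hap_contig_name(name: str) -> tuple[str, int]:
    contig, _, hapname = name.rpartition("_")
    return contig, HAPLOTYPE_NAMES.index(hapname)


def make_header(genome: PhasedGenome) -> pysam.AlignmentHeader:
    refs = []
    for contig in genome.contigs:
        for hap in (0, 1):
            refs.append(
                {"SN": hap_contig_name(contig, hap), "LN": len(genome.hap_seq[hap][contig])}
            )
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": refs}
    )


def _true_ref_start(genome: PhasedGenome, read: SimRead) -> int:
    """Reference-lifted 0-based start (nearest mapped base at or after start)."""
    hmap = genome.hap_to_ref_map[read.hap][read.contig]
    seg = hmap[read.start : read.end]
    mapped = seg[seg >= 0]
    return int(mapped[0]) if mapped.size else -1


def write_alignments(
    fragments: Iterable[SimFragment],
    genome: PhasedGenome,
    path: str | Path,
) -> Path:
    """Write a coordinate-sorted SAM/BAM of properly paired records.

    Tags: ``XH`` haplotype name, ``XT`` true reference-lifted start
    (0-based), ``XO`` fragment orientation (F1R2/F2R1).
    """
    path = Path(path)
    header = make_header(genome)
    records = []
    for frag in fragments:
        mates = sorted(frag.reads, key=lambda r: r.start)
        for read, mate in ((mates[0], mates[1]), (mates[1], mates[0])):
            a = pysam.AlignedSegment(header)
            a.query_name = read.name
            a.query_sequence = read.seq.decode()
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in read.qual)
            )
            a.reference_name = hap_contig_name(read.contig, read.hap)
            a.reference_start = read.start
            a.cigarstring = f"{len(read.seq)}M"
            a.mapping_quality = 60
            flag = 0x1 | 0x2  # paired, proper pair
            flag |= 0x40 if read.is_read1 else 0x80
            if read.is_reverse:
                flag |= 0x10
            if mate.is_reverse:
                flag |= 0x20
            a.flag = flag
            a.next_reference_name = a.reference_name
            a.next_reference_start = mate.start
            tlen = frag.end - frag.start
            a.template_length = tlen if read.start <= mate.start else -tlen
            a.set_tag("XH", HAPLOTYPE_NAMES[read.hap])
            a.set_tag("XT", _true_ref_start(genome, read))
            a.set_tag("XO", frag.orientation)
            records.append(a)
    records.sort(key=lambda a: (a.reference_id, a.reference_start, a.query_name))
    mode = "wb" if path.suffix == ".bam" else "w"
    with pysam.AlignmentFile(str(path), mode, header=header) as out:
        for a in records:
            out.write(a)
    if path.suffix == ".bam":
        pysam.index(str(path))
    return path


def load_reads(path: str | Path) -> list[SimRead]:
    """Read haplotype-coordinate alignments back into :class:`SimRead` objects."""
    reads = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for a in fh:
            contig, hap = split_hap_contig_name(a.reference_name)
            reads.append(
                SimRead(
                    a.query_name, contig, hap, a.reference_start,
                    bytearray(a.query_sequence, "ascii"),
                    np.asarray(a.query_qualities, dtype=np.uint8),
                    a.is_reverse, a.is_read1,
                )
            )
    return reads


class FragmentIndex:
    """Overlap queries for fragments/reads at a haplotype position."""

    def __init__(self, fragments: Sequence[SimFragment]):
        self._by_key: dict[tuple[str, int], tuple[np.ndarray, np.ndarray, list[SimFragment]]] = {}
        buckets: dict[tuple[str, int], list[SimFragment]] = {}
        for frag in fragments:
            buckets.setdefault((frag.contig, frag.hap), []).append(frag)
        for key, frs in buckets.items():
            frs.sort(key=lambda f: f.start)
            starts = np.array([f.start for f in frs], dtype=np.int64)
            max_len = max(f.end - f.start for f in frs)
            self._by_key[key] = (starts, np.int64(max_len), frs)

    def overlapping(self, contig: str, hap: int, hap_pos: int) -> list[SimFragment]:
        entry = self._by_key.get((contig, hap))
        if entry is None:
            return []
        starts, max_len, frs = entry
        lo = int(np.searchsorted(starts, hap_pos - max_len, side="left"))
        hi = int(np.searchsorted(starts, hap_pos, side="right"))
        return [f for f in frs[lo:hi] if f.start <= hap_pos < f.end]
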