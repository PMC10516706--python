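"""Somatic SNV planning and read editing: stochastic or read-fraction.

The stochastic mode treats each sequenced fragment of the variant's
haplotype as an independent Bernoulli trial with success probability
min(2f, 1): the resulting alternate-read count at the locus is binomial, as
it is in real sequencing, and a low-frequency variant can legitimately
receive zero alternate reads.  The read-fraction mode emulates
deterministic spike-in tools (BAMSurgeon-style): it always edits exactly
round(f x depth) reads at the locus, so the alternate count is a fixed
function of local depth with zero sampling variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

import numpy as np

from .phased_genome import PhasedGenome
from .read_sim import ErrorLog, FragmentIndex, SimFragment, SimRead
from .truth_set import TruthRecord

logger = logging.getLogger(__name__)

STOCHASTIC = "stochastic"
READ_FRACTION = "read_fraction"

_ALT_CHOICES = {b: [x for x in "ACGT" if x != b] for b in "ACGT"}


@dataclass(frozen=True)
class SomaticVariant:
    """A planned somatic SNV with its ground-truth allele frequency.

    ``pos`` is 1-based reference coordinate; ``hap`` the haplotype carrying
    the mutation.  For a pure diploid sample ``true_f`` is at most 0.5
    (one haplotype of a diploid locus).
    """

    contig: str
    pos: int
    ref: str
    alt: str
    hap: int
    true_f: float
    mode: str = STOCHASTIC

    def __post_init__(self):
        if self.alt == self.ref:
            raise ValueError("alt must differ from ref")
        if not 0.0 <= self.true_f <= 1.0:
            raise ValueError("true_f must be in [0, 1]")


@dataclass
class SpikeResult:
    variant: SomaticVariant
    n_overlapping: int
    n_edited: int
    edited_read_ids: list[str] = field(default_factory=list)
    skipped: bool = False  # locus fell in a haplotype deletion
    truth: TruthRecord | None = None


def plan_variants(
    frequencies: Sequence[float],
    target: Sequence[tuple[str, int, int]],
    genome: PhasedGenome,
    rng: np.random.Generator | int | None = None,
    exclude: set[tuple[str, int]] | None = None,
    mode: str = STOCHASTIC,
) -> list[SomaticVariant]:
    """Assign each ground-truth frequency a locus, haplotype and alt base.

    Loci are drawn uniformly without replacement over the target; positions
    covered by germline records (including deletion spans) are excluded, so
    every planned locus exists on both haplotypes.  The haplotype is chosen
    uniformly and the alt base uniformly among the three non-reference
    bases.
    """
    rng = np.random.default_rng(rng)
    freqs = np.asarray(list(frequencies), dtype=float)
    excluded = set(exclude or ())
    for v in genome.germline:
        for p in range(v.pos - 1, v.pos - 1 + len(v.ref)):
            excluded.add((v.contig, p))

    pools = []
    keys = []
    for contig, start, end in target:
        pos = np.arange(start, end, dtype=np.int64)
        pools.append(pos)
        keys.extend([contig] * len(pos))
    if not pools:
        raise ValueError("target is empty")
    all_pos = np.concatenate(pools)
    all_contig = np.array(keys)
    ok = np.array(
        [(c, int(p)) not in excluded for c, p in zip(all_contig, all_pos)], dtype=bool
    )
    all_pos, all_contig = all_pos[ok], all_contig[ok]
    if len(freqs) > len(all_pos):
        raise ValueError(
            f"cannot place {len(freqs)} variants on {len(all_pos)} available loci"
        )
    pick = rng.choice(len(all_pos), size=len(freqs), replace=False)
    haps = rng.integers(0, 2, size=len(freqs))
    variants = []
    for i, (idx, hap, f) in enumerate(zip(pick, haps, freqs)):
        contig = str(all_contig[idx])
        p0 = int(all_pos[idx])
        ref = genome.reference[contig][p0]
        alt = _ALT_CHOICES[ref][rng.integers(3)]
        variants.append(SomaticVariant(contig, p0 + 1, ref, alt, int(hap), float(f), mode))
    return variants


def _edit_fragment(
    frag: SimFragment, hap_pos: int, alt: str, error_log: ErrorLog | None
) -> list[str]:
    """Write the alt base into both mates wherever they cover the locus."""
    edited = []
    for read in frag.reads_covering(hap_pos):
        _edit_read(read, hap_pos, alt, error_log)
        edited.append(read.read_id)
    return edited


def _edit_read(read: SimRead, hap_pos: int, alt: str, error_log: ErrorLog | None) -> None:
    read.seq[hap_pos - read.start] = ord(alt)
    if error_log is not None:
        # the molecule now truly carries the variant; a previously logged
        # miscall at this base no longer exists in the data
        error_log.discard(read.read_id, hap_pos)


def apply_stochastic(
    index: FragmentIndex,
    variant: SomaticVariant,
    genome: PhasedGenome,
    rng: np.random.Generator,
    error_log: ErrorLog | None = None,
) -> SpikeResult:
    """Per-fragment Bernoulli spike-in on the variant's haplotype.

    Each fragment of the chosen haplotype with at least one read covering
    the locus independently carries the alt with probability min(2f, 1);
    both mates of an edited fragment are edited consistently.  Base
    qualities are untouched.
    """
    hap_pos = genome.ref_to_hap(variant.hap, variant.contig, variant.pos - 1)
    if hap_pos is None:
        logger.warning(
            "somatic locus %s:%d falls in a deletion on haplotype %d; skipped",
            variant.contig, variant.pos, variant.hap,
        )
        return SpikeResult(variant, 0, 0, skipped=True)
    frags = [
        f
        for f in index.overlapping(variant.contig, variant.hap, hap_pos)
        if f.reads_covering(hap_pos)
    ]
    p = min(2.0 * variant.true_f, 1.0)
    edited_ids: list[str] = []
    n_edited = 0
    hits = rng.random(len(frags)) < p
    for frag, hit in zip(frags, hits):
        if hit:
            edited_ids.extend(_edit_fragment(frag, hap_pos, variant.alt, error_log))
            n_edited += 1
    truth = TruthRecord(
        variant.contig, variant.pos - 1, variant.alt, "somatic_spike_in", variant.hap,
        {
            "true_f": variant.true_f,
            "mode": STOCHASTIC,
            "n_overlapping": len(frags),
            "n_edited": n_edited,
            "read_ids": edited_ids,
        },
    )
    return SpikeResult(variant, len(frags), n_edited, edited_ids, truth=truth)


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal(1), rounding=ROUND_HALF_UP))


def apply_read_fraction(
    index: FragmentIndex,
    variant: SomaticVariant,
    genome: PhasedGenome,
    error_log: ErrorLog | None = None,
) -> SpikeResult:
    """Deterministic spike-in: exactly round(f x depth) alt reads, every run.

    Depth counts all reads covering the locus on both haplotypes; the
    edited reads are chosen in a fixed, reproducible order (leftmost read
    start, then read id), so repeated runs give identical alternate counts
    with zero sampling variance.
    """
    covering: list[tuple[int, str, SimRead]] = []
    for hap in (0, 1):
        hap_pos = genome.ref_to_hap(hap, variant.contig, variant.pos - 1)
        if hap_pos is None:
            continue
        for frag in index.overlapping(variant.contig, hap, hap_pos):
            for read in frag.reads_covering(hap_pos):
                covering.append((read.start, read.read_id, read))
    depth = len(covering)
    k = min(_round_half_up(variant.true_f * depth), depth)
    covering.sort(key=lambda t: (t[0], t[1]))
    edited_ids = []
    for _, rid, read in covering[:k]:
        hap_pos = genome.ref_to_hap(read.hap, variant.contig, variant.pos - 1)
        _edit_read(read, hap_pos, variant.alt, error_log)
        edited_ids.append(rid)
    if k == 0:
        logger.warning(
            "read-fraction variant %s:%d at f=%.4g, depth %d receives 0 alt reads",
            variant.contig, variant.pos, variant.true_f, depth,
        )
    truth = TruthRecord(
        variant.contig, variant.pos - 1, variant.alt, "somatic_spike_in", variant.hap,
        {
            "true_f": variant.true_f,
            "mode": READ_FRACTION,
            "n_overlapping": depth,
            "n_edited": k,
            "read_ids": edited_ids,
        },
    )
    return SpikeResult(variant, depth, k, edited_ids, truth=truth)


def spike_variants(
    fragments: Sequence[SimFragment],
    variants: Sequence[SomaticVariant],
    genome: PhasedGenome,
    rng: np.random.Generator | int | None = None,
    mode: str | None = None,
    error_log: ErrorLog | None = None,
) -> tuple[list[SpikeResult], list[TruthRecord]]:
    """Apply a full spike-in plan, returning per-variant results and truth."""
    rng = np.random.default_rng(rng)
    index = FragmentIndex(fragments)
    results = []
    truth = []
    for v in variants:
        vmode = mode or v.mode
        if vmode == STOCHASTIC:
            res = apply_stochastic(index, v, genome, rng, error_log)
        elif vmode == READ_FRACTION:
            res = apply_read_fraction(index, v, genome, error_log)
        else:
            raise ValueError(f"unknown spike mode {vmode!r}")
        results.append(res)
        if res.truth is not None:
            truth.append(res.truth)
    return results, truth
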