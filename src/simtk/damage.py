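"""96-channel SBS signatures and orientation-pure DNA-damage artefacts.

FFPE fixation deaminates cytosine (seen as C>T) and oxidative damage
produces 8-oxoguanine (G>T on the damaged strand, C>A in the
pyrimidine-centred convention).  Both affect one strand of the original
molecule, so all alternate evidence at an artefact site shares one fragment
orientation class (F1R2 or F2R1) — the signal orientation-bias filters look
for.  Artefact loci are drawn so each site's reference trinucleotide
context matches its signature channel, and edited with the same
per-fragment Bernoulli machinery as somatic spike-ins, restricted to one
orientation class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import pysam

from .phased_genome import PhasedGenome
from .read_sim import F1R2, F2R1, ErrorLog, FragmentIndex, SimFragment
from .truth_set import TruthRecord

logger = logging.getLogger(__name__)

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

#: canonical channel order: substitution-major, then 5' base, then 3' base
CHANNELS = tuple(
    f"{f5}[{sub}]{f3}" for sub in SUBSTITUTIONS for f5 in _BASES for f3 in _BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def channel_of(trinucleotide: str, alt: str) -> str:
    """Pyrimidine-centred channel of a substitution in its reference context.

    ``trinucleotide`` is the 5'-base, ref-base, 3'-base string on the
    reference strand; purine-centred substitutions are reverse-complemented
    into the C/T convention (a G>A at 5'-TGC-3' counts as C>T in G[C>T]A).
    """
    f5, ref, f3 = trinucleotide
    if ref in "GA":
        f5, ref, f3 = revcomp(trinucleotide)
        alt = alt.translate(_COMP)
    return f"{f5}[{ref}>{alt}]{f3}"


@dataclass
class SBSSignature:
    """Probability vector over the 96 trinucleotide substitution channels."""

    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (96,):
            raise ValueError("signature must have 96 channels")
        if np.any(p < 0):
            raise ValueError("signature weights must be non-negative")
        total = p.sum()
        if total <= 0:
            raise ValueError("signature weights must not all be zero")
        self.probs = p / total

    def __getitem__(self, channel: str) -> float:
        return float(self.probs[_CHANNEL_INDEX[channel]])

    def cosine(self, other: "SBSSignature") -> float:
        a, b = self.probs, other.probs
        return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))

    def sample_channels(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Multinomial channel counts for a burden of n artefacts."""
        return rng.multinomial(n, self.probs)

    @classmethod
    def uniform(cls) -> "SBSSignature":
        return cls(np.full(96, 1.0 / 96.0))

    @classmethod
    def from_counts(cls, counts) -> "SBSSignature":
        return cls(np.asarray(counts, dtype=float))


def estimate_sbs_signature(
    variants: Sequence[tuple[str, int, str, str]],
    reference,
) -> SBSSignature:
    """Estimate a signature from SNVs and their reference context.

    ``variants`` are (contig, 1-based position, ref, alt); ``reference`` is
    a {contig: sequence} mapping (or a PhasedGenome, whose reference is
    used).  Non-SNV records are skipped with a warning; an empty usable
    input is an error.
    """
    if isinstance(reference, PhasedGenome):
        reference = reference.reference
    counts = np.zeros(96)
    n_used = 0
    for contig, pos, ref, alt in variants:
        if len(ref) != 1 or len(alt) != 1:
            logger.warning("skipping non-SNV record %s:%d %s>%s", contig, pos, ref, alt)
            continue
        seq = reference[contig]
        if pos < 2 or pos > len(seq) - 1:
            logger.warning("skipping variant %s:%d without full context", contig, pos)
            continue
        tri = seq[pos - 2 : pos + 1]
        if tri[1] != ref:
            raise ValueError(f"ref mismatch at {contig}:{pos}: {tri[1]} != {ref}")
        counts[_CHANNEL_INDEX[channel_of(tri, alt)]] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError("no usable SNVs for signature estimation")
    return SBSSignature(counts)


def load_cosmic_signature(source: str | Path | pd.DataFrame, column: str | None = None) -> SBSSignature:
    """Load a 96-row COSMIC-format signature table (labels like ``A[C>A]A``).

    The first column holds the channel labels; ``column`` selects the
    signature column (default: the first numeric column).  Weights are
    renormalized; missing or duplicate channels are a hard error.
    """
    df = source if isinstance(source, pd.DataFrame) else pd.read_csv(source, sep="\t")
    labels = df.iloc[:, 0].astype(str)
    if column is None:
        numeric = df.select_dtypes("number")
        if numeric.shape[1] == 0:
            raise ValueError("no numeric signature column found")
        values = numeric.iloc[:, 0]
    else:
        values = df[column]
    if labels.duplicated().any():
        raise ValueError("duplicate channel labels in signature table")
    missing = set(CHANNELS) - set(labels)
    if missing:
        raise ValueError(f"signature table missing channels, e.g. {sorted(missing)[:3]}")
    probs = np.zeros(96)
    for label, value in zip(labels, values):
        probs[_CHANNEL_INDEX[label]] = float(value)
    return SBSSignature(probs)


# ---------------------------------------------------------------------------
# orientation partitioning


def fragment_orientation_of_alignment(read: pysam.AlignedSegment) -> str:
    """F1R2 iff the first-in-pair read aligns to the forward strand."""
    if read.is_read1:
        return F2R1 if read.is_reverse else F1R2
    return F1R2 if read.is_reverse else F2R1


def partition_by_orientation(reads):
    """Split fragments/reads into (forward-fragment, reverse-fragment) sets.

    Accepts :class:`SimFragment` collections or pysam alignments; every
    element lands in exactly one class.  Unpaired alignments are assigned
    by their own strand with a logged warning.
    """
    forward, reverse = [], []
    for item in reads:
        if isinstance(item, SimFragment):
            (forward if item.orientation == F1R2 else reverse).append(item)
        else:
            if not item.is_paired:
                logger.warning("unpaired read %s assigned by its own strand", item.query_name)
                (reverse if item.is_reverse else forward).append(item)
            else:
                (forward if fragment_orientation_of_alignment(item) == F1R2 else reverse).append(item)
    return forward, reverse


# ---------------------------------------------------------------------------
# damage planning and spike-in


def default_vaf_sampler(a: float = 1.5, b: float = 50.0) -> Callable:
    """Low-frequency Beta sampler for artefact allele fractions.

    Default Beta(1.5, 50), mean ~0.029: most artefact sites sit well below
    typical somatic calling thresholds, matching the observation that
    damage manifests as a high burden of low-frequency artefacts.
    """

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return rng.beta(a, b, size=n)

    return sample


def empirical_vaf_sampler(values) -> Callable:
    """Resampling sampler over an empirical list of artefact VAFs."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise ValueError("empirical VAF list is empty")

    def sample(rng: np.random.Generator, n: int) -> np.ndarray:
        return vals[rng.integers(0, vals.size, size=n)]

    return sample


@dataclass
class DamagePlan:
    """A target artefact burden with its signature and VAF distribution.

    The burden is split exactly in half (+-1) between the two fragment
    orientation classes; orientation per site follows the damaged-base
    chemistry (pyrimidine on the reference strand -> forward class).
    """

    total_burden: int
    signature: SBSSignature
    target: Sequence[tuple[str, int, int]]
    vaf_sampler: Callable = field(default_factory=default_vaf_sampler)
    max_rejections: int = 50

    def __post_init__(self):
        if self.total_burden < 0:
            raise ValueError("burden must be non-negative")


@dataclass(frozen=True)
class DamageSite:
    contig: str
    ref_pos: int  # 0-based
    ref: str
    alt: str
    channel: str
    orientation: str  # orientation class carrying the artefact


def _context_pools(
    genome: PhasedGenome, target: Sequence[tuple[str, int, int]]
) -> dict[tuple[str, int], list[tuple[str, np.ndarray]]]:
    """Candidate positions per (channel-context id, strand-class).

    Context id is the 32-way (pyrimidine center, 5', 3') class; strand 0
    means the pyrimidine sits on the reference strand (forward-class
    artefact), 1 the reverse.
    """
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(b"ACGT"):
        code[b] = i
    comp = np.array([3, 2, 1, 0], dtype=np.int8)
    pools: dict[tuple[int, int], list[tuple[str, np.ndarray]]] = {}
    for contig, start, end in target:
        seq = genome.reference[contig]
        arr = code[np.frombuffer(seq.encode(), dtype=np.uint8)]
        lo, hi = max(start, 1), min(end, len(seq) - 1)
        if hi <= lo:
            continue
        pos = np.arange(lo, hi)
        c5, c0, c3 = arr[pos - 1], arr[pos], arr[pos + 1]
        ok = (c5 >= 0) & (c0 >= 0) & (c3 >= 0)
        pos, c5, c0, c3 = pos[ok], c5[ok], c0[ok], c3[ok]
        is_pyr = (c0 == 1) | (c0 == 3)  # C or T
        # pyrimidine-convention context: center in {C:0, T:1}
        ctx = np.where(
            is_pyr,
            (c0 == 3) * 16 + c5 * 4 + c3,
            (c0 == 0) * 16 + comp[c3] * 4 + comp[c5],
        )
        strand = np.where(is_pyr, 0, 1)
        for cid in np.unique(ctx):
            for s in (0, 1):
                sel = pos[(ctx == cid) & (strand == s)]
                if sel.size:
                    pools.setdefault((int(cid), s), []).append((contig, sel))
    return pools


def _channel_context_id(channel: str) -> int:
    f5, rest = channel[0], channel[2:]
    ref, alt, f3 = rest[0], rest[2], rest[4]
    return (ref == "T") * 16 + _BASES.index(f5) * 4 + _BASES.index(f3)


def _channel_alt(channel: str, strand: int) -> str:
    alt = channel[4]
    return alt if strand == 0 else alt.translate(_COMP)


def plan_damage_sites(
    plan: DamagePlan,
    genome: PhasedGenome,
    rng: np.random.Generator,
    exclude: set[tuple[str, int]] | None = None,
) -> list[DamageSite]:
    """Draw context-matched artefact loci, half per orientation class.

    Rejection behaviour: a channel whose context pool is exhausted has its
    remaining count redistributed over the other channels (logged).
    """
    pools = _context_pools(genome, plan.target)
    excluded = set(exclude or ())
    # flatten pools into per-(channel ctx, strand) position arrays
    flat: dict[tuple[int, int], list[tuple[str, int]]] = {}
    for key, chunks in pools.items():
        entries = [
            (contig, int(p))
            for contig, arr in chunks
            for p in arr
            if (contig, int(p)) not in excluded
        ]
        perm = rng.permutation(len(entries))
        flat[key] = [entries[i] for i in perm]

    halves = (plan.total_burden + 1) // 2, plan.total_burden // 2
    sites: list[DamageSite] = []
    for strand, half_burden in zip((0, 1), halves):
        counts = plan.signature.sample_channels(half_burden, rng)
        deficit = 0
        for ci, m in enumerate(counts):
            if m == 0:
                continue
            channel = CHANNELS[ci]
            pool = flat.get((_channel_context_id(channel), strand), [])
            take = min(m, len(pool))
            if take < m:
                deficit += m - take
                logger.warning(
                    "context pool exhausted for %s (strand class %d): %d sites resampled",
                    channel, strand, m - take,
                )
            for contig, p in pool[len(pool) - take :]:
                sites.append(
                    DamageSite(
                        contig, p, genome.reference[contig][p],
                        _channel_alt(channel, strand), channel,
                        F1R2 if strand == 0 else F2R1,
                    )
                )
            del pool[len(pool) - take :]
        # redistribute any deficit over channels with remaining capacity
        attempts = 0
        while deficit > 0 and attempts < plan.max_rejections:
            attempts += 1
            extra = plan.signature.sample_channels(deficit, rng)
            deficit = 0
            for ci, m in enumerate(extra):
                if m == 0:
                    continue
                channel = CHANNELS[ci]
                pool = flat.get((_channel_context_id(channel), strand), [])
                take = min(m, len(pool))
                deficit += m - take
                for contig, p in pool[len(pool) - take :]:
                    sites.append(
                        DamageSite(
                            contig, p, genome.reference[contig][p],
                            _channel_alt(channel, strand), channel,
                            F1R2 if strand == 0 else F2R1,
                        )
                    )
                del pool[len(pool) - take :]
        if deficit > 0:
            raise ValueError(
                f"could not place {deficit} artefacts in orientation class {strand}: "
                "target too small for the requested burden"
            )
    return sites


def spike_damage(
    fragments: Sequence[SimFragment],
    plan: DamagePlan,
    genome: PhasedGenome,
    rng: np.random.Generator | int | None = None,
    error_log: ErrorLog | None = None,
    exclude: set[tuple[str, int]] | None = None,
    sites: Sequence[DamageSite] | None = None,
) -> tuple[list[DamageSite], list[TruthRecord]]:
    """Spike context-matched artefacts into one orientation class per site.

    At each site an allele fraction is drawn from the plan's VAF sampler
    and fragments of the site's orientation class (both haplotypes) are
    edited with per-fragment probability min(2 x VAF, 1), so the marginal
    alternate fraction over all fragments equals the drawn VAF.  Passing
    ``sites`` reuses an existing plan — e.g. to spike the identical burden
    into the matched normal sample.
    """
    rng = np.random.default_rng(rng)
    if sites is None:
        sites = plan_damage_sites(plan, genome, rng, exclude)
    index = FragmentIndex(fragments)
    vafs = plan.vaf_sampler(rng, len(sites))
    truth: list[TruthRecord] = []
    for site, vaf in zip(sites, vafs):
        p = min(2.0 * float(vaf), 1.0)
        edited_ids: list[str] = []
        n_edited = 0
        for hap in (0, 1):
            hap_pos = genome.ref_to_hap(hap, site.contig, site.ref_pos)
            if hap_pos is None:
                continue
            for frag in index.overlapping(site.contig, hap, hap_pos):
                if frag.orientation != site.orientation or not frag.reads_covering(hap_pos):
                    continue
                if rng.random() < p:
                    for read in frag.reads_covering(hap_pos):
                        read.seq[hap_pos - read.start] = ord(site.alt)
                        if error_log is not None:
                            error_log.discard(read.read_id, hap_pos)
                        edited_ids.append(read.read_id)
                    n_edited += 1
        truth.append(
            TruthRecord(
                site.contig, site.ref_pos, site.alt, "damage_artefact", None,
                {
                    "channel": site.channel,
                    "orientation": site.orientation,
                    "vaf": float(vaf),
                    "n_edited": n_edited,
                    "read_ids": edited_ids,
                },
            )
        )
    return list(sites), truth
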