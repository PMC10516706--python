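"""Personalized phased diploid genome construction and coordinate liftover.

A phased germline VCF (GT like ``1|0``) is applied to a reference genome to
produce two haplotype sequences (maternal = first allele of the phased
genotype, paternal = second).  Because germline indels change coordinates,
the genome carries explicit monotone liftover maps in both directions
(haplotype -> reference and reference -> haplotype); positions deleted on a
haplotype have no image and lift to ``None`` rather than being interpolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

logger = logging.getLogger(__name__)

MATERNAL = 0
PATERNAL = 1
HAPLOTYPE_NAMES = ("maternal", "paternal")

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class GermlineVariant:
    """One phased germline SNV or short indel.

    ``pos`` is the 1-based reference coordinate of the first ref base (VCF
    convention; indels are left-anchored).  ``genotype`` is the ordered
    phased pair: ``genotype[0]`` is the maternal allele index (0 = ref,
    1 = alt), ``genotype[1]`` the paternal one.
    """

    contig: str
    pos: int
    ref: str
    alt: str
    genotype: tuple[int, int]

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def end(self) -> int:
        """1-based inclusive reference end of the ref allele."""
        return self.pos + len(self.ref) - 1


@dataclass
class PhasedGenome:
    """Two haplotype sequences plus bidirectional liftover maps.

    ``hap_seq[h][contig]`` is the haplotype nucleotide string,
    ``hap_to_ref_map[h][contig]`` maps every haplotype base to its 0-based
    reference position (-1 for inserted bases with no reference image) and
    ``ref_to_hap_map[h][contig]`` the inverse (-1 for reference bases
    deleted on that haplotype).
    """

    contigs: list[str]
    reference: dict[str, str]
    hap_seq: tuple[dict[str, str], dict[str, str]]
    hap_to_ref_map: tuple[dict[str, np.ndarray], dict[str, np.ndarray]]
    ref_to_hap_map: tuple[dict[str, np.ndarray], dict[str, np.ndarray]]
    germline: list[GermlineVariant] = field(default_factory=list)

    def hap_to_ref(self, hap: int, contig: str, pos: int) -> int | None:
        """Lift a 0-based haplotype position to reference space.

        Returns ``None`` for inserted bases (no reference image).
        """
        r = int(self.hap_to_ref_map[hap][contig][pos])
        return None if r < 0 else r

    def ref_to_hap(self, hap: int, contig: str, pos: int) -> int | None:
        """Lift a 0-based reference position onto a haplotype.

        Returns ``None`` where the position is deleted on that haplotype.
        """
        h = int(self.ref_to_hap_map[hap][contig][pos])
        return None if h < 0 else h

    def contig_length(self, contig: str) -> int:
        return len(self.reference[contig])


class RefMismatchError(ValueError):
    """VCF ref allele disagrees with the reference FASTA."""


class OverlapError(ValueError):
    """Two retained records overlap on the same haplotype."""


def read_reference(source) -> dict[str, str]:
    """Coerce a FASTA path, pyfaidx.Fasta, or mapping into {contig: seq}."""
    if isinstance(source, Mapping):
        return {str(c): str(s).upper() for c, s in source.items()}
    if isinstance(source, (str, Path)):
        import pyfaidx

        fa = pyfaidx.Fasta(str(source))
        return {name: str(fa[name][:]).upper() for name in fa.keys()}
    # pyfaidx.Fasta or similar keyed object
    return {name: str(source[name][:]).upper() for name in source.keys()}


def read_germline_vcf(path: str | Path) -> list[GermlineVariant]:
    """Load phased germline records from a VCF.

    Multi-allelic records are split into one record per alt allele (the
    genotype is binarised against that allele).  Unphased genotypes are
    rejected with a logged warning; symbolic alleles (``<DEL>`` etc.) are
    rejected outright.
    """
    out: list[GermlineVariant] = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = list(vcf.header.samples)[0] if list(vcf.header.samples) else None
        if sample is None:
            raise ValueError("germline VCF must contain one sample with phased GT")
        for rec in vcf.fetch() if vcf.index is not None else vcf:
            call = rec.samples[sample]
            gt = call.get("GT")
            if gt is None or len(gt) != 2 or any(a is None for a in gt):
                logger.warning("skipping record %s:%d with missing genotype", rec.contig, rec.pos)
                continue
            if not call.phased and gt[0] != gt[1]:
                logger.warning("skipping unphased het record %s:%d", rec.contig, rec.pos)
                continue
            for ai, alt in enumerate(rec.alts or (), start=1):
                if alt is None or alt.startswith("<") or "]" in alt or "[" in alt:
                    raise ValueError(
                        f"symbolic allele {alt!r} at {rec.contig}:{rec.pos} is not supported"
                    )
                allele_gt = (int(gt[0] == ai), int(gt[1] == ai))
                if allele_gt == (0, 0):
                    continue
                out.append(
                    GermlineVariant(rec.contig, rec.pos, rec.ref.upper(), alt.upper(), allele_gt)
                )
    return out


def _validate(variants: Sequence[GermlineVariant], reference: Mapping[str, str]) -> None:
    last_end: dict[tuple[str, int], int] = {}
    prev: tuple[str, int] | None = None
    for v in variants:
        if prev is not None and v.contig == prev[0] and v.pos < prev[1]:
            raise ValueError("germline records must be coordinate sorted")
        prev = (v.contig, v.pos)
        seq = reference.get(v.contig)
        if seq is None:
            raise ValueError(f"variant contig {v.contig!r} absent from reference")
        ref_slice = seq[v.pos - 1 : v.pos - 1 + len(v.ref)]
        if ref_slice != v.ref:
            raise RefMismatchError(
                f"{v.contig}:{v.pos} ref allele {v.ref!r} != reference {ref_slice!r}"
            )
        for hap in (MATERNAL, PATERNAL):
            if not v.genotype[hap]:
                continue
            key = (v.contig, hap)
            if key in last_end and v.pos <= last_end[key]:
                raise OverlapError(
                    f"{v.contig}:{v.pos} overlaps a previous record on haplotype "
                    f"{HAPLOTYPE_NAMES[hap]}"
                )
            last_end[key] = v.end


def build_phased_genome(reference, germline) -> PhasedGenome:
    """Apply phased germline SNVs/indels to a reference, building liftover.

    Parameters
    ----------
    reference
        FASTA path, ``pyfaidx.Fasta`` or ``{contig: sequence}`` mapping.
    germline
        VCF path or iterable of :class:`GermlineVariant` (phased, sorted,
        non-overlapping per haplotype).
    """
    ref = read_reference(reference)
    if isinstance(germline, (str, Path)):
        variants = read_germline_vcf(germline)
    else:
        variants = list(germline)
    _validate(variants, ref)

    hap_seq: tuple[dict, dict] = ({}, {})
    h2r: tuple[dict, dict] = ({}, {})
    r2h: tuple[dict, dict] = ({}, {})
    by_contig: dict[str, list[GermlineVariant]] = {}
    for v in variants:
        by_contig.setdefault(v.contig, []).append(v)

    for contig, seq in ref.items():
        n = len(seq)
        for hap in (MATERNAL, PATERNAL):
            carried = [v for v in by_contig.get(contig, []) if v.genotype[hap]]
            chunks: list[str] = []
            maps: list[np.ndarray] = []
            cur = 0  # 0-based ref cursor
            for v in carried:
                start = v.pos - 1
                chunks.append(seq[cur:start])
                maps.append(np.arange(cur, start, dtype=np.int64))
                chunks.append(v.alt)
                m = np.full(len(v.alt), -1, dtype=np.int64)
                # anchor bases of the alt map onto the ref allele span
                k = min(len(v.alt), len(v.ref))
                m[:k] = np.arange(start, start + k, dtype=np.int64)
                maps.append(m)
                cur = start + len(v.ref)
            chunks.append(seq[cur:n])
            maps.append(np.arange(cur, n, dtype=np.int64))
            hseq = "".join(chunks)
            hmap = np.concatenate(maps) if maps else np.empty(0, dtype=np.int64)
            inv = np.full(n, -1, dtype=np.int64)
            mapped = hmap >= 0
            inv[hmap[mapped]] = np.nonzero(mapped)[0]
            hap_seq[hap][contig] = hseq
            h2r[hap][contig] = hmap
            r2h[hap][contig] = inv

    return PhasedGenome(
        contigs=list(ref.keys()),
        reference=ref,
        hap_seq=hap_seq,
        hap_to_ref_map=h2r,
        ref_to_hap_map=r2h,
        germline=variants,
    )


# ---------------------------------------------------------------------------
# target intervals


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Parse a BED3 file; malformed lines raise with their line number."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"malformed BED line {i}: expected >=3 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"malformed BED line {i}: non-integer coordinate") from exc
            if start < 0 or end < start:
                raise ValueError(f"malformed BED line {i}: invalid interval [{start},{end})")
            out.append((fields[0], start, end))
    return out


def write_bed(intervals: Iterable[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for contig, start, end in intervals:
            fh.write(f"{contig}\t{start}\t{end}\n")


def pad_target(
    target: Iterable[tuple[str, int, int]],
    pad: int,
    contig_lengths: Mapping[str, int],
) -> list[tuple[str, int, int]]:
    """Extend each 0-based half-open interval by ``pad`` on both sides.

    Results are clipped to contig bounds and overlapping or adjacent
    intervals are merged.  Mirrors exome-capture practice of padding each
    capture range at the 5' and 3' ends (default 100 bp in the pipeline
    configuration).
    """
    padded: dict[str, list[tuple[int, int]]] = {}
    for contig, start, end in target:
        length = contig_lengths[contig]
        s = max(0, start - pad)
        e = min(length, end + pad)
        if e > s:
            padded.setdefault(contig, []).append((s, e))
    merged: list[tuple[str, int, int]] = []
    for contig in padded:
        ivs = sorted(padded[contig])
        cs, ce = ivs[0]
        for s, e in ivs[1:]:
            if s <= ce:
                ce = max(ce, e)
            else:
                merged.append((contig, cs, ce))
                cs, ce = s, e
        merged.append((contig, cs, ce))
    return merged


def target_length(target: Iterable[tuple[str, int, int]]) -> int:
    """Total covered bases of a merged interval set."""
    return sum(end - start for _, start, end in target)
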