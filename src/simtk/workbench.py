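"""Fixture generation and desk-scale pipeline orchestration.

Everything runs from synthetic inputs: a random reference contig, a phased
germline VCF and a set of capture intervals stand in for a real donor
genome and exome target, so the full pipeline — phased genome, matched
normal/pre-tumour reads, somatic spike-in, optional damage artefacts,
calling and evaluation — runs in seconds with no downloads.  All
randomness flows from one top-level seed fanned out into per-stage child
seeds recorded in the run manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from . import damage as damage_mod
from .evaluate import EvaluationReport, summarise
from .naive_caller import CallerParams, Pileup, call_somatic, write_calls_vcf
from .phased_genome import (
    GermlineVariant,
    PhasedGenome,
    build_phased_genome,
    pad_target,
    target_length,
    write_bed,
)
from .read_sim import ErrorLog, SimFragment, simulate_fragments, write_alignments
from .spectrum import SpectrumSpec, make_burden, semi_centile_bins
from .spike_in import SomaticVariant, SpikeResult, plan_variants, spike_variants
from .truth_set import TruthRecord, classify_mismatches, write_truth

logger = logging.getLogger(__name__)


@dataclass
class FixtureSpec:
    """Reproducible synthetic inputs: identical spec + seed give identical files."""

    contig: str = "chr1"
    length: int = 50_000
    gc: float = 0.45
    n_snv: int = 40
    n_indel: int = 10
    het_fraction: float = 0.67
    n_intervals: int = 4
    interval_length: int = 8_000
    pad: int = 100


def generate_toy_reference(
    length: int = 50_000,
    gc: float = 0.45,
    rng: np.random.Generator | int | None = None,
    contig: str = "chr1",
) -> dict[str, str]:
    """Random reference sequence at a requested GC fraction."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("GC fraction must be in [0, 1]")
    if length < 1000:
        raise ValueError("reference length must be at least 1 kb")
    rng = np.random.default_rng(rng)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
    return {contig: seq}


def generate_toy_germline(
    reference: Mapping[str, str],
    n_snv: int = 40,
    n_indel: int = 10,
    het_fraction: float = 0.67,
    rng: np.random.Generator | int | None = None,
    min_spacing: int = 12,
) -> list[GermlineVariant]:
    """Random phased het/hom SNVs and short indels, non-overlapping, sorted."""
    rng = np.random.default_rng(rng)
    variants: list[GermlineVariant] = []
    for contig, seq in reference.items():
        n_total = n_snv + n_indel
        if n_total == 0:
            continue
        usable = (len(seq) - 20) // min_spacing
        if n_total > usable:
            raise ValueError(f"cannot place {n_total} germline variants on {len(seq)} bp")
        slots = rng.choice(usable, size=n_total, replace=False)
        positions = np.sort(slots) * min_spacing + 10  # 0-based anchors
        kinds = np.array(["snv"] * n_snv + ["indel"] * n_indel)
        rng.shuffle(kinds)
        for p0, kind in zip(positions, kinds):
            ref_base = seq[p0]
            het = rng.random() < het_fraction
            gt = (1, 1) if not het else ((1, 0) if rng.random() < 0.5 else (0, 1))
            if kind == "snv":
                alt = [b for b in "ACGT" if b != ref_base][rng.integers(3)]
                variants.append(GermlineVariant(contig, int(p0) + 1, ref_base, alt, gt))
            else:
                size = int(rng.integers(1, 5))
                if rng.random() < 0.5:  # insertion
                    ins = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size)])
                    variants.append(
                        GermlineVariant(contig, int(p0) + 1, ref_base, ref_base + ins, gt)
                    )
                else:  # deletion
                    ref_allele = seq[p0 : p0 + 1 + size]
                    variants.append(
                        GermlineVariant(contig, int(p0) + 1, ref_allele, ref_base, gt)
                    )
    return variants


def generate_toy_target(
    reference: Mapping[str, str],
    n_intervals: int = 4,
    interval_length: int = 8_000,
    rng: np.random.Generator | int | None = None,
) -> list[tuple[str, int, int]]:
    """Evenly spaced capture intervals over each contig."""
    rng = np.random.default_rng(rng)
    target = []
    for contig, seq in reference.items():
        stride = len(seq) // max(n_intervals, 1)
        if interval_length > stride:
            raise ValueError("intervals would overlap; reduce count or length")
        for i in range(n_intervals):
            jitter = int(rng.integers(0, max(1, stride - interval_length)))
            start = i * stride + jitter
            target.append((contig, start, min(start + interval_length, len(seq))))
    return target


def write_fasta(reference: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for contig, seq in reference.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    import pyfaidx

    pyfaidx.Faidx(str(path))
    return path


def write_germline_vcf(
    variants: Sequence[GermlineVariant],
    reference: Mapping[str, str],
    path: str | Path,
    sample: str = "DONOR",
) -> Path:
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for contig, seq in reference.items():
        header.contigs.add(contig, length=len(seq))
    header.add_sample(sample)
    order = {c: i for i, c in enumerate(reference)}
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in sorted(variants, key=lambda v: (order[v.contig], v.pos)):
            rec = out.new_record(contig=v.contig, start=v.pos - 1, alleles=(v.ref, v.alt))
            rec.samples[sample]["GT"] = v.genotype
            rec.samples[sample].phased = True
            out.write(rec)
    return Path(path)


def germline_truth_records(genome: PhasedGenome) -> list[TruthRecord]:
    """Truth entries for every germline variant carried by either haplotype."""
    records = []
    for v in genome.germline:
        source = "germline_snv" if v.is_snv else "germline_indel"
        hap = None
        if v.genotype == (1, 0):
            hap = 0
        elif v.genotype == (0, 1):
            hap = 1
        records.append(TruthRecord(v.contig, v.pos - 1, v.alt, source, hap, {}))
    return records


def write_error_log(error_log: ErrorLog, path: str | Path) -> None:
    rows = [
        {
            "read_id": e.read_id,
            "contig": e.contig,
            "haplotype": e.hap,
            "hap_pos": e.hap_pos,
            "ref_pos": e.ref_pos if e.ref_pos is not None else ".",
            "true_base": e.true_base,
            "observed_base": e.observed_base,
            "quality": e.quality,
        }
        for e in error_log.entries
    ]
    pd.DataFrame(
        rows,
        columns=[
            "read_id", "contig", "haplotype", "hap_pos", "ref_pos",
            "true_base", "observed_base", "quality",
        ],
    ).to_csv(path, sep="\t", index=False)


def make_locus_fragments(
    genome: PhasedGenome,
    contig: str,
    ref_pos: int,
    n_reads: int,
    read_length: int = 100,
    fragment_length: int = 300,
) -> list[SimFragment]:
    """Deterministically build fragments so exactly ``n_reads`` reads cover a locus.

    Each fragment contributes exactly one covering read (the mate lands
    clear of the locus); haplotype and orientation alternate.  Useful for
    pinning local depth exactly, e.g. to demonstrate that read-fraction
    spike-in at frequency f always edits exactly round(f x depth) reads.
    """
    from .read_sim import F1R2, F2R1, SimRead

    frags = []
    for i in range(n_reads):
        hap = i % 2
        hap_pos = genome.ref_to_hap(hap, contig, ref_pos)
        if hap_pos is None:
            raise ValueError("locus deleted on a haplotype; pick another position")
        offset = i % read_length
        start = max(0, hap_pos - offset)
        end = start + fragment_length
        hseq = genome.hap_seq[hap][contig]
        if end > len(hseq):
            raise ValueError("locus too close to the contig end")
        orientation = F1R2 if i % 4 < 2 else F2R1
        name = f"fix{i:05d}"
        reads = []
        for left in (True, False):
            rstart = start if left else end - read_length
            reads.append(
                SimRead(
                    name, contig, hap, rstart,
                    bytearray(hseq[rstart : rstart + read_length], "ascii"),
                    np.full(read_length, 30, dtype=np.uint8),
                    is_reverse=not left,
                    is_read1=left == (orientation == F1R2),
                )
            )
        frags.append(SimFragment(name, contig, hap, start, end, orientation, tuple(reads)))
    return frags


# ---------------------------------------------------------------------------
# pipeline


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "outdir": None,
    "reference": {"contig": "chr1", "length": 50_000, "gc": 0.45},
    "germline": {"n_snv": 40, "n_indel": 10, "het_fraction": 0.67},
    "target": {"n_intervals": 4, "interval_length": 8_000, "pad": 100},
    "reads": {
        "depth": 100,
        "read_length": 100,
        "insert_mean": 300,
        "insert_sd": 30,
        "error_rate": 1e-3,
    },
    "spectrum": {
        "kind": "point_mass",
        "n_total": 200,
        "f0": 0.035,
        "f_min": 0.01,
        "f_max": 0.25,
        "n_clonal": 0,
        "clonal_f": 0.5,
        "purity": 1.0,
        "n_bins": 0,
        "per_bin": 0,
    },
    "spike": {"mode": "stochastic"},
    "damage": {
        "enabled": False,
        "burden": 2000,
        "signature": None,  # path to COSMIC TSV; None -> uniform
        "vaf_beta": [1.5, 50.0],
        "in_normal": False,
    },
    "caller": {"enabled": True, "params": {}},
    "evaluate": {"tmb_threshold": 0.05, "n_bins": 100},
}


def _merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(source) -> dict:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            override = yaml.safe_load(fh) or {}
    else:
        override = dict(source or {})
    return _merge(DEFAULT_CONFIG, override)


def _spectrum_spec(cfg: dict) -> SpectrumSpec:
    kind = cfg["kind"]
    if kind == "uniform_bins":
        bins = semi_centile_bins()[: cfg["n_bins"]]
        return SpectrumSpec(
            kind="uniform_bins",
            bins=bins,
            bin_counts=[cfg["per_bin"]] * len(bins),
            purity=cfg.get("purity", 1.0),
        )
    return SpectrumSpec(
        kind=kind,
        n_total=cfg["n_total"],
        f_min=cfg["f_min"],
        f_max=cfg["f_max"],
        clonal_f=cfg["clonal_f"],
        n_clonal=cfg["n_clonal"],
        f0=cfg["f0"],
        purity=cfg.get("purity", 1.0),
    )


@dataclass
class PipelineResult:
    config: dict
    genome: PhasedGenome
    target: list[tuple[str, int, int]]
    target_size_mb: float
    normal_fragments: list[SimFragment]
    tumour_fragments: list[SimFragment]
    normal_error_log: ErrorLog
    tumour_error_log: ErrorLog
    frequencies: np.ndarray
    variants: list[SomaticVariant]
    spike_results: list[SpikeResult]
    truth: list[TruthRecord]
    calls: list = field(default_factory=list)
    tumour_pileup: Pileup | None = None
    normal_pileup: Pileup | None = None
    report: EvaluationReport | None = None
    attribution: dict | None = None
    unattributed: int = 0
    outdir: Path | None = None
    manifest: dict = field(default_factory=dict)


def run_pipeline(config=None) -> PipelineResult:
    """Run genome -> reads -> spectrum -> spike -> damage -> call -> evaluate.

    ``config`` is a YAML path or nested dict overriding
    :data:`DEFAULT_CONFIG`.  Deterministic for a fixed seed; stage seeds
    are spawned from the top-level seed and recorded in the manifest.
    """
    cfg = load_config(config)
    ss = np.random.SeedSequence(cfg["seed"])
    stage_names = (
        "reference", "germline", "target", "reads_normal", "reads_tumour",
        "spectrum", "plan", "spike", "damage", "damage_normal",
    )
    children = dict(zip(stage_names, ss.spawn(len(stage_names))))
    rngs = {k: np.random.default_rng(v) for k, v in children.items()}

    rcfg = cfg["reference"]
    reference = generate_toy_reference(
        rcfg["length"], rcfg["gc"], rngs["reference"], rcfg["contig"]
    )
    gcfg = cfg["germline"]
    germline = generate_toy_germline(
        reference, gcfg["n_snv"], gcfg["n_indel"], gcfg["het_fraction"], rngs["germline"]
    )
    genome = build_phased_genome(reference, germline)

    tcfg = cfg["target"]
    capture = generate_toy_target(
        reference, tcfg["n_intervals"], tcfg["interval_length"], rngs["target"]
    )
    target = pad_target(capture, tcfg["pad"], {c: len(s) for c, s in reference.items()})
    size_mb = target_length(target) / 1e6

    rd = cfg["reads"]
    sim_kwargs = dict(
        read_length=rd["read_length"],
        insert_mean=rd["insert_mean"],
        insert_sd=rd["insert_sd"],
        error_rates=rd["error_rate"],
    )
    normal_fragments, normal_errors = simulate_fragments(
        genome, target, rd["depth"], rng=rngs["reads_normal"], **sim_kwargs
    )
    tumour_fragments, tumour_errors = simulate_fragments(
        genome, target, rd["depth"], rng=rngs["reads_tumour"], **sim_kwargs
    )

    spec = _spectrum_spec(cfg["spectrum"])
    frequencies = make_burden(spec, rngs["spectrum"])
    variants = plan_variants(
        frequencies, target, genome, rngs["plan"], mode=cfg["spike"]["mode"]
    )
    spike_results, somatic_truth = spike_variants(
        tumour_fragments, variants, genome,
        rngs["spike"], cfg["spike"]["mode"], tumour_errors,
    )

    truth: list[TruthRecord] = germline_truth_records(genome) + somatic_truth

    dcfg = cfg["damage"]
    damage_sites = []
    if dcfg["enabled"]:
        sig = (
            damage_mod.load_cosmic_signature(dcfg["signature"])
            if dcfg["signature"]
            else damage_mod.SBSSignature.uniform()
        )
        a, b = dcfg["vaf_beta"]
        plan = damage_mod.DamagePlan(
            total_burden=dcfg["burden"],
            signature=sig,
            target=target,
            vaf_sampler=damage_mod.default_vaf_sampler(a, b),
        )
        exclude = {(v.contig, v.pos - 1) for v in variants}
        for v in genome.germline:
            for p in range(v.pos - 1, v.pos - 1 + len(v.ref)):
                exclude.add((v.contig, p))
        damage_sites, damage_truth = damage_mod.spike_damage(
            tumour_fragments, plan, genome, rngs["damage"], tumour_errors, exclude
        )
        truth += damage_truth
        if dcfg["in_normal"]:
            # same artefact plan applied to the matched normal
            _, normal_damage_truth = damage_mod.spike_damage(
                normal_fragments, plan, genome, rngs["damage_normal"],
                normal_errors, exclude, sites=damage_sites,
            )

    result = PipelineResult(
        config=cfg,
        genome=genome,
        target=target,
        target_size_mb=size_mb,
        normal_fragments=normal_fragments,
        tumour_fragments=tumour_fragments,
        normal_error_log=normal_errors,
        tumour_error_log=tumour_errors,
        frequencies=frequencies,
        variants=variants,
        spike_results=spike_results,
        truth=truth,
    )

    if cfg["caller"]["enabled"]:
        result.tumour_pileup = Pileup(genome).add_fragments(tumour_fragments)
        result.normal_pileup = Pileup(genome).add_fragments(normal_fragments)
        params = CallerParams(**cfg["caller"]["params"])
        result.calls = call_somatic(
            result.tumour_pileup, result.normal_pileup, params, target
        )
        f0 = spec.f0 if spec.kind == "point_mass" else None
        result.report = summarise(
            result.calls, truth, result.tumour_pileup,
            target_size_mb=size_mb,
            tmb_threshold=cfg["evaluate"]["tmb_threshold"],
            point_mass_f0=f0,
            n_bins=cfg["evaluate"]["n_bins"],
        )

    counts, n_unattr, _ = classify_mismatches(
        tumour_fragments, genome, truth, tumour_errors
    )
    result.attribution = counts
    result.unattributed = n_unattr
    if n_unattr:
        logger.error("truth leak: %d unattributed mismatches", n_unattr)

    result.manifest = {
        "config": cfg,
        "stage_seeds": {k: int(v.generate_state(1)[0]) for k, v in children.items()},
        "target_size_mb": size_mb,
        "n_fragments": {
            "normal": len(normal_fragments),
            "tumour": len(tumour_fragments),
        },
        "n_truth_records": len(truth),
        "n_sequencing_errors": {
            "normal": len(normal_errors),
            "tumour": len(tumour_errors),
        },
        "attribution": counts,
        "unattributed": n_unattr,
    }

    if cfg["outdir"]:
        result.outdir = _write_run_dir(result)
    return result


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_run_dir(result: PipelineResult) -> Path:
    outdir = Path(result.config["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(result.genome.reference, outdir / "reference.fa")
    write_germline_vcf(result.genome.germline, result.genome.reference, outdir / "germline.vcf")
    write_bed(result.target, outdir / "target.bed")
    write_alignments(result.normal_fragments, result.genome, outdir / "normal.sam")
    write_alignments(result.tumour_fragments, result.genome, outdir / "tumour.sam")
    write_truth(result.truth, result.genome, outdir / "truth.vcf", outdir / "truth.tsv")
    write_error_log(result.tumour_error_log, outdir / "tumour_errors.tsv")
    write_error_log(result.normal_error_log, outdir / "normal_errors.tsv")
    if result.calls:
        write_calls_vcf(result.calls, result.genome, outdir / "calls.vcf")
    if result.report is not None:
        result.report.to_json(outdir / "report.json")
    checks = {
        p.name: _sha256(p)
        for p in sorted(outdir.iterdir())
        if p.suffix in (".tsv", ".vcf", ".bed", ".fa")
    }
    result.manifest["checksums"] = checks
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(result.manifest, fh, indent=2, default=str)
    return outdir
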