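"""Somatic spike-in: planning, stochastic binomial edits, read-fraction determinism."""

import numpy as np
import pytest
from scipy import stats

from simtk.naive_caller import Pileup
from simtk.read_sim import FragmentIndex
from simtk.spike_in import (
    READ_FRACTION,
    STOCHASTIC,
    SomaticVariant,
    apply_read_fraction,
    apply_stochastic,
    plan_variants,
    spike_variants,
)
from simtk.workbench import make_locus_fragments


def pooled_binomial_gof(ns, ks, p):
    """Chi-square GOF of counts k_i vs Binomial(n_i, p), pooled over loci."""
    kmax = int(max(ks))
    observed = np.bincount(ks, minlength=kmax + 1)
    expected = np.zeros(kmax + 1)
    for n in ns:
        pmf = stats.binom.pmf(np.arange(kmax + 1), n, p)
        pmf[kmax] += stats.binom.sf(kmax, n, p)
        expected += pmf
    # merge the tail so every bin has expected count >= 5
    while len(expected) > 2 and expected[-1] < 5:
        expected[-2] += expected[-1]
        observed[-2] += observed[-1]
        expected, observed = expected[:-1], observed[:-1]
    return stats.chisquare(observed, expected * observed.sum() / expected.sum()).pvalue


def test_empty_plan(genome, target):
    assert plan_variants([], target, genome, rng=0) == []


def test_plan_loci_unique_and_in_target(genome, target):
    variants = plan_variants([0.1] * 1000, target, genome, rng=1)
    keys = {(v.contig, v.pos) for v in variants}
    assert len(keys) == 1000
    germ = {(v.contig, p) for v in genome.germline for p in range(v.pos - 1, v.end)}
    for v in variants:
        assert any(s <= v.pos - 1 < e for c, s, e in target if c == v.contig)
        assert v.ref == genome.reference[v.contig][v.pos - 1]
        assert v.alt != v.ref
        assert (v.contig, v.pos - 1) not in germ


def test_plan_haplotype_assignment_binomial(genome, target):
    variants = plan_variants([0.1] * 2000, target, genome, rng=2)
    n_mat = sum(1 for v in variants if v.hap == 0)
    assert stats.binomtest(n_mat, 2000, 0.5).pvalue > 0.01


def test_plan_rejects_overfull_target(genome):
    with pytest.raises(ValueError, match="available loci"):
        plan_variants([0.1] * 300, [("chr1", 1000, 1200)], genome, rng=3)


def test_stochastic_zero_frequency_never_edits(genome, fragment_factory):
    fragments, _ = fragment_factory(mean_depth=40)
    index = FragmentIndex(fragments)
    ref = genome.reference["chr1"][2999]
    alt = "A" if ref != "A" else "C"
    v = SomaticVariant("chr1", 3000, ref, alt, 0, 0.0)
    res = apply_stochastic(index, v, genome, np.random.default_rng(4))
    assert res.n_edited == 0 and res.edited_read_ids == []


def test_stochastic_half_frequency_edits_every_haplotype_fragment(genome, target, fragment_factory):
    fragments, _ = fragment_factory(mean_depth=40)
    index = FragmentIndex(fragments)
    p0 = (target[0][1] + target[0][2]) // 2
    ref = genome.reference["chr1"][p0]
    alt = "A" if ref != "A" else "C"
    v = SomaticVariant("chr1", p0 + 1, ref, alt, 1, 0.5)
    res = apply_stochastic(index, v, genome, np.random.default_rng(5))
    assert res.n_overlapping > 0
    assert res.n_edited == res.n_overlapping  # p = min(2f, 1) = 1
    # overall VAF across both haplotypes ~ 0.5
    pu = Pileup(genome).add_fragments(fragments)
    vaf = pu.base_count("chr1", p0, alt) / pu.depth("chr1", p0)
    assert 0.3 < vaf < 0.7


def test_stochastic_mate_consistency(genome, target, fragment_factory):
    """Both mates of an edited fragment carry the alt wherever they cover."""
    fragments, _ = fragment_factory(mean_depth=60, seed=900)
    index = FragmentIndex(fragments)
    p0 = (target[0][1] + target[0][2]) // 2 + 137
    ref = genome.reference["chr1"][p0]
    alt = "G" if ref != "G" else "T"
    v = SomaticVariant("chr1", p0 + 1, ref, alt, 0, 0.5)
    res = apply_stochastic(index, v, genome, np.random.default_rng(6))
    hap_pos = genome.ref_to_hap(0, "chr1", p0)
    edited_frags = {rid.rsplit("/", 1)[0] for rid in res.edited_read_ids}
    for frag in fragments:
        if frag.name not in edited_frags:
            continue
        for read in frag.reads_covering(hap_pos):
            assert chr(read.seq[hap_pos - read.start]) == alt


def test_stochastic_alt_counts_binomial_and_zero_fraction(genome, target, fragment_factory):
    """Alt fragment counts follow Binomial(n_i, 2f); some loci get zero."""
    fragments, _ = fragment_factory(mean_depth=100, seed=901)
    f0 = 0.035
    variants = plan_variants([f0] * 600, target, genome, rng=7)
    results, _ = spike_variants(fragments, variants, genome, rng=8, mode=STOCHASTIC)
    ns = np.array([r.n_overlapping for r in results])
    ks = np.array([r.n_edited for r in results])
    assert pooled_binomial_gof(ns, ks, 2 * f0) > 0.01
    assert np.count_nonzero(ks == 0) > 0  # stochastic dropout, unlike read-fraction


def test_read_fraction_is_exact_and_deterministic(genome):
    """f=0.1 at depth 30 gives exactly 3 alt reads, on every run."""
    p0 = 10_000
    ref = genome.reference["chr1"][p0]
    alt = "C" if ref != "C" else "G"
    counts = []
    for seed in (0, 1, 2):
        fragments = make_locus_fragments(genome, "chr1", p0, n_reads=30)
        index = FragmentIndex(fragments)
        v = SomaticVariant("chr1", p0 + 1, ref, alt, 0, 0.10, READ_FRACTION)
        res = apply_read_fraction(index, v, genome)
        pu = Pileup(genome).add_fragments(fragments)
        assert pu.depth("chr1", p0) == 30
        counts.append(pu.base_count("chr1", p0, alt))
        assert res.n_edited == 3
    assert counts == [3, 3, 3]


@pytest.mark.parametrize("f, depth, expected", [(0.0, 25, 0), (0.2, 10, 2), (0.1, 30, 3)])
def test_read_fraction_rounding(genome, f, depth, expected):
    p0 = 20_000
    ref = genome.reference["chr1"][p0]
    alt = "T" if ref != "T" else "A"
    fragments = make_locus_fragments(genome, "chr1", p0, n_reads=depth)
    res = apply_read_fraction(
        FragmentIndex(fragments), SomaticVariant("chr1", p0 + 1, ref, alt, 0, f, READ_FRACTION), genome
    )
    assert res.n_edited == expected


def test_stochastic_vs_read_fraction_variance_contrast(genome):
    """At fixed depth, read-fraction alt counts are constant; stochastic disperse."""
    p0 = 15_000
    ref = genome.reference["chr1"][p0]
    alt = "A" if ref != "A" else "C"
    frac_counts, stoch_counts = [], []
    for seed in range(40):
        fragments = make_locus_fragments(genome, "chr1", p0, n_reads=60)
        res = apply_read_fraction(
            FragmentIndex(fragments),
            SomaticVariant("chr1", p0 + 1, ref, alt, 0, 0.1, READ_FRACTION),
            genome,
        )
        frac_counts.append(res.n_edited)
        fragments = make_locus_fragments(genome, "chr1", p0, n_reads=60)
        res = apply_stochastic(
            FragmentIndex(fragments),
            SomaticVariant("chr1", p0 + 1, ref, alt, 0, 0.1),
            genome,
            np.random.default_rng(seed),
        )
        stoch_counts.append(res.n_edited)
    assert np.var(frac_counts) == 0.0
    assert np.var(stoch_counts) > 0.0


def test_truth_conservation_alt_base_delta(genome, target, fragment_factory):
    """Post-spike alt bases minus pre-spike equals edited-base truth total."""
    fragments, _ = fragment_factory(mean_depth=50, seed=902)
    pre = Pileup(genome).add_fragments(fragments)
    variants = plan_variants([0.2] * 100, target, genome, rng=9)
    results, truth = spike_variants(fragments, variants, genome, rng=10, mode=STOCHASTIC)
    post = Pileup(genome).add_fragments(fragments)
    for v, res, t in zip(variants, results, truth):
        delta = post.base_count(v.contig, v.pos - 1, v.alt) - pre.base_count(
            v.contig, v.pos - 1, v.alt
        )
        assert delta == len(res.edited_read_ids) == len(t.metadata["read_ids"])


def test_deleted_locus_variant_skipped(genome, caplog):
    """A somatic locus falling in a haplotype deletion is skipped and logged."""
    found = None
    for v in genome.germline:
        if len(v.ref) > 1:
            for hap in (0, 1):
                if v.genotype[hap] and genome.ref_to_hap(hap, v.contig, v.pos) is None:
                    found = (v, hap)
                    break
        if found:
            break
    assert found is not None, "fixture should contain at least one het deletion"
    gv, hap = found
    p0 = gv.pos  # 0-based coordinate of the first deleted reference base
    ref = genome.reference[gv.contig][p0]
    alt = "A" if ref != "A" else "C"
    sv = SomaticVariant(gv.contig, p0 + 1, ref, alt, hap, 0.3)
    with caplog.at_level("WARNING"):
        res = apply_stochastic(FragmentIndex([]), sv, genome, np.random.default_rng(11))
    assert res.skipped and res.n_edited == 0
    assert "deletion" in caplog.text
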