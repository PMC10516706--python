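"""SBS signature estimation/loading and orientation-pure damage spike-in."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from simtk.damage import (
    CHANNELS,
    DamagePlan,
    SBSSignature,
    channel_of,
    estimate_sbs_signature,
    load_cosmic_signature,
    partition_by_orientation,
    plan_damage_sites,
    spike_damage,
)
from simtk.naive_caller import Pileup
from simtk.read_sim import F1R2, F2R1


def test_channel_strand_normalization():
    # a G>A variant at 5'-TGC-3' is C>T in G[C>T]A after reverse complement
    assert channel_of("TGC", "A") == "G[C>T]A"
    assert channel_of("ACA", "T") == "A[C>T]A"
    assert channel_of("AAT", "C") == "A[T>G]T"  # A>C center -> T>G on pyr strand


def test_point_mass_signature():
    ref = {"c": "ACATACATACAT"}
    variants = [("c", p, "C", "T") for p in (2, 6, 10)] * 3 + [("c", 2, "C", "T")]
    sig = estimate_sbs_signature(variants, ref)
    assert sig["A[C>T]A"] == pytest.approx(1.0)


def test_non_snv_skipped_and_empty_is_error(caplog):
    ref = {"c": "ACATACAT"}
    with caplog.at_level("WARNING"):
        sig = estimate_sbs_signature([("c", 2, "CA", "C"), ("c", 2, "C", "T")], ref)
    assert "non-SNV" in caplog.text
    assert sig["A[C>T]A"] == pytest.approx(1.0)
    with pytest.raises(ValueError):
        estimate_sbs_signature([], ref)


def test_signature_recovery_from_generated_variants(plain_genome):
    """Variants drawn from a known signature are recovered at cosine >= 0.99."""
    rng = np.random.default_rng(0)
    # a structured, FFPE-like signature: C>T rich with an 8-oxoG C>A shoulder
    w = np.zeros(96)
    for i, ch in enumerate(CHANNELS):
        if "[C>T]" in ch:
            w[i] = 3.0
        elif "[C>A]" in ch:
            w[i] = 1.5
        else:
            w[i] = 0.1
    truth_sig = SBSSignature(w)
    target = [("chr1", 0, plain_genome.contig_length("chr1"))]
    plan = DamagePlan(total_burden=5000, signature=truth_sig, target=target)
    sites = plan_damage_sites(plan, plain_genome, rng)
    variants = [(s.contig, s.ref_pos + 1, s.ref, s.alt) for s in sites]
    est = estimate_sbs_signature(variants, plain_genome)
    assert est.cosine(truth_sig) >= 0.99


def test_load_cosmic_signature_variants(tmp_path):
    rng = np.random.default_rng(1)
    df = pd.DataFrame({"Type": list(CHANNELS), "SBS45": np.full(96, 1.0)})
    sig = load_cosmic_signature(df)
    assert np.allclose(sig.probs, 1 / 96)
    # un-normalized weights are renormalized
    df2 = pd.DataFrame({"Type": list(CHANNELS), "SBS45": rng.random(96) * 40})
    sig2 = load_cosmic_signature(df2)
    assert sig2.probs.sum() == pytest.approx(1.0)
    # shuffled row order gives the identical signature (label-keyed)
    perm = rng.permutation(96)
    df3 = df2.iloc[perm].reset_index(drop=True)
    sig3 = load_cosmic_signature(df3)
    assert np.allclose(sig2.probs, sig3.probs)
    # file round trip
    path = tmp_path / "sig.tsv"
    df2.to_csv(path, sep="\t", index=False)
    assert np.allclose(load_cosmic_signature(path).probs, sig2.probs)


def test_load_cosmic_signature_rejects_bad_tables():
    df = pd.DataFrame({"Type": list(CHANNELS[:95]) + [CHANNELS[0]], "S": np.ones(96)})
    with pytest.raises(ValueError, match="duplicate"):
        load_cosmic_signature(df)
    df = pd.DataFrame({"Type": list(CHANNELS[:90]), "S": np.ones(90)})
    with pytest.raises(ValueError, match="missing"):
        load_cosmic_signature(df)


def test_partition_by_orientation_conservation(sim_run):
    fragments, _ = sim_run
    fwd, rev = partition_by_orientation(fragments)
    assert len(fwd) + len(rev) == len(fragments)
    assert all(f.orientation == F1R2 for f in fwd)
    assert all(f.orientation == F2R1 for f in rev)
    # class sizes Binomial(n, 1/2)-consistent
    assert stats.binomtest(len(fwd), len(fragments), 0.5).pvalue > 0.01


def test_partition_of_alignments(genome, target, tmp_path):
    import pysam

    from simtk.read_sim import simulate_fragments, write_alignments

    fragments, _ = simulate_fragments(genome, target, 3, error_rates=0.0, rng=2)
    path = write_alignments(fragments, genome, tmp_path / "a.sam")
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        reads = list(fh)
    fwd, rev = partition_by_orientation(reads)
    assert len(fwd) + len(rev) == len(reads)
    by_orient = {f.name: f.orientation for f in fragments}
    for a in fwd:
        assert by_orient[a.query_name] == F1R2
    for a in rev:
        assert by_orient[a.query_name] == F2R1


def test_zero_burden_no_edits(genome, target, fragment_factory):
    fragments, _ = fragment_factory(mean_depth=20)
    before = [bytes(r.seq) for f in fragments for r in f.reads]
    plan = DamagePlan(total_burden=0, signature=SBSSignature.uniform(), target=target)
    sites, truth = spike_damage(fragments, plan, genome, rng=3)
    assert sites == [] and truth == []
    assert [bytes(r.seq) for f in fragments for r in f.reads] == before


def test_plan_splits_burden_evenly_and_matches_context(genome, target):
    rng = np.random.default_rng(4)
    plan = DamagePlan(total_burden=1001, signature=SBSSignature.uniform(), target=target)
    sites = plan_damage_sites(plan, genome, rng)
    n_fwd = sum(1 for s in sites if s.orientation == F1R2)
    assert abs(n_fwd - (len(sites) - n_fwd)) <= 1
    assert len({(s.contig, s.ref_pos) for s in sites}) == len(sites) == 1001
    for s in sites[::7]:
        tri = genome.reference[s.contig][s.ref_pos - 1 : s.ref_pos + 2]
        assert channel_of(tri, s.alt) == s.channel
        # chemistry: pyrimidine on the reference strand -> forward class
        expected = F1R2 if s.ref in "CT" else F2R1
        assert s.orientation == expected


def test_orientation_purity_pre_error(genome, target, fragment_factory):
    """Every alt-carrying fragment at an artefact site shares one orientation."""
    fragments, _ = fragment_factory(mean_depth=60, error_rates=0.0, seed=950)
    plan = DamagePlan(total_burden=800, signature=SBSSignature.uniform(), target=target)
    sites, truth = spike_damage(fragments, plan, genome, rng=5)
    pu = Pileup(genome).add_fragments(fragments)
    n_with_alt = 0
    for t in truth:
        if t.metadata["n_edited"] == 0:
            continue
        n_with_alt += 1
        f1r2, f2r1 = pu.orientation_counts(t.contig, t.ref_pos, t.alt)
        if t.metadata["orientation"] == F1R2:
            assert f1r2 > 0 and f2r1 == 0
        else:
            assert f2r1 > 0 and f1r2 == 0
    assert n_with_alt > 100


def test_spiked_channel_distribution_matches_signature(plain_genome):
    """Chi-square GOF of spiked-site channels against the plan signature."""
    rng = np.random.default_rng(6)
    sig = SBSSignature(np.linspace(1, 4, 96))
    target = [("chr1", 0, plain_genome.contig_length("chr1"))]
    plan = DamagePlan(total_burden=10_000, signature=sig, target=target)
    sites = plan_damage_sites(plan, plain_genome, rng)
    observed = np.zeros(96)
    for s in sites:
        observed[CHANNELS.index(s.channel)] += 1
    expected = sig.probs * len(sites)
    keep = expected >= 5
    obs, exp = observed[keep], expected[keep]
    if (~keep).any():
        obs = np.append(obs, observed[~keep].sum())
        exp = np.append(exp, expected[~keep].sum())
    p = stats.chisquare(obs, exp * obs.sum() / exp.sum()).pvalue
    assert p > 0.01


def test_same_plan_spikes_into_normal(genome, target, fragment_factory):
    """The identical artefact site list can be applied to the matched normal."""
    tumour, _ = fragment_factory(mean_depth=30, seed=951)
    normal, _ = fragment_factory(mean_depth=30, seed=952)
    plan = DamagePlan(total_burden=300, signature=SBSSignature.uniform(), target=target)
    sites, _ = spike_damage(tumour, plan, genome, rng=7)
    sites2, truth2 = spike_damage(normal, plan, genome, rng=8, sites=sites)
    assert sites2 == list(sites)
    assert [(t.contig, t.ref_pos, t.alt) for t in truth2] == [
        (s.contig, s.ref_pos, s.alt) for s in sites
    ]
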