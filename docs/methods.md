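# Methods

## Model overview

`simtk` simulates a pure (purity 1), diploid tumour and its matched normal
from a personalized phased genome, tracks the provenance of every
non-reference base, and evaluates somatic-caller output against that
truth. The guiding principle is that sequencing is a *sampling process*:
the reads at a locus are a random sample of the DNA molecules present, so
the number of reads carrying a somatic allele at frequency f is binomial,
not a deterministic function of f and depth.

## Phased genome and coordinates

The phased germline VCF (GT such as `1|0`; allele 1 = maternal by
convention) is applied per haplotype to the reference. Internally all
coordinates are 0-based half-open; VCF positions are 1-based and BED
intervals 0-based half-open, with conversions at the I/O boundary.
Liftover is stored as explicit per-base index arrays in both directions.
Inserted haplotype bases have no reference image and deleted reference
bases no haplotype image; both lift to "undefined" rather than being
interpolated, which the truth-attribution step relies on. Multi-allelic
records are split per alt allele; unphased het records are skipped with a
warning; a ref-allele mismatch with the FASTA and same-haplotype overlaps
are hard errors (how a real donor VCF resolved overlapping annotations is
unknowable from the annotations alone, so we refuse to guess).

## Read simulation

Fragments are placed uniformly per haplotype over the padded capture
target (capture intervals extended by 100 bp at each end by default, then
merged). Insert lengths are Normal(300, 30) truncated below at the read
length (100 bp); the fragment count is chosen so the expected interior
depth equals the requested mean depth, split evenly between haplotypes —
realized depth and haplotype balance are therefore emergent and binomial,
matching the stochastic stance of the rest of the simulator. Fragment
orientation (whether the first-in-pair read is sequenced off the forward
strand, F1R2, or the reverse, F2R1) is a fair coin.

Base-calling errors are drawn per cycle from a configurable rate vector
(default flat 10⁻³) with Phred-consistent base qualities; each miscall is
logged with read id, haplotype coordinate and reference-lifted coordinate.
This error model is intentionally simple — no GC or capture bias, no
duplicates, no adapter read-through, no quality trimming; it is a declared
substitute for empirical sequencer profiles, sufficient for the phenomena
studied here (it supplies the opposite-strand "escape" evidence at damage
sites and the false evidence in the normal that drives `normal_artifact`
filtering).

## Somatic spike-in

Ground-truth frequencies come from three spectrum families:

- **neutral**: inverse-CDF draws with CDF ∝ (1/f_min − 1/f) on
  [f_min, f_max] (defaults 0.01–0.25), i.e. cumulative mutation count
  proportional to 1/f, optionally plus a clonal point mass at f = 0.5; the
  clonal/subclonal split is a free parameter (`n_clonal`, default 0)
  because no canonical value exists.
- **point_mass**: all variants at one frequency (default 0.035).
- **uniform_bins**: per-bin uniform draws over semi-centile bins
  [(i−1)/200, i/200) partitioning (0, 0.5].

Purity scales all frequencies multiplicatively. Loci are drawn uniformly
without replacement over the target, excluding positions covered by
germline records (so every locus exists on both haplotypes and truth
attribution stays unambiguous); haplotype and alternate base are uniform.

*Stochastic mode* (the default): each fragment of the chosen haplotype
with a read covering the locus independently carries the alternate allele
with probability min(2f, 1) — 2f because only half the fragments at a
diploid locus come from the mutated haplotype, giving marginal VAF f.
Both mates of an edited fragment are edited wherever they cover the locus
(a fragment is one molecule); base qualities are untouched. Alternate
*fragment* counts are exactly Binomial(n, 2f), so low-frequency variants
can draw zero alternate reads — such variants are flagged
`unrepresented` in the truth set and are undetectable in principle.

*Read-fraction mode* emulates deterministic spike-in tools: exactly
round(f × depth) *reads* (half-up; depth = reads covering the locus on
both haplotypes) are edited in a fixed order (leftmost start, then read
id), haplotype-blind, with zero sampling variance. The editing unit here
is the read, not the fragment, because the deterministic tools being
emulated edit reads and their printed arithmetic (3 alt reads at f = 0.1,
depth 30) counts reads.

If a spike-in or damage edit overwrites a base that had a logged
sequencing error, the error-log entry is removed: the molecule now truly
carries the variant, and the truth attribution must remain a partition.

## DNA-damage artefacts

Damage signatures live on the 96 pyrimidine-centred trinucleotide
channels; purine-centred substitutions are reverse-complemented into the
C/T convention. Signatures are estimated by counting channels of observed
SNVs (e.g. variants private to an FFPE sample relative to its fresh-frozen
pair) or loaded from COSMIC-format 96-row TSVs (label-keyed, renormalized).

Artefact planning splits the total burden exactly in half between the two
fragment-orientation classes. Chemistry fixes the class per site: the
damaged base (the C of a deamination, read as C>T; the G of an 8-oxoG,
read as C>A on the pyrimidine strand) sits on one strand, so sites with
the pyrimidine on the reference strand feed the forward (F1R2) class and
purine-on-reference sites the reverse class. Each half-burden's channels
are drawn multinomially from the signature and matched to target sites of
the right trinucleotide context by sampling without replacement from
per-context pools; a channel whose pool is exhausted has its remainder
redistributed over the other channels (logged). Per site an allele
fraction is drawn from the VAF sampler — default Beta(1.5, 50), mean
≈ 0.029, chosen as a low-frequency distribution typical of damage
artefacts; any empirical list can be plugged in — and fragments of the
site's orientation class (both haplotypes) are edited with per-fragment
probability min(2·VAF, 1), so the marginal alternate fraction equals the
drawn VAF. By construction all alternate evidence at an artefact site
shares one orientation before sequencing errors; only an error on the
opposite strand can break the purity, which is exactly the mechanism that
lets artefacts escape orientation-bias filters. The same planned site
list can be spiked into the normal sample to model FFPE-adjacent normal
controls.

## Truth set

Attribution walks every read, compares it base-by-base with the reference
through the liftover, and assigns each mismatch one source, in priority
order: logged sequencing error (exact read id + coordinate match) →
germline (haplotype differs from reference at the position and the read
shows the haplotype base) → somatic spike-in (position/alt/haplotype
match; haplotype-blind for read-fraction edits) → damage artefact
(position/alt match). Bases inside haplotype insertions are germline
indel evidence by construction (unless themselves miscalled). On
internally generated data the unattributed count must be zero; the
pipeline treats any leak as an error. One subtlety: a miscall at a het
germline SNV can coincidentally restore the *reference* base, so the
number of reference-visible errors can be slightly below the error-log
length; the recount oracle in the tests accounts for this.

The truth set serializes to a VCF (one record per position/alt/source;
INFO keys SRC, TF, CH, OR, HAP, NE) plus a TSV mirror; sequencing errors
are serialized separately as the error-log TSV since multiple reads can
repeat the same position/alt pair. A tag-based alignment audit compares
each read's position (lifted to reference space when the BAM is in
haplotype coordinates) with its `XT` true-start tag, so misalignment can
be quantified even after external realignment, provided tags survive.

## Naive caller

Per site, the best non-reference base is a candidate; records are emitted
at ≥ `min_emit` (2) alternate reads — below that, variants vanish without
trace, reproducing the "dropped without record" false-negative class.
Filters: `min_alt_reads` below k = 3; `weak_evidence` when the one-sided
binomial test of the alternate count against error rate e = 10⁻³ does not
reject at α = 0.01; `normal_artifact` at ≥ 2 same-base alternate reads in
the matched normal; `clustered_events` when more than two emitted
candidates fall within ±100 bp. PASS means no filters. For an unclustered
site with a clean normal the PASS rule collapses to a depth-dependent
alternate-count threshold, so detection probability and the conditional
mean inferred VAF, E[X/D | X ≥ t(D)] with X ~ Binomial(D, f), are exactly
enumerable — the oracle used throughout the tests. This caller makes no
claim to mirror any production caller's internals; it exists so the
detection-rate and VAF-bias phenomena are reproducible and provable at
desk scale.

## Evaluation

Classification is a partition. Each true somatic variant is TP (PASS call
at its position/alt) or one false-negative cause, in priority order:
`no_alt_coverage` (zero alternate reads in the data), `misaligned` (all
supporting reads flagged by the alignment audit), `filtered:<labels>`
(record present, non-PASS), `not_emitted` (no record). Each PASS call is
TP or one false-positive class: `FP_artefact` (damage truth site),
`FP_germline` (germline truth site), else `FP_error`. On top sit the
detection matrix (true-frequency semi-centile × inferred-frequency
semi-centile + a not-detected column; row sums conserve the per-bin
burden), filter attribution, TMB (PASS calls with inferred VAF ≥ 0.05 per
Mb; the ground-truth analogue counts true frequencies), the VAF-bias
summary against a point-mass truth, and the strand-evidence 2×2 table of
caller-considered artefact sites (TN/FP × single-/both-strand evidence)
with a one-sided Fisher exact test for enrichment of both-strand evidence
among false positives (for the archetypal published table the one- and
two-sided p agree to one significant figure). The artefact false-positive
rate is reported against an expected true burden (median pan-cancer TMB ×
target size), with FP/(FP+TP) reported separately as the precision
complement.

## Synthetic fixtures and scale

The workbench generates random references at a requested GC (default
0.45), phased germline variant sets (67% het, SNV:indel ≈ 4:1, indels
1–4 bp, minimum spacing to guarantee non-overlap) and evenly spaced
capture intervals. These stand in for a real donor genome and exome: they
reproduce the *mechanisms* (phasing, indel liftover, context-dependent
damage, binomial sampling) but not real-genome features — no repeats or
segmental duplications (so no genuine mapping ambiguity), no GC/capture
bias, no error-rate heterogeneity beyond the per-cycle vector, and
targets of tens of kilobases rather than 76 Mb. Passing tests therefore
certify the simulator's internal correctness and its statistical
contracts, not caller performance on real exomes. Default desk-scale
problem sizes (40–120 kb references, 100–600× depth, hundreds of spiked
variants, artefact burdens ≤ 10⁴) were chosen so every statistical check
retains power while the whole suite runs in well under a minute per test.

## Numerical choices

Half-up decimal rounding for displayed quantities (TMB to one decimal,
percentages to integers) to match conventional reporting. The Fisher test
uses the exact hypergeometric tail (scipy), p = 1 by convention when a
margin is zero. Chi-square goodness-of-fit tests pool per-locus binomials
with unequal n by summing exact pmfs and merging tail bins below expected
count 5. Seeds flow from a single top-level `SeedSequence` fanned out to
per-stage children recorded in the run manifest; identical config + seed
reproduces byte-identical truth artefacts.

## Known limitations

Somatic indels, structural variants and copy-number variation are not
simulated (frequencies assume a diploid locus, capped at 0.5 at purity 1).
Cross-sample contamination and base-quality recalibration are out of
scope. The read simulator does not reproduce any specific instrument's
empirical error profile. The alignment audit detects position shifts, not
aligner clipping decisions. The naive caller has no local assembly and no
orientation-bias filter of its own (orientation analysis lives in the
evaluator), so caller-specific published figures are not reproduction
targets for it.
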