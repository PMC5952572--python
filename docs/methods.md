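# Methods

## Problem setting

Silica-column RNA extraction kits can carry small RNA (sRNA) contaminants.
In sequencing libraries from low-biomass samples such as blood plasma these
reagent-derived sequences can reach thousands of counts per million (cpm)
and masquerade as exogenous (non-host) sRNAs. `srnaclean` implements a
contaminant-aware analysis built around three ideas:

1. **Extraction controls define the artefact class.** Mock extractions
   (water through the full protocol), bare column eluates, water and
   no-template controls are sequenced alongside the study samples; any
   sequence recurring in them is treated as an artefact.
2. **Copy-number arithmetic makes contamination recognisable.** Reagent
   contaminants enter at a fixed copy number per spin column, while
   sample-borne RNA scales with input volume. Relative contaminant levels
   therefore fall roughly as 1/V with input volume V — the signature used
   both to diagnose contamination and to choose a safe input volume.
3. **Absolute quantification anchors the read counts.** A synthetic
   spike-in of known concentration (40,000 copies/µL of eluate) converts
   cpm into copies/µL, and qPCR standard curves do the same for
   amplification data.

## Pipeline stages and their contracts

### Preprocessing (`preprocess`)

Reads pass through a fixed order: recursive 3′ adapter trimming → 5′ N
clipping → quality filtering → collapsing of identical reads. Adapter
occurrences are the earliest position where the adapter (or an adapter
prefix of ≥ 10 nt reaching the read end) matches with ≤ 1 substitution;
passes repeat until nothing changes. The quality rule keeps a read iff
≥ 90% of its bases have Phred quality ≥ 30 (Phred+33). Reads shorter than
15 nt after trimming are discarded: shorter sequences are effectively
unmappable and inflate artefact counts.

Collapsed reads across libraries form a sequences × libraries count table.
Two retention modes exist: **study** mode keeps sequences with a summed
count ≥ 30 over all libraries of the experiment (read literally as the
total across libraries, not per library); **public** mode — for screening
external datasets whose design is unknown — only removes singletons.
Library sizes (cpm denominators) are recorded *before* row filtering, so
cpm stays on the retained-read scale.

### Attribution (`attribution`)

Mapping is exhaustive gapless alignment (substitutions only, no indels) of
each collapsed read against each reference sequence on both strands,
reporting every hit with ≤ 2 mismatches. sRNA reads are short enough that
indel alignments add little and the mismatch-tier semantics stay exact; on
references ≤ 50 kb the implementation is verified against a brute-force
window scan.

Host attribution is host-first: any sequence with at least one host-genome
hit is host, regardless of non-host hits. Candidate non-host genomes are
then pruned by two independently switchable criteria: (a) the genome
recruits at least one real read of ≥ 25 nt, and (b) it recruits strictly
more real reads than shuffled decoys. The decoy set is a per-read uniform
permutation of nucleotides (seeded), preserving length and mononucleotide
composition. Whether the recruitment comparison should instead be a formal
test is left open deliberately; the rule is exposed as configuration.

Loci are maximal intervals of overlapping same-strand hits. Multi-mapped
read counts are redistributed by iterative proportional allocation: locus
weights start from uniquely mapping reads; each multi-mapped read's count
is split across its loci proportional to current weights; iterate to a
fixed point (max change < 1e-6, cap 100 iterations, non-convergence
returned with a warning flag). A read whose loci all lack unique evidence
is split by a symmetric pseudocount — this is the only place the
pseudocount enters, so a locus pair with unique counts 10 and 2 sharing a
read of count 6 converges to (15, 3), and an instance with no unique reads
at all splits 50/50. Every read's allocation sums exactly to its count, so
totals are conserved by construction.

### Contaminant identification and quantification (`contaminants`)

The packaged six-assay panel (sRNA sequence, qPCR primer, annealing
temperature) defines the confirmed column contaminants; self-consistency
(each primer matches its own sRNA) is asserted at load. A read is assigned
to an assay iff it shares a perfect-identity alignment of ≥ 14 nt with the
primer, with reads allowed to extend beyond the primer. Because the
identity requirement is 100%, this is equivalent to a longest-common-
substring threshold, which is how it is implemented and tested (ties:
longest overlap, then assay order). All sequences are canonicalised to DNA
(U→T) at load.

Control-based flagging marks a sequence as an artefact iff it is detected
(≥ 1 copy) in strictly more than half of the control libraries; spike-ins
are never flagged. The complementary, stricter 90%-absence rule belongs to
the candidate cascade below. Absence of control libraries is a hard error —
the analysis is not defined without extraction controls.

Spike-in normalisation computes copies(seq) = count(seq)/count(spike) ×
40,000 copies/µL per library; libraries without detectable spike-in are
flagged and excluded, never silently zeroed. Screening mode applies
public-mode preprocessing to any local FASTQ and reports per-assay reads
per million over *retained* reads (a deliberate choice; the alternative
denominator, all raw reads, is not used anywhere). Depletion reporting for
clean-up treatments is fold change (untreated/treated, ∞ flagged at
complete depletion) and percent reduction, aggregated as mean ± SD.

### Exogenous candidate cascade (`exogenous`)

Filters run in a fixed order, so survivor sets are nested:

1. sequences assigned to confirmed contaminants (or control-flagged);
2. sequences detected in more than 10% of controls ("absent from at least
   90%" read as: detected in at most 10%);
3. sequences ever reaching ≥ 10 copies in any single control;
4. keep sequences with **more than** 3 reads in **more than** 7 of the 28
   plasma libraries — both inequalities strict, exactly as printed; the
   7-of-28 rule is stored as the fraction 0.25 so other designs rescale;
5. low-complexity sequences;
6. sequences with any host hit;
7. sequences whose best reference hit is a genus commonly reported as a
   sequencing-kit contaminant.

Low complexity is defined as mononucleotide Shannon entropy < 1.5 bits or
a homopolymer covering ≥ 2/3 of the sequence (the criterion is not further
specified in the underlying protocol; this pair of rules is the package's
choice and both parts are tested). Best hits are fewest mismatches, then
longest overlap, with ties broken toward removal — conservative, matching
the caution appropriate for low-biomass data. Candidates without any hit
are labelled "unknown" rather than dropped.

### qPCR quantification (`quant`)

Cp values are called by the second-derivative-maximum method: the curve is
smoothed with a window-5 quartic Savitzky–Golay filter and interpolated
with an order-7 spline whose analytic second derivative is maximised on a
fine grid. The quartic/septic choice is numerical, not cosmetic: a
quadratic smoothing kernel shifts the second-derivative peak of a
unit-width logistic by ≈ 0.45 cycles, while the implemented scheme is
accurate to < 0.05 cycles on noise-free sigmoids and degrades gracefully
under per-cycle noise. Curves whose overall rise is below the noise floor
are flagged no-amplification; curves without a positive interior
second-derivative peak are flagged unusable. Replicate Cp values are
averaged before quantification.

Standard curves are least-squares fits of Cp against log₁₀ copies over a
dilution series (≥ 3 distinct concentrations; seven orders of magnitude in
the reference design), with efficiency E = 10^(−1/m) − 1. Quantification
inverts the line: copies = 10^((b − Cp)/(−m)) — the only reading of the
quantification formula consistent with Cp = b + m·log₁₀(C).

The titration fit regresses log₁₀(cpm) on log₁₀(V) per contaminant, with
zero observations floored at the 0.5-read pseudo-cpm of their library.
The safe input volume solves predicted cpm = 100 (the default threshold);
the smallest *tested* volume meeting the threshold empirically is reported
alongside, because the two can disagree and the underlying criterion could
be read either way. Slopes outside [−1.5, −0.5] are flagged as implausible
for a reagent contaminant; the overall safe volume is the maximum over
contaminants (the binding constraint).

## The synthetic-data generator (`synthdata`)

The generator emulates the titration-with-controls design: plasma input
volumes of 45, 100, 225, 500 and 1115 µL on regular and ultra-clean
columns (replicates 3/3/3/3/2 per column type → 28 plasma libraries), plus
spiked mock extractions, column eluates, water and no-template controls.

The composition model is copy-number based. Each library's fragment pool
is endogenous copies/µL × V (split over planted host sRNA loci by a
seeded lognormal expression profile) + per-contaminant copies per column +
exogenous copies/µL × V + spike-in copies; reads are drawn multinomially.
Because contaminants are per column and everything else per µL, the
inverse-volume law is emergent, not hard-coded. Default copy numbers
(7200/1700/1750/1450/830/730 per column; 2000 endogenous copies/µL) are
calibrated so a 100 µL extraction on a regular column reproduces the
observed per-contaminant cpm levels (tens of thousands of cpm for the most
abundant sequence, ≈ 6% of the library in total). Exogenous species
default to 0.08 copies/µL (≈ 40 cpm — low-abundance, near the levels at
which genuine exogenous candidates were reported). Ultra-clean columns
divide all contaminant copy numbers by a clean-up factor, default 60 (the
reported median across batches; individual batches ranged far wider, so
the 100 µL-sufficiency of particularly clean batches is not implied by the
median). The spike-in is added to mock/eluate controls at 40,000 copies/µL
of a 14 µL eluate.

Reads are the sRNA insert with per-base substitution errors (default
0.001), followed by the 3′ TruSeq small RNA adapter, padded by cycling the
adapter to 75 nt (single-end 75-cycle layout). Qualities are constant Q36
with an option to inject low-quality bases for filter tests. RNA is stored
as DNA (U→T) everywhere, matching sequencer output. Water/no-template
controls default to zero reads (no carry-over), configurable.

Panel draws (exogenous and any extra contaminants) reject low-complexity
sequences (entropy threshold 1.6): the planted panels stand in for genuine
biological sRNAs, and a ground truth indistinguishable from the degenerate
artefact class the cascade filters would be a mis-specified simulation.
Planted panels are also checked for exact-match collisions with the host
genome (either strand); the host genome is regenerated on collision and
persistent collision is a hard error.

qPCR curves are four-parameter sigmoids in cycle number: baseline +
amplitude/(1 + exp(−(c − mid)/width)), with mid shifted by −log₁₀(copies)
× cycles-per-decade and cycles-per-decade = ln 10 / ln(1 + efficiency)
(3.3219 at perfect doubling). Zero-copy reactions give a flat baseline.
Noise is additive Gaussian; noise_sd = 0 gives analytic curves.

**What the generator does not model** — and hence what passing tests do
not establish about real data: ligation bias, PCR duplicates, indel
errors, paired-end layouts, quality-score structure, multiplexing
cross-talk, RT/poly-adenylation efficiency (treated as 1), and any
sequence similarity between contaminants and the host transcriptome.
Recovery results on synthetic data show the pipeline's logic is correct
under its own composition model, not that real studies are free of the
confounders the controls are designed to catch.

## Determinism and problem sizes

Every stochastic step takes an explicit integer seed; per-library seeds
derive deterministically from a master seed, and identical (config, seed)
pairs give byte-identical outputs. The test suite and the acceptance
script run the study conditions at reduced sequencing depth — 100,000–
200,000 reads per library, a 50 kb host genome with 40 planted loci, two
embedded non-host genomes — sizes at which every planted contaminant and
abundance-rule-passing exogenous species is comfortably detectable while
whole studies simulate in seconds. Twenty independently seeded studies
back the recovery statistics.

## Known limitations

- Host attribution uses genome sequence only; junction-spanning host reads
  (exon-exon) are an accepted blind spot and can surface as spurious
  non-host sequences in real data.
- Only 3′ adapters are trimmed; 5′ primer sequences embedded mid-read are
  not removed.
- The taxonomic classification of candidates is only as good as the
  user-supplied local reference collection; no live queries to public
  databases are made, so published candidate partitions that depended on
  comprehensive nucleotide databases are reproducible only against
  equivalent local references.
- The decoy comparison uses a count excess, not a calibrated statistical
  test; its false-retention rate is checked empirically on simulations.
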