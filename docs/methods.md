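# Methods

`radmut` re-implements, as a tested pipeline over synthetic data, the
computational analysis of mutational profiles in clonally expanded,
particle-irradiated human cell lines: somatic variant filtering from
jointly genotyped multi-sample VCFs, SBS96/ID83/SV classification, NMF
signature extraction with reference decomposition, graph-based
clustered-mutation detection, label-shuffling burden inference, and
negative-binomial regional mutation-rate regression. This note records the
models, the parameter choices that matter, and what the synthetic cohort
does and does not emulate.

## Variant model and filter cascades

A cohort is one cell line's set of clonally expanded cultures ("clones"),
jointly genotyped so that a mutation acquired by one clone after the
population bottleneck is genotyped in exactly one sample. "Genotyped"
means a non-missing, non-homozygous-reference genotype call; only such
calls attribute a variant to a clone.

SNVs must satisfy six rules: (1) caller PASS, (2) uniquely mappable
position (a boolean INFO flag, or intersection with a user BED mask in
0-based half-open coordinates), (3) population allele frequency absent or
< 0.1% (absence from the database passes), (4) genotyped in exactly one
clone, (5) biallelic VCF row, (6) ≥ 2 alt-supporting reads in the
genotyped clone. Small indels additionally need genotype quality ≥ 10 in
the genotyped clone and are removed when more than two other clones carry
≥ 1 supporting read or more than one other clone carries ≥ 2 — the
signature of a germline variant mis-genotyped in one clone. SVs pass
rules 1–5 plus ≥ 2 supporting split reads, with no spanning-read
requirement. All thresholds are keyword arguments; each rule can be
toggled, and removing any rule provably yields a superset (tested).
Paired same-chromosome breakends with inverted orientation can be
collapsed to single inversion records by a converter utility.

## Mutation classification

SNVs are tallied strand-symmetrically on the pyrimidine strand: 6 classes
(C>A … T>G) and 96 classes adding the trinucleotide context read from the
reference genome; purine-centred sites are reverse-complemented together
with their context. Indels are first reduced to their event sequence and
**left-normalized** (shifted to the smallest start giving an identical
haplotype); the convention is a package decision, since repeat-unit counts
are ambiguous without it. Binning follows the standard 83-category layout:
1-bp events by homopolymer run (deletions count the run including the
deleted base, capped at "6+"; insertions count pre-existing copies, capped
at "5+"; A/G folded to the T/C channels), 2–5+-bp events by tandem-repeat
unit count of the event sequence, and deletions with exactly one copy by
flanking microhomology (longest prefix of the deleted sequence matching
the sequence immediately after it; repeat context takes precedence). A
consequence of left-normalization worth knowing: an event that looks
microhomology-flanked at its right-shifted position can left-align into a
bona-fide tandem repeat, in which case it is a repeat deletion. SVs map
1:1 to DEL/INS/DUP/INV with length `END − POS` (insertions: inserted
sequence length when resolvable, else missing).

## Signature extraction

The catalog V (categories × samples, counts) is factorized as V ≈ S·E
with Kullback–Leibler NMF (multiplicative updates, ≤ 1000 iterations,
relative tolerance 1e−8) — the natural likelihood for count data; the
generalized KL objective is non-increasing under these updates (tested,
and cross-checked against an independent NMF implementation). Per rank k,
replicates run on bootstrap catalogs (per-sample multinomial resampling
preserving column totals); replicate spectra are matched to a running
consensus by Hungarian assignment on cosine similarity, and per-signature
stability is the mean cosine of matched replicates to the consensus.

Rank selection: a rank qualifies when **every** signature reaches
stability ≥ 0.8; among qualifying ranks, a larger rank is preferred only
when it improves relative reconstruction error by ≥ 5%. The stricter
min-stability + error-elbow rule was adopted after observing that a
"largest stable rank" rule happily splits a 3-process catalog into 5
components whose surplus parts the subsampling check then flags as
irreproducible; the elbow criterion selects the generative rank on such
catalogs. Exposures are refit per sample by non-negative least squares
against the final spectra and rescaled so attributed counts sum to the
sample's observed total.

Extracted spectra are assigned to the best-cosine reference signature when
the similarity is ≥ 0.85 (inclusive; ties broken lexicographically with a
warning), and decomposed over the reference catalog by NNLS with pruning
of components below 5% weight and refitting; weights are normalized to
sum 1 and the cosine of the reconstruction is reported, with fits below
0.9 flagged. The robustness check removes ⌊half⌋ of each external panel's
samples uniformly at random, three times, re-extracts at the selected
rank, and reports best-match cosines and exposure correlations on the
cohort's own samples.

## Clustered mutations

Point mutations of one clone are nodes of a graph; an edge joins two
mutations on the same chromosome at distance **strictly** below 1 kb.
Clusters are connected components of size ≥ 2, so chained mutations more
than 1 kb apart end-to-end still form one cluster; components of size > 5
(strict) are kataegis-like showers, the rest omikli-like. The
implementation is a linear sweep: on sorted positions, components are
maximal runs split at consecutive gaps ≥ threshold, and edges are
enumerated with a two-pointer window; an O(n²) all-pairs + graph-library
oracle is kept for equivalence testing. Inter-mutation distances are edge
distances, each unordered pair counted once (a `consecutive` mode is
available as a config switch). Only SNVs enter clustering by default;
indels can be included by flag. The clustered 6-class spectrum is compared
against the genome-wide spectrum; group distance comparisons use a Welch
t-test on log10 distances.

## Burden statistics

For each statistic (burden, ratio, exposure) with one value per clone,
group labels of all 21 clones are shuffled globally per iteration
(default 100,000) even for stratified comparisons; group means are
recomputed each time and both one-sided empirical p-values
p = (r+1)/(n+1) are reported — the minimum attainable p is therefore
1/(n+1), never 0. The headline p per comparison is min(p_ge, p_le), a
package decision since the combination rule is not fixed by the original
description; both sides are retained in outputs. An exhaustive mode
enumerates every distinct assignment of the observed values (small
cohorts), counting the identity arrangement among the "as extreme" ones.
BH correction is applied separately within statistic families (SNV
signatures, indel signatures, burdens); comparisons with unadjusted
p ≤ 0.1 are flagged in reports. Deletion:insertion balance is
deletions/insertions for small indels and log2(DEL/(INS+DUP)) for SVs;
zero denominators are undefined unless a pseudocount is configured.

## Regional enrichment

Mutations are assigned to non-overlapping covariate bins (BED-style,
0-based half-open; variant positions are 1-based VCF, converted in one
place). Counts per bin are modelled with a negative-binomial GLM (log
link, NB2 dispersion estimated by maximum likelihood, with a
method-of-moments fallback on non-convergence, logged in the fit record).
Sequence composition is controlled through a log-opportunity offset
computed from per-bin trinucleotide counts (optionally weighted by
genome-wide per-context rates); entering contexts as covariate terms is
available as the alternative mode. Treatment effects on the regional
gradient are tested in a joint model with a treatment × (ordinal level)
interaction and Wald p-values. On generated bins (gamma-Poisson, 2,000
bins, dispersion 0.05, base rate 20/bin), a 2× late rate is recovered
within ±0.1 of ln 2.

## Synthetic cohort

The simulator is the package's stand-in for the study's whole-genome
data and defines the default study conditions:

- 3 cell lines × (1 control + 2 helium + 4 proton) = 21 clones over a
  random 60 Mb, 3-chromosome genome (GC 0.42). The genome is large
  relative to the burden so that chance 1 kb adjacencies stay modest and
  injected clusters, not burden, drive the clustered-mutation contrast.
- SNV burdens ~1,000/clone (1,100 for proton — a deliberately modest
  excess); categories drawn from exposure-weighted mixtures of three
  synthetic SBS96 spectra (oxidative-like C>A, clock-like C>T/T>C,
  bulky-adduct-like T>A; proton/helium shift 10%/5% of exposure toward
  the adduct-like process) and placed at context-matched sites sampled
  without replacement from a trinucleotide site index.
- Indels: 150/180/280 per control/helium/proton clone with
  deletion:insertion ratios 1.5/2.5/4.0; deletion categories mix a
  1-bp slippage block with a longer/microhomology block whose weight
  rises with treatment (0.2/0.4/0.5). Sites are chosen so the planted
  category is exact by construction (verified by round-trip
  classification: 100% of SNVs, ≥ 99% of indels).
- Clusters: controls get one pair; helium six pairs + two 6-mutation
  showers; proton five pairs + one shower; members are C>T by default,
  spaced < 1 kb.
- SVs: a handful per clone with a deletion excess and log10-normal
  lengths whose mean shrinks from control (10^4.3) to proton (10^3.7),
  mirroring the observed shorter proton deletions.
- Reads: fixed depth 40, alt reads binomial around the ploidy-dependent
  mean VAF (1.0 HAP1-like haploid, 0.5 A549-like diploid-het, 0.25
  MCF7-like tetraploid-het), conditioned on ≥ 2 alt reads so every truth
  record is detectable by the filters. One contaminant record per filter
  rule is planted per cohort (skipped when the cohort has too few clones
  to construct the violation), so filtering should retain exactly the
  truth set.

Unlike real data, the simulator has no sequencing-error reads, no
germline variation, uniform mutation placement (no replication-timing
gradient — the regional analysis on the cohort is a true null), no
copy-number segments (one VAF peak per clone), and perfectly resolved SV
breakpoints. Equal SNV burdens across cell lines are a deliberate
departure from the study's cell-line differences: they keep the
clustered-mutation contrast attributable to the injected clusters on a
desk-scale genome. Passing tests therefore demonstrate correctness and
calibration of the pipeline, not rediscovery of any biological result.

## Numerical choices and problem sizes

Tests and the acceptance script run the cohort at the default design
(21 clones, 60 Mb genome), signature recovery at 21 samples × 2,000–5,000
mutations with sparse (Dirichlet 0.5) exposures — dense mixing makes NMF
non-identifiable regardless of implementation — the cluster oracle on
up to 5,000 positions per set, the type-I simulation at 500 datasets ×
2,000 iterations, and the regional recovery at 2,000 bins. All stochastic
steps take explicit seeds; cohort simulation is byte-deterministic given
the seed.

## Known limitations

- ID83 classification assumes clean, single-event VCF alleles; complex
  substitutions raise rather than guess.
- The NMF stability score (cosine to consensus) is more permissive than a
  silhouette over replicate clusters; the error-elbow rank rule
  compensates.
- The exhaustive permutation mode enumerates distinct value assignments
  and is limited to small cohorts.
- Mappability masks and covariate bins are consumed, never derived, and
  SV insertion lengths are missing unless the inserted sequence is
  resolved in the ALT.
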