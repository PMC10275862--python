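# radmut

Analysis pipeline for mutational profiles of particle-irradiated, clonally
expanded human cell lines. Exposures of cultured cells to proton or helium
(alpha) beams — the dominant charged components of galactic cosmic
radiation, and increasingly relevant to tumor radiotherapy — leave subtle
footprints in the genome: shifts in indel spectra, a deletion excess,
clustered point mutations. Detecting them from whole-genome sequencing of
single-cell-derived clones requires a chain of careful statistics, which
this package implements as a reusable, fully tested library plus numbered
analysis drivers:

- **Somatic filtering** of jointly genotyped multi-sample VCFs: caller
  PASS, mappability, population AF < 0.1%, clone-private genotyping,
  biallelic rows, ≥ 2 supporting reads; indels add GQ ≥ 10 and cross-clone
  support rules; SVs require ≥ 2 split reads (`radmut.variants`).
- **Classification** into the strand-symmetric 6- and 96-class SNV
  spectra, the 83-category indel scheme (homopolymer / tandem-repeat /
  microhomology context), and SV classes with lengths (`radmut.classify`).
- **Signature analysis**: KL-NMF extraction `V ≈ S·E` with bootstrap
  stability, rank selection, cosine assignment to a reference catalog
  (threshold 0.85), NNLS decomposition, and an external-data subsampling
  robustness check (`radmut.signatures`).
- **Clustered mutations**: graph components over pairs < 1 kb apart;
  components of size > 5 are kataegis-like showers, smaller ones
  omikli-like fog; clustered spectra and inter-mutation distances
  (`radmut.clusters`).
- **Burden statistics**: global label-shuffling randomization tests with
  two empirical p-values `p = (r+1)/(n+1)`, BH correction per statistic
  family, deletion:insertion ratios, length comparisons (`radmut.burden`).
- **Regional enrichment**: negative-binomial regression of binned mutation
  counts on replication-timing-style covariates with trinucleotide
  opportunity offsets and treatment × level interactions
  (`radmut.regional`).
- **Synthetic cohort simulator** with record-level ground truth — 21
  clones (3 cell lines × control/helium/proton), signature-mixture SNVs,
  category-exact indels, SVs, injected clusters, ploidy-dependent VAF
  peaks at 1.0 / 0.5 / 0.25, and planted filter-rule contaminants
  (`radmut.simulate`).

See `docs/methods.md` for the models, conventions and design decisions.

## Worked example

Run the drivers in order (outputs land in `results/`, large intermediates
in `scratch/`):

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/02_filter_variants.py
python analysis/03_classify_mutations.py
python analysis/04_extract_signatures.py --seed 1
python analysis/05_cluster_mutations.py
python analysis/06_burden_tests.py
python analysis/07_regional_enrichment.py --seed 1
```

Script 01 prints the simulated burdens per treatment group:

```
Mean burdens by treatment:
            n_snv  n_del  n_ins  clustered
control    1002.0   93.7   56.3        2.0
helium     1024.0  127.0   53.0       24.0
proton     1116.0  223.2   56.8       16.0
```

Script 02 confirms that filtering retains exactly the truth records while
removing every planted contaminant (`kept == truth in every cohort:
True`). Script 04 surveys NMF ranks, selects `k=3`, and assigns each
extracted signature to its generating reference spectrum at cosine
≈ 0.9999; after removing half of each external panel three times, every
signature is re-found at cosine ≥ 0.999. Script 05 tallies the clustered
mutations:

```
           clustered_mutations  omikli_like  kataegis_like
control                     89           44              0
helium                     362          144             12
proton                     681          302             12
```

and shows the clustered 6-class spectrum shifting toward C>T (0.46
clustered vs 0.24 genome-wide) — the injected shower class. Script 06 runs
the randomization tests; the planted effects surface with, e.g.,
`ids_del_ins_ratio proton vs control: observed diff +2.31, p = 1e-5,
q < 0.001` and `clustered_mutations helium vs control: +30.7,
p = 1.6e-4`. Script 07 fits the regional NB model: the cohort's SNVs are
placed uniformly, so the replication-timing coefficients are null
(p ≥ 0.45), while the recovery demonstration estimates a log rate ratio
of 0.705 for a known 2× enrichment (ln 2 ≈ 0.693).

The same stages are scriptable through a thin CLI:
`radmut simulate|filter|classify|cluster|permtest|regional --help`.

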