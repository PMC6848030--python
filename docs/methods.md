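# Methods

This note documents the statistical models, conventions, and design
choices behind the package, in the spirit of a model-description page.

## Input model

The unit of observation is a predicted gene on an assembled contig,
treated as a single independent entry. A gene carries: sample of origin,
nucleotide length, a domain-level taxonomic call with optional
phylum/class/family/genus lineage, the percent amino-acid identity and
alignment-coverage fraction of its best reference hit, functional term
sets in four namespaces (COG, PF, KO, EC), an organelle flag for
eukaryotic genes, and an RNA marker. Identity and coverage exist exactly
when a taxonomic call exists; the organelle flag is meaningful only for
eukaryotes. Files are strict TSV (UTF-8, header row, ";"-separated
multi-value cells, empty cell = missing, decimal point only); the reader
either aborts on the first malformed row (strict) or drops and counts
malformed rows (lenient).

## Taxonomic profiling

Two annotation gates are used, both inclusive at the boundary:
**30/70** (identity ≥30%, coverage ≥0.70) for domain-level calls and
**60/70** for family/genus-level calls. Two denominators:

* *Percent of total annotated CDS* — domain composition over the five
  groups Archaea / Bacteria / Viruses / Bacillariophyta (diatoms) /
  other Eukaryota, which partition the 30/70-gated set, so columns sum
  to 100 within rounding.
* *Percent of total ABV* — the denominator restricted to
  Archaea+Bacteria+Viruses genes at 30/70. Eukaryotic genes never enter
  numerator or denominator, so diatom-load differences between samples
  (0.01%–26% in the reference survey) cannot distort prokaryote
  profiles; any perturbation of eukaryotic records leaves ABV matrices
  bit-identical. Numerators use the gate appropriate to the rank
  (60/70 by default for family/genus).

RNA genes are excluded from all CDS-based numerators and denominators by
default (a toggle exists): the analysis concerns protein-coding genes,
and RNA genes are ~1% of predictions. Multi-term genes count once per
distinct term; there is no fractional splitting. Phylum totals are always
computed from phylum-rank labels rather than by summing class rows, since
real annotation tables contain class-less members of a phylum (the
package's synthetic Bacteroidetes deliberately include one such family).

## Effective-genome normalization

Functional-category abundance comparisons across metagenomes of different
depth and community structure use genes per effective bacterial genome:
count of genes carrying the term divided by the sample's genome
equivalents G. The effective genome size (EGS, Mbp) is an *input* — it
comes from upstream marker-gene estimation and is not re-estimated here.
G is reconstructed as

    G = assembly_Mbp × (pct_bacteria/100) × (pct_tax_annotated/100) / EGS_Mbp

i.e. the bacterial, taxonomically-annotated fraction of the assembly
divided by the average bacterial genome length. On the packaged
11-sample survey this reconstruction matches the published
genome-equivalents row within ±4 for every sample (max deviation 3.8),
which is also the tolerance the tests enforce; the residual reflects
rounding in the published percentages.

Feature selection before clustering follows two conventions:
taxonomic features kept when reaching ≥0.35% of total ABV in at least
one sample (the "max" reading; a "mean" switch exists), functional
features kept at ≥1 gene/genome in ≥2 samples.

## Diatom physiological-state proxy

Diatom genomes encode >98% of proteins in the nucleus; the chloroplast
(4 membranes) protects its DNA roughly twice as well as the nucleus
(2 membranes) after cell death. The proxy is

    %RuBisCO = 100 × n(chloroplast-encoded EC 4.1.1.39) / n(diatom genes with ≥1 EC term)

The denominator *includes* the RuBisCO genes themselves, bounding the
statistic at 100%; an "exclusive" variant (divide by the non-RuBisCO
remainder) is available, and result files record which was used. The
two differ negligibly in the regime of interest (numerator ≪
denominator). EC 4.1.1.39 and KO:K01601 are treated as synonymous rbcL
markers; EC is authoritative for the proxy, either suffices for the
genus composition. A sample qualifies only with ≥10 diatom RuBisCO genes
(inclusive); below that the percentage is withheld as unstable.

Genus composition of rbcL uses only genes of length ≥500 bp (inclusive)
— roughly one third of full-length rbcL, below which genus assignment is
unreliable; genes without a genus label fall into an "unresolved" row.

Stage classification ("early" vs "late" bloom degradation) applies a
threshold to %RuBisCO. No canonical cutoff exists — observed regimes are
roughly 0.3–1.3% for fresh material and ≥3–10% for decayed material — so
the threshold is an explicit configuration parameter defaulting to 2.0%,
an implementation choice sitting between the regimes.

## Clustering and significance

* **Resemblance**: Spearman rank correlation with mid-ranks for ties
  (Pearson correlation of ranks); distance d = 1 − ρ ∈ [0, 2]. Only the
  ordering of d matters to the linkage, so the scale choice is
  inconsequential. Constant profiles have undefined ρ; they are excluded
  with a logged warning and listed on the result.
* **Average linkage (UPGMA)** is implemented in-package via the exact
  Lance–Williams update, with equal-height candidate merges resolved in
  favour of the lowest original index pair. This pins down dendrograms
  bit-for-bit across platforms, which a library implementation does not
  guarantee; tests verify agreement with an exhaustive cross-pair-mean
  oracle (100 random instances, n ≤ 8) and with SciPy's implementation
  on tie-free instances. UPGMA heights are monotone, so cophenetic
  distances are ultrametric (also property-tested). Newick exports carry
  cophenetic branch lengths; tip-to-tip path length equals twice the
  merge height.
* **SIMPROF**: top-down over the sample dendrogram. At a node with ≥3
  member samples, the observed profile is the sorted vector of pairwise
  Spearman similarities among members; the expected profile is the
  element-wise mean over `n_perm_mean` permutations, each independently
  permuting every feature's values across the member samples; the
  statistic is π = Σ|s₍ᵢ₎ − s̄₍ᵢ₎|; the p-value ranks the observed π
  among `n_perm_test` further permuted π values with add-one continuity.
  Recursion descends only into significant nodes (p ≤ α); groups of
  size <3 are untestable and accepted as-is. Permutation counts default
  to the conventional 1000 / 999 (configurable); the source
  publications of the procedure leave them unstated. SIMPROF runs on
  the sample axis only. Calibration: over 200 exchangeable null tables
  (11 samples × 160 features) the root-node rejection rate at α = 0.05
  is 0.03–0.07 (measured 0.035–0.05 depending on seed; the procedure is
  mildly conservative, as expected when the mean profile is estimated
  from the same null).
* **Query correlation**: Spearman ρ of a query feature's profile against
  every feature, two-sided p from t = ρ√((n−2)/(1−ρ²)) with n−2 df
  (|ρ| = 1 maps to p = 0). p-values are raw by default, matching common
  practice of reporting raw thresholds (p ≤ 0.001, p ≤ 0.05) in this
  literature; a Benjamini–Hochberg switch exists. A seeded Monte-Carlo
  permutation alternative (10,000 draws) is available for the small
  sample counts where the t-approximation is questionable.

All randomness flows from a single integer seed recorded in every
result object.

## Synthetic-data generator

The generator emulates the statistical shape of an annotated sediment
survey without any sequence content. Per sample, a category vector
(RNA, unannotated, diatom, taxon roster, domain-only remainder) is drawn
from a Dirichlet centred on the sample's cluster profile — the standard
overdispersed Dirichlet-multinomial model for community profiles — and
gene counts from a multinomial. Functional terms attach per taxon as
Bernoulli marks at configured per-gene rates, so taxon–function
correlations exist by construction (the basis of the query-correlation
tests). Identity/coverage are drawn from a mixture straddling the 30/70
and 60/70 gates, independent of taxon, so gating preserves planted
proportions. Diatom genes split into chloroplast and nuclear
compartments (deterministic split `round(n0·frac_chl0)`) and survive
decay state d independently with exp(−k·d), with k_nuc ≥ k_chl; the
default 2:1 rate ratio echoes the membrane-protection argument and is a
convention, not a measured value. Closed-form expected %RuBisCO is
emitted in the truth record.

The packaged default scenario mirrors the 11-sample reference design:
four clusters sized 4/2/1/4 (A: diatom-rich, bloom-utilizing
Bacteroidetes/Alteromonadaceae, low decay; B: high pre-decay diatom load
at high decay state with a distinct Bacteroidetes guild; C: a
methanogen/syntroph-flavoured singleton; D: chemolithotroph-leaning,
diatom-poor), 12,000 genes per sample, Dirichlet concentration 700.
The separation (concentration, profile contrasts) was calibrated so the
planted partition is the unambiguous 4-way cut of the sample dendrogram:
across 100 generator seeds the cut-at-4 partition matches the truth with
adjusted Rand index 1. Two generator parameters are deliberately
stylized relative to single-copy genomic ratios: the chloroplast share
of diatom genes (0.05) and the rbcL share of chloroplast genes (0.15)
are raised — defensible because chloroplasts and their genomes are
multi-copy per cell — so that the ≥10-RuBisCO qualification rule is
exercised on both sides at 12k genes/sample. Consequently absolute
%RuBisCO values (≈1% fresh → ≈3% decayed) compress the real-data
contrast (≈0.3–0.4% → 5–10%) while preserving its direction and the
monotone dependence on decay state.

What passing tests on synthetic data do **not** show: robustness to
annotation biases that correlate with taxon (identity noise here is
taxon-independent), to chimeric assembly, to reference-database
incompleteness, or to compositional artefacts beyond
Dirichlet-multinomial overdispersion. Real surveys also have far larger
per-sample gene counts (~10⁶), where the qualification rule and
multinomial noise matter much less.

## Numerical conventions and problem sizes

Percentages are computed at full precision and reported at 2 decimals.
ρ is clipped to [−1, 1] against floating-point overshoot. Samples with a
zero denominator (no annotated genes, zero ABV, zero genome equivalents)
yield absent values with a logged warning rather than silent zeros.
Validation-study sizes: SIMPROF calibration uses 200 null tables of
11 × 160 at the default 1000/999 permutations; oracle checks use 100
random instances each (≤8 leaves, ≤12 observations); the decay study
uses 20 samples of 15,000 diatom genes over d ∈ [0, 3]. These sizes give
stable statistics while keeping the full validation run in the
low-minutes range on one CPU.

## Known limitations

* EGS must be supplied; the package deliberately does not estimate it
  from marker genes.
* The genome-equivalents formula is a reconstruction of the published
  arithmetic; agreement within ±4 is demonstrated, exact agreement is
  not claimed.
* SIMPROF p-values inherit the mild conservatism of estimating the mean
  profile under the same permutation null.
* The CLI's partial-rerun logic keys on content digests of inputs and
  parameters; it does not track code versions beyond the package
  version string in the manifest.
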