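# sedprof

Gene-centric comparative profiling of estuarine sediment metagenomes.

In river-dominated estuaries, sediment microbial communities are shaped by
pulses of labile organic matter — chiefly diatom detritus deposited after
coastal blooms. Assembled, annotated shotgun metagenomes from such
sediments pose three recurring analysis problems that this package solves
as a tested, reusable pipeline over per-gene annotation tables (one row
per predicted CDS with taxonomy, best-hit identity/coverage, and
COG/Pfam/KO/EC functional terms):

1. **Comparable abundance profiles.** Taxon abundance is computed under
   two denominators: percent of all annotated CDS (domain composition),
   and percent of "total ABV" — only genes annotated as **A**rchaea,
   **B**acteria or **V**iruses at ≥30% amino-acid identity over ≥70% of
   the alignment — which makes prokaryote/virus profiles insensitive to
   wildly uneven eukaryotic (diatom) gene loads. Family/genus-level calls
   use the stricter ≥60%/≥70% gate. Functional-category abundance is
   normalized per *effective bacterial genome*:

   genes/genome = n(term) / G,  with
   G = assembly_Mbp · f_bacteria · f_annotated / EGS_Mbp

   where EGS is the effective (average) bacterial genome size and G the
   sample's genome equivalents.

2. **Are the diatoms alive or dead?** Diatom nuclear DNA (2 membranes)
   decays faster post-mortem than chloroplast DNA (4 membranes), and >98%
   of diatom genes are nuclear. The chloroplast:nuclear balance therefore
   proxies physiological state:

   %RuBisCO = 100 · n(chloroplast rbcL, EC 4.1.1.39) / n(diatom genes with an EC term)

   Low values (&lt;1–2%) indicate intact cells (early bloom degradation);
   strongly elevated values indicate decayed cells whose nuclear DNA is
   gone (late degradation). Samples with fewer than 10 diatom RuBisCO
   genes are reported as unqualified rather than given an unstable ratio.

3. **Which samples group together, and is the grouping real?** Samples
   and features are clustered in 2D with Spearman rank correlation
   (mid-ranks; distance d = 1 − ρ) and unweighted average linkage
   (UPGMA), with deterministic tie-breaking. Sample-group significance is
   tested with SIMPROF: at each dendrogram node the sorted profile of
   pairwise similarities s₍ᵢ₎ is compared against the mean profile s̄₍ᵢ₎
   from permutations that shuffle each feature independently across the
   member samples, via π = Σᵢ |s₍ᵢ₎ − s̄₍ᵢ₎| and a second, independent
   permutation set for the p-value. Cluster-associated features are then
   found by Spearman *query correlation* against a highly abundant
   "query" feature, with two-sided p from the t-approximation on n − 2
   degrees of freedom.

A synthetic-data generator (`sedprof.simulate`) produces annotation
tables with planted cluster structure, taxon blocks, decay states and
exchangeable nulls, so every stage is testable without downloads. The
published per-sample summary statistics of an 11-metagenome Columbia
River estuary sediment survey ship as packaged fixtures
(`sedprof.datasets`) for the summary arithmetic.

## Worked example

```python
import sedprof as sp

cfg = sp.default_config()                      # 11 samples, 4 planted clusters
table, summaries, metadata, truth = sp.simulate_annotation_table(cfg)

abv = sp.taxon_abundance_abv(table, rank="family")      # % total ABV
sel = sp.select_features_taxonomic(abv, min_pct=0.35)   # ≥0.35% in ≥1 sample
res = sp.simprof(sel, seed=cfg.seed)
print([tuple(g) for g in res.groups])

proxy = sp.rubisco_ratio(table)
stages = sp.classify_degradation_stage(proxy)
for r in proxy:
    print(r.sample_id, r.n_rubisco,
          "-" if r.pct_rubisco is None else round(r.pct_rubisco, 2),
          stages[r.sample_id])
```

prints the four planted sample groups, recovered exactly and all
SIMPROF-significant:

```
[('A1_BBB', 'A3_BBA', 'A2_BBI', 'A4_BBC'), ('B1_YBM', 'B2_CBA'),
 ('C1_BBB',), ('D1_YBM', 'D2_YBB', 'D4_CBK', 'D3_CBC')]
```

followed by the viability proxy: the diatom-rich, low-decay cluster A
sits near baseline (1.05–2.05% RuBisCO), the heavily decayed cluster B is
enriched about 3× (3.06–3.08%, labelled `late`), and the diatom-poor
C/D samples carry too few RuBisCO genes to qualify:

```
A1_BBB 13 1.08 early
A2_BBI 17 1.31 early
A3_BBA 27 2.05 late
A4_BBC 11 1.05 early
B1_YBM 16 3.08 late
B2_CBA 16 3.06 late
C1_BBB 2  -    unqualified
D1_YBM 2  -    unqualified
...
```

The same pipeline runs from the shell:

```
sedprof --outdir out all        # simulate → profile → proxy → cluster →
                                # simprof → query → report
```

Stage outputs are TSV files plus Newick dendrograms; `out/manifest.json`
records content digests so unchanged stages are skipped on rerun.

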