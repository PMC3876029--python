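# ksdev

Transcriptomics toolkit for the developing olfactory system, aimed at
candidate-gene discovery for Kallmann syndrome (KS): anosmia plus
hypogonadotropic hypogonadism caused by failed olfactory axon / GnRH-neuron
development. The package re-implements, as a tested and reusable pipeline,
the bespoke computations such a profiling study needs:

1. **Mesenchymal contamination correction.** Dissected olfactory epithelium
   (OE/VNO) inevitably carries adjacent nasal mesenchyme (MES). With a
   mixing fraction *F* estimated from tissue-exclusive marker genes
   (epithelial-only FoxJ1/Fmo2/Ehf, mesenchymal-only Sp7/Lect1; qPCR
   ratios via 2^(−ΔΔCq)), epithelial profiles are corrected replicate-wise
   on the linear scale: *E\_i^c(g) = E\_i(g) − F · M̄(g)*, where *M̄(g)* is
   the replicate-averaged mesenchymal expression. Genes driven to a
   "no expression" floor are flagged and tested for enrichment of
   mesenchymal up-regulated genes (hypergeometric).
2. **Rank Products differential expression.** For a triplicate-vs-triplicate
   contrast, all K = 9 between-replicate log2 fold changes are ranked per
   comparison and combined as RP\_g = (∏\_k r\_gk)^(1/K); significance is a
   permutation-based proportion of false positives (pfp), used as the
   FDR-adjusted p-value. DEGs are called at pfp ≤ 0.05 and |log2 FC| ≥ 0.9.
3. **Conservation-filtered PWM target prediction.** Homeodomain (Dlx5-style)
   binding sites are scored as log-likelihood ratios against an intergenic
   background model, keeping windows at ≥ 50% of the maximum possible score
   on either strand. A site is conserved with species S when its gaplessly
   aligned window in S is itself a site by the same rule; sites conserved in
   ≥ 2 species are associated to the nearest TSS, and a gene is a *best
   target* when some site has ≥ 3-species support and lies < 10 kb from the
   TSS. Target/DEG overlaps are tested hypergeometrically.
4. **Conserved co-expression prioritization.** Reciprocal top-k correlation
   networks are built per species, intersected through a one-to-one
   ortholog map, and candidate genes are ranked by how many known KS
   ("reference") genes sit among their conserved-network neighbors
   (hypergeometric neighborhood test, Benjamini–Hochberg adjusted).

Every stage runs on synthetic data with known ground truth
(`ksdev.synthetic`): mixed-tissue expression matrices with planted DEGs and
a known *F*, toy multi-species genomes with planted motif instances and a
per-site conservation plan, and two-species compendia with planted
conserved co-expression modules containing designated reference genes.

## Worked example

```sh
ksdev run --seed 2 --out run/
cat run/summary.md
```

prints

```
# Run summary
seed: 2  fingerprint: 7ba73d29521f9f90
F applied: 0.1582 (estimated: 0.1582)
genes dropped by subtraction: 422 (mesenchymal enrichment p = 1.48e-35)
DEGs [stage]: 32 up, 43 down (planted-DEG recall 0.7667)
DEGs [genotype]: 57 up, 52 down (planted-DEG recall 0.7)
PWM sites: 6 raw, 4 conserved
target genes: 4 (3 best)
printed-intersection check: 19/121 = 16%
conserved co-expression edges: 90
extract counts by min_k: {1: 14, 2: 14, 3: 6, 4: 6, 5: 0, 6: 0}
significant candidates (adj_p <= 0.05): 6
```

Reading this: the study was simulated with a true mesenchymal fraction of
0.15 and the marker-based estimate came back 0.158. After subtraction, 422
of 2000 genes hit the expression floor, and those are overwhelmingly the
planted mesenchyme-specific genes (p ≈ 1e−35). Rank Products recovers most
planted DEGs through the contamination (recall 0.70–0.77 on corrected
data; recall is ≥ 0.9 on uncontaminated data — the loss is a property of
tissue mixing, not of the statistic). Of 6 planted PWM sites, the 4 with
≥ 2-species support survive the conservation filter and 3 meet the best-
target rule. The conserved network keeps the two planted 10-gene modules
(45 edges each), and all planted disease genes score significantly against
the reference genes. The `19/121 = 16%` line is the worked
target×down-DEG intersection computed from its printed counts.

Each stage is also exposed separately (`ksdev simulate|correct|degs|scan|coexp`)
and as library functions for use on real matrices, genomes, and compendia.

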