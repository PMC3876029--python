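# Methods

This note records the models behind each stage, the defaults and why, what
the synthetic data do and do not emulate, and the choices made where the
design was genuinely open.

## Contamination model and correction

Observed epithelial intensity is modelled as a two-component linear
mixture, `E_obs(g) = (1 − F)·E_pure(g) + F·M(g)`, with one global mixing
fraction `F`. All mixing and subtraction arithmetic happens on the linear
intensity scale — RNA abundances add linearly; subtracting log
intensities would be dimensionally wrong — while matrices are stored and
modelled in log2.

- **F estimation** uses mesenchymal-only markers: per marker, the ratio of
  mean linear abundance in epithelial samples to that in pure mesenchyme;
  `F` is the median of the ratios (robust to one bad marker; the mean is
  available via `central="mean"`), clipped to [0, 1]. Markers whose
  mesenchymal abundance does not clear the matrix's 5th percentile carry
  no signal and are excluded with a warning. The companion qPCR route
  quantifies the same ratios as 2^(−ΔΔCq) fold differences normalized to
  reference genes (TBP/GAPDH by default in the generator).
- **Subtraction** removes `F` times the replicate-averaged mesenchymal
  profile from every epithelial replicate. "No expression" is
  operationalized as a floor at the 5th percentile of the linear
  epithelial matrix (configurable); corrected values below it are set to
  the floor.
- **Dropped genes.** A gene is dropped when at least half of its
  replicates hit the floor. A majority vote was chosen over unanimity
  deliberately: the noise model is multiplicative on the observed mixture,
  so for a gene whose signal is almost entirely mesenchymal a single
  replicate drawn a quarter log2-unit high clears the floor by chance, and
  a unanimity rule would almost never fire on exactly the genes the rule
  exists for. Dropped genes are tested for enrichment of mesenchymal
  up-regulated genes with the hypergeometric upper tail.
- The `F`-robustness claim is operationalized as: down-DEG lists from
  corrections at F = 0.10 and F = 0.20 have Jaccard similarity ≥ 0.7 on
  the default synthetic study (measured 0.75–0.90 across seeds).

Whether one `F` covers all stages/regions is exposed as a choice
(`estimate_mes_fraction(..., scope=...)`); the default is a single global
`F`, estimated at 0.153–0.156 on studies simulated at true F = 0.15 (the
small positive bias is the epithelial background term, (1−F)·2^−Δ with
marker contrast Δ = 8 log2 units).

## Rank Products

For contrast groups A, B (|A| = |B| = 3 by default) the K = |A|·|B|
pairwise log2 fold changes are ranked per comparison (rank 1 = most
changed in the tested direction; ties get average ranks) and combined as
the geometric mean, computed in log space. The null distribution permutes
each comparison's rank column independently — the original Rank Products
null — with `n_perm` = 1000 by default (150–500 in the test suite and
pipeline, which is ample at the simulated study sizes). For gene g, `E(g)`
is the expected count of null genes with RP ≤ RP_g and
`pfp(g) = E(g)/position(g)`, with a monotone (step-up style) envelope
enforced along the RP ordering; pfp is reported as-is and plays the role
of an FDR-adjusted p-value. DEG calling applies pfp ≤ α (0.05) and
|mean log2 FC| ≥ 0.9; the fold-change filter can be disabled
(`fc_cut=None`) since some published comparisons omit it.

The estimator is validated against an exact oracle: under the null a fixed
gene's per-comparison rank is marginally uniform and independent across
comparisons, so E(g) = n·P(rank-tuple geometric mean ≤ RP_g), enumerable
over n^K tuples. Null calibration on 1000 exchangeable genes gives ~3.5%
of genes at pfp ≤ 0.05.

## PWM scanning and conservation

Counts are converted to probabilities with a pseudocount of 0.01 per base
per column (avoids −∞ scores); window scores are log2 likelihood ratios
(bits) against a background of intergenic base frequencies. The keep rule
is score ≥ `rel_threshold` × maximum possible score (default 0.5,
pseudocounted matrix), which requires a positive maximum; both strands are
scanned and minus-strand hits are reported in plus-strand BED coordinates.
Windows containing non-ACGT bases are skipped.

Conservation follows the recursive definition: species S supports a hit
iff the hit's footprint lies inside a gapless aligned block and S's
aligned W bases score at or above the same relative threshold (either
strand; the focal background model scores all species — simpler and
symmetric than per-species backgrounds). Gapped footprints contribute no
support. Hits with support ≥ 2 species are kept; target association picks
the nearest TSS within `max_dist` (ties to the lower coordinate), and the
best-target flag requires support ≥ 3 and distance strictly < 10,000 bp,
measured 0-based from the nearest site base.

Gene ranking aggregates per site
`support × (score/max score) × exp(−distance/5 kb)` — a reconstruction,
since no canonical formula exists for this step; all three knobs are
configurable and the tests only rely on its dominance behavior.

## Conserved co-expression and prioritization

Per-species networks use reciprocal top-k Spearman neighbors (k = 10) with
|ρ| ≥ 0.5; both knobs are open because the original browser's internals
are not public, and the reciprocal-rank rule keeps hub sizes bounded.
Constant genes are excluded. The conserved network keeps an edge iff both
endpoints have one-to-one orthologs and the mapped edge exists in the
other species; genes without orthologs are reported separately rather than
failing (mirroring how KAL1, which lacks a mouse ortholog, must be set
aside). Candidate scoring: for a gene with degree d and k reference
neighbors, the hypergeometric upper tail of k among d draws from N−1 genes
containing K references, BH-adjusted across the candidate list, ranked by
adjusted p, then k, then gene id.

## Synthetic data: what it emulates, what it does not

The generators reproduce the *structure* of the study — three stages ×
two regions × two genotypes × three replicates, linear-scale mixing at
F = 0.15, planted DEG sets at ±2.0 log2, log2-Gaussian noise (sd 0.25),
tissue-exclusive markers 8 log2 units above background, 50
mesenchyme-specific genes, toy 10 kb genomes with 6 planted consensus
sites and a per-site conservation plan over 8 species, and 100-sample
two-species compendia with two conserved 10-gene modules (ρ = 0.9), one
single-species decoy module, and 6 designated reference genes. Default
sizes (400–2000 genes) are scaled-down study analogues chosen so the whole
suite and pipeline run in seconds while keeping every statistic
well-conditioned.

Not emulated: probe-level array artifacts and normalization (profiles are
born gene-level), realistic phylogenetic substitution (non-conserved site
copies are degraded deterministically below threshold, not evolved),
gapped alignments, multi-cell-type mixtures, and correlated gene-gene
background structure. Passing tests therefore demonstrate correctness of
the computations and recoverability under the stated model, not
performance on real arrays.

All randomness flows from one top-level seed; independent streams are
derived per named sub-task via `SeedSequence` spawn keys hashed from a
stable string label, so adding a consumer never perturbs existing streams.

## Numerical and degenerate-input choices

- RP computed via mean of log ranks; ties averaged (`scipy.stats.rankdata`).
- pfp monotone envelope: cumulative minimum from the weakest gene down.
- Subtraction at F = 0 short-circuits to an exact identity (no flooring).
- Hypergeometric tails via `scipy.stats.hypergeom.sf`; BH via statsmodels,
  cross-checked against a quadratic-time reference.
- PWM max score ≤ 0 (e.g. a flat matrix) is rejected rather than scanned.
- Empty DEG lists, empty candidate lists, and reports with zero
  candidates are explicit, not omitted.

## Known limitations

- One global F; no per-sample or multi-component deconvolution.
- The conservation filter requires gapless blocks of exactly the motif
  width; real MAF alignments would need gap-aware window extraction first.
- The target rank score and the network edge rule are reconstructions;
  conclusions that depend on their exact form should be checked against
  their configuration space.
- pfp can exceed 1 (capped only for display) and is a per-gene expected
  false-positive proportion, not a familywise error rate.
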