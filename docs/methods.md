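# Methods

`mitocub` implements the standard battery of codon-usage-bias (CUB)
diagnostics for small sets of mitochondrial protein-coding genes (PCGs),
together with a synthetic CDS generator that provides ground-truth test
surfaces for every stage. This note records the models, the conventions and
numerical choices behind them, and what the synthetic tests do and do not
establish about real data.

## Genetic codes and codon bookkeeping

All statistics are parameterised by an NCBI translation table
(`mitocub.codes.GeneticCode`). The default is table 4 (mold mitochondrial),
the annotation used for the fungal mitogenomes this package targets; table 1
(standard) is a one-flag switch. The choice matters structurally: under the
standard code Trp (UGG) and Met (AUG) are single-codon families and the
degenerate-codon space has 59 dimensions, while under table 4 UGA is
reassigned to Trp, making Trp two-fold and the degenerate space
61-dimensional. Every derived quantity (GC3s site set, RSCU columns, ENC
degeneracy classes, PR2 fourfold groups) is computed from the active table
rather than hard-coded, so both readings are available. Wherever the
literature says "excluding Met and Trp", the implementation excludes
*single-codon families under the active code* — identical for table 1,
Met-only for table 4.

Sequences are handled in the DNA alphabet internally; report files label
codons in RNA (UUU, GGU, ...).

## Codon counting conventions

A CDS is read in frame 0 of its annotation. The terminal stop codon is
dropped from counts; triplets containing N are skipped and tallied; internal
stop codons are excluded by default (with a warning carrying the position)
and countable under a flag. Sequences whose length is not a multiple of 3
are rejected by default or truncated under a flag. The core-gene length
filter uses raw nucleotide length / 3 with an inclusive boundary (300 nt =
100 codons is retained), applied before any stop-codon bookkeeping.

## Indices

* **Composition** — percent A/T/G/C over counted codon positions; GC1, GC2,
  GC3 per codon position; GC12 = (GC1+GC2)/2. GC3s and A3/T3/G3/C3 are
  restricted to third positions of synonymous codons (degenerate families,
  stops excluded). When a gene has no synonymous codons these are reported
  as missing, never as 0.
* **RSCU** — count × family size / family total; 1 for single-codon
  families; missing for unobserved families.
* **ENC** — Wright's effective number of codons. Per-family homozygosity
  F̂ = (nΣp²−1)/(n−1) (families with n ≤ 1 skipped), averaged within each
  degeneracy class; ENC = N₁ + Σ_k N_k/F̄_k with class sizes and
  multiplicities taken from the active code (2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ +
  3/F̄₆ for the standard code). A missing 3-fold class is imputed as
  (F̄₂+F̄₄)/2, the CodonW convention; any other missing class drops its term
  and the partial sum is rescaled over the remaining codon space. The result
  is clamped to [number of families, number of sense codons] — [20, 61] for
  the standard code, [20, 62] for table 4.
* **CAI** — geometric mean of relative-adaptiveness weights
  w = count/family max, built from a reference pool; unobserved reference
  codons are floored at w = 0.01 so the log-mean stays finite. No external
  reference set exists for these genomes, so the pipeline uses the
  lowest-ENC 10% of a species' genes as the putative high-expression
  reference. CAI values are therefore internally consistent but not
  comparable across reference choices.
* **CBI / FOP** — against a designated optimal-codon set:
  FOP = N_opt/N_syn and CBI = (N_opt−N_rand)/(N_syn−N_rand) with N_rand the
  expectation under within-family uniform usage. The pipeline supplies the
  species' own inferred optimal set (below); both indices inherit that
  choice and are reported for ranking, not cross-study comparison.
* **GRAVY / aromaticity** — mean Kyte–Doolittle hydropathy of the encoded
  residues and the fraction of Phe/Tyr/Trp. GRAVY is the conventional mean
  (sum divided by residue count), which is what keeps it inside the
  textbook [−2, 2] envelope.
* **Correlations** — pairwise Pearson r with two-sided t-distribution
  p-values, computed within one species across its genes (n = 11 for the
  default core set), requiring ≥ 3 complete pairs; zero-variance columns
  yield missing values.

## Mutation-vs-selection diagnostics

* **Neutrality plot** — unweighted OLS of GC12 on GC3 (percent scale)
  across a species' genes. Slope near 1: third-position pressure carries
  through all positions (mutation); near 0: first/second positions are
  constrained independently of GC3 (selection or amino-acid constraint).
  A constant-GC12 input is reported as slope 0, R² 0; constant GC3 is an
  error (the regression is undefined).
* **ENC–GC3s plot** — observed ENC against
  ENC_exp(s) = 2 + s + 29/(s² + (1−s)²), with
  ENC_Ratio = (ENC_exp − ENC_obs)/ENC_exp reported as a percent. The
  expected curve takes GC3s as a fraction; conversion from the percent-scale
  composition profile happens explicitly at the call boundary.
  **Known limitation**: Wright's curve is an approximation tuned to the
  standard code at moderate composition. At extreme AT-richness
  (GC3s ≈ 0.1) it overstates the exact mutation-only expectation by ~2–3
  ENC units, so even pure mutation-pressure data sits visibly "below the
  curve" there, and short genes (~120 codons) carry ENC sampling noise with
  a standard deviation of several units. Point-by-point proximity to the
  curve is therefore only a sharp diagnostic for moderate GC3s and long
  genes; the package's own tests verify the ±3 band at GC3s ≈ 0.3 with
  1000-codon genes, and regime separation at AT-rich defaults is asserted
  via the mean ENC_Ratio instead.
* **PR2 bias** — x = G₃/(G₃+C₃), y = A₃/(A₃+T₃) over third positions of
  fourfold-degenerate codon groups (quartets sharing a prefix and residue,
  including the fourfold subsets of sixfold families) — the standard PR2
  site set; an `all_synonymous` mode is available for sensitivity analysis.
  Quadrants are assigned around (0.5, 0.5) with ties resolved to the lowest
  quadrant index.

## Correspondence analysis

Classical CA of the genes × degenerate-codons RSCU matrix: divide by the
grand total, form standardized residuals (P − rcᵀ)/√(rcᵀ), SVD, principal
coordinates = singular vectors scaled by singular values over root margins;
inertia fractions are squared singular values over total inertia (which
equals the matrix chi-square over its grand total). Families absent from a
gene are imputed as RSCU 0 — no usage contributes no bias. A matrix that
fits the independence model exactly (zero inertia) is rejected as
degenerate. Axis signs are arbitrary; tests compare coordinates up to sign.
Per-species runs (11 × 59/61) are the pipeline default; a pooled
all-species run is available through the same API.

## Optimal codons

Genes are ranked by ENC; pool size is ceil(0.10 × n genes), minimum 1, with
ties broken by gene name (2 genes for the 11-gene core set; a `pool_size`
override allows strict single-gene pools). The low-ENC tail is treated as
the high-expression pool — the standard "stronger bias = higher expression"
assumption. ΔRSCU is computed from pooled counts per pool (not means of
per-gene RSCU), the stabler small-sample choice. Classification per
degenerate codon: optimal (ΔRSCU > 0.08 and overall RSCU > 1), highly
expressed (ΔRSCU > 0.08 only), high frequency (RSCU > 1 only), general.
Both inequalities are strict; a family absent from either pool leaves ΔRSCU
undefined and the codon cannot be optimal or highly expressed.

## RSCU clustering

Species-level RSCU (counts pooled over the core genes, then RSCU) is
standardized per codon column to Z-scores — sample standard deviation
(ddof = 1), the statistics-package default; a ddof argument exposes the
population variant. Zero-variance columns are dropped. Pairwise Euclidean
distances feed UPGMA: closest pair merges at height d/2, distances to the
merged cluster are size-weighted means, and ties break on the
lexicographically smallest leaf label so output is independent of input
order. The tree is ultrametric by construction and written as Newick with
branch lengths via scikit-bio.

## Synthetic data generator

Two regimes with fully known ground truth, defaults matching the target
system (8 species × 11 core PCGs at realistic mitochondrial codon lengths,
118–655 codons; GC3 target 0.13):

* **Mutation regime** — every codon position samples G/C with per-gene
  pressure g ~ Normal(gc3_target, 0.05) (clipped), bases uniform within
  class; stop codons are rejection-sampled. Because rejecting AT-rich stops
  conditions the distribution and would inflate realized GC by up to ~1.4
  percentage points, the sampling pressure is numerically inverted
  (Brent root-finding on the post-rejection expectation) so realized
  composition converges to the stated target. GC1 ≈ GC2 ≈ GC3 ≈ g by
  construction, so the neutrality slope across genes approaches 1 and AT
  content is ≈ 1 − g (≈ 87% at the default g = 0.13).
* **Selection regime** — residues drawn iid from a fixed hydrophobic,
  membrane-protein-like frequency profile (hard-coded; core mitochondrial
  PCGs are strongly hydrophobic), pinning GC12; synonymous codons drawn
  with weight exp(bias) on a planted preferred set, default one A-ending
  (else T-ending) codon per family with per-gene bias jitter
  (sd 0.3 around bias_strength = 2.0). GC3 is then governed by selection
  independently of GC12: slope ≈ 0, ENC well below the expected curve
  (mean ENC_Ratio ≈ 22% at defaults), PR2 y ≈ 0.87, realized AT ≈ 66%,
  ~19 high-frequency codons per species. Optional structure: per-gene bias
  overrides (planting "high/low expression" genes for optimal-codon
  recovery) and two-group preference sets (A-ending vs T-ending) for
  clustering recovery.

A single seeded NumPy generator drives all draws, so outputs are
byte-identical across reruns. Each simulated CDS is ATG + body + TAA, so
extraction and counting see realistic start/stop structure.

What the generator does **not** emulate: phylogenetic correlation between
species (draws are independent), within-gene spatial structure, indels,
strand-asymmetric replication bias, tRNA pools, or the coupling of
amino-acid composition to GC pressure in real proteomes. Passing the
recovery tests therefore shows the estimators and the pipeline are correct
and well-conditioned at realistic sizes, not that the biological
interpretation of any particular real dataset is settled.

## Problem sizes and determinism

Test and acceptance-script problem sizes were chosen to exercise the study
geometry at comfortable cost: oracle equivalence on ≥ 100 random instances
per estimator; regime diagnostics on 30–50 replicate species; clustering
recovery on 50–100 replicates of the full 8-species set; optimal-codon
recovery on 10 planted replicates. A full synthetic pipeline run completes
in about one second; the whole test suite in well under a minute. All
randomness flows from explicit integer seeds; pipeline outputs are a pure
function of (inputs, config, seed), and TSVs round numbers to 4 decimals
while `summary.json` keeps full precision.

## Known limitations

* ENC is noisy for genes near the 100-codon filter boundary; per-gene ENC
  values for the shortest core genes should be read with ±5-unit sampling
  error in mind.
* CAI/CBI/FOP depend on internally derived reference and optimal sets;
  absolute values are not comparable to studies using other references.
* The Wright expected-ENC curve systematically overstates the mutation-only
  expectation in extremely AT-rich genomes (above), which inflates
  ENC_Ratio for all genes there by a few percentage points.
* Scale effects: Z-scoring before Euclidean distances weights all codon
  columns equally, including rarely used ones whose RSCU estimates are
  noisy in short gene sets.
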