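# Methods

## Pathway model

A pathway definition is an ordered list of steps, each a non-empty OR-set of
gene families; a step is satisfied when any of its alternative families has
at least one copy. Five rule categories cover the analyses:

* **degradation_chain** — a polymer-to-monomer hydrolysis chain. Complete
  only when *every* step is encoded: a chain with a missing step cannot
  carry the substrate to its end product. At least one satisfied step (but
  not all) makes the MAG a *partial degrader* — ecologically, an opportunist
  that needs other community members to initiate breakdown.
* **enzyme_fraction** — complete when the satisfied-step fraction reaches a
  threshold, default 0.8 and *inclusive* (8 of 10 steps qualifies). Used for
  long energy/biosynthesis pathways (glycolysis, TCA, vitamin routes), where
  draft-genome incompleteness makes an all-genes rule too brittle.
* **gene_set_all** — every listed gene required; used where the biology is a
  fixed enzyme set (the four-enzyme beta-oxidation cycle, Pta–AckA
  acetogenesis, nitrate→nitrite→ammonia).
* **marker** — a single diagnostic step (L-lactate dehydrogenase, mcrA,
  hydrogenase group labels).
* **any_of_pathways** — complete when any member pathway is complete,
  partial when any member is partial and none complete; its fraction is the
  maximum member fraction. Used for hemicellulose (xylan OR mannan OR
  xyloglucan), the two chitinolytic routes, and the alternative biotin
  biosynthesis routes.

Threshold comparisons use a 1e-9 slack so binary representation of 0.8 never
flips a boundary case. Calls are deterministic; the status lattice
(absent < partial < complete) is monotone in copy counts.

Family identity is case-insensitive and whitespace-stripped because dbCAN
and KO exports vary in casing across versions. Counts are per-family gene
copy totals: one predicted gene counts once per distinct family even when
several domains of the same family hit it.

The shipped rule files encode standard family assignments (endo-/exo-/
β-glucosidase chain for cellulose; xylanase/xylosidase, mannanase/
mannosidase, xyloglucanase/α-xylosidase/β-glucosidase for the
hemicelluloses; a chitinase/hexosaminidase route and a deacetylase/
chitosanase route for chitin; KEGG Orthology sets for central carbon,
fermentation and vitamin pathways). They are data files, deliberately
editable: annotation schemes differ, and the engine is agnostic to the
specific lists.

## Function summary rules

Per MAG: each carbohydrate whose configured chain (or any-of) call is
complete is listed as a substrate; starch is listed when the amylase-family
copy total strictly exceeds 5; proteins when the exopeptidase total strictly
exceeds 10; "simple saccharides" only as a fallback when nothing else
qualifies but a β-glucosidase is encoded. Energy pathways are listed when
complete and flagged "(p)" when at least one step is encoded but the pathway
is below its completeness rule. Vitamins require a complete biosynthesis
call. Benefits derive mechanically: protein degradation from proteins,
plant-matter degradation from any complete carbohydrate/starch listing,
vitamin production from any vitamin.

## Normalization

Substrate-class copy totals are rescaled to copies per complete-genome
equivalent, `raw × 100 / completeness`, correcting the systematic
under-count in incomplete bins. Contamination is used only as a QC filter
(bins retained at ≥50 % completeness and ≤20 % contamination, the
conventional medium-quality threshold), never in normalization: foreign
contigs are not guaranteed to carry the profiled families, and a
contamination correction would presume they do. The hemicellulose total is
the union of the three hemicellulose chains' families, each family counted
once. Beta oxidation enters the feature matrix as a binary (all four cycle
enzymes or not) rather than a copy total, since the cycle is short and its
copy number mostly reflects paralog families rather than capability.

## Statistics

* **Scaled PCA.** Columns are centered and divided by the sample standard
  deviation (ddof = 1); scores/loadings come from the SVD of the scaled
  matrix, so variance fractions are squared singular values over their sum.
  Zero-variance columns are dropped with a warning — scaling is undefined
  for them and a constant feature carries no information for any of the
  downstream tests.
* **PERMANOVA.** pseudo-F = (SS_between/(k−1))/(SS_within/(n−k)) with sums
  of squares from squared pairwise distances (SS_total = Σ_{i<j} d²/n,
  within-group terms analogously). Default distance is Euclidean on the
  scaled features — consistent with the PCA the test accompanies —
  with Bray–Curtis available. p = (#{F* ≥ F} + 1)/(P + 1) over seeded label
  shuffles, P = 999 by default; `n_permutations="exact"` enumerates all
  distinct assignments (p then includes the identity in its denominator).
* **Dispersion.** Squared distances are double-centered and
  eigendecomposed; rows are embedded on real axes (positive eigenvalues)
  and imaginary axes (negative eigenvalues), and the squared distance to the
  own-group centroid subtracts the imaginary-axis part (clipped at zero) —
  the standard correction for semi-metric dissimilarities. With Euclidean
  input the embedding is an isometry and the distances equal direct
  feature-space computation. F is a one-way ANOVA on those distances; the
  permutation null shuffles group labels over the fixed distance vector.
  Centroids are group means, matching the "distances from group centroids"
  formulation; a spatial-median variant was considered and not adopted.
* **Kruskal–Wallis / Wilcoxon.** Midranks throughout; H is divided by the
  tie-correction factor 1 − Σ(t³−t)/(N³−N); an all-equal sample is defined
  as H = 0, p = 1 rather than 0/0. Post-hoc pairwise rank-sum tests run when
  the omnibus p ≤ α: exact enumeration of the rank-sum distribution when
  both samples have ≤ 12 observations and no ties, otherwise the normal
  approximation with tie-corrected variance and 0.5 continuity correction.
  Multiplicity adjustment defaults to Holm (raw p also reported).
* **Fold changes** are ratios of per-group arithmetic means of normalized
  copies ("gene copies per MAG"); a zero denominator raises an explicit
  error rather than returning infinity.

One integer seed governs every permutation draw; reports echo the seed,
permutation count and full configuration, and serialize losslessly to JSON.

## Synthetic communities

The generator draws, per MAG: completeness uniform in (70, 100] and
contamination uniform in [0, 10] (draft-bin quality range), and for each
step-bearing pathway a Bernoulli presence per step with probability set per
(group, pathway). A present step assigns copies to one uniformly chosen
alternative family, `1 + Poisson(max(base_rate × enrichment − 1, 0))`
copies, so presence always implies at least one copy (matching the
presence/absence semantics of the rules) while the mean stays at
`base_rate × enrichment` whenever that product is ≥ 1. Families on no
simulated step — the exopeptidase and amylase lists — draw plain Poisson
counts at `base_rate × enrichment`. Base rate defaults to 2 copies per
family.

Ground truth is recomputed from the *emitted* copy matrix by an
independently coded tally of the same rules (not by calling the pathway
engine), so generator and engine act as mutual oracles: any divergence in
rule semantics breaks the end-to-end recovery test. Recovery is exact by
construction even where chains share families (e.g. β-glucosidase in the
cellulose and xyloglucan chains).

The shipped default scenario mirrors a three-diet design with group sizes
18/18/7: herbivore-enriched cellulose/hemicellulose (×2.0), chitin (×2.2)
and starch (×1.5); protein enrichment (×1.7) in the piscivorous and
invertivorous groups; high beta-oxidation step presence in the piscivorous
(0.85) and invertivorous (0.8) groups versus 0.45 in the herbivorous group;
carbohydrate-chain step presence 0.9/0.55/0.35 across
herbivorous/piscivorous/invertivorous; and zero presence for the
invertivorous chitinolytic initial steps. The power-calibration scenario is
simpler: equal groups of 15, a single enrichment factor (default 2) on
cellulose, hemicellulose and chitin in one group, all step probabilities at
the 0.6 default.

What the generator does *not* emulate: phylogenetic correlation of gene
content, within-group heterogeneity of enrichment, copy-number
overdispersion beyond Poisson, annotation errors (false family calls), and
contamination leaking foreign families into a bin. Passing tests therefore
demonstrate the correctness and calibration of the *procedures* under the
stated model, not robustness of the biology to annotation noise.

## Calibration choices and problem sizes

Monte-Carlo checks use 500 null communities (3 × 15 MAGs) for type-I error,
200 replicates for power, and 199 permutations per test during calibration —
the permutation p is unbiased at any permutation count, and 199 gives
0.005-granularity, ample for a 0.05-level decision; single analyses default
to 999 permutations. Ground-truth recovery uses a 1,000-MAG community.
Exact-enumeration equality is verified on 3+3 designs (20 assignments).

## Limitations

* Calls are genomic potential only; no inference of expression or flux.
* Marker-based community profiles inherit single-copy assumptions; coverage
  arrives precomputed and no read mapping is performed.
* The QC "known species" tally is a strict ANI > 95 rule on the single
  stored ANI value; provenance of that value (which estimator produced it)
  is not modeled, and RED-only placements are conservatively never counted
  as known.
* The dispersion permutation shuffles the fixed centroid-distance vector;
  it does not recompute distances to permuted-group centroids.
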