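# Methods

This note documents the models, conventions and design choices behind
`daquscope`, in the spirit of a package methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## OTU-table processing

An `OtuTable` is a non-negative integer matrix (OTUs × samples) with
per-sample metadata and optional rank-prefixed lineage strings
(`p_…;o_…;f_…;g_…`). "Present" always means a nonzero raw count; no
detection-limit model is applied.

**Screening.** `filter_low_occupancy` keeps OTUs observed in at least 2
samples *and* with at least 20 reads in total — the negation of the usual
removal rule for singleton-sample and sub-20-tag OTUs, with "less than 20"
read strictly. The screen is idempotent, and raising either threshold can
only shrink the retained set.

**CSS normalization.** For sample *j* with counts *c·j*, the scaling
factor is the cumulative sum up to a quantile:
`s_j = Σ { c_ij : c_ij ≤ q_j }`, where `q_j` is the chosen quantile of the
sample's *positive* counts, computed as the lower empirical (type-1)
quantile so ties resolve downward. Normalized values are
`c_ij / s_j × 1000`; the factor-1000 rescale is fixed. The default
`quantile="adaptive"` scans the quantile grid and takes the smallest value
at which the per-sample quantile curves destabilize relative to their
median reference curve, falling back to 0.5 when the scan is degenerate or
would select below 0.5. Scaling a sample's counts by a constant scales
`s_j` identically, so CSS values are depth-invariant.

**Rarefaction and diversity.** `rarefy` subsamples each sample without
replacement (multivariate hypergeometric draw) to a fixed depth; samples
below the depth are *dropped with a warning* rather than raising, matching
minimum-count practice (the motivating survey rarefied at its observed
minimum of 988 reads). Alpha diversity is computed on the rarefied table:
Shannon entropy in **bits** (base 2, configurable) and the observed-OTU
count. A single seeded draw is the default; `iterations > 1` averages over
independent draws.

**Core microbiome and Venn.** A core OTU must be present in strictly more
than the threshold fraction (default 95%) of the chosen samples — with 20
samples, only OTUs present in all 20 qualify. Venn regions count OTUs by
the exact subset of groups in which they appear (nonzero in ≥ 1 sample of
the group).

## LOOCV stability selection

The marker-discovery procedure runs one fold per sample. In each fold the
held-out sample is excluded from both feature selection and classifier
fitting.

**Shadow-feature selection.** The all-relevant selector augments the
training matrix with an independently shuffled "shadow" copy of every
undecided feature, fits an extremely-randomized-trees ensemble, and scores
a *hit* for each real feature whose importance exceeds the maximum shadow
importance. After every iteration a two-sided binomial test on the
accumulated hit counts — Bonferroni-corrected across the starting feature
count, the published default of this selector family — confirms features
beating the shadows significantly more often than chance and rejects the
converse; rejected features leave the model. Features undecided at the
iteration cap (default 100) are *tentative*: dropped by default, or
resolved by comparing their median importance against the median shadow
maximum (`tentative_policy="median_fix"`).

Two deliberate economies keep a 54-fold run tractable on one CPU without
changing the procedure's logic: the per-iteration ensembles use impurity
importances (permutation importance is available via
`importance="permutation"`), and `selector_trees` can shrink the
per-iteration ensemble below `n_trees` — hit evidence accumulates
binomially across iterations, so at small feature counts (tens of OTUs) a
20–30-tree iteration ensemble loses no recoveries while per-tree fitting
overhead dominates runtime. At hundreds of features the full ensemble is
required: the shadow maximum is an extreme order statistic over all
shadows, and small forests cannot resolve mid-strength importances above
it. The default is therefore the full `n_trees`. The *reported*
importances — the per-fold classifier ranks — are genuine permutation
mean-decrease-accuracy values from the `n_trees` random forest (default
500 trees, √p features per split).

Two power caveats, visible in the analysis scripts' own output: with
hundreds of OTUs, spiked features that are individually significant
(Wilcoxon p < 1e-3) can still fail all-relevant confirmation when a
stronger co-spiked feature separates the classes almost perfectly —
impurity importance is competitive, and redundant signal is absorbed by
the dominant feature. Recovery experiments that assert *complete* marker
recovery therefore run at feature counts where the selector has that
power (tens of OTUs), while full-size runs report what they find.

**Fold bookkeeping.** Per-fold seeds derive deterministically from the
master seed and fold index, so folds are independent yet the whole report
is reproducible bit for bit. A fold whose selection is empty skips its
classifier and is logged as unpredicted (and counts as incorrect in the
accuracy). Markers are features selected in at least
`marker_cutoff(n, f)` folds — the smallest integer strictly exceeding
`f × n`; `(54, 0.9) → 49`.

**Normalization order.** By default CSS normalization is applied to the
full two-group table before the fold split, matching the published
pipeline order; `normalization="per_fold"` renormalizes inside each
training fold and is the leakage-free variant.

## LCA annotation cascade

`match_pct` is alignment length over **query** length × 100, capped at 100
(gapped alignments can exceed the query); the divisor convention is the
standard one for gene-catalog annotation. Stage 1 keeps hits with coverage
≥ 80 and identity ≥ 65 (inclusive boundaries throughout); stage 2 computes
the minimum e-value **after** stage 1 (a pre-filter variant is available)
and keeps hits within 10× of it. A minimum e-value of exactly 0 keeps only
exact-zero hits, avoiding division conventions. The gene is assigned to
the lowest common ancestor of the survivors' taxa on an 8-rank canonical
tree (root, kingdom, phylum, class, order, family, genus, species);
non-canonical ranks collapse to the nearest canonical ancestor at load
time. Genes with no hits, or none surviving, are `UNKNOWN`. Kingdom
profiles pool everything outside {Bacteria, Archaea, Fungi, Viruses} —
plants, animals, protists, above-kingdom assignments — into "Others";
microbe retention keeps the four microbial kingdoms and by default
renormalizes their abundance to 1.

## Functional profiles

KO assignment keeps the maximum-bitscore hit when its bit score is
*strictly* greater than 60, with ties broken by smaller e-value then
lexicographic subject id. EC abundances sum gene mass per enzyme; genes
without an EC contribute nothing, and a gene mapping to several ECs would
contribute its full mass to each (per-enzyme summaries, not a partition).
Pathway profiles intersect observed enzymes with a map's EC list (bundled
maps: starch-to-glucose, including 3.2.1.20 / 3.2.1.1 / 3.2.1.3, and
cellulose hydrolysis: 3.2.1.21 / 3.2.1.4 / 3.2.1.91), report absent map
enzymes as zero rows and rank by mean abundance. Heatmap values use
`log10(x + 1e-8)`, mapping 0 to exactly −8. Taxon breakdowns group genes
by their lowest assigned taxon label and pool groups under 1% into
"Others (<1%)"; a pooling threshold of 0 reproduces the unpooled
distribution.

## Statistics

Spearman's rho uses mid-ranks; p-values come from the t-approximation
with n − 2 df, or exact permutation enumeration for n ≤ 9. Wilcoxon
rank-sum enumerates all group assignments exactly when both samples have
≤ 10 observations (ties handled by mid-ranks inside the enumeration) and
otherwise uses the normal approximation with tie and continuity
corrections. BH-FDR is the standard step-up (delegated to statsmodels);
note that BH adjustment is *not* idempotent in general — re-adjusting
already-adjusted values can inflate them further — so only inflation and
order preservation are guaranteed.

PERMANOVA uses the direct distance-matrix pseudo-F,
`F = [(SS_T − SS_W)/(g−1)] / [SS_W/(n−g)]` with
`SS_T = (1/n) Σ_{i<j} d²_ij` and per-group within sums, on Bray-Curtis
distances of relative abundances by default (the distance is
configurable; nothing in the motivating work pins it). The Mantel
statistic correlates upper-triangle entries, rank-based by default, with
significance from simultaneous row/column permutation of the second
matrix. Both report `p = (1 + b)/(1 + B)` under random permutations
(default B = 999, seeded), or enumerate every relabelling exactly in
`exhaustive` mode. Correlation networks BH-adjust across the C(k,2) OTU
pairs; property screens treat each physicochemical index as its own BH
family ("individual property"), dropping samples with missing values per
property.

## Synthetic data: what it emulates, and what it does not

`simulate_community` draws per-sample compositions from
Dirichlet(c · w_g), where w_g is a lognormal baseline (σ = 1.5) modified
by group effects, and counts from a multinomial at a uniform random depth
in (988, 20000) — so the rarefaction path always operates above the
988-read floor. The concentration default c = 50 produces the strong
overdispersion typical of OTU tables. The default design mirrors the
study shape: W(27), Y(27) and six mature batches of 26/24/4/32/30/15
(131 samples), with 8 property indices (AC, SU, MO, ST, SA, LI, PA, CA).
Marker spikes multiply the baseline by 2^log2FC in one group; marker
baselines are pinned to the *median* baseline value so a stated fold
change is the same effect whatever the lognormal draw placed at that
index — planted-effect recovery is then a property of the procedure, not
of a baseline lottery. Group-exclusive OTUs have their baseline zeroed
elsewhere. Properties are Gaussian-copula transforms of an OTU's normal
scores at the Pearson equivalent `2 sin(πρ/6)` of the target Spearman ρ.
The copula target is only attained for OTUs without heavy zero-count
ties — tied mid-ranks attenuate the realized Spearman — so recovery
experiments plant links on prevalent OTUs.

Hit simulation plants a truth node at a chosen rank, emits 3–10 in-clade
hits spanning at least two child subtrees (so the LCA is exactly the truth
node) that provably pass all three filters, and adds off-clade decoys
engineered to fail at least one filter — or, under the `stress` flag, to
pass them all, in which case the assignment is provably an ancestor of the
truth. Gene profiles deal annotated genes round-robin across an EC pool
and scale their lognormal weights by per-EC mass factors, so expected
total-mass ratios equal the pool ratios.

None of the generators model sequence content, chimeras, read-level error,
phylogenetic signal between OTUs, or batch effects beyond the group means.
Passing recovery tests therefore demonstrates that the *procedures* invert
what the generators plant — not that real starter communities satisfy the
generators' assumptions.

## Calibration and known limitations

- PERMANOVA and Mantel type-I error is measured over 1000 homogeneous
  Dirichlet communities (12 samples, 199 permutations each) at α = 0.05.
- Wilcoxon p-value uniformity is checked on a *dense* null community
  (concentration 5 per OTU, so nearly every OTU is present everywhere):
  rank tests are only continuously calibrated without heavy ties. On
  sparse tables, zero-count ties make the per-OTU p-values conservative —
  a property of any rank test on such data (our p-values match the
  established asymptotic Mann-Whitney implementation to machine precision
  on identical inputs), documented rather than corrected.
- Exact Wilcoxon enumeration is O(C(n₁+n₂, n₁)) and is capped at 10 + 10;
  exact Spearman permutation at n ≤ 9.
- The LOOCV fold loop costs ~1–4 s per fold at 50–300 OTUs with 100 trees
  and a 40-iteration selector cap on one CPU; analysis scripts and
  acceptance runs use those sizes, while library defaults (500 trees,
  100 iterations) follow the cited selector's published configuration.
- `css_normalize` errors on samples with no positive counts; Bray-Curtis
  errors on a pair of all-zero samples; degenerate (constant) inputs to
  Spearman/Mantel return flagged NaN results rather than raising.
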