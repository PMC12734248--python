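# Methods

This note records the models, the parameters that matter, and the design
choices made where the design was genuinely open.  It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Genotype-likelihood covariance (`popstruct.gl_covariance`)

**Model.**  Each individual i and biallelic site j carries a likelihood
triple over dosages 0/1/2 (alternate-allele count).  Per-site allele
frequencies f_j are first estimated by EM under Hardy–Weinberg priors.
Posterior expected dosages E[g_ij] are then computed under an individual
prior Binomial(2, π_ij), initialized at π_ij = f_j.  The standardized
residual matrix

    R_ij = (E[g_ij] − 2 f_j) / sqrt(2 f_j (1 − f_j))

yields the sample covariance C = R Rᵀ / M.  The individual frequencies are
refreshed from the top-k SVD reconstruction of R mapped back to the
frequency scale (π = f + R̂·sqrt(2f(1−f))/2, truncated to [1e-4, 1−1e-4]),
and the loop repeats until max |ΔC| < tol.  Centering is by the population
frequency 2f_j, not 2π_ij: with that choice the procedure collapses exactly
onto the standard normalized genotype covariance when the likelihoods are
degenerate one-hot triples, which is the oracle equivalence the tests
enforce.  Missing data are uninformative (1/3,1/3,1/3) triples and
contribute their posterior expectation under the current π — the point of
the formulation for low-depth samples — never an imputed hard call.

**Parameters.**  `n_components` (SVD rank for the π update and number of
PCs returned, default 10); `max_iter=100`, `tol=1e-5`, truncation bound
1e-4.  These mirror common defaults for this family of estimators; the
covariance is insensitive to the truncation bound except at monomorphic
sites, which are dropped up front.  Non-convergence returns results with
`converged=False` and a warning rather than failing: on very small noisy
panels the covariance oscillates at amplitudes far below any quantity of
interest.

**Trees.**  NJ follows Saitou–Nei Q-minimization with the standard
branch-length formulas, terminating in a trifurcating root when three
nodes remain (two branches of d/2 for the 2-taxon case).  Negative branch
estimates are clamped to zero with the deficit shifted to the sister edge,
preserving the joined pair's path length.  On additive inputs the
algorithm is exact; the suite cross-checks path lengths against
scikit-bio's independent NJ on random Euclidean metrics.  The NJ input is
the covariance-derived distance d_ij = √(c_ii + c_jj − 2c_ij), so PCA and
tree are views of the same matrix.

## COI-DAPC origin tracer (`coitrace`)

**Curation** automates three proxies for manual alignment inspection:
internal stop codons under the invertebrate mitochondrial code (frame
given, or inferred from a reference row as the frame minimizing its
internal stops), more than `max_ambiguous` (default 5) N/IUPAC characters,
and gaps at columns where fewer than `gap_consistency` (default 5%) of
sequences are gapped.  Codons containing gaps or ambiguities are not
evaluated; the final codon is not "internal".  Manual curation in an
alignment viewer catches artifacts these rules cannot (chimeras,
misalignments that preserve the frame), so curation here is a floor, not a
replacement.

**Encoding** is haploid: one indicator column per observed base at each
polymorphic alignment column (major allele first), 1/0 for presence, all
indicators of a column missing when the individual has a gap/N there.
Mitochondria are effectively haploid, so diploid dosage coding would be
wrong.  Indicator columns with fewer than `min_mac` carriers can be
dropped (default 1 = keep everything).

**Cluster discovery** mean-imputes missing indicators, centers, takes PCA
(either the fewest PCs reaching a variance fraction, default 0.90, or a
fixed count — both entry points exist because either convention is
defensible), then runs k-means for k = 1..k_max with 10 seeded restarts,
scoring BIC(k) = n·ln(WSS_k/n) + k·ln(n).  The number of clusters follows
the successive-decrease (diffNgroup) heuristic: the drops
Δ_k = BIC(k)−BIC(k+1) are split into two groups by 1-D Ward clustering and
the chosen k is one past the largest k whose drop falls in the
high-decrease group.  Two guards handle degenerate curves: a never-
decreasing curve gives k = 1, and only strictly positive drops can select
k.  The heuristic assumes individuals are distinct; a reference set
dominated by exact duplicate haplotypes lets WSS collapse to ~0 at large k
and the BIC plunge, a known failure mode of WSS-based criteria on
duplicated points.

**PC selection** repeats stratified 90/10 splits (default 30 reps),
fitting the DAPC on the training side for each candidate PC count and
recording holdout assignment accuracy; ties break toward fewer PCs.
Clusters with fewer than 2 members cannot be split and are excluded with a
warning.

**DAPC fit.**  Fisher discriminant axes diagonalize between-cluster
scatter against pooled within-cluster covariance (generalized symmetric
eigenproblem; a 1e-8·trace ridge is added when the within-scatter is
singular, with a warning).  Axes are scaled so within-cluster covariance
in DA space is the identity, making Euclidean distance to centroids a
Mahalanobis distance — hence assignments match an LDA-on-PCs oracle with
equal priors, which the suite checks.  Membership posteriors are the
distance softmax P(g) ∝ exp(−½‖z−centroid_g‖²) under equal priors and a
shared identity covariance, reported to 4 decimals.  Query columns are
reconciled to the model's columns by label; model columns absent from the
query are imputed from stored training column means, and a query observing
under 50% of model columns is NA (`insufficient_overlap`).

**Regional profiles.**  For cluster c and region r, the raw fraction
count_cr / region_total_r corrects for unequal sampling effort before
normalizing within the cluster; individuals with unknown or excluded
regions are dropped first.  Cluster→origin mapping pools normalized
proportions per origin through the region→origin map (Africa→Africa,
East/South/Southeast Asia→Asia, Mascarenes→Asia, Pacific→Pacific — the
Mascarene populations carry Asian-like genetic signatures despite their
geography).  A top origin at or above `dominance_threshold` (default 0.90)
is called outright; otherwise the call is `ambiguous:` with every origin
above `minor_floor` (default 0.05) in descending order.  The 0.90/0.05
defaults make a ~95%-dominated cluster an outright call while a 70/25
mixed cluster stays ambiguous, matching how mixed haplotype clusters
should be treated in a regulatory context: an ambiguous mitochondrial
profile must not silently agree with the nuclear evidence.

## Diagnostic SNP panel (`snppanel`)

**Filters** keep sites with missing fraction ≤ 1%, MAF strictly above 5%
(computed from non-missing genotypes), and mean depth inside the closed
interval [8, 12]; order preserved, removals logged, idempotent by
construction.

**Imputation** is the deterministic class-conditional mode (ties to the
lower dosage; global mode when a class is entirely missing or the
individual is unlabelled).  The reference workflow uses a proximity-based
random-forest imputer; at the ≤1% missingness the filters allow, the two
differ only on ties, and a deterministic rule makes every downstream
result reproducible bit-for-bit.

**RFE.**  A stratified 30% holdout is split off first and never touches
selection.  On the remainder, repeated stratified k-fold CV (defaults 10
folds × 10 repeats) drives the elimination: per fold a random forest fit
on all sites ranks them by Gini importance, and each grid size s
(default grid 1, 2, 5, 10, 15, 20, 50, 80, 100, 150, 200) is re-evaluated
by refitting on the top-s sites and scoring the held fold.  Accuracies
aggregate to mean ± SD per size; the final ranking comes from a forest on
the full training portion, and the best size (highest mean, ties toward
smaller) is scored once on the 30% holdout.  The 30% internal holdout and
the separate 25%-holdout×100 validation (`validate_panel`) are kept
independent.  Forests use √p features per split and 100 trees by default:
the elimination loop retrains folds×repeats×|grid| forests, and on panels
of a few hundred sites the importance ranking and accuracies are already
stable at 100 trees, so larger forests only multiply runtime.  The count
is a parameter for anyone who wants the heavier setting.

**Decision tree.**  CART with Gini impurity on dosage features; because
dosages are integers 0/1/2, every split is equivalent to a cut at 0.5 or
1.5 and thresholds are snapped to that canonical pair.  Leaves store class
counts; the reported probability is the leaf majority fraction.

**Depth masking.**  `classify_specimen` refuses a call (NA,
`incomplete_panel`) whenever *any* site used anywhere in the tree — not
just the traversal path — is missing or below `min_depth` (default 6,
boundary inclusive).  Rationale: at depth <6 an apparently homozygous
genotype can be a heterozygote with one allele unsampled
(P ≈ 2·0.5⁵ ≈ 6% at depth 5), and a wrong dosage can silently flip the
traversal.  Off-path sites are masked too because the path itself depends
on dosages that dropout may have corrupted.

## Consensus (`consensus`)

NA calls are ignored; one ambiguous call forces `consensus = no` even when
its candidate set contains the other methods' origin (the only reading
consistent with treating a mixed mitochondrial profile as non-
confirmatory); remaining calls must be unanimous.  The nuclear PCA/NJT
origin enters as an externally supplied label — the underlying judgement
is a visual inspection of PCA and tree placement and is not automated
here.  The shipped `data/table2.tsv` transcribes the 22-specimen published
worked example used by the acceptance suite.

## Synthetic data (`simulate`)

**Nuclear.**  Neutral loci follow a Balding–Nichols model: ancestral
frequency Uniform(0.1, 0.9) per locus, population frequencies
Beta(p·c, (1−p)·c) with c = (1−F)/F, so `divergence` ≈ expected FST
(checked against a Hudson-estimator oracle).  The default divergence 0.1
is a placeholder for a realistic continental split — the real
Africa/Asia differentiation is not quantified in a way that pins the
parameter, and every acceptance property is checked at the configured
value, not at a fitted one.  Planted sites take exact frequency pairs
(default (0.02, 0.98), i.e. near-fixed differences like the two published
diagnostic loci).  Genotypes are Binomial(2, p); depth is negative
binomial with mean 10 (the downsampling target of the study design) and
overdispersion 5; genotypes go missing at `missing_rate` or whenever
depth is 0.

**Mitochondrial.**  A shared haplotype set (default: derived from one
ancestor at 2% divergence) with per-region frequency pools; each
individual draws a haplotype from its region's pool and mutates each site
with probability `mutation_rate` (default 0.002 ≈ 1.4 substitutions per
684 bp barcode).  Emitted sequences are kept free of frame-1 internal
stop codons so that clean simulator output passes curation, mimicking a
functional protein-coding gene.  `discordance_rate` individuals draw from
a different region's pool while keeping their recorded label — planted
mitonuclear discordance, used to show the COI stream mis-assigning
exactly that fraction.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: no linkage or recombination structure, no
within-region population substructure or isolation-by-distance, no
haplotype sharing between regions (unless pools overlap by construction),
no sequencing-error correlation along reads, no indels or alignment
error, no species mislabelling in the reference.  Real COI compilations
contain all of these; the published workflow's manual curation and its
caveats about the *B. dorsalis* complex exist precisely because of them.

## Problem sizes and determinism

The test and acceptance runs use deliberately modest sizes chosen as the
smallest at which each property is stable across seeds: reference panels
of 100–200 individuals × 200–500 sites, barcode sets of 90–120 × 684 bp,
RFE at 5 folds × 2 repeats with 50-tree forests.  All randomness flows
from explicit integer seeds (`numpy.random.default_rng`); same seed,
same bytes.

## Known limitations

* The diffNgroup heuristic inherits k-means' local optima; 10 restarts
  stabilize it on separated data but the chosen k on weakly structured
  data is seed-sensitive (as it is in the reference implementation).
* Posteriors assume equal cluster priors and shared identity covariance
  in DA space; they are calibrated membership scores, not probabilities
  of geographic origin.
* The depth-masking rule makes the SNP classifier conservative by design:
  on ~10× data roughly the fraction of specimens with any panel locus
  under 6× is refused, which is visible as NA rates in classifier output.
* VCF handling is read-only and biallelic-only; multiallelic records are
  dropped with a logged count rather than decomposed.
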