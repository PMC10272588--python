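# Methods

This note records the statistical models, the choices made where the design
was genuinely open, and the limits of what the synthetic validation shows.

## Genotype representation and QC

Genotypes are allele-dosage matrices (lines × markers, values 0/1/2,
missing allowed) read from VCF (GT field, alternate-allele count), HapMap
(two-letter or IUPAC calls, dosage counts the second-listed allele) or
delimited dosage tables. Internally indices are 0-based; file coordinates
are 1-based.

Two QC branches are maintained because structure analyses and prediction
have different needs:

* **Parent branch** (structure): call-rate filter (markers observed in
  < 90% of lines removed; a marker at exactly 90% is retained), biallelic
  filter, per-marker mode imputation, then greedy LD pruning — a marker is
  dropped when its squared dosage correlation with any earlier *kept*
  marker exceeds 0.99, within chromosomes when coordinates exist, over all
  pairs otherwise. Heterozygous and rare markers survive so that diversity
  analyses see all variability.
* **Hybrid branch** (prediction): additionally removes markers
  heterozygous in any parent, duplicate marker content across chromosomes
  (identical dosage vectors, first kept — within-chromosome duplicates are
  the LD filter's job), and markers with minor allele frequency < 0.05
  among the derived single crosses. In a full diallel the cross allele
  frequency equals the parental one; with an explicit incomplete design
  the realized crosses are used.

Mode imputation (ties broken toward the lower dosage) stands in for
haplotype-based imputation; on inbred panels, where most markers are
near-fixed within subpopulations, the marker mode is a reasonable fill-in,
and the choice keeps the package self-contained. Population-aware
imputation is out of scope. Every filter step is logged as
(name, markers_in, markers_removed, markers_out) with exact chaining, so
marker accounting is auditable.

## Population structure

Rogers distance is implemented as the per-locus allele-frequency distance
with within-line frequencies dosage/2; for biallelic markers this equals
|g_i − g_j|/2 averaged over loci, a Manhattan distance scaled to [0, 1].
Ordination uses classical metric scaling (principal coordinates) of the
Rogers matrix, with negative eigenvalues truncated to zero for
explained-variance normalization; a PCA directly on the centered dosage
matrix is provided as an alternative, but the distance-based path is the
default (both views of the structure should agree, and the distance-based
one composes with the concordance statistics). K-means (k-means++ with 100
restarts, best within-cluster sum of squares kept) runs on the first three
principal coordinates by default; the number of clusters is chosen by the
elbow of the WSS curve, operationalized as the maximum second difference
over the candidate range, with an explicit override. Partition agreement
between platforms uses Kendall tau after aligning labels by optimal
assignment on the contingency table (deterministic and invariant to label
names). The Mantel test permutes rows and columns of one matrix jointly and
reports the add-one estimator p = (1 + #{r_perm ≥ r_obs})/(n_perm + 1), so
p is never zero and is exact in distribution under the null.

## Kernels

* G_P = W_P W_P′/p with columns centered and standardized to unit
  population variance. "Standardized" is deliberate: it gives mean
  diagonal exactly 1, putting σ²_P on the residual scale.
* Single-cross codes from homozygous parents: W_A = mean parental dosage,
  W_D = 1 where the parents differ. Parent order is immaterial, and a
  heterozygous parent dosage is rejected with the offending line and
  marker named.
* G_a centers W_A columns by 2p_i and scales by 2Σp_i(1−p_i); G_d centers
  W_D by 2p_i(1−p_i) and scales by 4Σ(p_i(1−p_i))². Frequencies come from
  the cross matrix itself (the modeled population), not the parents.
  Centering is applied even though the raw codings could be used directly:
  uncentered kernels break the row-sum-zero property and the variance
  interpretation of the components. Note that away from allele frequency
  0.5 the mean diagonal of G_d exceeds 1 (≈1.5 in the simulated designs),
  so σ²_d is a kernel-scale parameter, not the realized dominance variance;
  recovery experiments must simulate from the model to compare like with
  like.
* The SCA kernel is the cross-indexed subset of G_P ⊗ G_P. Crosses are
  unordered, so entries are symmetrized: H[(i,j),(k,l)] =
  ½(G_P[i,k]G_P[j,l] + G_P[i,l]G_P[j,k]); the raw Kronecker lookup is
  available behind a flag. All kernels are validated symmetric with
  eigenvalues ≥ −1e−8, and a ridge of 1e−6 is added before any inverse.

## REML engine

The mixed-model core fits y = Xβ + Σ_r Z_r u_r + e with u_r ~ N(0, σ²_r
K_r) and residuals homogeneous or independent per group (per environment in
stage 1). Estimation is EM-REML: σ²_new = σ² + σ⁴(y′PG Py − tr(PG))/q per
component, which never decreases the restricted likelihood. By default an
average-information Newton step is attempted first — with an active set
that pins components at the floor (1e−8) and re-solves for the rest, and
with step-halving — and is accepted only when it improves the likelihood,
preserving monotonicity while converging in ~10–20 iterations where pure
EM crawls near the boundary. Convergence is declared on |Δ logL| < 1e−8
(not parameter change, which stalls near boundaries); non-convergence
returns the last iterate flagged, with the full likelihood trajectory.
Initialization splits the total phenotypic variance equally among all
components, making fits deterministic with no random restarts. BLUEs and
BLUPs are solved at the final components; predictions for unobserved
levels use K_new,train (K_train + 1e−6 I)⁻¹ û.

Stage-1 adjusted means use fixed environments (sum-to-zero coded, so entry
coefficients are already means across environments), fixed entries, fixed
checks and check×environment terms, random blocks within environments, and
per-environment residual variances by default. The full unstructured
residual covariance across environments that a multivariate formulation
would give is deliberately simplified to independent per-environment
variances: plots are single-environment observations, and the independent
form captures the heteroscedasticity (e.g. contrasting nitrogen levels)
without a latent multi-trait model; a homogeneous mode is available for
comparison. Entries are fixed so the stage-2 models consume unshrunken
BLUEs. Confounded design columns are detected by pivoted QR and dropped
with a warning.

## Diallel, heterotic groups, testers

The GCA/SCA model is fit with the generic engine: Z_P sums the two
parental GCA incidences per cross, Z_H is the identity on observed
crosses. The completed SCA surface takes BLUPs for observed pairs and
kernel-based BLUP predictions for unobserved pairs (the fitted H defines
them naturally, and K-means needs complete rows); the diagonal is zero by
convention (no self-crosses). K-means on the raw SCA rows (all entries
share trait units, so no re-scaling) forms k = 2 groups by default.

"The line with the highest GCA with the other group" is operationalized as
the highest mean predicted inter-group cross value ĝ_i + ĝ_j + ŝ_ij — the
quantity a breeder would actually rank testcrosses by; a pure-GCA ranking
mode is provided since the phrasing is ambiguous. Ties break toward the
lexicographically first line id. Partition agreement across platforms is
the Pearson correlation (phi coefficient) of aligned 0/1 membership
vectors; tester coincidence is the fraction of groups electing the same
line. Per-trait partitions are kept separate.

## Prediction and validation

CV-α is replicated random k-fold on crosses: per replicate a random
partition into 5 folds (sizes differ by ≤ 1), each fold masked in turn,
the model refit on the remainder, and validation GEBVs (â + d̂) predicted
through the kernel rows linking masked to training crosses. Predictive
ability is pooled per replicate over all validation predictions (pooling
per fold first and averaging is also recorded in the per-fold table).
No stratification by parent is attempted: validation crosses share parents
with training crosses, which inflates ability relative to predicting
crosses of unseen parents — users should interpret it as the "tested
parents, untested combinations" scenario. Accuracy is PA/√H², clamped to
[−1, 1]. Selection coincidence selects the top ⌈s·n/100⌉ crosses by
adjusted means and by GEBV at intensities {1, 10, 20, 30, 40}% (direction
configurable per trait) and reports the percent overlap.

## Synthetic-data generator

The generator emulates the study system end to end:

* **Germplasm:** fully homozygous lines (dosages {0, 2}) in `n_pools`
  subpopulations via a hierarchical Balding–Nichols model — ancestral
  frequency per marker from Uniform(0.1, 0.9) (avoiding near-fixed
  markers), pool frequencies Beta-distributed around it with spread set by
  a single Fst-like `divergence` knob; divergence 0 collapses to no
  structure. Panel-monomorphic markers are redrawn. Defaults: 330 lines,
  6 pools, divergence 0.15, 12,000 markers on 10 synthetic chromosomes.
* **Platforms:** marker subsets of the same lines; "random" ascertainment
  samples uniformly, "biased" samples proportionally to the minor allele
  frequency in a reference subset of lines (array-style ascertainment
  bias). Missingness is injected completely at random; a genotyping error
  rate is exposed but defaults to 0 (platform error processes are not
  modeled beyond this).
* **Genetics:** a 45-parent diallel (parents drawn evenly across pools)
  with ~76% of the 990 possible crosses realized. Additive marker effects
  are i.i.d. normal; dominance effects are half-normal (directional) by
  default, because heterosis of inter-pool crosses requires dominance
  toward the favorable allele — symmetric dominance would generate SCA
  noise but no systematic between-pool elevation for the grouping step to
  find. Both are rescaled so the realized variances over the design's
  crosses equal the configured σ²_a and σ²_d exactly (defaults 1.0 and
  0.5).
* **Trials:** per environment, entries are shuffled into blocks of 16 plus
  2 checks each (last block may be short; checks appear once per block);
  observations add an environment effect, a block effect, and a residual
  with an environment-specific variance factor Uniform(0.5, 1.5) around
  σ²_ε (default 1.0) — emulating heteroscedasticity across environments.
  Checks are not genotyped; they carry fixed true values at quartiles of
  the hybrid-value distribution. Defaults: 8 environments, σ²_env = 1.0,
  σ²_block = 0.25.

Everything derives from one master seed via independent spawned streams
(the pipeline likewise fans its seed out per stage and panel), so studies,
runs, and written artifacts are byte-reproducible.

What the generator does **not** emulate: linkage disequilibrium from a
recombination map (markers are exchangeable given the frequency model),
sequence-level processes (reads, enzymes, alignment), genotype–environment
interaction of the hybrids, and platform-specific error signatures.
Passing recovery tests therefore demonstrates the statistical machinery
under the assumed generative model, not robustness to LD structure, G×E,
or platform artifacts in real data.

## Validation design and problem sizes

The test suite validates each layer against independent oracles:
brute-force formula evaluation for distances and kernels (including an
explicit Kronecker product), closed-form ANOVA and profiled grid-search
REML oracles, direct mixed-model-equation solves for BLUPs, and
simulations with known truth for recovery properties. Problem sizes are
chosen so the full suite runs in well under a minute of compute per heavy
test: variance-component recovery uses a 25-parent diallel (300 crosses,
30 replicates); heterotic-pool recovery uses 40-parent two-pool panels
with 60% of crosses observed (20 replicates); platform concordance uses
100-line panels with two ≥2,000-marker views (10 replicates); Mantel
calibration uses 500 null replicates at 199 permutations. For recovery
experiments the diallel model consumes simulated adjusted means whose
error standard deviation is √(σ²_ε/n_envs) — the error stage-1 BLUEs carry
across the default 8 environments — rather than re-running the plot-level
stage-1 fit inside every replicate; stage-1 itself is validated separately
against least-squares oracles and noiseless designs.

Tester-election recovery deserves a caveat: true tester scores (mean true
inter-pool cross value) often differ by margins far smaller than their
spread across candidates (top-2 margins down to ~0.005 trait units where
the candidate spread is ~0.6). Even with noiseless means, an estimator
that must integrate over the ~40% unobserved crosses resolves the top
candidate in only ~90% of group elections, so recovery is asserted at the
group-election level (≥80% matching the true best), not as exact identity
of both testers in every replicate.

`scripts/acceptance.py` runs the pipeline end to end at a scaled-down
study size (120 lines, 6 pools, three panels of 2,700/2,400/1,200 markers,
30 diallel parents, 3 environments) chosen to exercise every stage —
including the plot-level stage-1 REML on ~1,100 plots — while completing
in well under a minute.

## Known limitations

* Dense linear algebra throughout: fits are O(n³) in observations, fine to
  a few thousand plots or crosses, not for biobank scales.
* LD pruning compares each marker to all previously kept markers on the
  chromosome, which is quadratic per chromosome; window-limited pruning is
  not implemented.
* The strict (uncentered) dominance-kernel mode and the unstructured
  residual covariance across environments are not implemented; see above
  for the rationale of each substitute.
* Kendall agreement between free-k cluster partitions is sensitive to the
  elbow rule picking different k on different platforms; this is reported,
  not hidden, and a fixed-k override exists.
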