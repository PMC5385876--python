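# Methods

`spectrum_effect` implements a spectrum–effect relevance workflow for
multi-herb formulations: given chromatographic fingerprints of
formulation variants built on a uniform experimental design, and a panel
of pharmacological indices measured per animal group, it ranks the
fingerprint components by their contribution to each aspect of the
measured bioactivity and reports a consensus set of core bioactive
components. This note records the model, the conventions, the defaults
and the design decisions; everything numeric it mentions is computed by
the test suite or by `scripts/acceptance.py`.

## Uniform design

Formulation variants are laid out by the good-lattice-point (GLP)
construction: for `n` runs and a generator `g` coprime with `n`, column
entries are `((i·g − 1) mod n) + 1`, so every column is a permutation of
`1..n`. Design quality is the Hickernell centered L2 discrepancy (CD2)
of the level midpoints `u = (level − 0.5)/n`; `search_design` scores all
strictly increasing coprime generator tuples with the first generator
fixed at 1 and returns the CD2 minimum, breaking ties toward the
lexicographically smallest tuple, so the search is deterministic and
exhaustive for single-generator-per-column designs. For nine runs and
two factors the searched optimum is the tuple (1, 4). Users reproducing
a published layout can instead load an explicit table from
`design.csv`; levels map to herb doses through a user-supplied affine
map (`dose = dose_offset + dose_scale · level`, identity by default).

## Preprocessing

* **Group means.** Indices are averaged per animal group (mean, SD, n);
  missing values are a hard error — no imputation anywhere.
* **Orientation.** Indices for which a larger value means a weaker drug
  effect are inverted by the reciprocal, applied to the group means.
  Defaults: whole-blood viscosity at the three shear rates, plasma
  viscosity, erythrocyte aggregation, electrophoresis and rigidity
  indices and the maximum platelet aggregation rate are inverse; the
  clotting times APTT and PT are direct (a longer time under treatment
  is a stronger effect). The map is fully overridable per run.
  Orientation is applied to group means rather than per animal; the two
  orders differ (reciprocal of a mean is not the mean of reciprocals)
  and the group-mean convention matches the stated processing order of
  the workflow this package follows.
* **Nondimensionalization.** Each column is divided by its mean over the
  nine formulation (S) groups only; control/model/positive-control rows
  are carried through scaled by the same divisor but never influence it.
  S-row column means are exactly one afterwards, and the transform is
  idempotent on its own output.
* **Clustering.** Samples are clustered by average ("between-groups")
  linkage on the Pearson-correlation distance `1 − r` between peak-area
  vectors (scipy's hierarchical clustering). Merge heights are rescaled
  so the final merge sits at 25 — the dendrogram convention of classic
  statistical packages — and classes are read at a rescaled cut,
  default 5.

## Bioactivity factors

The oriented, dimensionless S-group panel (9 samples × 10 indices) is
reduced by principal-component extraction from the correlation matrix:
unrotated loadings are eigenvectors scaled by the square root of their
eigenvalues, the retained count is either fixed (five for the ten-index
clinical panel) or chosen by the eigenvalue-greater-than-one rule, and
the cumulative variance is `100·Σ top-m eigenvalues / p` — invariant
under rotation. Rotation is varimax with Kaiser normalization,
implemented as the classical pairwise planar-rotation sweep with the
closed-form quartic angle; the gradient/SVD fixed-point iteration was
found to stall on exactly the block-structured inputs the tests use
(equal eigenvalues make the unrotated basis arbitrary and the identity a
saddle), while the pairwise sweep recovers simple structure there.
Scores use the regression (Thompson) method `F = Z R⁻¹ Λ` with a
pseudoinverse, since nine samples of ten indices leave the correlation
matrix rank-deficient. Two presentation conventions are applied because
score signs and factor order are otherwise arbitrary: each factor is
flipped so its largest-magnitude loading is positive, and factors are
reordered by explained variance. Factors are labelled by the clinical
group of their dominant loadings (indices within 90% of the factor's
maximum absolute loading contribute their group).

## Grey relational analysis

For a reference series `x0(k)` and comparatives `xi(k)` over the
`n` samples: deviations `Δ_i(k) = |x0(k) − xi(k)|`, extremes
`Δmin/Δmax` pooled over all comparatives and points *within one
reference series* (per factor, not across factors), coefficients
`ξ_i(k) = (Δmin + ρΔmax)/(Δ_i(k) + ρΔmax)` and the grey relational
degree `GRD_i = mean_k ξ_i(k)`. The distinguishing coefficient ρ
defaults to 0.5. If every comparative equals the reference (`Δmax = 0`)
all coefficients are set to 1 by the limit convention and the event is
logged. Ranking is by GRD descending with ties kept in component order.

Reference scaling: the comparatives are unit-mean dimensionless peak
areas, while factor scores are zero-mean. Four conventions are
provided — `raw` (scores as-is), `mean_one`, `zscore`, and `match`,
which affinely maps the reference to the comparatives' grand mean and
average per-series spread. `match` is the pipeline default: grey
relational generation requires all series on one dimensionless scale,
and with a zero-mean reference against unit-mean comparatives the
deviations are dominated by the offset rather than the shape (on
synthetic data the `raw` rankings were essentially unrelated to the
planted associations, while `match` tracks them). `raw` remains the
primitive-level default so the textbook worked examples hold verbatim.

## Gated stepwise regression

Each factor is regressed on the component matrix by forward selection
(partial-F entry at p ≤ 0.05, equivalent to the candidate's t-test in
the augmented model) and backward elimination (removal at p ≥ 0.10),
iterated to a fixpoint, with selection capped at `n − 2` terms and a
condition-number guard (10¹⁰) that drops a numerically collinear
entrant. A model is *valid* only if the overall F-test clears p < 0.05;
valid models contribute signed standardized (beta) coefficients, raw
coefficients are retained in the report. When no valid model exists the
fallback relevance is the normalized squared marginal Pearson
correlation of each component with the factor — deterministic and
monotone in marginal association; a leave-one-out ridge-stabilized
variant is available behind a config switch. The per-factor method tag
records which path was taken so the consensus stage knows whether signs
exist.

## RBF network importance

Per factor, a Gaussian radial-basis-function network is fitted on
standardized inputs: centers by seeded k-means (default three hidden
units for nine samples, keeping the output least-squares problem
overdetermined), widths equal to the nearest-other-center distance
divided by √2 (floored at 10⁻⁸; for a single center, the data spread is
used), and output weights with bias solved by least squares. With as
many centers as distinct samples the network interpolates exactly.
Per-component contribution is seeded permutation importance — the mean
increase in squared prediction error over (default) 30 shuffles of one
input column, negatives clipped, normalized to sum one. Permutation
importance is used because hidden-unit connection weights are not
per-input quantities; a flat model yields a uniform vector with a
warning. All seeds are explicit and recorded.

## Consensus core components

For each factor and method the top-k (default 3) components are taken by
score magnitude, ties broken by component order; **zero scores never
occupy a slot** — a zero means the method produced no evidence, and
counting zero-score placeholders would deterministically promote
early-numbered components whenever a valid regression selected fewer
than k terms. A component joins the core set when it reaches the top-k
of at least `min_methods` (default 2) methods for at least `min_factors`
(default 1) factor, and — where a valid regression model selected it in
those qualifying factors — its coefficient is nonnegative in at least
one of them. Components rejected purely by sign are listed with the
reason. The rule's thresholds are recorded in the report's audit block;
the core subset of the peak table is emitted as the bioactive
fingerprint for quality-control monitoring, with optional user-supplied
herb attribution. With one method available `min_methods` collapses to 1
(logged). The core set is monotone in k and the whole report is a
deterministic function of its inputs and parameters.

## Synthetic studies and what they show

The generator emulates the full study: GLP design → herb doses → peak
areas `peak_k(i) = Σ_h c_kh·dose_h(i)·exp(ε)` with lognormal noise
(peak areas are positive with scale-proportional error) → per-animal
index values `μ_j + Σ_k B_jk·peak_k(i) + N(0, σ)`. Effects are planted
on the latent oriented scale: inverse-oriented indices are emitted as
the reciprocal of the latent value, so the pipeline's orientation step
recovers the planted linear structure. Control and model groups carry
configured latent offsets and no component effects, giving the panel
the same shape as a real multi-group experiment. Ground truth (active
set, per-index signs, the effect matrix) is bundled with every study
and written as a sidecar JSON, and identical configurations produce
byte-identical fixture files.

Defaults: 9 samples, 2 herbs, 13 components, 10 indices, 10 animals per
group, baseline 50 (keeps latent values positive under reciprocals),
animal noise SD 1, lognormal fingerprint sigma 0.2. The fingerprint
sigma deserves a note: each formulation variant is a separately
prepared decoction, so per-component variability reflects extraction
chemistry (tens of percent), not just instrument repeatability — and
this variability is what makes single components statistically
identifiable at all. With noise-free dose mixing, every peak from the
same herb has an identical profile across samples, and no statistical
method can separate an active component from an inert herb-mate.

Two named study configurations are frozen as benchmarks:

* **`recovery_benchmark`** — the parameter-recovery study: three herbs,
  two of them bioactive with two active components each (P2, P5 and
  P8, P11), the third contributing the nine inert peaks. Every index is
  driven by three actives (own-herb pair at 2.4/1.2 with alternating
  dominance, one cross-herb active at 1.4), so each of the two emergent
  factors has its top ranks saturated by actives, while inerts share no
  dose direction with any factor. All planted weights exceed three
  animal-noise SDs per index (noise SD 0.5). This geometry is a design
  choice, not an accident: at n = 9 the marginal relevance methods (GRA,
  RBF importance) share their sampling noise, so any top-k slot not
  claimed by a genuine active is filled by the *same* spurious component
  in several methods at once. A recovery benchmark in which some factor
  has fewer than k true drivers therefore measures the noise coupling of
  the methods, not recovery.
* **`null_benchmark`** — the type-I study: zero effect matrix and
  deterministic chemistry (no fingerprint noise), isolating the
  stepwise gate's false-positive behaviour under the design's intrinsic
  peak collinearity. With preparation-level fingerprint noise the 13
  marginal entry tests decorrelate and the family-wise entry rate of a
  best-of-13 selection necessarily grows well beyond the single-test
  level; the deterministic-chemistry regime is the one in which the
  gate's calibration is a property of the design rather than of the
  noise level.

What passing synthetic tests do **not** show: real fingerprints have
retention-time drift, co-eluting peaks, and component correlations that
are not dose-driven; real pharmacology has inter-animal correlation,
nonlinearity and saturation. The generator shares none of these, so
recovery on the benchmark demonstrates internal consistency of the
pipeline under its own assumptions, not field performance.

## Numerical choices and degenerate inputs

* CD2 is computed vectorized with the round-off floor `max(·, 0)` before
  the square root; tests check it against a literal double-sum.
* Correlation-distance clustering fails loudly on constant peak vectors
  (undefined correlation); all-identical samples yield one class.
* The stepwise cap `|selected| ≤ n − 2` prevents saturated fits with 13
  candidate predictors and 9 samples.
* GRA with `Δmax = 0` returns all-ones coefficients (logged).
* Importance vectors falling to all-zero (flat model, constant target)
  return uniform weights with a warning rather than dividing by zero.
* Factor extraction refuses factor counts above the correlation-matrix
  rank and constant columns; the Kaiser rule retains at least one
  factor.

## Problem sizes

The test suite and the acceptance script run the study at its native
scale (9 samples × 13 components × 10 indices): 50 seeds for consensus
recovery, 200 seeds for null calibration of the stepwise gate, 100
random instances for the grey-relational oracle comparison, and 200
random Latin layouts for the design-quality baseline. These sizes give
binomial standard errors of a few percent on the reported rates, which
is adequate for the 90%/10% bounds they are compared against.

## Known limitations

* The published study's raw peak areas and per-animal pharmacology
  exist only in its supplementary material; the embedded reference
  tables (factor scores, GRD matrix) support rank-level regression
  checks, and exact numeric reproduction of the GRD table, the
  five-factor variance figure, the seven-class clustering and the
  regression selections is possible only once those tables are supplied
  as `fingerprints.csv` / `pharmacology.csv`.
* "Relative importance" and the RBF per-variable "connection weight" of
  the original SPSS workflow are not reconstructible from their
  descriptions; the definitions used here (marginal r², permutation
  importance) are documented approximations expected to agree at the
  rank level, not numerically.
* The consensus rule is a formalization of a narrative procedure; all of
  its thresholds are exposed in configuration and echoed in the audit
  block rather than claimed as the published study's exact rule.
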