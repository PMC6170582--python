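# Methods

This note documents the statistical model behind `aepymorph`, the choices
made where the design was genuinely open, and what the synthetic tests do
and do not demonstrate about real specimen data.

## Data model

Each skeletal element carries a fixed, ordered measurement scheme (femur
F1–F20, tibiotarsus Tt1–Tt21, tarsometatarsus Tmt1–Tmt44), all in mm as
recorded; no unit inference is attempted. Two codes (F15, Tt21) occur in
published per-taxon measurement tables without an anatomical definition in
the published measurement diagram; they are registered with an explicit
"definition unknown" description rather than a guessed one, because they
are needed to represent the published tables.

Missing markers: an empty cell and the literal `NA` are both accepted on
read; empty cells are written on output (common museum-spreadsheet
practice). A specimen's missing fraction is counted over the element's
full code list. The first-round inclusion gate is strict — a bone missing
exactly 25 % of its measurements is deferred to round 2 — reflecting the
rule "less than 25 % missing".

## Imputation

Iterative PCA (EM): scale each measurement to unit variance using
observed-cell means and sample standard deviations (codes observed fewer
than twice, or with zero spread, are rejected); initialise missing cells
at the column mean (zero in scaled space); then repeat

1. recentre the working matrix,
2. reconstruct it at rank S by truncated SVD,
3. replace missing cells with their reconstructions, restoring observed
   cells exactly,

until the largest absolute change on any imputed cell falls below `tol`
(default 1e-6 scaled units; `max_iter` 500; non-convergence is flagged,
not fatal). In the default *regularized* mode each retained singular value
λ is shrunk to (λ² − σ̂²)/λ with σ̂² the mean discarded eigenvalue, which
damps the overfitting that plain EM exhibits when much data is missing.
Observed cells are bit-identical between input and output by
construction, and this is asserted on every result.

The rank S is selected by k-fold (default fivefold) cross-validation on
*cells*: observed cells are randomly partitioned into folds (re-drawn, a
bounded number of times, if a fold would starve a column below two
training observations), each fold is masked and re-imputed under every
candidate rank, and squared errors accumulate on the held-out cells in
scaled space. The MSEP-minimising rank wins; exact ties go to the smaller
rank (parsimony). Cell-wise masking keeps every specimen in every
training set, matching the "error of predictions" framing. The candidate
grid is 1 … min(8, p−2, n−2). CV runs with a looser convergence
tolerance (1e-4) than the final imputation: it only ranks candidates, and
the ranking stabilises long before the imputed values do.

Scaling parameters are recomputed per analysis round (the alternative —
freezing round-1 scaling for round 2 — is not taken; the run report
records the per-round parameters).

## Clustering

PCA is a centred SVD of the scaled completed matrix with a deterministic
sign convention (the largest-magnitude loading of each component is made
positive). Mixtures are fitted by EM over six covariance
parameterisations named by the volume–shape convention — EII, VII
(spherical), EEI, VVI (diagonal), EEE, VVV (ellipsoidal); equal (E) or
varying (V) across components. The family constraint is re-imposed at
every M-step. Initialisation cuts a Ward agglomeration at K; additional
restarts use random hard assignments, and the best restart by
log-likelihood wins. An EM run that empties a component is retried from a
fresh random start, bounded. Near-singular covariances (condition number
above 1e10) receive a ridge of 1e-6 times the mean diagonal.

BIC = 2 log L − m log n, maximised. Model selection fits every
(K, family) pair; exact BIC ties break to smaller K, then fewer
parameters. A selection is *stable* when the winner beats the best model
with a different K by more than ΔBIC = 2 (configurable). Principal
components enter the cluster model stepwise; the search stops at the
first step that is stable **and** resolves a distinct pattern (K ≥ 2) —
a confidently unimodal one-dimensional view must not end the search when
clusters separate on a later component. If no step qualifies, the step
with the largest stability margin is returned, flagged unstable (this is
also the outcome on genuinely structureless data, where K = 1 wins at
every step).

Classification uncertainty is 1 − max posterior responsibility; the
removal threshold (0.05) is inclusive. Filtering is idempotent.

The two-round design: round 1 clusters the well-preserved subset
(missing fraction < 0.25). If another element resolved more clusters, a
supervised re-fit at that fixed K probes for subclusters on the same PCA
scores. Round 2 re-imputes an inclusive dataset — everything over the
gate, everything removed for uncertainty, all type specimens, all
localised specimens, plus the round-1 members so both rounds share a
reference frame (memberships are tagged so either subset can be
recovered) — and re-clusters at the K fixed by round 1, with a fresh
mixture fit rather than scoring against the round-1 model. An optional
log-transform variant re-runs the same chain on log-measurements.

## Nomenclatural resolution

A cluster's name is the senior available species name among the type
specimens assigned to it with uncertainty below threshold: earliest
publication year, ties broken by month. An unknown month is treated as
December — it cannot beat a known month in the same year. Poorly
predicted type specimens stay in the evidence chain, flagged, but lend no
name; a cluster with no usable type specimen is "unnamed". Resolution is
a pure function of the (name, year, month) tuples and memberships. Genus
availability beyond species seniority is out of scope and reported as
metadata only.

Interval assignment places a published measurement value (or min–max
range) into a cluster when it intersects exactly one cluster's observed
interval; gaps are "unassigned", multiple hits "ambiguous". One published
interval set (femoral least-shaft circumference) has a 1 mm overlap
between its two largest clusters, so it is not globally pairwise-disjoint;
the default mode therefore requires only that the *query* resolves
unambiguously, while `strict=True` refuses any non-disjoint set.

## Mass estimation

log₁₀ M = 2.411 · log₁₀ LCF − 0.065, with M in **grams** and LCF the
femoral least-shaft circumference (code F3) in mm; the gram scale is
confirmed by the published worked value for the largest femur (308 mm →
~861 kg ≈ the printed 860 kg). Conversion to kg divides by 1000;
rounding to the nearest kg happens only at presentation. Cluster
summaries (min/max/mean/sd/n) use unrounded per-specimen masses and, by
default, only observed (non-imputed) F3 cells; single-specimen clusters
report sd = 0 by convention, flagged by n = 1.

## Synthetic data generator

A specimen from cluster k is μₖ + f·λ + ε with f ~ N(0,1) a latent
overall-size factor shared across all measurements, λ the per-code size
loading, and ε independent residual noise; draws are truncated positive
by resampling the residual (keeping the size factor), avoiding a point
mass at zero. Cluster means default to the midpoints of the published
per-taxon min–max ranges; per-taxon gaps are filled by linear
interpolation (and edge extrapolation) along the taxon size order. The
total per-code standard deviation defaults to a quarter of the printed
range width — placing ±2 sd at the printed extremes — split equally in
variance between the size factor and the residual (each width/(4√2)).
The tibiotarsal tables print single type-specimen values rather than
ranges (and omit Tt15 entirely); there the dispersion default is 8 % of
the profile mean, a typical within-taxon coefficient of variation implied
by the femoral range widths, and Tt15 is filled from its anatomical
neighbours Tt14/Tt16.

Missingness is either MCAR (cells independently at `rate`) or *breakage*:
a bone is broken with probability `rate`, losing one whole anatomical
block (proximal end, distal end or shaft); an end break also removes the
span measurements that need both ends intact. Blocks are defined per
element from the anatomical definitions of the codes. The default
breakage rate (0.45) puts roughly 40–50 % of specimens over the 25 %
gate, as in real assemblages; recovery tests use 15 %.

The planted-subcluster scenario (`femoral_subcluster_config`) builds
three femoral morphs — the smallest and largest taxa at their published
midpoints, the middle one the mean of the two intermediate taxa — and
splits the middle morph into two subgroups offset ±0.85 per-code standard
deviations along size, with subgroup sizes (16, 14, 14, 16). That offset
is deliberately at the BIC detection threshold for these sample sizes:
unsupervised selection typically resolves three clusters while a
supervised four-component fit typically recovers the planted split. It
is a threshold phenomenon, so individual draws can flip either way; tests
and the acceptance script therefore assert and report the modal behaviour
over 20 seeds, not a per-seed guarantee.

What the generator does **not** emulate: sexual size dimorphism,
allochronic size drift, spatial autocorrelation, measurement error
structure, or any within-taxon covariance beyond the single size factor
(the published ranges imply no more). Passing recovery tests therefore
show that the pipeline recovers structure *of the kind the method
assumes*, not that real assemblages satisfy those assumptions. Notably,
the synthetic clusters separate almost entirely on the size axis, so
stepped selection usually stops at one principal component — real
specimen data needed several.

## Numerical choices and problem sizes

Imputation: tol 1e-6 (CV: 1e-4), max_iter 500, regularized mode default.
EM clustering: relative log-likelihood tolerance 1e-8, max_iter 500,
three restarts by default (four in the supervised subcluster probe, which
hunts a weak optimum). ANOVA diagnostics use observed cells only and a
Bonferroni threshold of 0.05 divided by the number of codes actually
testable (at least two clusters with at least two observations each).
Recovery statistics run on 72-specimen tarsometatarsal and 60-specimen
femoral tables over 20 seeds, and imputation error over 3 seeds — sizes
chosen to match the published collection scale while keeping a full
verification run in the minutes range.

## Known limitations

- The six-family covariance zoo covers the shapes the method names;
  rotationally constrained families (e.g. equal-orientation ellipsoids)
  are not implemented.
- Single imputation only: no multiple-draw variance pooling, so
  downstream uncertainties ignore imputation uncertainty.
- The stepped-selection rule is greedy (first qualifying step); it does
  not revisit earlier steps with different K ranges.
- Seniority resolution implements date priority only — no formal
  availability, homonymy or suppression logic.
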