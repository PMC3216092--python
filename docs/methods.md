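# Methods

This note documents the models, estimators, numerical choices and known
limitations of `tfa-cycle`.

## Activity model and robust regression

Relative expression is modelled multiplicatively: a gene's expression at
time t is the product of contributions from every TF binding its
promoter, `R_i(t) = c · ∏_j b_ij^{α_j(t)}`.  Binding coefficients are
strictly positive with non-targets at the neutral baseline `b = 1`, so in
log space non-targets contribute nothing and the model is an ordinary
linear regression per time point:

```
log R_i(t) = c'(t) + Σ_j α_j(t) · log b_ij + ε_i(t)
```

Natural logarithms are used throughout; the α coefficients are invariant
to the choice of base (only the intercept rescales).  Genes with a
missing or non-positive expression value at a time point are excluded
from that time point's regression only — rows are never dropped
wholesale, and nothing is imputed.

The fit is iteratively reweighted least squares with Tukey bisquare
weights, tuning constant 4.685 (95% efficiency under Gaussian errors),
starting from OLS.  At each iteration the residual scale is
`σ = MAD/0.6745` about the residual median; weights are
`w = (1 − u²)²` for `|u| < 1` with `u = r/(4.685·σ)`, else 0.  An
optional leverage adjustment (`r/√(1−h)`) is off by default.
Convergence is declared when the maximum coefficient change falls below
1e-7 relative, with a 300-iteration cap (bisquare IRLS converges
linearly; a non-converged fit is returned flagged with a warning).  On
effectively noiseless data the IRLS loop is skipped and the result is
exactly OLS.

Three residual-scale estimates are reported per time point: `σ_OLS`
(root-mean-square error of the unweighted fit), `σ_robust` (MAD-based as
above, from the converged fit), and the final scale
`σ_final = max(σ_robust, w·σ_OLS + (1−w)·σ_robust)` with blend weight
`w = 0.5` by default (configurable; an equal blend is the natural
uninformative choice).  Standard errors come from the diagonal of
`σ_final² (XᵀWX)⁻¹` and p-values from a two-sided t test with
`df = n_genes_used − n_TFs − 1`.

## Iterative TF selection

A TF is retained if its activity is significant (`p < 0.1`) at ≥ 9 of the
36 time points.  All failing TFs are dropped *simultaneously* each round
and the survivors refit, repeating to a fixed point; retained sets are
nested, so no TF re-enters.  Batch (rather than one-at-a-time)
elimination matches the recomputation-after-elimination structure of the
procedure and makes the iteration count small (typically 2–4 rounds).
Under the null the per-TF chance of passing is the Binomial(36, 0.1)
upper tail at 9, ≈ 0.8%, so with tens of decoys an occasional false
retention at this stage is expected; the periodicity filter downstream
removes such TFs in practice.

## Periodicity score

For a profile x of known period P samples,

```
score = Σ_{t≤n−P} x_t·x_{t+P}  /  Σ_t x_t²
```

— the *raw* autocorrelation at lag P normalized by lag 0, with no
mean-centering and no per-overlap scaling.  Consequences worth knowing:

- Any exactly P-periodic profile observed for three full cycles scores
  exactly 2/3 (the lag-P sum spans two of the three cycles); no profile
  exceeds 1 (Cauchy–Schwarz).  Empirical scores just under 2/3 are
  therefore near-ceiling.
- A constant profile also scores 2/3: the statistic rewards any
  non-zero mean.  Mean-centering is available behind a flag
  (`center_autocorrelation`, default off, matching the raw convention).
- The score is invariant to rescaling and sign flips.
- The lag is `round(period_minutes / sampling_interval)`; a non-integer
  ratio is rounded with a warning (the study-shaped 36-point grid over
  864 min gives 300/24.7 ≈ 12.15 → lag 12).

Significance: time points are uniformly permuted N times (default 1000)
and the score recomputed.  Two reference conventions are provided — the
observed score (standard permutation test; p is approximately uniform
under an exchangeable null) and a fixed threshold (used to calibrate the
0.44 cutoff; also reported pooled across a TF set as an exceedance
rate).  p-values use the add-one estimator `(1 + #exceed)/(N + 1)`.
The retention rule is inclusive: score ≥ threshold.

## Sine fits, peak phases, cycle-phase labels

The phase/amplitude summary fits `A·sin(2πt/P + φ) + m` with `t = 0` at
the first time point.  φ is scanned on a 1° grid (configurable); at each
φ, A and m are the exact least-squares solution, so over whole observed
cycles the sequential search equals joint minimization — this
equivalence is verified against a closed-form sin/cos two-regressor fit
in the tests.  A ≥ 0 by convention (φ shifted by 180° if needed); a
zero-variance profile gets amplitude 0 and an indeterminate-phase flag.
The constant offset m is included because activity profiles are not
zero-mean.

Peak phases: the three cycles are averaged position-wise into one
12-sample cycle; the argmax position k maps to `k·(360/P)` degrees
(position 0 → 0°), ties broken to the earliest position and flagged.

Angles map to cycle phases as Ox = [285°, 345°), R/B = [165°, 285°),
R/C = [345°, 360°) ∪ [0°, 165°) — half-open at the lower edge, arc
lengths 60° < 120° < 180° (R/C is the longest phase).  Per-time-point
labels can instead be derived from the oxygen trace: slopes are forward
differences (last point backward), with dead band θ = 0.5·std(slope);
slope < −θ → Ox, > +θ → R/B, else R/C.  Forward differences are used
because central differences straddle the break points of a
sawtooth-like trace and mislabel the trough and peak samples.  The
angular registration between sine-fit phases and absolute experiment
time is a convention (t = 0 at the first sample); it is fixed and
documented rather than inferred.

## Clustering

Hierarchical agglomerative clustering on |α| rows — absolute values
because activator/repressor pairs of one program have mirror-image
profiles and should co-cluster (they are at distance zero after |·|).
Defaults: Euclidean distance, average linkage, flat cut at k = 2; all
configurable.  Flat labels at k always refine those at k−1.

## Time-translation model

With columns as time points, A = activities dropping the last time point
and B = dropping the first, the model `α(t+1) = T·α(t)` is estimated as
`T = B·A⁺` (pseudoinverse — identical to the normal-equations solution
at full rank, minimum-norm with a warning when rank-deficient).  The
orientation contract is normative: `T` applied to the activity column at
time t approximates the column at t+1.  Identification requires
`n_timepoints − 1 ≥ n_factors`.  The constrained variant solves each row
of T by non-negative least squares (Lawson–Hanson active set via
`scipy.optimize.nnls`); because its feasible set is smaller, its
Frobenius fit residual is never below the unconstrained one — an
inequality asserted in the tests.

The dissolved-oxygen trace can be appended as an extra factor: it is
z-scored and rescaled to the median per-factor standard deviation of the
activity rows (affine-invariant, comparable in magnitude).

Model verification simulates from the first observed activity column
(`column s = T^s·α₀`) and reports per time point both the mean-activity
difference (observed factor-mean minus simulated factor-mean; signed,
can cancel across factors) and the RMSE across factors (stricter).  The
constrained matrix often has spectral radius above 1, so its forward
simulation can diverge over 35 steps; the Frobenius fit residual is the
bounded comparison.  Eigen-decomposition of T gives asymptotic modes:
each complex pair is an oscillatory mode with period `2π/|arg λ|`
samples and per-step decay/growth `|λ|`.

## Network extraction

`|T[k, j]| ≥ 0.5` (inclusive; the comparator is exposed because "greater
than" vs "threshold of" is ambiguous in common usage) defines edge
j → k with the entry's sign preserved.  When both directions of a pair
pass, only the larger-magnitude direction survives; exact ties keep both
edges flagged.  Self-loops are recorded in the outputs but excluded from
graph exports by default.  Exports: GraphML, DOT, tab-delimited edge
list, all with deterministic node ordering.

## Synthetic data

The generator emulates the study conditions: 36 time points at 25-min
spacing (three 300-min cycles, 12 samples per cycle), 200 genes, 13
active TFs among 37 decoys, 25 targets per TF with log-strengths
~ N(1.0, 0.3) truncated positive, log-scale expression noise sd 0.15,
2% missing cells, intercept c = 1.  The active set has two shape
families: 5 smooth sinusoids with phases concentrated around 200–255°
plus one mirror partner at 45° and amplitudes 0.30–0.45, and 8 spike
profiles sharing a single pulse position early in the cycle (the
oxidative burst) — Gaussian pulse of sd 0.8 samples, amplitude 0.9, four
positive-going and four negative-going, on low-amplitude (0.15)
baselines — mirroring the observed structure where several factors spike
up and their counterparts spike down at the same three time points.  The
oxygen sawtooth drops steeply over 2 samples, rises over 4 and plateaus
over 6 per cycle.

Binding transforms: stored numbers may be taken as coefficients directly
(`identity`) or converted from binding p-values via
`b = 1/clip(p, floor, 1)`, which maps absent/weak binding (p = 1) to the
neutral baseline 1; the floor (default 1e-4) keeps `log b` finite.

What the generator does *not* emulate: microarray hybridization physics,
gene–gene correlation beyond shared TF regulation, condition-dependent
binding (the binding matrix is static), TF–TF interaction terms, and
model misspecification (real expression is not exactly log-linear in
binding).  Passing closed-loop tests therefore demonstrates correctness
of the estimators under the model's own assumptions, not performance on
real microarray data.

## Problem sizes and determinism

Default test and acceptance problem sizes (200–300 genes, 50–55 TFs, 36
time points, 200–1000 permutations) were chosen so the whole suite runs
in well under a minute while preserving the genes ≫ TFs regime the
regression requires.  Every stochastic component — synthetic generation
and permutation tests — is driven by a single seed; rerunning the
pipeline with identical config, seed and inputs reproduces every output
file hash exactly.

## Known limitations

- The raw (uncentered) periodicity score conflates a non-zero mean with
  periodicity; a constant profile scores 2/3.  Use the centering flag if
  profiles may have large offsets relative to their oscillation.
- Iterative selection inherits the per-test false-retention rate of the
  p < 0.1 / ≥ 9 time-point rule (~0.8% per null TF per round).
- The linear time-translation model is first-order and time-invariant;
  it cannot represent phase-dependent coupling.
- The sine-fit phase grid (1°) limits phase resolution to half a grid
  step; amplitudes are exact given the chosen phase.
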