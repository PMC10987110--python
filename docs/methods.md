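# Methods

## Problem and model

Given a table of amino-acid substitutions scored by S heterogeneous
pathogenicity predictors, the package estimates a single ensemble
pathogenicity score per substitution and a potential-pathogenicity value
per protein residue. The model is a thresholded linear combination of
per-predictor scores brought onto a common scale; its parameters (the
non-negative weights e_s and the intercept e_t) are fitted to labeled
variants by maximizing the product of sensitivity and specificity.

### Homogenization

Each predictor's raw score B is mapped to a pathogenicity probability
p(P=1) ∈ [0, 1]:

- **direct** (PolyPhen-2, REVEL, VARITY): p = B, already on [0, 1] with 1
  most pathogenic;
- **inverted** (SIFT): p = 1 − B, since SIFT scores 0 as most deleterious;
- **signed_class** (MutationTaster on a ±100 scale, MLb-LDLr on ±1): the
  sign carries the predicted class and the magnitude that class's
  probability, so p = |B|/scale for B > 0 and p = 1 − |B|/scale otherwise.
  B = 0 sits on the benign branch and maps to p = 1 by the formula; in
  practice signed-class tools never emit 0 because the sign *is* the call.

Raw values outside the admissible range by at most 1e-9 are clamped
(floating-point noise from upstream exports); larger violations raise an
error naming the predictor and value.

### Normalization

A two-segment linear map pins each predictor's decision threshold t_s to
0.5 while keeping 0 and 1 fixed:

    p_Nor = 0.5 + 0.5 (p − t_s)/(max − t_s)   if p ≥ t_s
    p_Nor = 0.5 (p − min)/(t_s − min)          otherwise

with min = 0 and max = 1 for all bundled predictors. Values exactly at
t_s map to 0.5 and are classified pathogenic (SIFT, the only tool that
emits threshold-exact scores, treats them as deleterious, and the
convention is kept uniformly). For a predictor already on [0, 1] with
t_s = 0.5 the map is the identity, so PolyPhen-2/REVEL/VARITY scores pass
through unchanged. The map is monotone for every valid spec, which the
property suite checks, and invertible, which the synthetic raw-data
generator exploits.

Bundled thresholds: 0.5 for PolyPhen-2, VARITY, MutationTaster and
MLb-LDLr (homogenized scale); 0.5 for REVEL, which publishes no canonical
threshold — the registry value is editable; 0.95 for SIFT (raw 0.05 under
the inverted encoding). MutationTaster's percent scale (±100) is inferred
from its export format; both the scale and the thresholds live in the
registry file rather than in code.

### Combination and classification

The non-optimized combination is the plain sum of normalized scores, on
[0, S] with an inclusive decision threshold S/2. The optimized score is

    f(P)_opt = e_t + Σ_s e_s · p_Nor,s ,  pathogenic ⟺ f(P)_opt ≥ 0.

When a subset M of predictors is missing, the available weighted sum is
rescaled by W/(W − W_M) (W = Σ e_s, W_M the missing weight), keeping the
score's range; the uniform sum analogously uses S/S_available. Both
rescales log a warning. A row retaining zero total weight is an error.

The raw score lives on [e_t, e_t + W]. For presentation it is mapped onto
[0, display_max] (default 7) by the same two-segment construction, with
the decision point 0 sent to display_max/2 = 3.5. The display transform
is monotone and classification is defined on the raw score, so the two
views can never disagree; the suite checks this on 10⁴ random scores.

The bundled model (weights 0.76, 1.38, 0.67, 0.91, 0.51, 1.82 for SIFT,
PolyPhen-2, MLb-LDLr, MutationTaster, REVEL, VARITY; intercept −3.43) has
raw range [−3.43, 2.62]; the all-zero and all-one score vectors reproduce
those endpoints exactly, which the acceptance script recomputes.

### Residue potential pathogenicity

For residue r and predictor s, f(PP_rs) is the arithmetic mean of the
normalized scores of the substitutions observed at r (n_sr of them;
missing cells drop out of the mean). The per-predictor averages are then
combined with exactly the same code path as a single substitution's
scores — uniform sum or weighted optimized score on the display scale —
so a residue whose substitutions all share one score vector gets exactly
that vector's combined score. Residues are keyed by position; conflicting
reference residues at one position are a data inconsistency and raise.

Display values are binned for the hotspot map: bin 0 (white) for values
≤ 4.5, bins 1–5 for the upper-inclusive intervals (4.5, 4.9], (4.9, 5.3],
(5.3, 5.7], (5.7, 6.1], (6.1, 6.5]. The boundary 4.5 is white because the
red intervals include only their upper limits; values above 6.5 (possible
up to 7) clamp to bin 5 with a warning. The exported map covers every
residue of the annotated protein, emitting unscored residues with an
empty value and bin 0.

The bundled LDLr domain annotation (nine domains over 860 residues) is an
approximation assembled from public feature annotation; exact boundaries
are debatable and the file is meant to be edited.

## Weight fitting

F0 = Sn·Sp is piecewise constant in (e_s, e_t): it changes only when a
variant's call flips. Gradient methods are therefore useless and a
derivative-free evolutionary search is used
(`scipy.optimize.differential_evolution`, rand1bin strategy, polishing
disabled). Defaults: population 60, up to 300 generations, weights
bounded to [0, 3], intercept to [−S, 0], convergence tolerance 1e-6 on
the population's objective spread, fully seeded. Two deliberate choices:

- the uniform model (e_s = 1, e_t = −S/2), whose calls equal the
  non-optimized sum's, is seeded into the initial population, so the
  returned fit can never score below that baseline on training;
- F0 ties break toward higher sensitivity (a 1e-6-scale tie-break term,
  smaller than any F0 increment at the dataset sizes involved), matching
  the clinical preference for not missing pathogenic variants.

Non-convergence within the generation budget returns the best-so-far
model with a logged warning and `converged=False` in the diagnostics.

## Validation machinery

- **Split**: stratified random split assigning round(3/4 · n_pathogenic)
  and round(2/3 · n_benign) variants to training (half-up rounding), the
  remainder to validation; deterministic given a seed. A
  609-pathogenic/60-benign cohort yields 457/152 and 40/20.
- **Metrics**: Sn = 100·tp/(tp+fn), Sp = 100·tn/(tn+fp),
  F0 = (Sn/100)(Sp/100). Internal math keeps full precision; percentages
  round half-up to one decimal only at reporting.
- **Bootstrap**: percentile CIs from n_boot resamples with replacement at
  the original size; resamples missing a class are redrawn (not skipped)
  so exactly n_boot valid resamples contribute, with the redraw count
  logged. The CI need not bracket the point estimate; a calibration test
  checks that it does in ≥90% of replicate datasets.
- **AUROC**: the threshold sweep over all distinct score values with
  trapezoidal integration, computed via `sklearn.metrics.roc_auc_score`
  and cross-checked in the test suite against a brute-force pairwise
  Mann–Whitney oracle (exact equality on hundreds of random small
  datasets, ties contributing one half).
- **Concordance**: a variants × predictors correctness matrix tallied
  into an agreement histogram (levels 0..S) plus per-predictor totals;
  missing cells count as incorrect and are logged.
- **Per-domain metrics**: confusion metrics within each annotated residue
  range, with an `unassigned` pseudo-domain for uncovered positions;
  a domain missing one class reports only the defined metric.

## Synthetic data

The generator emulates the *geometry* of real predictor output on the
normalized scale, not the predictors' biology: label-conditional
truncated-normal draws on [0, 1] with class means 0.5 ± δ/2 (δ the
separation, default 0.6) and standard deviation 0.15 — values chosen so
that δ spans chance (δ=0) to perfect separation (δ=1) with realistic
overlap in between. Two presets exercise shapes seen in practice:
`polarized` (mass piled near 0 and 1, as conservation-based tools
produce) and `threshold_hugging` (scores compressed around 0.5, as
calibrated gene-specific tools produce). Missingness masks cells
independently per predictor at a configurable rate, never leaving a row
entirely unscored. Substitution placement draws positions uniformly with
a consistent reference residue per position and at most 9 substitutions
per residue; when a coding sequence is supplied, substitutions are
restricted to single-nucleotide-accessible ones under the standard
genetic code. Raw-scale tables are produced by inverting the
normalization and encoding maps, giving a round-trip oracle for the
normalization pipeline (recovery to 1e-9).

Passing tests on this data show that the machinery is self-consistent and
that the optimizer recovers planted signal; they do not show that real
predictors meet the distributional assumptions, nor do they reproduce
published cohort statistics, which require the original proprietary score
table.

## Problem sizes and determinism

The test suite and acceptance script run at desk scale: recovery studies
use 500+50 variants over 20 (suite) or 8 (script) seeded runs,
bootstraps use 1000 resamples, AUROC oracles 200 datasets of ≤50
variants. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); fits, splits, bootstraps and simulations
reproduce bit-exactly under a fixed seed.

## Known limitations

- The model is linear in the normalized scores; predictor interactions
  are not modeled.
- Weights are not identifiable when training F0 saturates at 1.0 (many
  optima classify identically); only the induced classifier is then
  meaningful, which is why recovery is assessed on validation F0 rather
  than on the weight vector.
- Signed-class homogenization is discontinuous at 0 by construction of
  that encoding.
- The bundled domain ranges are approximate; per-domain metrics inherit
  that approximation.
- Bootstrap CIs are percentile intervals; no bias correction (BCa) is
  applied.
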