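# Methods

`cvcausal` quantifies the complexity of beat-to-beat cardiovascular series
and the directed interactions among them with one shared construction — a
non-uniform multivariate embedding — and three estimators operating on it.
This note records the model, the numerical choices, and what the synthetic
benchmarks do and do not establish.

## Series model and preprocessing

The input is a set of M series sampled once per cardiac beat: heart period
HP(n) in ms, systolic arterial pressure SAP(n) in mmHg, and respiration
RESP(n) in arbitrary units, n = 1…N.  Analyses target short-term
regulation, so a window of N = 256 consecutive beats is drawn at random
from the recording.  Candidate windows are screened by a stationarity
heuristic: the detrended window is split in halves and rejected when the
absolute mean difference exceeds 0.5 pooled standard deviations or the
variance ratio exceeds 2 — an automatic stand-in for visual screening of
slow mean drift and sudden variance changes.  After `max_tries` failed
draws the best-scoring window is used with a warning.

Within the window each series is linearly detrended (least-squares line
over the beat counter) and then normalized to zero mean and unit variance.
The population variance convention (divide by N) is fixed throughout:
every index below is a ratio of variances or entropies, so the convention
cancels, but one choice must be pinned for exact tests.  Normalization
happens inside the selected window, after detrending; series are stored
0-based with 1-based beat numbering in logs and reports.

Baroreflex sequence analysis is the exception: it runs on the raw-unit
windowed series, because its thresholds are physical (5 ms, 1 mmHg).

## Non-uniform embedding

For effect series i, the candidate set contains lagged components
y_j(n−k) for every source j with τ_j ≤ k ≤ p, where τ_j is the minimum
delay of influence of j on i and p the maximal lag.  The self delay is
at least 1; other delays may be 0 to admit within-beat (instantaneous)
effects.  The defaults encode cardiovascular physiology:

| effect | HP | SAP | RESP |
|--------|----|-----|------|
| HP     | 1  | 0   | 0    |
| SAP    | 1  | 1   | 0    |
| RESP   | 1  | 1   | 1    |

(rows: effect; columns: source; entries: τ).  SAP and RESP may modify HP
within the same beat through the fast vagal arm; RESP reaches SAP within
the beat through intrathoracic pressure; HP cannot affect SAP within the
beat by construction of the measurement convention, and neither HP nor
SAP affects RESP within the beat.  p defaults to 8 (so each source
contributes 8 or 9 candidates).

Embedding rows always run over n = p+1…N, also for column subsets, so
full- and reduced-universe estimates share the same target samples and
their difference cannot reflect differing sample counts.  Columns are
ordered source-major, lags ascending — the canonical order used for every
deterministic tie-break downstream.

## The three estimators

**MB (linear model-based).**  The effect is regressed on the complete
candidate grid by ordinary least squares without intercept (the universe
is zero-mean).  The in-sample mean square prediction error λ²(p) is
computed for orders p = 1…8 and the order minimizing the Akaike figure
of merit AIC(p) = (N−p)·ln λ²(p) + 2·q(p) is retained, q(p) being the
number of estimated coefficients; λ² is floored at 1e−12 inside the
logarithm, and an order achieving λ² ≤ 1e−12 wins immediately (an exact
linear law has been found; higher orders would only re-fit it
rank-deficiently).  Because the series have unit variance, λ² at the
optimum is directly the normalized complexity index NCI^MB ∈ [0, 1].
Note the classical AIC penalty retains a spare parameter with
probability P(χ²₁ > 2) ≈ 0.16 per candidate order, so order recovery on
simulated AR(2) data plateaus near 70%, with the true order as the clear
mode — a property of the criterion, not a defect of the fit.

**LP (model-free local predictability).**  Each effect sample is
predicted as the inverse-distance-weighted mean of the images of the k
nearest embedding vectors (zero-order predictor) under the maximum norm,
with a Theiler exclusion window of half-width T around the query (T
defaults to p, removing trivially overlapping vectors; the width is a
sensitivity parameter, not a sharply determined constant).  Skill is the
squared Pearson correlation r² between series and prediction.  The
embedding is grown greedily: every remaining candidate is tentatively
appended, r² evaluated over all rows, the best kept; after selecting
(source s, lag l) all candidates of s with lag ≤ l are pruned; selection
continues until the candidate set is empty.  NCI^LP = 1 − max r² over
the trace, with the maximizing dimension q^o as the optimal description
length.  The per-row neighbor search excludes the query itself via the
temporal window, so the r² tested during selection is an
out-of-sample-style quantity; a constant prediction scores r² = 0, as
does the empty embedding.

**CE (model-free conditional entropy).**  The Shannon entropy of a
sample is estimated as −ln of the probability that two members lie
within a tolerance ε (unordered distinct pairs, closed inequality,
probability floored at 1/pair-count to keep the estimate finite).  The
conditional entropy of the effect given its embedding vector averages,
over rows, the entropy of the images of the row's k nearest neighbors.
ε = 0.1·(P84 − P16) of the normalized effect series, computed once on
the full window and reused for every conditional sample.  Selection
proceeds as in LP but minimizes CE; the dimension-0 baseline and the
NCI^CE normalizer are both the unconditional entropy of the target rows
(n = p+1…N), so NCI^CE = min CE / SE equals exactly 1 when conditioning
never helps, and 0 when the embedding pins the effect completely.  The
empty conditioning set reduces to the unconditional estimator by
definition.

k = 30 neighbors for both model-free estimators.

## Causality ratios

Causality from source j to effect i is the fractional change of the
effect's NCI when j is included in the universe:

    CR_{j→i} = (NCI_Ω − NCI_{Ω\j}) / NCI_{Ω\j}

CR < 0 indicates Granger causality (MB, LP) or information transfer
(CE).  An absolute-difference variant (NCI_Ω − NCI_{Ω\j}) is available
behind `normalization="absolute"`.

Per estimator the reduced index NCI_{Ω\j} is obtained as follows. MB:
re-fit in the reduced universe at the order optimized in the full
universe, over the same rows — the full design then nests the reduced
one and the in-sample ratio is never positive.  LP/CE: re-evaluate the
already-selected optimal embedding with the components of j removed (no
re-selection); when no component of j was selected the ratio is exactly
0, an explicit statement of absent causality.  A reduced NCI of 0 makes
the ratio undefined and raises a degenerate-denominator error.

## k-NN engine

Neighbor searches use the maximum norm, which makes incremental growth
cheap: appending a component updates the pairwise distance matrix as
D ← max(D, |outer difference of the new column|).  The selection loop
maintains this matrix and extracts per-row neighbor tables by partial
partition; every selection score (inverse-distance prediction, within-ε
pair counts) is invariant to the order of the k neighbors, so the
partition's arbitrary internal order is harmless.  The public per-query
search sorts by (distance, row index), breaking distance ties toward the
smaller index; exact agreement with an explicit brute-force scan is
asserted in the tests.  Exact embedding matches (distance 0) dominate
the zero-order predictor in the inverse-distance limit, so the
prediction is then the unweighted mean of the zero-distance images;
inverse weights are normalized by the smallest distance to stay finite
for subnormal distances.

## Baroreflex sequence method

A SAP ramp is a 4-beat window with three strictly same-sign SAP changes,
|ΔSAP| > 1 mmHg and |correlation(beat, SAP)| > 0.85.  A baroreflex
sequence additionally requires a concordant strictly monotone HP limb,
|ΔHP| > 5 ms and correlation(SAP, HP) > 0.85, at lag 0.  The slope of
the least-squares line in the [SAP, HP] plane (ms/mmHg), averaged over
sequences, is BRS; the fraction of ramps evoking a sequence is BEI.
Overlapping windows are each counted (the common convention for the
effectiveness index); strict inequalities reject boundary values.  With
no sequence BRS is NaN (undefined), not zero; with no ramp BEI is
likewise undefined.

## Synthetic benchmarks

`simulate_coupled` generates coupled stochastic systems with per-series
autoregressions, directed couplings at chosen lags (instantaneous links
allowed when acyclic; series are updated in topological order within a
beat), optional quadratic link nonlinearity (gain·(x²−1), centered for a
unit-variance source), and i.i.d. Gaussian innovations — the Gaussian
choice makes the model-based residual variance analytic for the AR(1)
benchmark (NCI^MB → 1 − a²).  The linear part must have companion-matrix
spectral radius below 1.  A 200-beat burn-in is discarded.  The default
trivariate preset (`cardio_like`) emulates the cardiovascular loop
(baroreflex SAP→HP at lag 0, RSA RESP→HP at lag 0, mechanical HP→SAP at
lag 1, RESP→SAP at lag 0, oscillatory AR(2) respiration with a period
of 4–5 beats) at N = 256, the study's window length.

These benchmarks exhibit known ground truth, stationarity and Gaussian
innovations.  Real beat series are nonstationary, artifact-prone and
subject to ectopic beats, and their couplings drift; passing the
benchmarks demonstrates correctness of the estimators and recovery under
the stated conditions, not performance on degraded recordings.
Waveform-level processing (R-peak detection, SAP peak picking) is out of
scope; the package starts from beat-indexed series.

The baroreflex toy interleaves planted 4-beat ramps with strictly
sign-alternating filler so no spurious 3-change run can arise; effective
ramps carry an HP limb exactly linear in SAP, making the planted slope
and the sequence/ramp ratio exact.  The cohort generator draws ages
uniformly on [21, 70] years and sets index = slope·age + Gaussian noise.

## Cohort association stage

Each index is correlated with age after a normality gate: the Lilliefors
variant of the Kolmogorov–Smirnov test (parameters estimated from the
sample — the appropriate null when no reference Gaussian is prespecified)
at α = 0.05 selects Pearson's r when normality is not rejected and
Spearman's rank correlation otherwise; significance is a two-sided
p < 0.05.  The reported r is whichever the gate selected, labeled.  No
multiple-testing correction is applied across the index family.  The
gate-plus-correlation compound keeps its type-I error near the nominal
5% (checked over 1000 null cohorts of n = 100).

## Problem sizes and numerical settings

Simulation-based checks use: N = 8192 and 20 seeds for the AR(1)
analytic limit; N = 4096 and 50 seeds for linear causality recovery;
N = 1024 and 50 seeds for the quadratic (nonlinear) benchmark; 50
trivariate subjects of 256 beats for the parsimony comparison; 1000 null
cohorts for the association level.  The reproduction script
(`scripts/acceptance.py`) uses moderately smaller replicate counts
(10/30/25/30/500) chosen so a single-CPU run completes comfortably;
rates at these sizes are stable to well within the margins asserted.
Tolerances: normalization checked to 1e−10; oracle equality to 1e−8
(OLS) and 1e−10 (CE); CR^MB non-positivity to 1e−10.  Condition numbers
above 1e8 abort a fit with a diagnostic rather than returning a
meaningless solution.

## Known limitations

* The Theiler width and the CE probability floor are conventions; both
  are configurable and their influence grows as N shrinks.
* NCI^CE at N = 256 sits high (≈0.8–0.95 for moderately autocorrelated
  series): with k = 30 images per conditional sample the entropy floor
  is coarse.  Comparisons across conditions or subjects remain valid;
  absolute CE levels should not be over-interpreted.
* The zero rule makes LP/CE causality ratios exactly 0 only when
  selection ignored the source entirely; on a truly unpredictable
  effect, spurious selections keep small negative ratios possible.
* AIC order selection intentionally tolerates ~30% single-order
  overselection (see above).
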