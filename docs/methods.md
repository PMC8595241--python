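# Methods

`isct` builds mechanistic in-silico clinical trials: cohorts of virtual
patients are synthesized to match published trial demographics, each
patient receives an individualized pharmacokinetic model, drug exposure is
converted into protein-activity mechanism-of-action (MoA) models over a
signed functional network, and the resulting efficacy statistic is analyzed
with the trial's statistical machinery. This note records the models, their
assumptions, the tunable parameters, and the design decisions taken where
the procedure was genuinely open.

## Virtual populations

**Adults.** The generator targets a reference summary (mean/SD of age,
height and weight, plus a female fraction). A multivariate normal over
(age, height, weight) is built from the reference moments; cross-variable
covariances are not published, so the height–weight correlation defaults to
0.5 (configurable) and other correlations to 0. BMI is never sampled: it is
derived as weight/(height/100)², which enforces the physical identity
exactly for every patient. If the reference constrains BMI, the derived-BMI
mismatch enters the annealing cost. Candidate populations are drawn from
the truncated MVND (age > 18, physically admissible height/weight) and
polished by simulated annealing on single-patient replacement moves. The
cost is the sum of squared standardized deviations of the sample means
(standardized by σ/√n) and sample SDs (by σ/√(2n)) from the reference
across targeted variables; the schedule is geometric cooling (T ← 0.95·T)
over 200 iterations per restart, at most 20 restarts. A population is
returned only when every targeted variable passes a two-sided one-sample
z-test at α = 0.05 — the acceptance rule itself — otherwise the whole
population is resampled (failing candidates are never repaired).

**Pediatric-adolescents (6–17 y).** Sex is fixed first by quota
(round-half-up on the female fraction). Per sex, a random-walk
Metropolis–Hastings chain samples the state (age, height, BMI); weight is
derived as BMI·(height/100)². The unnormalized target multiplies Gaussian
terms for every available reference variable with Gaussian
growth-consistency terms for height and BMI conditioned on the age–sex cell
of a growth reference table (nearest integer age; ages just under 18 use
the oldest cell), hard-truncated at 4 cell-SDs. Because the 6–18 age window
clips the upper tail of the reference normal, the chain targets a normal
whose *truncated* mean equals the reference mean (found by root-finding);
without this compensation the realized mean age would be biased upward by
about +0.2 y. Proposal steps are 0.5·SD per variable, burn-in 1000,
thinning 10 — conventional random-walk settings, exposed in `MHConfig`.
The same z-test acceptance rule gates the output.

**Determinism.** Identical inputs and seed reproduce populations
byte-for-byte; provenance (seed, reference hash, validation p-values,
restart count) is written next to every population table.

## PBPK model

A 14-compartment whole-body model with blood as the unique hub: gut,
liver, kidneys, brain, heart, lungs, muscle, adipose, skin, bone, spleen,
pancreas and a rest-of-body pool, each exchanging drug with blood through
its blood flow (hub-and-spoke; no organ-organ edges). Kinetics are linear:

* a first-order absorption depot (oral/subcutaneous routes) feeds blood
  with rate constant k_a; intravenous doses enter blood directly;
* each organ equilibrates flow-limited, dA_i/dt = Q_i(C_blood − C_i/P_i),
  with partition coefficients P_i defaulting to 1;
* elimination is restricted to gut, liver and kidneys and follows the
  plasma-clearance convention: each site removes drug at CL_site·C_blood,
  with per-site cumulative cleared amounts tracked. Referencing clearance
  to blood keeps the one-compartment limit exact: with organ flows removed
  and a single clearance site the blood curve reduces to the Bateman
  function, which the test suite checks within 0.5%.

Bioavailability F is applied at administration (each event adds F·dose to
the depot), so mass balance — depot + Σ organ amounts + Σ cleared =
F·administered — holds to solver precision at every output time (checked
within 0.1%). Integration uses a stiff-capable solver (LSODA) piecewise
between dose events, rtol 1e-8 / atol 1e-10, output grid 0.1 h.

**Individualization.** Organ volumes are fixed fractions of body weight;
flows are fractions of cardiac output = heart rate × weight-scaled stroke
volume (1 mL/kg), with heart rate by age band (90/78/70 bpm for <12,
12–18, adults). The fraction table is plain, user-replaceable data with
textbook-order physiological values — a deliberately transparent
anthropometric scaling, not a literature-calibrated one.

**Extended release.** Modified-release formulations are approximated by
repeated lower doses: biphasic capsules as two events of half the dose,
osmotic-release systems as three events of one third, spaced by the drug's
release interval. The interval defaults to 4 h (configurable); the source
PK curves we emulate were digitized at 4-hourly repeat dosing even where
prescribing language says twice daily, so 4 h is the default.

**Fitting.** (k_a, a common clearance scale, a blood-volume adjustment)
are fitted to observed blood concentrations by Levenberg–Marquardt least
squares in log-parameter space (positivity by construction), deterministic
from a fixed start. The blood-volume adjustment stands in for the
volume-of-distribution readjustment, whose exact rule is not published; we
expose it as a fitted multiplier. Fits report RMSE, R², and a degeneracy
flag when a Jacobian column is numerically null (flat objective).

## Exposure → MoA models → tSignal

**Target modulation.** Brain concentration timepoints are pooled by mean
(max selectable) through the Emax form c^h/(c^h + EC50^h) with Hill
coefficient h = 1 by default, signed by the drug's effect on each target
(+1 activation, −1 inhibition). How clinical efficacy observations map to
per-target EC50 values is not published; EC50s are user inputs here (the
end-to-end driver uses half the peak brain exposure as a synthetic
default).

**Propagation surrogate.** The proprietary supervised-training technology
that produces MoA models is replaced by a transparent surrogate with the
same interface and constraints: iterate x ← tanh(λ·(W x) + s + η) to a
fixed point (tolerance 1e-6, ≤200 iterations, else flagged
non-converged), where W is the signed weighted adjacency, s the stimulus
(drug modulation plus comorbidity inputs), λ = 0.5 the damping. When
λ is below 1/‖|W|‖₂ the map is a contraction with a unique fixed point —
which is why the per-solution Gaussian perturbation η (scale 0.1) is used
both as the start point *and* as a weak persistent input held fixed within
a solution: each solution then owns its own fixed point, giving genuine
intra-patient variability, while zero noise stays fully deterministic.
Activities are strictly inside (−1, 1) by construction. This surrogate
reproduces the published interface (bounded activities, ensembles,
accuracy gate); it makes no claim of molecular fidelity to the original
technology.

**Comorbidities.** A patient's comorbidity tags add the corresponding
signed protein definitions as weak persistent inputs (weight 0.25,
configurable) to the stimulus.

**tSignal.** For a signed disease definition {(i, v_i)} and activities
y_i, tSignal = −(1/n)·Σ v_i y_i ∈ [−1, 1]: +1 is complete reversion of the
signature, −1 the fully expressed signature. Definition proteins missing
from a solution contribute y = 0 (neutral) and keep n fixed — no silent
renormalization.

**Ensembles.** Per patient and drug, seeded perturbations are drawn until
at least 50 solutions (configurable) clear the training-set accuracy floor
of 85%. Accuracy is the percentage of training relationships whose
simulated tSignal change (stimulus-on vs stimulus-off under the *same*
frozen perturbation) matches the expected direction. Baseline
(stimulus-off) solutions are shared across both drug periods of the
crossover — both drugs replay the identical per-patient perturbation
stream, so each patient starts both periods from a cloned state and
carryover is zero by construction.

## Outcome mapping

Per-drug mean tSignal (solutions → patients → drug) is correlated with
pooled clinical efficacy (ADHD-RS-IV change from baseline; trials of the
same drug are plainly averaged — naïve pooling, no meta-analytic
weighting). The disease definition is optimized by greedy backward
elimination: repeatedly remove the single protein whose removal most
increases |ρ|, stop when no removal improves |ρ| by more than 1e-4 or the
floor (50% of the original size) is reached; ties break lexicographically
on protein id and the removal trace is logged, so trimming is replayable.
Exhaustive subset search is exponential; greedy elimination is our choice
where the published procedure is unspecified, and it is monotone in |ρ| by
construction. Correlation uses per-drug means (not per-trial points). The
expected sign of ρ is negative (higher tSignal = more reversion,
improvement = negative score change); a positive ρ raises a warning, not
an error. The final mapping to the clinical scale is ordinary least
squares.

## Analysis

**Local sensitivity.** One protein at a time is clamped across a grid of
21 points on (−0.99, 0.99), the propagation re-solved with the clamp held,
and the mean |tSignal − baseline| reported as a percentage of the maximal
possible variation, 2 − baseline tSignal. This is a one-at-a-time local
sweep with that stated normalization — not variance-decomposition Sobol
indices. Proteins above 15% are flagged as having real impact; ranking is
descending with lexicographic tie-break.

**Clustering.** Feature matrix: per-(patient, drug) mean activities of
the definition's effector proteins, drugs pooled. PCA to 5 dimensions,
k-means (k-means++, 25 restarts) for k = 2…7; candidates whose
smallest/largest cluster-size ratio falls below 0.05 are discarded as
heavily unbalanced (our concrete reading of the unbalanced-group filter,
which the source leaves undefined); among survivors the k with maximal
mean silhouette wins, bootstrap-Jaccard mean as tie-break. Quality
indices: Hopkins statistic (distances at the d-th power, so spatially
uniform data give expectation exactly 0.5; the internal generator stream
is keyed so it can never replay a caller's data stream), mean silhouette
(singletons score 0), and a B = 100 bootstrap Jaccard stability with
greedy best-match assignment.

**Comparison.** Per variable: one-way ANOVA across clusters plus
per-cluster two-sided Welch t-tests against the pooled rest,
Benjamini–Hochberg adjustment within each variable family, α = 0.05. When
any group has fewer than 30 samples the non-parametric pair
(Kruskal–Wallis / Mann–Whitney) substitutes automatically. Variables with
zero within-group variance are flagged test-undefined rather than erroring.

## Sample-size procedure

Normalized case/control expression (library-size CPM + log2(x + 0.5), a
deterministic stand-in for a limma-voom-style chain) restricted to the
disease-definition genes feeds a progressive-sampling learning curve: for
every even total n from 8 to twice the smallest cohort, 100 balanced
subsets are drawn without replacement, and a two-feature linear classifier
(univariate-t screen of 6 candidates, best pair by training accuracy,
least-squares fit with a 0.5 decision threshold) is scored by 10-fold
stratified cross-validation. Feature selection runs *inside* each training
fold; selecting on the full subset first would leak into the held-out
folds and push label-permuted data far above chance. The ceiling ("max
accuracy") is the same cross-validated estimate on the full dataset. A
normal is fitted to the per-n accuracies; the one-sided 5th/1st percentile
(95%/99% power) relative to the ceiling gives the %-of-max curves, and the
required sample size is the smallest n whose curve clears 85%.

## Synthetic data

The generators are pure functions of (parameters, seed) and emulate the
study's inputs at desk scale:

* **Demographics** — the packaged adult and pediatric reference columns
  carry the published trial summaries (adult: age 36.58 ± 10.10 y, height
  171.7 ± 9.4 cm, weight 78.75 ± 17.20 kg, 41.6% female; pediatric: age
  10.90 ± 2.80 y, weight 43.60 ± 15.10 kg, BMI 19.1 ± 3.4, 20% female).
  The growth grid is synthetic: monotone WHO-style height anchors per age
  and sex, a BMI curve centered so the age-marginal BMI matches the
  reference, and a deterministic height-scale calibration that makes the
  grid-implied population mean weight equal the reference mean weight
  under the reference age/sex distribution. It emulates the *shape* of a
  growth reference, not any real population's percentiles.
* **Molecular fixture** — a connected random signed network (spanning tree
  plus random edges, weights rescaled to spectral bound 1.5 so the default
  damping contracts). Disease signs are set opposite to the noiseless
  propagation of drug 1, so drug 1 reverses the signature, the sign-flipped
  drug 2 expresses it, and the training set is satisfiable by
  construction. Real interactomes are scale-free, noisy and unsigned in
  part; passing tests on this fixture demonstrates the machinery, not
  biological recall.
* **PK observations** — Bateman-curve datapoints with multiplicative
  log-normal noise.
* **Expression** — normal log2-scale baselines with the planted effect
  d·SD in the informative genes; real RNA-seq dispersion structure and
  batch effects are not emulated.

## Problem sizes

The shipped configurations are desk-scale by design: demo trials run tens
of patients with 8-solution ensembles; the test suite uses 500-patient
populations, 50-patient ensemble checks at the full 50-solution / 85%
constraints, 100-repetition learning curves on cohorts of 20–30, and
1000-rep null simulations. Full-scale arm bookkeeping (2 × [500 + 8×100] =
2,600 patients) is exercised end-to-end for the population stages.

## Known limitations

* The propagation surrogate shares only the published interface with the
  original supervised MoA technology; absolute tSignal values are not
  comparable across the two.
* The allometric table is transparent, not literature-calibrated; no
  enterohepatic recirculation, metabolite kinetics, transporter
  saturation, or inter-occasion variability.
* Trimming is greedy; it cannot escape local optima of the subset search.
* The pediatric generator assumes the growth table's cells are normal and
  conditionally independent given age and sex (apart from the derived
  weight).
* Sample-size results depend on the linear two-feature classifier family;
  richer classifiers would raise the ceiling and shift required sizes.
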