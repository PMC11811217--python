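# Methods

This note documents the models, numerical choices and open design
decisions behind `cardiocausal`, and what the synthetic cohorts do and do
not establish about real data.

## Synthetic cohorts

### Waveform level

Each subject carries a latent standard-normal "vascular tone" variable
`u`. The hypertension label is Bernoulli with a logistic link on `u`; the
link coefficient is *calibrated* (Gauss–Hermite quadrature + Brent root
finding) so that the realized between-class mean shift of `u` equals the
requested `confounder_effect`, in units of `u`'s SD. Effect sizes
throughout the package are standardized mean shifts, not raw logistic
coefficients, because shifts are what the downstream screening and
classification stages see. A logistic link cannot realize arbitrarily
large shifts (the ceiling is φ(z_p)/(p(1−p)), ≈ 1.60 at prevalence 0.5);
requesting more raises an error rather than silently saturating.

ECG is a template QRS — a Mexican-hat (Ricker) wavelet of width 20 ms at
each scheduled beat time — because only R-peak timing is consumed
downstream. PPG is a sum over beats of a closed-form two-Gaussian pulse
(systolic wave: amplitude 1.0, center 0.13 s after the pulse foot, width
0.055 s; dicrotic wave: amplitude 0.35, center 0.42 s, width 0.09 s),
delayed from the R peak by a subject-level pulse transit time
(0.20 ± 0.015 s). Having an analytic pulse means every fiducial landmark
has a computable ground-truth location (`pulse_landmark_times`, dense-grid
extrema of the exact derivatives), which is what the detector tests check
against.

Planted structure: hypertension shifts the subject's dicrotic-wave center
earlier by `causal_effect` × 0.03 s, where 0.03 s is the between-subject
SD of that center — so the effect is again a standardized shift. This
shortens the late-systolic timing features, most directly the
sdPPG-c-to-dPPG-valley duration (registry feature 52). The confounder
`u` raises heart rate (+3 bpm per SD) and PPG amplitude (+10 % per SD),
so RRI/TD and AM/AI/AR features acquire spurious label associations.
Beat-to-beat jitter (3 % on intervals and amplitudes, 4–5 ms on timings)
makes the six per-subject statistics non-degenerate.

Defaults mirror the emulated protocol: 405 subjects at prevalence
183/405, 24–36 segments of 15–30 s at 125 Hz. Tests and the demo config
use 3–40 subjects with few, short segments; those sizes are a deliberate
desk-scale choice, and all stochastic acceptance checks are formulated as
rates over seeds rather than point values.

What the generator does **not** model: validated hemodynamics, blood
pressure waveforms, motion artifacts, arrhythmia, sensor dropout, or
device heterogeneity. Passing tests therefore demonstrate that the
*analysis chain* is correct and that its discrimination claims hold when
the planted assumptions (additive confounding, logistic label, smooth
two-component pulses) are true — not that the same features are causal in
any real population.

### Feature level

`simulate_feature_sem` samples a linear-Gaussian / logistic structural
equation model in topological order; cycles are rejected with the cycle
listed. The standard planted cohort (`hypertension_feature_dag`) is

    conf → label          (logistic, calibrated to confounder_effect = 1.2 SD)
    conf → f_spur         (loading 0.9, unit total variance)
    label → f_causal      (shift = causal_effect = 1.0 within-class SD)
    f_noise_1..5          independent

The causal feature is modelled as a *child* of the label — the disease
altering waveform timing — which matches the waveform generator's
mechanism. Since CPDAG adjacency, not orientation, defines "direct causal
association" here (see below), the downstream logic is indifferent to
this choice. `confounder_effect` (1.2) is set above `causal_effect`
(1.0) so the confounded feature genuinely outranks the causal one in
correlation ranking — the regime the causal/correlational comparison is
about; both shifts sit inside the logistic ceiling.

## Feature registry

Table-style index ranges fix the six categories at 10/56/45/19/55/20
(= 205): PTT 1–10, TD 11–66, AM 67–111, AI 112–130, AR 131–185, RI
186–205. Within categories the ordering is lexicographic over landmark
pairs, with two published anchor indices pinned: 47 = TD(sdPPG c − PPG
peak) and 52 = TD(sdPPG c − dPPG valley); the two pairs displaced by
pinning take the vacated slots 46 and 53. The AI block cannot hold all
26 formula-implied values in 19 slots, so the registry adopts: PPG at all
ten primary landmarks, dPPG at {foot, max slope, min slope}, sdPPG at the
six a–f waves. The 20 RI ratios are fully formulated in
`registry.RI_NAMES` / `waveforms._ratio_index`; all are dimensionless
(amplitude ratios cancel scaling, time ratios are normalized by RRI).
The registry is shipped as data and unit-tested; it is the package's
reproducible contract for "feature *k*".

## Signal processing

Zero-phase 4th-order Butterworth band-passes (ECG 0.5–40 Hz, PPG
0.5–8 Hz, forward–backward) keep the channels phase-aligned so PTT is
unbiased; derivatives use Savitzky–Golay differentiation (window ≈ 70 ms,
cubic). R peaks are `find_peaks` above half the 99.8th-percentile
amplitude with a 0.3 s refractory distance. Fiducials are located by
windowed extremum search in the canonical order (each window bounded by
the previous landmark), which enforces strictly increasing landmark times
by construction; beats violating R-R bounds [0.3, 2.0] s or with empty
windows are flagged invalid with a reason code and excluded from
aggregation, never silently kept. Timing is in seconds, indices 0-based,
windows half-open.

## Aggregation and screening

SD uses the n−1 denominator; quartile deviation is (Q3−Q1)/2 with
linear-interpolation quantiles; CV = SD/mean is left missing when
|mean| ≤ 1e−9 and missing values are dropped per feature, not imputed.
Subjects need ≥ 10 valid beats. The two-sample test is Mann–Whitney U
(exact for small tie-free groups, tie-corrected normal approximation
otherwise) at α = 0.05 with no multiple-testing correction by default:
screening is a recall-oriented pre-filter ahead of the causal stage, which
is itself the specificity mechanism. Welch's t-test and
Benjamini–Hochberg are config switches. Survivors are ranked by ascending
p and capped at 50.

## GES engine

The search is the classic two-phase procedure over equivalence classes.
Insert(X,Y,T) validity requires NA_{Y,X} ∪ T to be a clique and every
semi-directed Y→X path to be blocked by it; Delete(X,Y,H) requires
NA_{Y,X}∖H to be a clique. Score deltas touch only Y's local term.
After each accepted move the PDAG is re-completed via a Dor–Tarsi
consistent extension followed by v-structure extraction and Meek closure
(rules 1–4; an orientation that would close a directed cycle is skipped
and recorded). Moves must improve the total score by > 1e−9; ties break
lexicographically on (source, target, subset) names, making the search
deterministic. A move budget of 4·p² guards termination.

Scores:

* **BIC** — from the ML covariance: σ²(Y|P) = C_YY − C_YP C_PP⁻¹ C_PY,
  score = −n/2·(log 2πσ² + 1) − (penalty/2)·(|P|+1)·log n, variance floored
  at 1e−12. Score-equivalent across Markov-equivalent DAGs, and cheap
  enough that `exhaustive_best_dag` (all ≤ 543 DAGs on ≤ 4 nodes) is a
  practical independent oracle. The binary label enters through its 0/1
  values.
* **Kernel generalized score** — k-fold (default 10) cross-validated
  Gaussian predictive log-likelihood of a kernel-ridge regression of the
  node on its parents: RBF kernel with median-heuristic bandwidth
  (γ = 1/median‖zᵢ−zⱼ‖²), ridge λ = 0.01, residual variance from the
  training fold (floored at 1e−6), empty parent sets scored by the fold
  mean. Fold assignment is fixed by a seed, so the score is deterministic
  and cacheable. The CV likelihood is inherently complexity-penalized, so
  no explicit parameter count is added. This treats linear, nonlinear,
  continuous and binary relationships uniformly; its cost is O(k·n³) per
  local score, which is why tests and the acceptance run exercise it at
  reduced cohort sizes (120–150 subjects) while BIC carries the
  exhaustive-oracle comparisons.

Continuous columns are standardized before scoring (bandwidth
comparability); binary columns keep their 0/1 coding.

## Consensus and fusion

Ten GES runs on 80 % subject subsamples per metric (a subsample that
loses a label class is redrawn, with the retry logged). "Direct causal
association" is operationalized as CPDAG **adjacency** to the hypertension
node — directed either way or undirected — because orientation adjacent to
a near-sink binary node is weakly identifiable and both directions are
substantively meaningful. An adjacency is kept iff present in strictly
more than half the iterations; its consensus direction is the majority
among directed occurrences, ties yielding an undirected edge. Across the
six metrics the rule is *union* (not a second majority): selection
operates per metric and the per-metric lists are then collapsed, features
sharing a base index becoming one node with per-metric provenance. Fusion
is order-invariant and raising the majority threshold can only remove
edges.

## Classification

Four classifiers with library-default hyperparameters and fixed seeds
(logistic regression behind a standardizer); stratified 10-fold CV;
metrics and curves computed from pooled out-of-fold predictions (per-fold
metrics are reported alongside; pooled is the default because single-fold
confusion matrices at desk-scale n are noisy). Point-biserial correlation
is computed as Pearson against the 0/1 coding (population-SD form). The
correlation arm always receives exactly as many features as the causal
arm. In the deployment-shift experiment, selection and model fitting use
the discovery cohort only; the held-out cohort is a fresh draw of equal
size with the confounder→feature loading changed (0.9 → 0.0), modelling a
measurement or population change that severs the spurious path while
leaving the causal mechanism intact.

## Degenerate inputs and numerical guards

Constant nodes score through a variance floor with a warning; ratio
features with vanishing denominators yield NaN and are dropped NaN-aware
downstream; screening excludes degenerate features; subsampling retries
class-empty draws; `MixedDataset` refuses missing values, so feature
columns containing NaN must be (and are) filtered before assembly.

## Known limitations

* The kernel score's exact form in the literature it follows is a family,
  not a single formula; the realization here (CV kernel-ridge predictive
  likelihood) is declared, not inferred from any original implementation.
* Exhaustive-oracle guarantees stop at 4 variables; beyond that,
  correctness evidence is the stability of consensus results and the
  planted-structure recoveries.
* Waveform-level causal discovery inherits whatever confounding the
  latent `u` induces among *observed* features; at small n the discovered
  neighbourhood can legitimately include confounded amplitude features
  (the confounder itself is not observed at waveform level). The
  quantitative discrimination claims are made at feature level, where the
  confounder is a measured variable.
* No do-calculus effect estimation, no latent-variable (FCI-style)
  search, no hypertension staging.
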