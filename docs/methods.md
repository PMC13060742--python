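# Methods

## The problem and the model

Older adults interact with medication adherence technologies (MATs — pill
dispensers, smart bottles, blister systems) through discrete *subtasks*:
inserting a battery, opening a compartment, reading an indicator. Whether a
given person succeeds at a given subtask depends on their cognitive,
physical, sensory, motivational, and environmental capabilities. The package
predicts the per-subtask proportion of success

    Y = (n_present − n_failed) / n_present

from a participant's demographic and functional-barrier profile, using
*personalized predictive modeling* (PPM): instead of one global regression, a
separate model is fitted for each target participant on the subset of
training participants most similar to them.

### Outcome model

For each (participant, device, subtask) exposure, the number of successes is
treated as binomial with denominator `n_present` and a logistic mean:

    logit(p_i) = β0 + β_age·age + β_sex·sex + β_mednum·mednum
               + β_medhist·medhist + β_cog·cog + β_phy·phy
               + β_vis·vision + β_seams·SEAMS + β_busy·MPEDbusy
               + β_hear·hear + Σ_c β_c·1[subtask = c]

Two variants differ only in the vision predictor: the performance-based SMAT
vision score or the self-reported DLTV summary score. The binomial
denominator enters as the row weight ("task count weights"), which makes a
row with `n_present = 2` exactly equivalent to two unit rows (tested).
Subtask indicators are one-hot with the lexicographically first code present
as the reference level. `age` is included by default; `include_age=False`
reproduces the predictor list that starts at sex. MPED routine is defined in
the data model but excluded from the default predictor list; a flag restores
it.

### Similarity and matching

Each participant is encoded as a vector of the same ten predictors,
z-standardized with location/scale estimated on the training cohort only
(`ScalingSpec`). Standardization is a design choice the source analysis
leaves open: raw non-negative scores would confine the cosine to [0, 1] and
let wide-range features dominate; centering realizes the full [−1, 1] range.
Similarity is the cosine of the angle between two vectors; zero vectors
raise rather than compare as 0. The matched subset for a target at matching
proportion m is the top `ceil(m·N)` most similar training participants, with
deterministic tie-breaking (descending similarity, then ascending
participant id). The target is always excluded from its own candidate pool.
At m = 1 the matched subset is the whole training pool and the fit is the
global, nonpersonalized model — the package guarantees this identity
bit-for-bit by assembling design rows in canonical input order and caching
fits on the matched set.

### Fitting

Fitting is Newton/IRLS on the weighted binomial log-likelihood with
step-halving, tolerance 1e-8 on the step, at most 100 iterations. Small
matched subsets can separate or lose rank; the fallback refits with ridge
1e-4 on the slopes (never the intercept) and records `penalty_used`, so
every cross-validation cell stays estimable without perturbing well-posed
fits. Non-convergence without a recorded penalty is a constructor-level
invariant violation. The linear predictor is clipped at ±30 inside the
likelihood; coefficients beyond 50 on the standardized scale are treated as
separation.

### Tuning, baselines, evaluation

Model error is the squared error in predicting the *number* of successful
attempts, `(p̂·n_present − n_success)²`, averaged over all rows of a test
set (unweighted across participants; predictions are not rounded to
integers). The matching proportion is tuned by participant-level k-fold
cross-validation over m = 0.20, 0.25, …, 1.00 (17 values; 9 folds split 117
participants evenly, 8 folds split 96). The optimal m minimizes the
fold-averaged MSE, smallest m on ties — at equal error the stronger
personalization is preferred, an explicitly arbitrary rule. Per-fold MSEs of
the tuned and global models are compared with a paired two-sided Wilcoxon
signed-rank test (exact null for ≤ 25 pairs; zero differences dropped;
all-zero differences degenerate to p = 1 with a warning).

Two baselines frame the results: the global model (m = 1) and the naive
constant predictor `p = Σ sᵢnᵢ / Σ nᵢ²`, the closed-form minimizer of the
count-scale squared error over constants, computed on training rows and
applied to test rows. Held-out validation fits each test participant against
the full training cohort at the tuned m and reports personalized, global,
and naive MSEs side by side.

## The synthetic-data generator

No study data are deposited, so the generator is a first-class module, not a
fixture. It emulates:

* **Profiles.** Truncated-normal ages (training analogue: mean 75.11,
  SD 7.70, range 61–95; validation analogue: mean 73.42, SD 8.56, range
  60–84), a 62.5% / 33.3% female split, and instrument scores drawn per band
  so that the derived barrier flags reproduce the configured prevalences
  (training analogue: cognitive 21/96, physical 37/96, SMAT vision 23/96,
  DLTV 37/96, both-ear hearing 55/96, motivation 34/96, environment 34/96).
  Within-barrier band splits follow the reported moderate/low counts;
  band interiors are uniform, with non-barrier bands kept strictly above the
  barrier cut so flags and prevalences stay consistent. These continuous
  shapes are modeling choices — only band counts are known.
* **Exposures.** 13 synthetic devices, each carrying a fixed random subset
  of 4–10 of the 32 subtask codes; 1–7 devices per participant; 1–3
  attempts per subtask. The real per-device subtask composition is
  unpublished, so realism here is structural (sparse, unbalanced), not
  empirical.
* **Outcomes.** Binomial draws with a logistic mean built from ground-truth
  coefficients (`TruthSet`), with per-subtask difficulty offsets drawn
  N(0, sd). A common intercept shift is solved by root-finding on the
  realized exposure rows so the pooled expected success proportion equals a
  target, 0.87 by default — matching the observed training-data mean and
  producing the left-skewed outcome that makes the naive constant a serious
  baseline.
* **Heterogeneity.** Optional latent subgroups with different slope vectors.
  Subgroup membership is correlated with the functional-score composite (or
  fixed by construction in `two_subgroup_cohort`, where subgroup feature
  distributions are shifted via low/high barrier prevalences), because
  cosine matching can only recover subgroups that are visible in feature
  space. With one subgroup the generator reduces to a homogeneous logistic
  population, on which personalization must show no benefit.

`two_subgroup_cohort` pairs opposite-sign slopes (±separation on the four
functional scores) with common structure shared by both subgroups (age −0.4,
hearing −0.6, medication count −0.2, busyness −0.3; subtask-difficulty
sd 0.8). The common part is what lets *both* covariate-informed models beat
the naive constant, as the subtask-level modeling premise requires; the
opposed part is what personalization alone can exploit.

What passing tests on these cohorts show is that the pipeline behaves
correctly under its own assumptions: real cohorts need not have
cosine-visible subgroup structure, their score distributions are not
band-uniform, and attempts-per-subtask may be larger and correlated with
ability. Synthetic results therefore validate the machinery and its
statistical properties, not clinical effect sizes.

## Numerical and procedural choices

* Barrier cuts: SMAT barrier at score ≤ 84 (the low and moderate-to-low
  bands; "high" starts at 90 and gap scores 85–89 count as non-barrier);
  DLTV < 79; SEAMS < 40; MPED busyness ≥ 15 or routine < 16; hearing
  barrier only at full (both-ear) impairment. All cuts are named module
  constants.
* Sex is coded 0 = female (the majority category), 1 = male; the whisper
  test maps to impairment fractions {0, 0.5, 1} with ear symmetry.
* Missing data are never imputed; a missing field raises a named error.
* `ceil(m·N)` subset sizes are guarded against binary-float grid noise
  (`ceil(m·N − 1e-9)`).
* Unfittable CV cells (degenerate matched subsets) are excluded from that
  fold's mean with a logged count; the optimal m is chosen over complete
  grid columns only.
* Whether the source analysis aggregated subtask rows across devices, or
  averaged fold MSEs over rows vs participants, is not recoverable; this
  package keeps one row per (participant, device, subtask) and averages
  over rows.
* All randomness flows from a root seed through named integer-sequence
  streams (`[seed, k]`), so profiles, exposures, outcomes, and fold splits
  are independently reproducible; repeated runs are byte-identical,
  including logs (which carry no timestamps).

## Problem sizes used in the test suite

Statistical properties are exercised at sizes chosen to give clear
separation between signal and Monte-Carlo noise while keeping the suite
quick: parameter recovery on 100 cohorts of N = 2,000 (slope SEs ≈ 0.01
against a ±0.1 band); the personalization ordering on ten N = 400
two-subgroup cohorts at separation 1.5 and one homogeneous N = 400 cohort;
calibration on an N = 2,000 cohort (≈ 1.1×10⁵ attempts, binomial SE ≈ 0.001
against a ±0.01 band); the heterogeneity-dial trend on N = 120 cohorts over
five separations × two seeds with a reduced m grid. Oracle equivalences run
1,000 random instances (cosine, naive closed form) and 200 (IRLS vs direct
optimization).

## Known limitations

* The intercept and subtask-indicator coefficients are reference-cell
  parameters whose precision is bounded by per-subtask exposure, not by the
  number of participants; recovery tests bound the standardized predictor
  slopes at ±0.1 and check cell parameters against their own Wald bands.
* Cosine similarity treats the binary sex indicator like any standardized
  coordinate; "mixed data types" are handled only in this embedding sense.
* The ridge fallback biases separated fits toward zero slopes; it is a
  stabilizer, not an uncertainty quantification. No confidence intervals are
  reported for personalized fits — with per-participant models there is no
  single global coefficient set to attach them to.
* The generator does not model assistance events, task timing, learning
  across devices, or correlation between attempts.
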