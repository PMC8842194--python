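# Methods

## Model

`depstates` fits a latent Markov (hidden Markov) model to item-level PHQ-9
panel data. For patient *i* with *T<sub>i</sub>* sessions (1 ≤ *T<sub>i</sub>*
≤ 10), the latent state sequence *U*<sub>1</sub>, …, *U*<sub>T<sub>i</sub></sub>
follows a first-order chain with initial distribution π<sub>u</sub> and one
transition matrix per time step, π<sub>t</sub>(v|u) — the transitions are
*time-heterogeneous*, so a state-to-state move may become more or less likely
as treatment progresses. Given the state, the nine PHQ-9 items are
conditionally independent categorical variables over {0, 1, 2, 3} with
emission probabilities φ<sub>j,y|u</sub> (local independence). The GAD-7
total is never an input to the state model; it only enters the clinical
outcome rules.

Free parameters for *k* states:
(*k*−1) + *k*(*k*−1)(*T*<sub>max</sub>−1) + 9·3·*k*; with
*T*<sub>max</sub> = 10 and *k* = 7 this is 573. The number of states is
chosen by BIC = −2ℓ + p·ln(n), with **n = number of patients**, the common
convention for latent Markov panel models (per-observation n would penalize
less; the choice is isolated in `bic()` and switchable by passing a different
n). Ties go to the smaller k.

Patients observed once contribute to π and φ only — they are deliberately
included so the first-timepoint state mix reflects everyone presenting to the
service, not just those who stayed.

## Estimation

EM with scaled forward–backward recursions (per-step normalizers, no
underflow for k ≤ 16, T ≤ 10). The M-step is closed form: π from the
first-session posteriors, each π<sub>t</sub> from summed pair posteriors at
that step, φ from expected item-category counts over non-missing items
(missing items are treated as missing at random and simply skipped in the
emission product). Time steps no patient reaches keep their transition matrix
at its initial value, with a logged warning.

Numerical safeguards and defaults:

- probability floor ε = 1e-6 applied after every M-step, then renormalized —
  prevents absorbing zeros without visibly perturbing the likelihood;
- convergence when the relative log-likelihood change drops below 1e-8,
  capped at 1000 iterations;
- the log-likelihood trace is monotone non-decreasing (asserted in tests with
  1e-8 absolute slack);
- Viterbi ties break toward the lowest state index, making decoding
  deterministic.

Multistart: `fit_k` runs one severity-quantile start (patients binned by
baseline PHQ-9 total into k groups; emissions from bin frequencies;
near-diagonal transitions) plus random Dirichlet(1) starts. All starts are
advanced 50 EM iterations and only the best is refined to full convergence —
the standard short-run strategy in mixture/latent-Markov software, which
spends the budget where it matters.

Because the likelihood is invariant under state relabelling,
`canonical_relabel` orders states by expected total PHQ-9 score
Σ<sub>j</sub>Σ<sub>y</sub> y·φ<sub>j,y|u</sub> (stable sort), so "state 1" is
always the least severe. States of nearly equal overall severity but
different profiles (cognitive/affective vs somatic vs hybrid) may swap ranks
within their severity tier between runs; identify them through
`state_profile_report`, not by index. Cross-fit comparisons use Hungarian
assignment on emission distance — L1 between category distributions averaged
over the nine items (range [0, 2]); this per-item normalization keeps the
distance comparable across k and interpretable against sampling noise.

## Synthetic cohort generator

No clinical data ship with the package; the generator produces panel data
with the structure the analysis assumes:

- **Emissions.** Each state×item cell has a location parameter (expected
  0–3 score); the category distribution is a tempered Binomial(3, loc/3)
  raised to a concentration exponent (default 2.0) and renormalized. The
  default 7-state location table follows the qualitative clinical structure —
  minimal, mild, cognitive/affective (peaks on the feeling-down, tiredness
  and self-esteem items 2/4/6), hybrid-moderate, somatic (peaks on sleep,
  tiredness, appetite items 3/4/5), moderately severe, severe — but the
  numbers are this package's design choice, not published estimates.
  **Separation requirement:** with concentration 2.0 the Jensen–Shannon
  divergence between any two states' 9-item emission distributions is ≥ ~0.6
  nats (Monte-Carlo estimate), close to the ln 2 ceiling. This matters: in an
  HMM the per-observation likelihood gain from splitting a state is bounded
  by ln 2, so at 2000 patients (~7800 observations) BIC can only resolve all
  seven states when the profiles are genuinely well separated. At a plain
  binomial (concentration 1.0, JS ≈ 0.3–0.45) the seventh state is not
  BIC-identifiable at that sample size.
- **Transitions.** Self-transition probability rises from 0.70 to 0.85 over
  the first six steps (movement stabilizes mid-treatment); 80% of the leaving
  mass flows to lower-severity states and 20% upward, decaying geometrically
  with state distance.
- **Lengths.** 30% of patients have a single record (the non-engaged
  analogue, giving ~70% engagement); the rest decay geometrically over 2–10
  sessions. A per-starting-state length matrix is supported to emulate
  state-linked dropout.
- **Demographics.** Binary covariates from logistic models on the true
  starting state; the defaults enrich the somatic state (+0.8 log-odds) for
  female gender, long-term condition and psychotropic medication. Age is
  state-independent. GAD-7 totals are Binomial(21, p) with p tied to state
  severity.
- **Seeding.** One root seed expands into independent child streams (paths,
  lengths, items, GAD, demographics), so adding a covariate never perturbs
  the sampled paths.

What the generator does **not** emulate: item-level missingness patterns,
therapist or service effects, measurement reactivity, informative dropout
beyond the optional state-linked length distribution, or the severity
gradations that made the real data favour more states than are
interpretable. Passing tests therefore demonstrate correctness of the
machinery and recoverability under the stated generating process — not that
seven states is the right description of any clinical population.

## Clinical outcome rules

Computed from first/last PHQ-9 and GAD-7 totals. Engagement defaults to ≥ 2
records (the minimum for a pre/post change score); a strict mode requiring
≥ 2 post-assessment treatment sessions (3 records) is available, since the
convention is ambiguous about counting the assessment. Reliable improvement:
drop of ≥ 6 PHQ-9 or ≥ 4 GAD-7 points with no such rise on either scale;
deterioration: a rise of ≥ 6 / ≥ 4; per cent improvement: ≥ 25% drop on
either scale with no ≥ 25% rise on either. All thresholds are inclusive, and
a scale with baseline 0 can neither qualify nor disqualify via percentage.
Improvement and deterioration are mutually exclusive by construction
(verified exhaustively over the full grid of totals).

## Trajectory summaries

Occupancy-over-time groups patients by decoded starting state; a patient who
leaves treatment is carried forward at the last decoded state, so each time
row is a proper distribution. Occupancy uses hard (Viterbi) paths to match
the global-decoding convention; the transition graph keeps an edge iff its
probability is ≥ 0.05 (configurable) for at least half of the nine time
steps — exactly half retains, since the omission rule's boundary is
ambiguous. Factor groupings default to cognitive/affective = items 1, 2, 6
and somatic = items 3, 4, 5; items 7–9 are unassigned because the two-factor
PHQ-9 literature disagrees on them, and the grouping is configurable.

## Post-hoc statistics

Pearson χ² on 2×2 tables (scipy backend; Yates correction off by default and
flaggable), df and N always reported separately. Logistic regression of
starting-state membership on demographics via statsmodels' ML fit, with
continuous predictors scaled/centred (SD with n−1, as R's `scale`),
categoricals dummy-coded against explicit reference levels, Wald SEs,
two-tailed p, no multiplicity correction. Separation and non-convergence
raise with diagnostics rather than returning garbage. VIF<sub>j</sub> =
1/(1−R²<sub>j</sub>) from regressing predictor j on the rest; perfect
collinearity reports inf.

## Problem sizes used in tests and the acceptance script

Model-order recovery uses 2000 patients per seed over 10 seeds (k scan 5–9,
10 starts); parameter recovery uses n = 500/2000/5000 at k = 2; fold
replication uses 6000 patients in 3 folds at k = 7; the null calibration of
the χ² battery uses 500 replicates of 240 patients; logistic effect recovery
uses n = 20000. Exact-oracle checks (forward–backward and Viterbi against
exhaustive path enumeration) run on 100+ random instances with k ≤ 3, T ≤ 5,
where enumeration is feasible.

## Known limitations

- Covariates never enter the measurement or latent model; they appear only
  in the post-hoc regressions.
- No bootstrap likelihood-ratio test or cross-validated likelihood for
  choosing k; BIC (or a fixed k) is the only selection rule.
- The EM floor technically breaks the exact monotonicity guarantee; in
  practice the trace is monotone at 1e-8 slack in every fit the suite runs,
  because floored cells carry essentially no posterior mass.
- Emission distances across folds conflate estimation noise with genuine
  disagreement; at fold sizes below ~1000 patients the 0.1 replication bound
  is dominated by sampling error.
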