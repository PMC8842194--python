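# depstates

Latent Markov modelling of item-level PHQ-9 trajectories over a course of
cognitive behavioural therapy.

Depression diagnoses hide heterogeneous symptom profiles: two patients with
the same PHQ-9 total may differ sharply in whether their burden is
cognitive/affective (feeling down, low self-esteem) or somatic (sleep,
energy, appetite). `depstates` is for researchers who want to define *fluid
depressive states* directly from item-level questionnaire panel data, track
how patients move between states from session to session, and test whether
patients starting in different states engage with and respond to therapy
differently.

## The model

Patients answer the nine PHQ-9 items (each scored 0–3) at up to 10 sessions.
A hidden first-order Markov chain with k states generates the responses:

- initial state probabilities π<sub>u</sub>;
- time-heterogeneous transition matrices π<sub>t</sub>(v|u), one per session
  step, so recovery- or relapse-type moves can wax and wane over treatment;
- categorical emission probabilities φ<sub>j,y|u</sub> for item j, score y,
  state u, with items conditionally independent given the state.

Estimation is EM with scaled forward–backward recursions; k is selected by
BIC = −2ℓ + p·ln(n patients); per-patient state paths come from global
(Viterbi) decoding; states are labelled in order of expected total severity
Σ<sub>j</sub>Σ<sub>y</sub> y·φ<sub>j,y|u</sub>. Downstream analyses:
occupancy-over-time by starting state (with last-state carry-forward), a
thresholded transition graph, IAPT-convention clinical outcomes (engagement,
reliable improvement, per cent improvement, deterioration), χ² comparisons
between starting states and logistic regression of state membership on
demographics with a VIF screen.

Because item-level clinical panel data cannot be redistributed, the package
includes a first-class synthetic cohort generator whose default truth is a
7-state structure (minimal, mild, cognitive/affective, hybrid, somatic,
moderately severe, severe) with treatment-like downward transition drift,
~70% engagement, and somatic-state-linked demographics. See
`docs/methods.md` for every modelling choice and its rationale.

## Worked example

```python
import depstates as ds

spec = ds.default_truth_spec(seed=1)
cohort, truth = ds.simulate_cohort(spec, 2000, seed=1)

table, fits = ds.fit_range(cohort, 5, 9, n_starts=10, seed=11)
print(table[["k", "loglik", "n_params", "bic"]].round(1))
k = ds.select_by_bic(table)          # -> 7
best = ds.canonical_relabel(fits[k])
decoded = ds.decode_cohort(best.params, cohort)
```

The selection table this prints:

```
 k   loglik  n_params      bic
 5 -55392.5       319 113209.6
 6 -52878.9       437 109079.5
 7 -50864.9       573 106085.0   <- BIC minimum
 8 -50795.5       727 107116.9
 9 -50679.7       899 108192.7
```

BIC bottoms out at the generating truth, k = 7: adding the 8th state buys
only ~70 log-likelihood points against a ~1170-point penalty. States of
similar overall severity are identified by profile, not index:

```python
prof = ds.state_profile_report(best.params.Phi)
cog = int(prof.loc[prof.dominant == "cognitive_affective", "state"].iloc[0])
som = int(prof.loc[prof.dominant == "somatic", "state"].iloc[0])
rep = ds.compare_states_report(
    cohort, decoded, cog, som,
    covariates=["female", "long_term_condition",
                "psychotropic_medication", "age"])
for name, t in rep.tests.items():
    print(f"{name}: chi2({t.df}, N={t.n}) = {t.statistic:.2f}, p = {t.p:.4g}")
print(rep.regression.table.round(3))
```

```
engagement: chi2(1, N=629) = 0.05, p = 0.8294
reliable_improvement: chi2(1, N=438) = 15.05, p = 0.0001046
deterioration: chi2(1, N=438) = 9.47, p = 0.002085
percent_improvement: chi2(1, N=438) = 22.95, p = 1.664e-06
                          coef     se      z      p
const                    1.518  0.201  7.569  0.000
age                      0.004  0.085  0.045  0.964
phq_baseline             0.108  0.086  1.248  0.212
gad_baseline             0.089  0.086  1.046  0.296
female                  -0.901  0.190 -4.741  0.000
long_term_condition     -0.952  0.177 -5.375  0.000
psychotropic_medication -0.469  0.171 -2.746  0.006
```

Patients decoded into the somatic state are significantly more likely to be
female, have a long-term condition and take psychotropic medication (the
negative coefficients are log-odds for cognitive/affective membership) —
recovering the covariate structure the generator planted, while age and
baseline severity are correctly flat. All VIFs are below 2.

A CLI mirrors the library (`depstates simulate / fit / select / decode /
transitions / outcomes / posthoc / replicate`):

```bash
depstates simulate --n 2000 --seed 7 --out cohort.csv
depstates select --cohort cohort.csv --k-min 5 --k-max 9 --starts 10 --seed 11
```

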