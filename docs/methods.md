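# Methods

## Diagnostic algorithm

The scoring rules are deterministic. An item is endorsed when its 0–4
response is ≥ 2; a symptom cluster (two items) or functional-impairment
block (three items) is met when at least one member item is endorsed; PTSD
requires the three PTSD clusters plus PTSD impairment without the full DSO
pattern; CPTSD requires all six clusters and both impairment blocks. The two
labels are mutually exclusive by construction, and a DSO-only presentation
is classified `none` — ICD-11 defines no stand-alone DSO disorder, and the
source analysis never tabulates that cell.

Under check gating an endorsement additionally requires a "yes" on the
item's clinical check. Checks are presented only for endorsed items, so a
record carrying a check answer for an unendorsed item, or no answer for an
endorsed one, violates the gating invariant; the reader reports such rows by
number and refuses the cohort. In gated scoring an endorsed item whose check
is recorded as not-presented raises an inconsistent-record error rather than
guessing.

Two items (emotional numbing, `dso_ad2`; feeling cut off from others,
`dso_dr1`) trialled two check variants. The final-instrument choice follows
the pre-set largest-decrease rule — variant 1 for numbing, variant 2 for
cut-off — and `select_check_variant` implements that rule with a
deterministic lowest-id tie-break (the published rule never needed one).
Which variant is consulted is a `ScoringMode` field, so either trial variant
can be scored.

Three decisions the source material leaves open:

* **Impairment checks.** The checks' exact administration to the
  impairment items is not documented in the available material; this package
  gates each impairment item by its own check, identically to symptom items,
  and aggregates with the same any-of rule.
* **Exposure precondition.** Published prevalences use all N = 975
  respondents as denominator, so diagnosis does not require reported trauma
  exposure; `ScoringMode(require_exposure=True)` adds that filter.
* **Missing scores.** Strict mode (default) refuses records with missing
  item scores, matching a forced-completion survey; lenient mode treats
  missing as 0 and is logged when used.

## Paired statistics

Relative decreases are computed from the *displayed* one-decimal
percentages, 100·(E% − CC%)/E%, because that is the convention the
reproduced tables follow (count-based decreases differ in the second
decimal, e.g. 101/247 = 40.9% vs (25.3 − 15.0)/25.3 = 40.7%); a
count-basis variant sits behind the `decrease_from_counts` flag. Display
rounding is half-up: percentages to one decimal, Z to two.

McNemar's Z is (b − c)/√(b + c), reported as a magnitude, with two-sided
normal p. The report applies a mixed correction policy, logged when
reporting: uncorrected at the symptom and cluster level (where the printed
statistics equal √b exactly), continuity-corrected ((|b − c| − 1)/√(b + c),
floored at zero) at the disorder level (where the printed statistics match
the corrected form). The library API always takes an explicit `corrected`
flag. The normal approximation is checked in tests against the exact
conditional binomial test (statsmodels) and agrees within 0.01 in p for
b + c ≥ 40, the regime of every reported comparison.

Cronbach's alpha, (k/(k − 1))(1 − Σ s²ᵢ / s²ₜₒₜ) with n − 1 variances, is
provided for scale reliability; published alphas (0.88/0.90) require the
unshared raw data, so tests validate the operation against an independent
implementation (pingouin) and on synthetic cohorts. The
prevalence-estimation sample size is the normal approximation
⌈z² p(1 − p)/E²⌉; for p = 0.05, 99% confidence, E = 0.02 it gives 788,
whereas the source analysis printed 782 from an unspecified calculator —
the function returns the formula value and this discrepancy is documented,
not patched.

## Synthetic cohort generator

The generator defines the conditions every simulation-based test runs
under. Per respondent:

1. **Exposure.** Zero events with probability 0.275; otherwise 1 + a
   negative-binomial count (mean 4.09, dispersion 1.5, clipped at the
   21-event inventory), spread uniformly over distinct events. This gives an
   exposed fraction of 0.725, overall mean 3.69 (the 0.725 × 5.09
   decomposition of that mean) and SD ≈ 4.0, median 3, matching the
   published exposure summary.
2. **Traits.** Latent PTSD and DSO severities are bivariate standard normal
   with correlation ρ = 0.80, both shifted by 0.35 · log(1 + events).
3. **Items.** Item propensity = scale trait + N(0, 0.60²) noise; the Likert
   score counts how many of the item's four ordered cutpoints lie below the
   propensity, a graded-threshold (ordinal) response model.
4. **Truth mixture.** An endorsement is a *true* symptom when the propensity
   also clears the item's clinical threshold (≥ the score-2 cutpoint);
   otherwise it is a false-positive endorsement — the construct the checks
   target.
5. **Checks.** Presented only for endorsed items; answered "yes" with
   probability 0.95 for true symptoms and 0.15 for false positives,
   independently across items given truth. The non-retained trial variants
   carry their own false-positive pass rates (≈ 0.33 for numbing check 2,
   ≈ 0.41 for cut-off check 1), which makes the retained variants the more
   stringent ones, as observed.

Cutpoints and clinical thresholds are not free-floating: they are solved in
closed form from target marginal rates. The score-2 cutpoint of item *j* is
the (1 − p_j)-quantile of the propensity distribution, with p_j the study's
ungated endorsement rate; the clinical threshold is the quantile at which
the expected gated rate, pass_true·P(true) + pass_false·P(false positive),
equals the study's gated rate. The per-item impairment targets (0.162/0.107
PTSD, 0.173/0.115 DSO) were calibrated once by simulation so the
any-of-three unions reproduce the published block rates (27.4% → 19.7%,
28.9% → 20.9%). ρ and the item noise SD were likewise fixed once so joint
outcomes land near the published marginals: at n = 10,000 the defaults give
ungated CPTSD prevalence ≈ 11%, either-disorder ≈ 18% falling ≈ 40% under
gating. Explicit `item_thresholds` / `clinical_threshold_overrides` fields
exist so experiments can vary pass probabilities with the generative truth
structure held fixed.

What the generator deliberately does not model: per-event exposure
frequencies (study-specific marginals, not model content), a shared
careless-responder factor behind check failures (not identifiable from the
published data; check answers are conditionally independent given truth),
item-specific trait loadings, and demographic structure. Consequently,
passing calibration tests shows the pipeline is correct under *one*
admissible data-generating mechanism consistent with the published
marginals — the truth-mixture interpretation of check failures is an
assumption, since the source study could not ask respondents why they
answered "no" — and does not validate that mechanism against real
respondents. The joint disorder-level structure is close to, but not
exactly, the published one (simulated either-disorder prevalence runs
~3 points above the printed 14.9%), which is why simulation checks use
calibration bands rather than exact targets.

## Numerical and reporting choices

* Problem sizes: property and calibration tests run at n = 2,000–20,000;
  law-of-large-numbers exposure checks at n = 100,000 (tolerances 0.005 on
  the exposed fraction, 0.05 on the mean). Parameter recovery uses 3
  binomial standard errors at n = 20,000.
* Determinism: one `numpy` Generator seeded from `CohortParams.seed` drives
  the whole cohort; a fixed seed reproduces the cohort file byte for byte.
  Hypothesis property tests are derandomised.
* Degenerate inputs raise typed errors rather than returning sentinels: zero
  base rate (decrease), no discordant pairs (McNemar), zero total variance
  (alpha), empty truth strata (recovery), empty cohorts (report).
* The verify harness treats printed tables as input data and recomputes
  derived cells; rows whose predicate is not monotone (the PTSD label) have
  an unrecoverable discordant split, so their Z is reported as not
  recomputable rather than approximated.
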