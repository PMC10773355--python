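# Methods

This note records the model's assumptions, the conventions the package
adopts where the underlying study design left choices open, and what the
synthetic-data machinery does and does not establish.

## Model structure and horizon

Five states: no abuse; abuse not identified; abuse identified and seeing
an advocate; abuse identified, not seeing an advocate; dead. Six-month
cycles match the duration of advocacy support. Transitions between the two
identified states are forbidden (support is offered at referral and not
re-offered within a cycle); death is absorbing; transition probabilities
are constant over time. The cohort is deterministic: expected occupancies
are propagated by matrix multiplication and fractional persons are carried
exactly, rounded only for display.

**Cycle convention.** The model uses 20 cycle points over the 10-year
horizon, with the *first* point holding the initial distribution — i.e.
19 transitions — and accrues costs and QALYs at every point, the first
undiscounted and point k discounted by (1.035)^−(k−1)/2. No half-cycle
correction is applied. This "state at period start" convention is the one
under which the package's deterministic results line up with the reference
results this model re-implements (final-cycle not-abused occupancy within
a handful of persons, arm totals within 0.2%); the alternative convention
(20 transitions after the initial distribution) shifts final occupancy by
roughly 40 persons and both arms' totals by under 1%, without changing any
qualitative conclusion.

**Stay probabilities.** Each diagonal entry is computed as one minus the
row's exit probabilities, which keeps every row exactly stochastic. For
the unidentified state this yields stays of 0.8759 (intervention) and
0.9128 (control); the corresponding published complements (0.8762/0.9131)
are consistent only with the identified-state death rate 0.0052 rather
than the unidentified row's own 0.0055, so the recomputed values are used.

**Initial distribution.** Prevalence 5.5% of the cohort starts in the
abuse states, split 0.003 / 0.033 / 0.964 (complement) between seeing
advocate / not seeing / unidentified; 94.5% starts in no abuse.

## Calibration

Abuse incidence (no abuse → unidentified, base 0.0037) and remission
(unidentified → no abuse, base 0.0500) are unobservable in routine data
and are pinned to a long-run prevalence target. Because death is
absorbing, "occupancy becomes constant after 3000 cycles" is only coherent
on the death-conditioned chain, so calibration removes the dead state and
renormalizes rows before iterating. The problem is underdetermined (one
target, two unknowns); by default remission is held at its published value
and incidence is solved by bisection (the share is strictly monotone in
each probability) to |share − target| < 1e-6. Calibration uses the control
arm's identification probabilities, since the target describes
pre-intervention natural history. Both targets are supported: a 94.5%
no-abuse share (5.5% general-population prevalence) and 83% (the 17%
prevalence reported among GP attenders). Power iteration is verified
against the dominant-eigenvector stationary distribution in the tests.

## Costs and QALYs

Societal perspective, 2019/20 GBP. Three cost streams, each reported
separately and summing exactly to the total:

* **abuse cost**: £4276 per abuse-state occupant per cycle — the weighted
  average 0.8 × £4858 (adults) + 0.2 × £1950 (children). The £4858 figure
  already excludes monetised QALY harms to avoid double counting. The
  child figure is the 2018 value; using the inflated £1969 variant (a
  config switch) gives £4280.2 instead. Occupants of the identified states
  carry multipliers (base 1.0, limits 0.75–1.25 and 0.9–1.1).
* **programme cost**: £0.75 per exposed (abuse-state) patient per cycle,
  intervention arm only — the £60 253 delivery budget spread over the
  79 485 exposed registered patients. Usual care is the comparator
  baseline and carries no programme cost.
* **onward referral**: £658 once per entry into the seeing-advocate state
  (57 advocate-hours × £29.60/h × 39% acceptance), charged in both arms
  (the referral service exists in both), including the initial occupants
  of the identified states at the first cycle.

QALYs use the area-under-the-curve approach: 0.5 years × occupancy ×
population-weighted utility per cycle point, with the dead state at zero.
Subgroup weights default to 20% children and a near-equal 40/40 adult
split (the adult sex split is not published; it is a config field).
'Abuse not identified' carries the same utility as 'identified, not
seeing advocate' — identification alone is assumed not to change quality
of life — and this tie is enforced at validation and preserved in
sampling.

## Distribution fitting

Published tables give a base value, 95% limits and a family per
parameter. Fits are moment-matched with mean = base and
sd = (upper − lower)/3.92, treating the limits as a symmetric normal 95%
interval: Beta for probabilities/utilities, Gamma for costs, Uniform for
the starting split (sampled over its printed limits, so its mean is the
midpoint rather than the off-centre base), and Dirichlet for whole
transition rows, with the concentration moment-matched from the first
non-complement entry's limits (s = m(1−m)/v − 1). Zero-width intervals
produce point masses; a Beta whose implied variance reaches m(1−m) is
rejected as infeasible. Asymmetric intervals still use the base as the
mean, since the base is the point estimate.

## Probabilistic sensitivity analysis

1000 draws by default; per draw both arms are rerun deterministically.
Transition rows are sampled through the gamma representation of the
Dirichlet (independent Gamma(αᵢ) variates normalized to one), so draws
are exact probability vectors and no redraws are needed.

**Correlation across arms.** Background mortality, the recovery rows,
prevalence, the starting split, utilities and costs describe common
biology and economics and are drawn once per draw, shared by both arms;
the arm-specific identification probabilities are always independent. The
calibrated incidence/remission pair is drawn *independently per arm* by
default (`correlation="independent"`): it is fixed by calibration rather
than by either arm's data, the two arms are distinct practice
populations, and this pair dominates the incremental uncertainty. Under
the fully shared alternative (`correlation="shared"`) incremental
uncertainty collapses — the probability of cost-effectiveness at
£20 000/QALY rises from roughly 0.5 to 0.8 — because both arms then ride
the same natural-history draw. Sharing mortality is not optional: drawing
it independently produces survival differences that compound over the
horizon into incremental-QALY spreads an order of magnitude beyond
anything the identification mechanism could generate.

The model consumes the weighted abuse cost, which is sampled directly
from its own printed limits; the adult/child component costs enter only
through that weighted figure. Quantiles are linear-interpolation
percentiles. Each draw i under seed s uses the dedicated bit stream
`default_rng([s, i])`, so runs are bit-reproducible and extending the
draw count leaves earlier draws unchanged; within a draw the sampling
order is fixed (prevalence, split, recovery rows, utilities, costs, death
variates, natural-history and identification variates, intervention arm
first). The CEAC counts draws with strictly positive NMB on a £0–£50 000
grid in £500 steps.

## Synthetic pilot data

`synthetic_pilot` emulates the primary data the model's inputs derive
from: six-month identification counts drawn Binomial(eligible, p) out of
the registered populations (99 337 all-ages patients in the intervention
practices; 39 382 women 16+ in the comparison practices, reflecting that
usual care serves women only), onward referrals Binomial(accepting, 0.39),
and utility forms drawn Beta around the true state utilities with an
effective sample size of 35 — chosen so the simulated form-level spread
matches the published interval widths at the pilot's sample sizes. The
published report does not give the pilot numerators or the subgroup split
of the ~30 baseline / ~16 follow-up forms; numerators are implied by the
published probabilities times the denominators, and the default form
split (16/6/8 baseline, 8/3/5 follow-up across women/men/children) is
this package's choice.

Estimation inverts generation: count/eligible with Wilson-score
intervals; baseline utility means feed 'identified, not seeing advocate'
(copied to 'unidentified'), follow-up means feed 'seeing advocate', with
normal-approximation intervals. The recovery study shows
identification-probability bias below 1e-4 with near-nominal Wilson
coverage, and utility means that are unbiased but carry wide intervals at
n ≈ 16 — the synthetic loop reproduces the *structure* of the pilot's
uncertainty. It does not reproduce real-data features such as non-response
bias, clustering by practice, repeat identification or measurement error
in the preference-mapping step, so passing recovery tests validates the
estimators, not the pilot's representativeness.

## Numerical choices and problem sizes

Cohort 10 000; 20 cycle points; calibration over 3000 alive-conditioned
cycles with share tolerance 1e-6; PSA 1000 draws; the agent-based
validation oracle uses 10⁵ agents compared within three binomial standard
errors; the recovery study uses 500 replicates. Row-stochasticity is
enforced to 1e-9, cohort conservation to 1e-6 persons, and the NMB
identity to 1e-9. Ties: a draw is "cost-effective" only at strictly
positive NMB; zero QALY difference leaves the ICER undefined and the
verdict is decided by the cost sign.

## Known limitations

* Constant transition probabilities and a 10-year horizon understate
  benefits for children, for whom effects plausibly persist longer.
* No half-cycle correction; with six-month cycles the discretisation
  error is small relative to parameter uncertainty.
* The PSA's arm-correlation policy is a modelling judgement (documented
  above and switchable); no empirical correlation structure is available.
* Whether the control arm incurs onward-referral costs, and whether the
  programme cost applies to the whole registered population rather than
  exposed patients, are not documented in the source material; both
  defaults (charged in both arms; exposed patients only) are deliberate
  and the amounts involved are too small to affect the verdict.
* Utilities enter as numbers; the survey-to-utility mapping algorithms
  (SF-12→SF-6D, CHU-9D) are out of scope.
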