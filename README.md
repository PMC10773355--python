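# dva-cea

A Markov cohort cost–utility model comparing two primary-care responses to
domestic violence and abuse (DVA): an enhanced identification-and-referral
programme that serves women, men and children (IRIS+), against usual care —
the established women-only IRIS programme. The package is aimed at health
economists and modellers who want a tested, configurable, fully scriptable
implementation of this class of decision model: deterministic base case,
steady-state calibration, societal costing, probabilistic sensitivity
analysis and a synthetic-pilot parameter-recovery harness.

## The model

A closed cohort of N = 10 000 registered patients moves between five health
states in six-month cycles over a 10-year horizon (20 cycles, the first
holding the initial distribution):

```
no abuse  ⇄  abuse, not identified  →  abuse identified, seeing advocate
                                   →  abuse identified, not seeing advocate
(every state)  →  dead                (identified states → no abuse)
```

Movement between the two identified states is forbidden (advocacy is
offered once, at referral), and death is absorbing. Each arm has its own
identification probabilities; everything else is common. With transition
matrix **P** and occupancy row **x**ₖ, the engine iterates
**x**ₖ = **x**ₖ₋₁**P**, carrying fractional persons exactly.

Per cycle k the model accrues, discounted at annual rate r = 3.5% with
factor (1+r)^−(k−1)/2:

* **QALYs** (area under the curve): occupancy × population-weighted
  utility × 0.5 years, with weights 20% children / 40% women / 40% men;
* **costs** (societal): the weighted six-month cost of abuse exposure
  (£4276 = 0.8×£4858 adults + 0.2×£1950 children) on abuse-state
  occupants, the programme cost (£0.75 per exposed patient per cycle,
  intervention arm), and a one-off £658 onward-referral cost
  (57 h × £29.60/h × 39% acceptance) per entry into advocacy.

Results are summarised as incremental cost ΔC, incremental QALYs ΔE, the
ICER ΔC/ΔE (or a dominance verdict), and net monetary benefit
NMB = λ·ΔE − ΔC at λ = £20 000/QALY. The PSA samples every parameter from
Beta/Gamma/Dirichlet/Uniform distributions moment-matched to published
base values and 95% limits, reruns both arms per draw, and reports the
cost-effectiveness plane, percentile intervals and the CEAC.

The unobserved abuse incidence and remission probabilities are fixed by
calibration: the death-conditioned chain is iterated 3000 cycles and one
of the pair is solved by bisection until the long-run 'no abuse' share
matches a prevalence target (94.5%, or 83% for the GP-attender variant).

## Worked example

```python
from dva_cea import default_parameters, run_base_case
print(run_base_case(default_parameters()).format_table())
```

prints

```
                                 Costs     QALYs
Intervention (IRIS+)             £3861     7.002
Control (IRIS, usual care)       £3963     7.000
Difference                       £-102     0.003
Verdict: dominant (ICER £-37314/QALY)
Incremental NMB at £20000/QALY: £157
```

Per patient over ten years the enhanced programme costs £102 less and
gains 0.003 QALYs, so it *dominates* usual care: the extra referrals move
more people out of abuse (8575 vs 8544 of 10 000 not abused at the final
cycle), avoiding abuse-related societal costs that far exceed the
programme's own cost. The positive NMB says the same thing in money terms.
Uncertainty around this verdict is substantial — run
`examples/sensitivity_analysis.py` to see that the probability of
cost-effectiveness at £20 000/QALY is only slightly above one half.

The `examples/` directory holds one short script per capability
(`base_case.py`, `calibration_targets.py`, `sensitivity_analysis.py`,
`pilot_recovery.py`), and the same functionality is exposed as a thin CLI:

```bash
dva-cea report
dva-cea run --out results
dva-cea calibrate --target-prevalence 0.055 --fix exit
dva-cea psa --draws 1000 --seed 1 --out results/psa
dva-cea synth --seed 1 --out pilot
```

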