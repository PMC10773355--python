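"""Probabilistic sensitivity analysis: 1000 draws, CEAC and intervals.

Samples all model parameters from their fitted distributions, reruns both
arms per draw, and summarises the uncertainty. The CEAC value at £20 000
per QALY is the probability the enhanced programme is cost-effective at
the UK's conventional threshold; values just above one half mean the
decision is genuinely uncertain.
"""

from dva_cea import default_parameters, make_figures, run_psa

params = default_parameters()
psa = run_psa(params, n_draws=1000, seed=1)

print(f"draws: {psa.n_draws}, seed: {psa.seed}")
print(f"mean incremental cost:  £{psa.delta_cost.mean():.0f}")
print(f"mean incremental QALYs: {psa.delta_qalys.mean():.4f}")
lo, hi = psa.intervals["delta_cost"]
print(f"95% interval, incremental cost:  £{lo:.0f} to £{hi:.0f}")
lo, hi = psa.intervals["delta_qalys"]
print(f"95% interval, incremental QALYs: {lo:.3f} to {hi:.3f}")
print(f"probability cost-effective at £20 000/QALY: {psa.ceac_at(20000):.2f}")
print(f"probability cost-saving (CEAC at £0):       {psa.ceac_at(0):.2f}")

paths = psa.write("results/psa")
paths += make_figures("results/psa")
print("wrote:", ", ".join(str(p) for p in paths))
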