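"""Base-case cost-effectiveness analysis: olaparib maintenance vs placebo.

Loads the packaged configuration (fitted Weibull survival parameters and
all cost/utility inputs), runs the three-state cohort model over 120
monthly cycles for both arms, and prints discounted costs, QALYs, and the
incremental cost-effectiveness ratio (ICER).
"""

from olacea import icer, load_config, run_strategies

config, inputs, arms, wtp = load_config()
results = run_strategies(arms, inputs, config)

for name, res in results.items():
    print(f"{name:9s} cost ${res.cost_total:>10,.2f}  "
          f"(PFS ${res.cost_pfs:,.2f} + PD ${res.cost_pd:,.2f})")
    print(f"{'':9s} QALYs {res.qaly_total:>8.3f}  "
          f"(PFS {res.qaly_pfs:.3f} + PD {res.qaly_pd:.3f})")

inc = icer(results["olaparib"], results["placebo"])
print(f"\nincremental cost  ${inc.delta_cost:,.2f}")
print(f"incremental QALYs  {inc.delta_qaly:.3f}")
print(f"ICER              ${inc.icer:,.2f}/QALY  (WTP threshold ${wtp:,.2f})")

# The ICER is the extra spend per quality-adjusted life-year gained by
# maintenance therapy; above the willingness-to-pay threshold it is not
# considered cost-effective at the base price.
verdict = "cost-effective" if inc.icer <= wtp else "NOT cost-effective"
print(f"=> olaparib is {verdict} at this threshold")
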