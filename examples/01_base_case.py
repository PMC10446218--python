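"""Base-case cost-effectiveness of the bundled reference scenario.

Runs both treatment arms of the third-line HER2+ metastatic breast cancer
comparison (neratinib+capecitabine vs lapatinib+capecitabine) through the
half-cycle-corrected Markov cohort model over a 5-year horizon, and prints
discounted totals, increments, ICER and net monetary benefit.
"""

import markovcea as mc

strategies, settings = mc.reference_scenario("whole_group")
results = [mc.run_strategy(s, settings) for s in strategies]
ce = mc.compare(results[0], results[1], settings)

for r in results:
    print(f"{r.strategy.name:28s} cost ${r.total_cost:9,.2f}   "
          f"QALYs {r.total_qaly:.3f}   dead at horizon {r.trace.death_fraction:.1%}")
print(f"\nincremental cost  ${ce.delta_cost:,.2f}")
print(f"incremental QALYs {ce.delta_qaly:.3f}")
print(f"ICER              ${ce.icer:,.2f}/QALY ({ce.icer_tag})")
print(f"NMB at ${ce.wtp:,.0f}/QALY: {ce.nmb_a:,.2f} vs {ce.nmb_b:,.2f}")
print(f"decision tier     {ce.decision.value}")
print("\nA positive ICER above the 3x-GDP willingness-to-pay threshold means "
      "the extra QALYs of the first arm are bought at a price the threshold "
      "does not justify under these cost assumptions.")
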