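"""Derive the per-cycle transition probabilities from median survival.

The DEALE conversion turns median OS, PFS and DoR into constant-hazard
per-cycle probabilities; in the published three-decimal rounding mode the
table below reproduces the source analysis exactly.
"""

import markovcea as mc
from markovcea.reporting import transition_table

strategies, settings = mc.reference_scenario("whole_group")
matrices = {
    s.name: mc.build_matrix(s.clinical, "published_3dp") for s in strategies
}
print(transition_table(matrices).to_string(index=False))
print("\nEach row names the formula behind the probability; self-transitions "
      "are complements of the row's outflows and death is absorbing.")
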