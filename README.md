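# markovcea

Markov cohort cost-effectiveness analysis of third-line treatment for
HER2-positive metastatic breast cancer: neratinib + capecitabine (N+C)
versus lapatinib + capecitabine (L+C), from a payer perspective.

The package is aimed at health economists and methodologists who want a
transparent, scriptable re-implementation of a published
decision-analytic model — every input is a printed clinical or price
datum, every output is recomputed from those inputs, and every modelling
assumption is explicit configuration.

## The model

A four-state cohort model — stable disease (SD), remission (RE),
progressive disease (PD), death (DE, absorbing) — with 21-day cycles, a
5-year horizon, half-cycle correction and 3% annual discounting.
Per-cycle transition probabilities come from median survival summaries by
the DEALE (declining-exponential) conversion, e.g.

```
p(SD→RE) = 1 − exp(−RR/3),          RR = (OS − PFS)/OS
p(RE→PD) = 1 − exp(−0.75·ln2/DoR)
p(PD→DE) = 1 − exp(−0.75·ln2/(OS − PFS))
p(SD→PD) = 4 · p(RE→PD)
```

Economics: ICER = ΔC/ΔE, NMB = λ·E − C at willingness-to-pay
λ = $36,000/QALY (3× Chinese per-capita GDP), with the GDP-band decision
tiers. Uncertainty: one-way deterministic sensitivity analysis (tornado)
and second-order Monte-Carlo probabilistic sensitivity analysis with
beta/gamma parameter distributions, CE-plane summaries and
cost-effectiveness acceptability curves. A seeded generator produces
random but structurally valid scenarios for testing. See
[docs/methods.md](docs/methods.md) for the full account.

## Worked example

```python
import markovcea as mc

strategies, settings = mc.reference_scenario("whole_group")
results = [mc.run_strategy(s, settings) for s in strategies]
ce = mc.compare(results[0], results[1], settings)
```

Running `python examples/01_base_case.py` (the same computation) prints:

```
neratinib+capecitabine       cost $30,177.88   QALYs 1.169   dead at horizon 91.5%
lapatinib+capecitabine       cost $22,260.08   QALYs 1.027   dead at horizon 92.8%

incremental cost  $7,917.81
incremental QALYs 0.142
ICER              $55,813.86/QALY (more_costly_more_effective)
NMB at $36,000/QALY: 11,904.65 vs 14,715.46
decision tier     not_worthwhile
```

N+C's stronger transition structure buys 0.142 extra QALYs, but because
drug cost is derived from unit prices and accrues while on treatment, the
longer pre-progression survival also makes N+C dearer — the ICER lands
above the $36,000/QALY threshold under the default accrual assumptions.
The published summary of this comparison reports N+C as cost-saving; its
aggregate cost figures are not derivable from its printed unit inputs,
and the package's reports show both sets of numbers side by side rather
than forcing agreement (see docs/methods.md, "Accrual conventions").

Other examples: `02_transition_table.py` (the per-cycle probability table
with formula provenance — in `published_3dp` rounding it reproduces the
source's three-decimal table exactly), `03_tornado.py`, `04_psa_ceac.py`,
`05_synthetic_scenarios.py`.

A thin CLI wraps the same library:

```
markovcea run  --scenario whole_group --outdir out/base
markovcea dsa  --scenario whole_group --outdir out/dsa --plots
markovcea psa  --scenario whole_group --n 1000 --seed 1 --outdir out/psa --plots
markovcea generate --seed 7 --n 5 --outdir out/synthetic
```

Every run writes a `manifest.json` (config hash, seed, version) so
deterministic outputs reproduce bit-identically.

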