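# fireclass

Quantitative classification of evoked neuronal firing patterns.

Electrophysiologists characterize neuron types by how they fire during
supra-threshold step-current injections: some cells spike steadily, others
adapt, stutter, burst on slow depolarizing waves, start after a long
latency, or fall silent before the pulse ends.  `fireclass` turns that
qualitative vocabulary into reproducible calls.  It takes per-trace spike
times (or digitized inter-spike-interval exports) and emits a firing
pattern in dot notation — e.g. `D.NASP`, `ASP.SLN`, `TSTUT.NASP`, `PSTUT` —
built from five transient elements (D., ASP., RASP., TSTUT., TSWB.) and
four steady states (NASP, SLN, PSTUT, PSWB).  On top of per-trace calls it
aggregates per-type phenotypes, clusters them into firing-pattern families,
and screens associations between firing-pattern elements and other
categorical neuron properties.

It is written for electrophysiology informatics: curators of neuron-type
knowledge bases, modelers validating simulated spike trains, and anyone who
needs firing-pattern labels that are criteria-driven rather than eyeballed.

## The method

For a train with first-spike latency *Delay*, inter-spike intervals
ISI₁…ISIₙ, and post-firing silence *PFS* (stimulus offset minus last
spike):

- **Delay (D.)** — `Delay > DF·(ISI₁+ISI₂)/2`, DF = 2.
- **Silence (SLN)** — `PFS > SF·(ISIₙ+ISIₙ₋₁)/2` and `PFS > SF·ISI_max`,
  SF = 2.
- **Transient stutter/burst (TSTUT./TSWB.)** — a break ISI at position
  i ∈ {2,3,4} with `ISIᵢ > F_pre·ISIᵢ₋₁`, `ISIᵢ > F_post·ISIᵢ₊₁`,
  `mean(ISIᵢ…ISIₙ) > F_pre·mean(ISI₁…ISIᵢ₋₁)`, and every pre-break ISI
  firing above f_min = 25 Hz (F_pre = 2.5, F_post = 1.5).  TSWB. when the
  slow-wave amplitude SWA > 5 mV, else TSTUT.
- **Persistent stutter/burst (PSTUT/PSWB)** —
  `ISI_max/ISI_prev + ISI_max/ISI_next > 5`, with the SWA rule deciding
  burst vs stutter.
- **Adaptation** — ISIs normalized to ISI_min are regressed on normalized
  time through four nested models (constant; line; continuous
  line-then-plateau; continuous two-segment line).  Extra-sum-of-squares
  F-tests at Bonferroni-corrected levels 0.05, 0.025, 0.05/3 select the
  model; slopes map to NASP / ASP. / ASP.NASP / ASP.ASP. / ACSP., with a
  minimum slope of 0.003 guarding against vanishing trends.  Rapid
  adaptation (RASP.) is a per-interval relative slope > 0.2 over the first
  2–3 ISIs.

Phenotypes (the set of patterns a type shows) are weighted by element
rarity, `W_e = (N − n_e)/N`, and clustered by a two-step-style procedure
(log-likelihood distance, BIC-guided leaf count, silhouette diagnostics).
Element-property association screening uses Barnard's unconditional exact
test on 2×2 tables (eligibility: total > 9, element observed > 3 times),
significance at p < 0.05 with Benjamini–Hochberg FDR < 0.25.

## Worked example

```python
import numpy as np
from fireclass import SpikeTrain, classify_trace, format_pattern

# 11 spikes: 100 ms latency, then ten constant 20-ms intervals
spikes = 100 + np.cumsum([0.0] + [20.0] * 10)
train = SpikeTrain(trace_id="demo", neuron_type="DG Basket",
                   spike_times=spikes, stim_duration=330.0,
                   stim_amplitude=200.0)
pat = classify_trace(train)
print(format_pattern(pat), pat.completed)
print({k: round(v, 4) for k, v in pat.diagnostics.items()
       if k in ("p_21", "a1")})
```

prints

```
D.NASP True
{'a1': 0.0, 'p_21': 1.0}
```

The 100-ms latency exceeds twice the mean of the first two intervals
(40 ms), so the response is delayed; the constant-rate fit is not improved
by a sloped line (p₂,₁ = 1), so the steady state is non-adapting spiking:
`D.NASP`, a completed pattern.

The same pipeline runs from the shell:

```bash
fireclass simulate --pattern all --n 5 --cv 0.05 --seed 7 --out synth.csv
fireclass classify --in synth.csv --out patterns.csv
fireclass assoc --elements elements.csv --properties props.csv --out assoc.csv
```

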