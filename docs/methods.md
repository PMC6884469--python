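# Methods

## Scope and data model

`fireclass` classifies evoked spiking responses to depolarizing
step-current pulses.  The unit of analysis is a trace: spike times in ms
relative to stimulus onset, the stimulus epoch (duration, amplitude), and
optionally either membrane-voltage samples or a pre-measured slow-wave
amplitude (SWA).  From a trace we derive the interval representation used
by every criterion: first-spike latency (*delay*), the ISI sequence,
post-firing silence (*PFS* = stimulus offset − last spike), and normalized
coordinates — each ISI divided by the shortest ISI of the train
(`norm_isis`, minimum exactly 1) against normalized time.  Spike detection
from raw voltage is out of scope: spike times are inputs.

Units are fixed at ms, mV, pA.  Traces whose pulse is cut off by the
recording window can be flagged `truncated`; their silence is censored, so
the SLN criterion reports "not evaluable" rather than a boolean.  Traces
with fewer than two spikes are retained with the sentinel classification
`UNCLASSIFIED(insufficient_spikes)`.

### Normalized-time convention

ISI_k is plotted at the time of the spike that *ends* it, rescaled so the
first spike maps to 0 and the last to 1.  The end-spike choice is the
natural reading of "the interval is known once its closing spike occurs";
it is a documented convention rather than a mathematical necessity, and
simulations at CV = 0.1 interval noise show the abscissa convention
(end-spike, midpoint, or fixed grid) does not materially change the
regression test level (all ≈ 5%).

## Threshold criteria

All inequalities are strict; values landing exactly on a threshold do not
qualify.  Ratio-based criteria are invariant under a common rescaling of
all times; the only absolute threshold is the minimum intra-cluster rate.

| parameter | meaning | default |
|---|---|---|
| DF | delay factor: latency vs mean of first two ISIs | 2 |
| SF | silence factor: PFS vs last-ISI mean and max ISI | 2 |
| F_pre, F_post | break-ISI dominance over its neighbours | 2.5, 1.5 |
| f_min | minimum intra-cluster firing rate | 25 Hz |
| F_PSTUT, F_PSWB | persistent-gap ratio-sum threshold | 5 |
| SWA_min | slow-wave amplitude separating burst from stutter | 5 mV |
| S_RASP | rapid-adaptation slope threshold | 0.2 |
| a1_min | minimum adaptation slope | 0.003 |
| α | base significance of the regression ladder | 0.05 |
| dV/dt thresholds | slow-wave initiation / spike threshold | 0.15, 20 V/s |

Notes on readings that the criteria table leaves ambiguous:

- The transient-break running-mean inequality is implemented as
  `mean(ISI_i..ISI_n) > F_pre · mean(ISI_1..ISI_{i-1})` — the break ISI
  opens the "other distinctive activity" that follows the cluster.
- The minimum-rate clause applies to all pre-break ISIs.
- When several break indices qualify, the smallest wins: transients
  precede steady states.
- A maximum ISI in first or last position has an undefined neighbour and
  cannot qualify as a persistent gap (no padding).
- By default f_min is not enforced on persistent-stutter clusters (the
  criteria table lists it under the transient form only); the
  `enforce_fmin_for_pstut` switch turns it on.
- Unknown SWA resolves burst-vs-stutter to stutter and is logged.

### Slow-wave amplitude measurement

SWA = V(first sample with dV/dt ≥ 20 V/s) − V(first preceding sample with
dV/dt ≥ 0.15 V/s), i.e. the spike threshold on top of the wave minus the
wave's initiation threshold.  With ms/mV axes the finite-difference slope
in mV/ms is numerically V/s.  A trace with an instantaneous upstroke and
no slow phase yields SWA = 0 and a "degenerate" warning; absent crossings
yield "unknown".

## Adaptation regression ladder

Normalized ISIs are regressed on normalized time through four nested
models: M1 constant (1 parameter), M2 line (2), M3 continuous
line-then-plateau (3: slope, intercept, breakpoint — the plateau level is
fixed by continuity), M4 continuous two-segment line (4).  Breakpoints are
found by exhaustive search over interior data abscissae: deterministic,
reproducible, and exact for the model class; continuity is enforced.

Model comparisons use extra-sum-of-squares F-tests with one extra
parameter per step and residual degrees of freedom n − p of the larger
model.  Thresholds follow a Bonferroni sequence: 0.05 (M2 vs M1), 0.025
(M3 vs M2), 0.05/3 ≈ 0.0167 (M4 vs M3).  The third threshold is stored in
the configuration (`p43_threshold`) so the truncated value 0.016 that some
write-ups quote can be restored exactly.

Labels: NASP when the line is not significant or |a₁| ≤ 0.003; ACSP. when
significant with a₁ < −0.003 (the negative-slope guard mirrors the
weak-adaptation guard); otherwise ASP.-family — ASP.NASP when the plateau
model wins, ASP.ASP. when the two-line model additionally wins with second
slope > 0.003, plain (uncompleted) ASP. otherwise.

Minimum data: 3 points to fit at all; the M2 comparison needs 4, M3 needs
5, M4 needs 6 — skipped comparisons report p = 1 and inherit the simpler
model's SSE.  Because the breakpoint search is restricted to interior
abscissae, the best constrained M3 fit can in principle fail to reach the
M2 SSE; in that case the M3 (likewise M4) SSE is credited with the simpler
model's value, which zeroes the F statistic and leaves the selection
unchanged while keeping the SSE sequence monotone.

### Rapid adaptation

RASP. captures adaptation confined to the first two or three ISIs.  For
k ∈ {2, 3}: the first k+1 ISIs, normalized to their own minimum, are
regressed on the ISI index; if the slope exceeds S_RASP = 0.2 and the
remaining ISIs (from ISI_{k+1} on, renormalized as their own segment)
classify as NASP or ASP-family, the smallest such k wins and the remainder
is classified separately under a RASP. prefix.  The index abscissa makes
the slope a per-interval relative increase — rapid adaptation such as
normalized ISIs 1→3→6 scores 2.5, a gentle ramp 1→1.05→1.1 scores 0.05 —
and it is far more stable under interval noise than a slope over the tiny
normalized-time span those first intervals occupy.

## Classification pipeline

Per trace: (1) derive the ISI series; (2) search for a transient cluster
boundary; if one exists *and* the remainder beyond it still contains a
qualifying persistent gap, the response is persistent interrupted firing
(PSTUT/PSWB) — piecewise regression across stutter gaps is meaningless, so
interrupted-firing checks precede regression; (3) otherwise a boundary
contributes a TSTUT./TSWB. prefix and the remainder (the break ISI
excluded) is classified on its own; (4) RASP. prefix check; (5) regression
label; (6) terminal steady state — SLN if the silence criterion holds on
the full train, else NASP when the fit supports it, else the pattern stays
uncompleted; (7) a qualifying latency prepends D.  The result is
deterministic for fixed input and configuration.

### Pattern grammar

The completed-pattern space is generated from: eight transient chains
(ASP., RASP., TSTUT., TSWB., RASP.ASP., TSTUT.ASP., TSWB.ASP., ASP.ASP.)
ending in NASP or SLN, each with an optional D. prefix (32); bare spiking
steady states with optional delay (NASP, SLN, D.NASP, D.SLN); and the
persistent interrupted steady states standing alone (PSTUT, PSWB) — 38
patterns.  The grammar encodes the observed composition rules: the four
main transients end in NASP or SLN, ASP. may be preceded by a rapid or
stutter/burst transient, and interrupted steady states form a separate
group that takes no prefix.  The classifier itself is not constrained to
this set (it reports what the criteria produce, e.g. a delayed persistent
stutter would be emitted as `D.PSTUT`); the grammar is the canonical
enumeration used for bookkeeping.

## Phenotypes, weighting, clustering

A type's phenotype is its set of patterns across traces and conditions.
Patterns differing only by a missing steady state are collapsed before
counting (an uncompleted `ASP.` is absorbed by `ASP.NASP`/`ASP.SLN` when
present, else kept with a `*` wildcard).  Behavior complexity is assigned
from metadata: *simple* (one pattern), *multi-behavior* (same cell,
different patterns at different amplitudes, same conditions),
*subtype-split* (different cells, same conditions and amplitude band,
different patterns — one record per subtype), *condition-dependent*
(differences co-occur only with differing condition signatures, a
normalized tuple of species, method, slice orientation, pipette solution
and temperature band).  Missing metadata yields "undetermined", never a
guess.  The stimulus-amplitude band width defaults to 50 pA.

Element weights are W_e = (N − n_e)/N over the nine canonical elements
(ACSP. is defined but excluded from the canonical set, matching its
absence from observed phenotypes).  Rarer elements never weigh less.

Clustering reimplements the two-step idea with open components: identical
profiles are collapsed (pre-clustering), then agglomerated under the
log-likelihood distance for weighted binary categorical attributes (the
increase in weighted entropy cost on merging), recorded as a binary tree.
The leaf count is chosen by the BIC-change-ratio rule (categorical BIC
with one parameter per element per cluster; coarse bound at ratio < 0.04)
refined by the largest jump in merge distance, capped at `max_k`.
Silhouette uses the same distance.  Determinism: profiles are ordered by
type_id and distance ties merge the lexicographically smallest pair, so
the result is invariant to input row order.  Proprietary two-step
implementations do not publish their internals, so the comparable output
is the leaf count and membership, not tree shape.

## Association screening

Element and property matrices are indexed by type with entries
positive/negative/unknown; unknowns are excluded pairwise.  A 2×2 table is
eligible when its informative total exceeds 9 and the element is expressed
more than 3 times.  Barnard's unconditional exact test treats the
property-positive and property-negative columns as independent binomials
with a common nuisance probability π under the null; "at least as extreme"
is judged by the pooled-variance score statistic (two-sided, ties
included), and the p-value is the supremum over π, approximated by a
200-point grid with two local refinements (π resolution ~1e-6, p accurate
to well under 1e-6 against 10⁴-point-grid enumeration).  Tie inclusion
makes the p-value weakly conservative relative to implementations that
drop score-tied outcomes through floating-point rounding.  Significance
requires p < 0.05 and survival of Benjamini–Hochberg at FDR < 0.25
(delegated to statsmodels).

## Synthetic generator

The generator emulates the canonical element gallery as idealized ISI
recipes: constant trains (NASP); adaptation rising from isi1 toward
isi_inf along a slow-onset ramp `isi1 + (isi_inf − isi1)·((k−1)/(n−1))^q`
(default q = 2, isi1 = 20 ms, isi_inf = 2·isi1) with an optional plateau
(ASP.NASP); uncompleted adaptation as a ramp linear in normalized time
with a ±0.4% alternating deterministic jitter (so the plain line, not
floating-point dust, is the best-supported model); a steep 1→3→6 rise for
RASP.; short 8-ms clusters with a dominant gap for transient
stutter/burst; repeated cluster+100-ms-gap blocks for persistent forms;
SWA attached as a scalar for *SWB patterns; delays at 3×(ISI₁+ISI₂) for
D. patterns; and terminal silence at 2.5×ISI_max for SLN.  Multiplicative
Gaussian ISI noise parameterized by a coefficient of variation preserves
the scale-covariance of the criteria; all randomness flows through one
seeded generator, so output is bit-reproducible.

The slow-onset ramp is a deliberate choice: an exponential approach
concentrates its rise in the first two or three ISIs, which is exactly the
rapid-adaptation signature — generating ordinary adaptation that way would
(correctly) earn a RASP. prefix.  The ramp keeps the early intervals
nearly flat while the total rise carries the statistical weight.

What the generator does *not* emulate: spike-shape features, realistic
AHP/voltage dynamics (voltage enters only as idealized two-slope ramps or
a scalar SWA), rate drift within steady states, recording artifacts, and
digitization error of figure-extracted data.  Benchmark accuracy therefore
demonstrates that the pipeline recovers the criteria it encodes under
interval noise — not performance on raw experimental archives.

## Benchmark and calibration figures

`scripts/acceptance.py` recomputes, from scratch at the given seed: the
10-pattern noiseless benchmark confusion (exactly diagonal), accuracy at
CV = 0.05 with 200 trains per class, the ladder's null false-adapting rate
on 1,000 constant trains (20 ISIs, CV = 0.1; the residual rate is the
nominal 5% F-test level plus a small errors-in-abscissa effect, and the
0.003 slope guard), ASP power at true normalized slope 0.5, Barnard
agreement with exhaustive enumeration over all designs with group sizes
≤ 6, the Barnard null rejection rate (n = 40), planted-association
recovery in a 40-type × 21-property screen, 4-archetype clustering
recovery (leaf count, silhouette, adjusted Rand), and the 38-pattern
grammar size.  Problem sizes mirror the test suite; the whole script runs
in seconds on one CPU.

## Known limitations

- The regression ladder assumes homoscedastic Gaussian residuals in
  normalized coordinates; no robust or information-criterion variants.
- Persistent-vs-transient interrupted precedence relies on a second
  qualifying gap in the post-break remainder; two-cluster responses are
  deliberately transient.
- Condition-dependence reproduces expert curation only insofar as the same
  condition metadata is supplied.
- Barnard's test is the score-statistic (CSM-score) variant; mid-p and
  fully recursive CSM variants are out of scope.
- Responses to hyperpolarizing current (rebound spiking) are not
  classified.
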