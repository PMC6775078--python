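# Methods

## Model

`refutesim` simulates emotional contagion in a closed, mixed population of
`N` agents during a rumor-refutation episode. It is an SIR-variant
compartment model in which the transmitted quantity is a continuous emotion
value `E ∈ [0, 1]` rather than a binary infection state. The unit interval
is partitioned into three bands — negative `[0, 0.33]`, immune/neutral
`(0.33, 0.66]`, positive `(0.66, 1.00]`; boundary values belong to the
lower band, with no epsilon fuzzing — and the three roles are tied to the
bands through threshold crossings:

* **Spreader (s)**: actively transmits its own emotion; unaffected by
  receivers; retires to the infected compartment after
  `spreader_active_days` days of activity.
* **Infected (r)**: emotion altered by contact; also transmits.
* **Immunized (m)**: disengaged; re-activates spontaneously to s or r with
  daily probabilities `f_s`, `f_r` (`f_s + f_r ≤ 1`, so the expected number
  of activations never exceeds the compartment).

A contact from an active agent (s or r) to a receiver transmits with
probability `R_sr = w·b·a·v`: the receiver's expression ability `w` and
spreading willingness `b`, and the exogenous refutation context —
credibility `a` and speed `v` of the refuting authority. A contact whose
`R_sr` falls below the contagion threshold `λ` never transmits. The
receiver update is

    E_recv ← clamp( d·E_recv + (E_src − E_recv)·R_sr ),

with `d` the receiver's subjective-judgment firmness. Every updated emotion
is clamped to `[0, 1]` so the stated range invariant holds even where the
raw arithmetic could leave it. Same-role pairs (s–s, r–r) update both
members simultaneously from their pre-contact values; the sign of the
difference term is a configuration flag:

* `convergent` (default): `(other − self)·R` — the same direction as the
  cross-role rule; each encounter contracts the pair's gap.
* `as_printed`: `(self − other)·R` — the divergent form; each encounter
  widens the gap until clamping.

Both variants are implemented and tested. The convergent form is the
package default because the divergent one makes same-role encounters
repulsive around the band boundaries: infected agents near 0.66 are
perpetually pushed back into the immune band and re-converted, so the
compartment counts churn indefinitely and the model never reaches the
stable late-phase distribution that is its central qualitative behaviour.

After the day's contacts, band transitions are applied to every contacted
agent: an m whose updated emotion left the immune band becomes r (infected
to a positive or negative state); an s or r whose emotion entered the
immune band becomes m. Then the remaining m agents draw their spontaneous
activations, spreaders age, and expired spreaders retire to r. Both
partitions of `N` (roles and emotion bands) are verified every day.

## Scheduling

Days are discrete and synchronous at the population level. Within a day,
every agent samples up to `contacts_per_agent_per_day` distinct network
neighbours; the merged, deduplicated pair list is executed in a uniformly
random order, each contact as a full pairwise event on the current emotion
values, with roles frozen at their day-start values. This is the
random-order event schedule of NetLogo-style agent models.

Two simpler within-day schemes were evaluated and rejected. Averaging an
agent's candidate updates dilutes a spreader's influence by the receiver's
total contact count, so a high-credibility refutation can never produce the
fast (2–3 day) convergence of infected emotions the model is meant to
exhibit at a 5 % spreader fraction. Summing the candidate updates instead
overshoots at high `R_sr` (total per-day gain above 1), producing
clamping-driven oscillations and outcomes non-monotone in `v·a`. The
sequential event schedule is free of both pathologies: each event is a
bounded contraction toward its source, and influence accumulates
multiplicatively (`k` events with probability `R` close `1 − (1−R)^k` of
the gap).

For speed, the shuffled event list is partitioned into maximal
vertex-disjoint rounds (a greedy matching in list order); within a round no
agent appears twice, so the vectorized round update reproduces the
sequential semantics exactly. An agent in exactly one contact receives
precisely the printed receiver equation. Uncontacted agents apply the
self-weighting `E ← d·E` once per day; with the default `d = 1` they are
exactly invariant, and with `d < 1` and no contacts every emotion follows
the closed form `d^t·E(0)` (used as an exact regression test). For agents
in several contacts, `d` is applied once per event, i.e. the firmness
weighting is part of each emotional interaction; under the default `d = 1`
this distinction is immaterial. A source's emotion is unchanged by the
agents it reaches, which under `d = 1` also keeps the spreader-invariance
property exact.

## Randomness and reproducibility

All randomness flows from a single integer seed through four named child
streams (population initialization, contact structure, daily contact
sampling, spontaneous activations), so toggling one mechanism never
perturbs the draws of another, and an identical configuration yields a
bit-identical trajectory. Experiment drivers take explicit seed lists;
every run's manifest records the configuration snapshot, seeds and output
checksums.

## Default study conditions

Defaults describe a moderately sized online crowd exposed to an effective
refutation campaign; all are overridable per run.

| Parameter | Default | Meaning / rationale |
|---|---|---|
| `N` | 1000 | population size; large enough for stable band proportions, small enough for desk-scale replication |
| topology | spatial, radius for mean degree ≈ 8 | agents uniform in the unit square; neighbours within an interaction radius (NetLogo-like interaction space); graph mode (Watts–Strogatz, Erdős–Rényi) available for sensitivity checks |
| `contacts_per_agent_per_day` | 8 | near-full neighbourhood exchange each day — heavy daily interaction during a salient public event |
| initial roles | 5 % s, 0 % r, 95 % m | the refutation starts from a small set of active spreaders; "only s carried emotions" at the start |
| initial emotions | s: positive band; m: immune band | spreaders carry the corrective (positive) message; the crowd is not yet engaged. Experiments 2 and 4 instead start the crowd majority-negative (`U(0, 0.5)`), the pre-refutation state they examine |
| `d` | 1.0 (constant) | agents firm in their own judgment — the near-1 regime the receiver equation is described in. `d < 1` (uniform ranges) is supported and tested |
| `w`, `b` | i.i.d. `U(0, 1)` | heterogeneous expressiveness and spreading willingness |
| `a`, `v` | 0.8, 0.8 | an authoritative, fast refutation (the favourable scenario) |
| `f_s`, `f_r` | 0.001/day each | rare spontaneous re-engagement; keeps the late phase quasi-stationary |
| `λ` | 0.25 | contagion threshold: links with `w·b·a·v < λ` never transmit, leaving a permanently immune remainder — without it conversions trickle indefinitely and the compartments never stabilize |
| `spreader_active_days` | 3 | spreaders burn out after three active days, matching the early-phase collapse of s |
| variant | convergent | see above |

Where the underlying study leaves a value unstated (`f_s`, `f_r`, `λ`, the
contact budget), the defaults were fixed once by requiring the default
configuration to reproduce the model's three published anchor behaviours —
stabilized infected emotion ≈ 0.81 at `(v, a) = (0.8, 0.8)` and ≈ 0.68 at
`(0.2, 0.2)`, and compartment stabilization after ≈ 4 days — and then
frozen. They are study conditions, not free dials; the acceptance checks
run against exactly these values.

## Experiment drivers

All four drivers are reproducible bit-for-bit from (config, seed list) and
report per-seed cells plus per-cell means.

**Experiment 1 — time period.** 30-day horizon; one arm per initial
spreader band (negative / immune / positive); snapshots at days 1, 3, 5, 8,
10. Stabilization of each compartment-count series is detected with a
sliding window (window 3 days, absolute tolerance 2 % of `N`): the reported
day is the earliest from which every subsequent window stays within
tolerance, maximized over the three series.

**Experiment 2 — network intimacy.** `R_sr` pinned to 0.2 / 0.5 / 0.8 for
every contact (`r_sr_override`), 10-day horizon, majority-negative crowd.
Because the level itself is the designed link strength, the driver disables
the `λ` gate and maintains the refutation source for the whole horizon.
Reported: final emotion-band proportions and count dynamics per level.

**Experiment 3 — speed × credibility.** The six combinations v1·a1, v2·a1,
v3·a1, v2·a2, v2·a3, v3·a3 with levels (0.8, 0.5, 0.2); only the two
endpoint levels are anchored externally, 0.5 is the natural midpoint and
matches Experiment 2's levels. Controlled design: `w = b = 1` so that
`R_sr = v·a` exactly (mirroring Experiment 2's pinning of `R_sr`), `λ`
gate off, refutation source maintained for the 10-day horizon — isolating
the authority's speed and credibility as the only varying factors. The
summary statistic is the *stabilized mean infected emotion*: the daily mean
emotion of r-role agents, averaged over the days after that series
stabilizes (window 3, tolerance 0.02; if it never stabilizes, the last
three days are used).

**Experiment 4 — before/after.** Majority-negative crowd, default
(effective) refutation context, 10-day horizon. Reports initial vs final
per-agent emotion distributions, band proportions, and the fraction of
final emotions in `(0.66, 0.87]`.

## Synthetic data

Two kinds of synthetic input are generated programmatically. The population
generator is the simulator's own initial condition and is governed by the
defaults above. The empirical-summary fixtures (`refutesim.fixtures`) emit
labeled-post tables whose negative share decays as a refutation episode
proceeds, media-record tables with log-normal follower counts spread over
the first event days, and a one-row sentiment-count table; they emulate the
*format and gross shape* of a scraped microblog dataset — timestamps,
three-class labels, engagement columns — but none of its real structure
(no user graph, no topic mixture, no diurnal cycle, no duplicate/spam
process). Tests passing on these fixtures therefore demonstrate the
correctness of the summary computations, not the validity of the model on
real data.

## Numerical choices and degenerate inputs

* Band boundaries are closed below (`0.33 → negative`, `0.66 → immune`),
  exactly as the bracket notation states.
* Every emotion update clamps to `[0, 1]`; the clamp is also the only
  nonlinearity in the divergent pair variant.
* `proportions_from_counts` rounds to two decimals for display; the
  unrounded values sum to 100 within 1e-9 and a zero total is a domain
  error.
* `detect_stabilization` requires `2 ≤ window ≤ len(series)`; windows
  containing NaN (e.g. days with no infected agents) never qualify.
* Zero-post days in the daily trend are emitted with count 0 and NaN
  proportions rather than being silently dropped.
* Follower-count tertiles use the empirical 1/3 and 2/3 quantiles; with
  heavy ties the lower ranks absorb the mass (deterministic, order-free).
* Isolated agents are allowed; they simply appear in no contact pair.
* Duplicate sampled contacts are merged; self-contacts are impossible by
  construction.

## Known limitations

* The contact structure is static; no rewiring or agent movement.
* Single refutation campaign, single rumor; no competing information
  sources, no directed or weighted asymmetries beyond `R_sr`.
* Time is discrete at one step per day; no event-driven (Gillespie)
  dynamics.
* The stabilized-emotion estimator and several defaults are package
  choices where the underlying study is silent (documented above); the two
  reported endpoint emotions are reproduced to within ±0.05, not exactly.
* The empirical-summary module consumes already-labeled posts; scraping,
  tokenization and sentiment scoring are out of scope.
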