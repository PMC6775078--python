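# refutesim

An agent-based simulator of how netizen emotions spread and settle while an
authority refutes an online rumor. It is aimed at researchers in
computational social science and epidemiological opinion modelling who want
a tested, reproducible implementation of a spreader/infected/immunized (SRM)
emotional-contagion model — an SIR-style compartment model in which the
"pathogen" is a continuous emotion value rather than a binary infection.

## The model

Each of `N` networked agents carries an emotion value `E ∈ [0, 1]`,
partitioned into three bands: **negative** `[0, 0.33]`, **immune/neutral**
`(0.33, 0.66]` and **positive** `(0.66, 1.00]`, and one of three roles:

* **s** (spreader) — knows the refutation information and transmits its own
  emotion; its emotion is not changed by the agents it reaches;
* **r** (infected) — has had its emotion altered by contact and passes it on;
* **m** (immunized) — disengaged (middle band) but re-activatable, with
  per-day probabilities `f_s` (to s) and `f_r` (to r); `s + r + m = N`.

When a spreader (or infected) agent contacts a receiver, the transmission
probability is the product of the receiver's subjective traits and the
refuting authority's objective ones:

```
R_sr(t) = w_r(t) · b_r(t) · a_s(t) · v_s(t)
```

with `w` the receiver's expression ability, `b` its willingness to spread,
`a` the authority's credibility and `v` its refutation speed (all in
`[0, 1]`). The receiver then moves toward the source:

```
E_r(t+1) = d_r · E_r(t) + [E_s(t) − E_r(t)] · R_sr(t)
```

where `d_r` is the receiver's subjective-judgment firmness (1 = fully firm).
Same-role encounters (s–s, r–r) use the analogous pair rule; a
`pair_update_variant` flag selects between the *convergent* difference sign
(the default; the pair moves together) and the *as-printed* sign (the pair
diverges). Crossing a band boundary after a contact switches roles: an m
leaving the middle band becomes r; an s or r entering it becomes m. Contacts
with `R_sr` below the contagion threshold `λ` never transmit. Days advance
synchronously: each day every agent exchanges with up to
`contacts_per_agent_per_day` network neighbours, each contact executed as a
full pairwise event in random order.

The package ships the four study experiments as drivers (time period,
network intimacy, refutation speed × credibility, before/after comparison),
plus small empirical summaries for labeled-microblog tables
(sentiment-count proportions, daily emotion trends, speed/credibility rank
assignment for media records). See `docs/methods.md` for assumptions,
parameter defaults and limitations.

## Worked example

```python
import refutesim as rs

config = rs.SimulationConfig(n=1000, days=10, seed=42)
traj = rs.run(config)
print(traj.records[['t', 'n_s', 'n_r', 'n_m',
                    'n_negative', 'n_immune', 'n_positive',
                    'mean_emotion']].to_string(index=False))
```

```
 t  n_s  n_r  n_m  n_negative  n_immune  n_positive  mean_emotion
 0   50    0  950           0       950          50      0.513933
 1   51   25  924           0       926          74      0.521699
 2   53   42  905           0       909          91      0.526900
 3    7  106  887           0       897         103      0.530748
 4    6  119  875           0       885         115      0.532210
 5    7  131  862           0       878         122      0.533785
 6    3  144  853           0       871         129      0.535229
 7    4  146  850           0       869         131      0.535580
 8    1  154  845           0       865         135      0.535467
 9    1  154  845           0       866         134      0.535246
10    2  159  839           0       864         136      0.535687
```

Fifty positive-band spreaders seed a crowd of 950 immunized (neutral)
agents. Over the first three days the reachable part of the crowd is pulled
across the 0.66 boundary and converts to infected (`n_r` rises, `n_m`
falls); the spreaders retire after their three active days (`n_s` collapses
at day 3); by day ~4 the compartments are essentially stable, with the crowd
split between persistent neutrals and a positively-infected minority — the
characteristic refutation outcome.

The empirical helpers work on plain tables:

```python
from refutesim import SentimentCounts, proportions_from_counts
proportions_from_counts(SentimentCounts(positive=6389, neutral=4679, negative=5015))
# (39.73, 29.09, 31.18)   # percent positive / neutral / negative
```

The same functionality is exposed on the command line
(`refutesim run|exp1|exp2|exp3|exp4|summarize|fixtures`); every command
writes its tables atomically together with a `manifest.json` recording the
config snapshot, seeds and output checksums, so runs are reproducible
bit-for-bit.

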