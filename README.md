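# callnet

Dyadic vocal-interaction analysis for individually recorded, group-living
songbirds.

When every bird in a group carries its own microphone, each vocalisation can
be assigned to an identified sender with a precise onset time. `callnet`
turns such call-event streams into interaction networks: it asks, for every
ordered pair of (bird, call type) streams, whether one bird's calls of type
*a* systematically change the timing of another bird's calls of type *b* —
the raw material for questions about pair formation, breeding stage and
reproductive success in species such as the zebra finch, where both sexes
call in large numbers and soft close-range calls are thought to carry the
pair's communication.

## The statistic at the core

For an ordered dyad — initiator stream *X* (triggers), responder stream *Y* —
every onset of *Y* is expressed as a lag relative to every onset of *X* and
accumulated into a peristimulus time histogram (PSTH): 160 half-open bins of
50 ms spanning ±4 s. Two 0.5-s blocks summarise it:

- *N*<sub>base</sub>: counts in the earliest block of the window
  (lag ∈ [−4.0, −3.5) s), far from the trigger;
- *N*<sub>response</sub>: counts just after the trigger, with the first
  50 ms discarded to avoid microphone crosstalk (lag ∈ [0.05, 0.5) s).

The correlation index is

&nbsp;&nbsp;&nbsp;&nbsp;*R* = (*N*<sub>response</sub> − *N*<sub>base</sub>) / (*N*<sub>response</sub> + *N*<sub>base</sub>) ∈ [−1, 1],

+1 when the initiator's calls reliably elicit responses, −1 when they
suppress them. A dyad is *valid* only if its PSTH holds more than 160 events
(one per bin on average), and is gated at the 95% level with an exact
binomial test of *N*<sub>response</sub> against the duration-corrected null
proportion *p*₀ = 0.45/0.95. Dyad results assemble into square interaction
matrices over all (bird, call type) combinations — 40 × 40 for 8 birds and
the five analysable call types (distance, tet, stack, cackle, whine) —
with within-bird cells excluded.

On top sit repertoire summaries (per-type counts extrapolated to a common
243-min reference duration, proportions, per-stage descriptives) and
pair-level dynamics (within-pair combination percentages by responder sex,
partner/non-partner specificity ratios, and combination counts by egg-laying
success). A synthetic-data module generates coupled point-process call
streams (baseline Poisson calling plus single-generation excitatory coupling
at 0.05–0.45 s latencies) and synthetic syllable audio with five separable
archetypes, so the whole pipeline — including segmentation, the nine
temporal–spectral features and k-means call classification — closes the loop
against known ground truth.

## Worked example

```python
from callnet import GroupSimConfig, analyse_dyad, build_psth, simulate_group_calls

cfg = GroupSimConfig(
    baseline_rates={("A", "tet"): 0.1, ("B", "tet"): 0.1},
    duration=4 * 3600.0,
    coupling={("A", "tet", "B", "tet"): 0.4},   # B answers 40% of A's tets
    seed=11,
)
events = simulate_group_calls(cfg)
triggers = events[events.bird_id == "A"].onset_s.to_numpy()
responses = events[events.bird_id == "B"].onset_s.to_numpy()
result = analyse_dyad(triggers, responses)
```

Running `python examples/02_dyad_psth.py` (the same analysis) prints:

```
PSTH: 160 bins of 50 ms, 2008 lag pairs from 1390 triggers
N_base=94 (lag -4.0..-3.5 s), N_response=631 (lag 0.05..0.5 s)
R = 0.741, valid=True, significant=+1
```

Bird A produced 1390 tet calls in 4 h; relative to those triggers, bird B's
calls piled up in the post-onset response block (631 events) far above the
baseline block (94), giving a strongly positive index that the binomial gate
flags as a significant excitatory interaction. With coupling 0 the two
counts would agree up to Poisson noise and the dyad would be flagged in only
about 5% of runs — the expected false-positive rate of an unadjusted 95%
gate.

The other scripts in `examples/` walk through group simulation, full
interaction matrices, repertoire summaries across nest stages, pair
specificity/success statistics, and the audio loop. A thin CLI exposes the
same stages (`callnet simulate | segment | classify | interact | repertoire
| pairstats`).

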