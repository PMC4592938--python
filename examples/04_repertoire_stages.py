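"""Track repertoire composition across nest stages.

Simulates recordings at two breeding stages with different per-type calling
rates (distance calls fall away once nesting starts, whines pick up),
computes per-bird counts extrapolated to the 243-min reference duration,
and prints the per-stage summary.
"""

from callnet import (
    GroupSimConfig,
    repertoire_table,
    simulate_stage_series,
    stage_summary,
)

def cfg(rates, seed):
    return GroupSimConfig(
        baseline_rates={("F0", t): r for t, r in rates.items()},
        duration=2 * 3600.0,
        seed=seed,
    )

configs = [
    ("Unpaired", cfg({"distance": 0.08, "tet": 0.05, "whine": 0.005}, seed=1)),
    ("Nest building", cfg({"distance": 0.02, "tet": 0.05, "whine": 0.04}, seed=2)),
]
events, recordings = simulate_stage_series(configs, recordings_per_stage=3)
recordings["breeding_stage"] = recordings.pop("stage")

rows = repertoire_table(events, recordings)
summary = stage_summary(rows, by="nest_stage")

cols = ["nest_stage", "call_type", "n_birds", "n_rows", "median_norm", "median_prop"]
print(summary[summary.call_type.isin(["distance", "tet", "whine"])][cols].to_string(index=False))
# median_norm is the per-recording count extrapolated to 243 min; the
# distance-call median drops between stages while whines rise, matching the
# rates the generator was given. Proportions shift the same way but are
# unaffected by the duration extrapolation.
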