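"""Analyse a single dyad: PSTH, correlation index and significance.

Simulates one coupled pair of (bird, call type) streams, builds the
peristimulus time histogram, and prints the baseline/response counts, the
correlation index R = (N_response - N_base) / (N_response + N_base) and the
outcome of the 95% binomial gate (+1 excitation, -1 suppression, 0 none).
"""

from callnet import GroupSimConfig, PsthConfig, analyse_dyad, build_psth, simulate_group_calls

cfg = GroupSimConfig(
    baseline_rates={("A", "tet"): 0.1, ("B", "tet"): 0.1},
    duration=4 * 3600.0,
    coupling={("A", "tet", "B", "tet"): 0.4},  # B answers 40% of A's tets
    seed=11,
)
events = simulate_group_calls(cfg)
triggers = events[events.bird_id == "A"].onset_s.to_numpy()
responses = events[events.bird_id == "B"].onset_s.to_numpy()

psth = build_psth(triggers, responses)
result = analyse_dyad(triggers, responses)

print(f"PSTH: {psth.config.n_bins} bins of {psth.config.binwidth * 1000:.0f} ms, "
      f"{psth.total_events} lag pairs from {psth.n_triggers} triggers")
print(f"N_base={result.n_base} (lag -4.0..-3.5 s), "
      f"N_response={result.n_response} (lag 0.05..0.5 s)")
print(f"R = {result.r_index:.3f}, valid={result.valid}, significant={result.significant:+d}")
# With 40% coupling the response block holds far more events than baseline,
# so R is strongly positive and the dyad is flagged +1; with coupling 0 the
# two counts would match up to Poisson noise and R would hover near 0.
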