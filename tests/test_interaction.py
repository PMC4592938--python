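"""PSTH construction, correlation index, validity and significance gating."""

import math

import numpy as np
import pandas as pd
import pytest

from callnet import (
    CALL_TYPES,
    DyadResult,
    PsthConfig,
    analyse_dyad,
    build_interaction_matrix,
    build_psth,
    check_validity,
    correlation_index,
    test_significance as significance_gate,
)
from callnet.types import ConfigError


def naive_psth_counts(triggers, responses, window=4.0, binwidth=0.05):
    """Independent oracle: enumerate every (trigger, response) lag pair.

    Counting logic (all pairs, half-open window) is independent of the
    library; the bin-index formula shares the library's edge convention
    (nominal-edge snap) so exact-edge lags land identically.
    """
    n_bins = int(round(2 * window / binwidth))
    counts = np.zeros(n_bins, dtype=int)
    for t in triggers:
        for r in responses:
            lag = r - t
            if -window <= lag < window:
                b = math.floor((lag + window) / binwidth + 1e-9)
                counts[min(b, n_bins - 1)] += 1
    return counts


class TestBuildPsth:
    def test_default_geometry_is_160_bins_of_50ms(self):
        psth = build_psth([], [])
        assert psth.config.n_bins == 160
        edges = psth.lag_edges()
        assert edges[0] == -4.0 and edges[-1] == 4.0
        assert np.allclose(np.diff(edges), 0.05)

    def test_known_lag_lands_in_expected_bin(self):
        # lag 0.2 s falls in the bin covering [0.20, 0.25)
        psth = build_psth([10.0], [10.2])
        assert psth.counts.sum() == 1
        assert psth.counts[84] == 1

    def test_empty_responses_give_zero_counts(self):
        psth = build_psth([1.0, 2.0], [])
        assert psth.total_events == 0
        assert psth.n_triggers == 2

    def test_lag_at_window_edge_is_excluded(self):
        # half-open upper edge: lag exactly +window does not count
        psth = build_psth([0.0], [4.0])
        assert psth.total_events == 0
        # lower edge is inclusive
        psth = build_psth([4.0], [0.0])
        assert psth.total_events == 1
        assert psth.counts[0] == 1

    def test_response_contributes_to_every_nearby_trigger(self):
        psth = build_psth([0.0, 1.0], [2.0])
        assert psth.total_events == 2

    def test_unsorted_onsets_rejected(self):
        with pytest.raises(ValueError, match="sorted"):
            build_psth([2.0, 1.0], [0.5])

    def test_binwidth_must_divide_window(self):
        with pytest.raises(ConfigError):
            PsthConfig(window=4.0, binwidth=0.07)

    def test_matches_naive_enumeration_on_random_streams(self, rng):
        for _ in range(20):
            trig = np.sort(rng.uniform(0, 100, rng.integers(0, 60)))
            resp = np.sort(rng.uniform(0, 100, rng.integers(0, 60)))
            psth = build_psth(trig, resp)
            assert np.array_equal(psth.counts, naive_psth_counts(trig, resp))

    def test_invariant_under_common_time_shift(self, rng):
        trig = np.sort(rng.uniform(0, 50, 30))
        resp = np.sort(rng.uniform(0, 50, 30))
        a = build_psth(trig, resp)
        b = build_psth(trig + 1000.0, resp + 1000.0)
        assert np.array_equal(a.counts, b.counts)


class TestCorrelationIndex:
    @pytest.mark.parametrize(
        "n_base,n_resp,expected",
        [(0, 5, 1.0), (5, 5, 0.0), (2, 6, 0.5), (6, 2, -0.5), (5, 0, -1.0)],
    )
    def test_formula(self, n_base, n_resp, expected):
        cfg = PsthConfig()
        counts = np.zeros(cfg.n_bins, dtype=int)
        # base events in the first 0.5 s block, responses inside [0.05, 0.5)
        counts[0] = n_base
        counts[85] = n_resp
        psth = build_psth([], [])
        psth.counts = counts
        res = correlation_index(psth)
        assert res.n_base == n_base and res.n_response == n_resp
        assert res.r_index == pytest.approx(expected)

    def test_r_index_bounded_and_antisymmetric(self, rng):
        for _ in range(50):
            nb, nr = rng.integers(0, 40, 2)
            if nb + nr == 0:
                continue
            r = (nr - nb) / (nr + nb)
            r_swapped = (nb - nr) / (nb + nr)
            assert -1.0 <= r <= 1.0
            assert r == pytest.approx(-r_swapped)

    def test_no_events_in_blocks_is_undefined_and_invalid(self):
        psth = build_psth([1.0], [])
        res = correlation_index(psth)
        assert math.isnan(res.r_index)
        assert not res.valid

    def test_crosstalk_bin_never_counts_toward_response(self):
        # simultaneous onsets (lag 0) fall in the excluded first 50 ms
        psth = build_psth([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        res = correlation_index(psth)
        assert res.n_response == 0  # lags of 0 s land in bin 80, excluded


class TestValidity:
    @pytest.mark.parametrize("total,expected", [(160, False), (161, True), (0, False)])
    def test_strict_threshold(self, total, expected):
        psth = build_psth([], [])
        psth.counts = np.zeros(160, dtype=int)
        psth.counts[40] = total
        assert check_validity(psth) is expected


class TestSignificance:
    def test_extreme_excess_flags_positive(self):
        res = DyadResult(n_base=0, n_response=30, r_index=1.0, valid=True, total_events=200)
        assert significance_gate(res, PsthConfig()) == 1

    def test_balanced_counts_not_significant(self):
        # 20/40 = 0.5 vs null p0 = 0.45/0.95 ~ 0.474: no rejection
        res = DyadResult(n_base=20, n_response=20, r_index=0.0, valid=True, total_events=200)
        assert significance_gate(res, PsthConfig()) == 0

    def test_no_events_returns_zero(self):
        res = DyadResult(n_base=0, n_response=0, valid=True, total_events=200)
        assert significance_gate(res, PsthConfig()) == 0

    def test_invalid_result_returns_zero(self):
        res = DyadResult(n_base=0, n_response=100, r_index=1.0, valid=False, total_events=50)
        assert significance_gate(res, PsthConfig()) == 0

    def test_deficit_flags_negative(self):
        res = DyadResult(n_base=60, n_response=5, r_index=-0.8, valid=True, total_events=300)
        assert significance_gate(res, PsthConfig()) == -1

    def test_null_proportion_duration_corrected(self):
        cfg = PsthConfig()
        assert cfg.null_p == pytest.approx(0.45 / 0.95)
        assert PsthConfig(null_model="symmetric").null_p == 0.5

    def test_sign_agrees_with_r_index_direction(self, rng):
        cfg = PsthConfig()
        for _ in range(30):
            nb, nr = int(rng.integers(0, 120)), int(rng.integers(0, 120))
            if nb + nr == 0:
                continue
            res = DyadResult(n_base=nb, n_response=nr, r_index=(nr - nb) / (nr + nb),
                             valid=True, total_events=500)
            s = significance_gate(res, cfg)
            if s == 1:
                assert nr / (nb + nr) > cfg.null_p
            elif s == -1:
                assert nr / (nb + nr) < cfg.null_p


class TestBaselineModes:
    def test_all_pre_blocks_uses_whole_pre_window(self):
        cfg = PsthConfig(baseline_mode="all-pre-blocks")
        counts = np.zeros(160, dtype=int)
        counts[:80] = 2  # uniform pre-onset: mean 20 per 0.5 s block
        counts[81:90] = 4  # 36 response events
        psth = build_psth([], [], cfg)
        psth.counts = counts
        res = correlation_index(psth)
        assert res.n_base == 160  # raw pre-onset count
        assert res.r_index == pytest.approx((36 - 20) / (36 + 20))
        assert cfg.null_p == pytest.approx(0.45 / 4.45)


class TestInteractionMatrix:
    def _events(self, rng, birds, rate=0.02, duration=2000.0):
        rows = []
        for b in birds:
            for t in CALL_TYPES:
                n = rng.poisson(rate * duration)
                for x in rng.uniform(0, duration, n):
                    rows.append({"bird_id": b, "call_type": t, "onset_s": x})
        return pd.DataFrame(rows).sort_values("onset_s")

    def test_cell_bookkeeping_eight_birds(self, rng):
        birds = [f"B{i}" for i in range(8)]
        m = build_interaction_matrix(self._events(rng, birds), birds)
        assert m.n_cells == 1600
        assert m.n_excluded == 200
        assert m.n_analysable == 1400

    def test_cell_bookkeeping_six_birds(self, rng):
        birds = [f"B{i}" for i in range(6)]
        m = build_interaction_matrix(self._events(rng, birds), birds)
        assert m.n_cells == 900
        assert m.n_excluded == 150

    def test_fewer_than_two_birds_rejected(self):
        with pytest.raises(ConfigError):
            build_interaction_matrix(pd.DataFrame(columns=["bird_id", "call_type", "onset_s"]), ["A"])

    def test_other_typed_events_ignored(self, rng):
        ev = self._events(rng, ["A", "B"])
        other = pd.DataFrame(
            {"bird_id": "A", "call_type": "other", "onset_s": rng.uniform(0, 2000, 500)}
        )
        m1 = build_interaction_matrix(ev, ["A", "B"])
        m2 = build_interaction_matrix(pd.concat([ev, other]), ["A", "B"])
        for a, b, res in m1.iter_analysable():
            assert m2.cells[(a, b)].total_events == res.total_events

    def test_display_value_gates_non_significant_to_zero(self, rng):
        birds = ["A", "B"]
        m = build_interaction_matrix(self._events(rng, birds, rate=0.05), birds)
        for a, b, res in m.iter_analysable():
            v = m.display_value(a, b)
            if not res.valid:
                assert math.isnan(v)
            elif res.significant == 0:
                assert v == 0.0
            else:
                assert v == res.r_index

    def test_analyse_dyad_matches_components(self, rng):
        trig = np.sort(rng.uniform(0, 5000, 400))
        resp = np.sort(rng.uniform(0, 5000, 400))
        cfg = PsthConfig()
        direct = analyse_dyad(trig, resp, cfg)
        psth = build_psth(trig, resp, cfg)
        step = correlation_index(psth)
        significance_gate(step, cfg)
        assert direct == step
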