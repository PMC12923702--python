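"""Phase-coherence state assignment and dynamics/complexity metrics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from taskfc.cohort import NetworkPartition, RegionalTimeseries
from taskfc.state_dynamics import (
    PhaseTimeseries,
    StateTimeseries,
    analytic_phase,
    assign_states,
    bandpass,
    bdmc,
    coherence_snapshot,
    ctm_table,
    dynamics_summary,
    encode_states_4bit,
    lzc,
    mean_dwell_time,
    state_metrics,
    transition_entropy,
)


def ts(data, tr=2.0):
    return RegionalTimeseries(data=np.asarray(data, float), tr=tr)


def states(labels, n_templates=9, tr=2.0):
    return StateTimeseries(labels=np.asarray(labels, int),
                           templates=tuple(f"n{i}" for i in range(n_templates)),
                           tr=tr)


class TestBandpass:
    def test_in_band_sinusoid_preserved(self):
        t = np.arange(600) * 2.0
        x = np.sin(2 * np.pi * 0.05 * t)[:, None]
        out = bandpass(ts(x)).data[50:-50, 0]
        assert out.var() >= 0.9 * x[50:-50, 0].var()

    def test_out_of_band_drift_removed(self):
        t = np.arange(600) * 2.0
        x = np.sin(2 * np.pi * 0.005 * t)[:, None]
        out = bandpass(ts(x)).data[50:-50, 0]
        assert out.var() < 0.05 * x[50:-50, 0].var()

    def test_zero_input_zero_output(self):
        out = bandpass(ts(np.zeros((100, 3))))
        assert not out.data.any()

    def test_nyquist_violation_reports_bound(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(ts(np.random.default_rng(0).standard_normal((50, 2)), tr=6.0))


class TestAnalyticPhase:
    def test_cosine_phase_advances_linearly(self):
        t = np.arange(400) * 2.0
        omega = 2 * np.pi * 0.05
        x = np.cos(omega * t)[:, None]
        ph = analytic_phase(ts(x)).phase[50:-50, 0]
        expected = omega * t[50:-50]
        diff = np.angle(np.exp(1j * (ph - expected)))  # wrap-safe comparison
        assert np.abs(diff).max() < 1e-2

    def test_unit_cosine_amplitude_one(self):
        t = np.arange(400) * 2.0
        x = np.cos(2 * np.pi * 0.05 * t)[:, None]
        amp = analytic_phase(ts(x)).amplitude[50:-50, 0]
        assert np.allclose(amp, 1.0, atol=1e-2)

    def test_negation_shifts_phase_by_pi(self):
        rng = np.random.default_rng(1)
        x = bandpass(ts(rng.standard_normal((300, 1)))).data
        p1 = analytic_phase(ts(x)).phase[:, 0]
        p2 = analytic_phase(ts(-x)).phase[:, 0]
        diff = np.angle(np.exp(1j * (p2 - p1)))
        assert np.allclose(np.abs(diff), np.pi, atol=1e-9)


class TestCoherenceAndAssignment:
    @pytest.mark.parametrize("delta,expected", [(0.0, 1.0),
                                                (np.pi, -1.0),
                                                (np.pi / 2, 0.0)])
    def test_snapshot_closed_forms(self, delta, expected):
        fc = coherence_snapshot(np.array([0.3, 0.3 + delta]))
        assert fc[0, 1] == pytest.approx(expected, abs=1e-12)
        assert fc[0, 0] == 1.0 and np.allclose(fc, fc.T)

    def _partition(self, n_regions=12, n_networks=3):
        membership = np.zeros((n_regions, n_networks), bool)
        per = n_regions // n_networks
        for k in range(n_networks):
            membership[k * per:(k + 1) * per, k] = True
        return NetworkPartition(membership,
                                tuple(f"n{k}" for k in range(n_networks)))

    def test_phase_locked_network_wins(self):
        part = self._partition()
        rng = np.random.default_rng(2)
        phase = rng.uniform(-np.pi, np.pi, (5, 12))
        phase[:, 4:8] = 0.25  # network n1 locked
        out = assign_states(PhaseTimeseries(phase=phase,
                                            amplitude=np.ones((5, 12)),
                                            tr=2.0), part)
        assert (out.labels == 1).all()

    def test_global_tie_breaks_to_first_template_and_logs(self):
        part = self._partition()
        phase = np.full((3, 12), 0.7)
        out = assign_states(PhaseTimeseries(phase=phase,
                                            amplitude=np.ones((3, 12)),
                                            tr=2.0), part)
        assert (out.labels == 0).all()
        assert out.n_ties == 3

    def test_small_template_rejected(self):
        membership = np.zeros((5, 2), bool)
        membership[:4, 0] = True
        membership[4, 1] = True
        part = NetworkPartition(membership, ("a", "b"))
        phase = np.zeros((2, 5))
        with pytest.raises(ValueError, match="fewer than 2"):
            assign_states(PhaseTimeseries(phase=phase,
                                          amplitude=np.ones((2, 5)),
                                          tr=2.0), part)


class TestStateMetrics:
    def test_two_state_example(self):
        lifetime, prob = state_metrics(states([0, 0, 1, 1], n_templates=2))
        assert prob.tolist() == [0.5, 0.5]
        assert lifetime.tolist() == [4.0, 4.0]

    def test_single_state_sequence(self):
        lifetime, prob = state_metrics(states([3] * 10))
        assert prob[3] == 1.0
        assert lifetime[3] == 10 * 2.0

    @given(st.lists(st.integers(0, 8), min_size=1, max_size=200))
    @settings(derandomize=True, max_examples=100)
    def test_probabilities_partition_and_lifetime_proportionality(self, labels):
        s = states(labels)
        lifetime, prob = state_metrics(s)
        assert prob.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(lifetime, prob * len(labels) * 2.0, atol=1e-9)

    def test_mean_dwell_variant_differs_from_lifetime(self):
        s = states([0, 0, 1, 0, 0], n_templates=2)
        lifetime, _ = state_metrics(s)
        dwell = mean_dwell_time(s)
        assert lifetime[0] == 8.0
        assert dwell[0] == 4.0  # two runs of 2 volumes


class TestEncoding:
    def test_examples(self):
        assert encode_states_4bit(states([5], 16)).tolist() == [0, 1, 0, 1]
        assert encode_states_4bit(states([0, 1], 16)).tolist() == [0, 0, 0, 0,
                                                                   0, 0, 0, 1]

    def test_round_trip_for_all_nine_states(self):
        lab = np.arange(9)
        bits = encode_states_4bit(states(lab))
        decoded = bits.reshape(-1, 4) @ np.array([8, 4, 2, 1])
        assert decoded.tolist() == lab.tolist()

    def test_too_many_states_rejected(self):
        with pytest.raises(ValueError, match="16"):
            encode_states_4bit(states([0], n_templates=17))


class TestLZ76:
    def test_all_zeros_anchor(self):
        assert lzc(np.zeros(300, dtype=int)) == 2

    def test_alternating_anchor(self):
        assert lzc(np.tile([0, 1], 150)) == 3

    def test_random_sequence_near_asymptotic_rate(self):
        n = 4096
        target = n / np.log2(n)
        for seed in range(20):
            c = lzc(np.random.default_rng(seed).integers(0, 2, n))
            assert abs(c - target) / target < 0.20

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            lzc(np.array([0, 1, 2]))


class TestBDMC:
    def test_repeated_block_formula(self):
        block = np.array([0, 1, 1, 0, 1, 0, 0, 1, 1, 1, 0, 0])
        code = int("".join(map(str, block)), 2)
        k = ctm_table(12)[code]
        seq = np.tile(block, 7)
        assert bdmc(seq) == pytest.approx(k + np.log2(7))

    def test_short_sequence_warns_and_returns_zero(self):
        with pytest.warns(UserWarning, match="shorter"):
            assert bdmc(np.array([0, 1, 0])) == 0.0

    def test_random_scores_above_periodic(self):
        n = 480
        periodic = np.tile([0, 1], n // 2)
        for seed in range(20):
            random_seq = np.random.default_rng(seed).integers(0, 2, n)
            assert bdmc(random_seq) > bdmc(periodic)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            bdmc(np.array([0, 2] * 12))


class TestTransitionEntropy:
    def test_constant_sequence_zero_for_all_orders(self):
        s = states([4] * 50)
        assert all(transition_entropy(s, o) == 0.0 for o in range(5))

    def test_uniform_counts_give_log2_k(self):
        s = states(np.tile(np.arange(9), 20))
        assert transition_entropy(s, 0) == pytest.approx(np.log2(9), abs=1e-12)

    def test_alternating_order_one_hand_value(self):
        s = states([0, 1] * 5, n_templates=2)  # "ABABABABAB"
        h = -(5 / 9) * np.log2(5 / 9) - (4 / 9) * np.log2(4 / 9)
        assert transition_entropy(s, 1) == pytest.approx(h, abs=1e-12)

    def test_entropy_nondecreasing_with_order_for_iid(self):
        rng = np.random.default_rng(3)
        s = states(rng.integers(0, 9, 3000))
        hs = [transition_entropy(s, o) for o in range(5)]
        assert np.all(np.diff(hs) >= -1e-9)

    def test_conditional_variant_is_block_difference(self):
        rng = np.random.default_rng(4)
        s = states(rng.integers(0, 4, 500))
        h2 = transition_entropy(s, 2)
        # H(next | previous 2) ~= H(3-gram) - H(2-gram) up to edge counts
        h_cond = transition_entropy(s, 2, conditional=True)
        h1 = transition_entropy(s, 1)
        assert h_cond == pytest.approx(h2 - h1, abs=0.01)
        # deterministic alternation carries no conditional surprise
        alt = states([0, 1] * 50, n_templates=2)
        assert transition_entropy(alt, 1, conditional=True) == pytest.approx(
            0.0, abs=1e-9)


class TestFullChain:
    def test_deterministic_given_fixed_input(self, small_cohort):
        from taskfc.state_dynamics import state_sequence

        t = small_cohort.subjects[0]["data"]["mid"].timeseries
        s1 = state_sequence(t, small_cohort.partition)
        s2 = state_sequence(t, small_cohort.partition)
        assert np.array_equal(s1.labels, s2.labels)
        d1, d2 = dynamics_summary(s1), dynamics_summary(s2)
        assert d1.lzc == d2.lzc and d1.bdmc == d2.bdmc
        assert np.array_equal(d1.transition_entropy, d2.transition_entropy)
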