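"""Replay epochs, transition matrices, directionality, predominance."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import wmreplay as w
from wmreplay.containers import NULL_LABEL, STATES, ValidationError
from wmreplay.replay import LENGTH_RANGES_MS
from wmreplay.simulate import _sample_chains


def seq(labels, trial_id=0, period="retention"):
    return w.DecodedSequence(
        trial_id=trial_id, period=period, labels=tuple(labels),
        distances=tuple(1.0 for _ in labels),
    )


def make_trial(trial_id=0, order=("F", "B", "C"), probe_pos=1):
    return w.TrialDesign(
        trial_id=trial_id, run_id=1,
        sequence=tuple((c, "front") for c in order),
        probe_position=probe_pos, probe_same=True,
        probe_item=(order[probe_pos - 1], "front"),
    )


class TestReplayEpochs:
    def test_run_length_decomposition(self):
        eps = w.extract_replay_epochs(seq("FFFNBB"))
        assert [(e.label, e.n_bins, e.length_ms) for e in eps] == [
            ("F", 3, 60.0), ("B", 2, 40.0)
        ]

    def test_all_null_yields_nothing(self):
        assert w.extract_replay_epochs(seq("N" * 10)) == []

    def test_single_maximal_run(self):
        eps = w.extract_replay_epochs(seq("F" * 150))
        assert len(eps) == 1 and eps[0].length_ms == 3000.0

    @given(st.lists(st.sampled_from(list(STATES)), min_size=0, max_size=60))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_decomposition_is_lossless(self, labels):
        s = seq(labels)
        eps = w.extract_replay_epochs(s)
        rebuilt = [NULL_LABEL] * len(labels)
        for e in eps:
            for b in range(e.start_bin, e.start_bin + e.n_bins):
                rebuilt[b] = e.label
        assert rebuilt == [lab for lab in labels]
        # maximality: neighbors of each run differ from the run's label
        for e in eps:
            if e.start_bin > 0:
                assert labels[e.start_bin - 1] != e.label
            end = e.start_bin + e.n_bins
            if end < len(labels):
                assert labels[end] != e.label


class TestHistogram:
    def test_one_count_per_range(self):
        eps = [
            w.ReplayEpoch(0, "retention", "F", 0, n)
            for n in (3, 10, 25, 75)  # 60, 200, 500, 1500 ms
        ]
        h = w.histogram_epoch_lengths(eps, "retention")
        assert h.counts.tolist() == [1, 1, 1, 1]

    def test_empty_list_gives_zero_histogram(self):
        h = w.histogram_epoch_lengths([], "iti")
        assert h.counts.sum() == 0 and h.n_epochs == 0

    def test_ranges_partition_all_attainable_lengths(self):
        for n_bins in range(1, 151):
            eps = [w.ReplayEpoch(0, "retention", "F", 0, n_bins)]
            h = w.histogram_epoch_lengths(eps, "retention")
            assert h.counts.sum() == 1

    def test_range_sums_equal_total(self):
        rng = np.random.default_rng(0)
        eps = [
            w.ReplayEpoch(0, "retention", "F", 0, int(n))
            for n in rng.integers(1, 150, size=200)
        ]
        h = w.histogram_epoch_lengths(eps, "retention")
        assert h.counts.sum() == 200


class TestRankSum:
    def test_exact_p_against_enumeration(self):
        r, iti = [10, 11, 12, 13], [1, 2, 3, 4]
        _, p = w.rank_sum_test(r, iti)
        # oracle: enumerate all C(8,4)=70 rank assignments
        ranks = range(8)
        observed = sum(range(4, 8))
        more_extreme = sum(
            1
            for c in itertools.combinations(ranks, 4)
            if abs(sum(c) - 14) >= abs(observed - 14)
        )
        assert p == pytest.approx(more_extreme / 70)  # = 2/70 = 0.0286
        assert p == pytest.approx(0.0286, abs=1e-4)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=8), rng.normal(size=8)
        _, p1 = w.rank_sum_test(x, y)
        _, p2 = w.rank_sum_test(np.exp(x), np.exp(y))
        assert p1 == p2

    def test_identical_samples_are_null(self):
        x = [1.0, 2.0, 3.0, 4.0]
        _, p = w.rank_sum_test(x, x)
        assert p > 0.5

    def test_compare_periods_table(self):
        out = w.compare_periods(
            {"n_epochs": [10, 11, 12, 13]}, {"n_epochs": [1, 2, 3, 4]}
        )
        assert out.loc[0, "p_value"] == pytest.approx(0.0286, abs=1e-4)
        with pytest.raises(ValidationError):
            w.compare_periods({"x": [1.0]}, {"x": [2.0]})


class TestTransitionMatrix:
    def test_deterministic_cycle(self):
        m = w.estimate_transition_matrix([seq("FBC" * 20)])
        p = m.probabilities
        i = {s: k for k, s in enumerate(m.states)}
        assert p[i["F"], i["B"]] == 1.0
        assert p[i["B"], i["C"]] == 1.0
        assert p[i["C"], i["F"]] == 1.0

    def test_constant_sequence(self):
        m = w.estimate_transition_matrix([seq("F" * 30)])
        p = m.probabilities
        assert p[0, 0] == 1.0 and p[0, 1:].sum() == 0.0
        assert np.isnan(p[1]).all()  # B never visited

    def test_counts_conservation_and_no_cross_trial_transitions(self):
        seqs = [seq("FFBB", trial_id=0), seq("CCNN", trial_id=1)]
        m = w.estimate_transition_matrix(seqs)
        assert m.n_transitions == 2 * 3  # (4 bins - 1) per trial

    def test_recovery_of_known_generator(self):
        gen = np.array(
            [
                [0.70, 0.10, 0.10, 0.10],
                [0.05, 0.80, 0.05, 0.10],
                [0.10, 0.10, 0.60, 0.20],
                [0.25, 0.25, 0.25, 0.25],
            ]
        )
        rng = np.random.default_rng(7)
        chain = _sample_chains(gen, np.full(4, 0.25), 1, 100_001, rng)[0]
        labels = [STATES[i] for i in chain]
        m = w.estimate_transition_matrix([seq(labels)])
        assert np.max(np.abs(m.probabilities - gen)) <= 0.02

    def test_estimator_consistency(self):
        gen = np.array(
            [
                [0.70, 0.10, 0.10, 0.10],
                [0.05, 0.80, 0.05, 0.10],
                [0.10, 0.10, 0.60, 0.20],
                [0.25, 0.25, 0.25, 0.25],
            ]
        )
        errs = []
        for n in (1_000, 100_000):
            rng = np.random.default_rng(8)
            chain = _sample_chains(gen, np.full(4, 0.25), 1, n, rng)[0]
            m = w.estimate_transition_matrix([seq([STATES[i] for i in chain])])
            errs.append(np.max(np.abs(m.probabilities - gen)))
        assert errs[1] < errs[0]

    def test_position_remap(self):
        trial = make_trial(order=("B", "F", "C"))
        m = w.estimate_transition_matrix(
            [seq("BFC", trial_id=0)], remap=w.position_remap([trial])
        )
        assert m.states == ("1", "2", "3", "N")
        p = m.probabilities
        assert p[0, 1] == 1.0 and p[1, 2] == 1.0  # B->F->C is 1->2->3


def _matrix_from_probs(p):
    counts = np.asarray(np.round(np.asarray(p) * 1000), dtype=np.int64)
    return w.TransitionMatrix(
        states=("1", "2", "3", "N"), counts=counts,
        n_transitions=int(counts.sum()),
    )


class TestDirectionality:
    def test_symmetric_generator_gives_equal_products(self):
        p = np.array(
            [
                [0.4, 0.2, 0.1, 0.3],
                [0.2, 0.4, 0.15, 0.25],
                [0.1, 0.15, 0.5, 0.25],
                [0.2, 0.2, 0.2, 0.4],
            ]
        )
        mats = [_matrix_from_probs(p) for _ in range(6)]
        stats_ = w.directionality_test(mats)
        assert np.allclose(stats_.p_forward, stats_.p_backward)
        fwd = stats_.tests.set_index("comparison").loc["forward_vs_backward"]
        assert fwd["p_value"] == 1.0

    def test_forward_bias_detected(self):
        rng = np.random.default_rng(0)
        mats = []
        for _ in range(14):
            base = np.array(
                [
                    [0.30, 0.50, 0.10, 0.10],
                    [0.10, 0.30, 0.50, 0.10],
                    [0.50, 0.10, 0.30, 0.10],
                    [0.30, 0.30, 0.30, 0.10],
                ]
            )
            jitter = rng.uniform(0.9, 1.1, base.shape)
            p = base * jitter
            p /= p.sum(axis=1, keepdims=True)
            mats.append(_matrix_from_probs(p))
        stats_ = w.directionality_test(mats)
        fwd = stats_.tests.set_index("comparison").loc["forward_vs_backward"]
        assert fwd["p_value"] < 0.05
        assert (stats_.p_forward > stats_.p_backward).all()

    def test_unvisited_rows_excluded_and_logged(self):
        p_ok = np.full((4, 4), 0.25)
        m_ok = _matrix_from_probs(p_ok)
        bad_counts = m_ok.counts.copy()
        bad_counts[0] = 0  # state 1 never visited
        m_bad = w.TransitionMatrix(("1", "2", "3", "N"), bad_counts,
                                   int(bad_counts.sum()))
        stats_ = w.directionality_test([m_ok, m_ok, m_bad])
        assert stats_.n_excluded["forward_vs_backward"] == 1

    def test_category_matrices_rejected(self):
        m = w.estimate_transition_matrix([seq("FBC")])
        with pytest.raises(ValidationError):
            w.directionality_test([m])


class TestPredominance:
    def test_majority_category_wins(self):
        labels = ["F"] * 80 + ["B"] * 10 + ["N"] * 60
        s = w.identify_predominant(seq(labels), make_trial())
        assert s.pm_category == "F" and s.pm_position == 1

    def test_all_null_has_no_pm(self):
        s = w.identify_predominant(seq("N" * 150), make_trial())
        assert s.pm_category is None and s.replay_group == "none"

    def test_probe_long_replay_group(self):
        labels = ["F"] * 60 + ["N"] * 90  # 1200 ms F epoch, probe is F
        s = w.identify_predominant(seq(labels), make_trial(probe_pos=1))
        assert s.replay_group == "long"

    def test_exact_1100ms_is_short(self):
        labels = ["F"] * 55 + ["N"] * 95  # 1100 ms: strict > rule
        s = w.identify_predominant(seq(labels), make_trial(probe_pos=1))
        assert s.replay_group == "short"

    def test_tie_broken_by_longest_epoch(self):
        # F and B both 20 bins, but B has the longer single run
        labels = (["F"] * 10 + ["N"] + ["F"] * 10 + ["N"] + ["B"] * 20)
        s = w.identify_predominant(seq(labels), make_trial())
        assert s.pm_category == "B"

    def test_longest_rule_option(self):
        labels = ["F"] * 30 + ["N"] + ["B"] * 25 + ["F"] * 10
        bins_rule = w.identify_predominant(seq(labels), make_trial(), rule="bins")
        long_rule = w.identify_predominant(seq(labels), make_trial(), rule="longest")
        assert bins_rule.pm_category == "F"  # 40 bins of F vs 25 of B
        assert long_rule.pm_category == "F"  # 30-bin epoch still longest
        with pytest.raises(ValidationError):
            w.identify_predominant(seq(labels), make_trial(), rule="bogus")


class TestPredominanceAnova:
    def _summaries(self, rng, force_position=None):
        out = {}
        for subj in range(8):
            trials = []
            for tid in range(54):
                order = tuple(rng.permutation(list("FBC")))
                trial = make_trial(trial_id=tid, order=order)
                pos = (
                    force_position
                    if force_position
                    else int(rng.integers(1, 4))
                )
                labels = [order[pos - 1]] * 30 + ["N"] * 120
                trials.append(w.identify_predominant(seq(labels, tid), trial))
            out[subj] = trials
        return out

    def test_uniform_pm_is_null(self):
        aov = w.predominance_anova(self._summaries(np.random.default_rng(0)))
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        assert (aov[p_col].dropna() > 0.05).all()

    def test_position_lock_detected(self):
        aov = w.predominance_anova(
            self._summaries(np.random.default_rng(1), force_position=1)
        )
        p_col = "p_unc" if "p_unc" in aov.columns else "p-unc"
        row = aov[aov["Source"].str.contains("position", case=False)]
        assert (row[p_col] < 0.05).any()

    def test_proportions_sum_to_one(self):
        s = self._summaries(np.random.default_rng(2))
        for subj, summaries in s.items():
            with_pm = [x for x in summaries if x.pm_category is not None]
            props = {}
            for cat in "FBC":
                props[cat] = sum(
                    1 for x in with_pm if x.pm_category == cat
                ) / len(with_pm)
            assert sum(props.values()) == pytest.approx(1.0)
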