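"""Dwell-constrained DP alignment: oracle equivalence, counting, Welch-t."""

import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import squigstr as sq
from squigstr.dtw_engine import DwellPolicy, _count_peaks
from squigstr.locus_model import build_base_automaton, expand_to_kmer_automaton
from squigstr.simulator import make_synthetic_pore_model


# ---------------------------------------------------------------------------
# independent brute-force oracle: enumerate all dwell-feasible paths
# ---------------------------------------------------------------------------

def brute_force_min_cost(values, automaton, policy: DwellPolicy) -> float:
    """Minimum cost over every dwell-feasible start-to-accept path (exhaustive)."""
    m = len(values)
    req = policy.requirements(m)
    levels = automaton.levels
    accepts = set(automaton.accepts)
    prefix = {}  # (state, pos, length) cost of a run, memo-free direct sums
    best = [np.inf]

    def rec(state, pos, cost):
        if cost >= best[0]:
            return
        r = int(req[pos])
        run_cost = 0.0
        for length in range(1, m - pos + 1):
            run_cost += abs(values[pos + length - 1] - levels[state])
            if length < r:
                continue
            total = cost + run_cost
            end = pos + length
            if end == m:
                if state in accepts:
                    best[0] = min(best[0], total)
            else:
                for nxt in automaton.succ[state]:
                    rec(nxt, end, total)

    for s in automaton.starts:
        rec(s, 0, 0.0)
    return best[0]


def small_automata():
    """Small k-mer automata (<= 8 states) over k=2 for the oracle grid."""
    model = make_synthetic_pore_model(2, 0)
    out = []
    for expr, left, right in [
        ("(CG)", "AA", "TT"),     # single 2-cycle
        ("CGT", "AA", "TT"),      # pure chain
        ("(C)", "AT", "GA"),      # 1-state cycle with self transition
        ("(CA)G", "TT", "AA"),
    ]:
        base = build_base_automaton(expr, left, right)
        auto = expand_to_kmer_automaton(base, model)
        norm_levels = (auto.levels - auto.levels.mean()) / max(auto.levels.std(), 1.0)
        auto.levels = norm_levels
        assert auto.n_states() <= 8
        out.append(auto)
    return out


class TestAlignmentOracle:
    def test_single_state_constant_signal(self):
        model = make_synthetic_pore_model(2, 0)
        base = build_base_automaton("(C)", "AT", "GA")
        auto = expand_to_kmer_automaton(base, model)
        # degenerate: signal sitting exactly on one state's level still must
        # traverse the whole automaton; a straight chain of exact levels is 0
        word = "ATCGA"
        levels = sq.ideal_levels(word, model)
        sig = np.repeat(levels, 4)
        res = sq.align_signal(sig, auto, DwellPolicy(4))
        assert res.cost == pytest.approx(0.0)
        assert len(res.event_spans()) == len(levels)

    def test_three_state_chain_exact_dwell(self):
        model = make_synthetic_pore_model(2, 0)
        base = build_base_automaton("G", "AC", "TT")
        auto = expand_to_kmer_automaton(base, model)  # AC CG GT TT chain
        sig = np.repeat(auto.levels[:4], 4)
        res = sq.align_signal(sig, auto, DwellPolicy(4))
        assert res.cost == pytest.approx(0.0)
        assert [s for _, _, s in res.event_spans()] == [0, 1, 2, 3]

    @pytest.mark.parametrize("s", [1, 2, 4])
    def test_dp_equals_bruteforce_on_random_signals(self, s):
        """DP cost == exhaustive enumeration over all dwell-feasible paths."""
        lengths = {1: 12, 2: 18, 4: 24}[s]
        rng = np.random.default_rng(100 + s)
        for auto in small_automata():
            for rep in range(6):
                m = int(rng.integers(max(lengths - 4, 5 * s), lengths + 1))
                sig = rng.uniform(-2.0, 2.0, size=m)
                try:
                    res = sq.align_signal(sig, auto, DwellPolicy(s))
                except sq.AlignmentInfeasibleError:
                    assert not np.isfinite(brute_force_min_cost(sig, auto, DwellPolicy(s)))
                    continue
                oracle = brute_force_min_cost(sig, auto, DwellPolicy(s))
                assert res.cost == pytest.approx(oracle, abs=1e-9)

    def test_dp_equals_bruteforce_with_window_override(self):
        rng = np.random.default_rng(42)
        auto = small_automata()[0]
        for rep in range(5):
            sig = rng.uniform(-2.0, 2.0, size=16)
            policy = DwellPolicy(2, overrides=((4, 9),))
            res = sq.align_signal(sig, auto, policy)
            assert res.cost == pytest.approx(brute_force_min_cost(sig, auto, policy), abs=1e-9)

    def test_infeasible_signal_raises(self):
        model = make_synthetic_pore_model(2, 0)
        base = build_base_automaton("CGT", "AA", "TT")
        auto = expand_to_kmer_automaton(base, model)
        # 7 states, 4 points each needs >= 28 points
        with pytest.raises(sq.AlignmentInfeasibleError):
            sq.align_signal(np.zeros(20), auto, DwellPolicy(4))

    def test_appended_point_cost_bound(self):
        """Appending one point raises the optimal cost by at most the cost of
        dwelling one more step in the previous end state (and never below 0).

        Plain nondecreasing cost is not a theorem for end-anchored alignment:
        truncating an (m+1)-optimal path needn't end in an accept state.
        """
        rng = np.random.default_rng(7)
        auto = small_automata()[0]
        sig = rng.uniform(-2, 2, size=30)
        prev = None
        for m in range(12, 31, 3):
            res = sq.align_signal(sig[:m], auto, DwellPolicy(2))
            assert res.cost >= 0.0
            if prev is not None:
                prev_res, m_prev = prev
                bound = prev_res.cost + sum(
                    abs(sig[i] - auto.levels[prev_res.path_states[-1]])
                    for i in range(m_prev, m)
                )
                assert res.cost <= bound + 1e-9
            prev = (res, m)

    def test_dwell_soundness_of_returned_paths(self, cag_automata, cag_model, cag_flanks):
        left, right = cag_flanks
        sim = sq.SimConfig(seed=5, noise_sd=3.0, reads_per_allele=2, pad=0)
        ds = sq.simulate_locus_dataset("(CAG)", left, right, (6, 6), cag_model, sim)
        for read in ds.reads:
            if read.strand != "+":
                continue
            seg = read.signal[read.move_index[cag_model.k - 1] :]
            norm = sq.normalize_median(seg)
            res = sq.align_signal(norm.values, cag_automata["+"], DwellPolicy(4))
            req = res.policy.requirements(len(norm.values))
            for a, b, _ in res.event_spans():
                assert b - a >= req[a]


class TestCounting:
    def test_forced_path_length_and_group_count(self, cag_automata, cag_model, cag_flanks):
        left, right = cag_flanks
        word = left + "CAG" * 5 + right
        levels = sq.ideal_levels(word, cag_model.normalized())
        sig = np.repeat(levels, 4)
        res = sq.align_signal(sig, cag_automata["+"], DwellPolicy(4))
        count = sq.count_str_length(res.path_states, cag_automata["+"])
        assert count.length == 15
        assert count.group_counts == {0: 5}

    def test_interrupted_unit_counts(self, cag_model):
        """A CAGG.CAGA.CAGG path counts two repeat units and one interruption."""
        left, right = "TTTCTT", "AAGAAA"
        auto = sq.build_locus_automata("(CAGG{CAGM})", left, right, cag_model.normalized())["+"]
        word = left + "CAGG" + "CAGA" + "CAGG" + right
        levels = sq.ideal_levels(word, cag_model.normalized())
        sig = np.repeat(levels, 4)
        res = sq.align_signal(sig, auto, DwellPolicy(4))
        count = sq.count_str_length(res.path_states, auto)
        assert count.length == 12
        assert count.group_counts == {0: 2}
        assert count.optional_counts == {0: 1}

    def test_zero_noise_simulated_reads_exact(self, cag_model, cag_flanks, run_config):
        from squigstr.cli import process_locus

        left, right = cag_flanks
        sim = sq.SimConfig(seed=21, noise_sd=0.0, reads_per_allele=5, pad=10)
        ds = sq.simulate_locus_dataset("(CAG)", left, right, (9, 9), cag_model, sim)
        rep = process_locus(ds.reads, "(CAG)", left, right, cag_model, run_config, "z")
        assert not rep.discards
        assert all(r.final_length == 27 for r in rep.read_results)


class TestWelchT:
    def welch_oracle(self, s1, s2):
        p = len(s1)
        v1 = statistics.pvariance(s1)
        v2 = statistics.pvariance(s2)
        return (statistics.fmean(s1) - statistics.fmean(s2)) / ((v1 + v2) / p) ** 0.5

    def test_identical_windows_zero(self):
        assert sq.welch_t(np.array([1.0, 2, 3]), np.array([1.0, 2, 3])) == 0.0

    def test_zero_variance_unequal_means_infinite(self):
        assert sq.welch_t(np.ones(4), np.full(4, 2.0)) == -np.inf
        assert sq.welch_t(np.full(4, 2.0), np.ones(4)) == np.inf

    def test_zero_variance_equal_means_zero(self):
        assert sq.welch_t(np.ones(4), np.ones(4)) == 0.0

    @pytest.mark.parametrize(
        "s1,s2",
        [
            ([0.0, 1, 0, 1], [1.0, 2, 1, 2]),
            ([0.5, 0.1, -0.3, 0.9], [1.5, -0.2, 0.4, 0.0]),
            ([3.0, 3.5], [1.0, 2.0]),
        ],
    )
    def test_matches_textbook_oracle(self, s1, s2):
        assert sq.welch_t(np.array(s1), np.array(s2)) == pytest.approx(
            self.welch_oracle(s1, s2)
        )


class TestWindowDetection:
    def _alignment_with_events(self, n_events, dwell, level=0.0):
        """Synthetic alignment over a chain automaton for window slicing."""
        class _Chain:
            pass

        path = np.repeat(np.arange(n_events), dwell)
        res = sq.AlignmentResult(0.0, path, None, DwellPolicy(4))
        return res

    def test_constant_signal_no_overrides(self):
        res = self._alignment_with_events(12, 6)
        values = np.zeros(len(res.path_states))
        assert sq.detect_short_event_windows(res, values, m_events=6, p=3) == []

    def test_window_count_partition(self):
        for n_events in (5, 6, 7, 12, 13):
            res = self._alignment_with_events(n_events, 5)
            values = np.zeros(len(res.path_states))
            windows = [
                res.event_spans()[i : i + 6]
                for i in range(0, len(res.event_spans()), 6)
            ]
            assert len(windows) == int(np.ceil(n_events / 6))

    def test_planted_shifts_trigger_override(self):
        """Eight clear level shifts inside a six-event window mark it short."""
        res = self._alignment_with_events(6, 9)  # one window, 54 points
        rng = np.random.default_rng(0)
        # 9 segments of 6 points alternating between well-separated levels
        vals = np.concatenate([
            np.full(6, 0.0 if i % 2 == 0 else 4.0) for i in range(9)
        ]) + rng.normal(0, 0.05, 54)
        over = sq.detect_short_event_windows(res, vals, m_events=6, p=3)
        assert over == [(0, 54)]

    def test_peak_counter_plateaus_count_once(self):
        vals = np.array([0.0, 5.0, 5.0, 0.0, 6.0, 0.0])
        assert _count_peaks(vals, 3.0) == 2
        assert _count_peaks(np.zeros(5), 3.0) == 0


class TestTwoPass:
    def test_zero_noise_both_passes_exact(self, cag_model, cag_flanks, cag_automata):
        left, right = cag_flanks
        sim = sq.SimConfig(seed=13, noise_sd=0.0, reads_per_allele=1, pad=0)
        ds = sq.simulate_locus_dataset("(CAG)", left, right, (10, 10), cag_model, sim)
        read = ds.reads[0]
        seg = read.signal[read.move_index[cag_model.k - 1] :]
        res = sq.run_two_pass(seg, cag_automata["+"], sq.AlignConfig())
        assert res.pass1_length == 30
        assert res.final_length == 30

    def test_distorted_reads_corrected_by_polish(self, cag_model, cag_flanks, run_config):
        from squigstr.cli import process_locus

        left, right = cag_flanks
        sim = sq.SimConfig(
            seed=5, noise_sd=3.0, reads_per_allele=10, pad=15,
            distortion=("piecewise", 90.0, 0.8, 1.25),
        )
        ds = sq.simulate_locus_dataset("(CAG)", left, right, (12, 12), cag_model, sim)
        rep = process_locus(ds.reads, "(CAG)", left, right, cag_model, run_config, "d")
        errs1 = [abs(r.pass1_length - 36) for r in rep.read_results]
        errs2 = [abs(r.final_length - 36) for r in rep.read_results]
        assert sum(e2 <= e1 for e1, e2 in zip(errs1, errs2)) >= 0.9 * len(errs1)
        assert np.median(errs2) == 0

    def test_spurious_repeat_removed_by_polish(self, cag_model, cag_flanks, run_config):
        """Regression fixture: pass 1 calls one repeat too many; the polished
        second pass removes the spurious unit."""
        from squigstr.cli import process_locus

        left, right = cag_flanks
        sim = sq.SimConfig(
            seed=20, noise_sd=4.0, reads_per_allele=2, pad=15,
            distortion=("piecewise", 85.0, 0.65, 1.2),
        )
        ds = sq.simulate_locus_dataset("(CAG)", left, right, (12, 12), cag_model, sim)
        rep = process_locus(ds.reads, "(CAG)", left, right, cag_model, run_config, "f")
        spurious = [r for r in rep.read_results if r.pass1_length > 36]
        assert spurious, "fixture lost its planted spurious repeat"
        assert all(r.final_length == 36 for r in spurious)

    def test_no_distortion_polish_rarely_changes_count(
        self, cag_model, cag_flanks, run_config, cag_cycle_gap
    ):
        from squigstr.cli import process_locus

        left, right = cag_flanks
        sim = sq.SimConfig(seed=31, noise_sd=0.2 * cag_cycle_gap, reads_per_allele=10, pad=10)
        ds = sq.simulate_locus_dataset("(CAG)", left, right, (10, 10), cag_model, sim)
        rep = process_locus(ds.reads, "(CAG)", left, right, cag_model, run_config, "n")
        truth = 30
        correct_pass1 = [r for r in rep.read_results if r.pass1_length == truth]
        changed_correct = sum(r.final_length != r.pass1_length for r in correct_pass1)
        # polishing must not perturb reads the first pass already got right...
        assert changed_correct <= 0.05 * len(correct_pass1)
        # ...and never increase the number of wrong reads overall
        errs1 = sum(r.pass1_length != truth for r in rep.read_results)
        errs2 = sum(r.final_length != truth for r in rep.read_results)
        assert errs2 <= errs1
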