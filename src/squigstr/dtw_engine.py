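"""Automaton-constrained dynamic time warping with minimum-dwell constraints.

The raw-signal segment is aligned to the locus k-mer automaton by a dynamic
program analogous to DTW: subproblem M[i, j] is the cost of the best
alignment of the first i signal points ending in state j,

    M[i, j] = min over k in {j} union pred(j) of M[i-1, k]  +  |s_i - e_j|,

with the additional constraint that every maximal run in one state must
contain at least s signal points (the minimum event size).  Because expected
levels of different states can be nearly identical, noise would otherwise be
explained by many spuriously short events, inflating the repeat count.

A first pass runs with the default s; windows of the signal whose Welch-t
context-change count exceeds the expected number of events get s reduced by
one in the second pass (adaptive event-size restriction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .locus_model import KmerAutomaton
from .signal_prep import (
    aggregate_state_signals,
    apply_polish,
    fit_polish_spline,
    normalize_median,
)

__all__ = [
    "DwellPolicy",
    "AlignmentResult",
    "AlignConfig",
    "ReadResult",
    "AlignmentInfeasibleError",
    "align_signal",
    "count_str_length",
    "StrCount",
    "welch_t",
    "detect_short_event_windows",
    "run_two_pass",
]


class AlignmentInfeasibleError(RuntimeError):
    """No dwell-feasible path covers the signal."""


@dataclass(frozen=True)
class DwellPolicy:
    """Minimum signal points per state, with per-window relaxations.

    ``overrides`` are half-open signal-index windows in which the minimum is
    reduced by one (never below 1); the requirement for a state run is looked
    up at the run's first signal index.
    """

    default_min: int = 4
    overrides: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.default_min < 1:
            raise ValueError("minimum dwell must be >= 1")

    def requirements(self, m: int) -> np.ndarray:
        req = np.full(m, self.default_min, dtype=np.int64)
        for a, b in self.overrides:
            req[max(a, 0) : min(b, m)] = max(self.default_min - 1, 1)
        return req


@dataclass
class AlignmentResult:
    """Optimal warping path through the automaton and its cost."""

    cost: float
    path_states: np.ndarray
    automaton: KmerAutomaton
    policy: DwellPolicy

    def event_spans(self) -> list[tuple[int, int, int]]:
        """Maximal constant-state runs as (start, end, state), half open."""
        path = self.path_states
        spans = []
        start = 0
        for i in range(1, len(path)):
            if path[i] != path[i - 1]:
                spans.append((start, i, int(path[i - 1])))
                start = i
        if len(path):
            spans.append((start, len(path), int(path[-1])))
        return spans


def align_signal(
    values: np.ndarray,
    automaton: KmerAutomaton,
    policy: DwellPolicy = DwellPolicy(),
) -> AlignmentResult:
    """Minimum-cost dwell-constrained path from a start to an accept state.

    The path covers every signal point in order, obeys the transition
    relation (stay, or move to a successor), starts in a start state at the
    first point and ends in an accept state at the last; cost is the sum of
    |s_i - e_j| along the path.  Ties prefer staying over moving, and earlier
    predecessors in lexicographic k-mer order.
    """
    values = np.asarray(values, dtype=float)
    m = len(values)
    n = automaton.n_states()
    smax = policy.default_min
    req = policy.requirements(m)
    if m < smax:
        raise AlignmentInfeasibleError(f"signal of {m} points shorter than minimum dwell {smax}")
    levels = automaton.levels
    predmat = automaton.pred_matrix()  # (n, P), padded with n
    INF = np.inf

    M = np.full((n + 1, smax), INF)
    cost0 = np.abs(values[0] - levels)
    for j in automaton.starts:
        M[j, req[0] - 1] = cost0[j]

    # traceback codes: >= 0 -> moved from that predecessor; < 0 -> stayed,
    # source dwell slot = -code - 1
    tb = np.zeros((m, n, smax), dtype=np.int32)
    stay_codes = np.empty((n, smax), dtype=np.int32)
    for d in range(1, smax):
        stay_codes[:, d] = -(d + 2)
    rows = np.arange(n)

    for i in range(1, m):
        cur = M[:n]
        cost = np.abs(values[i] - levels)
        stay = np.full((n, smax), INF)
        codes = stay_codes.copy()
        if smax > 1:
            stay[:, : smax - 1] = cur[:, 1:]
        use0 = cur[:, 0] <= stay[:, 0]
        stay[:, 0] = np.where(use0, cur[:, 0], stay[:, 0])
        codes[:, 0] = np.where(use0, -1, -2)

        cand = M[predmat, 0]  # (n, P)
        bi = np.argmin(cand, axis=1)  # first minimum -> lexicographic preference
        best_move = cand[rows, bi]
        best_pred = predmat[rows, bi].astype(np.int32)
        dt = req[i] - 1
        mv = best_move < stay[:, dt]
        stay[:, dt] = np.where(mv, best_move, stay[:, dt])
        codes[:, dt] = np.where(mv, best_pred, codes[:, dt])

        M[:n] = stay + cost[:, None]
        tb[i] = codes

    finals = M[automaton.accepts, 0]
    if not len(finals) or not np.isfinite(finals.min()):
        raise AlignmentInfeasibleError(
            "no dwell-feasible alignment reaches an accept state"
        )
    j = int(automaton.accepts[int(np.argmin(finals))])
    total = float(finals.min())

    path = np.empty(m, dtype=np.int64)
    d = 0
    path[m - 1] = j
    for i in range(m - 1, 0, -1):
        code = int(tb[i, j, d])
        if code >= 0:
            j, d = code, 0
        else:
            d = -code - 1
        path[i - 1] = j
    return AlignmentResult(total, path, automaton, policy)


@dataclass
class StrCount:
    """STR length (bases) and per-unit counts read off a warping path."""

    length: int
    group_counts: dict[int, int]
    optional_counts: dict[int, int]


def count_str_length(path_states: np.ndarray, automaton: KmerAutomaton) -> StrCount:
    """Count STR length and repeat-unit traversals from a warping path.

    The length is the number of transitions between distinct states whose
    destination is tagged repeat-region (one new repeat base per transition;
    flank transitions are excluded, which is the "subtract the flanks" rule).
    Per-group counts tally completed traversals of each repeat group's entry
    boundary; optional blocks are tallied per traversal.
    """
    path_states = np.asarray(path_states, dtype=np.int64)
    roles = automaton.role_codes()
    if not len(path_states) or roles[path_states[-1]] != 2:
        raise AlignmentInfeasibleError("path does not reach the right flank")
    group_counts = {}
    optional_counts = {}
    length = 0
    prev = int(path_states[0])
    for s in path_states[1:]:
        s = int(s)
        if s == prev:
            continue
        if roles[s] == 1:
            length += 1
        for kind, ident in automaton.transition_units(prev, s):
            target = group_counts if kind == "group" else optional_counts
            target[ident] = target.get(ident, 0) + 1
        prev = s
    return StrCount(length, group_counts, optional_counts)


def welch_t(s1: np.ndarray, s2: np.ndarray) -> float:
    """Welch's unequal-variances t over two equal-length half windows.

    ``t = (mean(S1) - mean(S2)) / sqrt((var(S1) + var(S2)) / p)`` with the
    population variance convention (divide by p).  Zero pooled variance gives
    0 for equal means, else a signed infinity sentinel.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    p = len(s1)
    if p != len(s2) or p < 2:
        raise ValueError("half windows must have equal length p >= 2")
    diff = s1.mean() - s2.mean()
    pooled = (s1.var() + s2.var()) / p
    if pooled == 0:
        return 0.0 if diff == 0 else float(np.sign(diff) * np.inf)
    return float(diff / np.sqrt(pooled))


def _count_peaks(absvals: np.ndarray, threshold: float) -> int:
    """Local optima of |t| above threshold; plateaus count once (earliest index).

    A run of equal values is a peak when strictly greater than both adjacent
    values (a missing neighbor at the array boundary does not disqualify).
    """
    n = len(absvals)
    peaks = 0
    i = 0
    while i < n:
        j = i
        while j + 1 < n and absvals[j + 1] == absvals[i]:
            j += 1
        left_ok = i == 0 or absvals[i - 1] < absvals[i]
        right_ok = j == n - 1 or absvals[j + 1] < absvals[i]
        if absvals[i] > threshold and left_ok and right_ok:
            peaks += 1
        i = j + 1
    return peaks


def detect_short_event_windows(
    alignment: AlignmentResult,
    values: np.ndarray,
    m_events: int = 6,
    p: int = 3,
    t_threshold: float = 3.0,
) -> list[tuple[int, int]]:
    """Signal windows with more context changes than aligned events.

    The first-pass alignment is split into non-overlapping windows of
    ``m_events`` events (ceil(#events / m) windows in total).  Each window of
    w points is scanned with a sliding 2p subwindow (w - 2p + 1 positions);
    Welch-t peaks above the threshold mark context changes.  A window with
    more peaks than events likely hides short events the dwell constraint
    suppressed, and is returned for a reduced minimum in the second pass.
    Windows shorter than 2p are skipped.
    """
    values = np.asarray(values, dtype=float)
    spans = alignment.event_spans()
    overrides = []
    for w0 in range(0, len(spans), m_events):
        chunk = spans[w0 : w0 + m_events]
        a, b = chunk[0][0], chunk[-1][1]
        w = values[a:b]
        if len(w) < 2 * p:
            continue
        tvals = np.array(
            [welch_t(w[q : q + p], w[q + p : q + 2 * p]) for q in range(len(w) - 2 * p + 1)]
        )
        if _count_peaks(np.abs(tvals), t_threshold) > m_events:
            overrides.append((a, b))
    return overrides


# ---------------------------------------------------------------------------
# Two-pass per-read pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignConfig:
    """Knobs of the per-read two-pass alignment."""

    min_dwell: int = 4           # default minimum event size s
    m_events: int = 6            # events per adaptive-restriction window
    half_window: int = 3         # p, Welch-t half window (signal points)
    t_threshold: float = 3.0     # |t| extremeness threshold for peaks
    spline_max_deviation: float = 2.0
    spline_sd_factor: float = 1.5
    spline_min_pairs: int = 8
    min_signal_points: int = 20


@dataclass
class ReadResult:
    """Per-read outcome of the two-pass alignment."""

    read_id: str
    strand: str
    pass1_length: int
    final_length: int
    pass1_cost: float
    final_cost: float
    group_counts: dict[int, int]
    optional_counts: dict[int, int]
    polished: bool
    n_window_overrides: int


def run_two_pass(
    segment: np.ndarray,
    automaton: KmerAutomaton,
    config: AlignConfig = AlignConfig(),
    read_id: str = "",
    strand: str = "+",
) -> ReadResult:
    """Normalize, align, polish, re-align with adaptive dwell, and count.

    Pipeline: median-normalize the extracted segment; align with the default
    minimum event size; aggregate per-state signal statistics; fit and apply
    the polishing spline; detect short-event windows; re-align the polished
    signal with per-window relaxed dwell; count the final STR length.
    """
    norm = normalize_median(segment, config.min_signal_points)
    policy1 = DwellPolicy(config.min_dwell)
    aln1 = align_signal(norm.values, automaton, policy1)
    count1 = count_str_length(aln1.path_states, automaton)

    aggs = aggregate_state_signals(aln1.path_states, norm.values)
    spline = fit_polish_spline(
        [a.mean for a in aggs],
        [automaton.levels[a.state] for a in aggs],
        [a.sd for a in aggs],
        max_deviation=config.spline_max_deviation,
        sd_factor=config.spline_sd_factor,
        min_pairs=config.spline_min_pairs,
    )
    polished = apply_polish(norm.values, spline)
    overrides = detect_short_event_windows(
        aln1, polished, config.m_events, config.half_window, config.t_threshold
    )
    policy2 = DwellPolicy(config.min_dwell, tuple(overrides))
    aln2 = align_signal(polished, automaton, policy2)
    count2 = count_str_length(aln2.path_states, automaton)
    return ReadResult(
        read_id=read_id,
        strand=strand,
        pass1_length=count1.length,
        final_length=count2.length,
        pass1_cost=aln1.cost,
        final_cost=aln2.cost,
        group_counts=count2.group_counts,
        optional_counts=count2.optional_counts,
        polished=not spline.is_identity,
        n_window_overrides=len(overrides),
    )
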