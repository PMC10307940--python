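"""Read records, flank localization, signal extraction, normalization, polishing.

A nanopore read enters the pipeline as a :class:`ReadRecord`: the raw current
trace, the basecalled sequence, and the basecall-to-signal index map (for each
called base, the first signal index of its event).  Flanking sequences of the
locus are located in the basecall by local alignment; the index map then
excises the STR-spanning raw-signal segment, which is median-normalized and,
after a first alignment pass, polished by a spline mapping observed per-state
signal means onto the expected pore-model levels.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from scipy.interpolate import PchipInterpolator, make_smoothing_spline
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "ReadRecord",
    "NormalizedSignal",
    "PolishSpline",
    "StateAggregate",
    "FlankNotFoundError",
    "SegmentError",
    "DegenerateSignalError",
    "FlankHit",
    "locate_flanks",
    "extract_signal_segment",
    "normalize_median",
    "aggregate_state_signals",
    "fit_polish_spline",
    "apply_polish",
    "baseline_length_from_basecall",
    "write_reads",
    "read_reads",
]


class FlankNotFoundError(RuntimeError):
    """Flank localization failed (low score, or out-of-order hits)."""


class SegmentError(RuntimeError):
    """Signal extraction produced an empty slice."""


class DegenerateSignalError(RuntimeError):
    """Signal cannot be normalized (constant, or too short)."""


@dataclass
class ReadRecord:
    """One sequencing read: raw signal, basecall, and their index mapping.

    ``move_index[i]`` is the first raw-signal index of the event of called
    base ``i``; it is nondecreasing with one entry per base.  ``strand`` is
    the read's mapped strand; the basecall and signal are always in the
    read's native orientation.
    """

    read_id: str
    signal: np.ndarray
    basecall: str
    move_index: np.ndarray
    strand: str = "+"
    mapping: tuple | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.move_index = np.asarray(self.move_index, dtype=np.int64)
        if len(self.move_index) != len(self.basecall):
            raise ValueError("move_index length must equal basecall length")
        if len(self.move_index) and (
            np.any(np.diff(self.move_index) < 0)
            or self.move_index[0] < 0
            or self.move_index[-1] >= len(self.signal)
        ):
            raise ValueError("move_index must be nondecreasing indices into the signal")
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class NormalizedSignal:
    """Median-normalized signal: ``values = (raw - shift) / scale``."""

    values: np.ndarray
    shift: float
    scale: float


@dataclass
class StateAggregate:
    """Signal statistics for one automaton state of an alignment path."""

    state: int
    mean: float
    sd: float
    count: int


@dataclass
class FlankHit:
    left: tuple[int, int]
    right: tuple[int, int]
    left_score: float
    right_score: float


# ---------------------------------------------------------------------------
# Per-read container (JSON lines, one read per line)
# ---------------------------------------------------------------------------

def write_reads(path, reads: Iterable[ReadRecord]) -> None:
    """Write reads to the canonical JSONL container (one JSON object/line)."""
    with open(path, "w") as fh:
        for r in reads:
            obj = {
                "read_id": r.read_id,
                "strand": r.strand,
                "basecall": r.basecall,
                "move_index": r.move_index.tolist(),
                "signal": np.round(r.signal, 6).tolist(),
            }
            if r.meta:
                obj["meta"] = r.meta
            fh.write(json.dumps(obj) + "\n")


def read_reads(path) -> list[ReadRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            out.append(
                ReadRecord(
                    read_id=obj["read_id"],
                    signal=np.array(obj["signal"], dtype=float),
                    basecall=obj["basecall"],
                    move_index=np.array(obj["move_index"], dtype=np.int64),
                    strand=obj.get("strand", "+"),
                    meta=obj.get("meta", {}),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Flank localization and signal extraction
# ---------------------------------------------------------------------------

def _local_aligner(match: float, mismatch: float, gap: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return aligner


def _best_local_hit(aligner, target: str, query: str) -> tuple[tuple[int, int], float]:
    alignments = aligner.align(target, query)
    try:
        best = alignments[0]
    except IndexError:
        return (0, 0), float("-inf")
    blocks = best.aligned[0]
    return (int(blocks[0][0]), int(blocks[-1][1])), float(best.score)


def locate_flanks(
    read: ReadRecord,
    left_flank: str,
    right_flank: str,
    min_score_frac: float = 0.7,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -1.0,
) -> FlankHit:
    """Locate flank sequences in the basecall by local alignment.

    Flanks must be given in the read's orientation (for a reverse-strand read
    that is the reverse complement of the reference flanks, in swapped order).
    Returns basecall-coordinate intervals; the left interval must end before
    the right interval starts, and each score must reach
    ``min_score_frac * len(flank)``, else :class:`FlankNotFoundError`.
    """
    if not read.basecall:
        raise FlankNotFoundError("empty basecall")
    aligner = _local_aligner(match, mismatch, gap)
    left_iv, left_score = _best_local_hit(aligner, read.basecall, left_flank)
    right_iv, right_score = _best_local_hit(aligner, read.basecall, right_flank)
    if left_score < min_score_frac * len(left_flank):
        raise FlankNotFoundError(
            f"left flank score {left_score:.1f} below threshold "
            f"{min_score_frac * len(left_flank):.1f}"
        )
    if right_score < min_score_frac * len(right_flank):
        raise FlankNotFoundError(
            f"right flank score {right_score:.1f} below threshold "
            f"{min_score_frac * len(right_flank):.1f}"
        )
    if left_iv[1] > right_iv[0]:
        raise FlankNotFoundError(
            f"flank hits out of order: left {left_iv}, right {right_iv}"
        )
    return FlankHit(left_iv, right_iv, left_score, right_score)


def extract_signal_segment(read: ReadRecord, interval: tuple[int, int]) -> np.ndarray:
    """Raw-signal slice spanned by a half-open basecall interval.

    The slice runs from the first signal index of the interval's first base
    to the first signal index of the base after the interval.
    """
    b0, b1 = interval
    if not (0 <= b0 < b1 <= len(read.basecall)):
        raise SegmentError(f"basecall interval {interval} outside read of length {len(read.basecall)}")
    s0 = int(read.move_index[b0])
    s1 = int(read.move_index[b1]) if b1 < len(read.basecall) else len(read.signal)
    if s1 <= s0:
        raise SegmentError(f"empty signal slice for basecall interval {interval}")
    return read.signal[s0:s1]


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def normalize_median(raw: np.ndarray, min_length: int = 20) -> NormalizedSignal:
    """Median normalization: mid-percentile shift, median-absolute-deviation scale.

    ``shift = (perc46.5(R) + perc53.5(R)) / 2``, ``scale = median |r - shift|``
    (percentiles with linear interpolation between order statistics).  The
    normalized values satisfy ``median |s| == 1``.
    """
    raw = np.asarray(raw, dtype=float)
    if len(raw) < min_length:
        raise DegenerateSignalError(f"signal of {len(raw)} points is below minimum {min_length}")
    shift = 0.5 * (np.percentile(raw, 46.5) + np.percentile(raw, 53.5))
    scale = float(np.median(np.abs(raw - shift)))
    if scale == 0:
        raise DegenerateSignalError("constant signal: zero scale")
    return NormalizedSignal((raw - shift) / scale, float(shift), scale)


# ---------------------------------------------------------------------------
# Per-state aggregation and spline polishing
# ---------------------------------------------------------------------------

def aggregate_state_signals(path_states: np.ndarray, values: np.ndarray) -> list[StateAggregate]:
    """Mean/SD/count of signal values per visited state of an alignment path.

    A state visited in several separate runs pools all of its points.  The
    counts partition the signal: they sum to ``len(values)``.
    """
    path_states = np.asarray(path_states, dtype=np.int64)
    values = np.asarray(values, dtype=float)
    if len(path_states) != len(values):
        raise ValueError("path and signal lengths differ")
    n = int(path_states.max()) + 1 if len(path_states) else 0
    counts = np.bincount(path_states, minlength=n)
    sums = np.bincount(path_states, weights=values, minlength=n)
    sqs = np.bincount(path_states, weights=values**2, minlength=n)
    out = []
    for j in np.nonzero(counts)[0]:
        c = int(counts[j])
        mean = sums[j] / c
        var = max(sqs[j] / c - mean**2, 0.0)
        out.append(StateAggregate(int(j), float(mean), float(np.sqrt(var)), c))
    return out


@dataclass
class PolishSpline:
    """Monotone-range mapping from observed to expected signal values.

    Inside the retained control range the fitted B-spline is evaluated;
    outside it the map extrapolates linearly with the boundary slope.  An
    identity instance (``spline is None``) is used when too few control pairs
    survive filtering.
    """

    spline: object | None
    x_range: tuple[float, float] = (0.0, 0.0)
    boundary_slopes: tuple[float, float] = (1.0, 1.0)
    control_points: tuple = ()

    @property
    def is_identity(self) -> bool:
        return self.spline is None

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        if self.spline is None:
            return x.copy()
        lo, hi = self.x_range
        y = self.spline(np.clip(x, lo, hi))
        flo, fhi = self.spline(lo), self.spline(hi)
        dlo, dhi = self.boundary_slopes
        y = np.where(x < lo, flo + dlo * (x - lo), y)
        y = np.where(x > hi, fhi + dhi * (x - hi), y)
        return y


def fit_polish_spline(
    observed: Sequence[float],
    expected: Sequence[float],
    sds: Sequence[float],
    max_deviation: float = 2.0,
    sd_factor: float = 1.5,
    min_pairs: int = 8,
    merge_tol: float = 0.05,
) -> PolishSpline:
    """Fit the polishing spline on retained (observed mean, expected level) pairs.

    Pairs where the observed state mean is too far from the expected level
    (``|m - e| > max_deviation``) or whose SD exceeds ``sd_factor`` times the
    median SD are dropped as likely misalignments.  With fewer than
    ``min_pairs`` survivors, polishing is skipped (identity, with a warning).
    The spline is a cubic smoothing B-spline with GCV-selected smoothing,
    falling back to interpolation when the fit is not possible.
    """
    m = np.asarray(observed, dtype=float)
    e = np.asarray(expected, dtype=float)
    s = np.asarray(sds, dtype=float)
    med_sd = np.median(s) if len(s) else 0.0
    keep = (np.abs(m - e) <= max_deviation) & ~(s > sd_factor * med_sd)
    m, e = m[keep], e[keep]
    if keep.sum() < min_pairs:
        warnings.warn(
            f"only {int(keep.sum())} control pairs after filtering "
            f"(minimum {min_pairs}); polishing skipped",
            stacklevel=2,
        )
        return PolishSpline(None)
    order = np.argsort(m)
    m, e = m[order], e[order]
    # merge near-coincident abscissae: two states whose observed means agree
    # within merge_tol but disagree in expected level are contradictory
    # control points (misalignment); their expected levels are averaged
    bins = np.concatenate([[0], np.cumsum(np.diff(m) > merge_tol)])
    counts = np.bincount(bins)
    ux = np.bincount(bins, weights=m) / counts
    uy = np.bincount(bins, weights=e) / counts
    if len(ux) < min_pairs:
        warnings.warn("too few distinct control abscissae; polishing skipped", stacklevel=2)
        return PolishSpline(None)
    # the transform is monotone by construction of the signal scale:
    # project expected levels onto a nondecreasing sequence first
    iso = IsotonicRegression(increasing=True)
    uy = iso.fit_transform(ux, uy)
    try:
        spline = make_smoothing_spline(ux, uy)
        grid = np.linspace(ux[0], ux[-1], 200)
        vals = spline(grid)
        span = uy[-1] - uy[0]
        if np.any(np.diff(vals) < -1e-6 * max(span, 1.0)) or np.any(
            (vals < uy[0] - 0.5 * span) | (vals > uy[-1] + 0.5 * span)
        ):
            raise ValueError("smoothing spline not monotone on control range")
    except Exception:
        # monotone piecewise-cubic interpolant through the control points
        spline = PchipInterpolator(ux, uy)
    deriv = spline.derivative()
    return PolishSpline(
        spline,
        (float(ux[0]), float(ux[-1])),
        (float(deriv(ux[0])), float(deriv(ux[-1]))),
        tuple(zip(ux.tolist(), uy.tolist())),
    )


def apply_polish(signal: NormalizedSignal | np.ndarray, f: PolishSpline) -> np.ndarray:
    """Apply the polishing map pointwise; length is preserved."""
    values = signal.values if isinstance(signal, NormalizedSignal) else np.asarray(signal, float)
    return f(values)


# ---------------------------------------------------------------------------
# Basecall-distance baseline
# ---------------------------------------------------------------------------

def baseline_length_from_basecall(
    read: ReadRecord,
    left_flank: str,
    right_flank: str,
    **flank_kwargs,
) -> int:
    """Baseline STR length: basecall distance between the two flank matches.

    Predicts the allele length as (start of right-flank hit) minus (end of
    left-flank hit); raises :class:`FlankNotFoundError` when either flank
    fails, which callers count toward the discard rate.
    """
    hit = locate_flanks(read, left_flank, right_flank, **flank_kwargs)
    return hit.right[0] - hit.left[1]
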