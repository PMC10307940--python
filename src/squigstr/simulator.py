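"""Synthetic pore models, squiggles and diploid locus datasets with known truth.

The simulator plays the role of the sequencer + basecaller: it turns a known
nucleotide sequence into a raw current trace by emitting, for each k-mer
context, a geometric-length dwell of points at the context's expected level
plus Gaussian noise, then shifts/scales the trace per read the way each pore
reports a different baseline.  An optional monotone piecewise-affine
distortion of the expected levels emulates the systematic deviation between
median-normalized signal and the pore-model table that the polishing phase
exists to correct.  Basecalls are emitted idealized (optionally with uniform
substitution noise), with an exact base-to-signal move map, and every
quantity later used as truth is recorded at generation time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .locus_model import (
    PoreModel,
    RepeatExpression,
    instantiate_expression,
    parse_repeat_expression,
    reverse_complement,
)
from .signal_prep import ReadRecord
from .truth_eval import TruthCall

__all__ = [
    "SimConfig",
    "make_synthetic_pore_model",
    "apply_distortion",
    "ideal_levels",
    "simulate_read",
    "simulate_locus_dataset",
    "LocusDataset",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the simulator.

    Dwell per k-mer context is a shifted geometric with configurable mean
    (default 8.5 points, the typical pore translocation rate) and minimum
    (default 3 points, emulating the lower bound real event segmentation
    imposes on event durations).  Noise is
    Gaussian per signal point, in pore-model units.  Each read gets its own
    baseline shift and scale, removed later by median normalization.
    ``distortion`` is None, a callable on level arrays, or one of
    ``("affine", a, b)`` / ``("piecewise", pivot, slope_lo, slope_hi)``
    applied to expected levels (monotone, hence invertible).
    """

    seed: int = 0
    dwell_mean: float = 8.5
    dwell_min: int = 3
    noise_sd: float = 0.0
    scale_range: tuple[float, float] = (1.8, 2.2)
    shift_range: tuple[float, float] = (180.0, 220.0)
    distortion: object = None
    pad: int = 20
    substitution_rate: float = 0.0
    reads_per_allele: int = 10

    def __post_init__(self) -> None:
        if self.dwell_mean < 1 or self.dwell_min < 1:
            raise ValueError("dwell mean and minimum must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise SD must be >= 0")


def kmers_of(sequence: str, k: int) -> set[str]:
    """All overlapping k-mers of a sequence."""
    return {sequence[i : i + k] for i in range(len(sequence) - k + 1)}


def repeat_cycle_kmers(motif: str, k: int) -> set[str]:
    """k-mers occurring in the periodic interior of a pure motif repeat."""
    tiled = motif * (k // len(motif) + 2)
    return {tiled[i : i + k] for i in range(len(motif))}


def make_synthetic_pore_model(
    k: int,
    seed: int,
    level_range: tuple[float, float] = (60.0, 120.0),
    separate_kmers: Sequence[str] | None = None,
    min_separation: float = 12.0,
    max_tries: int = 10_000,
) -> PoreModel:
    """Synthetic k-mer table: a random permutation of an even level grid.

    All 4^k levels are an evenly spaced grid over ``level_range`` shuffled by
    the seed, so any two k-mers are separated by at least
    ``span / (4^k - 1)``.  ``separate_kmers`` lists groups of k-mers that
    must be mutually distinguishable because they co-occur in one test
    automaton (each entry is a sequence whose k-mers form a group, e.g. a
    tiled repeat motif per strand); permutations are redrawn
    deterministically until every group is pairwise separated by at least
    ``min_separation``, putting neighboring automaton states safely above
    the noise floor.  Deterministic under the seed.
    """
    if not 2 <= k <= 6:
        raise ValueError("k must be in [2, 6]")
    rng = np.random.default_rng(seed)
    kmers = ["".join(p) for p in _product_acgt(k)]
    grid = np.linspace(level_range[0], level_range[1], len(kmers))
    index = {km: i for i, km in enumerate(kmers)}
    groups: list[np.ndarray] = []
    for s in separate_kmers or ():
        fset = kmers_of(s, k) if len(s) > k else {s}
        for km in fset:
            if km not in index:
                raise ValueError(f"unknown k-mer {km!r} for k={k}")
        groups.append(np.array([index[km] for km in sorted(fset)]))
    for _ in range(max_tries):
        levels = rng.permutation(grid)
        ok = all(
            len(g) < 2 or np.diff(np.sort(levels[g])).min() >= min_separation
            for g in groups
        )
        if ok:
            break
    else:
        raise RuntimeError(
            f"could not separate the k-mer groups by {min_separation} "
            f"within {max_tries} draws"
        )
    return PoreModel(k, dict(zip(kmers, levels)))


def _product_acgt(k: int):
    import itertools

    return itertools.product("ACGT", repeat=k)


def apply_distortion(levels: np.ndarray, distortion) -> np.ndarray:
    """Apply a level distortion spec (see :class:`SimConfig`)."""
    levels = np.asarray(levels, dtype=float)
    if distortion is None:
        return levels
    if callable(distortion):
        return np.asarray(distortion(levels), dtype=float)
    kind = distortion[0]
    if kind == "affine":
        _, a, b = distortion
        return a * levels + b
    if kind == "piecewise":
        _, pivot, slope_lo, slope_hi = distortion
        lo = pivot + slope_lo * (levels - pivot)
        hi = pivot + slope_hi * (levels - pivot)
        return np.where(levels < pivot, lo, hi)
    raise ValueError(f"unknown distortion spec {distortion!r}")


def ideal_levels(sequence: str, model: PoreModel) -> np.ndarray:
    """Expected level of each overlapping k-mer of a sequence."""
    k = model.k
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than k={k}")
    return np.array([model.level(sequence[i : i + k]) for i in range(len(sequence) - k + 1)])


def simulate_read(
    sequence: str,
    model: PoreModel,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    read_id: str = "read",
    strand: str = "+",
) -> tuple[ReadRecord, dict]:
    """Generate one squiggle read from a known sequence.

    Returns the read record plus truth annotations: per-k-mer dwells, the
    read's baseline shift/scale, and event start indices.  The move map
    assigns each called base the start of the event of the k-mer it
    completes (the first k-1 bases share the first event start).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    k = model.k
    levels = apply_distortion(ideal_levels(sequence, model), config.distortion)
    n_kmers = len(levels)
    mean_extra = config.dwell_mean - config.dwell_min
    if mean_extra > 0:
        dwells = config.dwell_min - 1 + rng.geometric(1.0 / (mean_extra + 1), size=n_kmers)
    else:
        dwells = np.full(n_kmers, config.dwell_min, dtype=np.int64)
    points = np.repeat(levels, dwells)
    if config.noise_sd > 0:
        points = points + rng.normal(0.0, config.noise_sd, size=len(points))
    scale = rng.uniform(*config.scale_range)
    shift = rng.uniform(*config.shift_range)
    raw = scale * points + shift
    event_starts = np.concatenate([[0], np.cumsum(dwells)[:-1]])
    move_index = np.empty(len(sequence), dtype=np.int64)
    move_index[: k - 1] = 0
    move_index[k - 1 :] = event_starts
    basecall = sequence
    if config.substitution_rate > 0:
        bases = np.frombuffer(sequence.encode(), dtype="S1").astype("U1")
        hit = rng.random(len(bases)) < config.substitution_rate
        for i in np.nonzero(hit)[0]:
            choices = [c for c in "ACGT" if c != bases[i]]
            bases[i] = choices[rng.integers(3)]
        basecall = "".join(bases)
    record = ReadRecord(
        read_id=read_id,
        signal=raw,
        basecall=basecall,
        move_index=move_index,
        strand=strand,
    )
    truth = {
        "dwells": dwells,
        "event_starts": event_starts,
        "scale": float(scale),
        "shift": float(shift),
        "sequence": sequence,
    }
    return record, truth


@dataclass
class LocusDataset:
    """Simulated diploid locus: reads plus complete ground truth."""

    reads: list[ReadRecord]
    truth: TruthCall
    left_flank: str
    right_flank: str
    expression: str
    read_truth: list[dict]


def simulate_locus_dataset(
    expr: RepeatExpression | str,
    left_flank: str,
    right_flank: str,
    alleles: tuple[int, int],
    model: PoreModel,
    config: SimConfig,
    locus_id: str = "locus",
) -> LocusDataset:
    """Simulate a diploid read set for a locus with known allele lengths.

    ``alleles`` are repeat counts per allele (applied to every repeat group
    of the expression); reads are split evenly between alleles and strands.
    Truth allele lengths are the instantiated STR lengths in bases.  Reverse
    reads carry the reverse-complemented sequence with signal in its native
    temporal order.
    """
    if isinstance(expr, str):
        expr = parse_repeat_expression(expr)
    c1, c2 = alleles
    if c1 < 1 or c2 < 1:
        raise ValueError("allele repeat counts must be >= 1")
    rng = np.random.default_rng(config.seed)
    str_seqs = [instantiate_expression(expr, c) for c in (c1, c2)]
    lengths = sorted(len(s) for s in str_seqs)
    zyg = "homozygous" if lengths[0] == lengths[1] else "heterozygous"
    truth = TruthCall(locus_id, (lengths[0], lengths[1]), zyg)
    reads: list[ReadRecord] = []
    read_truth: list[dict] = []
    idx = 0
    for allele, str_seq in enumerate(str_seqs):
        for r in range(config.reads_per_allele):
            pad_l = "".join(rng.choice(list("ACGT"), size=config.pad)) if config.pad else ""
            pad_r = "".join(rng.choice(list("ACGT"), size=config.pad)) if config.pad else ""
            seq = pad_l + left_flank + str_seq + right_flank + pad_r
            strand = "+" if idx % 2 == 0 else "-"
            if strand == "-":
                seq = reverse_complement(seq)
            rec, t = simulate_read(
                seq, model, config, rng, read_id=f"{locus_id}_a{allele}_r{r}", strand=strand
            )
            t["allele"] = allele
            t["str_length"] = len(str_seq)
            rec.meta.update({"allele": allele, "str_length": len(str_seq)})
            reads.append(rec)
            read_truth.append(t)
            idx += 1
    return LocusDataset(reads, truth, left_flank, right_flank, expr.to_string(), read_truth)
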