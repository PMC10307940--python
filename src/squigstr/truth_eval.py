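"""Gold-standard allele lengths from benchmark VCFs and evaluation metrics.

Benchmark VCFs give per-locus indel records with genotypes; per haplotype,
the true allele length is the reference STR length plus the signed length
deltas of that haplotype's variants.  Estimates from several callers are
combined by a consensus rule before a locus is accepted as ground truth.
Prediction quality is scored by per-read MAE/MedAE (distance to the nearer
truth allele) and by the genotype distance D (summed absolute allele-length
error of the final call).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "SimpleVariant",
    "TruthCall",
    "LocusErrors",
    "LocusDiscarded",
    "derive_allele_lengths",
    "consensus_truth",
    "locus_errors",
    "genotype_distance",
    "passes_locus_filters",
    "variants_from_vcf",
]


class LocusDiscarded(ValueError):
    """Locus cannot yield a truth call; carries the discard reason."""


@dataclass(frozen=True)
class SimpleVariant:
    """One indel/substitution record overlapping a locus.

    ``genotype`` is a pair of allele indices (0 = reference, i >= 1 = the
    i-th alternative); unphased heterozygous records conventionally carry the
    alternative on the second haplotype slot.
    """

    ref: str
    alts: tuple[str, ...]
    genotype: tuple[int, int]
    pos: int | None = None

    def delta(self, allele_index: int) -> int:
        if allele_index == 0:
            return 0
        return len(self.alts[allele_index - 1]) - len(self.ref)


@dataclass(frozen=True)
class TruthCall:
    """Gold-standard diploid allele lengths for a locus."""

    locus_id: str
    alleles: tuple[int, int]     # sorted ascending
    zygosity: str
    n_supporting: int = 0

    @property
    def allele_pair(self) -> tuple[int, int]:
        return self.alleles


@dataclass
class LocusErrors:
    """Per-read error summary against a truth allele pair (all values >= 0)."""

    mae: float
    medae: float
    per_read: np.ndarray


def derive_allele_lengths(
    reference_length: int,
    variants: Sequence[SimpleVariant],
) -> tuple[int, int]:
    """True allele lengths from a locus's variant records.

    Each haplotype's length is the reference allele length plus the sum of
    its insertion lengths minus its deletion lengths.  For example, reference
    length 40 with a heterozygous 4-base insertion and a homozygous 2-base
    deletion yields alleles (38, 42).  Overlapping records (when positions
    are given) discard the locus.
    """
    positioned = [v for v in variants if v.pos is not None]
    positioned.sort(key=lambda v: v.pos)
    for a, b in zip(positioned, positioned[1:]):
        if a.pos + len(a.ref) > b.pos:
            raise LocusDiscarded(
                f"overlapping variant records at positions {a.pos} and {b.pos}"
            )
    deltas = [0, 0]
    for v in variants:
        for hap in (0, 1):
            deltas[hap] += v.delta(v.genotype[hap])
    lengths = sorted(reference_length + d for d in deltas)
    if lengths[0] < 0:
        raise LocusDiscarded(f"negative allele length {lengths[0]}")
    return (lengths[0], lengths[1])


def consensus_truth(
    estimates: Sequence[tuple[int, int]],
    locus_id: str = "",
) -> tuple[TruthCall | None, str]:
    """Combine per-caller allele-length estimates into a truth call.

    A single caller is discarded; two callers must agree exactly; with k >= 3
    callers at least k-1 must share one estimate.  Returns (call, reason);
    the call is None when the locus is discarded.
    """
    norm = [tuple(sorted(e)) for e in estimates]
    k = len(norm)
    if k == 0:
        return None, "no caller estimates"
    if k == 1:
        return None, "only one caller"
    counts: dict[tuple[int, int], int] = {}
    for e in norm:
        counts[e] = counts.get(e, 0) + 1
    best, support = max(counts.items(), key=lambda kv: kv[1])
    required = 2 if k == 2 else k - 1
    if support < required:
        return None, f"no consensus: best estimate supported by {support}/{k} callers"
    zygosity = "homozygous" if best[0] == best[1] else "heterozygous"
    return TruthCall(locus_id, best, zygosity, support), "consensus"


def locus_errors(calls: Sequence[float], truth: tuple[int, int]) -> LocusErrors:
    """Per-read minimum distance to either truth allele; MAE and MedAE."""
    calls = np.asarray(calls, dtype=float)
    if len(calls) == 0:
        raise ValueError("no calls")
    m1, m2 = truth
    per_read = np.minimum(np.abs(calls - m1), np.abs(calls - m2))
    return LocusErrors(float(per_read.mean()), float(np.median(per_read)), per_read)


def genotype_distance(
    predicted: Sequence[int],
    truth: Sequence[int],
) -> int:
    """Genotype distance D between a predicted and a true allele set.

    With both sides homozygous (single values), D = |y - m|.  Otherwise the
    homozygous side's single allele is duplicated, both pairs are sorted and
    D = |y1 - m1| + |y2 - m2|.
    """
    pred = tuple(predicted)
    tru = tuple(truth)
    if not 1 <= len(pred) <= 2 or not 1 <= len(tru) <= 2:
        raise ValueError("allele sets must have 1 or 2 entries")
    pred_hom = len(pred) == 1 or pred[0] == pred[1]
    tru_hom = len(tru) == 1 or tru[0] == tru[1]
    if pred_hom and tru_hom:
        return abs(pred[0] - tru[0])
    p = sorted(pred * 2 if len(pred) == 1 else pred)
    t = sorted(tru * 2 if len(tru) == 1 else tru)
    return abs(p[0] - t[0]) + abs(p[1] - t[1])


def passes_locus_filters(
    motif: str,
    reference_region: str,
    min_motif: int = 2,
    max_motif: int = 6,
    min_region: int = 31,
    max_homopolymer: int = 6,
) -> bool:
    """Benchmark locus-selection filter: motif length 2-6, region > 30 bp,
    no homopolymer run longer than 6 in the reference region."""
    if not (min_motif <= len(motif) <= max_motif):
        return False
    if len(reference_region) < min_region:
        return False
    run = 1
    for a, b in zip(reference_region, reference_region[1:]):
        run = run + 1 if a == b else 1
        if run > max_homopolymer:
            return False
    return True


def variants_from_vcf(path, chrom: str, start: int, end: int) -> list[SimpleVariant]:
    """Read locus-overlapping variant records from a VCF (first sample).

    Coordinates are 0-based half-open.  Multi-allelic records are kept with
    their allele indices; records without a genotype are skipped with a
    warning.
    """
    import pysam

    out: list[SimpleVariant] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf.fetch(chrom, start, end) if vcf.index is not None else (
            r for r in vcf if r.chrom == chrom and start < r.stop and r.start < end
        ):
            if not rec.samples:
                warnings.warn(f"record at {rec.chrom}:{rec.pos} has no sample; skipped")
                continue
            sample = rec.samples[0]
            gt = sample.get("GT")
            if gt is None or any(a is None for a in gt):
                warnings.warn(f"record at {rec.chrom}:{rec.pos} has no genotype; skipped")
                continue
            if len(gt) == 1:
                gt = (gt[0], gt[0])
            out.append(
                SimpleVariant(
                    ref=rec.ref,
                    alts=tuple(rec.alts or ()),
                    genotype=(int(gt[0]), int(gt[1])),
                    pos=rec.start,
                )
            )
    return out
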