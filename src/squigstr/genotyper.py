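"""Diploid genotype calls from per-read STR length estimates.

Per-read estimates at a locus are first cleaned of outliers (further than two
standard deviations from the mean), then clustered with a Bayesian Gaussian
mixture of at most two components.  If the smaller cluster holds no more than
a fifth of the reads the locus is called homozygous and the overall median
length is reported; otherwise it is heterozygous and the two cluster medians
are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.mixture import BayesianGaussianMixture

__all__ = ["GenotypeConfig", "GenotypeCall", "filter_outliers", "genotype"]


@dataclass(frozen=True)
class GenotypeConfig:
    """Mixture and decision-rule settings.

    Defaults: tied covariance, weight concentration prior 0.25, 5
    initializations, 1000 iterations, homozygosity when the smaller cluster
    does not exceed 20% of all unfiltered reads, 2-SD outlier filter.
    """

    min_reads: int = 3
    outlier_sd: float = 2.0
    max_components: int = 2
    weight_concentration_prior: float = 0.25
    n_init: int = 5
    max_iter: int = 1000
    homozygous_fraction: float = 0.20
    # denominator of the homozygosity fraction: reads entering the genotyper
    # ("unfiltered") or reads surviving the outlier filter ("filtered")
    fraction_denominator: str = "unfiltered"
    seed: int = 0


@dataclass
class GenotypeCall:
    """Genotype of one locus: zygosity plus 1-2 allele lengths."""

    status: str                      # "called" | "no_call"
    zygosity: str | None = None      # "homozygous" | "heterozygous"
    alleles: tuple[int, ...] = ()
    cluster_labels: tuple[int, ...] = ()
    cluster_counts: tuple[int, ...] = ()
    filtered_indices: tuple[int, ...] = ()
    reason: str | None = None

    @property
    def is_called(self) -> bool:
        return self.status == "called"


def filter_outliers(lengths: Sequence[float]) -> list:
    """Drop estimates further than two SDs (population) from the mean.

    A zero SD (all estimates equal, or a single estimate) retains everything.
    """
    arr = np.asarray(lengths, dtype=float)
    if len(arr) == 0:
        raise ValueError("no length estimates")
    mean, sd = arr.mean(), arr.std()
    keep = np.abs(arr - mean) <= 2.0 * sd
    return [lengths[i] for i in np.nonzero(keep)[0]]


def _lower_median(values: Sequence) -> int:
    s = sorted(values)
    return int(s[(len(s) - 1) // 2])


def genotype(lengths: Sequence[int], config: GenotypeConfig = GenotypeConfig()) -> GenotypeCall:
    """Call a diploid genotype from per-read length estimates.

    Deterministic under a fixed config seed.  Allele lengths are reported as
    lower medians (integer alleles) sorted ascending.
    """
    arr = np.asarray(lengths, dtype=float)
    if len(arr) == 0:
        return GenotypeCall("no_call", reason="no reads")
    mean, sd = arr.mean(), arr.std()
    keep_mask = np.abs(arr - mean) <= config.outlier_sd * sd
    retained = arr[keep_mask]
    filtered_idx = tuple(int(i) for i in np.nonzero(~keep_mask)[0])
    if len(retained) < config.min_reads:
        return GenotypeCall(
            "no_call",
            filtered_indices=filtered_idx,
            reason=f"{len(retained)} reads after outlier filtering "
            f"(minimum {config.min_reads})",
        )
    denominator = len(arr) if config.fraction_denominator == "unfiltered" else len(retained)

    if np.unique(retained).size == 1:
        labels = np.zeros(len(retained), dtype=int)
    else:
        gmm = BayesianGaussianMixture(
            n_components=config.max_components,
            covariance_type="tied",
            weight_concentration_prior=config.weight_concentration_prior,
            n_init=config.n_init,
            max_iter=config.max_iter,
            random_state=config.seed,
        )
        labels = gmm.fit_predict(retained.reshape(-1, 1))

    uniq, counts = np.unique(labels, return_counts=True)
    cluster_counts = tuple(int(c) for c in counts)
    smaller = int(counts.min()) if len(uniq) > 1 else 0
    homozygous = smaller <= config.homozygous_fraction * denominator
    if not homozygous:
        medians = sorted(
            _lower_median(retained[labels == u]) for u in uniq
        )
        if medians[0] == medians[1]:
            homozygous = True  # degenerate split: one allele length
    if homozygous:
        return GenotypeCall(
            "called",
            zygosity="homozygous",
            alleles=(_lower_median(retained),),
            cluster_labels=tuple(int(v) for v in labels),
            cluster_counts=cluster_counts,
            filtered_indices=filtered_idx,
        )
    return GenotypeCall(
        "called",
        zygosity="heterozygous",
        alleles=tuple(medians),
        cluster_labels=tuple(int(v) for v in labels),
        cluster_counts=cluster_counts,
        filtered_indices=filtered_idx,
    )
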