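"""Shared fixtures: a well-separated synthetic pore model and a CAG locus."""

import numpy as np
import pytest

import squigstr as sq
from squigstr.cli import RunConfig

# Cycle k-mers of both strands of a CAG repeat must be mutually separable
# within their automata for signal-level tests to be well-posed.
CAG_CYCLES = ["CAGCAGCAG", "CTGCTGCTG"]


@pytest.fixture(scope="session")
def cag_model() -> sq.PoreModel:
    return sq.make_synthetic_pore_model(3, 7, separate_kmers=CAG_CYCLES)


@pytest.fixture(scope="session")
def cag_flanks() -> tuple[str, str]:
    rng = np.random.default_rng(7)
    left = "".join(rng.choice(list("ACGT"), size=40))
    right = "".join(rng.choice(list("ACGT"), size=40))
    return left, right


@pytest.fixture(scope="session")
def cag_cycle_gap(cag_model) -> float:
    """Minimum inter-level gap among co-occurring repeat-cycle k-mers."""
    gaps = []
    for cycle in (["CAG", "AGC", "GCA"], ["CTG", "TGC", "GCT"]):
        levels = sorted(cag_model.levels[k] for k in cycle)
        gaps.append(min(np.diff(levels)))
    return float(min(gaps))


@pytest.fixture(scope="session")
def run_config() -> RunConfig:
    return RunConfig(
        loci=[],
        k=3,
        flank_length=40,
        automaton_flank_length=40,
        align=sq.AlignConfig(),
        genotype=sq.GenotypeConfig(seed=1),
    )


@pytest.fixture(scope="session")
def cag_automata(cag_model, cag_flanks):
    left, right = cag_flanks
    return sq.build_locus_automata("(CAG)", left, right, cag_model.normalized())
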