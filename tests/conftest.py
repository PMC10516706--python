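"""Shared fixtures: small synthetic genomes, targets and read sets.

Session-scoped fixtures are read-only; tests that edit reads (spike-in,
damage) build their own fragments from the factories.
"""

from __future__ import annotations

import numpy as np
import pytest

from simtk.phased_genome import build_phased_genome, pad_target
from simtk.read_sim import simulate_fragments
from simtk.workbench import (
    generate_toy_germline,
    generate_toy_reference,
    generate_toy_target,
)


@pytest.fixture(scope="session")
def reference():
    return generate_toy_reference(length=40_000, gc=0.45, rng=101)


@pytest.fixture(scope="session")
def germline(reference):
    return generate_toy_germline(reference, n_snv=30, n_indel=12, rng=102)


@pytest.fixture(scope="session")
def genome(reference, germline):
    return build_phased_genome(reference, germline)


@pytest.fixture(scope="session")
def plain_genome(reference):
    """Variant-free genome: haplotypes identical to the reference."""
    return build_phased_genome(reference, [])


@pytest.fixture(scope="session")
def target(reference, genome):
    capture = generate_toy_target(reference, n_intervals=2, interval_length=8_000, rng=103)
    return pad_target(capture, 100, {c: len(s) for c, s in reference.items()})


@pytest.fixture(scope="session")
def sim_run(genome, target):
    """Pristine 60x run with errors; do not mutate reads in tests."""
    fragments, error_log = simulate_fragments(
        genome, target, mean_depth=60, error_rates=1e-3, rng=104
    )
    return fragments, error_log


@pytest.fixture()
def fragment_factory(genome, target):
    """Fresh, mutable fragment sets for spike-in / damage tests."""

    def build(mean_depth=60, error_rates=0.0, seed=105, tgt=None):
        return simulate_fragments(
            genome, tgt or target, mean_depth, error_rates=error_rates,
            rng=np.random.default_rng(seed),
        )

    return build
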