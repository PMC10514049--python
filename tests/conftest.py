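"""Shared fixtures: small synthetic loci and read sets.

Everything is generated programmatically and seeded; nothing is read
from disk.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from cenwalk.coverage import GenomeIndex, align_reads_minimal
from cenwalk.synthetic import (
    CorruptionSpec,
    DomainSpec,
    ReadSimParams,
    corrupt_reference,
    derive_seed,
    make_true_locus,
    simulate_chip_pairs,
)


@pytest.fixture(scope="session")
def locus12k():
    return make_true_locus(12_000, 0.42, 7)


@pytest.fixture(scope="session")
def locus40k():
    return make_true_locus(40_000, 0.42, 999)


@pytest.fixture(scope="session")
def locus40k_index(locus40k):
    return GenomeIndex([locus40k], 24)


@pytest.fixture(scope="session")
def corrupted12k(locus12k):
    spec = CorruptionSpec(
        dup_block=(5000, 6999),
        gap_specs=((6999, 800),),
        emit_unplaced=True,
    )
    return corrupt_reference(locus12k, spec)


def chip_run(locus, index, seed, fold=8.0, domain=(16_000, 23_999), depth=30.0):
    """One ChIP + matched input library, aligned to the locus."""
    spec = DomainSpec(homolog1=domain, enrichment_fold=fold)
    null = DomainSpec(homolog1=domain, enrichment_fold=1.0)
    chip, _ = simulate_chip_pairs(
        locus,
        spec,
        ReadSimParams(depth=depth, seed=derive_seed(seed, "chip"), error_rate=0.001),
        prefix="c",
    )
    inp, _ = simulate_chip_pairs(
        locus,
        null,
        ReadSimParams(depth=depth, seed=derive_seed(seed, "input"), error_rate=0.001),
        prefix="i",
    )
    chip_aln = align_reads_minimal(chip, [locus], index=index)
    input_aln = align_reads_minimal(inp, [locus], index=index)
    return chip_aln, input_aln
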