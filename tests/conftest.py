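"""Shared fixtures: small synthetic cohorts and random-call factories."""

from __future__ import annotations

import numpy as np
import pytest

from clonehema import synthetic
from clonehema.types import VariantCall


@pytest.fixture(scope="session")
def small_cohort():
    """30-donor cohort at default study conditions (session-cached)."""
    return synthetic.simulate_cohort(synthetic.CohortConfig(n_donors=30, seed=123))


@pytest.fixture(scope="session")
def default_cohort():
    """Full-size default cohort, shared by the slower end-to-end tests."""
    return synthetic.simulate_cohort(synthetic.CohortConfig(seed=0))


def make_call(
    chrom="1",
    pos=100,
    ref="C",
    alt="T",
    alt_reads=10,
    depth=40,
    vaf=None,
    caller_pass=True,
    sample_id="S1",
    **kw,
) -> VariantCall:
    if vaf is None:
        vaf = alt_reads / depth if depth else 0.0
    return VariantCall(
        chrom=chrom, pos=pos, ref=ref, alt=alt, alt_reads=alt_reads,
        depth=depth, vaf=vaf, caller_pass=caller_pass, sample_id=sample_id,
        **kw,
    )


def random_calls(rng: np.random.Generator, n: int, n_samples: int = 5,
                 chrom_len: int = 10_000) -> list[VariantCall]:
    """Random SNV calls spread over a few samples and two chromosomes."""
    calls = []
    bases = "ACGT"
    for _ in range(n):
        ref = bases[rng.integers(4)]
        alt = bases[(bases.index(ref) + 1 + rng.integers(3)) % 4]
        depth = int(rng.integers(10, 80))
        alt_reads = int(rng.integers(0, depth + 1))
        calls.append(VariantCall(
            chrom=str(rng.integers(1, 3)),
            pos=int(rng.integers(2, chrom_len)),
            ref=ref, alt=alt, alt_reads=alt_reads, depth=depth,
            vaf=alt_reads / depth,
            caller_pass=bool(rng.random() < 0.8),
            sample_id=f"S{rng.integers(n_samples)}",
        ))
    return calls
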