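from __future__ import annotations

import numpy as np
import pytest

from coalabc.io import Alignment, PopulationMap


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def make_alignment():
    """Factory for random alignments with a controllable fraction of
    polymorphic sites."""

    def _make(
        rng: np.random.Generator,
        n: int = 8,
        length: int = 30,
        n_poly: int = 5,
        locus: str = "test",
    ) -> Alignment:
        bases = np.array(list("ACGT"))
        ref = rng.integers(0, 4, size=length)
        rows = np.tile(ref, (n, 1))
        poly = rng.choice(length, size=min(n_poly, length), replace=False)
        for site in poly:
            alt = (ref[site] + rng.integers(1, 4)) % 4
            carriers = rng.random(n) < rng.uniform(0.2, 0.8)
            rows[carriers, site] = alt
        seqs = [(f"s{i}", "".join(bases[row])) for i, row in enumerate(rows)]
        return Alignment(locus, seqs)

    return _make


@pytest.fixture
def uniform_popmap():
    """Everything in a single population/region."""

    def _make(aln: Alignment) -> PopulationMap:
        return PopulationMap({sid: ("pop1", "r1") for sid in aln.sample_ids})

    return _make


@pytest.fixture
def two_pop_map():
    """First half pop1, second half pop2 (one region each)."""

    def _make(aln: Alignment) -> PopulationMap:
        half = aln.n // 2
        return PopulationMap(
            {
                sid: (("pop1", "r1") if i < half else ("pop2", "r2"))
                for i, sid in enumerate(aln.sample_ids)
            }
        )

    return _make
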