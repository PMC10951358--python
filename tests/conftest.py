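import itertools

import numpy as np
import pytest
from hypothesis import settings

from diagmark.core_io import Alignment, TaxonMap

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def tiny_alignment() -> Alignment:
    """Three 4-column sequences with hand-countable pairwise differences."""
    return Alignment(name="tiny", accessions=["s1", "s2", "s3"],
                     sequences=["ACGT", "ACGA", "ACTA"])


@pytest.fixture
def two_taxon_map() -> TaxonMap:
    return TaxonMap(
        assignments={"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        outgroup=set(),
    )


def random_alignment(rng: np.random.Generator, n_seqs: int, length: int,
                     gap_rate: float = 0.0) -> Alignment:
    rows = []
    for i in range(n_seqs):
        chars = rng.choice(list("ACGT"), size=length)
        if gap_rate:
            mask = rng.random(length) < gap_rate
            chars[mask] = "-"
        rows.append("".join(chars))
    return Alignment(name="rand", accessions=[f"s{i}" for i in range(n_seqs)],
                     sequences=rows)


def naive_pi(alignment: Alignment, columns=None) -> float:
    """Brute-force mean pairwise per-site difference (independent oracle)."""
    cols = (range(1, alignment.length + 1) if columns is None
            else sorted(set(columns)))
    usable = []
    for c in cols:
        chars = [s[c - 1] for s in alignment.sequences]
        if all(ch in "ACGT" for ch in chars):
            usable.append(chars)
    if not usable:
        return float("nan")
    n = alignment.n_sequences
    total = 0.0
    for chars in usable:
        diff = sum(1 for a, b in itertools.combinations(chars, 2) if a != b)
        total += diff / (n * (n - 1) / 2)
    return total / len(usable)
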