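"""Shared fixtures and the independent naive motif-matching oracle.

The oracle re-states the consensus tiers character by character, without
using any of the package's motif machinery, so scanner results can be
checked against a truly independent implementation.
"""

from __future__ import annotations

import numpy as np
import pytest

from ampkscan.proteome_io import ProteinRecord

BASIC = set("RKH")
HYDROPHOBIC = set("MLIFV")
STANDARD = "ACDEFGHIKLMNPQRSTVWY"


def naive_tier_match(
    seq: str, center0: int, tier: str, full_window_permissive: bool = True
) -> bool:
    """Character-by-character consensus check on a full sequence.

    ``center0`` is the 0-based index of the candidate phosphoacceptor.
    """

    def res(off: int) -> str | None:
        i = center0 + off
        return seq[i] if 0 <= i < len(seq) else None

    if res(0) not in ("S", "T"):
        return False
    if tier == "strict":
        return (
            res(-6) in BASIC
            and res(-5) in HYDROPHOBIC
            and res(-4) in BASIC
            and res(4) in HYDROPHOBIC
        )
    if tier == "relaxed":
        return res(4) in HYDROPHOBIC and (
            res(-5) in HYDROPHOBIC or res(-4) in HYDROPHOBIC
        )
    if tier == "permissive":
        if full_window_permissive:
            return center0 - 6 >= 0 and center0 + 4 < len(seq)
        return True
    raise ValueError(tier)


def naive_scan(seq: str, tier: str) -> list[int]:
    """1-based positions of all sites the naive checker accepts."""
    return [
        i + 1 for i in range(len(seq)) if seq[i] in "ST" and naive_tier_match(seq, i, tier)
    ]


def random_sequences(n: int, length_range: tuple[int, int], seed: int) -> list[str]:
    rng = np.random.default_rng(seed)
    letters = np.array(list(STANDARD))
    lo, hi = length_range
    return [
        "".join(rng.choice(letters, size=int(rng.integers(lo, hi + 1))))
        for _ in range(n)
    ]


@pytest.fixture
def uniform_freqs() -> dict[str, float]:
    return {aa: 1.0 / 20.0 for aa in STANDARD}


@pytest.fixture
def nadsyn1_fixture_record() -> ProteinRecord:
    """Single protein embedding the NADSYN1 assay peptide with flanking Ala."""
    return ProteinRecord("fix1", "AAAKVKRFFSKYSMAAA")
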