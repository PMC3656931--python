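"""Shared fixtures and independent oracles.

The brute-force matcher here is deliberately naive (per-position set
membership) and independent of the package's compiled-regex scanner, so it
can serve as the oracle for site-scanning equivalence tests.
"""

from __future__ import annotations

import numpy as np
import pytest

# Independent IUPAC table: pattern symbol -> set of concrete bases it
# matches.  Subject characters outside A/C/G/T (N and friends) are in no
# set, so they never match any pattern symbol.
ORACLE_IUPAC = {
    "A": set("A"), "C": set("C"), "G": set("G"), "T": set("T"),
    "R": set("AG"), "Y": set("CT"), "W": set("AT"), "S": set("CG"),
    "K": set("GT"), "M": set("AC"),
    "B": set("CGT"), "D": set("AGT"), "H": set("ACT"), "V": set("ACG"),
    "N": set("ACGT"),
}


def brute_force_sites(sequence: str, pattern: str) -> list[int]:
    """O(n*m) sliding-window match of an IUPAC pattern; the scanning oracle."""
    seq = sequence.upper()
    pat = pattern.upper()
    m = len(pat)
    hits = []
    for i in range(len(seq) - m + 1):
        if all(seq[i + j] in ORACLE_IUPAC[pat[j]] for j in range(m)):
            hits.append(i)
    return hits


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.5,
               n_fraction: float = 0.0) -> str:
    """Random sequence for oracle comparisons, optionally salted with N runs."""
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    bases = np.array(list("ACGT"))
    seq = rng.choice(bases, size=length, p=probs)
    if n_fraction > 0:
        mask = rng.random(length) < n_fraction
        seq[mask] = "N"
    return "".join(seq)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20130517)
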