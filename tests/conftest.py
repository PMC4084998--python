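"""Shared fixtures and independent oracles for the test suite.

The brute-force first-passage oracle here deliberately shares no code
with the package's single-pass scanner: it walks forward/backward from
every anchor position one residue at a time.
"""

from __future__ import annotations

import numpy as np
import pytest

from fpscan.alphabet import AMINO_ACIDS
from fpscan.proteome_io import OrganismRecord, Proteome


def brute_force_first_passages(chains, x, y, direction):
    """Reference first-passage counts by explicit per-anchor walking.

    Returns (counts dict, n_anchors, n_censored).
    """
    counts: dict[int, int] = {}
    n_anchors = n_censored = 0
    step = 1 if direction == "C" else -1
    for chain in chains:
        n = len(chain)
        for i, aa in enumerate(chain):
            if aa != x:
                continue
            n_anchors += 1
            j = i + step
            found = False
            while 0 <= j < n:
                if chain[j] == y:
                    counts[abs(j - i)] = counts.get(abs(j - i), 0) + 1
                    found = True
                    break
                j += step
            if not found:
                n_censored += 1
    return counts, n_anchors, n_censored


def brute_force_all_pairs(chains, direction):
    """All-pair oracle in one walk per anchor (first hit per target letter)."""
    step = 1 if direction == "C" else -1
    counts = {}  # (x, y) -> {L: n}
    anchors = {aa: 0 for aa in AMINO_ACIDS}
    for chain in chains:
        n = len(chain)
        for i, x in enumerate(chain):
            anchors[x] += 1
            seen = set()
            j = i + step
            while 0 <= j < n and len(seen) < 20:
                yaa = chain[j]
                if yaa not in seen:
                    seen.add(yaa)
                    d = counts.setdefault((x, yaa), {})
                    L = abs(j - i)
                    d[L] = d.get(L, 0) + 1
                j += step
    return counts, anchors


def random_proteome(rng, n_chains=10, max_len=500, min_len=5, organism_id="test"):
    chains = []
    letters = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)
    for _ in range(n_chains):
        n = int(rng.integers(min_len, max_len + 1))
        chains.append(letters[rng.integers(0, 20, size=n)].tobytes().decode())
    return Proteome(organism=OrganismRecord(organism_id=organism_id), chains=chains)


@pytest.fixture
def rng():
    return np.random.default_rng(20240707)


@pytest.fixture
def make_random_proteome():
    return random_proteome


@pytest.fixture
def fp_oracle():
    return brute_force_first_passages


@pytest.fixture
def all_pairs_oracle():
    return brute_force_all_pairs
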