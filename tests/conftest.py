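"""Shared fixtures and independent brute-force oracles.

The oracles deliberately use naive enumeration (exhaustive runs, subset
search) so they share no code path with the implementations they check.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

REPO_ROOT = Path(__file__).resolve().parent.parent
EXAMPLES = REPO_ROOT / "examples"


@pytest.fixture
def demo_config_path() -> Path:
    return EXAMPLES / "demo_config.yaml"


@pytest.fixture
def segment_dir() -> Path:
    return EXAMPLES / "segments"


# ---------------------------------------------------------------------------
# oracle: maximal valid chains (exhaustive enumeration over contiguous runs)
# ---------------------------------------------------------------------------


def chain_oracle(
    q: np.ndarray, t: np.ndarray, max_gap_q: float, max_gap_t: float, min_markers: int
) -> list[tuple[int, ...]]:
    """All maximal contiguous runs (on the q-sorted marker list) in which
    every consecutive pair satisfies both gap constraints, filtered by
    minimal size.  O(n^3) by construction."""
    n = len(q)

    def valid(i: int, j: int) -> bool:  # run i..j inclusive
        return all(
            q[k + 1] - q[k] <= max_gap_q and abs(t[k + 1] - t[k]) <= max_gap_t
            for k in range(i, j)
        )

    runs = []
    for i in range(n):
        for j in range(i, n):
            if valid(i, j):
                left_ext = i > 0 and valid(i - 1, j)
                right_ext = j < n - 1 and valid(i, j + 1)
                if not left_ext and not right_ext:
                    runs.append(tuple(range(i, j + 1)))
    return [r for r in sorted(set(runs)) if len(r) >= min_markers]


# ---------------------------------------------------------------------------
# oracle: longest common subsequence by subset enumeration
# ---------------------------------------------------------------------------


def lcs_oracle(a: list, b: list) -> int:
    """LCS length by enumerating subsequences of the shorter sequence."""
    short, long_ = (a, b) if len(a) <= len(b) else (b, a)

    def is_subseq(sub, seq):
        it = iter(seq)
        return all(any(x == y for y in it) for x in sub)

    for length in range(len(short), 0, -1):
        for idxs in combinations(range(len(short)), length):
            if is_subseq([short[i] for i in idxs], long_):
                return length
    return 0


# ---------------------------------------------------------------------------
# oracle: true conserved segments from two marker orders
# ---------------------------------------------------------------------------


def true_blocks_oracle(genome_a, genome_b, shared: set[str]) -> list[frozenset]:
    """Recount conserved segments directly from the two genomes' marker
    orders (no event log, no shared code with the generator): group shared
    markers by chromosome pair, then greedily cut each group's A-ordered
    list wherever no extension keeps the members consecutive within the
    group's B order."""
    pos_a = {m: (c.name, i) for c in genome_a.chromosomes for i, m in enumerate(c.markers)}
    pos_b = {m: (c.name, i) for c in genome_b.chromosomes for i, m in enumerate(c.markers)}

    groups: dict[tuple[str, str], list[str]] = {}
    for m in shared:
        groups.setdefault((pos_a[m][0], pos_b[m][0]), []).append(m)

    blocks = []
    for key in sorted(groups):
        members = sorted(groups[key], key=lambda m: pos_a[m][1])
        b_order = sorted(members, key=lambda m: pos_b[m][1])
        b_rank = {m: i for i, m in enumerate(b_order)}

        def contiguous(ms: list[str]) -> bool:
            ranks = sorted(b_rank[m] for m in ms)
            return ranks == list(range(ranks[0], ranks[0] + len(ranks)))

        i = 0
        while i < len(members):
            j_best = i
            for j in range(i, len(members)):
                if contiguous(members[i : j + 1]):
                    j_best = j
            blocks.append(frozenset(members[i : j_best + 1]))
            i = j_best + 1
    return blocks


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)
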