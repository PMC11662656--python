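"""Shared fixtures and independent reference implementations (oracles).

The oracles here deliberately avoid the code paths they check: the motif
oracle enumerates block decompositions by hand instead of using regular
expressions, the window oracle slides over every residue-aligned window,
and the rank-sum oracle enumerates rank assignments combinatorially.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from punscan.simulate import SyntheticSpec, write_bundle

DEFAULT_BOUNDS = ((1, 3), (1, 3), (2, 3), (1, 3), (1, 3))


def oracle_scan(
    seq: str,
    bounds=DEFAULT_BOUNDS,
    positive=frozenset("RK"),
) -> list[tuple[int, int]]:
    """Leftmost-greedy non-overlapping matcher by explicit block decomposition.

    At each scan position, block lengths are tried in greedy order (longest
    first, backtracking later blocks first); after a match the scan resumes
    at the match end.
    """
    classes = (True, False, True, False, True)  # block residues positive?
    n = len(seq)

    def rec(pos: int, b: int) -> int | None:
        if b == 5:
            return pos
        lo, hi = bounds[b]
        want = classes[b]
        run = 0
        while run < hi and pos + run < n and (seq[pos + run] in positive) == want:
            run += 1
        for length in range(min(run, hi), lo - 1, -1):
            end = rec(pos + length, b + 1)
            if end is not None:
                return end
        return None

    out: list[tuple[int, int]] = []
    i = 0
    while i < n:
        end = rec(i, 0)
        if end is None:
            i += 1
        else:
            out.append((i, end))
            i = end
    return out


def oracle_anchored(
    s: str, bounds=DEFAULT_BOUNDS, positive=frozenset("RK")
) -> bool:
    """Exhaustive 5-part block decomposition: is the whole string a motif?"""
    classes = (True, False, True, False, True)
    ranges = [range(lo, hi + 1) for lo, hi in bounds]
    for combo in itertools.product(*ranges):
        if sum(combo) != len(s):
            continue
        pos = 0
        ok = True
        for length, want in zip(combo, classes):
            seg = s[pos : pos + length]
            if any((c in positive) != want for c in seg):
                ok = False
                break
            pos += length
        if ok:
            return True
    return False


def oracle_max_in_window(
    spans: list[tuple[int, int]], window: int, length: int, mode: str = "span"
) -> int:
    """Brute force over every residue-aligned window start."""
    best = 0
    for w in range(length + 1):
        if mode == "span":
            c = sum(1 for s, e in spans if s >= w and e <= w + window)
        else:
            c = sum(1 for s, _ in spans if w <= s <= w + window)
        best = max(best, c)
    return best


def oracle_ranksum_exact(x, y) -> float:
    """Two-sided exact rank-sum p by full enumeration (tie-free data)."""
    pooled = sorted(list(x) + list(y))
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"
    rank = {v: i + 1 for i, v in enumerate(pooled)}
    w_obs = sum(rank[v] for v in x)
    n1, n = len(x), len(pooled)
    ws = [sum(c) for c in itertools.combinations(range(1, n + 1), n1)]
    total = len(ws)
    p_low = sum(1 for w in ws if w <= w_obs) / total
    p_high = sum(1 for w in ws if w >= w_obs) / total
    return min(1.0, 2.0 * min(p_low, p_high))


def random_motif_alphabet_string(rng: np.random.Generator, max_len: int = 60) -> str:
    letters = np.array(list("RKADESG"))
    n = int(rng.integers(0, max_len + 1))
    return "".join(letters[rng.integers(0, len(letters), n)])


@pytest.fixture(scope="session")
def small_bundle(tmp_path_factory):
    """A small synthetic bundle shared by pipeline/CLI tests."""
    out = tmp_path_factory.mktemp("bundle")
    spec = SyntheticSpec(n_proteins=150, pun_fraction=0.08, length_max=400)
    manifest = write_bundle(spec, seed=7, out_dir=out)
    return out, spec, manifest
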