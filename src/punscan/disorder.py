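"""Disorder comparison: PUN proteins vs a random zero-motif background.

The disorder input is a per-residue score track in [0, 1] per protein (e.g.
IUPred2 output, consumed as data, never predicted here).  Group comparison
uses a two-sided Wilcoxon rank-sum (Mann-Whitney U) test: the exact null
distribution is enumerated when the smaller group has <= 10 observations
and the pooled data are tie-free, otherwise a normal approximation with
tie and continuity corrections is used.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as _sps

from .proteome import ProteinMotifProfile

__all__ = [
    "DisorderTrack",
    "RankSumResult",
    "mean_disorder",
    "sample_background",
    "rank_sum_test",
]


@dataclass(frozen=True)
class DisorderTrack:
    """Per-residue disorder scores for one protein; values in [0, 1]."""

    protein_id: str
    scores: np.ndarray

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 1:
            raise ValueError("scores must be one-dimensional")
        if scores.size and (scores.min() < 0.0 or scores.max() > 1.0):
            raise ValueError(f"track {self.protein_id!r}: scores outside [0, 1]")
        object.__setattr__(self, "scores", scores)

    def __len__(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # Mann-Whitney U for the first group
    p_value: float
    n_group1: int
    n_group2: int
    method: str  # "exact" | "normal-approximation"


def mean_disorder(track: DisorderTrack) -> float:
    """Arithmetic mean of the per-residue disorder scores."""
    if len(track) == 0:
        raise ValueError(f"track {track.protein_id!r} is empty")
    return float(np.mean(track.scores))


def sample_background(
    profiles: Iterable[ProteinMotifProfile],
    n: int,
    seed: int | np.random.Generator,
) -> list[str]:
    """Uniform sample (without replacement) of proteins with zero PUN motifs.

    The background pool requires ``motif_count == 0`` exactly, which is
    stricter than merely not qualifying as a PUN protein.  ``profiles``
    may be profile objects or a profiles table with columns
    ``protein_id`` / ``motif_count``.
    """
    import pandas as pd

    if isinstance(profiles, pd.DataFrame):
        pool = profiles.loc[profiles["motif_count"] == 0, "protein_id"].astype(str).tolist()
    else:
        pool = [p.protein_id for p in profiles if p.motif_count == 0]
    if n == 0:
        return []
    if len(pool) < n:
        raise ValueError(
            f"only {len(pool)} zero-motif proteins available; "
            f"request a background of at most that size (asked for {n})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in idx]


def _rank_sum_counts(n1: int, n2: int) -> np.ndarray:
    """Null distribution of the rank sum W of group 1 (tie-free case).

    counts[s] = number of n1-subsets of ranks {1..n1+n2} with sum s,
    built by dynamic programming over ranks.
    """
    n = n1 + n2
    max_sum = n1 * n + 1
    # f[j, s]: subsets of size j with rank-sum s, ranks processed so far
    f = np.zeros((n1 + 1, max_sum), dtype=float)
    f[0, 0] = 1.0
    for r in range(1, n + 1):
        for j in range(min(r, n1), 0, -1):
            f[j, r:] += f[j - 1, :-r] if r else f[j - 1, :]
    return f[n1]


def rank_sum_test(x: Sequence[float], y: Sequence[float]) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum / Mann-Whitney test of two samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p-value set to 1")
        return RankSumResult(n1 * n2 / 2.0, 1.0, n1, n2, "normal-approximation")

    ranks = _sps.rankdata(pooled)
    w = float(ranks[:n1].sum())
    u = w - n1 * (n1 + 1) / 2.0
    tie_free = np.unique(pooled).size == pooled.size

    if min(n1, n2) <= 10 and tie_free:
        counts = _rank_sum_counts(n1, n2)
        total = counts.sum()
        wi = int(round(w))
        p_low = counts[: wi + 1].sum() / total
        p_high = counts[wi:].sum() / total
        p = min(1.0, 2.0 * min(p_low, p_high))
        return RankSumResult(u, float(p), n1, n2, "exact")

    # normal approximation with tie correction and continuity correction
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    mu = n1 * n2 / 2.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        warnings.warn("degenerate rank variance; p-value set to 1")
        return RankSumResult(u, 1.0, n1, n2, "normal-approximation")
    z = (u - mu - 0.5 * np.sign(u - mu)) / np.sqrt(var)
    p = float(min(1.0, 2.0 * _sps.norm.sf(abs(z))))
    return RankSumResult(u, p, n1, n2, "normal-approximation")
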