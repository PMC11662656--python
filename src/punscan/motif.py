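"""PUN motif grammar and sequence scanner.

A PUN motif (positively charged, unstructured nucleic acid binding motif)
is three runs of positively charged residues (by default R/K) separated by
two short spacers free of positively charged residues::

    [RK]{1,3} [^RK]{1,3} [RK]{2,3} [^RK]{1,3} [RK]{1,3}

i.e. run lengths 1-3 / 1-3 / 2-3 / 1-3 / 1-3, giving a total motif length
of 6-13 residues under the default bounds.  Scanning uses standard
Perl-style leftmost, greedy, non-overlapping semantics: after each match
the scan resumes at the match end, and per-block quantifiers prefer the
longest feasible extent (with backtracking).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "MotifPattern",
    "ProteinRecord",
    "MotifMatch",
    "compile_pattern",
    "scan_sequence",
    "motif_mask",
    "DEFAULT_PATTERN",
]

_DEFAULT_BOUNDS = ((1, 3), (1, 3), (2, 3), (1, 3), (1, 3))


class PatternConfigError(ValueError):
    """Raised for invalid motif grammar configuration."""


@dataclass(frozen=True)
class MotifPattern:
    """Run/spacer grammar: three positive runs separated by two spacers.

    Parameters
    ----------
    positive_alphabet : frozenset of str
        Residue letters counted as positively charged (default ``{R, K}``).
        Spacers match the strict complement of this set, so ambiguity codes
        (X, B, Z, U, O) count as spacer characters.
    block_bounds : five (min, max) pairs
        Length bounds for [run1, spacer1, run2, spacer2, run3].
    """

    positive_alphabet: frozenset[str] = frozenset("RK")
    block_bounds: tuple[tuple[int, int], ...] = _DEFAULT_BOUNDS

    def __post_init__(self) -> None:
        if not self.positive_alphabet:
            raise PatternConfigError("positive_alphabet must be non-empty")
        for ch in self.positive_alphabet:
            if len(ch) != 1 or not ch.isupper():
                raise PatternConfigError(
                    f"positive_alphabet entries must be single uppercase letters, got {ch!r}"
                )
        object.__setattr__(self, "positive_alphabet", frozenset(self.positive_alphabet))
        bounds = tuple((int(lo), int(hi)) for lo, hi in self.block_bounds)
        if len(bounds) != 5:
            raise PatternConfigError("block_bounds must have exactly five (min, max) pairs")
        for lo, hi in bounds:
            if lo < 1 or hi < lo:
                raise PatternConfigError(f"invalid block bounds ({lo}, {hi}): need 1 <= min <= max")
        object.__setattr__(self, "block_bounds", bounds)

    @property
    def min_length(self) -> int:
        return sum(lo for lo, _ in self.block_bounds)

    @property
    def max_length(self) -> int:
        return sum(hi for _, hi in self.block_bounds)

    def regex(self) -> str:
        """Regular-expression source for the grammar (greedy quantifiers)."""
        pos = "".join(sorted(self.positive_alphabet))
        cls = [f"[{pos}]", f"[^{pos}]", f"[{pos}]", f"[^{pos}]", f"[{pos}]"]
        return "".join(
            f"{c}{{{lo},{hi}}}" for c, (lo, hi) in zip(cls, self.block_bounds)
        )


DEFAULT_PATTERN = MotifPattern()


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence; '*' and whitespace are stripped, letters uppercased."""

    id: str
    description: str
    sequence: str

    def __post_init__(self) -> None:
        seq = re.sub(r"[\s*\-]", "", self.sequence).upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"protein {self.id!r}: empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifMatch:
    """A located motif occurrence, 0-based half-open coordinates."""

    protein_id: str
    start: int
    end: int
    matched_seq: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid match span [{self.start}, {self.end})")
        if len(self.matched_seq) != self.end - self.start:
            raise ValueError("matched_seq length disagrees with span")


def compile_pattern(pattern: MotifPattern) -> re.Pattern[str]:
    """Compile the grammar to a regex matcher.

    The matcher recognises exactly the strings decomposable into the five
    blocks within their length bounds; invalid bounds raise
    :class:`PatternConfigError` at pattern construction.
    """
    return re.compile(pattern.regex())


def scan_sequence(
    record: ProteinRecord, pattern: MotifPattern = DEFAULT_PATTERN
) -> list[MotifMatch]:
    """All non-overlapping motif matches, leftmost-greedy, sorted by start.

    After each match scanning resumes at the match end (no second pass from
    ``start + 1``), so overlapping occurrences are not counted.
    """
    matcher = compile_pattern(pattern)
    return [
        MotifMatch(record.id, m.start(), m.end(), m.group(0))
        for m in matcher.finditer(record.sequence)
    ]


def motif_mask(matches: Iterable[MotifMatch], length: int) -> np.ndarray:
    """Boolean per-residue track: True where a residue lies inside >=1 match."""
    track = np.zeros(int(length), dtype=bool)
    for m in matches:
        if m.start < 0 or m.end > length:
            raise ValueError(
                f"match [{m.start}, {m.end}) out of bounds for length {length}"
            )
        track[m.start : m.end] = True
    return track
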