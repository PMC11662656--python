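"""Proteome-wide scanning, PUN-protein classification and density ranking.

A protein is called a PUN protein when it carries at least ``min_motifs``
PUN motifs of which at least ``cluster_min`` co-occur within a window of
``window_aa`` residues (defaults 5 / 3 / 150).  For proteomes of much
shorter proteins (the E. coli variant) the clustering clause is dropped and
the count threshold lowered to 3 (:data:`ECOLI_RULE`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .motif import DEFAULT_PATTERN, MotifMatch, MotifPattern, ProteinRecord, scan_sequence

__all__ = [
    "PunCallRule",
    "ECOLI_RULE",
    "ProteinMotifProfile",
    "ProteomeSummary",
    "max_motifs_in_window",
    "classify_protein",
    "scan_proteome",
    "rank_by_density",
]


@dataclass(frozen=True)
class PunCallRule:
    """Classification rule for PUN proteins.

    ``cluster_mode`` selects the clustering-window interpretation:
    ``"span"`` requires the full motif spans inside the window
    (end(last) - start(first) <= window_aa, the default), ``"start"`` only
    the motif starts (start(last) - start(first) <= window_aa).
    """

    min_motifs: int = 5
    cluster_min: int = 3
    window_aa: int = 150
    require_cluster: bool = True
    cluster_mode: str = "span"

    def __post_init__(self) -> None:
        if self.window_aa < 13:
            raise ValueError("window_aa must be >= 13")
        if self.require_cluster and not (self.min_motifs >= self.cluster_min >= 1):
            raise ValueError("need min_motifs >= cluster_min >= 1 when clustering is required")
        if self.cluster_mode not in ("span", "start"):
            raise ValueError(f"unknown cluster_mode {self.cluster_mode!r}")


ECOLI_RULE = PunCallRule(min_motifs=3, require_cluster=False)


@dataclass(frozen=True)
class ProteinMotifProfile:
    protein_id: str
    length: int
    matches: tuple[MotifMatch, ...]
    max_in_window: int
    is_pun: bool

    @property
    def motif_count(self) -> int:
        return len(self.matches)

    @property
    def density(self) -> float:
        """Motifs per residue; the denominator is the full protein length."""
        return self.motif_count / self.length

    @property
    def density_per_100aa(self) -> float:
        return 100.0 * self.density


@dataclass(frozen=True)
class ProteomeSummary:
    n_proteins: int
    n_pun: int
    max_motif_count: int  # max among PUN proteins (0 if none)


def max_motifs_in_window(
    matches: Sequence[MotifMatch], window_aa: int, mode: str = "span"
) -> int:
    """Maximum number of motifs co-locatable within one window of ``window_aa`` aa.

    Matches must be sorted by start and non-overlapping.  In ``span`` mode a
    run of consecutive matches counts when end(last) - start(first) <=
    window_aa; in ``start`` mode when start(last) - start(first) <= window_aa.
    """
    if mode not in ("span", "start"):
        raise ValueError(f"unknown cluster mode {mode!r}")
    if not matches:
        return 0
    best = 0
    lo = 0
    for hi in range(len(matches)):
        while True:
            extent = (
                matches[hi].end - matches[lo].start
                if mode == "span"
                else matches[hi].start - matches[lo].start
            )
            if extent <= window_aa:
                break
            lo += 1
        best = max(best, hi - lo + 1)
    return best


def classify_protein(
    protein_id: str,
    length: int,
    matches: Sequence[MotifMatch],
    rule: PunCallRule = PunCallRule(),
) -> ProteinMotifProfile:
    """Build a motif profile and apply the PUN-protein rule."""
    matches = tuple(sorted(matches, key=lambda m: m.start))
    miw = max_motifs_in_window(matches, rule.window_aa, rule.cluster_mode)
    is_pun = len(matches) >= rule.min_motifs and (
        not rule.require_cluster or miw >= rule.cluster_min
    )
    return ProteinMotifProfile(protein_id, length, matches, miw, is_pun)


def _dedupe_ids(records: list[ProteinRecord]) -> list[ProteinRecord]:
    seen: dict[str, int] = {}
    out = []
    for rec in records:
        if rec.id in seen:
            seen[rec.id] += 1
            new_id = f"{rec.id}.{seen[rec.id]}"
            warnings.warn(f"duplicate protein id {rec.id!r}; renamed to {new_id!r}")
            rec = ProteinRecord(new_id, rec.description, rec.sequence)
        else:
            seen[rec.id] = 1
        out.append(rec)
    return out


def scan_proteome(
    source: str | Path | Iterable[ProteinRecord],
    pattern: MotifPattern = DEFAULT_PATTERN,
    rule: PunCallRule = PunCallRule(),
) -> tuple[list[ProteinMotifProfile], ProteomeSummary]:
    """Scan every record of a proteome; input order is preserved.

    ``source`` may be a FASTA path or an iterable of :class:`ProteinRecord`.
    Duplicate ids are suffix-deduplicated with a warning.
    """
    if isinstance(source, (str, Path)):
        from .io import read_fasta

        records = read_fasta(source)
        if not records:
            raise ValueError(f"no sequences found in {source}")
    else:
        records = list(source)
    records = _dedupe_ids(records)
    profiles = [
        classify_protein(rec.id, rec.length, scan_sequence(rec, pattern), rule)
        for rec in records
    ]
    pun = [p for p in profiles if p.is_pun]
    summary = ProteomeSummary(
        n_proteins=len(profiles),
        n_pun=len(pun),
        max_motif_count=max((p.motif_count for p in pun), default=0),
    )
    return profiles, summary


def rank_by_density(profiles: Iterable[ProteinMotifProfile]) -> pd.DataFrame:
    """PUN proteins ranked by motif density (descending).

    Ties break by motif count (descending), then protein id (ascending).
    """
    rows = [
        {
            "protein_id": p.protein_id,
            "length": p.length,
            "motif_count": p.motif_count,
            "max_in_window": p.max_in_window,
            "density": p.density,
            "density_per_100aa": p.density_per_100aa,
        }
        for p in profiles
        if p.is_pun
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "protein_id",
            "length",
            "motif_count",
            "max_in_window",
            "density",
            "density_per_100aa",
        ],
    )
    if df.empty:
        return df
    df = df.sort_values(
        ["density", "motif_count", "protein_id"], ascending=[False, False, True]
    ).reset_index(drop=True)
    df.index = df.index + 1
    df.index.name = "rank"
    return df
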