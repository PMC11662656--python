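"""Conservation of PUN-protein status between two scanned proteomes.

Given per-protein motif profiles for a source proteome (e.g. yeast) and a
target proteome (e.g. human), plus an ortholog table with homology classes
one2one / one2many / many2many, summarise how often source PUN proteins
have orthologs and how often those orthologs are themselves PUN proteins.
many2many relations are excluded from the conservation call; a source
protein with at least one PUN target among its one2one/one2many orthologs
counts as conserved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .proteome import ProteinMotifProfile

__all__ = [
    "OrthologTable",
    "ConservationSummary",
    "conservation_summary",
    "architecture_compare",
]

_HOMOLOGY_TYPES = frozenset({"one2one", "one2many", "many2many"})


@dataclass(frozen=True)
class OrthologTable:
    """Rows of (source_id, target_id, homology_type). Duplicates are ignored."""

    rows: frozenset[tuple[str, str, str]]

    @classmethod
    def from_rows(cls, rows: Iterable[tuple[str, str, str]]) -> "OrthologTable":
        clean = set()
        for src, tgt, htype in rows:
            if htype not in _HOMOLOGY_TYPES:
                raise ValueError(f"unknown homology_type {htype!r}")
            clean.add((src, tgt, htype))
        return cls(frozenset(clean))

    def targets_of(self, source_id: str, types: frozenset[str]) -> set[str]:
        return {t for s, t, h in self.rows if s == source_id and h in types}

    def types_of(self, source_id: str) -> set[str]:
        return {h for s, _, h in self.rows if s == source_id}


@dataclass(frozen=True)
class ConservationSummary:
    n_source_pun: int
    n_no_ortholog: int
    n_mappable: int  # one2one or one2many
    n_many2many_only: int
    n_conserved_pun: int  # mappable sources with >=1 PUN target
    n_target_orthologs: int
    n_target_orthologs_pun: int

    @property
    def fraction_no_ortholog(self) -> float:
        return self.n_no_ortholog / self.n_source_pun if self.n_source_pun else 1.0

    @property
    def fraction_mappable(self) -> float:
        return self.n_mappable / self.n_source_pun if self.n_source_pun else 0.0

    @property
    def fraction_many2many_only(self) -> float:
        return self.n_many2many_only / self.n_source_pun if self.n_source_pun else 0.0

    @property
    def fraction_conserved_pun(self) -> float:
        return self.n_conserved_pun / self.n_mappable if self.n_mappable else 0.0

    @property
    def fraction_target_orthologs_pun(self) -> float:
        return (
            self.n_target_orthologs_pun / self.n_target_orthologs
            if self.n_target_orthologs
            else 0.0
        )


def conservation_summary(
    source_profiles: Iterable[ProteinMotifProfile],
    target_profiles: Iterable[ProteinMotifProfile],
    table: OrthologTable,
) -> ConservationSummary:
    """Summarise ortholog coverage and PUN conservation for source PUN proteins."""
    target_by_id = {p.protein_id: p for p in target_profiles}
    source_pun = [p for p in source_profiles if p.is_pun]
    mappable_types = frozenset({"one2one", "one2many"})

    n_no, n_map, n_m2m_only, n_cons = 0, 0, 0, 0
    target_seen: set[str] = set()
    for prof in source_pun:
        types = table.types_of(prof.protein_id)
        if not types:
            n_no += 1
            continue
        if not (types & mappable_types):
            n_m2m_only += 1
            continue
        n_map += 1
        targets = table.targets_of(prof.protein_id, mappable_types)
        known = set()
        for tid in targets:
            if tid not in target_by_id:
                warnings.warn(f"ortholog target {tid!r} absent from target profiles; excluded")
            else:
                known.add(tid)
        target_seen |= known
        if any(target_by_id[t].is_pun for t in known):
            n_cons += 1

    return ConservationSummary(
        n_source_pun=len(source_pun),
        n_no_ortholog=n_no,
        n_mappable=n_map,
        n_many2many_only=n_m2m_only,
        n_conserved_pun=n_cons,
        n_target_orthologs=len(target_seen),
        n_target_orthologs_pun=sum(1 for t in target_seen if target_by_id[t].is_pun),
    )


def architecture_compare(
    source: ProteinMotifProfile, target: ProteinMotifProfile
) -> dict:
    """Descriptive motif-architecture comparison for one ortholog pair.

    Reports count difference, density ratio, clustering difference and
    normalized motif-start positions (start/length) for plotting; no
    similarity score is computed.
    """
    return {
        "source_id": source.protein_id,
        "target_id": target.protein_id,
        "motif_count_diff": target.motif_count - source.motif_count,
        "density_ratio": (target.density / source.density) if source.density else float("nan"),
        "max_in_window_diff": target.max_in_window - source.max_in_window,
        "source_norm_starts": [m.start / source.length for m in source.matches],
        "target_norm_starts": [m.start / target.length for m in target.matches],
    }
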