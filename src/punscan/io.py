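"""Readers and writers for the standard text formats used by the pipeline.

FASTA (protein, UniProt header dialect supported), long-format disorder
score TSV, GAF 2.x and two-column annotation TSV, three-column ortholog
TSV, titration / melting TSV tables, and the TSV/JSON outputs of the scan.
All coordinates written are 0-based half-open and say so in a header
comment.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .binding import MeltCurve, TitrationSeries
from .disorder import DisorderTrack
from .enrichment import GeneSetAnnotation
from .motif import MotifMatch, ProteinRecord
from .orthologs import OrthologTable
from .proteome import ProteinMotifProfile

__all__ = [
    "read_fasta",
    "write_fasta",
    "write_matches_tsv",
    "write_profiles_tsv",
    "read_profiles_tsv",
    "read_disorder_tsv",
    "write_disorder_tsv",
    "read_gaf",
    "read_term_tsv",
    "write_annotation_tsv",
    "read_ortholog_tsv",
    "write_ortholog_tsv",
    "read_titration_tsv",
    "read_melt_tsv",
]


def _parse_fasta_id(raw: str) -> str:
    """First whitespace token; UniProt 'sp|ACC|NAME' headers resolve to ACC."""
    token = raw.split()[0] if raw.split() else raw
    parts = token.split("|")
    if len(parts) >= 3 and parts[0] in ("sp", "tr"):
        return parts[1]
    return token


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description
        records.append(ProteinRecord(_parse_fasta_id(desc), desc, str(rec.seq)))
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if rec.description in ("", rec.id) else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def write_matches_tsv(matches: Iterable[MotifMatch], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# coordinates: 0-based, half-open [start, end)\n")
        fh.write("protein_id\tstart\tend\tsequence\n")
        for m in matches:
            fh.write(f"{m.protein_id}\t{m.start}\t{m.end}\t{m.matched_seq}\n")


def write_profiles_tsv(profiles: Iterable[ProteinMotifProfile], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "protein_id\tlength\tmotif_count\tmax_in_window\tdensity_per_100aa\tis_pun\n"
        )
        for p in profiles:
            fh.write(
                f"{p.protein_id}\t{p.length}\t{p.motif_count}\t{p.max_in_window}\t"
                f"{p.density_per_100aa:.6f}\t{str(p.is_pun).lower()}\n"
            )


def read_profiles_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    df["is_pun"] = df["is_pun"].astype(str).str.lower().map({"true": True, "false": False})
    return df


def read_disorder_tsv(path: str | Path) -> dict[str, DisorderTrack]:
    """Long-format disorder scores: columns protein_id, pos (1-based), score."""
    df = pd.read_csv(path, sep="\t", comment="#")
    df.columns = [c.lower() for c in df.columns]
    required = {"protein_id", "pos", "score"}
    if not required <= set(df.columns):
        raise ValueError(f"disorder TSV needs columns {sorted(required)}")
    tracks = {}
    for pid, grp in df.groupby("protein_id", sort=False):
        grp = grp.sort_values("pos")
        tracks[str(pid)] = DisorderTrack(str(pid), grp["score"].to_numpy(dtype=float))
    return tracks


def write_disorder_tsv(tracks: Mapping[str, DisorderTrack], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tpos\tscore\n")
        for pid in tracks:
            for i, s in enumerate(tracks[pid].scores, start=1):
                fh.write(f"{pid}\t{i}\t{s:.4f}\n")


def read_gaf(path: str | Path, term_names: Mapping[str, str] | None = None) -> dict[str, GeneSetAnnotation]:
    """GAF 2.x: DB Object ID (col 2) -> GO ID (col 5); NOT-qualified rows dropped."""
    members: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 5:
                continue
            qualifier = cols[3]
            if "NOT" in qualifier.split("|"):
                continue
            members.setdefault(cols[4], set()).add(cols[1])
    names = term_names or {}
    return {
        tid: GeneSetAnnotation(tid, names.get(tid, tid), frozenset(ids))
        for tid, ids in members.items()
    }


def read_term_tsv(
    path: str | Path, term_names: Mapping[str, str] | None = None
) -> dict[str, GeneSetAnnotation]:
    """Two-column annotation: protein_id <tab> term_id (optional header)."""
    members: dict[str, set[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 2:
                raise ValueError(f"annotation row with <2 columns: {line!r}")
            if cols[0] == "protein_id":  # header
                continue
            members.setdefault(cols[1], set()).add(cols[0])
    names = term_names or {}
    return {
        tid: GeneSetAnnotation(tid, names.get(tid, tid), frozenset(ids))
        for tid, ids in members.items()
    }


def write_annotation_tsv(annotation: Mapping[str, GeneSetAnnotation], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("protein_id\tterm_id\n")
        for tid in sorted(annotation):
            for pid in sorted(annotation[tid].members):
                fh.write(f"{pid}\t{tid}\n")


def read_ortholog_tsv(path: str | Path) -> OrthologTable:
    """Three-column table: source_id <tab> target_id <tab> homology_type."""
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if cols[0] == "source_id":
                continue
            if len(cols) < 3:
                raise ValueError(f"ortholog row with <3 columns: {line!r}")
            rows.append((cols[0], cols[1], cols[2]))
    return OrthologTable.from_rows(rows)


def write_ortholog_tsv(table: OrthologTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("source_id\ttarget_id\thomology_type\n")
        for src, tgt, htype in sorted(table.rows):
            fh.write(f"{src}\t{tgt}\t{htype}\n")


def _read_two_numeric_columns(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError("need two tab-separated columns")
    return df.iloc[:, 0].to_numpy(dtype=float), df.iloc[:, 1].to_numpy(dtype=float)


def read_titration_tsv(path: str | Path, p_tot: float) -> TitrationSeries:
    """Titration table: ligand concentration (uM) <tab> CSP (ppm)."""
    L, csp = _read_two_numeric_columns(path)
    return TitrationSeries(p_tot, L, csp)


def read_melt_tsv(path: str | Path, reference: str = "") -> MeltCurve:
    """Melting table: temperature <tab> normalized intensity."""
    T, I = _read_two_numeric_columns(path)
    return MeltCurve(T, I, reference)


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
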