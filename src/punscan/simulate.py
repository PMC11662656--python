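"""Synthetic proteomes with implanted PUN motifs and a ground-truth manifest.

The generator emulates the statistical structure of the real analysis with
fully known ground truth so every pipeline stage runs offline:

* background sequences drawn i.i.d. from a residue frequency table with
  R and K down-weighted (2% each by default) so accidental motifs are
  rare but possible;
* a controlled fraction of proteins receives 5-8 implanted motifs sampled
  from the grammar, placed without collisions, each flanked by at least
  one non-positive residue, with a guaranteed cluster of >= 3 motifs
  inside one 150-aa window;
* after implantation every sequence is re-scanned and resampled (bounded
  budget) until the detected motifs equal the implanted ones and the
  intended PUN/background label holds under the default call rule;
* per-residue disorder scores are Beta-distributed with a stated upward
  mean shift for PUN proteins; one annotation term is enriched among PUN
  proteins; an ortholog table pairs a configurable fraction of PUN
  proteins to a second generated proteome.

Identical spec + seed reproduce byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np

from .disorder import DisorderTrack
from .enrichment import GeneSetAnnotation
from .motif import DEFAULT_PATTERN, MotifPattern, ProteinRecord, scan_sequence
from .proteome import PunCallRule, classify_protein

__all__ = [
    "SyntheticSpec",
    "SyntheticDataset",
    "sample_motif",
    "generate_proteome",
    "generate_ortholog_table",
    "write_bundle",
]

AMINO_ACIDS = tuple("ACDEFGHIKLMNPQRSTVWY")


def _default_frequencies() -> dict[str, float]:
    freqs = {aa: 0.96 / 18 for aa in AMINO_ACIDS if aa not in "RK"}
    freqs["R"] = 0.02
    freqs["K"] = 0.02
    return freqs


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for one synthetic proteome."""

    n_proteins: int = 1000
    length_min: int = 80
    length_max: int = 600
    pun_fraction: float = 0.05
    motifs_min: int = 5
    motifs_max: int = 8
    cluster_min: int = 3
    window_aa: int = 150
    p_cluster: float = 1.0
    frequencies: Mapping[str, float] = field(default_factory=_default_frequencies)
    disorder_mu: float = 0.30
    disorder_shift: float = 0.20
    disorder_concentration: float = 10.0
    enriched_term: str = "TERM:ENRICHED"
    q_pun: float = 0.80
    q_background: float = 0.05
    n_decoy_terms: int = 20
    decoy_coverage: float = 0.08
    resample_budget: int = 100

    def __post_init__(self) -> None:
        for p in (self.pun_fraction, self.p_cluster, self.q_pun, self.q_background,
                  self.decoy_coverage):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        total = sum(self.frequencies.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"residue frequencies must sum to 1 (got {total})")
        if not (1 <= self.length_min <= self.length_max):
            raise ValueError("invalid length bounds")
        if not (1 <= self.motifs_min <= self.motifs_max):
            raise ValueError("invalid motif count bounds")
        if not 0.0 <= self.disorder_mu + self.disorder_shift <= 1.0:
            raise ValueError("disorder mean + shift must stay within [0, 1]")


@dataclass
class SyntheticDataset:
    records: list[ProteinRecord]
    tracks: dict[str, DisorderTrack]
    annotation: dict[str, GeneSetAnnotation]
    manifest: dict


def sample_motif(
    pattern: MotifPattern = DEFAULT_PATTERN, rng: np.random.Generator | None = None
) -> str:
    """Draw one string from the motif grammar.

    Block lengths are uniform within bounds; positive residues uniform over
    the positive alphabet, spacer residues uniform over the 20 standard
    amino acids minus the positive alphabet.
    """
    rng = rng or np.random.default_rng()
    pos = sorted(pattern.positive_alphabet)
    spacer = sorted(set(AMINO_ACIDS) - set(pattern.positive_alphabet))
    parts = []
    for i, (lo, hi) in enumerate(pattern.block_bounds):
        n = int(rng.integers(lo, hi + 1))
        alphabet = pos if i % 2 == 0 else spacer
        parts.append("".join(alphabet[j] for j in rng.integers(0, len(alphabet), n)))
    return "".join(parts)


def _random_residues(n: int, letters: np.ndarray, probs: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    return letters[rng.choice(len(letters), size=n, p=probs)]


def _place_intervals(
    lengths: list[int],
    seq_len: int,
    cluster_k: int,
    window_aa: int,
    rng: np.random.Generator,
    tries: int = 200,
) -> list[tuple[int, int]] | None:
    """Non-colliding start positions with 1-residue flanks inside [1, L-1).

    The first ``cluster_k`` motifs are constrained to one window of
    ``window_aa`` residues.
    """
    if cluster_k > 0:
        w_hi = max(1, seq_len - 1 - window_aa)
        window_start = int(rng.integers(1, w_hi + 1)) if w_hi > 1 else 1
        window_end = min(seq_len - 1, window_start + window_aa)
    for _ in range(tries):
        intervals: list[tuple[int, int]] = []
        ok = True
        for i, L in enumerate(lengths):
            if i < cluster_k:
                lo, hi = window_start, window_end - L
            else:
                lo, hi = 1, seq_len - 1 - L
            if hi < lo:
                ok = False
                break
            placed = False
            for _ in range(50):
                s = int(rng.integers(lo, hi + 1))
                e = s + L
                # 1-residue flank on each side must stay free of other motifs
                if all(e + 1 <= a or b + 1 <= s for a, b in intervals):
                    intervals.append((s, e))
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok:
            return sorted(intervals)
    return None


def generate_proteome(
    spec: SyntheticSpec,
    seed: int,
    pattern: MotifPattern = DEFAULT_PATTERN,
    rule: PunCallRule | None = None,
    id_prefix: str = "SYN",
) -> SyntheticDataset:
    """Generate sequences, disorder tracks, annotation and the manifest."""
    rng = np.random.default_rng(seed)
    rule = rule or PunCallRule(cluster_min=spec.cluster_min, window_aa=spec.window_aa)
    letters = np.array(sorted(spec.frequencies), dtype="<U1")
    probs = np.array([spec.frequencies[a] for a in sorted(spec.frequencies)])
    pos_set = set(pattern.positive_alphabet)
    nonpos_mask = np.array([a not in pos_set for a in letters])
    np_letters = letters[nonpos_mask]
    np_probs = probs[nonpos_mask] / probs[nonpos_mask].sum()

    n_pun = int(round(spec.n_proteins * spec.pun_fraction))
    pun_flags = [i < n_pun for i in range(spec.n_proteins)]

    records: list[ProteinRecord] = []
    manifest_proteins: dict[str, dict] = {}
    for i, is_pun in enumerate(pun_flags):
        pid = f"{id_prefix}{i:06d}"
        entry = _generate_protein(pid, is_pun, spec, pattern, rule, rng,
                                  letters, probs, np_letters, np_probs)
        records.append(entry[0])
        manifest_proteins[pid] = entry[1]

    tracks: dict[str, DisorderTrack] = {}
    for rec in records:
        info = manifest_proteins[rec.id]
        mu = spec.disorder_mu + (spec.disorder_shift if info["is_pun"] else 0.0)
        mu = float(np.clip(mu, 0.02, 0.98))
        nu = spec.disorder_concentration
        scores = rng.beta(mu * nu, (1 - mu) * nu, size=rec.length)
        tracks[rec.id] = DisorderTrack(rec.id, np.clip(scores, 0.0, 1.0))
        info["disorder_mean_target"] = mu

    annotation = _generate_annotation(spec, manifest_proteins, rng)
    for tid, term in annotation.items():
        for pid in term.members:
            manifest_proteins[pid]["terms"].append(tid)
    for info in manifest_proteins.values():
        info["terms"].sort()

    manifest = {
        "seed": int(seed),
        "spec": _spec_to_dict(spec),
        "enriched_term": spec.enriched_term,
        "proteins": manifest_proteins,
    }
    return SyntheticDataset(records, tracks, annotation, manifest)


def _generate_protein(pid, is_pun, spec, pattern, rule, rng,
                      letters, probs, np_letters, np_probs):
    for _ in range(spec.resample_budget):
        if is_pun:
            m = int(rng.integers(spec.motifs_min, spec.motifs_max + 1))
            motifs = [sample_motif(pattern, rng) for _ in range(m)]
            need = sum(len(s) + 2 for s in motifs) + 10
            lo = max(spec.length_min, need)
            length = int(rng.integers(lo, max(spec.length_max, lo) + 1))
            cluster_k = spec.cluster_min if rng.random() < spec.p_cluster else 0
            intervals = _place_intervals(
                [len(s) for s in motifs], length, cluster_k, spec.window_aa, rng
            )
            if intervals is None:
                continue
            seq = _random_residues(length, letters, probs, rng)
            # intervals come back sorted by start; re-pair motif strings to
            # intervals of identical length
            intervals_sorted = intervals
            pool: dict[int, list[str]] = {}
            for s_ in motifs:
                pool.setdefault(len(s_), []).append(s_)
            placed = []
            feasible = True
            for (s, e) in intervals_sorted:
                L = e - s
                if not pool.get(L):
                    feasible = False
                    break
                placed.append(pool[L].pop())
            if not feasible:
                continue
            for (s, e), mot in zip(intervals_sorted, placed):
                seq[s:e] = np.array(list(mot), dtype="<U1")
                seq[s - 1] = np_letters[rng.choice(len(np_letters), p=np_probs)]
                if e < length:
                    seq[e] = np_letters[rng.choice(len(np_letters), p=np_probs)]
            sequence = "".join(seq)
            rec = ProteinRecord(pid, "", sequence)
            matches = scan_sequence(rec, pattern)
            detected = [(mm.start, mm.end) for mm in matches]
            if len(detected) != m or not set(intervals_sorted) <= set(detected):
                continue
            prof = classify_protein(pid, rec.length, matches, rule)
            if not prof.is_pun:
                continue
            info = {
                "length": rec.length,
                "is_pun": True,
                "implanted": [list(iv) for iv in intervals_sorted],
                "terms": [],
            }
            return rec, info
        else:
            length = int(rng.integers(spec.length_min, spec.length_max + 1))
            sequence = "".join(_random_residues(length, letters, probs, rng))
            rec = ProteinRecord(pid, "", sequence)
            if scan_sequence(rec, pattern):
                continue
            info = {"length": rec.length, "is_pun": False, "implanted": [], "terms": []}
            return rec, info
    raise RuntimeError(
        f"resampling budget exhausted for {pid}; "
        "lower the R/K background frequencies or raise the budget"
    )


def _generate_annotation(spec, manifest_proteins, rng):
    terms: dict[str, set[str]] = {spec.enriched_term: set()}
    decoys = [f"TERM:DECOY{i:02d}" for i in range(spec.n_decoy_terms)]
    for tid in decoys:
        terms[tid] = set()
    for pid, info in manifest_proteins.items():
        q = spec.q_pun if info["is_pun"] else spec.q_background
        if rng.random() < q:
            terms[spec.enriched_term].add(pid)
        for tid in decoys:
            if rng.random() < spec.decoy_coverage:
                terms[tid].add(pid)
    names = {spec.enriched_term: "synthetic enriched process"}
    names.update({tid: f"synthetic decoy process {i:02d}" for i, tid in enumerate(decoys)})
    return {
        tid: GeneSetAnnotation(tid, names[tid], frozenset(ids))
        for tid, ids in terms.items()
    }


def generate_ortholog_table(
    source_manifest: dict,
    target_manifest: dict,
    rng: np.random.Generator,
    frac_one2one: float = 0.6,
    frac_one2many: float = 0.1,
):
    """Pair source PUN proteins to target PUN proteins.

    A fraction maps one2one (distinct targets), a further fraction
    one2many (two targets each); the remainder has no ortholog row.
    """
    from .orthologs import OrthologTable

    src_pun = sorted(
        pid for pid, info in source_manifest["proteins"].items() if info["is_pun"]
    )
    tgt_pun = sorted(
        pid for pid, info in target_manifest["proteins"].items() if info["is_pun"]
    )
    if not tgt_pun:
        return OrthologTable.from_rows([])
    order = list(rng.permutation(len(src_pun)))
    n11 = int(round(frac_one2one * len(src_pun)))
    n1m = int(round(frac_one2many * len(src_pun)))
    rows = []
    tgt_cycle = list(rng.permutation(len(tgt_pun)))
    ti = 0

    def next_target() -> str:
        nonlocal ti
        t = tgt_pun[tgt_cycle[ti % len(tgt_cycle)]]
        ti += 1
        return t

    for j in order[:n11]:
        rows.append((src_pun[j], next_target(), "one2one"))
    for j in order[n11 : n11 + n1m]:
        rows.append((src_pun[j], next_target(), "one2many"))
        rows.append((src_pun[j], next_target(), "one2many"))
    return OrthologTable.from_rows(rows)


def _spec_to_dict(spec: SyntheticSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["frequencies"] = {k: float(v) for k, v in sorted(spec.frequencies.items())}
    return d


def write_bundle(
    spec: SyntheticSpec,
    seed: int,
    out_dir: str | Path,
    target_spec: SyntheticSpec | None = None,
) -> dict:
    """Generate and write a complete synthetic bundle to ``out_dir``.

    Files: proteome.fasta, disorder.tsv, annotation.tsv, target_proteome.fasta,
    orthologs.tsv, manifest.json (source manifest; the target manifest is
    stored under manifest["target"]).
    """
    from . import io as pio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    source = generate_proteome(spec, seed, id_prefix="SYN")
    tspec = target_spec or spec
    target = generate_proteome(tspec, seed + 1, id_prefix="TGT")
    rng = np.random.default_rng(seed + 2)
    table = generate_ortholog_table(source.manifest, target.manifest, rng)

    pio.write_fasta(source.records, out / "proteome.fasta")
    pio.write_fasta(target.records, out / "target_proteome.fasta")
    pio.write_disorder_tsv(source.tracks, out / "disorder.tsv")
    pio.write_annotation_tsv(source.annotation, out / "annotation.tsv")
    pio.write_ortholog_tsv(table, out / "orthologs.tsv")
    manifest = dict(source.manifest)
    manifest["target"] = target.manifest
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
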