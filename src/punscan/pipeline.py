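"""End-to-end run: scan -> disorder -> enrichment -> orthologs -> report.

A single :class:`RunConfig` (typically loaded from YAML, with CLI flags
overriding) drives all stages.  Optional inputs that are absent cause
their stage to be skipped with an explicit SKIPPED log line; the effective
merged configuration is written beside the results, and the JSON report
carries every headline number.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as pio
from .disorder import mean_disorder, rank_sum_test, sample_background
from .enrichment import hypergeom_enrich, membership_fractions
from .motif import MotifPattern
from .orthologs import conservation_summary
from .proteome import PunCallRule, rank_by_density, scan_proteome

__all__ = ["RunConfig", "run_full"]

log = logging.getLogger("punscan")


@dataclass
class RunConfig:
    fasta: str
    out_dir: str = "punscan-out"
    # classification rule
    min_motifs: int = 5
    cluster_min: int = 3
    window_aa: int = 150
    require_cluster: bool = True
    cluster_mode: str = "span"
    # optional stage inputs
    disorder_scores: str | None = None
    annotation: str | None = None
    annotation_format: str = "tsv"  # "tsv" | "gaf"
    membership_terms: list[str] = field(default_factory=list)
    ortholog_table: str | None = None
    target_fasta: str | None = None
    # stage parameters
    n_background: int = 500
    seed: int = 42
    alpha: float = 0.05
    min_set: int = 10
    max_set: int = 500
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def rule(self) -> PunCallRule:
        return PunCallRule(
            min_motifs=self.min_motifs,
            cluster_min=self.cluster_min,
            window_aa=self.window_aa,
            require_cluster=self.require_cluster,
            cluster_mode=self.cluster_mode,
        )

    def validate_paths(self) -> None:
        required = [("fasta", self.fasta)]
        optional = [
            ("disorder_scores", self.disorder_scores),
            ("annotation", self.annotation),
            ("ortholog_table", self.ortholog_table),
            ("target_fasta", self.target_fasta),
        ]
        for name, path in required + [(n, p) for n, p in optional if p]:
            if path is None or not Path(path).exists():
                raise FileNotFoundError(f"{name}: {path}")


def run_full(config: RunConfig, pattern: MotifPattern | None = None) -> dict:
    """Execute every configured stage and return the consolidated report."""
    config.validate_paths()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    try:
        report = _run_stages(config, pattern or MotifPattern(), out)
    finally:
        log.removeHandler(handler)
        handler.close()
    return report


def _run_stages(config: RunConfig, pattern: MotifPattern, out: Path) -> dict:
    with open(out / "effective-config.yaml", "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)

    rule = config.rule()
    log.info("scan: fasta=%s rule=%s", config.fasta, rule)
    profiles, summary = scan_proteome(config.fasta, pattern, rule)
    pio.write_profiles_tsv(profiles, out / "profiles.tsv")
    pio.write_matches_tsv(
        (m for p in profiles for m in p.matches), out / "matches.tsv"
    )
    ranking = rank_by_density(profiles)
    ranking.to_csv(out / "density_ranking.tsv", sep="\t")
    top5 = [
        {
            "protein_id": row.protein_id,
            "motif_count": int(row.motif_count),
            "length": int(row.length),
            "density_per_100aa": float(row.density_per_100aa),
        }
        for row in ranking.head(5).itertuples()
    ]
    report: dict = {
        "scan": {
            "n_proteins": summary.n_proteins,
            "n_pun": summary.n_pun,
            "max_motif_count": summary.max_motif_count,
            "top5_density": top5,
        }
    }
    pun_ids = [p.protein_id for p in profiles if p.is_pun]
    universe = [p.protein_id for p in profiles]

    if config.disorder_scores:
        log.info("disorder: scores=%s n_background=%d seed=%d",
                 config.disorder_scores, config.n_background, config.seed)
        tracks = pio.read_disorder_tsv(config.disorder_scores)
        background_ids = sample_background(profiles, config.n_background, config.seed)
        pun_means = [mean_disorder(tracks[i]) for i in pun_ids if i in tracks]
        bg_means = [mean_disorder(tracks[i]) for i in background_ids if i in tracks]
        rs = rank_sum_test(pun_means, bg_means)
        report["disorder"] = {
            "n_pun": len(pun_means),
            "n_background": len(bg_means),
            "mean_pun": sum(pun_means) / len(pun_means),
            "mean_background": sum(bg_means) / len(bg_means),
            "statistic_U": rs.statistic,
            "p_value": rs.p_value,
            "method": rs.method,
        }
    else:
        log.info("disorder: SKIPPED (no scores supplied)")

    if config.annotation:
        log.info("enrichment: annotation=%s alpha=%g", config.annotation, config.alpha)
        reader = pio.read_gaf if config.annotation_format == "gaf" else pio.read_term_tsv
        annotation = reader(config.annotation)
        results = hypergeom_enrich(
            pun_ids, annotation, universe, config.min_set, config.max_set
        )
        rows = [dataclasses.asdict(r) for r in results]
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "enrichment.tsv", sep="\t", index=False)
        significant = [r for r in results if r.p_adjusted < config.alpha]
        report["enrichment"] = {
            "n_terms_tested": len(results),
            "n_significant": len(significant),
            "top_terms": [
                {"term_id": r.term_id, "p_adjusted": r.p_adjusted}
                for r in results[:5]
            ],
        }
        if config.membership_terms:
            frac = membership_fractions(pun_ids, config.membership_terms, annotation)
            frac.to_csv(out / "membership_fractions.tsv", sep="\t", index=False)
            report["membership_fractions"] = {
                row.term_id: {"annotated": int(row.annotated), "fraction": float(row.fraction)}
                for row in frac.itertuples()
            }
    else:
        log.info("enrichment: SKIPPED (no annotation supplied)")

    if config.ortholog_table and config.target_fasta:
        log.info("orthologs: table=%s target=%s", config.ortholog_table, config.target_fasta)
        table = pio.read_ortholog_tsv(config.ortholog_table)
        target_profiles, _ = scan_proteome(config.target_fasta, pattern, rule)
        cs = conservation_summary(profiles, target_profiles, table)
        report["orthologs"] = {
            "n_source_pun": cs.n_source_pun,
            "fraction_no_ortholog": cs.fraction_no_ortholog,
            "fraction_mappable": cs.fraction_mappable,
            "fraction_conserved_pun": cs.fraction_conserved_pun,
            "fraction_target_orthologs_pun": cs.fraction_target_orthologs_pun,
        }
    else:
        log.info("orthologs: SKIPPED (table or target proteome missing)")

    pio.write_json(report, out / "report.json")
    log.info("done: report written to %s", out / "report.json")
    return report
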