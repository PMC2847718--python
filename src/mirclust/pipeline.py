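"""End-to-end run orchestration: clusters -> consistency -> homogeneity ->
enrichment, with provenance manifest and per-stage TSV reports."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

from . import __version__
from .clusters import ClusterConfig, call_clusters, clusters_frame, membership_counts
from .consistency import consistency_report
from .enrichment import (
    EnrichmentBackground,
    enrichment_report,
    global_positive_lod_pvalue,
    mean_enrichment,
)
from .homogeneity import homogeneity_report
from .io import read_annotation_tsv, read_gff3_positions, write_report_tsv

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Resolved configuration of one full pipeline run."""

    table_path: str
    gff_path: str
    out_dir: str
    threshold_bp: int = 5000
    anchor: str = "gap"
    respect_strand: bool = False
    permutations: int = 10_000
    shuffles: int = 100_000
    seed: int = 0
    tie_rule: str = "strict"
    microarray_only: bool = True
    min_mirnas: int = 3
    strict_cross_denominator: bool = False
    min_cluster_mirnas: int = 1
    stratify_by: str | None = None


def run_all(config: RunConfig) -> dict[str, Path]:
    """Execute every stage and write all reports under ``config.out_dir``.

    Writes, in order: clusters.tsv, consistency.tsv (+ detail files),
    homogeneity.tsv, enrichment.tsv, summary.txt and manifest.json.  On a
    stage failure, partial outputs are kept next to a FAILED marker naming
    the stage, and the exception propagates.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "config": asdict(config),
        "version": __version__,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    paths: dict[str, Path] = {"manifest": out / "manifest.json"}
    stage = "load"
    try:
        table = read_annotation_tsv(config.table_path)
        positions = read_gff3_positions(config.gff_path)

        stage = "clusters"
        cluster_cfg = ClusterConfig(
            threshold_bp=config.threshold_bp,
            anchor=config.anchor,
            respect_strand=config.respect_strand,
        )
        clusters, singletons = call_clusters(positions, cluster_cfg)
        x_all, y_all, n_loci = membership_counts(clusters, singletons)
        paths["clusters"] = out / "clusters.tsv"
        write_report_tsv(
            clusters_frame(clusters, positions),
            paths["clusters"],
            comments=[
                f"threshold_bp={config.threshold_bp} anchor={config.anchor}",
                f"x_overall={x_all} y_overall={y_all} n_clusters={n_loci}",
            ],
        )

        stage = "consistency"
        summary, detail, cross_detail = consistency_report(
            table,
            min_mirnas=config.min_mirnas,
            strict_denominator=config.strict_cross_denominator,
        )
        paths["consistency"] = out / "consistency.tsv"
        write_report_tsv(summary, paths["consistency"], ["per-disease consistency"])
        write_report_tsv(detail, out / "consistency_intra_detail.tsv", [])
        write_report_tsv(cross_detail, out / "consistency_cross_detail.tsv", [])

        stage = "homogeneity"
        hom = homogeneity_report(
            table,
            clusters,
            n_permutations=config.permutations,
            seed=config.seed,
            tie_rule=config.tie_rule,
        )
        paths["homogeneity"] = out / "homogeneity.tsv"
        write_report_tsv(
            hom,
            paths["homogeneity"],
            [f"permutations={config.permutations} seed={config.seed} tie_rule={config.tie_rule}"],
        )

        stage = "enrichment"
        background = EnrichmentBackground(x_all, y_all, n_loci)
        enr = enrichment_report(
            table,
            clusters,
            background,
            microarray_only=config.microarray_only,
            min_cluster_mirnas=config.min_cluster_mirnas,
        )
        paths["enrichment"] = out / "enrichment.tsv"
        write_report_tsv(
            enr,
            paths["enrichment"],
            [f"background x_overall={x_all} y_overall={y_all} n_loci={n_loci}"],
        )
        glob = global_positive_lod_pvalue(
            enr, background, n_shuffles=config.shuffles, seed=config.seed
        )
        summary_lines = [
            f"miRNAs: {x_all + y_all} ({x_all} clustered in {n_loci} clusters, {y_all} singletons)",
            f"diseases analyzed (enrichment): {glob.n_diseases}",
            f"diseases with positive LOD: {glob.n_positive_observed}"
            f" ({100 * glob.n_positive_observed / max(glob.n_diseases, 1):.1f}%)",
            f"global shuffle p-value ({glob.n_shuffles} shuffles): {glob.p_value:.4g}",
        ]
        enriched = enr[enr["classification"] == "enriched"]
        if len(enriched):
            mean_lod, fold_of_mean, mean_of_folds = mean_enrichment(enriched["lod"])
            summary_lines.append(
                f"enriched diseases: mean LOD={mean_lod:.3f}"
                f" (fold of mean {fold_of_mean:.2f}, mean of folds {mean_of_folds:.2f})"
            )
        if config.stratify_by:
            for value, grp in enr.groupby(config.stratify_by):
                if not len(grp):
                    continue
                g = global_positive_lod_pvalue(
                    grp, background, n_shuffles=config.shuffles, seed=config.seed
                )
                summary_lines.append(
                    f"stratum {config.stratify_by}={value}: {g.n_positive_observed}/"
                    f"{g.n_diseases} positive, p={g.p_value:.4g}"
                )
        paths["summary"] = out / "summary.txt"
        paths["summary"].write_text("\n".join(summary_lines) + "\n")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage={stage}: {exc}\n")
        raise
    return paths
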