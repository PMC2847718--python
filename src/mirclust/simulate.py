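"""Synthetic miRNA genomes and curated-style annotation tables.

The generator plants known ground truth so every pipeline stage can be
validated without external downloads:

* a genome whose miRNAs are laid out in polycistronic clusters (intra-
  cluster gaps well below the calling threshold) separated by large
  inter-locus gaps, so cluster calling recovers the planted partition
  exactly;
* per-disease deregulation where a selected cluster enters the disease as
  one unit — all members, one shared direction — with probability ``rho``
  (cluster co-deregulation), and member miRNAs behave independently
  otherwise;
* paired patient (in-vivo) and cell-culture (in-vitro) study entries whose
  directions agree with probability ``kappa`` per miRNA, so the measured
  cross-consistency converges to the planted concordance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .io import (
    AnnotationTable,
    ExpressionObservation,
    MiRNAPosition,
    write_annotation_tsv,
    write_gff3_positions,
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset.

    Genome layout: ``n_mirnas`` genes, a target ``clustered_fraction`` of
    them grouped into clusters whose sizes follow a truncated geometric law
    on 2..6 (or an explicit ``cluster_sizes`` list), spread over
    ``n_chromosomes``.  Members of one cluster sit ``intra_cluster_gap_bp``
    apart; distinct loci are ``inter_locus_gap_bp`` apart, far beyond any
    calling threshold in use.

    Disease model: each of ``n_diseases`` diseases accumulates deregulated
    units until about ``mirnas_per_disease`` miRNAs are associated.  ``rho``
    is the cluster co-deregulation probability, ``kappa`` the in-vivo /
    in-vitro direction concordance, ``direction_up_prob`` the chance a unit
    is upregulated.  Each design contributes ``entries_per_design`` study
    entries per disease.
    """

    n_mirnas: int = 695
    clustered_fraction: float = 0.345
    cluster_sizes: tuple[int, ...] | None = None
    n_chromosomes: int = 3
    intra_cluster_gap_bp: int = 1_000
    inter_locus_gap_bp: int = 100_000
    mirna_length_bp: int = 80
    n_diseases: int = 15
    mirnas_per_disease: int = 100
    rho: float = 0.8
    kappa: float = 0.75
    direction_up_prob: float = 0.5
    entries_per_design: int = 2
    randomize_placement: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("clustered_fraction", "rho", "kappa", "direction_up_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.intra_cluster_gap_bp >= self.inter_locus_gap_bp:
            raise ValueError("intra_cluster_gap_bp must be < inter_locus_gap_bp")
        if self.mirnas_per_disease > self.n_mirnas:
            raise ValueError("mirnas_per_disease cannot exceed n_mirnas")
        if self.cluster_sizes is not None and any(s < 2 for s in self.cluster_sizes):
            raise ValueError("cluster sizes must be >= 2")


@dataclass(frozen=True)
class SyntheticGenome:
    positions: tuple[MiRNAPosition, ...]
    planted_clusters: tuple[frozenset[str], ...]

    @property
    def clustered_ids(self) -> frozenset[str]:
        return frozenset(m for c in self.planted_clusters for m in c)


@dataclass
class SyntheticDataset:
    """Genome + annotation table + the planted ground truth."""

    genome: SyntheticGenome
    table: AnnotationTable
    disease_directions: dict[str, dict[str, str]]
    config: SimulationConfig

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write positions.gff3, dump.tsv and truth.tsv; returns the paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {
            "positions": out_dir / "positions.gff3",
            "table": out_dir / "dump.tsv",
            "truth": out_dir / "truth.tsv",
        }
        write_gff3_positions(self.genome.positions, paths["positions"])
        write_annotation_tsv(self.table, paths["table"])
        rows = []
        cluster_of = {
            m: f"planted_{i}"
            for i, c in enumerate(self.genome.planted_clusters)
            for m in c
        }
        for disease in self.disease_directions:
            for mirna, direction in self.disease_directions[disease].items():
                rows.append(
                    {
                        "disease": disease,
                        "mirna": mirna,
                        "direction": direction,
                        "unit": cluster_of.get(mirna, "singleton"),
                    }
                )
        pd.DataFrame(rows, columns=["disease", "mirna", "direction", "unit"]).to_csv(
            paths["truth"], sep="\t", index=False
        )
        return paths


_SIZE_CHOICES = np.arange(2, 7)
_SIZE_WEIGHTS = 0.5 ** np.arange(5)
_SIZE_PROBS = _SIZE_WEIGHTS / _SIZE_WEIGHTS.sum()


def _draw_cluster_sizes(n_clustered: int, rng: np.random.Generator) -> list[int]:
    if n_clustered == 0:
        return []
    if n_clustered < 2:
        raise ValueError(
            "clustered_fraction leaves a single clustered miRNA; clusters need >= 2"
        )
    sizes: list[int] = []
    remaining = n_clustered
    while remaining >= 2:
        s = int(rng.choice(_SIZE_CHOICES, p=_SIZE_PROBS))
        s = min(s, remaining)
        if remaining - s == 1:  # never strand a lone leftover miRNA
            s += 1
        sizes.append(s)
        remaining -= s
    return sizes


def simulate_genome(config: SimulationConfig) -> SyntheticGenome:
    """Lay out a genome with planted clusters and singleton loci.

    Exactly ``round(n_mirnas * clustered_fraction)`` miRNAs end up in
    clusters (or ``sum(cluster_sizes)`` when given explicitly); cluster
    recovery by distance-based calling is exact at any threshold between
    ``intra_cluster_gap_bp`` and ``inter_locus_gap_bp``.
    """
    rng = np.random.default_rng([config.seed, 0x67])
    if config.cluster_sizes is not None:
        sizes = list(config.cluster_sizes)
    else:
        sizes = _draw_cluster_sizes(
            int(round(config.n_mirnas * config.clustered_fraction)), rng
        )
    n_clustered = sum(sizes)
    if n_clustered > config.n_mirnas:
        raise ValueError("cluster sizes exceed n_mirnas")
    n_singletons = config.n_mirnas - n_clustered

    # units: clusters first, then singletons; interleaved over chromosomes
    units: list[int] = [*sizes, *([1] * n_singletons)]
    names = iter(f"mir-{i + 1}" for i in range(config.n_mirnas))
    cursors = {f"chr{c + 1}": 10_000 for c in range(config.n_chromosomes)}
    chrom_names = list(cursors)
    positions: list[MiRNAPosition] = []
    planted: list[frozenset[str]] = []
    for u, size in enumerate(units):
        chrom = chrom_names[u % len(chrom_names)]
        members = []
        for j in range(size):
            if config.randomize_placement:
                gap = int(rng.integers(0, config.intra_cluster_gap_bp + 1))
            else:
                gap = config.intra_cluster_gap_bp
            start = cursors[chrom] if j == 0 else cursors[chrom] + gap
            name = next(names)
            positions.append(
                MiRNAPosition(
                    mirna_id=name,
                    chrom=chrom,
                    start=start,
                    end=start + config.mirna_length_bp - 1,
                    strand="+" if u % 2 == 0 else "-",
                )
            )
            members.append(name)
            cursors[chrom] = start + config.mirna_length_bp - 1
        if config.randomize_placement:
            skip = int(rng.integers(config.inter_locus_gap_bp, 2 * config.inter_locus_gap_bp))
        else:
            skip = config.inter_locus_gap_bp
        cursors[chrom] += skip
        if size >= 2:
            planted.append(frozenset(members))
    return SyntheticGenome(tuple(positions), tuple(planted))


def simulate_disease_associations(
    genome: SyntheticGenome, config: SimulationConfig
) -> dict[str, dict[str, str]]:
    """Draw each disease's deregulated miRNAs and their directions.

    Candidate miRNAs are visited in random order.  A clustered candidate
    recruits its whole cluster with one shared direction with probability
    ``rho``; otherwise (and always for singletons) it enters alone with an
    independent direction.  Accumulation stops once the disease holds at
    least ``mirnas_per_disease`` miRNAs, so whole-cluster recruitment can
    overshoot the target slightly.
    """
    rng = np.random.default_rng([config.seed, 0xD15])
    cluster_of: dict[str, frozenset[str]] = {
        m: c for c in genome.planted_clusters for m in c
    }
    all_ids = [p.mirna_id for p in genome.positions]
    out: dict[str, dict[str, str]] = {}
    for d in range(config.n_diseases):
        disease = f"disease_{d:02d}"
        assoc: dict[str, str] = {}
        order = rng.permutation(len(all_ids))
        for idx in order:
            if len(assoc) >= config.mirnas_per_disease:
                break
            m = all_ids[idx]
            if m in assoc:
                continue
            draw_dir = "up" if rng.random() < config.direction_up_prob else "down"
            if m in cluster_of and rng.random() < config.rho:
                for member in sorted(cluster_of[m]):
                    assoc.setdefault(member, draw_dir)
            else:
                assoc[m] = draw_dir
        out[disease] = assoc
    return out


def simulate_study_entries(
    disease_directions: Mapping[str, Mapping[str, str]],
    config: SimulationConfig,
) -> AnnotationTable:
    """Expand per-disease directions into paired study entries.

    In-vivo entries report the planted direction (method: microarray, with
    a cohort size).  For each miRNA one in-vitro direction is drawn — the
    planted one with probability ``kappa``, flipped otherwise — and shared
    by that disease's in-vitro entries, so eligible-miRNA agreement between
    the designs estimates ``kappa`` directly.
    """
    rng = np.random.default_rng([config.seed, 0x5E])
    flip = {"up": "down", "down": "up"}
    observations: list[ExpressionObservation] = []
    for d, disease in enumerate(sorted(disease_directions)):
        directions = disease_directions[disease]
        disease_class = "cancer" if d % 2 == 0 else "non-cancer"
        vitro_dir = {
            m: (directions[m] if rng.random() < config.kappa else flip[directions[m]])
            for m in sorted(directions)
        }
        for design, dirmap in (("in_vivo", directions), ("in_vitro", vitro_dir)):
            tag = "V" if design == "in_vivo" else "T"
            for r in range(config.entries_per_design):
                entry_id = f"E{d:03d}{tag}{r}"
                pubmed_id = f"PM{d:04d}{tag}{r}"
                cohort = int(rng.integers(10, 120)) if design == "in_vivo" else None
                for m in sorted(dirmap):
                    observations.append(
                        ExpressionObservation(
                            entry_id=entry_id,
                            pubmed_id=pubmed_id,
                            disease=disease,
                            disease_class=disease_class,
                            design=design,
                            method="microarray",
                            mirna_id=m,
                            direction=dirmap[m],
                            fold_change=float(np.round(rng.lognormal(0.7, 0.5), 3)),
                            cohort_size=cohort,
                        )
                    )
    return AnnotationTable(observations, provenance="synthetic")


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full synthetic dataset: genome, associations and annotation table."""
    genome = simulate_genome(config)
    directions = simulate_disease_associations(genome, config)
    table = simulate_study_entries(directions, config)
    return SyntheticDataset(
        genome=genome,
        table=table,
        disease_directions=directions,
        config=config,
    )
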