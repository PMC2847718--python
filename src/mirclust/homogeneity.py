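"""Expression homogeneity of miRNA clusters across diseases.

For each disease, every annotated miRNA is collapsed to one up/down
consensus (majority vote; ties dropped).  A cluster is *present* in a
disease when at least half of its members carry a consensus there (both
members, for two-member clusters), and *homogeneous* when all present
members share one direction.  The homogeneous-fraction of a cluster is
T/(T+F) over the diseases where it is present.

The permutation null redistributes, within every disease independently,
the observed up/down labels uniformly at random over that disease's
annotated miRNAs — clustered or not — preserving the disease's up/down
counts, and recomputes the cluster's homogeneous fraction over the same
present-sets.  Under this label shuffle the number of "up" labels landing
on a cluster's k present members is hypergeometric in the disease's
(up, down) totals, which is how the Monte-Carlo draws are generated.
"""

from __future__ import annotations

import zlib
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clusters import MiRNACluster
from .io import AnnotationTable


@dataclass(frozen=True)
class DiseaseClusterView:
    """One disease's consensus directions and the clusters present in it."""

    disease: str
    mirna_directions: Mapping[str, str]
    clusters_present: Mapping[str, frozenset[str]]

    @property
    def n_up(self) -> int:
        return sum(1 for d in self.mirna_directions.values() if d == "up")

    @property
    def n_down(self) -> int:
        return sum(1 for d in self.mirna_directions.values() if d == "down")


@dataclass(frozen=True)
class HomogeneityResult:
    cluster_id: str
    T: int
    F: int
    homogeneous_fraction: float
    p_value: float
    n_permutations: int
    seed: int


def majority_direction(directions: Iterable[str]) -> str | None:
    """Majority up/down call; None on a tie."""
    counts = Counter(directions)
    up, down = counts.get("up", 0), counts.get("down", 0)
    if up == down:
        return None
    return "up" if up > down else "down"


def cluster_presence_ok(n_present: int, cluster_size: int) -> bool:
    """Presence rule: at least half the members; both, for pairs."""
    if cluster_size == 2:
        return n_present == 2
    return 2 * n_present >= cluster_size


def build_disease_views(
    table: AnnotationTable, clusters: Sequence[MiRNACluster]
) -> list[DiseaseClusterView]:
    """Per-disease consensus directions and surviving cluster present-sets.

    The consensus pools all of a miRNA's observations within the disease
    (any study design or method); tied votes drop the miRNA from the view.
    """
    per_disease: dict[str, dict[str, list[str]]] = {}
    for o in table:
        per_disease.setdefault(o.disease, {}).setdefault(o.mirna_id, []).append(
            o.direction
        )
    views: list[DiseaseClusterView] = []
    for disease, groups in per_disease.items():
        directions = {}
        for mirna, dirs in groups.items():
            consensus = majority_direction(dirs)
            if consensus is not None:
                directions[mirna] = consensus
        present: dict[str, frozenset[str]] = {}
        for c in clusters:
            members_here = frozenset(m for m in c.members if m in directions)
            if members_here and cluster_presence_ok(len(members_here), c.size):
                present[c.cluster_id] = members_here
        views.append(
            DiseaseClusterView(
                disease=disease,
                mirna_directions=directions,
                clusters_present=present,
            )
        )
    return views


def is_homogeneous(view: DiseaseClusterView, cluster_id: str) -> bool:
    """True iff all of the cluster's present members share one direction."""
    if cluster_id not in view.clusters_present:
        raise ValueError(f"cluster {cluster_id} not present in {view.disease}")
    dirs = {view.mirna_directions[m] for m in view.clusters_present[cluster_id]}
    return len(dirs) == 1


def homogeneous_fraction(
    views: Sequence[DiseaseClusterView], cluster_id: str
) -> tuple[int, int, float]:
    """(T, F, T/(T+F)) over the views where the cluster is present."""
    T = F = 0
    for view in views:
        if cluster_id not in view.clusters_present:
            continue
        if is_homogeneous(view, cluster_id):
            T += 1
        else:
            F += 1
    if T + F == 0:
        raise ValueError(f"cluster {cluster_id} present in no disease view")
    return T, F, T / (T + F)


def _cluster_rng(seed: int, cluster_id: str) -> np.random.Generator:
    # per-cluster stream independent of cluster iteration order
    return np.random.default_rng(
        [int(seed), zlib.crc32(cluster_id.encode("utf-8")) & 0x7FFFFFFF]
    )


def permutation_pvalue(
    views: Sequence[DiseaseClusterView],
    cluster_id: str,
    n_permutations: int = 10_000,
    seed: int = 0,
    tie_rule: str = "strict",
) -> float:
    """Monte-Carlo p-value for a cluster's homogeneous fraction.

    ``strict`` counts permuted fractions strictly exceeding the observed one
    (so a cluster homogeneous everywhere gets p = 0); ``inclusive`` counts
    ties as well, which keeps the p-value a valid test level.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if tie_rule not in {"strict", "inclusive"}:
        raise ValueError("tie_rule must be 'strict' or 'inclusive'")
    present_views = [v for v in views if cluster_id in v.clusters_present]
    if not present_views:
        raise ValueError(f"cluster {cluster_id} present in no disease view")
    _, _, observed = homogeneous_fraction(present_views, cluster_id)

    rng = _cluster_rng(seed, cluster_id)
    hom_counts = np.zeros(n_permutations, dtype=np.int64)
    for view in present_views:
        k = len(view.clusters_present[cluster_id])
        n_up, n_down = view.n_up, view.n_down
        ups = rng.hypergeometric(n_up, n_down, k, size=n_permutations)
        hom_counts += (ups == k) | (ups == 0)
    fractions = hom_counts / len(present_views)
    if tie_rule == "strict":
        return float(np.mean(fractions > observed))
    return float(np.mean(fractions >= observed - 1e-12))


def homogeneity_report(
    table: AnnotationTable,
    clusters: Sequence[MiRNACluster],
    n_permutations: int = 10_000,
    seed: int = 0,
    tie_rule: str = "strict",
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-cluster T/F counts, homogeneous-fraction and permutation p-value.

    Clusters never present in any disease are excluded.  Optional
    Benjamini-Hochberg q-values (off by default).
    """
    views = build_disease_views(table, clusters)
    rows = []
    for c in clusters:
        if not any(c.cluster_id in v.clusters_present for v in views):
            continue
        T, F, frac = homogeneous_fraction(views, c.cluster_id)
        p = permutation_pvalue(
            views, c.cluster_id, n_permutations=n_permutations, seed=seed,
            tie_rule=tie_rule,
        )
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "n_members": c.size,
                "T": T,
                "F": F,
                "homogeneous_fraction": frac,
                "p_value": p,
            }
        )
    report = pd.DataFrame(
        rows,
        columns=["cluster_id", "n_members", "T", "F", "homogeneous_fraction", "p_value"],
    )
    if bh_correction and len(report):
        from statsmodels.stats.multitest import multipletests

        report["q_value"] = multipletests(report["p_value"], method="fdr_bh")[1]
    return report
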