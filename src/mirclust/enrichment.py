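"""LOD-score enrichment of clustered miRNAs among disease-associated miRNAs.

For each disease d, x_d counts its associated miRNAs that lie in a
polycistronic cluster and y_d those that do not.  The miRNA-level log-odds
score compares the disease's clustered fraction with the genome-wide one:

    LOD_d = log2( (x_d / (x_d + y_d)) / (x_overall / (x_overall + y_overall)) )

A locus-level variant counts distinct clusters hit instead of member
miRNAs, with the genome-wide locus count as background; a non-cluster
variant scores the complementary fraction.  The global test shuffles, per
disease, which of its associated miRNAs are cluster members (sampling
labels without replacement from the genome-wide pool of x_overall
clustered / y_overall non-clustered miRNAs, i.e. a hypergeometric draw)
and asks how often at least as many diseases as observed attain a positive
LOD.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .clusters import MiRNACluster, membership_map
from .io import AnnotationTable

NEG_INF = float("-inf")


@dataclass(frozen=True)
class EnrichmentBackground:
    """Genome-wide clustered/non-clustered miRNA counts and locus count."""

    x_overall: int
    y_overall: int
    n_loci: int

    def __post_init__(self) -> None:
        if min(self.x_overall, self.y_overall, self.n_loci) < 0:
            raise ValueError("background counts must be non-negative")
        if self.x_overall + self.y_overall == 0:
            raise ValueError("background must contain at least one miRNA")

    @property
    def total(self) -> int:
        return self.x_overall + self.y_overall

    @property
    def clustered_fraction(self) -> float:
        return self.x_overall / self.total


@dataclass(frozen=True)
class DiseaseEnrichment:
    disease: str
    x_d: int
    y_d: int
    loci_hit: int
    lod: float
    lod_locus: float
    classification: str


@dataclass(frozen=True)
class GlobalEnrichment:
    n_diseases: int
    n_positive_observed: int
    p_value: float
    n_shuffles: int
    seed: int


def disease_counts(
    table: AnnotationTable,
    clusters: Sequence[MiRNACluster],
    microarray_only: bool = True,
) -> pd.DataFrame:
    """Per-disease (x_d, y_d, loci_hit) from deduplicated miRNA sets.

    With ``microarray_only`` (default), only patient-study microarray data
    enter (design ``in_vivo``, method ``microarray``) — profiling platforms
    survey most known miRNAs, so targeted methods such as RT-PCR would bias
    the clustered fraction.  A miRNA reported both up and down still counts
    once: association is a set property, direction is ignored here.
    """
    member_of = membership_map(clusters)
    assoc: dict[str, set[str]] = {}
    classes: dict[str, str] = {}
    for o in table:
        if microarray_only and not (o.design == "in_vivo" and o.method == "microarray"):
            continue
        assoc.setdefault(o.disease, set()).add(o.mirna_id)
        classes.setdefault(o.disease, o.disease_class)
    rows = []
    for disease, mirnas in assoc.items():
        clustered = {m for m in mirnas if m in member_of}
        loci = {member_of[m] for m in clustered}
        rows.append(
            {
                "disease": disease,
                "disease_class": classes[disease],
                "x_d": len(clustered),
                "y_d": len(mirnas) - len(clustered),
                "loci_hit": len(loci),
            }
        )
    return pd.DataFrame(
        rows, columns=["disease", "disease_class", "x_d", "y_d", "loci_hit"]
    )


def lod_mirna_level(x_d: int, y_d: int, background: EnrichmentBackground) -> float:
    """Base-2 log of disease vs genome-wide clustered-miRNA fraction."""
    n = x_d + y_d
    if n < 1:
        raise ValueError("x_d + y_d must be >= 1")
    if x_d == 0:
        return NEG_INF
    return math.log2((x_d / n) / background.clustered_fraction)


def lod_locus_level(loci_hit: int, y_d: int, background: EnrichmentBackground) -> float:
    """Locus-level LOD: distinct clusters hit vs the genome-wide locus pool."""
    n = loci_hit + y_d
    if n < 1:
        raise ValueError("loci_hit + y_d must be >= 1")
    if loci_hit == 0:
        return NEG_INF
    bg = background.n_loci / (background.n_loci + background.y_overall)
    return math.log2((loci_hit / n) / bg)


def lod_noncluster(x_d: int, y_d: int, background: EnrichmentBackground) -> float:
    """LOD of the non-clustered fraction (explicit formula, not -LOD_d)."""
    n = x_d + y_d
    if n < 1:
        raise ValueError("x_d + y_d must be >= 1")
    if y_d == 0:
        return NEG_INF
    bg = background.y_overall / background.total
    return math.log2((y_d / n) / bg)


def classify_disease(
    x_d: int, lod: float, min_cluster_mirnas: int = 1
) -> str:
    """Figure-style point classes: enriched / neutral / depleted.

    Depleted diseases have too few deregulated cluster members (x_d below
    ``min_cluster_mirnas``); enriched ones have a positive LOD; the rest
    are neutral.
    """
    if x_d < min_cluster_mirnas:
        return "depleted"
    if lod > 0:
        return "enriched"
    return "neutral"


def enrichment_report(
    table: AnnotationTable,
    clusters: Sequence[MiRNACluster],
    background: EnrichmentBackground,
    microarray_only: bool = True,
    min_cluster_mirnas: int = 1,
) -> pd.DataFrame:
    """Per-disease counts, miRNA/locus/non-cluster LODs and classification."""
    counts = disease_counts(table, clusters, microarray_only=microarray_only)
    lods, lods_locus, lods_nc, cls = [], [], [], []
    for row in counts.itertuples(index=False):
        lod = lod_mirna_level(row.x_d, row.y_d, background)
        lods.append(lod)
        lods_locus.append(lod_locus_level(row.loci_hit, row.y_d, background))
        lods_nc.append(lod_noncluster(row.x_d, row.y_d, background))
        cls.append(classify_disease(row.x_d, lod, min_cluster_mirnas))
    counts = counts.copy()
    counts["lod"] = lods
    counts["lod_locus"] = lods_locus
    counts["lod_noncluster"] = lods_nc
    counts["classification"] = cls
    return counts


def global_positive_lod_pvalue(
    counts: pd.DataFrame,
    background: EnrichmentBackground,
    n_shuffles: int = 100_000,
    seed: int = 0,
) -> GlobalEnrichment:
    """Global shuffle test for enrichment across all diseases.

    Each shuffle re-draws every disease's clustered count x_d from the
    genome-wide label pool (hypergeometric with the disease's n_d draws)
    and counts diseases with a positive LOD; the p-value is the fraction of
    shuffles whose positive count is at least the observed one (inclusive
    tie rule).  Diseases with zero associated miRNAs are excluded.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    counts = counts[(counts["x_d"] + counts["y_d"]) > 0]
    if not len(counts):
        raise ValueError("no disease with associated miRNAs")
    n_obs = 0
    for row in counts.itertuples(index=False):
        # integer form of lod_mirna_level(x_d, y_d) > 0, immune to rounding
        if row.x_d * background.total > background.x_overall * (row.x_d + row.y_d):
            n_obs += 1

    rng = np.random.default_rng(int(seed))
    pos = np.zeros(n_shuffles, dtype=np.int64)
    for row in counts.itertuples(index=False):
        n_d = row.x_d + row.y_d
        draws = rng.hypergeometric(
            background.x_overall, background.y_overall, n_d, size=n_shuffles
        )
        # positive LOD <=> x/n_d > x_overall/total, kept in integers
        pos += draws * background.total > background.x_overall * n_d
    p = float(np.mean(pos >= n_obs))
    return GlobalEnrichment(
        n_diseases=int(len(counts)),
        n_positive_observed=n_obs,
        p_value=p,
        n_shuffles=n_shuffles,
        seed=int(seed),
    )


def mean_enrichment(lods: Iterable[float]) -> tuple[float, float, float]:
    """Summaries over finite positive-LOD diseases.

    Returns (mean LOD, 2**mean LOD, mean of per-disease 2**LOD).  All three
    are reported because "average fold enrichment" can mean either the fold
    of the mean LOD or the mean of the per-disease folds.
    """
    finite = [v for v in lods if math.isfinite(v)]
    if not finite:
        raise ValueError("no finite LOD scores")
    mean_lod = float(np.mean(finite))
    return mean_lod, 2.0 ** mean_lod, float(np.mean([2.0 ** v for v in finite]))
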