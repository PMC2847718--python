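"""Partition miRNA genes into polycistronic clusters by genomic distance.

A cluster is a set of miRNAs in which each member lies within a distance
threshold (default 5 kb) of at least one other member on the same
chromosome — i.e. the connected components, of size >= 2, of the "within
threshold" relation.  Remaining miRNAs are singletons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io import MiRNAPosition


@dataclass(frozen=True)
class ClusterConfig:
    """Distance rule for cluster calling.

    threshold_bp
        Maximum separation (bp) linking two miRNAs; boundary inclusive.
    anchor
        ``gap``: separation is the gap between nearest ends (0 when
        overlapping).  ``start``: start-to-start distance.
    respect_strand
        Restrict linkage to same-strand pairs (off by default; the cluster
        definition uses chromosomal location only).
    """

    threshold_bp: int = 5000
    anchor: str = "gap"
    respect_strand: bool = False

    def __post_init__(self) -> None:
        if self.threshold_bp <= 0:
            raise ValueError("threshold_bp must be positive")
        if self.anchor not in {"gap", "start"}:
            raise ValueError("anchor must be 'gap' or 'start'")


@dataclass(frozen=True)
class MiRNACluster:
    """One polycistronic locus: >= 2 miRNAs chained within the threshold."""

    cluster_id: str
    chrom: str
    members: frozenset[str]
    span_start: int
    span_end: int

    @property
    def size(self) -> int:
        return len(self.members)


def pair_distance(a: MiRNAPosition, b: MiRNAPosition, anchor: str = "gap") -> int:
    """Separation in bp between two loci under the chosen anchor."""
    if anchor == "start":
        return abs(a.start - b.start)
    if a.start > b.start:
        a, b = b, a
    return max(0, b.start - a.end)


def _linked(a: MiRNAPosition, b: MiRNAPosition, config: ClusterConfig) -> bool:
    if a.chrom != b.chrom:
        return False
    if config.respect_strand and a.strand != b.strand:
        return False
    return pair_distance(a, b, config.anchor) <= config.threshold_bp


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def call_clusters(
    positions: Sequence[MiRNAPosition],
    config: ClusterConfig | None = None,
) -> tuple[list[MiRNACluster], set[str]]:
    """Single-linkage clustering of miRNA loci per chromosome.

    Returns the clusters (size >= 2, sorted by chromosome then leftmost
    coordinate) and the set of singleton miRNA ids; together they partition
    the input.  Cluster ids are deterministic: ``<chrom>:<leftmost member>``.
    """
    config = config or ClusterConfig()
    if not positions:
        raise ValueError("positions must be non-empty")
    ids = [p.mirna_id for p in positions]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate mirna_id in positions")

    by_chrom: dict[str, list[MiRNAPosition]] = {}
    for p in positions:
        by_chrom.setdefault(p.chrom, []).append(p)

    clusters: list[MiRNACluster] = []
    singletons: set[str] = set()
    for chrom in by_chrom:
        chrom_pos = sorted(by_chrom[chrom], key=lambda p: (p.start, p.end, p.mirna_id))
        n = len(chrom_pos)
        uf = _UnionFind(n)
        # sorted by start: for fixed i the separation to j grows with j,
        # so the scan can stop once the threshold is exceeded
        for i in range(n):
            for j in range(i + 1, n):
                if config.anchor == "gap":
                    sep = chrom_pos[j].start - chrom_pos[i].end
                else:
                    sep = chrom_pos[j].start - chrom_pos[i].start
                if sep > config.threshold_bp:
                    break
                if _linked(chrom_pos[i], chrom_pos[j], config):
                    uf.union(i, j)
        groups: dict[int, list[MiRNAPosition]] = {}
        for i, p in enumerate(chrom_pos):
            groups.setdefault(uf.find(i), []).append(p)
        for members in groups.values():
            if len(members) < 2:
                singletons.add(members[0].mirna_id)
                continue
            members.sort(key=lambda p: (p.start, p.end, p.mirna_id))
            clusters.append(
                MiRNACluster(
                    cluster_id=f"{chrom}:{members[0].mirna_id}",
                    chrom=chrom,
                    members=frozenset(p.mirna_id for p in members),
                    span_start=min(p.start for p in members),
                    span_end=max(p.end for p in members),
                )
            )
    clusters.sort(key=lambda c: (c.chrom, c.span_start, c.cluster_id))
    return clusters, singletons


def membership_counts(
    clusters: Iterable[MiRNACluster], singletons: Iterable[str]
) -> tuple[int, int, int]:
    """Genome-wide totals: (clustered miRNAs, non-clustered miRNAs, loci)."""
    clusters = list(clusters)
    x_overall = sum(c.size for c in clusters)
    y_overall = len(set(singletons))
    return x_overall, y_overall, len(clusters)


def membership_map(clusters: Iterable[MiRNACluster]) -> dict[str, str]:
    """mirna_id -> cluster_id for every clustered miRNA."""
    out: dict[str, str] = {}
    for c in clusters:
        for m in c.members:
            out[m] = c.cluster_id
    return out


def clusters_frame(
    clusters: Sequence[MiRNACluster], positions: Sequence[MiRNAPosition] | None = None
) -> pd.DataFrame:
    """Tabular cluster report (cluster_id, chrom, span, size, members)."""
    order: dict[str, int] = {}
    if positions is not None:
        order = {p.mirna_id: p.start for p in positions}
    rows = []
    for c in clusters:
        members = sorted(c.members, key=lambda m: (order.get(m, 0), m))
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "chrom": c.chrom,
                "span_start": c.span_start,
                "span_end": c.span_end,
                "size": c.size,
                "members": ",".join(members),
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cluster_id", "chrom", "span_start", "span_end", "size", "members"],
    )
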