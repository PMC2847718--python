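"""Concordance of up/down calls within and between study designs.

For each disease, observations are pooled across publications and grouped
by miRNA.  The *intra-consistency score* of a design (patient studies,
``in_vivo``, or cell-culture studies, ``in_vitro``) is the fraction of
miRNAs with at least two observations whose calls are unanimous.  The
*cross-consistency score* compares the per-design consensus directions:
among miRNAs with a defined consensus (unanimous, or a single observation)
in both designs, the fraction whose directions agree.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .io import AnnotationTable

INCONSISTENT = "inconsistent"


@dataclass(frozen=True)
class ConsistencyResult:
    """Per-disease concordance summary; None marks an undefined score."""

    disease: str
    intra_in_vivo: float | None
    intra_in_vitro: float | None
    cross: float | None
    n_mirnas_intra_vivo: int
    n_mirnas_intra_vitro: int
    n_mirnas_cross: int
    low_coverage: bool = False


def consensus_direction(directions) -> str:
    """Consensus of a multiset of up/down calls.

    Unanimous calls (including a single observation) yield that direction;
    any disagreement yields ``inconsistent``.
    """
    counts = Counter(directions)
    if not counts:
        raise ValueError("directions must be non-empty")
    if len(counts) == 1:
        return next(iter(counts))
    return INCONSISTENT


def _direction_groups(table: AnnotationTable, disease: str, design: str):
    # keyed by (entry_id, direction) so exact curation duplicates collapse
    entries: dict[str, dict[tuple[str, str], None]] = {}
    for o in table:
        if o.disease == disease and o.design == design:
            entries.setdefault(o.mirna_id, {})[(o.entry_id, o.direction)] = None
    return {m: [d for _, d in keys] for m, keys in entries.items()}


def intra_consistency(
    table: AnnotationTable, disease: str, design: str
) -> tuple[float | None, pd.DataFrame]:
    """Fraction of multiply-observed miRNAs with unanimous calls.

    Groups with fewer than two observations are discarded.  Returns the
    score (None when no eligible group exists) and a per-miRNA detail frame.
    """
    groups = _direction_groups(table, disease, design)
    rows = []
    n_consistent = 0
    n_eligible = 0
    for mirna in groups:
        dirs = groups[mirna]
        eligible = len(dirs) >= 2
        consensus = consensus_direction(dirs)
        consistent = eligible and consensus != INCONSISTENT
        if eligible:
            n_eligible += 1
            n_consistent += int(consistent)
        rows.append(
            {
                "disease": disease,
                "design": design,
                "mirna": mirna,
                "n_entries": len(dirs),
                "consensus": consensus,
                "eligible": eligible,
                "consistent": consistent,
            }
        )
    detail = pd.DataFrame(
        rows,
        columns=[
            "disease",
            "design",
            "mirna",
            "n_entries",
            "consensus",
            "eligible",
            "consistent",
        ],
    )
    score = n_consistent / n_eligible if n_eligible else None
    return score, detail


def cross_consistency(
    table: AnnotationTable,
    disease: str,
    strict_denominator: bool = False,
) -> tuple[float | None, pd.DataFrame]:
    """Agreement of per-design consensus directions for one disease.

    Default mode: miRNAs with an ``inconsistent`` consensus in either design
    are excluded from the denominator (no direction can be compared).  With
    ``strict_denominator`` they stay in the denominator, counted as
    non-consistent — a sensitivity-analysis mode.
    """
    vivo = {m: consensus_direction(d) for m, d in _direction_groups(table, disease, "in_vivo").items()}
    vitro = {m: consensus_direction(d) for m, d in _direction_groups(table, disease, "in_vitro").items()}
    shared = sorted(set(vivo) & set(vitro))
    rows = []
    n_agree = 0
    n_eligible = 0
    for mirna in shared:
        cv, ct = vivo[mirna], vitro[mirna]
        defined = INCONSISTENT not in (cv, ct)
        agree = defined and cv == ct
        eligible = defined or strict_denominator
        if eligible:
            n_eligible += 1
            n_agree += int(agree)
        rows.append(
            {
                "disease": disease,
                "mirna": mirna,
                "consensus_in_vivo": cv,
                "consensus_in_vitro": ct,
                "eligible": eligible,
                "agree": agree,
            }
        )
    detail = pd.DataFrame(
        rows,
        columns=[
            "disease",
            "mirna",
            "consensus_in_vivo",
            "consensus_in_vitro",
            "eligible",
            "agree",
        ],
    )
    score = n_agree / n_eligible if n_eligible else None
    return score, detail


def consistency_report(
    table: AnnotationTable,
    min_mirnas: int = 3,
    strict_denominator: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Per-disease summary plus per-miRNA intra and cross detail frames.

    ``min_mirnas`` is a coverage gate: diseases whose cross comparison rests
    on fewer eligible miRNAs are still reported but flagged low-coverage.
    """
    summaries = []
    details = []
    cross_details = []
    for disease in table.diseases:
        iv, div = intra_consistency(table, disease, "in_vivo")
        it, dit = intra_consistency(table, disease, "in_vitro")
        cx, dcx = cross_consistency(table, disease, strict_denominator=strict_denominator)
        n_cross = int(dcx["eligible"].sum()) if len(dcx) else 0
        summaries.append(
            ConsistencyResult(
                disease=disease,
                intra_in_vivo=iv,
                intra_in_vitro=it,
                cross=cx,
                n_mirnas_intra_vivo=int(div["eligible"].sum()) if len(div) else 0,
                n_mirnas_intra_vitro=int(dit["eligible"].sum()) if len(dit) else 0,
                n_mirnas_cross=n_cross,
                low_coverage=n_cross < min_mirnas,
            )
        )
        details.extend([div, dit])
        cross_details.append(dcx)
    summary = pd.DataFrame(
        [
            {
                "disease": r.disease,
                "intra_in_vivo": r.intra_in_vivo,
                "intra_in_vitro": r.intra_in_vitro,
                "cross": r.cross,
                "n_mirnas_intra_vivo": r.n_mirnas_intra_vivo,
                "n_mirnas_intra_vitro": r.n_mirnas_intra_vitro,
                "n_mirnas_cross": r.n_mirnas_cross,
                "low_coverage": r.low_coverage,
            }
            for r in summaries
        ]
    )
    detail = pd.concat(details, ignore_index=True) if details else pd.DataFrame()
    cross_detail = (
        pd.concat(cross_details, ignore_index=True) if cross_details else pd.DataFrame()
    )
    return summary, detail, cross_detail
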