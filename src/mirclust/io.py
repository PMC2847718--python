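"""Readers and writers for curated miRNA-disease annotation tables and
miRNA genomic coordinates, plus miRNA name normalization.

The annotation table is a UTF-8 TSV with a header row and columns
``entry_id, pubmed_id, disease, disease_class, design, method, mirna,
direction, fold_change, cohort_size`` (the last two may be empty).  Each row
is one curated data point: one deregulated miRNA in one published
experiment.  Genomic positions come from a standard GFF3 file such as a
miRBase genome annotation.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

logger = logging.getLogger(__name__)

VALID_DIRECTIONS = frozenset({"up", "down"})
VALID_DESIGNS = frozenset({"in_vivo", "in_vitro"})
VALID_METHODS = frozenset({"microarray", "rtpcr", "northern", "other"})

MANDATORY_COLUMNS = ("entry_id", "disease", "design", "method", "mirna", "direction")

TABLE_COLUMNS = (
    "entry_id",
    "pubmed_id",
    "disease",
    "disease_class",
    "design",
    "method",
    "mirna",
    "direction",
    "fold_change",
    "cohort_size",
)


class FormatError(ValueError):
    """A file does not conform to the expected tabular layout."""


# Species prefix ("hsa-", "mmu-", ...) followed by a mir/let stem.
_SPECIES_PREFIX = re.compile(r"^[a-z]{3,4}-(?=(mir|let)\b|(mir|let)-)")
# Trailing mature-arm markers: -5p / -3p and the historical "*" minor arm.
_ARM_SUFFIX = re.compile(r"(-[35]p|\*)+$")


def normalize_mirna_name(raw: str, aliases: Mapping[str, str] | None = None) -> str:
    """Collapse a miRNA designation to its lowercase precursor stem.

    Lowercases, strips a species prefix (``hsa-``), maps ``miR`` to ``mir``,
    and removes trailing mature-arm suffixes (``-5p``, ``-3p``, ``*``).
    Letter-suffixed paralogs (``mir-125a`` vs ``mir-125b``) are distinct
    precursors and are left intact.  An optional alias table is applied
    last, keyed on the already-normalized form.  Idempotent.

    >>> normalize_mirna_name("hsa-miR-17-5p")
    'mir-17'
    >>> normalize_mirna_name("hsa-miR-106b*")
    'mir-106b'
    """
    if not raw or not raw.strip():
        raise ValueError("miRNA name must be a non-empty string")
    name = raw.strip().lower()
    name = _SPECIES_PREFIX.sub("", name)
    name = _ARM_SUFFIX.sub("", name)
    if aliases:
        name = aliases.get(name, name)
    return name


@dataclass(frozen=True)
class MiRNAPosition:
    """A miRNA gene locus; coordinates are 1-based inclusive (GFF3)."""

    mirna_id: str
    chrom: str
    start: int
    end: int
    strand: str = "unknown"

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"{self.mirna_id}: start must be >= 1")
        if self.end < self.start:
            raise ValueError(f"{self.mirna_id}: end < start")
        if self.strand not in {"+", "-", "unknown"}:
            raise ValueError(f"{self.mirna_id}: invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class ExpressionObservation:
    """One curated data point: a deregulated miRNA in one study entry."""

    entry_id: str
    disease: str
    design: str
    method: str
    mirna_id: str
    direction: str
    pubmed_id: str = ""
    disease_class: str = ""
    fold_change: float | None = None
    cohort_size: int | None = None

    def __post_init__(self) -> None:
        if self.direction not in VALID_DIRECTIONS:
            raise ValueError(f"invalid direction {self.direction!r}")
        if self.design not in VALID_DESIGNS:
            raise ValueError(f"invalid design {self.design!r}")
        if self.method not in VALID_METHODS:
            raise ValueError(f"invalid method {self.method!r}")
        if self.fold_change is not None and not self.fold_change > 0:
            raise ValueError("fold_change must be positive when present")
        if self.cohort_size is not None and not self.cohort_size > 0:
            raise ValueError("cohort_size must be positive when present")


@dataclass
class AnnotationTable:
    """Ordered collection of curated observations with source provenance."""

    observations: list[ExpressionObservation] = field(default_factory=list)
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.observations)

    def __iter__(self):
        return iter(self.observations)

    def to_frame(self) -> pd.DataFrame:
        """Tabular view, one row per observation, columns as in the TSV."""
        rows = [
            {
                "entry_id": o.entry_id,
                "pubmed_id": o.pubmed_id,
                "disease": o.disease,
                "disease_class": o.disease_class,
                "design": o.design,
                "method": o.method,
                "mirna": o.mirna_id,
                "direction": o.direction,
                "fold_change": o.fold_change,
                "cohort_size": o.cohort_size,
            }
            for o in self.observations
        ]
        return pd.DataFrame(rows, columns=list(TABLE_COLUMNS))

    def filter(self, **criteria) -> "AnnotationTable":
        """New table keeping observations whose attributes equal `criteria`."""
        kept = [
            o
            for o in self.observations
            if all(getattr(o, k) == v for k, v in criteria.items())
        ]
        return AnnotationTable(kept, provenance=self.provenance)

    @property
    def diseases(self) -> list[str]:
        seen: dict[str, None] = {}
        for o in self.observations:
            seen.setdefault(o.disease, None)
        return list(seen)


def _opt_float(token: str) -> float | None:
    token = token.strip()
    return float(token) if token else None


def _opt_int(token: str) -> int | None:
    token = token.strip()
    return int(float(token)) if token else None


def read_annotation_tsv(
    path: str | Path,
    strict: bool = False,
    aliases: Mapping[str, str] | None = None,
) -> AnnotationTable:
    """Load a curated annotation dump.

    Rows with unknown direction/design tokens raise in strict mode and are
    skipped with a logged warning otherwise.  Unknown detection methods are
    coerced to ``other``.  Duplicate ``(entry_id, mirna, direction)`` triples
    keep the first occurrence.  miRNA names are normalized on load.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s): {', '.join(missing)}")

    observations: list[ExpressionObservation] = []
    seen: set[tuple[str, str, str]] = set()
    n_skipped = 0
    for idx, row in enumerate(df.itertuples(index=False), start=2):
        rec = row._asdict()
        direction = rec["direction"].strip().lower()
        design = rec["design"].strip().lower()
        method = rec["method"].strip().lower()
        if method not in VALID_METHODS:
            logger.warning("%s line %d: method %r coerced to 'other'", path, idx, method)
            method = "other"
        try:
            if direction not in VALID_DIRECTIONS:
                raise ValueError(f"unknown direction token {direction!r}")
            if design not in VALID_DESIGNS:
                raise ValueError(f"unknown design token {design!r}")
            obs = ExpressionObservation(
                entry_id=rec["entry_id"].strip(),
                pubmed_id=rec.get("pubmed_id", "").strip(),
                disease=rec["disease"].strip(),
                disease_class=rec.get("disease_class", "").strip(),
                design=design,
                method=method,
                mirna_id=normalize_mirna_name(rec["mirna"], aliases=aliases),
                direction=direction,
                fold_change=_opt_float(rec.get("fold_change", "")),
                cohort_size=_opt_int(rec.get("cohort_size", "")),
            )
        except ValueError as exc:
            if strict:
                raise FormatError(f"{path} line {idx}: {exc}") from exc
            n_skipped += 1
            logger.warning("%s line %d skipped: %s", path, idx, exc)
            continue
        key = (obs.entry_id, obs.mirna_id, obs.direction)
        if key in seen:
            continue
        seen.add(key)
        observations.append(obs)
    if n_skipped:
        logger.warning("%s: skipped %d unparseable row(s)", path, n_skipped)
    return AnnotationTable(observations, provenance=str(path))


def write_annotation_tsv(table: AnnotationTable, path: str | Path) -> None:
    """Write a table back out in the dump layout (round-trips with the reader)."""
    df = table.to_frame()
    df["fold_change"] = df["fold_change"].map(
        lambda v: "" if v is None or pd.isna(v) else repr(float(v))
    )
    df["cohort_size"] = df["cohort_size"].map(
        lambda v: "" if v is None or pd.isna(v) else str(int(v))
    )
    df.to_csv(path, sep="\t", index=False)


_PRIMARY_TYPES = {"miRNA_primary_transcript", "pre_miRNA", "miRNA", "gene"}


def read_gff3_positions(
    path: str | Path, aliases: Mapping[str, str] | None = None
) -> list[MiRNAPosition]:
    """Read miRNA gene coordinates from a GFF3 file.

    One position per primary-transcript record (``miRNA_primary_transcript``
    preferred when present, as in miRBase genome builds); coordinates are kept
    1-based inclusive.  Records with end < start are rejected with a warning;
    duplicate names keep the first occurrence.
    """
    path = Path(path)
    raw: list[tuple[str, MiRNAPosition]] = []
    for feat in gffutils.iterators.DataIterator(str(path)):
        name = feat.attributes.get("Name", feat.attributes.get("ID", [None]))[0]
        if name is None:
            logger.warning("%s: record without Name/ID skipped", path)
            continue
        if feat.end < feat.start:
            logger.warning("%s: %s has end < start; record rejected", path, name)
            continue
        strand = feat.strand if feat.strand in {"+", "-"} else "unknown"
        raw.append(
            (
                feat.featuretype,
                MiRNAPosition(
                    mirna_id=normalize_mirna_name(name, aliases=aliases),
                    chrom=feat.seqid,
                    start=int(feat.start),
                    end=int(feat.end),
                    strand=strand,
                ),
            )
        )
    types_present = {t for t, _ in raw}
    if "miRNA_primary_transcript" in types_present:
        raw = [(t, p) for t, p in raw if t == "miRNA_primary_transcript"]
    positions: list[MiRNAPosition] = []
    seen: set[str] = set()
    for _, pos in raw:
        if pos.mirna_id in seen:
            logger.warning("%s: duplicate name %s; keeping first", path, pos.mirna_id)
            continue
        seen.add(pos.mirna_id)
        positions.append(pos)
    return positions


def write_gff3_positions(positions: Sequence[MiRNAPosition], path: str | Path) -> None:
    """Write positions as GFF3 ``miRNA_primary_transcript`` records."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for p in positions:
            strand = p.strand if p.strand in {"+", "-"} else "."
            fh.write(
                f"{p.chrom}\t.\tmiRNA_primary_transcript\t{p.start}\t{p.end}"
                f"\t.\t{strand}\t.\tID={p.mirna_id};Name={p.mirna_id}\n"
            )


def write_report_tsv(
    df: pd.DataFrame, path: str | Path, comments: Iterable[str] = ()
) -> None:
    """Write an analysis report: '#'-prefixed comment lines, then a TSV."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in comments:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
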