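from __future__ import annotations

import pytest

from mirclust.io import AnnotationTable, ExpressionObservation, MiRNAPosition


def obs(
    mirna: str,
    direction: str,
    disease: str = "glioma",
    design: str = "in_vivo",
    method: str = "microarray",
    entry: str | None = None,
    **kwargs,
):
    """Shorthand observation builder; entry ids auto-increment per call."""
    if entry is None:
        obs.counter += 1
        entry = f"E{obs.counter:04d}"
    return ExpressionObservation(
        entry_id=entry,
        disease=disease,
        design=design,
        method=method,
        mirna_id=mirna,
        direction=direction,
        **kwargs,
    )


obs.counter = 0


def table(*observations) -> AnnotationTable:
    return AnnotationTable(list(observations))


def pos(name: str, chrom: str, start: int, end: int, strand: str = "+") -> MiRNAPosition:
    return MiRNAPosition(mirna_id=name, chrom=chrom, start=start, end=end, strand=strand)


@pytest.fixture
def three_locus_chr1():
    """Three loci on chr1 whose gaps (2020, 4220) chain under a 5-kb rule."""
    return [
        pos("mir-a", "chr1", 100, 180),
        pos("mir-b", "chr1", 2200, 2280),
        pos("mir-c", "chr1", 6500, 6580),
    ]
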