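"""Coverage-based accounting of germline sequence complexity.

Mapping a sample's reads onto contigs assembled from excision-deficient
cells (the best available representation of the unrearranged germline
genome) and asking which contigs are covered above a normalized cutoff
measures how much germline sequence complexity the sample retains.  The
normalized unit is RPKM: reads per kilobase of contig per million mapped
library reads; a contig counts as covered at >= 2 RPKM, and only contigs
longer than 1 kb enter the accounting.  The same RPKM unit, normalized by
the library's reads mapped against the somatic (MAC) reference, quantifies
per-element coverage of individual transposon copies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd
import pysam

__all__ = [
    "ComplexityReport",
    "count_mapped_reads",
    "contig_rpkm",
    "covered_complexity",
    "subset_not_covered_by",
    "element_coverage",
]

DEFAULT_RPKM_CUTOFF = 2.0
DEFAULT_MIN_CONTIG_LENGTH = 1000


@dataclass(frozen=True)
class ComplexityReport:
    reference_name: str
    cutoff_rpkm: float
    min_contig_length: int
    covered_mb: float
    total_mb: float

    def __post_init__(self) -> None:
        if self.covered_mb > self.total_mb + 1e-9:
            raise ValueError("covered complexity cannot exceed the reference total")

    def __str__(self) -> str:
        return (
            f"{self.reference_name}: {self.covered_mb:.2f} Mb of {self.total_mb:.2f} Mb "
            f"covered at >= {self.cutoff_rpkm:g} RPKM "
            f"(contigs > {self.min_contig_length} bp)"
        )


def count_mapped_reads(alignments: str, mapq_min: int = 0) -> tuple[dict[str, int], int]:
    """Primary mapped reads per reference sequence, mates independently.

    Returns (per-contig counts, total mapped).  Secondary and supplementary
    records are excluded so each read is counted at most once.
    """
    counts: dict[str, int] = {}
    total = 0
    with pysam.AlignmentFile(str(alignments), check_sq=False) as handle:
        for name in handle.references:
            counts[name] = 0
        for aln in handle.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            if aln.mapping_quality < mapq_min:
                continue
            counts[aln.reference_name] += 1
            total += 1
    return counts, total


def contig_rpkm(
    counts: Mapping[str, int],
    lengths: Mapping[str, int],
    library_mapped_total: int,
) -> pd.DataFrame:
    """RPKM per contig: count / (length/1000) / (library_mapped/1e6)."""
    if library_mapped_total <= 0:
        raise ValueError("library_mapped_total must be positive")
    rows = []
    for contig, length in lengths.items():
        if length <= 0:
            raise ValueError(f"contig {contig!r} has non-positive length")
        count = int(counts.get(contig, 0))
        rpkm = count / (length / 1000.0) / (library_mapped_total / 1e6)
        rows.append(
            {"id": contig, "length": int(length), "count": count, "rpkm": rpkm}
        )
    return pd.DataFrame(rows)


def covered_complexity(
    records: pd.DataFrame,
    cutoff: float = DEFAULT_RPKM_CUTOFF,
    min_len: int = DEFAULT_MIN_CONTIG_LENGTH,
    reference_name: str = "reference",
) -> ComplexityReport:
    """Summed length (Mb) of contigs longer than ``min_len`` at >= cutoff RPKM."""
    eligible = records[records["length"] > min_len]
    covered = eligible[eligible["rpkm"] >= cutoff]
    return ComplexityReport(
        reference_name=reference_name,
        cutoff_rpkm=cutoff,
        min_contig_length=min_len,
        covered_mb=float(covered["length"].sum()) / 1e6,
        total_mb=float(eligible["length"].sum()) / 1e6,
    )


def subset_not_covered_by(
    control_records: pd.DataFrame, cutoff: float = DEFAULT_RPKM_CUTOFF
) -> set[str]:
    """Contigs below the cutoff in the control: germline DNA not collinear
    with somatic chromosomes."""
    below = control_records[control_records["rpkm"] < cutoff]
    return set(below["id"])


def element_coverage(
    alignments: str,
    element_lengths: Mapping[str, int],
    mac_library_mapped_total: int,
) -> pd.DataFrame:
    """Per-element RPKM for a small element reference (e.g. transposon copies).

    The denominator is the sample's read count mapped against the somatic
    (MAC) reference — not the element reference itself — so profiles are
    comparable across samples of different library sizes.
    """
    counts, _ = count_mapped_reads(alignments)
    missing = set(element_lengths) - set(counts)
    if missing:
        raise ValueError(
            f"element(s) {sorted(missing)} absent from the alignment header"
        )
    return contig_rpkm(counts, element_lengths, mac_library_mapped_total)
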