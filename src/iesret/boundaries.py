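"""Classify aligned reads at IES boundaries and tally per-IES counts.

A read supports *retention* (IES+) when, aligned against the MAC+IES
reference, it spans an IES end — the left boundary (last somatic base |
first IES base) or the right boundary (last IES base | first downstream
somatic base) — with at least ``anchor`` matched bases on each side.  A read
supports *excision* (IES-) when, aligned against the MAC reference, it spans
the somatic junction TA with at least ``anchor`` matched bases on each side
of the dinucleotide.  Counting only at IES ends avoids the length biases a
whole-element count would introduce.  Only unambiguous (primary, MAPQ >= 1
by default) alignments are counted, and each read contributes at most once
per IES; a read whose two alignments support both categories at one IES is
dropped and logged.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd
import pysam

from .genome_model import CoordinateMap, IesAnnotation

__all__ = [
    "Classification",
    "ClassifierConfig",
    "classify_on_mac",
    "classify_on_mac_plus_ies",
    "count_boundaries",
    "read_id",
]


class Classification(Enum):
    IES_PLUS = "IES+"
    IES_MINUS = "IES-"
    NONE = "none"


@dataclass(frozen=True)
class ClassifierConfig:
    """Anchoring and uniqueness rules for boundary classification.

    ``anchor`` is the minimum number of matched bases required on each side
    of a boundary; it must exceed the 2-bp ambiguity of the shared TA (a
    read ending inside the TA cannot distinguish the retained from the
    excised form).  Soft-clipped bases never count toward anchors.
    """

    anchor: int = 5
    mapq_min: int = 1
    require_no_indel_in_anchor: bool = True

    def __post_init__(self) -> None:
        if self.anchor < 1:
            raise ValueError("anchor must be at least 1")


def read_id(aln: pysam.AlignedSegment) -> str:
    """Identifier under which a read is counted; mates count independently."""
    if aln.is_paired:
        return f"{aln.query_name}/{1 if aln.is_read1 else 2}"
    return str(aln.query_name)


def _qualifies(aln: pysam.AlignedSegment, cfg: ClassifierConfig) -> bool:
    return (
        not aln.is_unmapped
        and not aln.is_secondary
        and not aln.is_supplementary
        and aln.mapping_quality >= cfg.mapq_min
        and aln.cigartuples is not None
    )


def _matched_runs(
    aln: pysam.AlignedSegment, merge_across_insertions: bool
) -> list[tuple[int, int]]:
    """Maximal runs of matched reference positions (1-based, inclusive).

    Runs are broken by deletions/skips always, and by insertions unless
    ``merge_across_insertions``; clips and pads never contribute.
    """
    runs: list[list[int]] = []
    ref = aln.reference_start + 1
    ref_gap = False
    insertion = False
    for op, ln in aln.cigartuples:
        if op in (0, 7, 8):  # M, =, X
            if (
                runs
                and not ref_gap
                and (merge_across_insertions or not insertion)
                and runs[-1][1] + 1 == ref
            ):
                runs[-1][1] = ref + ln - 1
            else:
                runs.append([ref, ref + ln - 1])
            ref += ln
            ref_gap = insertion = False
        elif op == 1:  # I
            insertion = True
        elif op in (2, 3):  # D, N
            ref += ln
            ref_gap = True
        # S, H, P: no reference consumption, no matched bases
    return [(a, b) for a, b in runs]


def _covers(runs: Sequence[tuple[int, int]], lo: int, hi: int) -> bool:
    for a, b in runs:
        if a <= lo and b >= hi:
            return True
    return False


def classify_on_mac(
    aln: pysam.AlignedSegment, junction_pos: int, cfg: ClassifierConfig
) -> Classification:
    """IES- if the alignment matches through the junction TA with anchors.

    The required window is ``[junction - anchor, junction + 1 + anchor]``:
    the 2-bp TA plus ``anchor`` matched bases on each side (12 bp at the
    default anchor of 5).
    """
    if not _qualifies(aln, cfg):
        return Classification.NONE
    runs = _matched_runs(aln, merge_across_insertions=not cfg.require_no_indel_in_anchor)
    if _covers(runs, junction_pos - cfg.anchor, junction_pos + 1 + cfg.anchor):
        return Classification.IES_MINUS
    return Classification.NONE


def classify_on_mac_plus_ies(
    aln: pysam.AlignedSegment,
    ies_bounds_lifted: tuple[int, int],
    cfg: ClassifierConfig,
) -> Classification:
    """IES+ if the alignment spans either IES end with anchors.

    ``ies_bounds_lifted`` are the MAC+IES positions of the first and last
    IES base (1-based, inclusive).  A read spanning both boundaries of a
    short IES still counts once.
    """
    if not _qualifies(aln, cfg):
        return Classification.NONE
    first, last = ies_bounds_lifted
    a = cfg.anchor
    runs = _matched_runs(aln, merge_across_insertions=not cfg.require_no_indel_in_anchor)
    if _covers(runs, first - a, first + a - 1) or _covers(runs, last - a + 1, last + a):
        return Classification.IES_PLUS
    return Classification.NONE


def _check_contigs(aln_file: pysam.AlignmentFile, contigs: set[str], label: str) -> None:
    missing = contigs - set(aln_file.references)
    if missing:
        raise ValueError(
            f"{label}: contig(s) {sorted(missing)} absent from the alignment header"
        )


def count_boundaries(
    mac_alignments: str,
    mac_plus_ies_alignments: str,
    annotations: Sequence[IesAnnotation],
    cmap: CoordinateMap,
    cfg: ClassifierConfig | None = None,
    conflict_log: list[str] | None = None,
) -> pd.DataFrame:
    """Per-IES (IES+, IES-) read tallies from the two alignment files.

    Returns one row per annotated IES (``ies_id``, ``ies_plus``,
    ``ies_minus``), in annotation order, with zero counts where no read
    qualified.  A read id contributes to at most one category per IES;
    conflicting ids are dropped and appended to ``conflict_log``.  The order
    of records in the alignment files does not affect the result.
    """
    cfg = cfg or ClassifierConfig()
    contigs = {a.contig for a in annotations}

    junctions: dict[str, list[int]] = {}
    junction_ies: dict[str, list[str]] = {}
    bounds: dict[str, list[tuple[int, int]]] = {}
    bound_ies: dict[str, list[str]] = {}
    for ann in sorted(annotations, key=lambda a: (a.contig, a.mac_junction)):
        junctions.setdefault(ann.contig, []).append(ann.mac_junction)
        junction_ies.setdefault(ann.contig, []).append(ann.ies_id)
        first = cmap.ies_lifted_start(ann.contig, ann.mac_junction)
        bounds.setdefault(ann.contig, []).append((first, first + ann.length - 1))
        bound_ies.setdefault(ann.contig, []).append(ann.ies_id)

    votes: dict[str, dict[str, Classification]] = {a.ies_id: {} for a in annotations}
    dropped: dict[str, set[str]] = {a.ies_id: set() for a in annotations}

    def record(ies_id: str, rid: str, call: Classification) -> None:
        if rid in dropped[ies_id]:
            return
        prior = votes[ies_id].get(rid)
        if prior is None:
            votes[ies_id][rid] = call
        elif prior is not call:
            del votes[ies_id][rid]
            dropped[ies_id].add(rid)
            if conflict_log is not None:
                conflict_log.append(f"{ies_id}\t{rid}\tconflicting IES+/IES- support")

    with pysam.AlignmentFile(str(mac_alignments), check_sq=False) as mac_file:
        _check_contigs(mac_file, contigs, "MAC alignments")
        for aln in mac_file.fetch(until_eof=True):
            if not _qualifies(aln, cfg) or aln.reference_name not in junctions:
                continue
            juncs = junctions[aln.reference_name]
            span_lo = aln.reference_start + 1
            span_hi = aln.reference_end  # 1-based inclusive
            lo = bisect.bisect_left(juncs, span_lo)
            hi = bisect.bisect_right(juncs, span_hi)
            for k in range(lo, hi):
                call = classify_on_mac(aln, juncs[k], cfg)
                if call is Classification.IES_MINUS:
                    record(junction_ies[aln.reference_name][k], read_id(aln), call)

    with pysam.AlignmentFile(str(mac_plus_ies_alignments), check_sq=False) as plus_file:
        _check_contigs(plus_file, contigs, "MAC+IES alignments")
        for aln in plus_file.fetch(until_eof=True):
            if not _qualifies(aln, cfg) or aln.reference_name not in bounds:
                continue
            pairs = bounds[aln.reference_name]
            span_lo = aln.reference_start + 1
            span_hi = aln.reference_end
            # candidate elements: any whose first..last interval comes near the span
            firsts = [p[0] for p in pairs]
            lasts = [p[1] for p in pairs]
            lo = bisect.bisect_left(lasts, span_lo - cfg.anchor)
            hi = bisect.bisect_right(firsts, span_hi + cfg.anchor)
            for k in range(lo, hi):
                call = classify_on_mac_plus_ies(aln, pairs[k], cfg)
                if call is Classification.IES_PLUS:
                    record(bound_ies[aln.reference_name][k], read_id(aln), call)

    rows = []
    for ann in annotations:
        tally = votes[ann.ies_id]
        plus = sum(1 for v in tally.values() if v is Classification.IES_PLUS)
        minus = sum(1 for v in tally.values() if v is Classification.IES_MINUS)
        rows.append({"ies_id": ann.ies_id, "ies_plus": plus, "ies_minus": minus})
    return pd.DataFrame(rows)
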