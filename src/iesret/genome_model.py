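"""Somatic (MAC) and germline-like (MAC+IES) reference genomes.

In ciliates such as *Paramecium tetraurelia*, Internal Eliminated Sequences
(IESs) are short, single-copy germline segments that are precisely excised
during development of the somatic macronucleus (MAC).  Every IES is bounded
by 5'-TA-3' dinucleotides, one copy of which is left at the somatic junction
after excision.  This module loads the somatic assembly and an IES
annotation, rebuilds the unexcised "MAC+IES" reference by re-inserting each
IES immediately before its junction TA, and maps positions between the two
coordinate systems.

Conventions
-----------
* Coordinates are 1-based and fully closed (GFF3 style).
* ``mac_junction`` is the position of the first base of the junction TA on
  the MAC contig.
* The IES ``sequence`` *includes* its leading TA; excision is therefore the
  deletion of exactly ``length`` bases, leaving the MAC TA behind.
* IESs are recorded on the forward strand only (the TA motif is its own
  reverse complement, and excision is strand symmetric).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence
import warnings

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomeFlavor",
    "ReferenceGenome",
    "IesAnnotation",
    "CoordinateMap",
    "ParseError",
    "ValidationError",
    "MIN_IES_LENGTH",
    "load_mac_reference",
    "load_ies_annotation",
    "build_mac_plus_ies",
    "lift_coordinate",
    "write_fasta",
    "write_ies_gff3",
    "write_coordinate_map",
]

MIN_IES_LENGTH = 26
_ALPHABET = frozenset("ACGTN")
GFF_FEATURE_TYPE = "internal_eliminated_sequence"


class ParseError(ValueError):
    """Raised for malformed input files."""


class ValidationError(ValueError):
    """Raised when a record violates a domain invariant."""


class GenomeFlavor(Enum):
    MAC = "MAC"
    MAC_PLUS_IES = "MAC_PLUS_IES"


@dataclass(frozen=True)
class ReferenceGenome:
    """A reference assembly: contig name -> upper-case A/C/G/T/N sequence."""

    sequences: dict[str, str]
    flavor: GenomeFlavor

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise ValidationError(f"contig {name!r} has an empty sequence")
            bad = set(seq) - _ALPHABET
            if bad:
                raise ValidationError(
                    f"contig {name!r} contains characters outside ACGTN: {sorted(bad)}"
                )

    def __contains__(self, contig: str) -> bool:
        return contig in self.sequences

    def length(self, contig: str) -> int:
        return len(self.sequences[contig])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass(frozen=True)
class IesAnnotation:
    """One TA-initiated germline-limited element anchored at a MAC junction.

    ``mac_junction`` is 1-based: the first base of the TA that remains on the
    somatic chromosome after excision.  ``sequence`` starts with that same TA.
    """

    ies_id: str
    contig: str
    mac_junction: int
    length: int
    sequence: str

    def __post_init__(self) -> None:
        if self.length != len(self.sequence):
            raise ValidationError(
                f"IES {self.ies_id}: declared length {self.length} != "
                f"sequence length {len(self.sequence)}"
            )
        if not self.sequence.startswith("TA"):
            raise ValidationError(
                f"IES {self.ies_id}: sequence does not start with TA "
                f"(starts {self.sequence[:2]!r})"
            )
        if self.length < MIN_IES_LENGTH:
            warnings.warn(
                f"IES {self.ies_id}: length {self.length} below the genome-wide "
                f"minimum of {MIN_IES_LENGTH} bp",
                stacklevel=2,
            )


class CoordinateMap:
    """Lift positions between MAC and MAC+IES coordinates.

    For a MAC position ``p``, the lifted position is ``p`` plus the summed
    lengths of all IESs whose junction is at or before ``p`` — a position at
    the junction itself lies downstream of the inserted element.  The lift is
    therefore monotone non-decreasing, and positions strictly before the
    first junction are unchanged.
    """

    def __init__(self, entries: dict[str, Sequence[tuple[int, int]]]):
        self._junctions: dict[str, list[int]] = {}
        self._cumlen: dict[str, list[int]] = {}
        for contig, pairs in entries.items():
            pairs = sorted(pairs)
            juncs = [p for p, _ in pairs]
            if any(b <= a for a, b in zip(juncs, juncs[1:])):
                raise ValidationError(
                    f"contig {contig}: IES junctions are not strictly increasing"
                )
            cum: list[int] = []
            total = 0
            for _, ln in pairs:
                total += ln
                cum.append(total)
            self._junctions[contig] = juncs
            self._cumlen[contig] = cum

    @property
    def contigs(self) -> list[str]:
        return list(self._junctions)

    def shift(self, contig: str, mac_pos: int) -> int:
        """Summed IES length inserted at or before ``mac_pos``."""
        juncs = self._junctions.get(contig, [])
        i = bisect.bisect_right(juncs, mac_pos)
        return self._cumlen[contig][i - 1] if i else 0

    def lift(self, contig: str, mac_pos: int) -> int:
        if mac_pos < 1:
            raise ValueError(f"position {mac_pos} out of range (1-based)")
        return mac_pos + self.shift(contig, mac_pos)

    def unlift(self, contig: str, lifted_pos: int) -> int:
        """Inverse of :meth:`lift` for positions outside inserted IESs."""
        juncs = self._junctions.get(contig, [])
        cum = self._cumlen.get(contig, [])
        # binary search over junctions: find largest i with lift(junc_i) <= pos
        lo, hi = 0, len(juncs)
        while lo < hi:
            mid = (lo + hi) // 2
            if juncs[mid] + cum[mid] <= lifted_pos:
                lo = mid + 1
            else:
                hi = mid
        shift = cum[lo - 1] if lo else 0
        mac_pos = lifted_pos - shift
        if self.lift(contig, mac_pos) != lifted_pos:
            raise ValueError(
                f"{contig}:{lifted_pos} lies inside an inserted IES; "
                "no MAC coordinate exists"
            )
        return mac_pos

    def ies_lifted_start(self, contig: str, mac_junction: int) -> int:
        """MAC+IES position of the first base of the IES at ``mac_junction``."""
        juncs = self._junctions.get(contig, [])
        i = bisect.bisect_left(juncs, mac_junction)
        if i >= len(juncs) or juncs[i] != mac_junction:
            raise KeyError(f"no IES at {contig}:{mac_junction}")
        prev = self._cumlen[contig][i - 1] if i else 0
        return mac_junction + prev

    def iter_entries(self) -> Iterable[tuple[str, int, int, int]]:
        """Yield (contig, mac_junction, ies_length, lifted_start)."""
        for contig, juncs in self._junctions.items():
            cum = self._cumlen[contig]
            prev = 0
            for j, c in zip(juncs, cum):
                yield contig, j, c - prev, j + prev
                prev = c


def load_mac_reference(fasta_path) -> ReferenceGenome:
    """Read a somatic (MAC) reference FASTA.

    Raises :class:`ParseError` for an empty or malformed file and
    :class:`ValidationError` for duplicate contig names or a non-ACGTN
    alphabet.
    """
    sequences: dict[str, str] = {}
    n = 0
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        n += 1
        if record.id in sequences:
            raise ValidationError(f"duplicate contig name {record.id!r}")
        sequences[record.id] = str(record.seq).upper()
    if n == 0:
        raise ParseError(f"no FASTA records found in {fasta_path}")
    return ReferenceGenome(sequences=sequences, flavor=GenomeFlavor.MAC)


def _check_junction(genome: ReferenceGenome, ann: IesAnnotation) -> None:
    if ann.contig not in genome:
        raise ValidationError(f"IES {ann.ies_id}: unknown contig {ann.contig!r}")
    seq = genome.sequences[ann.contig]
    j = ann.mac_junction
    if j < 1 or j + 1 > len(seq):
        raise ValidationError(
            f"IES {ann.ies_id}: junction {j} outside contig {ann.contig} "
            f"(length {len(seq)})"
        )
    if seq[j - 1 : j + 1] != "TA":
        raise ValidationError(
            f"IES {ann.ies_id}: MAC {ann.contig}:{j}-{j + 1} is "
            f"{seq[j - 1:j + 1]!r}, expected the junction TA"
        )


def _parse_gff_attributes(raw: str) -> dict[str, str]:
    out = {}
    for part in raw.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" not in part:
            raise ParseError(f"malformed GFF3 attribute {part!r}")
        key, value = part.split("=", 1)
        out[key] = value
    return out


def load_ies_annotation(gff3_path, genome: ReferenceGenome) -> list[IesAnnotation]:
    """Read a GFF3-style IES annotation and validate it against the MAC.

    Each feature line of type ``internal_eliminated_sequence`` carries
    ``ID=<ies_id>;sequence=<IES string>`` attributes; the feature start is the
    junction position (first base of the MAC TA).  Every record is checked
    for the TA invariants; violations raise :class:`ValidationError` naming
    the record.
    """
    if genome.flavor is not GenomeFlavor.MAC:
        raise ValidationError("IES annotations must be validated against a MAC genome")
    annotations: list[IesAnnotation] = []
    with open(gff3_path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{gff3_path}:{lineno}: expected 9 columns, got {len(fields)}")
            contig, _source, ftype, start, _end, _score, _strand, _phase, attrs = fields
            if ftype != GFF_FEATURE_TYPE:
                continue
            attributes = _parse_gff_attributes(attrs)
            try:
                ies_id = attributes["ID"]
                sequence = attributes["sequence"].upper()
            except KeyError as exc:
                raise ParseError(
                    f"{gff3_path}:{lineno}: missing attribute {exc}"
                ) from None
            ann = IesAnnotation(
                ies_id=ies_id,
                contig=contig,
                mac_junction=int(start),
                length=len(sequence),
                sequence=sequence,
            )
            _check_junction(genome, ann)
            annotations.append(ann)
    return annotations


def build_mac_plus_ies(
    genome: ReferenceGenome, annotations: Sequence[IesAnnotation]
) -> tuple[ReferenceGenome, CoordinateMap]:
    """Re-insert every annotated IES to construct the unexcised reference.

    Each IES sequence is spliced in immediately before its junction TA, so
    the germline locus reads ``...TA-body-TA...`` and deleting ``length``
    bases starting at the lifted junction restores the MAC byte-for-byte.
    """
    by_contig: dict[str, list[IesAnnotation]] = {}
    for ann in annotations:
        _check_junction(genome, ann)
        by_contig.setdefault(ann.contig, []).append(ann)

    sequences: dict[str, str] = {}
    entries: dict[str, list[tuple[int, int]]] = {}
    for contig, mac_seq in genome.sequences.items():
        anns = sorted(by_contig.get(contig, []), key=lambda a: a.mac_junction)
        seen: set[int] = set()
        parts: list[str] = []
        prev = 0  # 0-based index of next MAC base to copy
        for ann in anns:
            if ann.mac_junction in seen:
                raise ValidationError(
                    f"two IESs share the junction {contig}:{ann.mac_junction}"
                )
            seen.add(ann.mac_junction)
            cut = ann.mac_junction - 1  # insert before the junction TA
            parts.append(mac_seq[prev:cut])
            parts.append(ann.sequence)
            prev = cut
        parts.append(mac_seq[prev:])
        sequences[contig] = "".join(parts)
        entries[contig] = [(a.mac_junction, a.length) for a in anns]

    cmap = CoordinateMap(entries)
    return ReferenceGenome(sequences=sequences, flavor=GenomeFlavor.MAC_PLUS_IES), cmap


def lift_coordinate(cmap: CoordinateMap, contig: str, mac_pos: int) -> int:
    """MAC -> MAC+IES position (1-based)."""
    return cmap.lift(contig, mac_pos)


def write_fasta(genome: ReferenceGenome, path) -> None:
    """Write a genome as FASTA, line-wrapped at 60 columns."""
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in genome.sequences.items()
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(records)


def write_ies_gff3(annotations: Sequence[IesAnnotation], path) -> None:
    with open(path, "w") as handle:
        handle.write("##gff-version 3\n")
        for ann in annotations:
            handle.write(
                "\t".join(
                    [
                        ann.contig,
                        "iesret",
                        GFF_FEATURE_TYPE,
                        str(ann.mac_junction),
                        str(ann.mac_junction + 1),
                        ".",
                        "+",
                        ".",
                        f"ID={ann.ies_id};sequence={ann.sequence}",
                    ]
                )
                + "\n"
            )


def write_coordinate_map(cmap: CoordinateMap, path) -> None:
    with open(path, "w") as handle:
        handle.write("contig\tmac_junction\ties_length\tlifted_start\n")
        for contig, junction, length, lifted in cmap.iter_entries():
            handle.write(f"{contig}\t{junction}\t{length}\t{lifted}\n")
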