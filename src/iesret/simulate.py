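"""Synthetic sequencing experiments for IES retention analysis.

The generator emulates the DNA-seq experiments used to quantify programmed
DNA elimination: an AT-rich somatic genome, TA-flanked single-copy IESs
whose lengths follow the periodic genome-wide size distribution (peaks every
~10 bp from 26 bp), and paired-end reads drawn from a mixture of molecule
pools.  Each sequenced fragment comes either from the maternal somatic pool
(probability ``c``, the maternal-MAC contamination fraction, in which every
IES is excised) or from the developing zygotic pool (probability ``1-c``, in
which each IES is retained independently with its molecular retention
fraction ``r_i``).  The per-locus fraction of molecules carrying an IES is
therefore ``(1-c) * r_i``, the quantity the retention score estimates.

Fragment placement
------------------
Both mates of a fragment are anchored on somatic (MAC) coordinates: the
forward mate starts at a uniformly drawn MAC position and the reverse mate
ends at the corresponding MAC position one insert away; retained IESs are
spliced into the walk as it crosses their junctions.  Anchoring on somatic
coordinates gives the excised and the retained configuration of a locus
classification windows of equal size (up to an O(anchor/read_length) edge
term), so the downstream retention score is a consistent estimator of
``(1-c) * r_i`` regardless of IES length.  The cost of this choice is that
the interior of a long retained IES is only covered within one insert of its
boundaries; see the methods note.

Because the generator knows the provenance of every base, it can emit exact
SAM alignments against both references alongside the FASTQ: collinear runs
are reported as matches and the remainder of the read is soft-clipped, which
is the behaviour of a local aligner at an excision breakpoint.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .cohort import DEFAULT_SIZE_BINS, DEFAULT_SIZE_BIN_COUNTS
from .genome_model import (
    CoordinateMap,
    GenomeFlavor,
    IesAnnotation,
    ReferenceGenome,
    build_mac_plus_ies,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "SimulatedGenome",
    "DEFAULT_IES_LENGTH_MIXTURE",
    "sample_ies_length",
    "simulate_genome",
    "simulate_reads",
    "write_truth_tsv",
    "read_truth_tsv",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Default length mixture: the 23 genome-wide size groups weighted by their
# published element tallies; within a bin, lengths are uniform.  The open
# last bin (>1 kb) is sampled up to 2 kb.
DEFAULT_IES_LENGTH_MIXTURE: tuple[tuple[int, int, float], ...] = tuple(
    (lo, hi if hi is not None else 2032, cnt / sum(DEFAULT_SIZE_BIN_COUNTS))
    for (lo, hi), cnt in zip(DEFAULT_SIZE_BINS.edges, DEFAULT_SIZE_BIN_COUNTS)
)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic sequencing experiment.

    Defaults mirror the real experiments the analysis was designed for: an
    AT-rich genome (GC 0.28), 100-bp paired-end reads at 25x depth with a
    0.5% substitution error rate, and a maternal-MAC contamination fraction
    of 0.23 — the value at which complete excision failure yields the
    observed retention-score plateau of 0.77.
    """

    n_contigs: int = 2
    contig_length: int = 100_000
    gc_fraction: float = 0.28
    n_ies: int = 400
    ies_length_distribution: tuple[tuple[int, int, float], ...] = (
        DEFAULT_IES_LENGTH_MIXTURE
    )
    read_length: int = 100
    insert_mean: float = 300.0
    insert_sd: float = 30.0
    depth: float = 25.0
    substitution_error_rate: float = 0.005
    contamination: float = 0.23
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must lie in [0, 1]")
        if not 0.0 <= self.contamination <= 1.0:
            raise ValueError("contamination must lie in [0, 1]")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if min(self.n_contigs, self.contig_length, self.n_ies + 1,
               self.read_length) <= 0:
            raise ValueError("all sizes must be positive")
        if self.insert_mean < self.read_length:
            raise ValueError("insert size must be at least one read length")
        if not 0.0 <= self.substitution_error_rate < 1.0:
            raise ValueError("substitution_error_rate must lie in [0, 1)")


@dataclass(frozen=True)
class SimulationTruth:
    """Per-IES molecular retention fractions plus the global contamination."""

    retention: Mapping[str, float]
    contamination: float

    def __post_init__(self) -> None:
        for ies_id, r in self.retention.items():
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"retention fraction for {ies_id} outside [0, 1]")
        if not 0.0 <= self.contamination <= 1.0:
            raise ValueError("contamination outside [0, 1]")

    @classmethod
    def uniform(
        cls, annotations: Sequence[IesAnnotation], r: float, contamination: float
    ) -> "SimulationTruth":
        return cls({a.ies_id: r for a in annotations}, contamination)

    def expected_molecular_fraction(self, ies_id: str) -> float:
        """Expected fraction of molecules carrying the IES: (1-c) * r."""
        return (1.0 - self.contamination) * self.retention[ies_id]


@dataclass(frozen=True)
class SimulatedGenome:
    mac: ReferenceGenome
    annotations: tuple[IesAnnotation, ...]
    mac_plus_ies: ReferenceGenome
    coordinate_map: CoordinateMap


def sample_ies_length(
    distribution: Sequence[tuple[int, int, float]], rng: np.random.Generator
) -> int:
    """Draw one IES length from a periodic bin mixture.

    ``distribution`` is a sequence of ``(low, high, weight)`` bins with
    weights summing to 1; within a bin lengths are uniform.
    """
    if len(distribution) == 0:
        raise ValueError("empty length distribution")
    weights = np.array([w for _, _, w in distribution], dtype=float)
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0, atol=1e-6):
        raise ValueError("mixture weights must be non-negative and sum to 1")
    i = int(rng.choice(len(distribution), p=weights / weights.sum()))
    lo, hi, _ = distribution[i]
    length = int(rng.integers(lo, hi + 1))
    if length < 26:
        raise ValueError(f"sampled length {length} below the 26 bp minimum")
    return length


def _random_sequence(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def simulate_genome(config: SimulationConfig) -> SimulatedGenome:
    """Generate a MAC genome, IES annotations and the MAC+IES reference.

    Junctions are placed on a jittered grid, at least two read lengths
    apart and away from contig ends, and the MAC site is overwritten with
    the junction TA; each IES sequence starts with TA and has the same base
    composition as the genome.  Same-seed reruns are byte-identical.
    """
    rng = np.random.default_rng(config.seed)
    margin = int(config.insert_mean + 4 * config.insert_sd + config.read_length)
    spacing = max(2 * config.read_length, 200)

    per_contig = [config.n_ies // config.n_contigs] * config.n_contigs
    for k in range(config.n_ies % config.n_contigs):
        per_contig[k] += 1

    mac_seqs: dict[str, str] = {}
    annotations: list[IesAnnotation] = []
    serial = 0
    for ci in range(config.n_contigs):
        contig = f"contig_{ci + 1}"
        arr = _random_sequence(config.contig_length, config.gc_fraction, rng)
        span = config.contig_length - 2 * margin
        n_slots = span // spacing
        if per_contig[ci] > n_slots:
            raise ValueError(
                f"{per_contig[ci]} IESs do not fit on a {config.contig_length} bp "
                f"contig with {spacing} bp junction spacing"
            )
        slots = np.sort(rng.choice(n_slots, size=per_contig[ci], replace=False))
        jitter = rng.integers(0, max(spacing - 2 * config.read_length, 1) + 1,
                              size=per_contig[ci])
        junctions = margin + slots * spacing + jitter + 1  # 1-based
        for j in junctions:
            j = int(j)
            arr[j - 1] = ord("T")
            arr[j] = ord("A")
            length = sample_ies_length(config.ies_length_distribution, rng)
            body = _random_sequence(length - 2, config.gc_fraction, rng)
            sequence = "TA" + body.tobytes().decode()
            serial += 1
            annotations.append(
                IesAnnotation(
                    ies_id=f"ies_{serial:05d}",
                    contig=contig,
                    mac_junction=j,
                    length=length,
                    sequence=sequence,
                )
            )
        mac_seqs[contig] = arr.tobytes().decode()

    mac = ReferenceGenome(sequences=mac_seqs, flavor=GenomeFlavor.MAC)
    mac_plus, cmap = build_mac_plus_ies(mac, annotations)
    return SimulatedGenome(
        mac=mac,
        annotations=tuple(annotations),
        mac_plus_ies=mac_plus,
        coordinate_map=cmap,
    )


# ---------------------------------------------------------------------------
# read simulation


@dataclass
class _ContigIndex:
    """Per-contig lookup tables used by the fragment walk."""

    name: str
    mac_seq: str
    junctions: list[int]           # 1-based, sorted
    ies_lengths: list[int]
    ies_seqs: list[str]
    ies_ids: list[str]
    lifted_starts: list[int]       # MAC+IES position of first IES base
    retention: np.ndarray          # r_i per IES, aligned with junctions


def _build_indexes(
    sim: SimulatedGenome, truth: SimulationTruth
) -> dict[str, _ContigIndex]:
    by_contig: dict[str, list[IesAnnotation]] = {}
    for ann in sim.annotations:
        by_contig.setdefault(ann.contig, []).append(ann)
    out: dict[str, _ContigIndex] = {}
    for contig, seq in sim.mac.sequences.items():
        anns = sorted(by_contig.get(contig, []), key=lambda a: a.mac_junction)
        out[contig] = _ContigIndex(
            name=contig,
            mac_seq=seq,
            junctions=[a.mac_junction for a in anns],
            ies_lengths=[a.length for a in anns],
            ies_seqs=[a.sequence for a in anns],
            ies_ids=[a.ies_id for a in anns],
            lifted_starts=[
                sim.coordinate_map.ies_lifted_start(contig, a.mac_junction)
                for a in anns
            ],
            retention=np.array(
                [truth.retention.get(a.ies_id, 0.0) for a in anns], dtype=float
            ),
        )
    return out


def _walk_forward(
    idx: _ContigIndex, start: int, n_bases: int, retained: dict[int, bool]
) -> list[tuple[str, int, int, int]]:
    """Germline segments of a read starting at MAC position ``start``.

    Returns ``(kind, ref_index, offset_or_pos, length)`` segments in read
    order: ``("M", -1, mac_start, length)`` for MAC-collinear stretches
    (split at every junction) and ``("I", ies_index, ies_offset, length)``
    for retained-IES stretches.
    """
    segs: list[tuple[str, int, int, int]] = []
    pos, need = start, n_bases
    k = bisect.bisect_right(idx.junctions, pos)
    while need > 0:
        nxt = idx.junctions[k] if k < len(idx.junctions) else None
        limit = (nxt - pos) if nxt is not None else (len(idx.mac_seq) - pos + 1)
        take = min(need, limit)
        if take > 0:
            segs.append(("M", -1, pos, take))
            pos += take
            need -= take
        if need > 0 and nxt is not None and pos == nxt:
            if retained.get(k, False):
                L = idx.ies_lengths[k]
                t = min(need, L)
                segs.append(("I", k, 0, t))
                need -= t
            k += 1
        elif nxt is None and take == 0:
            break  # ran off the contig end
    return segs


def _walk_backward(
    idx: _ContigIndex, end: int, n_bases: int, retained: dict[int, bool]
) -> list[tuple[str, int, int, int]]:
    """Germline segments of a read ending at MAC position ``end``."""
    rsegs: list[tuple[str, int, int, int]] = []
    pos, need = end, n_bases
    k = bisect.bisect_right(idx.junctions, pos) - 1  # junction at or before pos
    while need > 0:
        j = idx.junctions[k] if k >= 0 else None
        lo = j if j is not None else 1
        take = min(need, pos - lo + 1)
        if take > 0:
            rsegs.append(("M", -1, pos - take + 1, take))
            pos -= take
            need -= take
        if need > 0 and j is not None and pos == j - 1:
            if retained.get(k, False):
                L = idx.ies_lengths[k]
                t = min(need, L)
                rsegs.append(("I", k, L - t, t))
                need -= t
            k -= 1
        elif j is None and take == 0:
            break
    return rsegs[::-1]


def _segments_to_read(idx: _ContigIndex, segs) -> str:
    parts = []
    for kind, ref, off, ln in segs:
        if kind == "M":
            parts.append(idx.mac_seq[off - 1 : off - 1 + ln])
        else:
            parts.append(idx.ies_seqs[ref][off : off + ln])
    return "".join(parts)


def _mac_blocks(segs) -> list[tuple[int, int, int]]:
    """(mac_start, read_offset, length) runs collinear with the MAC."""
    blocks: list[tuple[int, int, int]] = []
    read_off = 0
    for kind, _ref, off, ln in segs:
        if kind == "M":
            if blocks:
                s, ro, bl = blocks[-1]
                if s + bl == off and ro + bl == read_off:
                    blocks[-1] = (s, ro, bl + ln)
                    read_off += ln
                    continue
            blocks.append((off, read_off, ln))
        read_off += ln
    return blocks


def _macplus_blocks(idx: _ContigIndex, segs, cmap_shift) -> list[tuple[int, int, int]]:
    """(mac_plus_start, read_offset, length) runs collinear with MAC+IES."""
    blocks: list[tuple[int, int, int]] = []
    read_off = 0
    for kind, ref, off, ln in segs:
        if kind == "M":
            start = off + cmap_shift(off)
        else:
            start = idx.lifted_starts[ref] + off
        if blocks:
            s, ro, bl = blocks[-1]
            if s + bl == start and ro + bl == read_off:
                blocks[-1] = (s, ro, bl + ln)
                read_off += ln
                continue
        blocks.append((start, read_off, ln))
        read_off += ln
    return blocks


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _sam_header(genome: ReferenceGenome) -> str:
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, seq in genome.sequences.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{len(seq)}")
    return "\n".join(lines) + "\n"


_MIN_ALIGN_BLOCK = 30  # shorter collinear runs are treated as unalignable


def _sam_record(
    qname: str,
    mate: int,
    reverse: bool,
    contig: str,
    blocks: list[tuple[int, int, int]],
    seq_ref_orientation: str,
    qual_char: str,
) -> str | None:
    if not blocks:
        return None
    start, read_off, blen = max(blocks, key=lambda b: (b[2], -b[1]))
    if blen < _MIN_ALIGN_BLOCK:
        return None
    read_len = len(seq_ref_orientation)
    flag = 0x1 | (0x40 if mate == 1 else 0x80) | (0x10 if reverse else 0)
    left = read_off
    right = read_len - read_off - blen
    cigar = ""
    if left:
        cigar += f"{left}S"
    cigar += f"{blen}M"
    if right:
        cigar += f"{right}S"
    return "\t".join(
        [
            qname,
            str(flag),
            contig,
            str(start),
            "60",
            cigar,
            "*",
            "0",
            "0",
            seq_ref_orientation,
            qual_char * read_len,
        ]
    )


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    n = len(seq)
    k = rng.binomial(n, rate)
    if k == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    positions = rng.choice(n, size=k, replace=False)
    for p in positions:
        choices = _BASES[_BASES != arr[p]]
        arr[p] = rng.choice(choices)
    return arr.tobytes().decode()


def simulate_reads(
    sim: SimulatedGenome,
    truth: SimulationTruth,
    config: SimulationConfig,
    fastq1: str | Path,
    fastq2: str | Path,
    truth_tsv: str | Path | None = None,
    sam_mac: str | Path | None = None,
    sam_mac_plus: str | Path | None = None,
    seed: int | None = None,
) -> int:
    """Simulate paired-end reads; returns the number of fragments.

    Writes a FASTQ pair (``/1``, ``/2`` read names, constant Q30 Phred+33
    qualities) and, optionally, the truth table and exact SAM alignments
    against the MAC and MAC+IES references.  Each fragment is maternal
    (always excised) with probability ``c`` and zygotic otherwise, with
    independent per-fragment retention draws at every IES it crosses;
    substitution errors are i.i.d. per base; mates are FR-oriented.
    Identical seeds give byte-identical outputs.
    """
    if config.insert_mean < config.read_length:
        raise ValueError("insert size must be at least one read length")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    indexes = _build_indexes(sim, truth)
    contigs = list(sim.mac.sequences)
    lengths = np.array([len(sim.mac.sequences[c]) for c in contigs], dtype=float)
    total = lengths.sum()
    n_fragments = int(round(config.depth * total / (2 * config.read_length)))
    R = config.read_length
    qual = chr(33 + 30)

    contig_draws = rng.choice(len(contigs), size=n_fragments, p=lengths / total)
    inserts = np.clip(
        np.round(rng.normal(config.insert_mean, config.insert_sd, size=n_fragments)),
        R,
        config.insert_mean + 4 * config.insert_sd,
    ).astype(int)
    # the truth table is authoritative for the molecule mixture; the config
    # value only seeds truth construction
    maternal = rng.random(n_fragments) < truth.contamination

    handles = {}
    try:
        handles["fq1"] = open(fastq1, "w")
        handles["fq2"] = open(fastq2, "w")
        if sam_mac is not None:
            handles["sam_mac"] = open(sam_mac, "w")
            handles["sam_mac"].write(_sam_header(sim.mac))
        if sam_mac_plus is not None:
            handles["sam_plus"] = open(sam_mac_plus, "w")
            handles["sam_plus"].write(_sam_header(sim.mac_plus_ies))
        cmap = sim.coordinate_map

        for i in range(n_fragments):
            idx = indexes[contigs[contig_draws[i]]]
            G = len(idx.mac_seq)
            ins = int(min(inserts[i], G))
            x = int(rng.integers(1, G - ins + 2))
            y = x + ins - 1

            retained: dict[int, bool] = {}
            lo = bisect.bisect_right(idx.junctions, x)
            hi = bisect.bisect_right(idx.junctions, y)
            if not maternal[i] and hi > lo:
                draws = rng.random(hi - lo) < idx.retention[lo:hi]
                retained = {lo + k: bool(d) for k, d in enumerate(draws)}

            segs1 = _walk_forward(idx, x, R, retained)
            segs2 = _walk_backward(idx, y, R, retained)
            qname = f"frag{i:08d}"

            shift = lambda p: cmap.shift(idx.name, p)  # noqa: E731
            for mate, segs in ((1, segs1), (2, segs2)):
                germ = _segments_to_read(idx, segs)
                germ = _apply_errors(germ, config.substitution_error_rate, rng)
                sequenced = germ if mate == 1 else _revcomp(germ)
                fq = handles["fq1"] if mate == 1 else handles["fq2"]
                fq.write(f"@{qname}/{mate}\n{sequenced}\n+\n{qual * len(sequenced)}\n")
                if "sam_mac" in handles:
                    rec = _sam_record(
                        qname, mate, mate == 2, idx.name,
                        _mac_blocks(segs), germ, qual,
                    )
                    if rec:
                        handles["sam_mac"].write(rec + "\n")
                if "sam_plus" in handles:
                    rec = _sam_record(
                        qname, mate, mate == 2, idx.name,
                        _macplus_blocks(idx, segs, shift), germ, qual,
                    )
                    if rec:
                        handles["sam_plus"].write(rec + "\n")
    finally:
        for h in handles.values():
            h.close()

    if truth_tsv is not None:
        write_truth_tsv(truth, [a.ies_id for a in sim.annotations], truth_tsv)
    return n_fragments


def write_truth_tsv(truth: SimulationTruth, ies_ids: Sequence[str], path) -> None:
    with open(path, "w") as handle:
        handle.write("ies_id\tretention_fraction\tcontamination\n")
        for ies_id in ies_ids:
            handle.write(
                f"{ies_id}\t{truth.retention[ies_id]:.6g}\t{truth.contamination:.6g}\n"
            )


def read_truth_tsv(path) -> SimulationTruth:
    retention: dict[str, float] = {}
    contamination = 0.0
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header != ["ies_id", "retention_fraction", "contamination"]:
            raise ValueError(f"unexpected truth-table header in {path}")
        for line in handle:
            ies_id, r, c = line.rstrip("\n").split("\t")
            retention[ies_id] = float(r)
            contamination = float(c)
    return SimulationTruth(retention=retention, contamination=contamination)
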