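"""Junction-read classification and per-IES boundary counting."""

import random
import warnings

import numpy as np
import pysam
import pytest

from iesret.boundaries import (
    Classification,
    ClassifierConfig,
    classify_on_mac,
    classify_on_mac_plus_ies,
    count_boundaries,
)
from iesret.genome_model import (
    GenomeFlavor,
    IesAnnotation,
    ReferenceGenome,
    build_mac_plus_ies,
)

CFG = ClassifierConfig()  # anchor 5, mapq >= 1, no indels in anchors

MAC_HEADER = pysam.AlignmentHeader.from_dict(
    {"HD": {"VN": "1.6"}, "SQ": [{"SN": "c1", "LN": 10_000}]}
)


def aln(pos, cigar="100M", mapq=60, flag=0, name="r1", header=MAC_HEADER):
    """1-based pos; build a minimal aligned segment."""
    a = pysam.AlignedSegment(header)
    a.query_name = name
    a.flag = flag
    a.reference_id = 0
    a.reference_start = pos - 1
    a.mapping_quality = mapq
    a.cigarstring = cigar
    length = sum(n for op, n in a.cigartuples if op in (0, 1, 4, 7, 8))
    a.query_sequence = "A" * length
    return a


JUNCTION = 1000  # first base of the MAC junction TA


class TestClassifyOnMac:
    def test_centered_read_is_ies_minus(self):
        a = aln(JUNCTION - 50)
        assert classify_on_mac(a, JUNCTION, CFG) is Classification.IES_MINUS

    def test_read_ending_at_junction_unmet_anchor(self):
        a = aln(JUNCTION - 99)  # covers up to the junction base only
        assert classify_on_mac(a, JUNCTION, CFG) is Classification.NONE

    def test_insertion_inside_window_rejected(self):
        # I between matched runs at ref 998/999 — inside the 12 bp window
        a = aln(JUNCTION - 51, cigar="50M2I48M")
        assert classify_on_mac(a, JUNCTION, CFG) is Classification.NONE
        lax = ClassifierConfig(require_no_indel_in_anchor=False)
        assert classify_on_mac(a, JUNCTION, lax) is Classification.IES_MINUS

    def test_deletion_inside_window_always_rejected(self):
        a = aln(JUNCTION - 51, cigar="50M2D50M")
        lax = ClassifierConfig(require_no_indel_in_anchor=False)
        assert classify_on_mac(a, JUNCTION, lax) is Classification.NONE

    def test_low_mapq_and_secondary_excluded(self):
        assert classify_on_mac(aln(JUNCTION - 50, mapq=0), JUNCTION, CFG) \
            is Classification.NONE
        assert classify_on_mac(aln(JUNCTION - 50, flag=0x100), JUNCTION, CFG) \
            is Classification.NONE

    def test_soft_clips_do_not_anchor(self):
        # matched run ends at junction+1: only 1 matched base beyond the TA
        a = aln(JUNCTION - 48, cigar="50M50S")
        assert classify_on_mac(a, JUNCTION, CFG) is Classification.NONE


class TestClassifyOnMacPlusIes:
    BOUNDS = (2000, 2299)  # a 300 bp element, lifted coordinates

    def test_left_boundary_spanning(self):
        a = aln(self.BOUNDS[0] - 20)  # 20 bases before the element, 80 inside
        assert classify_on_mac_plus_ies(a, self.BOUNDS, CFG) is Classification.IES_PLUS

    def test_interior_read_not_counted(self):
        a = aln(self.BOUNDS[0] + 50)  # entirely inside, touches no end
        assert classify_on_mac_plus_ies(a, self.BOUNDS, CFG) is Classification.NONE

    def test_right_boundary_spanning(self):
        a = aln(self.BOUNDS[1] - 50)
        assert classify_on_mac_plus_ies(a, self.BOUNDS, CFG) is Classification.IES_PLUS

    def test_short_ies_spanning_both_boundaries_counts_once(self):
        bounds = (2000, 2027)  # 28 bp element inside one read
        a = aln(1970)
        assert classify_on_mac_plus_ies(a, bounds, CFG) is Classification.IES_PLUS

    def test_insufficient_anchor(self):
        a = aln(self.BOUNDS[0] - 3)  # only 3 matched bases on the MAC side
        assert classify_on_mac_plus_ies(a, self.BOUNDS, CFG) is Classification.NONE


# ---------------------------------------------------------------------------
# counting over hand-built SAM files


def _toy_references():
    mac = "A" * 99 + "TA" + "G" * 99  # junction TA at 100..101
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ann = IesAnnotation(
            ies_id="iesX", contig="c1", mac_junction=100, length=40,
            sequence="TA" + "C" * 38,
        )
    genome = ReferenceGenome(sequences={"c1": mac}, flavor=GenomeFlavor.MAC)
    plus, cmap = build_mac_plus_ies(genome, [ann])
    return genome, plus, ann, cmap


def _sam(path, contig_len, records):
    lines = ["@HD\tVN:1.6\tSO:unsorted", f"@SQ\tSN:c1\tLN:{contig_len}"]
    for name, flag, pos, cigar in records:
        length = sum(
            int(n) for n, op in zip(
                "".join(c if c.isdigit() else " " for c in cigar).split(),
                [c for c in cigar if not c.isdigit()],
            ) if op in "MIS"
        )
        lines.append(
            f"{name}\t{flag}\tc1\t{pos}\t60\t{cigar}\t*\t0\t0\t"
            f"{'A' * length}\t{'?' * length}"
        )
    path.write_text("\n".join(lines) + "\n")
    return path


def _write_fixture(tmp_path, shuffle_seed=None):
    genome, plus, ann, cmap = _toy_references()
    # 3 junction-spanning MAC records, 2 boundary-spanning MAC+IES records
    mac_records = [
        ("m1", 65, 60, "80M"),    # covers 60-139, spans the junction window
        ("m2", 129, 70, "60M"),   # covers 70-129
        ("m3", 65, 90, "40M"),    # covers 90-129
        ("far", 65, 1, "50M"),    # nowhere near the junction
    ]
    plus_records = [
        ("p1", 65, 80, "60M"),    # spans the left boundary (element at 100-139)
        ("p2", 129, 120, "40M"),  # spans the right boundary
        ("mid", 65, 105, "30M"),  # interior only -> not counted
    ]
    if shuffle_seed is not None:
        random.Random(shuffle_seed).shuffle(mac_records)
        random.Random(shuffle_seed + 1).shuffle(plus_records)
    mac_sam = _sam(tmp_path / "mac.sam", 200, mac_records)
    plus_sam = _sam(tmp_path / "plus.sam", 240, plus_records)
    return genome, ann, cmap, mac_sam, plus_sam


class TestCountBoundaries:
    def test_hand_built_fixture_counts(self, tmp_path):
        _, ann, cmap, mac_sam, plus_sam = _write_fixture(tmp_path)
        counts = count_boundaries(str(mac_sam), str(plus_sam), [ann], cmap)
        row = counts.iloc[0]
        assert (row.ies_plus, row.ies_minus) == (2, 3)

    def test_record_order_invariance(self, tmp_path):
        results = []
        for i, seed in enumerate([None, 5, 23]):
            sub = tmp_path / f"v{i}"
            sub.mkdir()
            _, ann, cmap, mac_sam, plus_sam = _write_fixture(sub, shuffle_seed=seed)
            counts = count_boundaries(str(mac_sam), str(plus_sam), [ann], cmap)
            results.append(tuple(counts.iloc[0][["ies_plus", "ies_minus"]]))
        assert len(set(results)) == 1

    def test_conflicting_read_dropped_and_logged(self, tmp_path):
        genome, ann, cmap, _, _ = _write_fixture(tmp_path)
        # same mate id supports IES- on the MAC and IES+ on MAC+IES
        mac_sam = _sam(tmp_path / "m.sam", 200, [("dup", 65, 60, "80M")])
        plus_sam = _sam(tmp_path / "p.sam", 240, [("dup", 65, 80, "60M")])
        log: list[str] = []
        counts = count_boundaries(
            str(mac_sam), str(plus_sam), [ann], cmap, conflict_log=log
        )
        row = counts.iloc[0]
        assert (row.ies_plus, row.ies_minus) == (0, 0)
        assert len(log) == 1 and "dup/1" in log[0]

    def test_missing_contig_in_header_is_error(self, tmp_path):
        _, ann, cmap, _, plus_sam = _write_fixture(tmp_path)
        bad = tmp_path / "bad.sam"
        bad.write_text("@HD\tVN:1.6\tSO:unsorted\n@SQ\tSN:other\tLN:100\n")
        with pytest.raises(ValueError, match="c1"):
            count_boundaries(str(bad), str(plus_sam), [ann], cmap)


class TestSimulatedCounts:
    def test_excised_only_has_no_ies_plus(self, counted_control):
        _, _, counts = counted_control
        assert counts.ies_plus.sum() == 0

    def test_expected_reads_per_boundary(self, counted_control, small_sim,
                                         tmp_path_factory):
        """Classified reads per IES match the window-size bookkeeping.

        With both mates anchored on somatic coordinates, an excised junction
        presents a start window of (R - 2a - 1) positions per mate and a
        retained element ~(R - a) per mate; expected per-IES counts are
        depth * window / R, checked to 3 standard errors of the mean.
        """
        from iesret.simulate import SimulationTruth
        from conftest import run_counting

        cfg, sim = small_sim
        _, _, control = counted_control
        R, a, depth = cfg.read_length, 5, cfg.depth

        exp_minus = depth * (R - 2 * a - 1) / R
        obs = control.ies_minus.to_numpy(float)
        assert abs(obs.mean() - exp_minus) < 3 * obs.std(ddof=1) / np.sqrt(len(obs))

        truth = SimulationTruth.uniform(sim.annotations, 1.0, 0.0)
        retained = run_counting(
            sim, truth, cfg, tmp_path_factory.mktemp("allret"), seed=31
        )
        lengths = {x.ies_id: x.length for x in sim.annotations}
        short = retained[retained.ies_id.map(lengths) < R - 2 * a]
        exp_plus = depth * (R - a) / R
        obs = short.ies_plus.to_numpy(float)
        assert abs(obs.mean() - exp_plus) < 3 * obs.std(ddof=1) / np.sqrt(len(obs))
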