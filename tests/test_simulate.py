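"""Synthetic-data generator: determinism, mixtures and molecule pools."""

import numpy as np
import pytest
from scipy import stats

from iesret.simulate import (
    DEFAULT_IES_LENGTH_MIXTURE,
    SimulationConfig,
    SimulationTruth,
    read_truth_tsv,
    sample_ies_length,
    simulate_genome,
    simulate_reads,
)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"gc_fraction": 1.5},
            {"contamination": -0.1},
            {"depth": 0.0},
            {"insert_mean": 50.0, "read_length": 100},
            {"substitution_error_rate": 1.0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    def test_truth_fraction_bounds(self):
        with pytest.raises(ValueError):
            SimulationTruth({"a": 1.2}, 0.0)


class TestSampleIesLength:
    def test_degenerate_distribution(self):
        rng = np.random.default_rng(0)
        assert all(
            sample_ies_length([(28, 28, 1.0)], rng) == 28 for _ in range(20)
        )

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            sample_ies_length([], np.random.default_rng(0))

    def test_two_point_mixture_proportions(self):
        # binomial sampling bound: within 3 s.e. of the 50/50 mixture
        rng = np.random.default_rng(1)
        dist = [(28, 28, 0.5), (45, 45, 0.5)]
        draws = np.array([sample_ies_length(dist, rng) for _ in range(10_000)])
        prop = (draws == 28).mean()
        assert abs(prop - 0.5) < 3 * np.sqrt(0.25 / 10_000)
        assert draws.min() >= 26

    def test_default_mixture_matches_configured_weights(self):
        # chi-square goodness of fit of 10,000 draws against the mixture
        rng = np.random.default_rng(2)
        draws = [sample_ies_length(DEFAULT_IES_LENGTH_MIXTURE, rng)
                 for _ in range(10_000)]
        edges = [lo for lo, _, _ in DEFAULT_IES_LENGTH_MIXTURE]
        observed = np.zeros(len(edges))
        for d in draws:
            observed[np.searchsorted(edges, d, side="right") - 1] += 1
        expected = 10_000 * np.array([w for _, _, w in DEFAULT_IES_LENGTH_MIXTURE])
        keep = expected >= 5
        chi2 = ((observed[keep] - expected[keep]) ** 2 / expected[keep]).sum()
        p = stats.chi2.sf(chi2, keep.sum() - 1)
        assert p > 1e-3  # draws consistent with the configured mixture


class TestSimulateGenome:
    def test_no_ies_identity(self):
        cfg = SimulationConfig(n_contigs=1, contig_length=8000, n_ies=0, seed=0)
        sim = simulate_genome(cfg)
        assert sim.mac.sequences == sim.mac_plus_ies.sequences

    def test_determinism_same_seed(self):
        cfg = SimulationConfig(n_contigs=2, contig_length=10_000, n_ies=12, seed=5)
        a, b = simulate_genome(cfg), simulate_genome(cfg)
        assert a.mac.sequences == b.mac.sequences
        assert a.mac_plus_ies.sequences == b.mac_plus_ies.sequences
        assert [x.sequence for x in a.annotations] == [x.sequence for x in b.annotations]

    def test_too_many_ies_rejected(self):
        with pytest.raises(ValueError, match="do not fit"):
            simulate_genome(
                SimulationConfig(n_contigs=1, contig_length=5000, n_ies=400, seed=0)
            )

    def test_gc_content_near_target(self):
        cfg = SimulationConfig(n_contigs=1, contig_length=50_000, n_ies=0,
                               gc_fraction=0.28, seed=1)
        sim = simulate_genome(cfg)
        seq = sim.mac.sequences["contig_1"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert abs(gc - 0.28) < 3 * np.sqrt(0.28 * 0.72 / len(seq))


class TestSimulateReads:
    def test_same_seed_byte_identical(self, small_sim, tmp_path):
        cfg, sim = small_sim
        small = SimulationConfig(n_contigs=1, contig_length=20_000, n_ies=30,
                                 depth=5.0, seed=13)
        g = simulate_genome(small)
        truth = SimulationTruth.uniform(g.annotations, 0.5, 0.1)
        outs = []
        for tag in ("a", "b"):
            files = {k: tmp_path / f"{tag}.{k}" for k in
                     ("r1", "r2", "truth", "mac.sam", "plus.sam")}
            simulate_reads(g, truth, small, files["r1"], files["r2"],
                           truth_tsv=files["truth"], sam_mac=files["mac.sam"],
                           sam_mac_plus=files["plus.sam"], seed=77)
            outs.append({k: p.read_bytes() for k, p in files.items()})
        assert outs[0] == outs[1]

    def test_truth_tsv_roundtrip(self, tmp_path):
        small = SimulationConfig(n_contigs=1, contig_length=15_000, n_ies=10,
                                 depth=2.0, seed=3)
        g = simulate_genome(small)
        truth = SimulationTruth.uniform(g.annotations, 0.25, 0.4)
        simulate_reads(g, truth, small, tmp_path / "r1.fq", tmp_path / "r2.fq",
                       truth_tsv=tmp_path / "t.tsv")
        back = read_truth_tsv(tmp_path / "t.tsv")
        assert back.contamination == pytest.approx(0.4)
        assert back.retention == {a.ies_id: 0.25 for a in g.annotations}

    def test_fully_retained_reads_carry_ies_sequence(self, tmp_path):
        """c=0, r=1: every junction-overlapping fragment carries the element."""
        small = SimulationConfig(n_contigs=1, contig_length=20_000, n_ies=20,
                                 depth=10.0, seed=6, substitution_error_rate=0.0)
        g = simulate_genome(small)
        truth = SimulationTruth.uniform(g.annotations, 1.0, 0.0)
        simulate_reads(g, truth, small, tmp_path / "r1.fq", tmp_path / "r2.fq")
        reads = [l.strip() for i, l in enumerate(open(tmp_path / "r1.fq"))
                 if i % 4 == 1]
        mac = g.mac.sequences["contig_1"]
        plus = g.mac_plus_ies.sequences["contig_1"]
        n_mac_only, n_plus = 0, 0
        for r in reads:
            if r in plus:
                n_plus += 1
            elif r in mac:
                n_mac_only += 1
        # with full retention, every read is a germline (MAC+IES) substring
        assert n_plus == len(reads)

    def test_fully_excised_reads_match_mac(self, tmp_path):
        """c=1: every read is a somatic substring (no IES+ support exists)."""
        small = SimulationConfig(n_contigs=1, contig_length=20_000, n_ies=20,
                                 depth=10.0, seed=6, substitution_error_rate=0.0)
        g = simulate_genome(small)
        truth = SimulationTruth.uniform(g.annotations, 1.0, 1.0)  # maternal only
        simulate_reads(g, truth, small, tmp_path / "r1.fq", tmp_path / "r2.fq")
        reads = [l.strip() for i, l in enumerate(open(tmp_path / "r1.fq"))
                 if i % 4 == 1]
        mac = g.mac.sequences["contig_1"]
        assert all(r in mac for r in reads)

    def test_mixture_law_molecular_fraction(self, tmp_path):
        """Across fragments, the IES-bearing fraction converges to (1-c)r."""
        small = SimulationConfig(n_contigs=1, contig_length=40_000, n_ies=40,
                                 depth=40.0, seed=14, substitution_error_rate=0.0)
        g = simulate_genome(small)
        r, c = 0.6, 0.25
        truth = SimulationTruth.uniform(g.annotations, r, c)
        from conftest import run_counting

        counts = run_counting(g, truth, small, tmp_path, seed=15)
        # per-read classification probability given the molecule state is
        # (almost) equal for the two states, so the classified-read fraction
        # estimates the molecular fraction (1-c)r
        frac = counts.ies_plus.sum() / (counts.ies_plus.sum() + counts.ies_minus.sum())
        target = (1 - c) * r
        n = counts.ies_plus.sum() + counts.ies_minus.sum()
        se = np.sqrt(target * (1 - target) / n)
        assert abs(frac - target) < max(3 * se, 0.02)
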