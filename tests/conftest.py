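"""Shared fixtures: toy references and cached synthetic pipeline runs."""

from __future__ import annotations

from pathlib import Path

import pytest

from iesret.boundaries import ClassifierConfig, count_boundaries
from iesret.genome_model import GenomeFlavor, IesAnnotation, ReferenceGenome
from iesret.simulate import (
    SimulationConfig,
    SimulationTruth,
    simulate_genome,
    simulate_reads,
)

TOY_MAC = "CCCTAGGG"
TOY_IES = IesAnnotation(
    ies_id="toy1", contig="c1", mac_junction=4, length=26,
    sequence="TA" + "TTGCAT" * 4,
)


@pytest.fixture
def toy_genome() -> ReferenceGenome:
    return ReferenceGenome(sequences={"c1": TOY_MAC}, flavor=GenomeFlavor.MAC)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated genome shared across tests (150 IESs, 2 contigs)."""
    cfg = SimulationConfig(
        n_contigs=2, contig_length=60_000, n_ies=150, depth=25.0, seed=11
    )
    return cfg, simulate_genome(cfg)


def run_counting(sim, truth, cfg, outdir: Path, seed: int | None = None):
    """Simulate reads with exact alignments and tally boundary counts."""
    outdir.mkdir(parents=True, exist_ok=True)
    mac_sam = outdir / "mac.sam"
    plus_sam = outdir / "plus.sam"
    simulate_reads(
        sim, truth, cfg,
        fastq1=outdir / "r1.fastq", fastq2=outdir / "r2.fastq",
        sam_mac=mac_sam, sam_mac_plus=plus_sam, seed=seed,
    )
    return count_boundaries(
        str(mac_sam), str(plus_sam), sim.annotations, sim.coordinate_map,
        ClassifierConfig(),
    )


@pytest.fixture(scope="session")
def counted_half_retained(small_sim, tmp_path_factory):
    """Counts for r=0.5, c=0 on the shared genome."""
    cfg, sim = small_sim
    truth = SimulationTruth.uniform(sim.annotations, 0.5, 0.0)
    counts = run_counting(sim, truth, cfg, tmp_path_factory.mktemp("half"), seed=21)
    return sim, truth, counts


@pytest.fixture(scope="session")
def counted_control(small_sim, tmp_path_factory):
    """Counts for an excised-only control (r=0) on the shared genome."""
    cfg, sim = small_sim
    truth = SimulationTruth.uniform(sim.annotations, 0.0, 0.0)
    counts = run_counting(sim, truth, cfg, tmp_path_factory.mktemp("ctl"), seed=22)
    return sim, truth, counts
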