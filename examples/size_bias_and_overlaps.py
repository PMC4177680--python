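"""Cohort analyses: size-group retention bias and knockdown-set overlaps.

Simulates an experiment in which the molecular retention fraction rises
with IES length (long elements depend more strongly on the silenced
factor), summarizes retention scores by the 23 default size groups, and
intersects the significant sets of two nested in-silico knockdowns.
"""

from pathlib import Path
import tempfile

from iesret import (
    ClassifierConfig,
    SimulationConfig,
    SimulationTruth,
    call_significant,
    count_boundaries,
    group_summaries,
    overlap_sets,
    proportion_significant_by_group,
    simulate_genome,
    simulate_reads,
)

cfg = SimulationConfig(n_contigs=2, contig_length=100_000, n_ies=400,
                       depth=40.0, seed=7)
sim = simulate_genome(cfg)
lengths = {a.ies_id: a.length for a in sim.annotations}

# retention rises with length: r = min(1, 0.1 + 0.002 * length)
size_dependent = {i: min(1.0, 0.1 + 0.002 * L) for i, L in lengths.items()}


def run(truth, tag, work, seed):
    mac, plus = work / f"{tag}.mac.sam", work / f"{tag}.plus.sam"
    simulate_reads(sim, truth, cfg, work / f"{tag}.r1.fq", work / f"{tag}.r2.fq",
                   sam_mac=mac, sam_mac_plus=plus, seed=seed)
    return count_boundaries(str(mac), str(plus), sim.annotations,
                            sim.coordinate_map, ClassifierConfig())


with tempfile.TemporaryDirectory() as tmp:
    work = Path(tmp)
    ctl = run(SimulationTruth.uniform(sim.annotations, 0.0, 0.0), "ctl", work, 1)
    kd = run(SimulationTruth(size_dependent, contamination=0.23), "kd", work, 2)
    # a weaker, nested knockdown: only the longest elements respond
    weak = {i: (r if lengths[i] > 150 else 0.0) for i, r in size_dependent.items()}
    kd2 = run(SimulationTruth(weak, contamination=0.23), "kd2", work, 3)

rec = call_significant(kd, ctl)
rec2 = call_significant(kd2, ctl)

print("size-group summaries (main knockdown):")
print(f"{'group':>10} {'n':>5} {'median RS':>10} {'% significant':>14} stars")
for s in group_summaries(rec, lengths):
    if s.n:
        print(f"{s.label:>10} {s.n:>5} {s.median_rs:>10.3f} "
              f"{100 * s.proportion_significant:>13.1f}% {s.stars}")
print("\nstars mark a shift vs the previous size group "
      "(* p<0.05, ** p<1e-10, *** p<2.2e-16): retention climbs with length.")

curve = proportion_significant_by_group(rec, lengths)
climb = curve.dropna().proportion.tolist()
print(f"\nproportion-significant curve rises from {climb[0]:.2f} to {max(climb):.2f} "
      "and then flattens, as expected when length drives sensitivity.")

sets = {
    "main": rec.loc[rec.significant, "ies_id"],
    "weak": rec2.loc[rec2.significant, "ies_id"],
}
print("\noverlap of significant sets (the weak knockdown's calls fall "
      "largely inside the main set):")
print(overlap_sets(sets).to_string(index=False))
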