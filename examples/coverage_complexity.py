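"""Germline sequence-complexity accounting from contig coverage.

Mimics the comparison of a control sample (which retains only somatic
DNA) with an excision-deficient sample on a germline contig set: contigs
collinear with somatic chromosomes are covered by both samples, while
purely germline contigs are covered only when elimination fails.  A contig
counts as covered at >= 2 RPKM (reads/kb contig/million mapped), contigs
> 1 kb only.
"""

from pathlib import Path
import tempfile

from iesret import contig_rpkm, count_mapped_reads, covered_complexity, \
    subset_not_covered_by

# 12 germline contigs: 8 somatic-collinear, 4 germline-specific
lengths = {f"collinear_{k}": 3000 + 500 * k for k in range(8)}
lengths.update({f"germline_{k}": 2500 + 400 * k for k in range(4)})


def write_sam(path, placements):
    lines = ["@HD\tVN:1.6\tSO:unsorted"]
    for name, ln in lengths.items():
        lines.append(f"@SQ\tSN:{name}\tLN:{ln}")
    serial = 0
    for contig, count in placements.items():
        for k in range(count):
            serial += 1
            pos = 1 + (k * 53) % (lengths[contig] - 100)
            lines.append(f"r{serial}\t0\t{contig}\t{pos}\t60\t100M\t*\t0\t0\t"
                         f"{'A' * 100}\t{'?' * 100}")
    path.write_text("\n".join(lines) + "\n")
    return str(path)


with tempfile.TemporaryDirectory() as tmp:
    work = Path(tmp)
    # the control only covers collinear contigs; the deficient sample covers all
    ctl_sam = write_sam(work / "ctl.sam", {c: 60 for c in lengths if "collinear" in c})
    kd_sam = write_sam(work / "kd.sam", {c: 60 for c in lengths})

    for tag, sam in (("control", ctl_sam), ("excision-deficient", kd_sam)):
        counts, total = count_mapped_reads(sam)
        records = contig_rpkm(counts, lengths, total)
        report = covered_complexity(records, cutoff=2.0, min_len=1000,
                                    reference_name=tag)
        print(report)

    ctl_counts, ctl_total = count_mapped_reads(ctl_sam)
    ctl_records = contig_rpkm(ctl_counts, lengths, ctl_total)
    germline_only = subset_not_covered_by(ctl_records, cutoff=2.0)
    print(f"\ncontigs below the control cutoff (pure germline DNA, "
          f"not collinear with somatic chromosomes): {sorted(germline_only)}")
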