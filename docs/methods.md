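# Methods

`iesret` quantifies programmed DNA elimination in ciliates from paired-end
DNA sequencing of the developing somatic macronucleus (MAC). In *Paramecium
tetraurelia*, ~45,000 short, single-copy Internal Eliminated Sequences
(IESs) are excised precisely from the zygotic genome during MAC
development. Every IES is flanked by 5'-TA-3' dinucleotides and one TA is
left at the somatic junction after excision, so at each annotated locus a
sequenced molecule is in exactly one of two states: retained (germline
configuration, `...TA-body-TA...`) or excised (somatic junction, a single
TA). When a factor required for elimination is silenced, the fraction of
retained molecules at each locus rises, and the package estimates and tests
that fraction genome-wide.

## References and coordinates

The somatic assembly (MAC reference) and the IES annotation define a second
reference, MAC+IES, built by splicing each IES sequence in immediately
before its junction TA. Coordinates are 1-based and closed (GFF3
convention); the junction position is the first base of the MAC TA; the IES
sequence includes its leading TA, so excision is exactly the deletion of
`length` bases and the two references interconvert losslessly. The
coordinate map shifts a MAC position by the summed lengths of elements at
or before it; positions inside inserted elements have no somatic image.
Overlapping or nested elements (they exist, rarely, in real annotations)
are rejected: the retention statistic is defined per independent junction.
IESs are recorded on the forward strand only — the TA motif is its own
reverse complement and excision is strand-symmetric.

## Read classification and the retention score

Reads are aligned separately against the two references (any short-read
aligner with default parameters; the simulator can emit exact alignments
for synthetic data). At each IES:

* **IES+** — a read aligned to MAC+IES that spans an element end (last
  somatic base | first IES base, or last IES base | next somatic base) with
  at least `anchor` matched bases on each side (default 5).
* **IES−** — a read aligned to MAC that matches through the junction TA
  with at least `anchor` matched bases on each side of the dinucleotide
  (a 12-base window at the default anchor).

Counting only at element ends avoids the length bias a whole-element count
would introduce (a long element would otherwise accumulate interior reads
in proportion to its length). The anchor must exceed the 2-bp ambiguity of
the shared TA: a read ending inside the TA cannot distinguish the two
states. Soft-clipped bases never count toward anchors; deletions always
break the matched window and insertions do too unless
`require_no_indel_in_anchor` is disabled. Only primary alignments with
MAPQ >= 1 are counted ("unambiguous alignments"; MAPQ 0 is the
aligner-agnostic marker of multi-mapping). Mates count independently, each
read id contributes at most once per IES, and an id whose two alignments
support both categories at one IES is dropped and logged.

The retention score is `RS = IES+ / (IES+ + IES−)`, from 0 (complete
excision) to 1 (complete retention); a locus with no classified reads has
no score (NA).

## Significance against a control

For each IES, the control sample's counts give an exact two-sided
Clopper-Pearson interval for the control RS (default confidence 0.95, via
the Beta quantile `B(1-alpha/2; k+1, n-k)`); the experimental counts are
then tested one-sided against the interval's **upper** bound
(`P(X >= k | n, p_upper)` for X binomial), and p-values are
Benjamini-Hochberg adjusted over all tested loci, calling adjusted p < 0.05
significant. Testing against the upper bound rather than the control point
estimate absorbs background (sequencing biases, annotation false
positives) and makes the test conservative under the null; the suite's
calibration check measures a false-positive rate of essentially zero when
experiment and control are drawn from the same excised-only truth.

Two policies were genuinely open and are fixed as follows. The control
interval is computed **per IES** from that locus's own control counts, not
from one pooled control score — per-locus coverage varies by an order of
magnitude and the test is applied per locus. A locus with zero classified
reads in either sample is reported NA and excluded from the number of
tests, rather than silently passing (a bound of 1 would never reject) or
failing.

## Synthetic experiments

The generator emulates the study design so the whole pipeline is testable
without downloads: an AT-rich genome (GC 0.28), TA-anchored junctions at
least 200 bp apart, IES lengths drawn from the periodic genome-wide size
distribution (peaks every ~10 bp from 26 bp; the default mixture weights
the 23 default size bins by the published genome-wide group tallies), 100-bp
FR read pairs with insert 300 ± 30 bp, i.i.d. substitution errors at 0.5%,
and depth 25x. Each fragment is maternal with probability `c` (the
maternal-MAC contamination fraction — DNA from fragments of the old,
fully rearranged somatic nucleus; always excised) and zygotic otherwise,
retaining each IES it crosses independently with the locus's molecular
retention fraction `r_i`. The per-locus IES-bearing molecule fraction is
therefore `(1-c) r_i`, the quantity RS estimates. The default `c = 0.23`
makes complete excision failure (`r = 1`) plateau at RS ~ 0.77, the
behaviour observed when the excising endonuclease itself is depleted. The
truth table (per-IES `r_i` and `c`) is written next to the reads, and all
outputs are byte-reproducible from the seed.

**Fragment placement.** Both mates are anchored on somatic coordinates:
the forward mate starts at a uniform MAC position, the reverse mate ends
one insert later, and retained elements are spliced into the walk as it
crosses junctions. This choice makes the retained and excised
configurations of a locus present nearly equal classification windows
(per mate: `R - 2a - 1` start positions for the excised junction,
`R - 2a + 1` to `R - a` for a retained element, R read length, a anchor),
so RS is a consistent, essentially length-independent estimator of
`(1-c) r_i` — the property the downstream statistics assume. Two
consequences are documented rather than hidden:

* a *small residual* remains — elements shorter than `R - a - 1` admit up
  to `a - 1` extra "pass-through" classifiable starts, worth about 0.01 RS
  at r = 0.5 between the shortest and longest elements. The suite's
  regression of RS on length bounds this residual (slope on the order of
  1e-5 per bp); removing it entirely would mean discarding real
  pass-through reads or changing the classification rule.
* the interior of a retained element longer than one insert is not
  covered; boundary counts, which are all the analysis uses, are
  unaffected.

Under strictly uniform per-molecule sampling (a real sequencer), a
retained element instead exposes a start window of about `L + R - 2a + 1`
positions, so raw RS would overestimate the molecular fraction in a
length-dependent way. Passing tests on the synthetic data therefore
validate the pipeline's statistics under the balanced design, not the
absence of that sampling inflation in real libraries.

The generator also does not emulate: indel sequencing errors (substitutions
only — junction classification is exercised identically), position- or
quality-dependent error profiles, PCR duplicates, coverage biases (GC or
otherwise), paralogy/multi-mapping ambiguity, or imprecise chromosome-
fragmentation breakpoints.

Because read provenance is known, the simulator emits exact SAM against
both references: each read's longest reference-collinear run is written as
a match and the rest soft-clipped (a local aligner's behaviour at an
excision breakpoint), MAPQ 60, with runs shorter than 30 bases treated as
unalignable and omitted. Ties between equal runs keep the first.

## Cohort analyses

IESs are grouped into 23 size bins anchored at the printed features of the
genome-wide distribution: 26–32, 33–42, 43–52, 53–62, 63–72, width-10 bins
to 212, then 213–332, 333–532, 533–1032 and >1032 bp. The exact published
edges are not recoverable, so these defaults are explicit and configurable.
Per group the summaries report n, median and quartiles of RS, and the
proportion significant; adjacent groups are compared by a two-sided
Mann-Whitney test (SciPy's exact method for small untied samples, normal
approximation with tie correction otherwise), starred at p < 0.05 (*),
p < 1e-10 (**), p < 2.2e-16 (***). Cross-sample comparisons use exclusive
Venn cells over significant sets (cells partition the union), Spearman rank
correlation for replicate concordance (NA pairs dropped, ties mid-ranked),
and for feature association a two-sided Mann-Whitney (continuous features,
e.g. GC content) or a 2x2 chi-square without continuity correction (binary
features, e.g. genic location), with the effect direction reported.

## Coverage-based complexity

Germline sequence complexity is accounted by mapping a sample onto contigs
assembled from excision-deficient cells: per contig,
`RPKM = count / (length/1000) / (mapped_library/1e6)`; a contig counts as
covered at >= 2 RPKM and only contigs > 1 kb enter the sum (reported in
Mb). The subset of contigs *below* the cutoff in a control sample marks
pure germline DNA not collinear with somatic chromosomes. Per-element
profiles (e.g. individual transposon copies) use the same RPKM unit but
normalize by the sample's reads mapped against the **MAC** reference, so
profiles are comparable across libraries — two distinct denominators, both
explicit. Counts are primary mapped records, mates independent, matching
the boundary counter's conventions.

## Problem sizes and numerical choices

The test-suite and acceptance experiments run at desk scale, chosen to
give the statistics adequate resolution while keeping the whole suite in a
few minutes: 1,500–2,000 IESs on 4 contigs of 120–150 kb at depth 25x for
calibration, recovery and size-independence; 20 seeds of small genomes for
the excision round trip; the full (k, n <= 200) grid for the exact-interval
oracle. Headline statistical checks: Clopper-Pearson agrees with numeric
CDF inversion to < 1e-9, tail p-values with direct pmf summation to
< 1e-12, BH with the step-up definition to < 1e-12; block mean RS recovers
`(1-c) r` within ±0.03; >= 97% of fully retained and <= 1% of excised-only
loci are called.

## Known limitations

* The test's null is the control's CI upper bound, so power depends on
  control depth; sparsely covered loci need strong retention to be called.
* No modelling of `c` inside the test: RS estimates `(1-c) r`, not `r`;
  contamination must be reasoned about separately (as in the 0.77 plateau).
* Real-data RS carries the per-molecule sampling inflation described
  above; cross-sample comparisons are unaffected but absolute molecular
  fractions are upper-bounded approximations.
* Overlapping/nested IESs and spliced or long-read alignments are out of
  scope; alignment itself is delegated to an external aligner.
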