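# Methods

## The analysis model

`repeatploidy` treats repeat families as clusters in a read-similarity
graph, their genomic abundance as a read-depth quantity, and their tandem
vs dispersed organisation as a paired-end signal. Its assumptions:

- **Low-pass regime for identification.** Mutual-similarity clustering
  separates repeats from single-copy sequence only when the per-copy read
  coverage of unique sequence is well below 1× — otherwise overlapping
  background reads chain into spurious components. The pipeline therefore
  clusters a deterministic prefix subsample of the reads (default an
  effective ~1× genome coverage; reads are uniform and unordered, so a
  prefix is an unbiased subsample) and maps *all* reads for abundance.
  This mirrors real survey datasets, which are a few percent of a genome
  equivalent.
- **Symmetrical hybrid.** Parental additivity uses the arithmetic mean of
  the two parental genome proportions, which presumes roughly equal
  parental genome sizes. Unequal parents would need weighted means; that is
  out of scope.
- **Read-depth abundance.** Genome proportion is computed per contig as
  GR/dataset-total where GR is the sum of aligned bases (equivalently mean
  depth × contig length, with all contig positions, including zero-depth
  termini, in the mean). Each read counts once, toward its best-scoring
  contig. GP therefore measures the repeat's share of the *sequenced
  bases*, a proxy for its genomic fraction under uniform coverage.

## Alignment engine

All similarity decisions use one seed-and-extend engine: shared k-mers
(k = 13 for ~360 bp reads, k = 11 for ~95–100 bp mates) define candidate
diagonals; the few best-seeded, well-separated diagonal bands are each
scored over two windows (the seed span and the full dovetail extension)
with edlib edit distance; identity = matching columns / alignment columns,
gaps counted as mismatches. Among windows meeting the caller's
identity/overlap thresholds the longest wins, ties to the higher identity.
Both strands are always tried. Multiple diagonal bands matter for tandem
targets: the most-seeded diagonal can be a clipped same-cohort window at a
contig end while a less-seeded diagonal carries the full-length alignment.

Consequences worth knowing:

- The engine searches for the best *local* window, like any HSP-based
  aligner. Two families whose overall divergence sits near the edge
  threshold (e.g. ~10–15% apart under a 90% identity rule) will be linked
  through their locally conserved windows; family separation is reliable
  only clearly beyond the threshold.
- The k-mer candidate screen bounds sensitivity: pairs sharing no sampled
  k-mer are never aligned. With the default k and sampling this loses only
  pairs far below any clustering threshold.
- Substitution-only simulations make diagonal windows exact; the edlib
  scoring still tolerates small indels in real data, but the simulator does
  not generate them (no 454 homopolymer model — a stated non-goal).

## Clustering, assembly, monomer detection

Edges require ≥90% identity over ≥55% of the read length (the short-read
mapping stringency reused as the clustering default; the choice is this
package's, not prescribed). Clusters are connected components ordered by
size and named CL1, CL2, …; singletons stay in the GP denominator but form
no family. Assembly is greedy overlap-layout-consensus: seed with the
longest read, stack every read whose best alignment to the evolving
consensus passes the overlap contract, majority-vote the columns
(lexicographic tie-break), repeat until nothing attaches; leftover reads
seed further contigs; contigs are ordered by total depth. Assembling
across a head-to-tail junction yields a contig of one monomer plus the
start of the next, so the tandem period appears as a terminal direct
repeat.

`detect_monomer` scans candidate periods p and scores each by the *best
50 bp window* of the shifted self-comparison (contig vs contig offset by
p). A true period always has a clean junction-crossing stretch even when
the contig ends run into mixed flanking sequence or into a monomer copy
from a divergence cohort ~15% away, while wrong periods score ~0.25
anywhere; the smallest period within 0.01 of the maximum (the longest
terminal repeat) wins, subject to a 0.7 floor. The monomer is the contig's
first p bases.

Cluster merging accepts either evidence class: spanning read pairs (one
mate per cluster, default ≥20 pairs) or consensus-to-consensus identity
(default ≥80% over ≥200 bp). The pipeline does not auto-merge; merging is
an explicit operation.

## Abundance and additivity

Mapping uses 80% identity over 50% of the read. Equal-scoring ties go to
the contig with the greater total assembly depth, then to the lowest
contig id — reads from an interspersed partner family that tie between
their own contig and a junction contig of the satellite cluster belong
with the more abundant reference; determinism is preserved. Parental GPs
below 0.01% (the reporting detection limit) count as zero in the
additivity mean. Reported tables round half-even to two decimals at the
reporting layer only; deficits are observed/expected at full precision,
undefined (NA) when the expectation is zero.

## Paired-end classification

Pairs fail QC unless both mates are ≥95 bp with ≤5 Ns; passing mates are
trimmed to 95 bp. Against the target contig (90% identity over 55% of the
mate), both mates hitting → dual HSP; one → provisional solo, reassigned
to dual if the partner hits another contig of the same cluster; neither →
excluded from the denominator. Mates hitting different monomer copies are
dual (no distance check). The solo profile folds each target-hitting
mate's interval onto monomer coordinates ((pos − monomer start) mod
monomer length) and reports, per position, solo coverage / total coverage
— the per-position convention; positions with no coverage are absent. The
overall solo fraction is solo/(solo+dual) at the pair level.

## Similarity distributions

Within-family scores are best-local-alignment identities for every
unordered read pair with ≥100 bp aligned (self-hits excluded, no
low-complexity masking). The density estimate is a Gaussian-kernel KDE
(Silverman bandwidth) computed by histogram convolution with the sample
reflected about identity 1.0, so the identical-copy mode cannot leak past
the boundary; the reported density integrates to ~1 on the kept half-axis.
A peak is a local maximum whose prominence within a 0.05-wide window is at
least 5% of its own height and whose height is at least 5% of the maximum:
the own-height criterion keeps genuine cohort modes that ride on their
neighbours' shoulders and rejects ripples on flat plateaus, which a
fraction-of-global-maximum floor cannot do when the 1.0 mode is
near-degenerate. Location comparison is the two-sample Wilcoxon rank-sum
test: exact null for tie-free samples up to n = 50 per side, normal
approximation with tie correction otherwise; identical constant samples
report p = 1. Pairwise scores within a sample are not independent (each
read contributes many pairs); the output carries that caveat. The
consensus-match profile aligns reads at mapping stringency and reports,
per consensus position, matching/covering reads, averaged over consecutive
20 bp windows (trailing window over its actual width).

## The simulator

The generator emulates the study system: a paternal diploid carrying a
2,200 bp-monomer tandem satellite at ~1.8% of the genome (16 units in 4
loci at the 2 Mb default) partially interspersed with a 4,800 bp
retroelement partner shared ancestrally with the maternal genome; a
maternal diploid lacking the satellite; an allopolyploid that is the union
of both sub-genomes with unit-boundary-respecting elimination of a
configurable fraction of tandem units (contiguous blocks per locus by
default, apportioned genome-wide by largest remainder; scattered mode
available), optional whole-locus losses, and homogenisation sweeps in
which a random donor unit overwrites k recipients within a locus (the
minimal mechanism that reproduces the similarity-peak structure; unequal
crossover is not modelled).

Divergence cohorts are shared-mutation cohorts: each cohort derives once
from the family monomer at its substitution rate and all units of a cohort
are identical. Pairwise identities then cluster at 1.0 (within cohort) and
1 − r against the undiverged cohort — the multi-peak homogenisation
signature by construction. Default cohorts: 40% at rate 0, 30% at 0.05,
30% at 0.10, giving peaks near 1.0, 0.95, 0.90 (plus a minor cross-cohort
mode near 0.855).

Dispersed satellite copies are 150 bp monomer fragments (configurable via
`dispersed_span`), each adjacent to a retroelement copy. The fragment
length is deliberately below the long-read clustering overlap (~198 bp) so
junction reads cannot chain the satellite component into the retroelement
cluster, while 95 bp mates still detect the dispersed copies — the
paired-end stage, not the clustering stage, carries the dispersed signal,
as in the real workflow.

Reads are uniform shotgun: 454-like 360 bp single reads and Illumina-like
95–100 bp inward-facing pairs (Normal insert, default 300 ± 30), i.i.d.
per-base substitution errors and N-substitutions (defaults 0), truth tags
(source position, majority copy class) in the read metadata, ignored by
all analysis modules. Expected read count is coverage × genome length /
read length, both mates counted. Fixed seeds give byte-identical FASTA and
FASTQ output; all pipeline randomness derives from one seed.

What the simulator does *not* emulate: indels and platform-specific error
profiles, methylation, chromosome structure, GC-biased coverage, unequal
parental genome sizes, and a divergence *continuum* (cohorts are
discrete). Passing tests therefore demonstrate the pipeline's arithmetic
and its qualitative behaviour under the stated model, not robustness to
real-platform artefacts.

## Problem sizes and numerical choices

Genomes default to 2 Mb per sub-genome (repeat fractions preserved from
the ~2,650 Mb system, so all GP arithmetic is scale-faithful) — a desk
scale at which an end-to-end trio analysis runs in well under a minute.
Abundance-recovery checks run at 10–15× mapping coverage: the satellite GP
estimator's noise is essentially binomial read sampling (relative sd
≈ √((1−p)/(n·p)) ≈ 4.4% at 5×), and those coverages put the sampling noise
well inside the tolerance bands being asserted. Clustering always runs on
a ~1× subsample regardless of mapping coverage. The remaining small
negative bias of GP estimates (~1–3%) comes from array-edge reads whose
repeat content falls below the 50%-of-read mapping floor.

Determinism notes: consensus ties break lexicographically (A<C<G<T);
mapping ties break by depth then contig id; cluster ordering by size then
lexicographic first read; k-mer subsampling in the candidate screen uses
CRC32, not Python's randomised `hash`. Degenerate inputs: empty graphs
cluster to nothing; a cluster whose reads share nothing assembles one
contig per read; a digest with no site returns one full-length fragment;
similarity of fewer than two reads is an empty distribution.

## Known limitations

- Connected-component clustering over-merges families that are genuinely
  linked by shared sequence; the hierarchical refinements of dedicated
  repeat pipelines are out of scope.
- The solo-HSP fraction at desk scale is dominated by array edges (few
  units per locus), so its absolute value is larger than in a full-scale
  genome; only directions and ratios are comparable across scales.
- The rank-sum p-value treats pairwise scores as exchangeable
  observations; it describes the score sets, not independent units.
- GP assumes uniform coverage; no GC or mappability correction is applied.
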