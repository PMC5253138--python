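# Methods

## Genetic model

**Genome.** Twelve chromosomes with Nipponbare-scale physical lengths
(43.3, 35.9, 36.4, 35.5, 29.9, 31.2, 29.7, 28.4, 23.0, 23.2, 29.0,
27.5 Mb; 373 Mb total), configurable.  All positions are 1-based base
pairs; interval sizes are reported as `end − start`, matching the
convention used for substituted-segment and QTL intervals (so the
interval 1–688,039 has size 688,038).  BED exports shift to 0-based.

**Recombination.** Haldane model (no crossover interference) on a
uniform physical-to-genetic map of 1 cM per 400 kb (≈ 0.93 M genome-wide
genetic length).  Published linkage maps for rice average roughly
0.25 cM/100 kb, and nothing downstream is sensitive to the exact
constant; it is exposed on `RecombinationMap`.  Interval-based meiosis
draws a Poisson crossover count per chromosome (mean = genetic length in
Morgans) with uniform positions.  For very large F₂/F₃ populations where
only marker-locus genotypes matter, a vectorised sampler exploits the
Markov property of the origin process under Haldane's model: the origin
switches between adjacent queried sites with probability equal to the
recombination fraction.  The two samplers draw the same distribution
(cross-checked in the test suite) — the fast path is a restriction of
the same process to the queried positions, not an approximation.

**Gametophytic selection.** A pollen grain of an S-cytoplasm plant
functions iff it carries a restorer allele at ≥ 1 restorer locus; ovules
are never selected, and N-cytoplasm pollen is never selected.  Restorer
alleles ride on donor DNA: a haplotype carries *Rf* at a restorer locus
exactly when its origin there is donor.  Closed forms follow directly:
a single-locus heterozygote sheds 50% functional pollen; *k* unlinked
heterozygous loci shed 1 − 2⁻ᵏ.  Crosses draw ovules freely and pollen
by rejection from the functional pool; a father with S cytoplasm and no
*Rf* allele anywhere raises (no functional pollen), while such a plant
as mother is simply a CMS line.

**Restorer loci (defaults).** An Rf6-like locus at chr8:340,000 (inside
the first sub-megabase bin of chromosome 8) and an Rf5-like locus at
chr10:17,700,000 (mid-chromosome 10).  Both configurable.

## Synthetic breeding design

**CSSL construction.** Each line gets a target position; the F₁
(recipient × donor) is backcrossed to the recipient for `n_backcrosses`
generations (default 4).  At each generation a batch of `mas_batch`
(default 12) progeny is genotyped on a 1-Mb marker grid; the candidate
retaining donor at the target with the least donor content elsewhere is
advanced — marker-assisted selection with perfect markers.  Fixation to
homozygosity is modelled by drawing one target-retaining gamete from the
final backcross plant and doubling it: the distributional endpoint of
repeated selfing with selection for the target, at a fraction of the
cost.  Under these defaults lines carry 1–7 donor segments.  A designed
panel pins the first `carrier_lines_per_locus` × (number of restorer
loci) targets to the restorer positions (default 3 per locus), the way a
real panel guarantees coverage of regions of interest; remaining targets
are uniform over the genome.

**SNP calls.** Parental SNP panels are placed at a configurable density
(default 50 SNPs/Mb in the pipeline; the per-chromosome count is
deterministic, positions uniform).  Calls are donor dosages {0, 1, 2}
read from the true diplotype, flipped to one of the other two states
with probability `error_rate` (default 0.005) and dropped to missing
with `missing_rate` (default 0.02).

**Phenotypes.** Seed-setting % is a truncated-Gaussian draw per plant
around a (genotype class, temperature regime) cell mean.  Defaults
(mean ± SD):

| class | normal | heat |
|---|---|---|
| *Rf6/rf6* het | 87.41 ± 2.30 | 67.22 ± 10.02 |
| *Rf5/rf5* het | 85.45 ± 3.02 | 36.85 ± 13.12 |
| double het | 88.00 ± 5.00 | 75.10 ± 12.91 |
| *Rf* homozygote | 90.12 ± 4.24 | 82.46 ± 3.87 |
| sterile (bagged) | 0 | 0 |
| sterile (natural) | U[0, 5) | U[0, 5) |

The heat regime represents flowering during a ≥ 37 °C heat wave, under
which single-restorer heterozygotes lose fertility (Rf5 more severely
than Rf6) while homozygotes and double heterozygotes stay near normal.
The double-het normal-regime cell was not observed in the source field
data (early-sowing plots of a cool year lacked that genotype); 88 ± 5 is
our choice, consistent with the > 80% "normal spikelet fertility" of all
restored genotypes under normal conditions.  The sterile natural seed
set is outcrossing, uniform below 5%.  Only the two discrete regimes are
modelled; no continuous temperature dose-response is attempted.

## Analysis chain

**Window calling.** Defaults: window 15 SNPs, step 5, bridging ≤ 1
ambiguous window inside a run; `WindowParams.scaled_to` grows the window
when expected SNPs per window fall below 10.  Thresholds (80% for
homozygous calls, dosage band [0.3, 0.7] for het) are configurable.
Segment boundaries are run-endpoint SNP positions — boundary error is
bounded by the window span, which the round-trip test asserts.  Windows
mixing donor and recipient calls (dosage in the het band) arise at
segment boundaries and around segments shorter than the window span;
in a finished homozygous panel these surface as short het segments and
are logged as warnings, not errors, since F₂-type inputs genuinely
contain het segments.

**Panel statistics.** Per chromosome: segment count, summed length, and
density = union of segments across lines / chromosome length.  Totals
are sums of rows except density, which is the genome-wide union share.
The mean segment length is reported as total length / total count.

**Bin map.** Per chromosome, breakpoints are the sorted union of all
segment starts and ends; bins are consecutive breakpoint intervals
intersecting ≥ 1 segment, numbered serially in genome order.  Every
segment is an exact union of bins (property-tested), and the line × bin
matrix entry is the covering segment's state.

**QTL scan.** Single-bin one-way ANOVA, carrier (dosage > 0) versus
non-carrier lines, on per-line mean natural seed-setting rate; the
statistic suite (F, partial R², p) is computed from sums of squares,
vectorised over bins.  Genome-wide significance: (1 − α) quantile of
max-F over phenotype permutations (default α = 0.05, 1000 permutations).
Contiguous supra-threshold bins merge into one hit reported at the peak
bin; additionally, same-chromosome runs whose peak carrier sets are
nested merge into one region, because a single introgression can split
into two runs when intermediate bins (carried by extra non-restoring
lines) dip below threshold.  This can also merge genuinely distinct
linked QTLs with nested carriers — composite-interval mapping and
multi-QTL models are out of scope.  A hit whose carriers all carry
another hit's peak bin cannot be separated from it with the panel at
hand and is flagged `confounded` (the situation that discredits a
two-chromosome artifact hit when one line carries both bins).

Power note: with two planted restorers the non-carrier group of each
bin contains the *other* locus's fertile carriers, which inflates the
within-group variance.  Empirically the scan recovers both loci
essentially always for panels of ≥ 50 lines with ≥ 3 carrier lines per
locus, but a locus carried by only 2 lines in a 50-line panel is usually
missed — single-marker ANOVA needs more carriers than stepwise
partial-R² scans.

**Segregation test.** χ² goodness of fit of hom-donor : het to 1:1
(df 1, no Yates correction) plus a hom-recipient tolerance of ≤ 1% of
the non-missing population (rare marker–locus recombinants; a real
200-plant population tolerated 1).  Verdict `consistent-single-Rf`
requires both.  The pipeline runs the test on a marker inside the
fine-mapped interval — the most tightly linked marker available —
mirroring the practice of testing with a marker from the candidate
region; a marker megabases from the locus would count its recombinants
as 1:1 violations.

**Fine mapping.** Fertile plants hom-recipient at a marker are
recombinants (their fertility proves an *Rf* allele).  Each recombinant
whose hom-recipient run anchors at an end of the marker ladder excludes
the locus from that run, i.e. votes for every inter-marker gap
compatible with a single crossover; the candidate interval spans the
best-supported gaps.  Maximum parsimony makes the placement robust to
the rare double recombinants expected in 4,000-plant screens under a
no-interference model (≈ r² per side), which would otherwise contradict
the consensus; evidence incompatible with every gap raises
`inconsistent recombinants`.  Adjacent markers never separated by a
recombinant cannot shrink the interval, and a side with no informative
recombinant stays at the chromosome bound.  Interval size is the
distance between the flanking marker positions.

**Allele diffing.** Global Needleman–Wunsch alignment at unit mismatch
and unit gap cost (edit distance), with substitutions and maximal gaps
read off the alignment path.  Positions are 1-based on the reference
allele; an insertion reported at +p sits immediately before reference
base p.  Equal-cost alignments are possible in repetitive context
(e.g. inserting a base next to an identical base); the library reports
one optimal alignment, and the round-trip tests construct mutations in
non-repetitive context where the optimum is unique.

## Reproducibility and problem sizes

A single run seed is expanded through `numpy.random.SeedSequence.spawn`
into independent substreams per stage (panel, CSSLs, SNP noise,
phenotypes, scan permutations, segregation, fine mapping), so identical
(config, seed) pairs give byte-identical artifacts and any stage can be
re-drawn in isolation.  Machine-readable outputs keep full float
precision; report tables round to 4 significant digits.

Default pipeline sizes follow the study design it emulates: 127 CSSLs,
four backcrosses, 400-plant F₂ segregation tests, 4,000-plant fine-map
screens, 1,000 scan permutations.  The test suite exercises the same
code paths on smaller panels (24–50 lines, 2–3 chromosome toy genomes,
120–500 permutations), chosen so the whole suite completes in well under
a minute while the statistical assertions retain 3σ resolution; the
100-replicate two-locus property uses 50-line panels with four pinned
carriers per locus, the carrier count of the strongest region in the
design being emulated.

## What the simulator does and does not capture

It captures: mosaic diplotypes from recurrent backcrossing, segment-size
variation, gametophytic transmission distortion, genotyping error and
missingness, genotype × regime phenotype structure, and the bin-level
confounding that arises when one line carries two unlinked donor
segments.  It does not capture: read-level sequencing artifacts (we
start from SNP calls), crossover interference, segregation distortion
from causes other than pollen selection, marker polymorphism failure,
environmental field gradients, or the molecular mechanism of restoration
(mRNA processing of the sterility ORF).  Passing tests therefore
demonstrate the correctness of the inference chain under the stated
genetic model, not the field behaviour of real populations.
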