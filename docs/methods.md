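# Methods

## Model and calling procedure

`lohscape` analyses heterozygous diploid mutation-accumulation (MA) lines: a
hybrid ancestor heterozygous at a genome-wide set of *markers* (sites where
the two parental haploids carry different alleles) is propagated purely
vegetatively through repeated single-cell bottlenecks, and each surviving
line is genotyped at the end.  Loss of heterozygosity (LOH) is read out as
marker-state conversion; de novo single-nucleotide mutations (SNMs) appear
as line-exclusive variants at non-marker sites.

### Marker definition and tagging

A position becomes a marker when the parental calls show exactly one
alternate allele between them, the two parents resolve to different alleles,
and the summed parental depth is at least `min_combined_depth` (default 50
reads, read as a sum over the two parents).  Per line, each marker is tagged
HET, HOM_P1, HOM_P2 or MISSING; calls with GQ below `min_gq` (default 20)
are MISSING.  A homozygous call matching neither parental allele is also set
to MISSING but counted and logged: it is a candidate de novo variant and is
handled by the mutation caller, not the LOH caller — dropping it silently
would risk counting one event twice.

### Tract calling

Per line and chromosome, maximal runs of identically tagged markers are
segmented; MISSING calls are transparent (they neither extend nor break a
run, carrying no evidence either way).  Runs with fewer than two converted
markers are discarded — a two-site support threshold keeps the event
definition comparable across backgrounds whose marker densities differ by
an order of magnitude.  Consecutive tracts of the same parental origin are
merged when fewer than two heterozygous calls separate them (a disruption
unsupported by two heterozygous sites is not believed); merging iterates to
a fixed point, only HET calls count against a merge, and merged-over markers
are spanned but not counted as converted support.  Filtering precedes
merging, in that order.

Tracts reciprocally overlapping by at least `shared_overlap` (default 80% of
*both* marker spans) in at least `shared_lines` (default 50%) of a hybrid's
lines — same chromosome, same parental origin, the tract's own line included,
decisions taken on the pre-removal sets — are removed as ancestral
homozygosity rather than de novo events.  The reciprocal reading prevents a
megabase tract from absorbing unrelated short tracts; a one-sided variant is
available behind a switch.  The exclusion runs on marker spans, before
boundary resolution, since marker spans are the objects comparable across
lines.

Boundaries are resolved as the floored midpoint between the tract's
outermost converted marker and the nearest flanking non-missing marker, so
tract size is the distance between the midpoints of the closest unconverted
sites; with no flanking marker the tract extends to position 1 or the
chromosome end (required for fully homozygous chromosomes).  A tract is
TERMINAL when its resolved span intersects the first or last
`terminal_window` bp of its chromosome (default 20,000), INTERSTITIAL
otherwise.  Coordinates are 1-based inclusive everywhere except BED export
(0-based half-open).

### Mutation calling

Candidate SNMs are biallelic non-marker positions covered by more than
`min_depth` reads (default 10, strict) in every line of the background where
exactly one line deviates from the shared ancestral state.  Homozygous
candidates inside a called LOH tract of their own line are removed: at a
position where the parents differed but which fell below the marker
thresholds, an LOH event masquerades as a homozygous substitution.
Heterozygous candidates are kept regardless of position.  Chains of SNMs
separated by at most one base pair form multi-nucleotide mutations (MNMs);
an MNM is one event, and its members enter neither the SNM count nor the
spectrum.  Spectra are strand-collapsed to the six pyrimidine-reference
classes; Ts/Tv is (C>T + T>C) over the rest and the GC→AT/AT→GC bias is
C>T over T>C.  Genic/intergenic splits use gene features from a GFF3;
triplet contexts need a reference FASTA.

### Rates and statistics

With `N` base pairs under LOH (the sum of resolved, pairwise disjoint tract
spans), `D` total divisions and `G` the genome size (sum of chromosome
lengths), the LOH site rate is `N/(D·G)` and the event rate `n_events/D`,
each also restricted to the interstitial/terminal subsets.  The identity
`site_rate × D = genome_fraction` holds exactly and is asserted in the test
suite.  Mutation rates divide by the diploid genome (`2G`) and double
homozygous events — under the simulator's generative model this weighting
makes the estimator unbiased when LOH fixes half and erases half of the
overwritten heterozygous mutations; unweighted variants are reported
alongside.  Divisions derive from exponential growth `N = e^{rt}`:
generation time `g = ln2/r`, hence `hours × r / ln2` divisions per
bottleneck.  Lines are grouped by genome fraction under LOH with thresholds
(0.10, 0.85); the upper default is deliberately below the nominal "more than
90%" description of nearly homozygous lines because observed nearly
homozygous lines span 88–98%.  Parental bias uses an exact two-sided
binomial test on base pairs under LOH per origin (event counts are an
option); cross-line analyses use Pearson correlation (ancestral
heterozygosity vs per-line T-LOH/I-LOH/total counts), Kruskal–Wallis across
hybrids and two-sided Mann–Whitney U between fertility groups, reported with
statistic, p and n, degenerate groups as NaN with a warning.

## Simulator

Single-cell bottlenecks make exactly one lineage ancestral to each sequenced
clone, so a line is simulated as one genome undergoing `D =
n_bottlenecks × divisions_per_bottleneck` divisions; within-colony population
dynamics (selection, clonal interference) are deliberately absent, matching
the MA design's near-neutrality.  Per division the lineage draws:

* **Interstitial events** at `i_loh_rate` (Poisson): chromosome chosen in
  proportion to length, start uniform, length geometric with mean
  `i_loh_mean_len` (default 2 kb, the kb scale of mitotic gene-conversion
  tracts — the simplest law matching a short-mode mean), origin a fair coin.
* **Terminal events** at `t_loh_rate` (Poisson): breakpoint uniform on a
  length-weighted chromosome, tract to the *nearer* end (mean length L/4 on
  a chromosome of length L), origin a fair coin.
* **Mutations** at `snm_rate` per *haploid* site per division
  (Poisson(rate × 2G × D) per line), each on one homologue chosen by a fair
  coin, transition odds `ts_tv_bias` (default 1.35), at non-marker sites
  unless `mutate_marker_sites` is set (kept separate so LOH genotyping and
  SNM calling remain independently testable).

Later events overwrite earlier state.  A heterozygous mutation overwritten
by a later LOH event fixes (homozygous) when the conversion copies its
homologue and is erased otherwise; the first covering event after the
mutation decides, and a fixed mutation stays fixed.  Genotype qualities are
uniform integers in `gq_range` (default 10–99, so a realistic fraction of
calls fails the GQ 20 filter), depths uniform in `dp_range`, and calls drop
out with probability `missing_rate` (default 0.02).  All randomness flows
from one root seed: stream *i* of numpy's `default_rng([seed, i])` drives
line *i* (stream 0 places markers), so any line is reproducible in
isolation.

Defaults reproduce the nine-hybrid study conditions: 20 lines, 75
bottlenecks × 24.2 divisions, genome-wide event intensities 5.6×10⁻²
(interstitial) and 9.2×10⁻³ (terminal) events per division, mutation rate
1.1×10⁻¹⁰ per site per division.  The bundled study-design table (marker
counts, line counts, bottleneck and division totals per hybrid) provides the
per-background parameters; marker placement is uniform per chromosome with
Poisson counts at the configured density (0.8–10 markers/kb across the
design).

### What the simulator does not emulate

Uniform terminal breakpoints make simulated T-LOH tracts (mean L/4)
substantially longer than empirically observed terminal tracts, which
cluster towards telomeres; simulated genome fractions under LOH are
correspondingly higher than real ones at the same event rates.  There is no
aneuploidy, no read-level noise, no genotyping error besides missingness and
the GQ floor, no marker clustering, and no return-to-growth mechanism.
Passing recovery tests therefore demonstrates the correctness of the calling
logic under the stated generative model, not calibration against any real
dataset.

## Validation benchmarks

The recovery benchmarks use a 1 Mb toy karyotype of 16 × 62.5 kb chromosomes
(the yeast karyotype at 1/12 scale) with the terminal window scaled in
proportion to 2 kb — an unscaled 20 kb window would cover 64% of a toy
chromosome and void the interstitial/terminal distinction.  Conditions: 20
noise-free lines, 5 markers/kb, D = 2,000, interstitial 5×10⁻² and terminal
5×10⁻³ events per division.

Because later events overwrite earlier ones, the configured per-division
intensities are not recoverable in principle at this event density (≈17% of
geometric 2 kb tracts span fewer than two markers at 5 markers/kb; same-origin
overlaps merge; terminal events swallow interstitial ones).  The oracle is
therefore the ground-truth log's *realized final state*: maximal final-state
segments, with marker-invisible disruptions (< 2 intervening markers) fused
and sub-two-marker segments dropped — exactly the detectability the calling
rules themselves define.  A truth segment is recovered when a called tract of
the same line, chromosome and origin matches its marker-resolvable span with
reciprocal overlap ≥ 0.9.  Scored this way the caller recovers ≥ 95% of
detectable segments, matches event rates within a few percent, mean
interstitial size within ~1%, and classifies matched terminal segments
correctly ≥ 95% of the time (terminal classification accuracy is scored
among matched segments; missed segments are recovery failures, not
classification errors).  The called-over-configured event-rate ratio (~0.65
at this density) is reported for transparency but is a property of overwrite
saturation, not of the caller.

Mutation recovery plants μ = 10⁻⁷ per haploid site per division with Ts/Tv
odds 2:1.  The homozygous-in-LOH filter is fed the ground-truth tract set,
isolating the mutation pipeline from caller boundary rounding (called
boundaries are midpoint-resolved and may differ from true event boundaries
by about half a marker gap).  Detection is then exact (precision = recall
= 1) against the detectable truth: surviving, line-private heterozygous
mutations — homozygous survivors necessarily sit inside LOH and are removed
by the filter, and a site mutated in two lines is not line-exclusive for any
caller.  The weighted rate estimate lands within ±20% of the planted rate
(the residual deficit is the heterozygous-survivor fraction at the benchmark's
LOH coverage).

The study replica in `scripts/acceptance.py` runs the nine-hybrid design at
1/8 genome scale with event intensities divided by 8 (event counts are
extensive in DNA content, so this preserves the study's areal event
density); event rates are additionally reported rescaled to full-genome
equivalents.  Problem sizes throughout (toy karyotype, 1/8 replica, 10–20
lines per benchmark) are chosen so the whole validation suite runs in
seconds while keeping per-benchmark event counts in the hundreds to
thousands.

## Numerical and design choices

* Midpoint boundaries are floored to integers (base-pair coordinates must be
  integral; one direction, fixed once).
* Merging counts HET calls only; MISSING never blocks a merge (a filtered
  genotype carries no evidence of heterozygosity).
* "Sites under LOH" means base pairs covered by resolved tract spans, not
  marker counts — the only reading under which `site_rate × D` equals the
  genome fraction under LOH.
* Per-hybrid aggregate rates are means of per-line rates, not pooled counts.
* The shared-tract partner must share parental origin (an ancestrally
  homozygous block carries one origin in every line).
* `G` defaults to the sum of chromosome lengths of the supplied genome
  table.
* VCF input is parsed with cyvcf2 (GT/DP/GQ only; phased and unphased
  separators are equivalent); the single-sample VCF writer emits a minimal
  VCF 4.2 by hand.
* Within a planted event the two parental origins are equally likely; the
  probability is configurable since nothing pins it empirically.
* Ties in the terminal-event breakpoint (equidistant from both ends) break
  towards the left end.

## Known limitations

* Gene conversion, crossover and BIR are distinguished only through the
  interstitial/terminal proxy; no coverage analysis, so copy-neutral LOH and
  deletion cannot be told apart.
* Indels, aneuploidy and structural variation are out of scope.
* The per-line depth filter applies to mutation calling only; marker tagging
  trusts upstream GT/GQ/DP as produced.
* With very few lines the shared-tract exclusion is aggressive at the 50%
  boundary (with two lines, every tract is trivially "shared by half the
  lines"); it warns and passes through single-line inputs unchanged.
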