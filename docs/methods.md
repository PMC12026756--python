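# Methods

This note records the models behind each estimator, the defaults and why
they are set where they are, what the synthetic-data generator does and
does not emulate, and the numerical choices a maintainer would want
written down. Every number quoted here is produced by the test suite,
the analysis scripts, or `scripts/acceptance.py`; nothing is asserted
that the code does not compute.

## Pedigree inbreeding (F_PED)

F_PED of an individual is the kinship of its parents under the standard
recursion (φ(a,a) = (1+F_a)/2; φ(a,b) averages over the parents of
whichever argument has the deeper ancestor DAG — expanding the deeper
one guarantees it is never an ancestor of the other, which is the
recursion's validity condition). Computation is memoized per pedigree;
the test suite checks it against an exhaustive path-counting oracle
(Σ over common ancestors and non-overlapping path pairs of
(½)^(n₁+n₂+1)(1+F_A)) on randomized looped pedigrees.

Depth truncation uses *minimum* parent-link distance: an ancestor
reachable at distances 4 and 7 is retained by a g = 5 truncation, and
individuals at exactly g keep their id but lose their parents. This
matches the "most recent N generations" semantics of pedigree software
and makes F_PED monotone nondecreasing in g (truncation only removes
positive path terms). Unknown-parent codes accepted: `0`, empty, `NA`.
Reported pedigree depth is the *longest* ancestor path; population
summaries sometimes mean the mean complete depth instead — the two are
not distinguished in common usage, so the choice is documented here and
exposed as is.

## ROH calling

The caller is the classic sliding-window procedure for unphased calls
(window of W SNPs accepting if ≤ H het and ≤ M missing; SNP in-run if
the accepting fraction of covering windows ≥ T; maximal in-run
stretches trimmed to the outermost homozygous non-missing call; split
at inter-SNP gaps > max-gap; filtered by min SNPs, min length, max kb
per SNP). Defaults mirror the common dialect: W = 50, H = 1, M = 5,
T = 0.05, gap = 1000 kb, density = 50 kb/SNP.

Two presets bracket the data types: `array_preset` (min length 1000 kb —
long enough to capture recent plus ancestral autozygosity while
excluding LD-scale runs) and `wgs_preset` (min length 70 kb, zero
heterozygotes — the dense-variant setting used when sequence data are
reduced to comparable homozygosity calls). The minimum segment SNP
count is data-derived: L = ⌈ln(α/(m·n)) / ln(1−het)⌉ bounds the
expected number of chance all-homozygous stretches below α across m
markers × n samples; at study scale (α = 0.05, m = 158,378, n = 244,
het = 0.31) L = 56. No MAF/HWE/LD pruning is applied before calling
(pruning deletes exactly the homozygous stretches being measured); an
optional pruning path exists only for comparison runs.

A detail worth recording: with T = 1 the in-run rule demands *every*
covering window be accepting, which structurally trims W−1 SNPs from
each end of a run; equivalence with plain maximal-homozygous-run
enumeration holds when a single accepting covering window suffices,
i.e. T ≤ 1/W. The brute-force equivalence tests therefore run at
T = 1/W; the production default T = 0.05 behaves the same way for all
W ≤ 20 and nearly so at W = 50.

F_ROH divides summed segment length by the marker-covered autosomal
span Σ(max pos − min pos + 1) — not the assembly length — so a fully
homozygous chromosome gives exactly 1 and panels of different densities
are compared on the genome they actually observe. Segment lengths are
closed-interval (end − start + 1). Length classes use cumulative
class-F_ROH (mean F_ROH over segments ≥ the class lower bound): the
shortest class then equals overall F_ROH and consecutive classes differ
exactly by the intervening coverage fraction — the identity the
acceptance suite checks (the >16 Mb class evaluates to 0.13 from the
published coverages). Observed homozygosity (O_HOM) excludes missing
calls and cohort-monomorphic markers from both numerator and
denominator.

## LD decay, N_e(t), ΔF

r² is the squared Pearson correlation of unphased alternate-dosage
vectors over pairwise-complete samples (the standard unphased-data
choice; no EM haplotype phase). Pairs are restricted to the same
chromosome within a distance window (default 1 Mb) and pooled
genome-wide into equal-count distance bins (default 100; ties broken by
stable sort). Each bin's mean distance maps to c Morgans at a fixed
1 cM/Mb — no species-specific genetic map is assumed — and Sved's
equilibrium E[r²] = 1/(1 + 4N_e c) is inverted to
N_e = (1/r̄² − 1)/(4c) at t = 1/(2c) generations, with ΔF = 1/(2N_e).
The finite-sample floor E[r²] ≈ 1/n for unlinked loci (verified by
simulation in the tests) means an optional r̄² − 1/n correction is
available; it is **off** by default and recorded in the output
attributes, because the published trajectories this mirrors did not
apply it. Half-decay distance is linear interpolation between bin
means, with an explicit "not reached" sentinel. Validation: a forward
Wright–Fisher population at constant N = 50 (100 generations,
10 Mb chromosome, 30 sampled diploids) yields Sved estimates averaging
~49 over bins with t ∈ [15, 40] — within a factor of two, which is the
realistic accuracy of the method.

## F_ST

Per-marker two-population Weir–Cockerham (1984) variance components
a, b, c with F_ST = a/(a+b+c); negative per-marker values are sampling
noise around zero differentiation and are reported unclamped. The
genome-wide estimate is the ratio of sums Σa/Σ(a+b+c) (the per-marker
mean is biased low — both are computed, the ratio-of-sums is what
recovers a Balding–Nichols F_target = 0.2 to 0.199 at 5000 markers,
n = 100+100). The >0.75 flag is a strict inequality. First-degree
relative removal is accepted as a precomputed exclusion list, not
computed internally (kinship pruning is a separate concern and changed
nothing in the motivating analyses).

## ROH sharing windows

Windows are fixed-width (default 100 kb), anchored at the first marker
position of each chromosome, last window truncated at the last marker —
anchoring at the marker span (not coordinate 0) is what makes window 1
start at the first observed position. Overlap is closed-interval on
1-based coordinates; a sample counts at most once per window however
many of its segments touch it, so counts are invariant to splitting a
run into abutting pieces. Published tables in this area sometimes show
~99.9 kb windows (a span/N artifact); this implementation keeps exact
fixed widths and exposes the width as a parameter so either convention
is expressible. BED export converts to 0-based half-open.

## Variant-impact homozygosity

ANN strings are parsed per the SnpEff spec (comma-separated entries,
impact in pipe-field 3). LOW and MODIFIER merge into NEUTRAL with
per-variant de-duplication (a variant both LOW and MODIFIER counts once
in NEUTRAL, keyed by chrom/pos/ref/alt); a variant annotated in several
categories is tallied in each — category totals therefore legitimately
exceed the distinct-variant count, and the tests assert this on fixtures
with known overlap. The alternate allele is the effect allele
throughout; percent homozygous-alternate uses the non-missing
denominator. F_ROH–impact correlations are plain Pearson; on the
published 23-dog columns the WGS F_ROH column is used (the correlations
belong to the sequence analysis), giving r² 0.88/0.61/0.42 for
NEUTRAL/MODERATE/HIGH from the printed 2-dp values. ROH membership of a
variant is evaluated per sample (closed intervals; boundary positions
are inside); both variant-sample pairs and distinct variants are
reported because cohort-level phrasing is ambiguous between them.

## Synthetic-data generator

What it emulates: a closed breed. Founders (default 40) are unrelated;
8 discrete generations of ~50 offspring are bred under random,
full-sib-loop, or popular-sire mating (default fraction 0.25 of males
siring everything in the popular-sire scheme, which is what pushes
cohort mean autozygosity to the ~0.2 level typical of pedigree dogs).
Gene dropping transmits uniquely labelled founder haplotypes with
Poisson crossovers (Haldane, no interference — interference is
irrelevant at the ≥ 1 Mb ROH scale) at 1 cM/Mb over 30 chromosomes ×
100 Mb. True autozygosity is the exact bp fraction where the two
homologs carry the same founder label; across replicates its mean
matches pedigree F_PED (the linking test: full-sib offspring mean
0.247 ± SE over 200 replicates against the exact 0.25; selfing gives
0.5).

Marker panels: the sequence-like panel places a marker every 4 kb with
founder alternate frequencies Beta(0.2, 2) — rare-variant heavy, as
sequence data are; the array-like panel subsamples it to markers whose
realized founder MAF ≥ 0.10, thinned to ≥ 15 kb spacing (realized
~25 kb/marker). These are deliberate scale-downs of real densities
(~0.4 kb for WGS variants, ~14 kb for the 173k canine array) chosen so
a 3 Gb genome × 100 dogs runs in seconds; the *ratio* of panel
densities and the ascertainment structure, which drive the
array-overestimation effect, are preserved. Genotyping error (0.002)
flips to a uniformly random different state; missingness (0.02) masks
calls — plausible array rates, configurable.

What it does not emulate: mutation within the pedigree (founder
variation only), selection, sex chromosomes (sexes alternate, autosomes
only), linkage between founder allele frequencies and genomic features,
genotype-calling error structure (errors are independent), and real
LD/haplotype structure among founders (founder haplotypes are
independent draws per marker, so background LD arises only from drift
within the simulated pedigree). Passing tests therefore demonstrate
estimator correctness under the model's assumptions — they do not
certify behaviour on real array chemistry, real ascertainment schemes,
or populations far from the simulated demography.

The forward Wright–Fisher simulator (constant 2N haplotypes, random
union of recombined gametes, Uniform(0.1, 0.9) initial frequencies,
monomorphic markers dropped at sampling) exists purely to give the LD
module a population of known size; 100 generations suffices for the
drift-recombination equilibrium at the map distances used (t ≤ 50).

## Statistics

One-way ANOVA and Tukey HSD come from scipy; the compact letter display
uses insert-and-absorb over the significance matrix at α = 0.01 (the
post-hoc convention adopted for cohort-mean superscripts; the exact
post-hoc behind published superscripts is typically unstated, so Tukey
is an assumption and is flagged as such). The {1,2,3} vs {4,5,6}
hand-check gives F = 13.5; the null calibration test requires the
type-I error at α = 0.05 to land in [0.03, 0.07] over 1000 replicates.

## Numerical and interface choices

* Call codes 0/1/2/3 (hom-ref/het/hom-alt/missing) in uint8; dosage is
  the alternate-allele count with NaN for missing.
* BED/BIM orientation: A1 = alternate/effect allele, so 2-bit code 00 =
  hom-alt and 11 = hom-ref. PLINK recodes A1 to the minor allele by
  default; datasets from other tools need `--keep-allele-order`
  upstream for the codes to agree. This is stated in the io docstring
  and README because silent disagreement would flip dosages.
* Coordinates 1-based, intervals closed, everywhere; chromosome labels
  are strings without `chr`; default autosome set 1–38 (canine),
  configurable.
* QC order: exclusion list → sample call rate (default ≥ 0.94) →
  marker call rate (default ≥ 0.95); idempotent; removing every sample
  is an explicit error. Duplicate detection itself is out of scope — an
  exclusion-list hook stands in for it.
* Degenerate inputs have defined behaviour: chromosomes with fewer SNPs
  than the window are skipped with a warning; empty marker maps,
  zero-het thresholds, zero baselines in percent change, r̄² ∉ (0,1) in
  Sved inversion, and <2 cohorts in F_ST all raise with specific
  messages.
* Problem sizes: the recovery analyses run at 100 dogs × 30 × 100 Mb
  (regression slope), 10 × 20 dogs × 10 × 50 Mb (panel inflation), 200
  replicates (full-sib IBD), 5000 markers × 200 samples (F_ST), three
  Wright–Fisher populations (N_e) — sizes at which the Monte-Carlo error
  of each check is comfortably inside its acceptance band.

## Known limitations

* The ROH caller follows the windowed dialect, not HMM or IBD-haplotype
  methods; those are intentionally out of scope.
* Sved inversion assumes equilibrium and a uniform 1 cM/Mb map; N_e(t)
  at small t (large distances) is noisy and bin-count dependent; the
  bin count is a parameter because no canonical value exists.
* The fixed-width sharing windows differ by ~0.1% from span-divided
  window conventions seen in some published tables.
* `read_vcf` loads into memory; it is meant for cohort-scale variant
  sets, not full WGS VCFs, and region iteration is the escape hatch.
* The path-counting oracle (tests) is exponential in pedigree loop
  depth; it is a verification tool for bounded-depth pedigrees, not an
  estimator.
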