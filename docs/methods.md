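# Methods

This note documents the statistical models implemented in `rohmix`, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical decisions a maintainer would want
recorded. It states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Admixture genomic breed composition

An animal's genotype dosage g_k at SNP k (count of allele A) is modeled as
Binomial(2, f_k) with f_k = Σ_j w_j x_jk, the admixture-weighted mean of the
reference breeds' allele-A frequencies. Missing genotypes contribute
nothing; SNPs are treated as independent (no linkage modeling). The
log-likelihood constant is written Σ_k ln C(2, g_k) — ln 2 for a
heterozygote, 0 otherwise — so the likelihood equals the product of HWE
genotype probabilities exactly.

*Optimization.* The simplex constraint is handled by a softmax
reparameterization (w = softmax(θ), θ ∈ R^T) and BFGS with an analytic
gradient, started at uniform weights, with up to 5 random restarts on
non-convergence (restarts seeded by the caller). The parameterization is
one dimension redundant; BFGS is indifferent to the flat direction. Mixture
frequencies are clamped to [ε, 1−ε], ε = 1e-6, to guard the logs at
(near-)monomorphic SNPs; configurable.

*Pruning.* Because all breeds share ancestral variation, the unpruned MLE
for a genuinely purebred animal routinely places a few percent on a closely
correlated breed — identical-in-state noise, not ancestry. After
convergence the smallest-weight breed is removed and the model refitted
while the log-likelihood loss per removed breed is below the 1-df
likelihood-ratio critical bound at α = 0.05 (Δll < χ²₁(0.95)/2 ≈ 1.92).
This reads "does not significantly improve the fit" as a significance
test, and it is what produces the characteristic purebred plateau at a
weight of exactly 1.0; a fixed tiny tolerance (say 1e-3) cannot prune a
correlated-breed component whose spurious likelihood gain is of order 1.
The tolerance is a plain keyword argument for users who want stricter or
looser pruning. A side effect worth knowing: power to declare a small
admixture component significant grows with panel size, so the number of
animals at exactly 1.0 shrinks (or stays equal) as panels grow — the
stringency property the tests check.

*Filters and classification.* After pruning, components below the
nullification threshold (default 1%) are zeroed and the remainder rescaled
to sum to one. Purebred classification is `weight ≥ cutoff` (default 0.94,
boundary inclusive). Two-breed typing nullifies components below 5%,
rejects the animal (returns None, not an exception) unless exactly the two
named breeds survive with positive weight, and rescales the pair to sum to
one.

*Change point.* The purity cut-off diagnostic sorts per-animal GBC values
ascending and places a single least-squares breakpoint (the split
minimizing total within-segment squared error, computed exactly by an
O(n) prefix-sum scan). The value at the first index of the upper segment is
reported. A constant sequence has no change point and returns None. Whether
such an analysis should operate on sorted values or an index scale is a
genuine open choice; sorted values are used because the quantity of
interest is the GBC level where the plateau begins.

## Quality control

Filters and thresholds: individual call rate < 0.90 removes the animal, SNP
call rate < 0.95 removes the SNP, then a Hardy–Weinberg chi-square test
(1 df, expected counts from the observed allele frequency; monomorphic SNPs
pass trivially) removes SNPs with p < 1e-6. No minor-allele-frequency
pruning is applied — rare-allele SNPs carry ROH signal and removing them
loses runs. Because removing a high-missingness SNP changes animal call
rates (and vice versa), the three passes repeat in that fixed order until a
full pass removes nothing; QC output is therefore a fixed point, and
re-applying the filter never removes anything further. The chi-square test
was chosen over an exact test for determinism and speed; the alpha is so
stringent that the difference is immaterial at the sample sizes involved.

*File formats.* Dosage is the count of the A1 allele. Binary variant files
declare A1 explicitly (the writer emits A = A1, B = A2, SNP-major 2-bit
packing with the standard magic bytes). Text PED/MAP files declare no
alleles, so the reader fixes A1 per SNP: files coded with the array-style
A/B symbols always count allele "A" (the designation is fixed even when a
SNP is monomorphic in the sample — re-reading a written file can never flip
coding), while nucleotide-coded files use the alphabetically first allele
observed at the SNP. Swapping a file's allele symbols therefore yields
complementary dosages (d + d' = 2), which the tests assert.

Uniform panel selection (for GBC panel-size experiments) allocates SNP
counts to chromosomes proportionally to their bp span (largest-remainder
rounding, at least one SNP each) and greedily picks the SNP nearest each
point of an even target grid, left to right. It is a deliberately simple
stand-in for model-based SNP-selection methods, which are out of scope.

## Runs of homozygosity

The scanner is the classic sliding-window design: windows of 50 consecutive
SNPs move one SNP at a time within each chromosome; a window is a hit when
it contains ≤1 heterozygous and ≤2 missing calls. Each SNP's score is the
hit fraction among the windows covering it (edge SNPs use the windows that
exist; a chromosome shorter than the window is scanned as one truncated
window). SNPs scoring ≥ 0.05 — the conventional hit-fraction threshold for
this window design — and not themselves heterozygous are eligible; maximal
runs of eligible SNPs are split where consecutive SNPs are >1 Mb apart and
kept when the span is ≥1 Mb, contains ≥50 homozygous SNPs, and averages at
least one SNP per 100 kb. Two consequences of the per-SNP eligibility rule:
final segments never contain a heterozygous call (window tolerance forgives
hets in scoring, not in membership), and missing calls inside a run are
tolerated up to the window limits. Segment length is end − start + 1 bp,
reported in Mb at 2 decimals.

A detail that matters in practice: the ROH criteria imply a minimum marker
density. At 1 SNP per ~50 kb, a 2 Mb segment spans ~40 homozygous SNPs and
the 50-SNP floor is only reached near 2.5 Mb; sparser panels push the
detection floor higher. The pipeline's default simulated map (~44K SNPs
genome-wide, ~51 kb spacing) is chosen to be ROH-compatible, while GBC is
also exercised on much sparser panels where ROH scanning would be
inappropriate.

## F_ROH, length classes and age dating

F_ROH = Σ L_ROH / L_genome per animal. The genome denominator defaults to
the SNP-covered autosome, Σ per chromosome (last SNP − first SNP + 1), with
an explicit override for a known assembly length; per-class and
per-chromosome F_ROH use the same denominator, so an animal's class values
sum exactly to its overall F_ROH, and any subset of segments gives a value
≤ the all-segment value. Length classes are half-open [low, high) over
{1, 5, 10, 20, 40, ∞} Mb — a segment of exactly 5.0 Mb belongs to 5–10 Mb.
Class summaries report count, count share, mean length and share of total
length; shares each sum to 100 up to rounding (percentages and Mb printed
at 2 decimals).

Age dating uses the exponential-segment-length result: a segment surviving
g generations has mean length 100/(2g) cM, and with the 1 cM = 1 Mb
shortcut a class of mean L Mb dates to 100/(2L) generations, reported both
exactly and rounded half-away-from-zero. Note the rounding is honest:
a class mean of 6.72 Mb dates to 7.44 → 7 generations, even though coarser
roundings of the same arithmetic are sometimes quoted as 8.

## ROH islands

Incidence is the percentage of animals with an ROH covering the SNP
(computed by a difference-array sweep over segment endpoints; an animal's
segments never overlap, so it counts at most once per SNP). The threshold
is the empirical (1 − top_fraction) quantile of incidence (linear
interpolation between order statistics), default top 1%; SNPs at or above
it qualify (ties qualify — "over the threshold" is implemented inclusively).
Qualifying SNPs merge into islands when map-adjacent with no intervening
below-threshold SNP; a bp gap allowance is available as a config hook but
off by default, since adjacency is the conservative reading. Island extent
runs from the first to the last qualifying SNP position.

Annotation intervals come from BED (0-based half-open, normalized to
1-based inclusive by start+1) or GFF3 (already 1-based inclusive; the
feature name is taken from the Name= or ID= attribute). Overlap is ≥1 bp
intersection in 1-based inclusive coordinates. Records on chromosome names
that cannot be interpreted as autosome numbers are skipped and counted.

## Population structure

Breed relationships are summarized by the Pearson correlation of allele-A
frequency rows (zero-variance rows yield flagged NaN entries), clustered by
average-linkage agglomeration on the distance 1 − r (scipy linkage;
deterministic tie handling), serialized to Newick. Genotype PCA mean-centers
dosages per SNP (missing imputed at the SNP mean), optionally standardizes,
and takes the SVD; scores are U·S and explained-variance fractions are
normalized squared singular values. Centering-only is the default because
dosage variance already carries frequency information; unit-variance scaling
is a flag.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *study conditions* the analyses need:

* **Marker maps** — 18 autosomes, uniform or jittered spacing; defaults of
  650 SNPs/chromosome (~11.7K, the GBC panel scale) or 2,450 SNPs/chromosome
  (~44K, the ROH-compatible scale), 125 Mb chromosomes (2,250 Mb autosome,
  the denominator consistent with published mean coverage and F_ROH
  figures).
* **Breed frequencies** — hierarchical Balding–Nichols drift down a breed
  tree: ancestral frequency ~ Uniform(0.05, 0.95) per SNP (bounded away
  from fixation so the likelihood's logs stay stable), then child ~
  Beta(p(1−F)/F, (1−p)(1−F)/F) along every branch (F = 0 handled as the
  no-drift limit). The default 8-breed tree was calibrated once so that the
  correlation structure mirrors a real two-cluster pig panel: a tight
  indigenous cluster (within ~0.85–0.96, one closest pair), a looser
  commercial cluster (~0.6), cross-cluster lowest (~0.4). A known
  limitation: under a common uniform ancestral distribution the shared root
  variance puts a floor of roughly 0.4 under cross-cluster correlations, so
  the near-zero cross-cluster correlations seen between real indigenous and
  commercial panels are not reproducible with this generator — orderings
  and within-cluster magnitudes are faithful, absolute cross-cluster values
  are not.
* **Genotypes** — purebreds are Binomial(2, x_k) HWE draws; crosses draw
  each allele's breed of origin Bernoulli(expected fraction) per SNP (F1:
  exactly one allele per breed) and then the allele from that breed's
  frequency; missingness is uniform at random. There is *no linkage
  disequilibrium* and no segment structure in cross genomes — breed origin
  is independent across SNPs, which is an idealization adequate for
  marker-level GBC but not for haplotype methods.
* **Autozygosity** — segments with Exponential(mean) lengths (1 cM = 1 Mb)
  placed uniformly without overlap, chromosome chosen proportional to
  length, until planted coverage reaches the target F; the final segment is
  trimmed to the remaining budget so realized coverage lands on target
  rather than overshooting by up to a segment (which matters on small test
  genomes). Inside a segment both alleles are copies of one haplotype
  sampled from the base frequencies; an unreachable target raises an error
  reporting the shortfall.

Because background genotypes are LD-free, background (false-positive) ROH
are much rarer in simulation than in real data; the scanner's measured
recovery of planted segments is therefore an upper bound on real-data
behavior, and recovery statistics are quoted for planted segments ≥ 2 Mb,
where the 50-homozygous-SNP floor is reachable at the simulated densities.
Passing tests show the implementation is correct under these conditions;
they do not show that real LD, array ascertainment or genotyping-error
structure is handled — those are properties of data, not of this code.

## Pipeline

One config drives simulate-or-ingest → QC → GBC (classification, two-breed
typing, change point) → ROH on purebred-classified animals → length-class
and chromosome summaries → F_ROH → islands (optional annotation) →
structure. All stage outputs are tab-separated text; the manifest records
the package version, seed, a full config echo and SHA-256 checksums, and
rerunning the same config and seed reproduces identical checksums. Child
seeds for the simulation stages derive from the single config seed.
Problem sizes in the examples, tests and acceptance script (cohorts of tens
of animals, maps of 3–18 chromosomes with 5K–44K SNPs) were chosen as the
smallest at which every distributional check is comfortably powered;
everything scales linearly in animals × SNPs.

## Known limitations

* Reference breed frequencies are fixed, error-free inputs; no joint
  re-estimation of frequencies and ancestry, and no identical-by-descent
  interpretation — GBC here measures identity-in-state by construction.
* The ROH scanner does not replicate any specific external tool's output
  byte-for-byte; the criteria are implemented as stated above.
* No imputation: missingness is either simulated and tolerated by the
  window rules, or should be handled upstream.
* VCF input, sex chromosomes and recombination-map (non 1:1 cM/Mb) dating
  are not supported.
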