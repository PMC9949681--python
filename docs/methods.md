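# Methods

`ovintro` implements the analysis chain used to detect and characterize
introgression from wild relatives into domestic sheep genomes, and to connect
one candidate region to a quantitative trait. Every stage can be exercised on
synthetic phased data with exact ground truth; this note records the models,
the defaults and why, the numerical choices, and what the synthetic data does
and does not emulate.

## Coordinate and data conventions

All coordinates are 0-based half-open internally; 1-based inclusive
coordinates appear only in VCF output and printed tables. Panels are phased
biallelic haplotype matrices (0 = REF/ancestral, 1 = ALT/derived, -1 =
missing), two haplotypes per sample. Windows are 50 kb with a 20-kb step by
default; windows running past a contig end are kept, flagged as clipped, and
normalized by their true length. A window statistic is reported only when at
least `min_sites = 10` usable sites fall in the window (unstable ratios
otherwise; configurable).

## Synthetic panels

The generator produces study conditions, not botanical realism:

* **Sites** are placed by a Poisson process (default density 1e-3 per bp, one
  segregating site per kb — the order of cross-population SNP density in
  resequenced sheep panels).
* **Population structure.** Allele frequencies drift along a population tree:
  each branch perturbs logit(p) by a Normal with variance
  (branch generations)/(2 Ne), Ne = 10,000 by default. This is a cheap
  stand-in for a coalescent: it reproduces divergence that scales with branch
  length, but generates **no linkage disequilibrium within populations** —
  haplotypes are independent Bernoulli draws from their population's
  frequencies. Consequently within-population haplotype sharing is weaker
  than in real data; tests passing here say nothing about phasing error or
  background LD.
* **Admixture pulses.** A pulse (donor, recipient, time t, fraction f) writes
  donor tracts into every recipient haplotype independently, as a stationary
  alternating-renewal process: donor segments are Exponential with mean
  1/(r·t_gen) — the expected admixture-tract length t_gen generations after a
  pulse — separated by recipient gaps Exponential with mean
  (1-f)/(f·r·t_gen). This makes the per-bp probability of donor ancestry
  exactly f at every position (and full replacement in the f -> 1 limit,
  which is special-cased), while preserving the exponential tract-length law.
  Tract alleles are copied verbatim from a randomly chosen donor haplotype of
  the panel, and the placed intervals are recorded as exact truth tracts
  (later pulses overwrite earlier ones on overlap). Placement is independent
  across haplotypes, so tract sharing between haplotypes arises only by
  chance overlap — ground truth stays exact, at the cost of not modelling the
  shared genealogy of introgressed haplotypes.
* **Default trees.** The introgression fixtures use an outgroup at 3.12 Ma, a
  wild donor at 1.26 Ma (urial depth), a non-introgressed European reference
  and four recipient meta-populations splitting 10 ka ago; 10 diploid samples
  per group (4 for the outgroup) on a 2-Mb contig. The default pulse is 10%
  from the donor into DOM1 at 6 ka (mean tract ~67 kb); the outlier fixture
  strengthens this to 60% at 2 ka (mean tract 200 kb, long shared tracts);
  the null fixture has no pulse.
* **F2 founders** are two breeds 10 ka apart with breed-scale effective size
  (Ne = 500), giving the strong drift and near-fixed differences expected
  between phenotypically divergent breeds.

Root frequencies are Uniform(0.05, 0.95) — flatter than a neutral site
frequency spectrum, which is deliberate: it maximizes informative
intermediate-frequency sites per simulated base. All randomness flows from a
single integer seed through one NumPy generator; fixture files are
byte-identical across runs with the same seed.

## Windowed statistics

* **F_ST** uses the Weir–Cockerham (1984) estimator with the diploid
  heterozygosity terms, summed as a ratio of per-site variance components
  over the window (the estimator vcftools reports for windows). Hudson's
  estimator is available as `estimator="hudson"` for sensitivity analysis.
* **d_XY** is the mean per-bp divergence
  (1/L)·sum_sites [pA(1-pB)+pB(1-pA)].
* **D and f_d** use outgroup-polarized derived-allele frequencies: the
  outgroup consensus allele is ancestral, sites with outgroup ALT frequency
  in (0.1, 0.9) are excluded, and frequencies are flipped where the outgroup
  is fixed derived. D = sum(ABBA-BABA)/sum(ABBA+BABA);
  f_d = S(P1,P2,P3,O)/S(P1,P_D,P_D,O) with P_D the per-site max of P2 and P3.
  f_d is reported NA where the window's D < 0 (the statistic is a bounded
  admixture-proportion estimator only under an ABBA excess); a tolerance of
  1e-12 keeps windows whose ABBA-BABA sum cancels exactly. On the default
  fixture the genome-wide mean f_d tracks the simulated admixture fraction to
  within a few hundredths, with a small upward bias from conditioning on
  D > 0.
* **Z tests.** Window statistics are Z-transformed against their own
  genome-wide mean and SD; f_d uses a two-tailed Normal P, the F_ST selection
  scan an upper one-tailed P (high differentiation is the signal of
  interest), both flagged at P < 0.001.
* **Permutation threshold.** Each replicate draws 33 domestic samples, pools
  them with 33 wild samples, splits the pool randomly into two equal
  pseudo-populations and records the maximum windowed F_ST genome-wide; the
  threshold is the largest of the 100 replicate maxima.

## Local ancestry inference

A target haplotype is decoded as a mosaic of reference haplotypes by dynamic
programming: cost = mismatches + λ·switches, λ = 1.5 mismatch-equivalents per
switch by default. The DP is exact (O(sites × templates)); ties prefer
staying on the current template (fewest switches), then the lowest template
index. Sites missing in either sequence never count as mismatches. The
non-introgressed reference group is always included as a source so "no donor"
is expressible. Ancestry-run boundaries are placed at the midpoint between
the flanking sites of a switch (unbiased on average); the first and last runs
extend to the contig ends, so tracts partition each haplotype. Optional
bagging (off by default; 20 reps of 80% template subsampling, per-site
majority vote, ties to the recipient source) trades runtime for robustness.
λ should be treated as a sensitivity parameter: larger λ merges small runs
and can only reduce the switch count (a tested monotone property).

## ILS filter

The expected length of a shared ancestral tract surviving since divergence T
generations of total branch length is L = 1/(rT), with T = 2·(divergence
years)/(generation time): both descendant lineages accumulate recombination.
With r = 1e-8 and a 4-year generation this gives 6,250 bp (0.032 Ma,
mouflon), 159 bp (1.26 Ma, urial), 85 bp (2.36 Ma, argali) and 64 bp
(3.12 Ma, bighorn/thinhorn). Tract length under ILS is approximately
Gamma(shape 2, rate 1/L), so P(length >= m) = (1+m/L)·exp(-m/L); inferred
tracts strictly shorter than their source's L are removed (length exactly L
is kept). When a recombination map is supplied the local interval rate
replaces the genome-wide default.

## Outlier tracts

Each inferred fragment is a candidate interval; a haplotype carries a
candidate when its same-source ancestry covers >= 80% of the interval (the
carrier rule is this package's construction — with it, the carrier frequency
of locus-scale intervals equals the per-bp ancestry fraction, while very long
intervals are penalized). Frequencies are computed per meta-population; the
SD weights meta-populations equally, and the total frequency pools all
recipient haplotypes. Outliers satisfy length >= 100 kb AND total frequency
>= 0.05 AND SD > 0.1. High-F_ST regions join windows with upper-tail
P < 0.001 separated by <= 50 kb; outliers are annotated with the regions they
overlap by >= 1 bp.

## Region haplotypes and networks

Regions are extracted with sites at MAF <= 0.05 removed. Recombinant
screening seeds consensus strings from the 3 largest identical-haplotype
classes and flags a haplotype when its best single-breakpoint chimera of two
consensus strings beats its best single consensus by >= 5 mismatches (both
the rule and its parameters are this package's construction and should be
reported alongside results). Haplogroups are single-linkage clusters at
Hamming distance <= 5% of sites (pairwise-complete over missing data),
labelled hap-1, hap-2, ... by size. Frequency tables report carriers/total
and a round-half-even 3-decimal frequency, so the exact fraction is always
recoverable. Networks collapse identical haplotypes and take a Kruskal
minimum spanning tree over Hamming distances with deterministic tie-breaking
(edges sorted by weight, then node labels); non-MST edges that could replace
an MST edge on their cycle without increasing total weight are flagged as
alternatives.

## Association scan

The model is y = Wα + xβ + u + ε with u ~ MVN(0, λτ⁻¹K) and
ε ~ MVN(0, τ⁻¹I). QC removes samples with > 10% missing genotypes first,
then SNPs with MAF < 0.05 or > 10% missingness; a DR²-style
imputation-quality hook exists but is inert on complete data. K is the
centered genotype cross-product divided by the SNP count (zero-variance SNPs
excluded; missing dosages mean-imputed). λ is estimated once by maximum
likelihood on the null model — a log10 grid over [1e-5, 1e5] with
golden-section refinement on the eigendecomposition of K — and held fixed
across SNPs (the standard scan approximation); each SNP is then tested by
generalized least squares in the rotated space with a 1-df Wald χ² using the
residual variance on n − c − 1 degrees of freedom. With K = I the scan
reduces exactly to OLS. The genome-wide threshold is Bonferroni α/m reported
to 3 significant figures.

The F2 fixture uses a dense genetic map (1e-6 Morgans/bp, i.e. the 5-Mb
fixture chromosome carries 5 Morgans) so that marker–causal LD decays on the
100-kb scale — a deliberate compression that lets a single small chromosome
stand in for genome-scale LD decay in a 300-individual cross. The phenotype
is intercept + β·dosage + a polygenic term (variance 0.5× the causal
variance, from 100 background SNPs) + Gaussian noise scaled so the genetic
variance fraction equals the target h². The null-calibration fixture instead
uses ~1,200 unlinked 1-kb contigs, because the KS uniformity check on
permuted-trait P values requires independent markers; one marker per contig
is tested.

## Problem sizes

Test and acceptance runs use 2-Mb panels (~2,000 sites, 128 haplotypes),
500-window null scans (five contigs), 100 simulated F2 crosses of 300
individuals over ~5,000 markers, and ~1,200 unlinked calibration markers —
sizes chosen so each stage has enough windows, tracts or replicates for its
Monte-Carlo bands while a full run of everything completes in about a minute.

## Known limitations

* No within-population LD, no phasing error, no genotyping error: local
  ancestry inference is easier here than on real data, and the measured
  precision/recall are upper bounds.
* Tract placement is independent across haplotypes; frequency-based outlier
  statistics on real data reflect shared genealogy that this generator does
  not produce.
* No selection during simulation, so high-F_ST "selection" regions are empty
  on the fixtures (the machinery is exercised against constructed scan
  tables).
* The copying model is a simplified reimplementation of the haplotype-mosaic
  idea behind dedicated LAI software, not a reproduction of any external
  tool's objective; results should be read as sensitivity over λ.
* Genome-wide D is computed per window; block-jackknife standard errors for a
  single genome-wide D are out of scope.
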