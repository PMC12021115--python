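# Methods

This note records the models, estimators, parameter choices and numerical
conventions behind `ponypop`, and what the synthetic-data validation does
and does not demonstrate about real resequencing data.

## Coordinate and data conventions

Genotypes are diploid alternate-allele dosages {0, 1, 2} with −1 for a
missing call; phased haplotypes, where present, are binary vectors paired
per sample. Variant positions are 1-based (VCF convention); windows, BED
intervals and sweep specifications are 0-based half-open. Windows tile
each chromosome from position 0 in non-overlapping 10-kb blocks (the
default; configurable). All inequalities in filters are strict, matching
the hard-filter expression they implement.

## Simulator: Balding–Nichols drift on an admixture graph

Each site's ancestral frequency is drawn uniformly on [0.05, 0.95], for
which E[p(1−p)] = 0.25 − (0.45²)/3 = 0.1825. A drift edge with parameter
F ∈ [0, 1) draws the child frequency from Beta(p(1−F)/F, (1−p)(1−F)/F),
i.e. mean p and variance F·p(1−p); an admixture event sets the child to
α·p_A + (1−α)·p_B. Fixation is absorbing and frequencies are clipped (not
reflected) at the boundaries; sites fixed everywhere are retained for the
downstream filters to handle. This model was chosen over a coalescent
simulator because it yields closed-form expectations: the expected f2
between parent and child is F·E[p(1−p)], f3/f4 are sums over shared drift
paths, and two populations drifted F each from a common ancestor satisfy
E[(p_A − p_B)²] = 2F·0.1825. Genotypes are binomial draws given the
population frequency (Hardy–Weinberg within populations, no inbreeding);
haplotypes are site-independent Bernoulli draws, so background linkage
disequilibrium is absent except where a sweep is implanted.

Sweeps are implanted mechanically rather than by re-simulating
genealogies: a chosen fraction (default 0.9) of the target population's
haplotypes have the sweep interval overwritten by one shared core
haplotype. This produces, by construction, the three signals the scan
intersects — reduced θπ in the target, elevated FST against the other
population, and extended haplotype homozygosity around the interval — but
it does not produce the flanking gradients, soft-sweep structure or
hitchhiking patterns of a real sweep. The standard validation scenario
(`default_sweep_fixture`) is one 2-Mb chromosome with 2,000 SNPs, two
populations of 25 diploids each drifted F = 0.05, and a 20-kb sweep at
the chromosome centre; 20 seeds of it form the recovery battery. These
sizes keep a full 20-seed scan under a minute on one CPU while leaving
~200 windows per replicate, enough for a meaningful top-1% tail.

Depth profiles treat "depth" as a per-bp read-start rate: males get X and
Y at half the autosomal rate, females get X at the autosomal rate and Y at
a residual mismapping rate (default 0.5% of autosomal). Read counts are
gamma-Poisson with a small per-chromosome overdispersion (CV 0.05), and
covered fraction follows the Poisson coverage identity 1 − e^(−λ). The
default chromosome lengths put the X:Y length ratio at 10:1 so the Ry
index separates the sexes cleanly at realistic depths.

## QC

The hard filter evaluates the standard GATK germline SNP expression
clause by clause; absent annotations never trigger their clause (recorded
as "not evaluated"), and a non-numeric annotation is reported as a
per-site error without aborting the run. Genotype-level filtering is
ordered: samples by missing rate first, then variants by missing rate,
then MAF recomputed on the retained samples — site decisions therefore
depend only on genotype counts and are invariant to sample order. The
per-sample missingness default is 0.0008, a literal transcription of the
protocol value ">0.08%"; it is almost certainly intended as 8% and is
exposed as configuration.

The Hardy–Weinberg test is the conditional exact test on the heterozygote
count (no mid-p): probabilities over all heterozygote counts with the
observed allele totals are computed by recurrence and the two-sided
p-value sums those not exceeding the observed probability (tolerance
1 + 1e−12 on the ratio). It matches full enumeration to < 1e−12 for all
tables with ≤ 30 diploids.

LD pruning slides a window of 50 SNPs advanced by 5: while any retained
pair in the window has dosage-correlation r² above the threshold, the
highest-r² pair is resolved by removing its lower-MAF member (tie: the
later position) — the removal rule is a determinism choice; the tool this
mirrors leaves it unspecified. GRM kinship uses the VanRaden-style
standardized matrix; note that with in-sample allele frequencies the
off-diagonal mean sits at −1/(n−1), not 0. Exclusion is greedy: among
samples in any above-threshold pair, the one with the highest mean
relatedness to all retained samples is removed first.

## Windowed statistics

Per-site FST uses the Weir & Cockerham (1984) two-population variance
components (a, b, c) computed from sample sizes, allele frequencies and
observed heterozygosity; windows combine sites as Σa / Σ(a+b+c)
(ratio-of-sums, the weighted estimator), with mean-of-ratios reported
alongside for comparison. Windows with no usable sites or non-positive
total variance are undefined and excluded from quantile ranking.

θπ per site is c_ref·c_alt / C(n, 2) over the n called chromosomes; the
window value divides the summed site π by the window length in bp (not by
the SNP count), so sparse windows are not inflated. The π ratio
θπ_pony/θπ_horse is undefined where the denominator is 0 or either side
has fewer than a configurable minimum of SNPs (default 1).

The ROH caller follows the scanning-window scheme: a 50-SNP window is a
hit if it has ≤ 1 heterozygous and ≤ 5 missing calls; a SNP is in-ROH if
it is itself a homozygous call and the fraction of overlapping windows
that are hits is ≥ 0.05. The homozygosity requirement is an
implementation choice: the hit-rate rule alone would exclude the exact
endpoints of a clean homozygous tract (the outermost SNP is covered by at
most two hit windows, 2/50 < 0.05) while admitting heterozygous flank
SNPs, and segments should neither begin nor end on a heterozygote. Runs
split at adjacent-SNP gaps above 100 kb; emitted segments must span
≥ 500 kb, contain ≥ 50 SNPs, and have density ≤ 50 kb per SNP. The
"maximum between-variant distance ≤ 100" protocol parameter is read as
kb, the unit convention of the tool it parameterizes.

LD decay accumulates dosage-correlation r² for all same-chromosome pairs
within the maximum distance (default 500 kb) into distance bins,
requiring ≥ 8 individuals; for unlinked sites the expected mean r² is the
finite-sample bias ≈ 1/n, which the tests assert.

## XP-EHH

EHH at extension x groups haplotypes by identity over [core..x] and
returns Σ_g C(n_g, 2)/C(n, 2); at the core itself the grouping is by core
allele. iHH integrates the whole-population EHH curve (not per core
allele — the standard definition for the cross-population statistic) by
trapezoid over physical position, both directions, stopping once EHH
falls below 0.05 (the crossing segment is included), at 1 Mb of
extension, or at any adjacent-site gap above 200 kb; the cutoff, cap and
gap mirror the defaults of the tool family this reimplements, since the
source protocol names only the tool, and are configurable. Cores are
restricted to pooled MAF ≥ 0.05; a core is skipped (with a reason) rather
than scored ±∞ when either panel yields zero iHH. Raw scores
ln(iHH_query/iHH_ref) are standardized by the genome-wide mean and SD in
one bin — not frequency-binned, as a single standardized track is
reported. With ponies as the query, positive standardized scores localize
selection on the pony side.

## f-statistics and the breed network

f3 and f4 are site-means of frequency products, complete-case per
statistic (sites missing a frequency in any required population are
dropped for that statistic only). Uncertainty is a delete-one weighted
block jackknife (Busing et al. 1999) over contiguous physical blocks,
default 5 Mb — no block size is stated in the source protocol; 5 Mb
comfortably exceeds LD ranges in horse. With equal blocks the formula
reduces to the textbook delete-one jackknife, which the tests verify.

The network's directional distance disf4(a, b) averages f4(a, i; b, O)
over third breeds i. The index set excludes i = a and i = b by default:
i = a contributes an identical zero and i = b a self-referential term,
both of which only dilute the mean; a flag restores the literal
all-breeds summation for sensitivity analysis. disedge symmetrizes the
two directions; edges are ranked by disedge (larger shared drift =
stronger) and binned into quintiles purely for rendering — the raw table
is always emitted. Breeds flagged as geographically adjacent to the
Yakutian horse can be excluded before computation when building the
pony-focused network.

## Sweep calling and overlap testing

Quantile thresholds are empirical quantiles over defined windows only;
flagging is strictly beyond the threshold, so ties at the threshold are
excluded. The relevant tail is per metric: upper for FST, lower for the
π ratio when scanning for pony-side sweeps, and configurable for XP-EHH
by contrast direction. Flagged windows merge when adjacent (or within a
configurable gap); a candidate is any maximal interval covered by at
least two metrics' merged regions. For the SNP-level XP-EHH overlap mode,
flagged SNPs closer than 100 bp merge into intervals before windowing.

The interval-overlap test builds its 2×2 table interval-wise: n11 =
A-intervals overlapping ≥ 1 B-interval, n12 the rest of A, n21 =
B-intervals hitting no A, and n22 = max(0, round(L/(mean_len_A +
mean_len_B)) − n11 − n12 − n21) as an estimate of remaining genomic
slots — an approximation mirroring the interval-wise construction of the
standard tool, reported alongside the raw counts. The odds ratio uses the
Haldane 0.5 correction only when the table has a zero cell. The
permutation null re-places the A intervals uniformly at random
(per-interval lengths and chromosome assignments preserved, placements
non-overlapping — the conservative within-chromosome null; a free
placement mode is out of scope) and reports the empirical p as
(1 + #{null OR ≥ observed OR})/(n_shuffles + 1), never a literal zero:
with the default 10,000 shuffles the attainable floor is 1/10001.

## Sex assignment and the Y chromosome

Indices per sample: covY (covered fraction of Y), X/Chr1 and Y/Chr1
per-bp rate ratios, Rx (X rate over the mean autosomal rate) and Ry
(Y reads over X+Y reads); all are invariant to global read-count
rescaling. The primary male rule is covY > 0.94 (the printed coverage
threshold); Ry ≥ 0.075 / ≤ 0.016 and Rx ≈ 0.5 / ≈ 1.0 corroborate, with
the band edges taken from the indices' source methods — they are
configuration, not contract. Any conflict between the primary and
corroborating rules produces "ambiguous" with both rules named, so low
coverage degrades to ambiguity rather than to wrong-sex calls;
recorded-sex mismatches are reported rather than silently overwritten.
"Y coverage" is read as covered fraction, not mean depth, following the
axis convention of the diagnostic plot it reproduces.

MSY filtering treats heterozygous diploid calls on the hemizygous Y as
genotyping errors: any site heterozygous in any male is dropped, then
sample missingness, variant missingness (> 2%) and MAF (< 0.005) filters
apply, and the haplotype mode finally drops any site with a remaining
missing call. Each stage's attrition is reported. A haplotype is the full
allele vector over retained sites; counting is order-invariant.

P-distance scores site pairs 0 / 0.5 / 1 (identical / one shared allele /
opposite homozygotes), averaged over both-called sites — stated
explicitly here because the protocol names only a tool. Neighbor joining
uses the standard Q-criterion with a deterministic lowest-index
tie-break; the tree is rooted by splitting the outgroup's pendant branch
at its midpoint. On additive matrices the tree reproduces all pairwise
distances exactly (verified for up to 8 leaves).

## What the validation shows — and does not

Every estimator is checked three ways where possible: exact agreement
with an independent brute-force oracle on small inputs (θπ vs pairwise
differences, EHH vs pair enumeration, HWE vs full enumeration, NJ vs
path-length recovery), analytic recovery of simulator parameters at
moderate scale (FST within ±0.02 of F = 0.1 at 50,000 sites; f3/f4
within 3 jackknife SEs of path-overlap expectations; admixture detected
with the predicted sign), and end-to-end behaviour across seeds (sweep
recovery, permutation calibration, sex-call accuracy). Because the
simulator draws sites independently and implants sweeps mechanically,
these results demonstrate correctness of the estimators and of the
calling logic, not their power or false-discovery behaviour on real
genomes with background LD, demographic complexity, genotyping error and
reference bias. Phasing, alignment and variant calling are upstream of
this package and are consumed, not reproduced.
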