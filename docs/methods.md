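# Methods

## Model

Plasma cfDNA after transplantation is modelled as a two-person mixture: a
donor fraction *f* on a recipient background. At a biallelic SNP where the
recipient dosage is `d_r` and the donor dosage `d_d` (alt-allele counts in
{0, 1, 2}), the expected alternative-allele fraction of the mixture is

    p = (1 − f) · d_r / 2 + f · d_d / 2.

At recipient-homozygous SNPs, the donor genotype therefore shifts the ALT
ratio by 0, f/2 or f. The estimator recovers *f* from the empirical cluster
structure of those shifts without knowing either genotype; the direct
reference method computes the same quantity per SNP when both genotypes are
known.

## Allele counting

Each panel SNP is represented by the k-mer of its probe context centered on
the variant, in a reference and an alternative version (k = 31, odd so the
variant sits exactly at the center). A read supports an allele iff it
contains the corresponding k-mer, or by default its reverse complement, as
an exact substring; a 31-mer is long enough that spurious matches in a
~150 bp read are vanishingly rare, and exact matching keeps ref/alt
attribution unambiguous. Panel entries whose k-mers collide across entries
(either strand) are excluded up front with a per-locus report, since a
shared k-mer cannot attribute a read. Reads carrying both alleles of one
SNP (possible only for chimeric inserts) increment neither counter and are
tallied in an `ambiguous` diagnostic. No depth filter is applied by default
(`min_depth = 1`); zero-depth SNPs get an undefined ratio and drop out of
all downstream steps.

## Genotype binning

ALT-ratio bins [0, 0.1] → AA, [0.4, 0.6] → AB, [0.9, 1.0] → BB; everything
else (and undefined ratios) → excluded. Bin edges are closed on both ends —
inclusivity is genuinely ambiguous at the stated precision, and closed bins
keep boundary values usable while the gaps (0.1, 0.4) and (0.6, 0.9) remain
exclusion zones either way. Heterozygous (AB) SNPs show far larger
ALT-ratio variability than homozygous ones and are never used by the
estimator. Binning runs on the pre-transplant sample when one exists and on
the post sample itself otherwise, mirroring the two estimation modes.

## Clustering

The per-group shifts are one-dimensional, so instead of stochastic
k-means++ the package computes the *global* minimum within-cluster
sum-of-squares partition: in 1-D the optimum is a contiguous partition of
the sorted values, found exactly by an O(k n²) dynamic program over prefix
sums (n ≤ a few hundred here, so cost is negligible). This makes every
estimate deterministic and seed-independent; a seeded k-means++ mode
(scikit-learn) remains available behind `method="kmeans++"` for fidelity
experiments, and a test asserts the dynamic program never does worse than
50 k-means++ restarts.

Outlier handling: clusters with ≤ 3 members (`min_cluster_size = 4`) are
treated as outliers, their members removed, and the remainder re-clustered
with the same k. This is iterated to a fixpoint (the iteration count is
recorded; one pass is typical) rather than applied once, for robustness
when pruning reshapes the partition. If pruning leaves fewer than k points
the group is reported unusable.

Cluster→genotype labels are assigned by magnitude of mean shift: the
near-zero cluster is recipient-like, the largest-|mean| cluster the fully
mismatched donor genotype, the middle one the heterozygous donor. Working
with magnitudes makes the AA-side (shifts upward in raw ALT ratio) and
BB-side (downward) groups symmetric; negating all shifts leaves the
estimate unchanged.

## Combining clusters into an estimate

Per group, two quantities estimate *f*: the span |mismatched − recipient|
and twice the heterozygous gap 2·|het − recipient|; the group component is
their mean (for k = 2, only the doubled heterozygous gap exists). The
combined estimate is the mean of the usable group components — equivalently
the mean of all four per-group quantities when both groups are usable. If
one group is unusable the other carries the estimate, flagged
`single-group-estimate`; if both are unusable an `EstimationError` with
per-group diagnostics is raised. A zero-variance group (noise-free f = 0)
is reported as component 0 with a `no-donor-signal` flag rather than an
error.

Without a baseline, raw post ratios are clustered after subtracting the
ideal homozygous baseline (0 for AA, 1 for BB); this is a constant offset
per group, so cluster-mean differences — and hence the component formulas —
are unchanged. Two degradations are flagged `low-confidence->10%` in this
mode: a combined estimate above 10% (the heterozygous and mismatched
clusters approach the bin edges and each other there), and an excluded-bin
share more than ~10 percentage points above the expected background, which
signals that the mixed signal has drifted out of the genotype bins
entirely (at f ≈ 27%, most het/mismatched SNPs leave the bins and the
estimate collapses toward the recipient-like cluster). No slope
recalibration is applied to the known mild reference-free underestimation.

## Direct reference method

At informative SNPs (recipient homozygous, donor carrying at least one
differing allele), the contribution is the ALT-ratio increase (recipient
hom-ref) or decrease (hom-alt) from baseline, doubled when the donor is
heterozygous; the estimate is the unweighted mean of contributions.
Negative contributions are kept unclipped so the mean stays unbiased near
f = 0. The baseline is the measured pre-transplant ratio when a pre profile
is supplied and the ideal 0/1 otherwise; both are supported because
published use does not pin down which was applied, and "measured when
available" is the less biased default.

## Agreement statistics

MAE, RMSE, ordinary least squares (r² = squared Pearson correlation; a
constant response is defined to have slope 0 and r² = 0), and Lin's CCC
with population (1/n) moments — CCC is invariant to the common 1/n vs
1/(n−1) factor, so the choice is cosmetic but fixed for determinism. The
thresholded CCC drops pairs whose *reference* (x) value is ≥ the cutoff
(default 10%) before computing the coefficient — keying on the reference
series reproduces the published coefficients — and reports not-calculable
when fewer than 4 pairs survive, matching the published treatment of the
parent–child series, where exactly 3 surviving points were deemed too few.

## Simulator

The generator mirrors the spike-in validation design: 300 SNPs, alt-allele
frequency uniform in [0.45, 0.5] (the panel's design range), genotypes
Hardy–Weinberg with relatedness options (unrelated i.i.d.; full sibs
sharing two simulated parents; parent→child with one transmitted allele),
mixtures on the grid {0, 0.5, 1, 3, 5, 10, 50, 100}%, per-SNP depth
Poisson with mean 3000 (high enough to resolve 0.5% mixtures; the real
capture depth profile is not published, and Poisson is the minimal
overdispersion-free choice, with a fixed-depth mode for analytic checks),
and a symmetric per-read allele-flip error ε = 0.001 approximating
post-filter substitution error. Binomial downsampling thins each count
c → Binomial(c, fraction). FASTQ emission plants exactly the tabulated
k-mers in random background at random offset and strand, so
counting-from-reads round-trips losslessly. All randomness derives from the
single config seed.

What the simulator does **not** model: capture-efficiency bias between
libraries, GC/fragment-length effects, index hopping, or overdispersed
depth. Consequently simulated full-depth estimates are cleaner (MAE
≈ 0.04 pp over the 0.5–10% grid at depth 3000) than real spike-in data
(≈ 0.3 pp), and passing recovery tests demonstrates correctness of the
estimator on the stated noise model, not field performance. One visible
consequence: after quarter-depth downsampling the f = 0.5% shift components
(spacing 0.25 pp) overlap the per-SNP noise (sd ≈ 0.36 pp), and optimal
clustering of an overlapping mixture systematically widens the cluster
span, giving a +0.2 pp bias at the smallest fractions — the same small-f
overestimation seen in the real 0.5% spike-in. Relative to the very small
full-depth simulated MAE this exceeds a 2× inflation, which real data —
whose full-depth error is dominated by non-depth noise — does not show.

## Problem sizes used in tests

The test suite simulates 20 replicates per fraction over
f ∈ {0.5, 1, 3, 5, 10}% at 300 SNPs and mean depth 3000 (with 50% and 25%
downsampled variants), checks the exact clusterer against brute-force
enumeration up to n = 200, and uses 10⁴–10⁵-SNP draws for genotype-
frequency checks; the whole suite runs in well under a minute on one core.

## Known limitations

* Estimates below ~1% carry large relative uncertainty (sampling noise at
  low allele counts); longitudinal trends matter more than single values.
* Reference-free mode degrades above ~10% donor fraction and is flagged
  rather than recalibrated.
* The k-mer counter assumes panel SNPs are sparse: a read overlapping two
  panel SNPs would increment both, which is intended for genome-sparse
  panels and wrong only for adversarially overlapping probes (excluded at
  k-mer construction time anyway).
* The workbook evaluator expects per-SNP read-count sheets; layouts other
  than the default `<label>_ref` / `<label>_alt` column convention need a
  column-mapping sidecar (layouts in the wild are not standardised).
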