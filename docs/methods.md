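# Methods

## Data model

A **CNV call** is one sample's diploid copy number for one gene. ddPCR
reports a real-valued point estimate (`raw_copy_number`) with a
per-reaction technical error; the analysis value (`copy_number`) is the
raw estimate rounded to the nearest whole copy, ties away from zero
(7.5 → 8). Calls aggregated from published studies carry only the
integer value; their missing raw value and technical error are kept as
explicit missing markers, never imputed as 0. Duplicate
(sample, gene) pairs are rejected at load time, and merging collected
with aggregated calls refuses sample-id collisions so no individual is
double-counted.

**Breed metadata** assigns each breed a latitude of origin in
[−90°, 90°] and a diet category (`high` / `moderate` / `low`) per
nutrient (starch, sugar, phytanic acid). The two Japanese breeds
(Akita, Shiba Inu) are pooled under one label via the loader's alias
map, since their separate sample sizes are too small to treat alone.

Genomic coordinates are 0-based half-open everywhere internally;
VCF-style 1-based positions are converted at the boundary. Delimited
tables accept comma or tab, sniffed from the header line.

## Statistical procedures (`dogcnv.stats`)

**Fligner–Policello robust rank-order test.** For samples x (size n)
and y (size m), placements P(xᵢ) = #{yⱼ < xᵢ} + ½#{yⱼ = xᵢ} and
symmetrically P(yⱼ); with mean placements P̄ₓ, P̄ᵧ and variability
indices Vₓ = Σ(P(xᵢ) − P̄ₓ)², Vᵧ analogous, the statistic is

    z = (ΣP(yⱼ) − ΣP(xᵢ)) / (2·√(Vₓ + Vᵧ + P̄ₓ·P̄ᵧ)),

two-sided p from the standard normal; z > 0 when y tends larger.
Placement conservation ΣP(x) + ΣP(y) = n·m is asserted on every call.
Ties count one half (the standard convention). Complete separation
zeroes the denominator; the result is flagged degenerate with p = 0
(p = 1 for identical constant samples) rather than raising, so
pipelines over near-separated data keep running and report the flag.
An exact permutation twin (`fligner_policello_exact`) enumerates all
C(n+m, n) relabelings (bound n+m ≤ 14) and reports the proportion with
|z| at least the observed value, infinite |z| counting as extreme; it
is the oracle for the asymptotic version in the tests.

**Fligner–Killeen test.** Groups are centered at their medians; pooled
absolute deviations are midranked and scored
aᵢ = Φ⁻¹(½ + rᵢ/(2(N+1))); the statistic Σⱼ nⱼ(Āⱼ − ā)²/s² (s² the
N−1 variance of all scores) is referred to χ²(k−1). Matches
`scipy.stats.fligner` to 1e-10 (cross-checked in tests, never used as
the implementation). All-zero deviations give a degenerate p = 1.

**Welch's t** uses Satterthwaite degrees of freedom; **OLS** returns
slope, intercept, R², the slope's two-sided t-test p, and vertical
residuals with mean and n−1 standard deviation. Residual means are
zero to ~1e-8·scale with an intercept (property-tested). A spread that
underflows to a zero sum of squares is treated as a constant design and
rejected.

All p-values are two-sided and reported raw — each comparison stands
alone, so no multiple-testing correction is applied anywhere.

## Diet comparisons (`dogcnv.diet`)

`compare_by_diet` maps diet categories onto two sides (default: high
and moderate → "high" side, low → "low"; categories absent from the
map are excluded, which is how moderate-only analyses are run), then
reports group means and SDs (n−1), both tests, and optionally the
per-group fraction of calls at or above a copy threshold (10 copies for
the amylase analyses). Means are exact before the 1-decimal formatting
of output tables. Breed matching is case-insensitive; results are
invariant to call order.

`latitude_analysis` regresses copy number on |latitude| and splits
calls at 40° — strictly below vs at-or-above, the boundary going to the
"above" group since "below 40°" reads as strict — then compares spreads
with Fligner–Killeen. `cladogram_overlay` is purely descriptive: breed
mean copy numbers listed in cladogram leaf order, with breeds missing
from the tree appended and warned about (no phylogenetic-signal
statistics are attempted — six breeds cannot support them).

## aCGH outlier (`dogcnv.acgh`)

Site means are arithmetic means of per-sample log2 ratios per breed; a
site enters the null set only with ≥1 sample in each focal breed. The
null fit regresses breed-y means on breed-x means over null sites only;
the focal point is never part of the fit (adding it demonstrably moves
the fit — property-tested). The outlier statistic is
z = (residual − residual_mean)/residual_sd over the null fit's
residuals; with an intercept the residual mean is ≈0, so z is the focal
vertical residual in null-SD units. Vertical residuals make z depend on
orientation, so the CLI reports both orientations (default x = Alaskan
Malamute, y = Shar Pei). A residual SD at floating-point rounding scale
(≤1e-9·scale) means the null sites are collinear; the result is flagged
degenerate with z = 0 for an on-line focal point rather than an
astronomical ratio of rounding errors. `cnv_to_log2` places ddPCR copy
numbers on the aCGH scale as log2(CN/reference CN); the reference
diploid count is a required input with no silent default.

## Introgression scan (`dogcnv.introgression`)

Derived allele frequencies are counts over 2 × non-missing individuals;
missing genotypes are dropped per locus, never imputed. ΔDAF =
DAF_dogs − DAF_wolves exactly; the genome-wide mean and SD (n−1) over
non-missing loci set thresholds mean ± 2·SD, and a locus is flagged
when its ΔDAF strictly exceeds the upper or falls below the lower
threshold. This two-sided mean-centered rule (rather than a symmetric
|ΔDAF| > 2SD) is what asymmetric published thresholds such as
0.557/−0.579 imply; `threshold_moments` inverts any threshold pair back
to the moments ((u+l)/2, (u−l)/4 at multiplier 2) to machine precision.
The dog panel pools all dog individuals for the genome scan (the
pooling set is caller-visible); per-breed frequencies appear only in
the wolf-allele ranking. The wolf allele is the allele above frequency
½ in wolves; at an exact 0.5/0.5 tie the derived allele is chosen
deterministically and flagged. Gene windows span the flanking genes'
TSSs padded by 500 kb per side (the typical wolf-introgressed haplotype
length), clamped at 0, half-open. The chromosome control is a Welch
t-test of one chromosome's ΔDAF against the genome-wide set (which
includes that chromosome, so a chromosome that is the whole genome
gives t = 0, p = 1 by construction). VCF input takes the ancestral
allele from a configurable INFO field and skips multiallelic records or
records whose ancestral allele matches neither REF nor ALT.

## Synthetic data (`dogcnv.simulate`)

**Copy-number calls.** True copy numbers per breed are drawn from a
normal truncated at 0 — tight around an optimum under "selection", wide
around a lower mean under "drift" — then ddPCR measurement noise
(SD 0.3 copies by default, the scale of typical ddPCR technical error)
is added, truncated at 0, and rounded. A truncated normal was chosen
over a Poisson because observed breed SDs fall both above and below the
Poisson mean-variance line. The study-scale scenario fixes the five
breed labels at the published per-breed sample sizes, means and SDs
(16/18/14/17/15 samples; high-starch breeds 11.1±2.7 and 10.7±1.7 under
selection, low-starch 8.3±3.4, 7.8±3.9, 6.1±5.0 under drift; 80 calls).

**aCGH tables.** Null-site x-means are uniform on [−1, 1]; y-means are
slope·x + intercept + N(0, noise). Per-sample values jitter around site
means with the jitter centered per site, so aggregation reproduces the
generating means exactly and the noiseless/offset-free case yields
z = 0 exactly. Defaults: 156 null sites, slope 1, noise SD 0.15, focal
offset 0.9 — an expected |z| of 6, the scale of the real focal-gene
result.

**Genotype panels.** Background frequencies follow a Balding–Nichols
model: per locus an ancestral frequency q ~ Beta(0.7, 0.7), then dog
and wolf frequencies ~ Beta(q·k, (1−q)·k) with k = 10, i.e. dog–wolf
F_ST ≈ 1/(k+1) ≈ 0.09 and a genome ΔDAF SD of ~0.16–0.2, the same order
as the 0.284 implied by the published thresholds. Planted
ancestry-informative loci get frequencies (1±effect)/2 (effect 0.8 by
default) and sit inside the planted gene region; the introgressed breed
draws each haplotype from the wolf frequency with probability equal to
the introgression fraction (0.5 by default), else from the shared dog
frequency. Loci are independent — the scan statistic is per-locus
frequency-based, so no linkage is simulated. Defaults: 1000 loci, four
dog breeds and one wolf population of 20 individuals each, loci cycled
over two chromosomes.

**Latitude datasets.** Breed latitudes are uniform within each side of
the split; copy numbers have a latitude-independent mean (11.8, the
pooled scale of the 252-call dataset) and an SD given by a pluggable
variance model (default 4.4 below 40°, 5.3 at/above — the published
group spreads). Calls are grouped into breeds of ~4; counts default to
75 below / 177 above.

Every generator is a pure function of its config including the seed;
changing only the seed changes the draws, not the ground truth.

## What the synthetic data do and do not show

The generators reproduce the study's *structure* — sample sizes, group
means and spreads, null-site counts, effect magnitudes — with
independent draws. They do not emulate breed substructure or kinship
among sampled dogs, ddPCR error growth at high copy number, linkage
between loci, site-specific aCGH probe effects, or ascertainment of the
genotyped loci. Passing recovery tests therefore demonstrates that the
implementations are correct and adequately powered at study scale, not
that the study's biological conclusions follow from its real data,
which are not bundled here.

## Numerical choices and problem sizes

Monte-Carlo checks use fixed seeds and study-scale sizes chosen as the
smallest that make the checks sharp: 200 datasets for the rank-order
oracle comparison (values on the 0–15 diploid-copy scale, n = m ≤ 6 so
exact enumeration is feasible), 5000 null and 500 power replicates for
the variance test, 100 seeds for the planted aCGH outlier (whose
single-seed |z| has ~6% sampling SD from estimating the residual SD on
156 sites, so recovery is judged on the across-seed mean), and 200
seeds at 1000 loci for introgression recovery. Calibration assertions
use bands of ±3.5–4 binomial SDs around the nominal rate.

## Known limitations

The robust rank-order test's normal approximation is rough below ~6
observations per group and with heavy ties; the exact permutation mode
exists for exactly that regime. The ΔDAF scan assumes a correct
ancestral-allele designation and biallelic loci; ambiguous records are
skipped, not rescued. The aCGH outlier statistic assumes the null-site
relation is linear and its residual spread homoscedastic across the x
range. The package does not implement haplotype-based introgression
statistics (D-statistics, f4, local-ancestry HMMs) or any selection
scan beyond the variance contrast.
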