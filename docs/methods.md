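# Methods

This note documents the models implemented in `wingpop`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that matter for reproducing results.

## The scientific setting

Rock pigeons (*Columba livia*) carry an allelic series at a single locus
controlling wing-shield pigment patterning (T-check, checker, bar, barless in
decreasing dominance and melanism). The derived checker haplotype — a ~103 kb
interval on Scaffold 68 containing a tandem copy-number variant between
*EFHC2* and *NDP* — shows three converging signatures of recent interspecies
introgression from the speckled pigeon (*C. guinea*): extreme allele-frequency
differentiation between bar and checker birds confined to this interval;
four-taxon D-statistics approaching 1 in the interval while the genome-wide
mean is near zero; and checker–donor sequence similarity far exceeding what
incomplete lineage sorting predicts for species that diverged 4–5 million
years ago. Two clocks date the haplotype: pairwise SNP counts among checker
haplotypes (mutation clock) date their common ancestor to tens of thousands
of years, while the decay of extended haplotype homozygosity (recombination
clock) dates the introgression into *C. livia* to within the last ~1,000
years — a discrepancy expected when a haplotype is sampled from a diverged
source population and then spread recently.

## Differentiation scan

Per site, with alternate-allele counts (k1, n1) and (k2, n2) in the two
groups, the statistic is the 1-df binomial likelihood-ratio

  Λ = 2 [ ℓ(k1; p̂1) + ℓ(k2; p̂2) − ℓ(k1; p̂) − ℓ(k2; p̂) ],  p̂ = (k1+k2)/(n1+n2),

with p-values from χ²(1). This is an allele-count analogue of probabilistic
case/control differentiation scans; the original tool's genotype-likelihood
model is not re-implemented, so published per-site p-values are reproduction
references, not checks. Genome-wide significance is Bonferroni
(alpha / number of sites actually tested — a threshold of 9.72e-10 at
alpha = 0.05 corresponds to ~5.1e7 tested sites). Significant sites separated
by ≤ `merge_gap` (default 10 kb) fuse into candidate regions.

`minimal_shared_haplotype` returns the maximal interval around a focal site
over which all carrier haplotypes are mutually identical; missing alleles are
wildcards, and bounds sit at the sites adjacent to the nearest discordant
site on each side. Its boundary error is limited by local informative-site
spacing.

## D-statistics

Pattern weights use the standard frequency formulation (see README for the
formulas); sites where the outgroup carries the derived allele are retained
with weight (1−pO) rather than dropped. The global D is the ratio of summed
weights, which is not the mean of window Ds; both are computed and reported
separately. Windows with zero informative weight are flagged missing (NaN),
never zero. `combo_mean_d` reproduces the per-individual-pair protocol: each
(P1 individual, P2 individual) combination is tested with the full donor and
outgroup groups, windows are averaged within a combination, and combinations
are averaged into a grand mean. Both a genotype mode (both haplotypes of the
individual) and a single-haplotype mode are provided because the original
per-combination protocol is ambiguous on this point.

Confidence intervals use a moving-blocks bootstrap with genomic windows as
blocks: each replicate draws n windows with replacement (n = number of
non-missing windows) and records the mean; the percentile interval is
reported (1,000 replicates by default; the replicate count and percentile
method are package choices, as the original analysis states neither).
Percentile bootstrap coverage approaches nominal only with an adequate
number of blocks; the validation suite uses ≥ 40 windows per replicate.

## Triplet similarity scan

For a (bar, checker, donor) haplotype triplet, windows contain a fixed
number of triplet-informative sites (not all three alleles equal, none
missing; default 100 sites, step 1), and each window reports 100 ×
matches/window for the three pairs at the window-center coordinate. Inside
an introgressed tract the checker–donor trace exceeds the bar–checker trace
and the relationship reverses outside — the qualitative signature this scan
exists to display.

## Dating

**Mutation clock.** T = S / (2 μ L) generations for S observed differences
over L bp at rate μ; its inverse gives the SNP count expected after T
generations. With μ = 1.42e-9 and L = 102,909 bp, a 4–5 MY divergence
predicts 1169–1461 differences; 26 mean differences give ≈ 89 thousand years
(KY) at 1 generation/year, which is the year convention used whenever "KY"
is reported. L is always an explicit argument: `GenomicRegion.length()` uses
inclusive arithmetic (1,702,691–1,805,600 → 102,910 bp) while the dating
constant 102,909 is passed verbatim where the original analysis used it.

**Percent similarity** is 100·(1 − S/K) with K the total segregating sites in
the region. Group summaries are reported both as the mean of per-pair
similarities and as the similarity of the mean count; the two differ in the
second decimal and published group values match per-pair averaging.

**Recombination clock.** EHH from a focal site is Σ_g C(n_g,2) / C(n,2) over
groups of carriers identical from the focal site out to each position;
haplotypes with missing data in the span leave both numerator and
denominator from that point on, and the curve truncates below two remaining
haplotypes. The haplotype boundary per side is the first site with
EHH < 0.25; p is the mean of the two sides' boundary EHH values. Assuming a
star-shaped genealogy since the haplotype's origin, Pr[homoz] = e^(−2 r g),
so g = −100 ln(p) / (2 r_cM) — the natural logarithm is forced by the
exponential form, and the factor 100 converts centiMorgans to Morgans. The
point estimate uses the mean of the two sides' map distances. The CI treats
the non-recombined carrier count as N ~ Binom(n, p), takes exact CDF
quantiles (smallest N with CDF ≥ target, continuity corrections off), maps
N/n through the age formula, and flags the upper age unbounded when the
lower quantile is 0. Map distances come from a uniform cM/bp rate or a
2-column cumulative map with linear interpolation.

## CNV genotyping and expression

Copy number is 2 × mean depth in the CNV region / mean depth in a
copy-neutral reference region (the original normalization regions were
1,500,000–2,000,000 and 800,000–1,400,000 on Scaffold 68). The continuous
estimate is snapped to the nearest attainable diploid total from
per-chromosome copies {1,2,4} — {2,3,4,5,6,8} — with ties rounding down
(estimate 7.0 → call 6). The estimator is scale-invariant in sequencing
effort by construction.

Copy-phenotype association uses pairwise Mann-Whitney rank-sum tests (exact
when sample sizes and ties permit) with Benjamini-Hochberg adjustment across
pairs. Pigment-area regression fits a four-parameter logistic by nonlinear
least squares by default (the saturating shape reflects that wing-shield
darkening plateaus at high copy number); a linear model is available, as
both were used historically; r² = 1 − SSres/SStot in either case. qPCR
expression is 2^−ΔCt after averaging replicate Cts (ΔΔCt against a
calibrator is optional). Allele-specific expression divides each bird's cDNA
checker:bar signal ratio by its matched gDNA ratio to cancel amplification
bias; tests are a two-sample t between 1- and 4-copy classes, a linear trend
of normalized ratio on copy count, and per-class one-sample t against 1:1.
Degenerate inputs with zero variance return (t = 0, p = 1) when the null is
exactly satisfied.

## Synthetic-data generator

**Quartet.** msprime simulates a three-population demography — recipient
(*C. livia*, holding both bar and checker samples), donor, and outgroup —
with splits at `T_split_donor` (default 4.5e6 generations, the midpoint of
the 4–5 MY range at 1 generation/year) and `T_out` (default 9e6, chosen only
to be safely deeper). Mutations use a binary 0/1 model at μ = 1.42e-9.
Effective sizes are not reported for this system; the default Ne = 6e5 for
every population makes 4·Ne·μ ≈ 0.0034, matching nucleotide diversity
reported for free-living rock pigeons, and is a package choice documented
here rather than a literature value.

**Introgression pulse.** Gene flow is a single dated pulse implemented as a
haplotype overlay: a hidden donor "founder" haplotype is sampled, and each
carrier haplotype in the checker group copies the founder over a tract
containing the focal site, with per-side tract ends at exponential distances
(rate `T_intro × rho`) — the recombination erosion a star-shaped genealogy
predicts after `T_intro` generations (default 857). By default tracts are
confined to the target region (`confine_to_region=True`), emulating a
haplotype bounded by fixed historical breakpoints, which is how the real
minimal haplotype was delineated; setting it False lets tracts erode freely
into the flanks. The overlay is exactly the model the recombination-clock
estimator assumes, which makes truth recovery well defined: the estimator is
being validated against its own model class, so passing tests demonstrate
correct implementation and calibration, not robustness to demographic
violations. Private mutations accumulating on carrier tracts since the pulse
(expected ≈ 0.12 per haplotype over 100 kb at 857 generations) are omitted
as negligible.

**Recombination rates.** Haplotype erosion and dating use the map-derived
rate `rho` (default 1.57e-8/bp/generation, i.e. 1.57 cM/Mb — the rate under
which the ~51.5 kb focal-to-boundary span corresponds to the 0.0809 cM that
inverts to 857 generations at Pr = 0.25). The coalescent background uses a
separate, smaller `background_rho` (default 2e-9): simulating 4–5 MY of
divergence at the full map rate costs ~50 s per 400 kb replicate, and the
background rate's only role in these analyses is to decorrelate genomic
windows; the erosion process, which is what the dating measures, always uses
the true rate.

**Sample sizes** default to 10 bar / 11 checker diploids (22 carrier
haplotypes, the carrier count behind the published binomial CI), 1 donor,
and 1 outgroup. The validation suite uses 17 bar / 24 checker for the
differentiation-scan recovery checks (the original scan's panel) and smaller
5+5 panels over 300 kb chunks for null-D batches, purely for speed. The
simulated chunk is the 102,909 bp region plus 250 kb flanks by default.

**Coordinates** are laid out so the simulated region lands at the published
Scaffold 68 positions (region start 1,702,691; focal site 1,751,072),
making outputs directly comparable with printed coordinates. Synthetic
ref/alt nucleotides are arbitrary seeded draws — the pipeline only consumes
0/1 codes.

**Depth, phenotype, and expression panels.** Depth is Poisson per bin
(default 100 bp): mean coverage scaled by total_copies/2 inside the CNV
region. Percent dark wing-shield area follows a logistic in diploid copy
number (10→90% between totals 2 and 8, midpoint 4) plus Gaussian noise
truncated to [0,100]; the default noise (sd 25) was calibrated once so a
mixed 90-bird panel yields fitted r² ≈ 0.5, the regime reported for real
mixed panels. ASE panels draw gDNA ratios around parity and multiply by a
per-class fold change (defaults 1.3 / 1.6 / 2.0 for 1 / 2 / 4 copies —
qualitative increases chosen to mirror the reported direction, not fitted
values).

**What the generator does not emulate**: read-level errors and mapping bias,
selection and non-random mating after introgression, population structure
within *C. livia*, phasing errors, indels/multiallelic variation, and the
ascertainment of real panels. Consequently, passing recovery tests show the
pipeline is implemented and calibrated correctly under its stated model —
not that the estimators are robust to these real-data complications.

**Determinism.** All generators accept a single integer seed; numpy
`SeedSequence` spawns independent streams for ancestry, mutation, overlay,
and site labels, and msprime receives explicit seeds, so a fixed seed gives
byte-identical VCF output across runs on a given dependency set.

## Numerical conventions and edge cases

- Coordinates 1-based inclusive everywhere; BED export converts to 0-based
  half-open. Haplotype columns sample-major, phase-minor.
- Missing alleles: pairwise statistics use site-wise pairwise deletion; EHH
  excludes haplotypes from the point a missing call appears; shared-haplotype
  matching treats missing as a wildcard.
- Windows advance by `step` until one reaches the region end; a final short
  window is flagged partial. With step = size the tiling is exact.
- D is NaN (flagged missing) when no pattern weight exists — never 0.
- The LD-age point estimate inherits two small biases: the boundary is the
  first *site* below threshold (discretization), and when tracts stop at a
  hard breakpoint the EHH drop just beyond the boundary is abrupt; under the
  default confined generator this inflates the point estimate by roughly
  20-30% (median ≈ 1.08k generations for a truth of 857) while the binomial
  CI still covers the truth in well over 80% of replicates — the empirical
  coverage is recomputed by the validation suite and the acceptance script.
- The exact-binomial age CI can be one-sided unbounded (lower N quantile 0 →
  infinite upper age); this is reported as `inf`, not an error.
- Problem sizes in the validation suite (50-replicate batches, 300-600 kb
  chunks, 20-replicate scan batches) were chosen to keep the full suite and
  the acceptance script in the minutes range on a single CPU while leaving
  Monte-Carlo error well inside the asserted margins.

## Known limitations

- The differentiation test is an allele-count LRT, not the original
  genotype-likelihood model; p-values agree qualitatively, not numerically.
- The recombination-clock CI convention (exact CDF quantiles) is one of
  several defensible conventions; published CI bounds for the real data are
  not reproducible without the original boundary sites and are not asserted.
- The star-phylogeny assumption ignores coalescence among carriers between
  the pulse and the present; for very recent pulses this is mild, but the
  overlay shares this assumption, so the validation cannot detect it.
- `combo_mean_d` excludes combinations with no informative windows with a
  warning, which can make the grand mean an average over fewer than n1×n2
  combinations on sparse data.
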