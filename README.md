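# wingpop

Population-genomic analyses of the rock pigeon (*Columba livia*) wing-pattern
locus: localizing the derived *checker* haplotype, testing whether it entered
the species by introgression from the speckled pigeon (*C. guinea*), and
dating both the haplotype's common ancestor and the introgression event.

The package is aimed at population geneticists who want a tested, scriptable
re-implementation of this analysis pipeline that runs end-to-end on synthetic
data — every stage is exercised against simulated cohorts with known truth,
so no sequencing downloads are required.

## What it computes

- **Differentiation scan** (`wingpop.diffscan`): per-site allele-frequency
  differentiation between phenotype groups via a 1-df binomial
  likelihood-ratio test, Bonferroni genome-wide threshold (alpha / sites
  tested), merging of significant sites into candidate regions, and
  delineation of the minimal haplotype shared by all carriers around a focal
  site.
- **Four-taxon D-statistics** (`wingpop.introgression`): with derived-allele
  frequencies (p1, p2, p3, pO) for the quartet (bar, checker, donor,
  outgroup),

  ABBA = (1−p1)·p2·p3·(1−pO),  BABA = p1·(1−p2)·p3·(1−pO),
  D = (ΣABBA − ΣBABA) / (ΣABBA + ΣBABA).

  Windowed smoothing, per-individual-combination averaging, moving-blocks
  bootstrap CIs (windows as blocks), and triplet percent-identity scanning
  over informative sites.
- **Dating** (`wingpop.dating`): the mutation clock T = S / (2·μ·L) and its
  inverse E[S] = 2·μ·L·T; pairwise SNP-difference matrices and
  percent-similarity summaries; extended haplotype homozygosity (EHH) from a
  focal site; and the recombination clock g = −100·ln(Pr[homoz]) / (2·r_cM)
  with an exact-binomial CI on the number of non-recombined carriers,
  N ~ Binom(n, p).
- **CNV and expression** (`wingpop.cnv_expression`): diploid copy number as
  2 × mean depth in the CNV region / mean depth in a copy-neutral reference
  region, snapped to the attainable totals {2,3,4,5,6,8}; rank-sum
  copy-phenotype tests with Benjamini–Hochberg adjustment; logistic/linear
  pigment-area regression; qPCR 2^−ΔCt; allele-specific expression with
  gDNA-normalized cDNA ratios and the associated t/trend tests.
- **Synthetic data** (`wingpop.synthetic_data`): an msprime coalescent
  quartet (recipient, donor split 4.5 M generations, deeper outgroup) with a
  dated introgression pulse whose carrier tracts erode by recombination —
  plus Poisson depth tracks, pigment-phenotype panels, and paired gDNA/cDNA
  allele-ratio panels, all with truth records.

## Worked example

```python
from wingpop import dating, diffscan, introgression, popgen_io, synthetic_data

# 1. Simulate a quartet with a full introgression pulse 857 generations ago
cfg = synthetic_data.QuartetSimConfig(seed=42, f_intro=1.0)
ds = synthetic_data.simulate_quartet(cfg)

# 2. Differentiation scan (bar vs checker) and candidate-region delineation
scan = diffscan.genome_scan(ds.sites, ds.haplotypes, ds.panel)

# 3. Four-taxon D-statistic: global and in the candidate window
global_d = introgression.d_statistic(introgression.pattern_sums(ds.haplotypes, ds.panel))
windows = popgen_io.make_windows(cfg.span, 100_000, 100_000)
wd = introgression.windowed_d(ds.haplotypes, ds.panel, windows)
focal_d = next(r.D for r in wd if r.window.contains(ds.truth.focal))

# 4. Mutation-clock dating of the checker haplotype (study constants as inputs)
t = dating.coalescent_time(26, 1.42e-9, 102_909)

# 5. LD-decay age of the simulated haplotype (truth: 857 generations)
focal = ds.haplotypes.nearest_site(ds.truth.focal)
left = dating.ehh_curve(ds.haplotypes, focal, ds.truth.carriers, "left")
right = dating.ehh_curve(ds.haplotypes, focal, ds.truth.carriers, "right")
est = dating.estimate_haplotype_age(left, right, rate_cm_per_bp=cfg.rho * 100)
```

Output:

```
simulated 30553 SNPs x 46 haplotypes
genome-wide threshold 1.64e-06; significant region Scaffold68:1704852-1799762
global D = 0.929; focal-window D = 0.980
mutation-clock divergence: 89 KY from 26 mean differences
LD-decay age: 1066 generations (95% CI 624-1906)
```

Reading the numbers: the scan recovers a single significant region
overlapping the true introgressed interval (Scaffold68:1,702,691–1,805,599);
the D-statistic approaches 1 in the focal window, the signature of checker
haplotypes being closer to the donor species than to conspecific bar
haplotypes; 26 mean pairwise differences over 102,909 bp at
μ = 1.42e-9/site/generation date the checker haplotypes' common ancestor to
~89 thousand years; and the EHH-decay clock brackets the simulated
857-generation pulse.

A thin CLI mirrors the library: `wingpop simulate | scan | dstat | triplet |
pairdiff | ehh | age | cnv | express | ase` (see `wingpop --help`).

## Documentation

`docs/methods.md` describes the models, the synthetic-data generator and its
deliberate simplifications, parameter defaults with their rationale, and
known limitations.
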