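# Methods

## Model overview

`sweepnet` treats sweep detection as binary classification of genomic
windows. A window is summarized by eleven statistics evaluated at 21
centre points with five nested window sizes; the resulting 11 × 105
tensor is classified by a small CNN trained on simulated neutral and
sweep loci. The approach assumes phased haplotypes, known
ancestral/derived polarization, biallelic SNPs, and a training simulation
set whose demography is at least roughly appropriate for the scanned
population; it makes no assumption about the type, age, softness or
completeness of the sweep beyond the ranges covered by the training
distributions.

## Statistic definitions and conventions

Focal variants are sites with derived allele frequency (DAF) in
[0.25, 0.95], bounds inclusive; below that range there is little power,
above it the ancestral background is too small to compare. Sites outside
the range are skipped (they contribute no per-SNP value). For each focal
variant the sample splits into the derived and ancestral backgrounds.

* **hapDAF** = Σ(f_d² − f_a²)/k over flanking variants in a
  focal-centred window satisfying, with strict inequalities: present on
  ≥ 1 haplotype of each background; f_d > f_a; f_a < c; f_d + f_a > c,
  with c = 0.25 (hapDAF-o, tuned for older sweeps) or c = 0.10
  (hapDAF-s, sweeps from standing variation). k = 0 gives 0.
* **Sratio** = S_a / S_d, counts of sites segregating within each
  background in the window; S_d = 0 is not computable (no pseudocount —
  a pseudocount would manufacture unbounded artifacts in low-diversity
  windows).
* **lowfreq / highfreq** = Σ(1 − f_dd)²/k and Σ f_dd²/k over flanking
  derived alleles on the derived background with 0 < f_dd < 0.25 and
  f_dd > 0.25 respectively (strict). Requiring presence (f_dd > 0)
  keeps absent alleles from contributing maximal terms; the statistics
  describe alleles hitchhiking on the derived background.
* **iHS / nSL** are oriented sweep-positive: ln(iHH_d / iHH_a) and
  ln(SL_d / SL_a), so that extended homozygosity on the derived
  background gives positive values, consistent with DIND (π_a / π_d)
  and Sratio. EHH is integrated by trapezoid outward from the focal
  site, truncated where EHH < 0.05 or at the window edge; distance is
  physical bp, or cM when a recombination map is supplied. A focal site
  where EHH fails to decay on both sides of both backgrounds is flagged
  not computable. nSL measures pairwise shared-segment length in numbers
  of segregating sites and uses no map.
* **SAFE/iSAFE**: SAFE(i) = (φ(i) − κ(i)) / √(f(1−f)), where φ is the
  fraction of total haplotype-allele-frequency (HAF) mass carried by the
  carriers of i and κ the fraction of distinct haplotypes among them.
  iSAFE aggregates SAFE over overlapping 300-SNP windows (step 150)
  weighted by each window's peak score. Windows under 300 SNPs use SAFE
  directly — iSAFE's windowing is meaningless there — and the window
  summary is the maximum per-SNP score, since SAFE is a localization
  statistic whose extreme identifies the candidate driver.
* **HAF**: mean of the top ⌈0.1 n⌉ per-haplotype HAF scores; the top
  decile carries the signal of incomplete sweeps while the bulk dilutes
  it. **H12**: haplotype frequencies are pooled by greedy clustering at
  ≥ 80% pairwise identity (seeds in descending multiplicity, ties by
  first occurrence) before (p₁+p₂)² + Σp_i²; the threshold lets
  recombined/mutated copies of a sweeping haplotype count toward the
  leading classes. Both are single per-locus values.

Per-SNP windows are focal-centred with span equal to the nested window
size; a window cell aggregates the standardized per-SNP values of the
focal variants inside the window by their mean (robust to SNP count, and
the natural summary when per-SNP values are already z-scores).

## Standardization

Per-SNP statistics are standardized as (x − E_p[x])/SD_p[x] with moments
estimated from neutral simulations in fifty 2%-wide DAF bins, (0, 0.02],
(0.02, 0.04], …; moments are estimated per (statistic, window size).
Bins with fewer than 20 values — or zero variance, which happens
routinely for hapDAF in small windows where most neutral values are
exactly 0 — are pooled symmetrically with neighbouring bins until both
conditions resolve; a statistic constant across all bins is an error.
Per-locus statistics (HAF, H12) and the per-window SAFE/iSAFE maximum
have no focal DAF and use a single global neutral bin each. Norms are
serialized as a versioned TSV (statistic, bin_low, bin_high, mean, sd)
with a provenance tag that binds downstream models to the norms they
were trained with.

## Feature tensor

21 centres, spaced at the centre-step (10 kb at default scale) and
symmetric about the locus midpoint, cover the central 200 kb of a 1.2-Mb
locus so that the largest (1-Mb) window always fits inside the locus.
Columns are centre-major; rows interleave statistic families —
iHS, hapDAF-o, DIND, nSL, hapDAF-s, Sratio, iSAFE, lowfreq, HAF,
highfreq, H12 — so that small convolution kernels span different kinds
of information; the order is configurable, and a tensor records its row
order. HAF and H12 are broadcast across all 105 columns to keep the
tensor rectangular. Not-computable cells are imputed with 0 — the
neutral-standardized mean, the least informative value — and counted;
windows with more than 20% imputed cells are not classified in the scan.

## Simulations

Neutral loci come from the standard coalescent (msprime) under a
piecewise-constant demography (presets: equilibrium, 5× decline, 10×
expansion, bottleneck; size changes at 0.05·4Ne generations, chosen as a
round recent-history scale). Sweep loci use msprime's structured-
coalescent sweep model with the selected site at the locus centre,
composed as StandardCoalescent(duration = τ) → SweepGenicSelection →
StandardCoalescent, so the sample is taken τ generations after the
beneficial allele reached its ending frequency. Defaults: 1.2-Mb locus,
100 chromosomes (50 diploids), Ne = 10,000, μ = ρ = 1.25 × 10⁻⁸ (a
human-typical point value; the distributions behind published training
sets are supplementary material and not reproduced here). Sweep
parameters are drawn per replicate: τ ~ U(0, 0.125·4Ne), s ~
log-uniform(0.001, 0.1), SAF ~ U(0, 0.10), EAF ~ U(0.2, 1.0); all
user-overridable, validated against τ ≤ 0.25·4Ne and s ≥ 10/(2Ne).
Mispolarization robustness experiments flip whole site columns
independently at a given rate. Externally simulated data (discoal, SLiM
— e.g. background-selection sets with a deleterious DFE such as
Γ(mean = −0.030, shape = 0.206), or heterogeneous recombination maps)
are ingested from ms-format with a label manifest; this package does not
itself simulate background selection.

## Classifier

Input 1 × 11 × 105; three convolution blocks (16/32/32 filters, 3 × 3
kernels — spanning three statistic rows and three window columns — with
max-pooling), a 64-unit dense layer, dropout 0.25, sigmoid output;
binary cross-entropy, Adam (10⁻³), batch 32, stratified 80/20
train/validation split (an unstratified shuffle lets early stopping
select on a class-skewed validation set, which destabilizes the decision
threshold), early stopping on validation loss (patience 10) with
best-weight restore. The network is implemented directly in numpy (im2col
convolutions, explicit backprop) and is exactly reproducible under a
seed. The output is a binary sweep probability only; attempting
multi-class sweep typing costs power, so downstream tools should be used
to characterize detected regions. Evaluation reports ROC/AUC, the
confusion matrix, and both false-positive-rate conventions at each
threshold — FP/true-neutrals (ROC sense) and FP/all-positives (the
discovery-oriented sense) — since both are in circulation and differ
substantially on unbalanced sets.

## Genome scan

Chromosomes are tiled into windows of one locus length stepped by 10 kb;
each window is featurized with the training norms and classified at a
confidence threshold (default 0.5). Windows with under 2 SNPs in the
window set or over 20% imputed cells are flagged unclassifiable and break
streaks. Maximal streaks of sweep-classified windows merge into regions
spanning the union of their member windows, with the peak at the centre
of the most confident member (leftmost on ties — the paper-style peak is
not otherwise specified, and the max-probability centre is the natural
point estimate of the driver's location). The FDR over a scan is
estimated from sets of windows spaced ≥ 1 Mb apart (approximately
independent): expected false positives per set = validation FPR × set
size, divided by the positives observed in the set, averaged over 100
random offset sets. An optional second-pass mode re-scores
low-recombination regions with an alternative model trained at lower
recombination rates (supply it via the CLI with a BED of regions).

## Scaled study conditions

Library defaults are the full-scale conditions above. The test suite and
`scripts/acceptance.py` run a 1/10-scaled profile chosen once for desk
scale: 120-kb locus, nested windows 5/10/20/50/100 kb, 1-kb centre step,
50 chromosomes, Ne = 10,000, and μ = ρ = 3.75 × 10⁻⁸ — three times the
human-typical point value, so that each window retains a workable SNP
density (~800 segregating sites per locus; at unscaled rates a 120-kb
locus carries an order of magnitude less information than the windows
the method was designed around). Norms come from 40 neutral replicates,
training sets are 150 + 150, test sets 80 + 80.

What the scaled study shows: every statistic agrees exactly with
brute-force oracles; standardization self-consistency holds; the CNN
learns separable synthetic data essentially perfectly and stays at
chance on label-shuffled data; strong recent sweeps (τ = 0, s = 0.05,
90% complete) are detected at high rates and recovered as merged regions
covering the selected site in a chromosome scan; detection rates order
correctly along sweep age, starting frequency, strength and completeness.

What it does not show: full-scale power. At 150 + 150 training
replicates and 1/10 geometry the CNN reaches an overall AUC around
0.6 on the *full* sweep-parameter distribution (most of which is old,
weak or very incomplete at this locus size), far from the published
regime of ~10,000 + 10,000 training simulations at 1.2 Mb; scaling the
pipeline up is a matter of compute, not code. The simulations also do
not emulate missing genotypes, unphased or mispolarized real data
(except via the explicit mispolarization injector), variable SNP density
from mappability, or background selection.

## Numerical notes and limitations

* Positions are integer bp; ms-format positions are rescaled and
  rounded, with +1-bp jitter resolving duplicates (strict ordering is
  required downstream).
* VCF ingestion drops sites that are multiallelic, contain missing
  alleles, lack an ancestral allele, or whose ancestral allele matches
  neither REF nor ALT; every category is counted in the read report.
  Unphased genotypes are a hard error.
* NaN is the not-computable marker throughout; it is distinct from a
  true 0 (e.g. hapDAF with no qualifying variants) and excluded from
  aggregation rather than imputed at the per-SNP level.
* The bulk engine and the per-focal reference implementations are both
  kept; their exact agreement is a standing regression test.
* Ratios and logs use the sweep-positive orientation everywhere; flip
  signs when comparing with tools using the classic negative-iHS
  convention.
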