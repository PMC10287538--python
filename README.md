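# sweepnet

Versatile selective-sweep detection for population-genomic data.

A selective sweep — the rapid rise of a beneficial allele — drags linked
variation along with it, depleting diversity on the haplotypes that carry
the derived allele and distorting the site frequency spectrum and
haplotype structure around the selected site. `sweepnet` detects these
footprints by combining **eleven summary statistics** into a per-locus
feature image classified by a **convolutional neural network trained on
coalescent simulations**, and provides a sliding-window **genome-scan**
mode that merges sweep-classified windows into candidate regions and
estimates a false discovery rate. It is aimed at population geneticists
scanning phased, ancestral-polarized diploid data — including nonmodel
species, since the training simulations are user-specified.

## The statistics

Five statistics contrast the *derived background* (haplotypes carrying the
derived allele at a focal variant with derived allele frequency
p ∈ [0.25, 0.95]) with the *ancestral background*:

| statistic | definition (per focal variant) |
|---|---|
| hapDAF-o / hapDAF-s | Σᵢ (f_dᵢ² − f_aᵢ²) / k over flanking variants shared by both backgrounds with f_dᵢ > f_aᵢ, f_aᵢ < c and f_dᵢ + f_aᵢ > c (c = 0.25 for *-o*, 0.10 for *-s*) |
| Sratio | S_a / S_d, the ratio of segregating-site counts on the two backgrounds |
| lowfreq | Σᵢ (1 − f_ddᵢ)² / k over flanking derived alleles with 0 < f_ddᵢ < 0.25 on the derived background |
| highfreq | Σᵢ f_ddᵢ² / k over flanking derived alleles with f_ddᵢ > 0.25 |

They are joined by six established statistics — iHS, nSL, DIND, SAFE/iSAFE
(SAFE below 300 SNPs per window), HAF (mean of the top 10% of per-haplotype
scores) and H12 computed on 80%-identity haplotype clusters. Every per-SNP
statistic is standardized against its neutral-simulation distribution in
fifty 2%-wide derived-allele-frequency bins,

    z = (x − E_p[x]) / SD_p[x],

so values are comparable across focal allele frequencies. A locus is
summarized as an 11 × 105 tensor: 21 centre points spaced across the
middle of the locus × 5 nested windows (50 kb – 1 Mb at the default
1.2-Mb locus), with statistics of different families interleaved along the
rows so that convolution kernels mix information types early.

## Worked example

Simulate a small training study, train the classifier, and score a strong
recent sweep (this is the scaled fixture geometry used throughout the
tests; ~3 minutes):

```python
import numpy as np
import sweepnet as sn
from sweepnet.features import FeatureConfig, assemble, build_norms_from_neutral

cfg  = sn.SimulationConfig(locus_length=120_000, n_haplotypes=50,
                           mutation_rate=3.75e-8, recombination_rate=3.75e-8)
fcfg = FeatureConfig.scaled(10)           # 5-100 kb nested windows

neutral = [sn.simulate_neutral(cfg, seed) for seed in range(40)]
norms   = build_norms_from_neutral(neutral, fcfg, provenance="demo")

tensors, labels = [], []
for i in range(80):
    tensors.append(assemble(sn.simulate_neutral(cfg, 100 + i), norms, fcfg))
    labels.append(0)
    params = sn.draw_sweep_params(cfg, 200 + i)
    tensors.append(assemble(sn.simulate_sweep(cfg, params, 300 + i), norms, fcfg))
    labels.append(1)

model = sn.train(tensors, np.array(labels), seed=7)
sweep = sn.simulate_sweep(
    cfg, sn.SweepParams(tau=0, s=0.05, saf=0.0, eaf=0.9, ne=10_000), 999)
prob = sn.predict(model, assemble(sweep, norms, fcfg))
print(f"sweep probability: {prob:.3f}")
```

```
sweep probability: 1.000
```

A probability near 1 means the window's haplotype structure looks like the
sweep class of the training simulations; the genome-scan mode
(`sweepnet scan`) applies the same computation to each 1.2-Mb window of a
phased VCF (stepped by 10 kb), merges streaks of sweep calls into regions
(`sweepnet regions`) and estimates an FDR from the model's validation
false-positive rate (`sweepnet fdr`). See `sweepnet --help` for the full
command-line surface: `simulate`, `norms`, `featurize`, `train`,
`evaluate`, `scan`, `regions`, `fdr`.

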