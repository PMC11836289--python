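# vocevo

Analysis pipeline for studies that connect **molecular evolution** with
**mouse vocal behavior**: population-genetic selection statistics on a
candidate gene, ultrasonic-vocalization (USV) syllable analysis, Gaussian
mixture bimodality of call features, percent-spliced-in (PSI)
quantification of alternative splicing, and a resampling gene-set
enrichment test.  Every stage is exercisable on synthetic data with known
ground truth, so the whole pipeline is testable without any external
download.

## Who this is for

Groups characterizing a humanized or knock-in mouse line who need, in one
place:

1. evidence of selection on the candidate locus in human population data;
2. a quantitative description of the vocal phenotype of the mouse line;
3. splicing-level molecular readouts and their enrichment in behavior gene
   sets.

## The statistics at the core

**Selection on the site frequency spectrum.**  For an unfolded spectrum
ξ₁…ξₙ₋₁ over *n* chromosomes the package computes θ_W = S/a₁,
θ_π = Σ 2i(n−i)ξᵢ/(n(n−1)), θ_H = Σ 2i²ξᵢ/(n(n−1)) and
θ_L = Σ iξᵢ/(n−1), then

* **Tajima's D** = (θ_π − θ_W)/√(e₁S + e₂S(S−1)), and its theoretical
  minimum **D(min)** attained when every site is a singleton; the ratio
  **D/D(min)** compares genes with very different SNP counts,
* **Fay–Wu's H** = θ_π − θ_H (negative after a selective sweep), its
  variance-normalized form, and Zeng's **E** = (θ_L − θ_W)/√Var,
* the joint **DH test**, calibrated against a neutral Kingman-coalescent
  null conditioned on the observed number of segregating sites S, with
  add-one–smoothed empirical p-values,
* a bootstrap upper confidence bound for the mean minor-allele frequency,
  and the population-scaled selection coefficient S = 2·N_e·s.

**USV syllables.**  Recordings (nominally 250 kHz, 1024-point FFT) are
turned into sonograms truncated to the 35–125 kHz song band, denoised with
a per-frequency-bin robust noise threshold, and tracked for peak
frequency.  Voiced runs separated by < 10 ms merge into one syllable;
syllables shorter than 3 ms are discarded.  Syllables are classified by
their instantaneous pitch jumps: none = `s`, one upward = `u`, one
downward = `d`, several = `m`, unevaluable = `notIDd`; per-syllable
features include Fq_start/min/max/end/mean, pitch variance, bandwidth,
duration, inter-syllable interval, amplitude and spectral purity.

**Bimodality.**  A two-component Gaussian mixture is fitted by EM;
separation is scored with **Ashman's D** = √2·|μ₁−μ₂|/√(σ₁²+σ₂²) (D > 2 =
well-separated), and populations are split at the intersection of the two
weighted component densities, or at a fixed physical threshold (100 kHz
for high-Fq_max calls, strictly exceeding).

**Splicing and enrichment.**  PSI = (inc/n_inc)/(inc/n_inc + skip/n_skip)
from junction reads normalized by junction multiplicity; events need ≥ 20
reads in both groups, and a differential call requires p < 0.05 (2×2
exact test) *and* |ΔPSI| > 0.05.  Gene-set enrichment is assessed by
drawing query-sized gene sets uniformly from the expressed universe and
comparing the observed category overlap with the resampled distribution.

## Worked example

```python
import numpy as np
from vocevo import SyllableAnalyzer, TwoGaussianBimodality
from vocevo import synthetic as syn, sfs

# 1. synthesize a recording with 12 planted syllables, then analyze it
plan = syn.random_plan(12, seed=42, snr_db=20.0)
samples, rate, truth = syn.gen_usv_recording(plan)
table = SyllableAnalyzer().analyze(samples, rate)
print(table[["onset_s", "class", "duration_ms", "fq_mean_khz",
             "bandwidth_khz"]].head(4).round(2).to_string(index=False))
```

```
 onset_s class  duration_ms  fq_mean_khz  bandwidth_khz
    0.05     s        44.03        87.71           5.13
    0.13     u        68.61        94.09          21.97
    0.25     d        54.27        74.53          18.07
    0.34     m        61.44        78.88          48.83
```

All 12 planted class labels are recovered exactly.  Continuing with the
adult syllable-duration split and a sweep-distorted spectrum:

```python
# 2. short/long duration split of adult "s" syllables
rng = np.random.default_rng(0)
dm = syn.adult_duration_mixture()
dur = syn.sample_two_gaussian(20_000, dm["w"], dm["mu"], dm["sigma"],
                              rng, floor=3.0)
est = TwoGaussianBimodality(seed=0).fit(dur)
labels = est.predict(dur)

# 3. selection statistics on a sweep-distorted spectrum (n=20, S=30)
spec = syn.gen_sfs(20, 30, regime="sweep", lam=0.6, seed=5)
null = sfs.simulate_neutral_sfs(20, 30, 5000, seed=1)
res = sfs.dh_test(spec, null)
```

which prints

```
Ashman's D = 3.53, cutoff = 42.7 ms
long fraction = 0.290
D = -1.49, D/Dmin = 0.59, H = -14.24, p_DH = 0.0074, p_joint = 0.0184
```

The duration distribution is well-separated (D > 2) with the short/long
cutoff near 44 ms and 29% of syllables long; the distorted spectrum shows
the joint sweep signature (negative D *and* negative H), significant
against 5000 conditioned neutral replicates.

A `vocevo` command-line tool exposes each stage
(`vocevo usv-analyze`, `vocevo sfs-stats`, `vocevo dh-test`,
`vocevo bimodality`, `vocevo psi`, `vocevo enrich`, `vocevo compare`,
`vocevo simulate ...`); run `vocevo --help` for options.

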