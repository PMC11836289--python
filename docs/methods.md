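# Methods

This note documents the models, the tunable parameters, what the
synthetic generators do and do not emulate, and the numerical choices
made where the design was genuinely open.  It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Site-frequency-spectrum selection statistics

**Model.**  All statistics are functions of the unfolded spectrum
ξ₁…ξₙ₋₁ of derived-allele counts among *n* sampled chromosomes, assuming
sites are polarized (derived vs ancestral) and independent.  Folded
spectra are refused by the high-frequency-weighted estimators (θ_H, θ_L,
H, E), which are undefined without polarity.

**Harmonizing heterogeneous coverage.**  Public frequency databases
genotype each site in a different number of chromosomes.  Before any
statistic, each site is projected to a common size *n* by hypergeometric
downsampling (the expected class occupancy of a random subsample); mass
that projects to the monomorphic classes is discarded.  The default *n*
is the 5th percentile of `total_count`, a compromise between resolution
(large *n*) and usable sites (all sites must have coverage ≥ *n*).  The
coverage filter keeps `total_count ≥ 200`, inclusively.

**Tajima's D and D(min).**  D uses the standard variance coefficients
(a₁, a₂, b₁, b₂, c₁, c₂, e₁, e₂).  D(min) evaluates the same formula at
the minimizing configuration for fixed S — every site a singleton, so
θ_π = 2S/n.  D/D(min) is reported only when S ≥ 2 and D(min) < 0;
otherwise it is flagged undefined rather than returned as 0.

**Normalized H and E.**  The variances of θ_π − θ_L and θ_L − θ_W are
the published second-order formulas in θ and θ², with θ̂ = S/a₁ and
θ²̂ = S(S−1)/(a₁² + a₂).  Their transcription is validated in the test
suite by neutral simulation (mean of the normalized statistics ≈ 0) and
by exact zero cases constructed by hand.

**Neutral null conditioned on S.**  The null for the DH test draws a
Kingman genealogy per replicate (epoch times Exp(k(k−1)/2), uniformly
random merges, branch length accumulated per descendant-count class) and
places exactly S mutations multinomially with probabilities proportional
to class branch lengths.  Conditioning on the observed S removes the
nuisance dependence on θ, matching how the test is applied to per-gene
SNP counts.  A consequence worth knowing: **conditioning on S shifts the
mean of the raw statistics.**  Short, relatively star-like trees count
equally with long singleton-rich trees once the mutation count is fixed,
so E[θ_π − θ_H | S] is positive (about +0.45 at n = 20, S = 30, confirmed
against an independent msprime-based simulation in the test suite),
whereas the unconditional mean is 0.  This does not bias the test itself:
observed and replicate statistics share the same conditional
distribution, so empirical p-values remain calibrated.

**Joint DH decision.**  Marginal p-values are lower-tail (the sweep
signature is jointly negative D and H) with add-one smoothing, so no
finite Monte-Carlo p is 0.  Two joint quantities are reported:

* `p_DH`: the joint lower-orthant fraction
  P(D_rep ≤ D_obs and H_rep ≤ H_obs).  Because D and H are positively but
  imperfectly correlated under the null, the orthant probability is *not*
  uniform — rejecting when `p_DH ≤ α` gives a type-I rate above α
  (measured ≈ 0.12 at α = 0.05 in this configuration).
* `p_joint`: the calibrated joint p-value from the max-marginal-rank
  statistic max(F_D(D), F_H(H)).  Rejecting when `p_joint ≤ α` is
  equivalent to requiring both statistics below marginal critical values
  whose common level is tuned so the joint null rate equals α — the
  conventional construction of the joint test.  `dh_reject` uses it; its
  measured type-I rate at α = 0.05 is inside [0.035, 0.065].

**MAF confidence bound.**  The construction of the published MAF
confidence profile is not fully specified anywhere we could follow, so
the package uses a bootstrap percentile interval of the mean (default
10,000 resamples; the upper bound of the two-sided 95% interval is the
97.5th percentile).  This is a deliberate, documented default, not a
claim about the original implementation.

## USV syllable analysis

**Spectrogram.**  1024-point Hann-window STFT, hop 256 samples (≈ 1.02 ms
at 250 kHz — chosen so a 3 ms syllable spans ≥ 2 frames), magnitude
squared in dB, truncated to 35–125 kHz.  All thresholds are in physical
units (ms, kHz), so other sampling rates work unchanged.

**Noise threshold.**  Per frequency bin, the floor is the median power
over frames and cells below `floor + k·σ` are masked (default k = 3).
The robust spread σ is estimated from the *lower* side of the per-bin
distribution (median minus 20th percentile, scaled by 1/0.8416 to a
Gaussian σ).  A plain MAD was rejected during development: when a call
occupies more than roughly a quarter of the frames of its bin, the call's
own power inflates the MAD and the threshold can rise above the tone.
The lower-side spread stays noise-dominated in that regime.  With k = 0
the threshold reduces exactly to the per-bin median.

**Segmentation and edge handling.**  Voiced runs separated by < 10 ms
merge; merged runs shorter than 3 ms are discarded.  Because a 4 ms
analysis window smears energy ≈ 2 ms beyond a tone's edges, runs are
edge-trimmed: leading/trailing frames whose peak power falls more than
`edge_rel_db` (default 4 dB) below the run maximum are dropped before the
duration test.  The default was chosen so that (a) onsets and offsets of
planted tones are recovered within one hop and (b) a lone 2 ms tone is
rejected at any sub-hop alignment while ≥ 4 ms tones are always kept.  A
syllable's onset/offset are the outer edges of its first/last retained
frame (center ∓ half a hop).

**Pitch, jumps, classes.**  Peak frequency per voiced frame, ties broken
to the lower bin for reproducibility.  A pitch jump is a step ≥ 10 kHz
(configurable; the magnitude criterion is not standardized) between
consecutive voiced frames; consecutive same-direction super-threshold
steps collapse into one jump.  Classes: 0 jumps `s`, one up `u`, one down
`d`, ≥ 2 `m`; tracks with < 2 voiced frames are `notIDd`.  "Frequency
modulation" is implemented as the total absolute inter-frame pitch change
excluding the jump steps; spectral purity is the peak bin's share of
in-band power.  Amplitude is the mean peak-bin power in absolute dB
(whether the original comparisons used absolute or floor-relative dB is
unknown; absolute is the simpler convention and is stated here).

## Mixture bimodality

EM fits (via scikit-learn's GaussianMixture) use one start anchored at
the 25th/75th percentiles plus random-responsibility restarts, best
log-likelihood wins; σ is floored at 10⁻⁶ of the data range to prevent
variance collapse; components are reported with μ₁ ≤ μ₂.  Ashman's
D = √2|μ₁−μ₂|/√(σ₁²+σ₂²) decides bimodality at D > 2; below that the
feature is reported unimodal and not split.  The split cutoff solves
w₁ϕ(x; μ₁, σ₁) = w₂ϕ(x; μ₂, σ₂) — a quadratic after logs — keeping the
root strictly between the means; when the weighted densities cross
outside (μ₁, μ₂) (strongly unequal weights), the cutoff is flagged
undefined rather than extrapolated.  An unweighted variant exists behind
a flag.  Fixed-threshold splits (100 kHz for high-Fq_max) label "high"
only values *strictly* exceeding the threshold.  Mixtures are fitted on
pooled syllables; splitting and ratio statistics are per animal.

## Splicing and enrichment

**PSI.**  Inclusion reads are divided by the number of inclusion
junctions before anything else (a cassette exon has two inclusion
junctions, one skipping junction; tandem cassettes three; mutually
exclusive exons two and two), making PSI invariant to junction
multiplicity and to uniform count scaling.  Zero-read events are NaN,
never silently 0.

**Differential calls.**  Coverage requires ≥ 20 raw junction reads in
*both* groups (inclusive).  The per-event test runs on the 2×2 table of
normalized pooled counts; the exact test is the default strategy, a
chi-square alternative is selectable, because the upstream pipeline's
internal test is not published.  A call additionally requires
|ΔPSI| > 0.05, which gates statistically significant but biologically
negligible shifts.  Power depends on the baseline PSI: a planted
ΔPSI = 0.2 at read depth 100 is called in roughly 78% of events at a
mid-range baseline (0.3 → 0.5) and ~90% off-center (0.15 → 0.35), where
binomial variance is smaller.  The test suite asserts the comparative
property rather than a single absolute figure.

**Resampling enrichment.**  Query-sized draws without replacement from
the universe; empirical p = (1 + #{overlap ≥ observed})/(n + 1).  The
test suite checks convergence to the exact hypergeometric tail at 10⁵
resamples on a 50-gene universe.  The vocal-gene configuration uses a
universe of 19,500 expressed genes: the published query (630
differentially spliced transcripts), category (22 vocal-behavior genes)
and resampled-overlap mean (0.71) jointly imply a universe of
630·22/0.71 ≈ 19,500, which is also a realistic expressed-gene count for
bulk midbrain RNA-seq; the exact list behind the original number is not
public.

## Cohort statistics

The unit of inference is the animal: feature means per session, session
means averaged per animal (pups have one session), then two-sided
Wilcoxon rank-sum tests per genotype pair — exact null when the combined
n ≤ 20 with no ties, normal approximation with tie correction otherwise
(the switch point is standard practice, not prescribed).  Bonferroni
multiplies by the number of genotype pairs; within-syllable call-structure
features can skip the correction (they are strongly inter-correlated, and
correcting them mainly inflates type-II error), with the feature list
configured explicitly.  Litter structure is not modeled.

## Synthetic data: what it emulates, and what it does not

* **USV audio**: frequency-modulated tones synthesized by integrating the
  instantaneous frequency into a continuous phase, so pitch is smooth
  within notes and steps exactly at planted jumps; constant amplitude per
  syllable; additive white Gaussian noise at a planned SNR (default
  20 dB).  Real recordings add harmonics, amplitude modulation, echoes
  and non-stationary noise — perfect recovery on this generator
  demonstrates correctness of the detector logic, not field performance.
* **Spectra**: the sweep regime reassigns each mutation with probability
  λ to class 1 or n−1 — a stylized footprint (excess singletons and
  high-frequency derived alleles), not a structured-coalescent sweep;
  sufficient to test statistic signs and test power.
* **Junction counts**: inclusion molecules ~ Binomial(depth, PSI) per
  group; raw reads are molecules × junction multiplicity, making the PSI
  estimator exactly invertible.  No overdispersion between biological
  replicates is modeled.
* **Cohorts**: syllable counts Poisson(rate × 5 min), features drawn from
  per-genotype mixtures.  The adult duration components
  (μ = 22.53/67.92 ms, σ = 9.37/14.76, w = 0.702/0.298) were solved so the
  mixture's *observable* split statistics equal the published phenotype —
  44 ms weighted-density intersection, 29% long, split-group means
  22.6/69.0 ms — because the published numbers are group statistics, not
  component parameters (a Gaussian component with σ = 40 above a 44 ms
  cutoff is not internally consistent).  The adult Fq_max main component
  is truncated below 100 kHz so the high peak (N(107.1, 2.1²), weight
  0.085) is a genuinely distinct population; an untruncated N(80.8,
  11.5²) would alone put ~4% of its mass above 100 kHz, contradicting the
  ~8.5% total high fraction.  The pup "u" mixture sets the center gap so
  Ashman's D is exactly 1.603 (the weakly separated case) with
  representative spreads; its absolute centers are not constrained by any
  published value.

## Problem sizes in `scripts/acceptance.py`

Neutral ensemble 5000 replicates (n = 20, S = 30); DH type-I over 1500
fresh neutral observations against a 2000-replicate null; 200 planted
syllables in five recordings; duration corpus 20,000 syllables, Fq_max
corpus 50,000, pup-"u" corpus 30,000 (weakly separated mixtures need
~10⁴ observations for a stable separation estimate); 12-animal call-rate
cohort; 500 junction events at depth 100; 1000 enrichment resamples.
These sizes make every Monte-Carlo standard error small relative to the
quantity being measured while the full script completes in well under a
minute.

## Known limitations

* θ estimators assume free recombination across sites when variances are
  interpreted; linkage makes the DH null optimistic on short regions.
* The coalescent null is constant-size panmictic; demographic structure
  is out of scope (the joint test is chosen partly for its robustness).
* The syllable analyzer is single-animal; overlapping callers and
  harmonic stacks are not separated.
* EM on weakly separated mixtures (D < 2) has a weakly identified
  likelihood surface; separation scores there carry sampling error of
  several percent even at 10⁴ observations.
* Fisher's exact test on normalized counts is conservative at low depth;
  the strategy hook exists so a likelihood-ratio or replicate-aware test
  can be swapped in.
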