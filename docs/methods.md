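# Methods

`songvar` quantifies two facets of birdsong variability — syllable
*sequence* and syllable *phonology* — and tests paired condition
differences with resampling statistics. This note documents the models,
the numerical choices, and what the synthetic validation does and does
not establish.

## Sequence model

Song is treated as a first-order Markov chain over the bird's syllable
repertoire. For a leading syllable A, the transition probability to an
outcome B is the plug-in estimate

    p(A→B) = F(A→B) / F(A),

where F(A→B) counts how often A is immediately followed by B and F(A) is
A's total outgoing-transition count. The transition entropy of A is

    H(A) = −Σ_i p_i log2 p_i    (0·log 0 := 0),

normalized by the maximum attainable entropy H_max of the repertoire, so
scores are comparable across birds with different repertoire sizes.
*Motif entropy* is the mean normalized syllable entropy; *stereotypy* is
1 − motif entropy (1 = perfectly fixed order). A frequency-weighted
variant multiplies each syllable's normalized entropy by
w_s = F_s / F_most-frequent before averaging, damping rarely-sung
syllables whose estimated entropies are dominated by sampling noise.

Two estimation modes reflect how data are transcribed:

* **motif mode** — input is a set of segmented motifs; the transition
  from each motif's last syllable to an END marker is counted (this is
  informative: motif truncation is a form of sequence variability).
* **string mode** — input is one long unsegmented string (nominally 300
  syllables); no boundary information exists, so the final symbol simply
  contributes no transition, and requesting END transitions is an error.

### Numerical and definitional choices

* **Log base 2** (bits). Normalized entropy, motif entropy and
  stereotypy are base-invariant; raw H is always reported beside H_max.
* **H_max with END**: when END transitions are counted, END is one more
  possible outcome, so H_max = log2(n_unique + 1). This is required for
  normalized entropy ≤ 1 (a syllable transitioning uniformly to all
  syllables plus END would otherwise exceed 1). `legacy_hmax=True`
  computes log2(n_unique) for sensitivity analysis.
* **Weights use leading-syllable frequency** (occurrences with an
  outgoing transition), so weights and transition distributions are
  estimated on the same support.
* Syllables with no outgoing transition (possible only as a string's
  final symbol) have an undefined distribution and are excluded from the
  model with a warning.
* **Percent change** between conditions is 100 × (UD − NS) / NS:
  negative when the singing condition is less stereotyped.

## Phonology

Per (bird, syllable, condition, feature) the package reports mean,
sample SD (n−1 denominator, conventional for ~25-rendition samples),
SE = SD/√n, and CV = SD/|mean| over renditions. The absolute value makes
CV meaningful for the one feature with a negative scale (Wiener entropy,
a log spectral-flatness measure ≤ 0); CV is undefined (missing, with a
warning) at zero mean. CVs aggregate either per bird first or flat over
syllables; which unit is appropriate is an empirical question answered
by the permutation ANOVA below.

All-vs-all score batches of m items yield m² − m off-diagonal scores
(self-comparisons excluded); mean and the naive SE over those scores
summarize a bird's self-similarity. The identity score,
similarity × accuracy / 100, is applied per comparison before averaging.

The **trajectory scorer** is an intentionally simplified feature-based
similarity measure, not a replication of any spectrogram-comparison
product. Syllables are per-frame trajectories of pitch, FM, Wiener
entropy and pitch goodness; features are scaled by the comparison set's
median absolute deviation; a local frame score is 100·exp(−d/τ) with d
the scaled Euclidean distance and τ = 1/ln 2, calibrated so one scaled
unit of distance scores 50. Accuracy averages local scores over aligned
9 ms frames; similarity averages 70 ms-window scores, either at matched
positions (symmetric) or at each window's best offset in the other item
(asymmetric — position-independent matching of the most similar
elements). Window and frame sizes, and τ, are configurable.

**Sample-count stabilization** grows a batch from 10 items in steps of
5 until the off-diagonal mean similarity and accuracy both change by
less than 0.5 score units (on the 0–100 scale) for two consecutive
increments, returning the first stable n. The tolerance and the
two-increment confirmation are package defaults; a single increment is
easily satisfied by chance at noisy small n.

## Resampling statistics

**Sign-flip paired bootstrap.** The statistic M is the mean of per-unit
paired differences. Each of 10,000 iterations multiplies the difference
vector elementwise by independent uniform ±1 draws and records the mean;
the two-tailed p-value is the inclusive fraction of null means at least
as extreme as M, extremeness being distance from the null center (M and
its reflection are the critical values). The null center used is the
exact mean of the sign-flip distribution, which is 0 by construction,
rather than its Monte-Carlo estimate: with the estimated center, the
mirrored critical value's tie atom (the fully sign-flipped vector,
probability 2⁻ⁿ) is broken by sampling jitter and the p-value would not
converge to the exhaustive 2ⁿ test as iterations grow — material at the
small n (≈ 11 birds) this design uses. The empirical null mean is still
reported. Significance is declared at p < α (α = 0.05).

**Permutation one-way ANOVA on absolute deviations.** The statistic is
[Σ_g n_g·|mean_g − grand mean|] / [Σ_g Σ_i |x_gi − mean_g|] — the
absolute-deviation analogue of the F ratio, with group sizes weighting
the between term (an unweighted variant is available). The null permutes
group labels without replacement; p is the inclusive fraction of null
statistics ≥ observed. Zero within-group variability gives an infinite
statistic, matched inclusively by equally degenerate permutations. Note
the granularity limit of small designs: with two groups of three, only
20 distinct splits exist and the smallest attainable p is 2/20 = 0.1.

**Wilcoxon signed-rank** (scipy) cross-checks significance calls only.

**Power analysis** resamples the observed differences with replacement
at a prospective n, runs the sign-flip test on each replicate, and
reports the significant fraction (default 1,000 outer replicates × 2,000
inner iterations). Resampling uses only quantities the test itself uses;
a parametric Gaussian alternative (observed mean and SD) is available
behind a flag. Power estimates carry Monte-Carlo error ≈
√(p(1−p)/n_outer).

## Synthetic data

The generator's chain family mixes a deterministic cycle with a uniform
chain: syllable i transitions to its cycle successor with probability
(1−ε) + ε/n and to every other syllable with probability ε/n. This is
the simplest one-parameter family spanning normalized entropy 0 (ε = 0)
to 1 (ε = 1) with a closed form h(ε, n), making estimator consistency
exactly checkable. Paired datasets draw one ε per bird and condition
from a Gaussian truncated to [0, 1] around the condition means
(defaults: 0.2 non-singing, 0.4 singing, between-bird SD 0.05 — a
strong, low-heterogeneity regime; inflating the SD emulates the
developmental stage where within-condition variability swamps the
effect). Feature renditions are independent Gaussians per feature with
SD = CV × |mean| (default CV 0.074, ×1.5 after singing), truncated just
above zero for physically positive features; defaults are plausible for
a harmonic zebra-finch syllable (pitch ≈ 700 Hz, duration ≈ 85 ms).

What the generator does *not* emulate: real syllable syntax is not
first-order in general; acoustic features covary; repertoires drift with
age (syllables merge and split); motif lengths vary systematically.
Passing the recovery suite therefore shows the estimators and tests are
correct and well calibrated under a known Markov ground truth — not that
real song satisfies these assumptions.

## Validation problem sizes

The standard validation suite uses: strings of length 3,000 (estimator
consistency, mean absolute error < 0.03 against h(ε, n)); exhaustive 2ⁿ
sign-flip enumeration up to n = 12 as the bootstrap's oracle; 1,000
Gaussian-null datasets of n = 11 for type-I calibration (expected
rejection ≈ 5%, slightly below due to the 2/2ⁿ granularity floor of the
exact test); and 200 replicate paired datasets of 11 birds for
end-to-end power (> 0.8 at an ε gap of 0.2) and null calibration.

## Known limitations

* Plug-in entropy is biased low at short strings (≈ −(k−1)/(2N ln 2)
  per row); at 300 syllables and 5-syllable repertoires this is ≪ the
  0.03 validation tolerance but matters for much larger repertoires.
* The trajectory scorer's scores are not comparable to any external
  software's scales; only orderings and its own calibration are
  meaningful.
* The ANOVA's naive SE over m² − m pairwise scores ignores their
  dependence (each item appears in 2(m−1) scores); it is reported as the
  field conventionally reports it.
* No multiple-testing correction is applied anywhere; per-measure tests
  are reported as-is.
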