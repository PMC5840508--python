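# Methods

## Pipeline

### Wavelet decomposition

Trials are decomposed with the orthonormal (L2-normalized) dyadic Haar
transform via PyWavelets (`haar`, periodization mode). On a dyadic epoch this
is an orthogonal change of basis: `N` samples map to `N` coefficients,
energy is conserved (Parseval) and reconstruction is exact, which the test
suite asserts against an explicitly constructed Haar basis matrix.
Coefficients are stored coarse-to-fine, `[A5 | D5 | D4 | D3 | D2 | D1]`,
time-ascending within each level; this ordering is part of the on-disk
contract. Each coefficient carries its level, translation `k`, approximate
frequency band (dyadic halving of Nyquist) and half-open time support
`[k 2^j, (k+1) 2^j)` samples, with `t = 0` at stimulus onset and 0-based
sample indexing throughout.

Non-dyadic epochs raise an error by default; an optional reflection-padding
flag (`WIConfig.pad_non_dyadic`) pads to the next multiple of `2^levels` and
excludes coefficients supported entirely beyond the original epoch from
selection. Silent padding would alter information estimates, hence the
explicit opt-in.

The Haar wavelet is kept deliberately: the goal is maximal class contrast,
not faithful signal reconstruction, and its rectangular basis makes the
orthonormality properties exact. Smoother mother wavelets are out of scope.

### Coefficient selection

Single-trial coefficients are too noisy to rank directly, so information is
estimated on bootstrap *sub-ensemble averages*: per class, 200 averages of 30
trials drawn with replacement (trials may recur both within and across
averages). Each coefficient's values over the averages are quantized into
4 equal-width bins spanning their min–max range (training data only — the
range is parameter-free and scale-invariant), and the plug-in mutual
information of the (class, bin) histogram is computed in bits with
`0 log 0 := 0`. Class priors in the estimate are the empirical frequencies of
the sub-average set, which are uniform by construction.

No bias correction is applied: the estimator only needs to *rank*
coefficients, and the positive plug-in bias is common to all of them. The 25
highest-information coefficients are selected; ties break deterministically
(coarser level first, then earlier time support, then channel order). In the
multichannel case information is estimated per coefficient of every channel
and the top 25 of the pooled, channel-qualified ranking are taken — no
constraint forces any channel to contribute.

Defaults (`n_subaverages=200`, `trials_per_average=30`, `quant_bits=2`,
`n_select=25`) are deliberately flat optima: the acceptance suite shows <2
percentage points of movement when the sub-average count is swept over
50–400 or the selection size is reduced to 1/8 of the coefficients.

### Decoding

A uniform-prior naive-Bayes classifier with per-(class, coefficient)
Gaussian likelihoods. Variances are floored at `1e-9` times the pooled
per-feature variance (absolute floor `1e-9` for degenerate features) so that
noiseless inputs remain decodable. Uniform priors are literal: class counts
never enter the prediction. Exact ties resolve to the first class in model
order. The likelihood family is this package's choice; any one-dimensional
family would fit the same interface.

Cross-validation is leave-one-out, and the *entire* feature-extraction stage
(sub-ensemble draws, information estimate, selection) is recomputed per fold
from the remaining trials only. Each fold draws from a dedicated RNG
substream keyed by `(seed, trial_index)`, so folds are independent and any
fold can be reproduced bit-exactly in isolation (the no-leakage test does
exactly this). Wavelet decompositions are trial-wise constants and are cached
across folds.

### Significance and maps

The permutation null reruns the full pipeline (including per-fold selection)
on label-shuffled data, 100 shuffles by default, each with an independent
substream keyed by `(seed, shuffle_index)`. The p-value is the proportion of
shuffle performances *strictly above* the observed one; its resolution is
`1/n_shuffles`, and an optional add-one correction `(r+1)/(n+1)` is available
when a nonzero p is needed. On balanced classes the null mean sits at
`1/n_classes`; on unbalanced data it tracks the majority-class proportion —
an apparent >chance shuffle performance there reflects the label imbalance,
not an optimistic bias.

Selection-rate maps report, per coefficient, the fraction of folds in which
it was selected, and aggregate to a channel × time image by averaging the
`n_levels + 1` coefficients (one per scale) whose support covers each
post-stimulus sample.

## Synthetic benchmark generator

The generator emulates a four-class single-channel evoked-potential
experiment: 500 ms post-stimulus epochs at 256 Hz (128 samples), 100 trials
per class, each trial a clean class waveform jittered by a uniform ±5 ms
draw plus background noise scaled so that clean-pattern power over noise
power is exactly 0.33 in every trial.

Class waveforms (amplitude, latency, width of Gaussian components):

| class | components | role |
|---|---|---|
| 1 | (1.0, 150 ms, 12 ms) | sharp early peak |
| 2 | (0.65, 150 ms, 28 ms) | broad early peak, same latency and same energy as class 1 |
| 3 | (0.8, 210 ms, 12 ms) | slightly smaller, later peak |
| 4 | (0.55, 190 ms, 12 ms) + (0.55, 265 ms, 18 ms) | two-component complex |

Classes 1 and 2 are energy-matched (`A^2 sigma` equal): they differ in
*shape*, not in power, so the per-trial SNR constraint treats them
identically and no class information leaks through the noise level. By
design, peak amplitude and latency separate {1, 2} from {3, 4} but not the
members of each pair; the width pair (1, 2) and the complex (4) are only
resolvable from waveform shape. This is what produces the benchmark's
characteristic hierarchy — peak-amplitude decoding ~38%, amplitude+latency
~60%, wavelet-information ~96% (four balanced classes; chance 25%).

Background noise is phase-randomized noise shaped to a target amplitude
spectrum: a broadband floor (`1/f^alpha` in power; default exponent 0) plus
a Gaussian alpha bump at 10 Hz (sigma 2 Hz) whose default gain puts the
alpha-band power at ~3× the floor. Uniform phases with Hermitian symmetry
are attached on the rFFT grid and inverted; DC is zero, so every realization
is exactly zero-mean, and only the spectral *shape* matters because the SNR
scaling sets the total power. With total noise power pinned by SNR = 0.33, a
steep 1/f floor would concentrate the noise budget below the ERP band and
make single-trial peaks unrealistically clean; the flat-floor default keeps
the in-band noise at a level consistent with the benchmark's intended
difficulty. The exponent, bump center, width and gain are all configurable.

What the generator does **not** emulate: eye-blink/muscle artifacts,
trial-to-trial amplitude variability of the evoked components, non-stationary
background (the surrogate is stationary within the epoch), volume-conduction
correlations between channels (multichannel noise is independent per
channel), and pre-stimulus baselines by default (`t0_ms = 0`). Passing tests
on this benchmark therefore demonstrates the pipeline's statistical
machinery, not robustness to artifacts or correlated-noise topographies.

RNG design: one `SeedSequence` per dataset, spawned per channel and split
into jitter and noise substreams, so channel `c` of an `n`-channel dataset
equals channel `c` of any wider dataset with the same seed.

## Peak-feature baseline

The comparison decoder extracts the single-trial peak amplitude (and
optionally latency) of a component window after linear detrending, and feeds
it to the same naive-Bayes/LOO machinery. Interior local extrema are
preferred; a window with none (monotone segment) yields the edge extremum
with an `edge` flag. For epochs that include pre-stimulus samples a
simplified denoising step is available: per scale, coefficients whose
magnitude z-scored against the pooled baseline-period coefficient
distribution falls below a threshold (default z* = 3) are zeroed before
reconstruction. This is a deliberately simple baseline-referenced shrinkage,
not a port of any published denoising algorithm. The benchmark epochs start
at stimulus onset, so there the baseline decoders use detrended raw trials
and denoising degrades to the identity with a warning.

Peak windows are an a-priori, supervised choice — that is the point of the
comparison: the peak method needs the experimenter to know where and when
the component lives, the wavelet-information pipeline does not. The library
default is the whole epoch; the benchmark experiments use the component
window 50–450 ms, which contains every class component (150–265 ms) with
generous margin and excludes only the component-free epoch edges.

## Problem sizes

The shipped experiments use the full benchmark geometry (400 trials, 128
samples): a complete leave-one-out run takes ~2 s on one core, the 100-
shuffle permutation null a few minutes, and the whole acceptance script
about five minutes. The multichannel checks use 9 channels (1 informative +
8 noise); the benchmark statistics average 5 independent dataset seeds.

## Known limitations

- The plug-in information estimate is biased upward for small sub-average
  counts; rankings are stable but the absolute bit values should not be
  reported as information estimates.
- Haar bands are approximate: a pure 10 Hz tone leaks ~20% of its energy
  below the nominal 8–16 Hz band; band labels are for orientation only.
- Leave-one-out is the only cross-validation scheme; for very large trial
  counts a k-fold variant would be cheaper but is not implemented.
- The permutation p-value has resolution `1/n_shuffles`; p = 0 means "above
  the entire null", not an exact zero.
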