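# Methods

This note records the models, parameter choices and numerical decisions
behind `emgclean`, and what the synthetic experiments do and do not show
about real recordings.

## The cleaning model

The contaminated channel is modelled as x(t) = s(t) + v(t): cortical EEG
s plus volume-conducted facial EMG v, spectrally overlapping, with
in-burst SNR possibly far below 0 dB. No external noise reference is
assumed. Instead, a reference is synthesized from x itself: a
decomposition x = Σₘ cₘ concentrates the burst energy in components whose
noise-region amplitude is small, so per-component soft-thresholding
tcₘ = sign(cₘ)(|cₘ| − k·σₘ)₊, with σₘ the component SD over the
noise-only region, suppresses the background while passing the bursts.
The thresholded sum is the EMG reference; x minus that sum is the EEG
reference. An adaptive FIR canceller driven by the reference then removes
from x whatever the reference linearly predicts (EMG reference → cleaned
signal is the error; EEG reference → cleaned signal is the output). The
selection rule is the only reading under which both reference kinds
remove EMG, and is stated explicitly in `adaptive.clean_eeg`.

The soft-thresholding subtraction direction is contaminated − EMG
reference, so the EEG reference keeps EEG polarity; the quadratic
cancellers are indifferent to the sign.

## Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| non-linear detrend window | 20 | ms | 100 samples at 5 kHz; follows slow drift, passes oscillations above ~25 Hz |
| outlier threshold | mean ± 10·SD | µV | of the EMG-contaminated region; replacements are literal N(0,1) draws, i.e. near-zero on a µV scale |
| max components | 10 | — | all decompositions |
| SSA/CiSSA window | 100 | samples | embedding length |
| SSA / EMD-PCA variance retention | 80 | % | descending eigenvalue order |
| EEMD ensembles / noise | 5 / 0.2·SD | — | seeded per member |
| wavelet | coif5 | — | up to 9 levels → ≤ 10 band components |
| soft-threshold k | 1.5 | — | conventional shrinkage level; swept 0.1–2.0 for the feature curves |
| LMS step µ | 1e-7 | — | appropriate for µV²-scale reference power |
| NLMS step µ̃ / ε | 0.1 / 1e-7 | — | power-normalized update; order 4 |
| RLS λ / δ | 0.9999 / 1e-7 | — | see below |
| filter order | 10 (NLMS 4) | taps | — |
| envelope window | 100 | ms | moving RMS |
| burst level | mean + 3·SD, floored at 0.1·P95(env) | — | see below |
| burst cleanup | merge < 200 ms, drop < 400 ms | ms | protocol timing margins |
| evaluation window | 1 | s | per-window RMS, median across windows |
| AR model order / grid | 10 / 0.01 | — / Hz | Yule-Walker via biased autocovariances (Levinson-Durbin) |
| EEG bands | Delta 0.5–4, Theta 4–7, Alpha 7–13, Beta 13–30, Gamma 30–70 | Hz | closed left, open right |

## Numerical choices

**EMD.** Envelopes interpolate extrema with monotone piecewise cubics
(PCHIP), with up to two extrema mirrored past each record edge. The sift
stop is the ratio-of-sums criterion Σ(h_prev − h)² / Σh_prev² ≤ 0.2
(bounded even at zero crossings, unlike the pointwise sum of ratios),
max 100 sifts; extraction stops below two maxima or minima. The procedure
telescopes, so IMFs + residual reconstruct the input exactly.

**SSA.** Eigendecomposition of the lagged covariance of the trajectory
matrix; elementary components are diagonal-averaged rank-1 terms
(anti-diagonal sums of an outer product are a convolution, which is how
they are computed). Components are retained in descending eigenvalue
order until 80% cumulative variance; the remainder is appended as a final
component so reconstruction-based stages can use the full sum.

**CiSSA.** The circulant approximation's eigenvectors are Fourier
vectors; conjugate bins (k, L−k) are paired so components are real, and
the L/2+1 bins are reduced to ≤ 10 groups by repeatedly merging the
smallest-energy group into its smaller-energy adjacent neighbour, which
preserves frequency adjacency and keeps dominant bins intact.

**EMD-PCA.** Principal axes of the *uncentered* second-moment matrix of
the IMF stack, so retaining all axes reproduces the IMF sum exactly; each
component is one axis's contribution to that sum. Axes are kept to 80%
variance and no thresholding is applied — the truncation itself is the
de-noising.

**RLS forgetting factor.** λ is genuinely open in this design. A
burst-gated EMG reference leaves the canceller almost without excitation
during the ≥ 2 s neutral gaps; with λ = 0.999 (memory ≈ 1000 samples at
1 kHz) the inverse-correlation matrix inflates inside a single gap and
the taps swing to fit the background from the tiny baseline, destroying
the signal at burst onsets (measured GL ≈ +50 dB). λ = 0.9999 straddles
gaps and bursts (GL ≈ 0, GH ≈ −10 dB) and is the default; both λ and the
initialization δ are exposed in `FilterConfig`.

**Burst binarization.** The level is envelope mean + 3·SD over the
declared noise window, with two robustness guards: the noise-stat
interval is trimmed by half an envelope window (so adjacent burst energy
cannot leak in), and the level is floored at 10% of the envelope's 95th
percentile — after soft-thresholding, a clean channel's noise window can
be nulled almost perfectly, and without the floor the level collapses to
numerical residue. The floor scales with the envelope (the mask is
invariant to amplitude scaling) and sits below the noise-rule level on
burst-free records. Cleanup merges sub-200 ms gaps *before* dropping
short runs, so a burst briefly dipping under the level is not discarded
piecewise; the 400 ms duration floor rejects background excursions while
passing every protocol contraction, because the moving-RMS envelope
widens true bursts and the shortest contraction is 500 ms.

**Evaluation windows** are tiled over the concatenated samples of each
region, so 0.5 s bursts (a third of the protocol) still contribute to the
1 s windows; "20 log" is taken as base-10 dB. The normalized distance is
‖u−v‖₂/(‖u‖₂+‖v‖₂): symmetric, zero iff equal, bounded by 1. The spectral
grid defaults to 0.01 Hz; tests use 0.1 Hz, and the features are
grid-converged at that resolution. Degenerate inputs raise: constant
signals (singular autocorrelation), masks without noise samples, regions
shorter than one window, zero-mass spectra.

## The synthetic generator

It emulates the contraction-protocol structure that the method's
evaluation depends on: per muscle and eye condition, 15 contractions
(5 × 3 s, 5 × 1 s, 5 × 0.5 s, seeded random order), each followed by a
2 s neutral gap; an open-eyes block then a closed-eyes block; 150 events
per participant and 22.5 s of contamination per muscle block. EEG is a
superposition of band-limited Gaussian noise per canonical band (default
variances 25/9/16/4/1 µV², ≈ 7 µV RMS) with alpha variance multiplied by
4 while eyes are closed. EMG is 20–450 Hz Gaussian noise gated by a
trapezoidal envelope (50 ms ramps inside the event, so mask support
equals event support) over a −40 dB always-on baseline. The mixture gain
is solved exactly from the mask-high powers, so the requested in-burst
SNR (default −10 dB) is achieved to rounding. Muscle order is fixed;
only duration-class order is randomized within a block.

What it does **not** model: volume-conduction spatial structure and
electrode montage (single channel only), eye-blink/ECG artifacts,
non-Gaussian EMG statistics, motor-unit firing structure,
muscle-specific spectra (all five muscles share one band), impedance
drift, or line interference. Passing tests therefore demonstrate the
pipeline's internal correctness and its behaviour under controlled
burst-gated broadband contamination — not performance on any particular
clinical recording.

## Problem sizes

Tests and the acceptance script run at fs = 1 kHz on records between 10 s
(decomposition completeness) and 315 s (a 3-muscle × 2-condition protocol
subset for the −10 dB cancellation experiment, mirroring the full
protocol's structure at a third of its length); burst detection and the
k-sweeps use single 54.5 s muscle blocks. These sizes keep every spectral
band and protocol duration class represented while staying desk-scale.

## Known limitations

- The 20 ms median detrend passes only content above roughly 25 Hz; it
  removes most delta/theta/alpha energy along with the drift. Both the
  filtered and unfiltered signals pass through the same stage, so the
  dB features compare like with like, but absolute band powers after
  detrending are not physiological.
- LMS at µ = 1e-7 adapts very slowly on desk-scale records (GH barely
  below 0 after 300 s); it is retained for completeness with its
  conventional step.
- EEMD averages IMFs across ensemble members without mode alignment;
  mode mixing between members blurs component boundaries.
- With an EEG-kind reference the least-squares compromise can inflate the
  background when the reference retains correlated burst residue; the
  EMG-kind reference route is the robust default on heavily contaminated
  synthetic data.
- EDF files are read (via mne) but not written; delimited text is the
  round-trip format.
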