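# emgclean

Single-channel attenuation of facial-EMG contamination in EEG.

Scalp EEG rarely exceeds 100 µV, and the electrical activity of facial
muscles — Frontalis, Masseter, Zygomatic, Orbicularis Oris and Orbicularis
Oculi — reaches every electrode through volume conduction at amplitudes
that can bury the cortical signal (in-burst signal-to-noise ratios of
−10 dB and below). Because surface EMG overlaps the EEG spectrum in
essentially every band, frequency-selective filtering cannot separate
them. `emgclean` implements a single-channel alternative for people who
have no spare electrodes to spend on a noise reference: the reference is
*manufactured from the contaminated channel itself* by decomposition and
shrinkage, then used to drive an adaptive noise canceller.

## Method

For a contaminated channel x:

1. **Detrend** — subtract the least-squares line, then a non-linear trend
   (20 ms windowed medians, PCHIP-interpolated); replace amplitude
   outliers beyond mean ± 10·SD of the contaminated regions.
2. **Mask** — a binary contamination signal marks EMG bursts, either
   supplied or detected (detrend → EMD → soft-threshold → moving-RMS
   envelope → threshold → morphological cleanup).
3. **Decompose** — x = Σₘ cₘ by EMD, EEMD, SSA, CiSSA, multilevel wavelet
   (coif5), or EMD-PCA, capped at 10 components.
4. **Shrink** — each component is soft-thresholded,
   tcₘ = sign(cₘ)·(|cₘ| − tₘ)₊ with tₘ = k·SD(cₘ | noise region), k = 1.5
   by default. Summing gives the **EMG reference** (bursts preserved,
   background suppressed); subtracting that from x gives the **EEG
   reference**. EMD-PCA skips the shrinkage: its retained principal axes
   (≥ 80% variance) are already the de-noised reconstruction.
5. **Cancel** — LMS, NLMS, RLS, or a batch FIR Wiener filter driven by
   the reference; the cleaned signal is the error d − y for an EMG
   reference and the output y for an EEG reference.
6. **Score** — windowed-RMS median features
   GL = 20·log₁₀(Xout₀′/Xin₀′) and GH = 20·log₁₀(Xout₁′/Xin₁′)
   (subscript 0: noise-only regions, 1: EMG regions), plus GXin/GXout,
   soft-threshold k-sweep curves whose normalized Euclidean distance
   d = ‖GL−GH‖/(‖GL‖+‖GH‖) quantifies contamination, and Yule-Walker
   AR(10) spectra (median frequency and its power, per EEG band).

A protocol-faithful synthetic generator (5 muscles × 15 contractions of
3/1/0.5 s per eye condition, 2 s neutral gaps, eyes-closed alpha
enhancement, trapezoid-gated band-limited EMG mixed at a controlled
in-burst SNR) makes every stage testable with ground truth.

## Worked example

```python
from emgclean import (
    FilterConfig, SynthParams, clean_eeg, feature_curve, generate_protocol,
    make_emg_reference, mix, normalized_distance, synthesize_eeg,
    synthesize_emg, time_features,
)
from emgclean.synth import EyeCondition, Muscle

timeline = generate_protocol(1, seed=1, fs=1000,
                             muscles=[Muscle.MASSETER],
                             eye_conditions=[EyeCondition.OPEN])
params = SynthParams(fs=1000, seed=1)
eeg = synthesize_eeg(timeline, params)
emg, mask = synthesize_emg(timeline, params)
contaminated = mix(eeg, emg, mask, snr_db=-10.0)   # 54.5 s, 15 bursts

emg_ref = make_emg_reference(contaminated, "ssa", mask, k=1.5,
                             params={"var_target": 1.0})
cleaned = clean_eeg(contaminated, emg_ref,
                    FilterConfig(method="rls", reference_kind="emg"))
tf = time_features(contaminated, cleaned, mask)
print(f"GL = {tf.GL:+.2f} dB, GH = {tf.GH:+.2f} dB")

curve = feature_curve(contaminated, "ssa", mask, params={"var_target": 1.0})
print("contamination distance:",
      round(normalized_distance(curve.GL_of_k, curve.GH_of_k), 3))
```

prints

```
GL = -0.94 dB, GH = -11.27 dB
contamination distance: 0.865
```

GH ≈ −11 dB means the canceller removed over 90% of the in-burst power;
GL ≈ −1 dB means the EMG-free background was left essentially untouched —
exactly the asymmetry a good canceller should show. The contamination
distance near 0.87 reflects the heavy −10 dB mixture; on the clean EEG
channel the same metric falls below 0.1.

The same steps are available from the shell:

```sh
emgclean synth session/ --fs 1000 --snr-db -10 --seed 1
emgclean filter session/contaminated.csv session/mask_intervals.csv out.csv \
    --method rls --decomp ssa --reference emg
emgclean sweep-k session/contaminated.csv session/mask_intervals.csv curve.csv
```

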