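# cryscope

Multimodal analysis of newborn cry: links the acoustics of crying to
concurrent EEG band power, NIRS oxygenation / heart rate and
behavioural COMFORT scores across three arousal conditions — resting,
cry and distress — and trains classifiers that recognise distress
cries automatically.

Who it is for: researchers in neonatal physiology and infant-cry
analysis who want a tested, end-to-end reference implementation of
this analysis style, runnable entirely on synthetic sessions (the
generator is a first-class module with known ground truth, so every
stage is verifiable without access to clinical recordings).

## What it computes

**Cry acoustics.** Recordings are segmented into cry episodes (CEs)
and cry units (CUs, single expiratory vocalisations). Per episode:
`cryCE` and `unvoicedCE` (seconds of vocalised / silent time and their
fractions). Per unit: the F0 contour restricted to 200–1200 Hz with
mean/min/max/SD, the fraction of high-pitch (F0 ≥ 800 Hz) and
hyper-phonated (F0 ≥ 1000 Hz) frames, vocal-tract resonances F1–F3
(after a 10 kHz low-pass), local jitter
`mean|T_{i+1} − T_i| / mean T_i`, local shimmer (the same statistic on
cycle amplitudes), and the harmonics-to-noise ratio
`HNR = 10·log10(r / (1 − r))` with `r` the correlation between
consecutive glottal cycles. MFCC summaries and fixed-size log-mel
spectrograms feed the classifiers.

**EEG.** 8 channels (F3 F4 C3 C4 T7 T8 P3 P4) at 512 Hz: 1–45 Hz
band-pass, bad-channel detection, spherical-spline interpolation of at
most one bad channel, average reference, 4-s epochs tiled inside each
condition interval, 200 µV amplitude rejection, Welch relative power
in δ (1–4), θ (4–8) and α (8–12 Hz) normalised by total 1–45 Hz power,
and percent change of each condition against resting (resting = 100 %).

**NIRS.** rSO2 / SpO2 / pulse-rate samples every 2 s: flat-line removal
(60-s window SD < 0.5), 1.5·IQR outlier fences, condition segmentation
with 15 s trimmed from each end, and segment-mean plausibility floors
(SpO2 ≥ 80 %, rSO2 ≥ 50 %, PR ≥ 70 bpm).

**COMFORT.** Six behavioural items (alertness, agitation, crying, body
movements, muscular tone, facial tension), each 1–5; totals range 6–30.

**Integration.** Balanced subsampling, Mann–Whitney U, Kruskal–Wallis
with Dunn's post-hoc and Holm–Bonferroni adjustment, bootstrap
Tukey–Kramer after one-way ANOVA (10,000 resamples), the Spearman
correlation matrix across all features, and tie-corrected Kendall
concordance W per (audio feature, other-modality feature) pair and
condition, with W ≥ 0.5 / W > 0.7 agreement flags.

**Classification.** Cry vs distress per unit: a 500-tree random forest
on 26-value MFCC summaries and a small convolutional network
(3 conv/batch-norm/max-pool blocks with 16/32/64 filters) on 64×59
log-mel spectrograms, 80/20 random split, reported as a confusion
matrix with distress as the positive class plus accuracy, sensitivity
and specificity.

## Worked example

```python
from cryscope import RunConfig, SimulateConfig, run_all

cfg = RunConfig(seed=7, out_dir="demo_out", classifier="rf",
                classifier_n_units=120,
                simulate=SimulateConfig(n_cry_episodes=1,
                                        n_distress_episodes=1,
                                        resting_block_s=40.0))
art = run_all(cfg)
print(art["report"]["counts"])
print(art["report"]["classifier"]["rf"])
print(art["feature_table"][["condition", "f0_mean", "hnr", "PR", "comfort_total"]].round(3))
```

prints (seed 7):

```
{'units': 60, 'episodes': 2, 'eeg_bad_channels': [], 'eeg_n_epochs': 51,
 'eeg_n_rejected': 0, 'nirs_segments': 5, 'comfort_records': 2}
{'tp': 11, 'fp': 0, 'tn': 13, 'fn': 0, 'accuracy': 1.0,
 'sensitivity': 1.0, 'specificity': 1.0}
  condition  f0_mean     hnr       PR  comfort_total
0       cry  460.635  12.026  143.662           17.0
1  distress  416.486   6.740  145.512           18.0
```

Reading it: the 30 units of the cry episode average F0 ≈ 461 Hz with
HNR ≈ 12 dB while the distress episode is lower-pitched and noisier
(≈ 416 Hz, ≈ 6.7 dB), matching the generator's condition profiles;
pulse rate is elevated during both crying bouts relative to the
resting baseline of ~120 bpm; the COMFORT total is higher under
distress. The random forest separates the two unit classes perfectly
on this easy synthetic validation set (11 distress and 13 cry units,
no errors).

The same pipeline is scriptable from the shell:

```sh
cryscope synth --seed 7 --out session/
cryscope acoustics --in session/audio.wav --ann session/annotations.tsv --out features.csv
cryscope run-all --seed 7 --out full_run/
```

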