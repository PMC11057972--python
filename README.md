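# myospect

Spectral characterization of leg-muscle surface electromyograms (EMG):
signal conditioning, spike-triggered estimation of motor unit action
potential (MUAP) waveforms, periodogram median-frequency analysis,
fatigue half-split testing, and the group-level statistics — together
with an interference-pattern EMG simulator so the entire pipeline can be
validated on synthetic cohorts with known ground truth.

## Who this is for

Researchers modeling or analyzing surface EMG of the ankle muscles —
soleus (SO), medial and lateral gastrocnemius (MG, LG), and tibialis
anterior (TA) — who need reproducible spectral summaries of myoelectric
signals: the median frequency (MDF) of interference-pattern recordings
at low contraction intensities (5–20% of maximum voluntary contraction,
MVC), and the morphology (MDF, duration, phase count) of surface MUAP
waveforms estimated by spike-triggered averaging. The synthetic cohort
generator doubles as a test bed for EMG simulation work: it builds
interference signals as sums of Hermite–Rodriguez MUAP models driven by
renewal-process discharge trains.

## The analysis in brief

A conditioned recording is reduced to its **median frequency**: with a
rectangular-window periodogram `P_1 … P_M` (bin spacing `fs/N`, no zero
padding), the MDF is the frequency that splits the spectrum into halves
of equal power,

```
sum_{i<=MDF} P_i = sum_{i>=MDF} P_i = (1/2) sum_{i=1..M} P_i
```

resolved on the discrete grid as the lowest bin whose cumulative power
reaches half the total. A 75 ms MUAP window at 20 kHz gives 13.333 Hz
bins; a 30 s interference segment gives 1/30 Hz bins. Conditioning is a
zero-phase Butterworth band-pass (20–1000 Hz) plus a zero-phase notch
comb on 60 Hz and its odd harmonics up to 900 Hz, followed by removal of
the first/last 5 s and selection of the initial 30 s. Fatigue is probed
by comparing the MDFs of the two 15 s halves with paired t-tests;
between-muscle and between-intensity effects with between-subject
one-way/two-way ANOVAs (Kruskal–Wallis as a non-parametric check,
Bonferroni-corrected post hoc contrasts).

MUAP waveforms are estimated by averaging at least one hundred 75 ms
surface-EMG windows centered on motor-unit discharge instants, which are
detected as supra-threshold peaks (on the surface channel itself, or on
a simultaneous intramuscular channel), clustered by waveform similarity,
quality-controlled by a peak-to-peak/baseline SNR, and de-duplicated
across recordings keeping the highest-SNR copy.

## Worked example

```python
import numpy as np
from myospect import (generate_study_cohort, run_full_analysis)

signals, truth = generate_study_cohort(n_subjects=20, fs=2500.0, seed=0)
report = run_full_analysis(signals)
muscle = report.get("two-way ANOVA", "muscle")
print(f"muscle effect: F{muscle.df} = {muscle.statistic:.1f}, p = {muscle.p_value:.2g}")
means = report.cohort.data.groupby("muscle")["mdf_full"].mean().round(1)
print(means.to_dict())
```

prints (seed 0):

```
muscle effect: F(3, 228) = 74.0, p = 1.9e-33
{'LG': 136.2, 'MG': 126.5, 'SO': 124.1, 'TA': 100.2}
```

The four numbers are the cohort-mean median frequencies in Hz. TA sits
lowest (its longer-duration MUAPs concentrate power at lower
frequencies) and the gastrocnemii highest, with the muscle main effect
overwhelmingly significant at n = 20 subjects per cell — the pattern the
simulator is calibrated to produce and that the statistical layer is
designed to detect.

A command-line interface mirrors the stages (`myospect preprocess`,
`mdf`, `fatigue`, `muap`, `simulate`, `report`); see `myospect --help`.

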