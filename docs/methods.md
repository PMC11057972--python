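# Methods

## Signal model and scope

Surface EMG at low constant force is modeled as an interference pattern:
the superposition of motor unit action potential (MUAP) trains,

```
x(t) = sum_u sum_k h_u(t - t_uk) + n(t)
```

where `h_u` is unit *u*'s surface waveform, `t_uk` its discharge
instants, and `n` additive white Gaussian noise. The package implements
the analysis side (conditioning, spectral summaries, statistics) and the
synthesis side (the model above) symmetrically, so every analysis stage
can be validated against known generating parameters.

The four muscles handled are the ankle plantar flexors soleus (SO),
medial gastrocnemius (MG) and lateral gastrocnemius (LG), and the
dorsiflexor tibialis anterior (TA). Volume-conductor/finite-element
simulation, motor-unit recruitment-threshold models, and full
interactive EMG decomposition are out of scope.

## Conditioning

Surface recordings pass through, in order: a zero-phase Butterworth
band-pass (order 4 per pass, applied forward–backward, cutoffs
20–1000 Hz), a zero-phase notch comb at 60, 180, 300, 420, 540, 660,
780 and 900 Hz (second-order IIR notches, −3 dB bandwidth 2 Hz each,
forward–backward), removal of the first and last 5 s (which also
absorbs filter transients — no additional padding is applied), and
selection of the initial 30 s analysis segment. Intramuscular channels
are analyzed raw. All filters are evaluated in second-order-sections
form; direct-form polynomials of effective order 8 at a 20 kHz rate are
numerically fragile. The Butterworth order and notch bandwidth are
conventional choices for surface EMG; they satisfy the contract of
≥ 40 dB attenuation at each notch/stopband target with ≤ 1 dB ripple in
the passband, but exact sample-level replication of any particular
laboratory's filtered traces is not claimed.

## Spectral summaries

Power spectra are plain rectangular-window, mean-removed periodograms
with no zero padding, expressed as power per bin so that the bins sum to
the segment's mean square (Parseval). Bin spacing is therefore `fs/N`:
13.333 Hz for 75 ms MUAP windows at 20 kHz, 1/30 Hz for 30 s segments,
1/15 Hz for the 15 s fatigue halves.

The median frequency (MDF) is the discrete median of the spectrum:
the lowest-indexed bin whose cumulative power first reaches half the
total. No interpolation between bins is performed — the convention is
deterministic and, at the 1/30 Hz interference resolution, numerically
immaterial; at the 13.333 Hz MUAP resolution it quantizes the MDF to the
bin grid, which is why bin-level tolerances appear throughout the tests.
The DC bin is excluded (mean removal empties it; the band restriction to
20–1000 Hz used for interference signals excludes it anyway). MUAP
waveform MDFs use the full one-sided axis, since the averaging window is
already band-limited by prior conditioning.

Fatigue is assessed by the half-split: MDFs of the first and second 15 s
halves of the 30 s segment, compared across subjects with a paired
t-test per muscle and intensity. Spectral compression (second half
lower) indicates myoelectric fatigue; stationary contractions give
mean-zero differences.

## MUAP estimation

Discharge detection is a deliberately simple, fully automatic stand-in
for interactive decomposition software: local maxima of |x| above
`5 ×` a median-absolute-deviation baseline SD, separated by a 10 ms
refractory distance, aligned to the extremum sample. It is validated
against ground-truth discharge times on synthetic data only; it is not
intended to decompose real interference-pattern recordings at high
force.

Triggers are grouped into putative units by greedy template matching on
(peak-to-peak amplitude, phase count, duration): a snippet joins a
cluster when its zero-lag normalized cross-correlation with the running
centroid is ≥ 0.8 and amplitudes agree within 1.5-fold; amplitude is
deliberately a grouping feature, so scaled copies of one shape are
distinct units. The spike-triggered average is the sample-wise mean of
75 ms windows centered on each trigger (half-window each side);
edge-clipped windows are dropped rather than zero-padded, and fewer than
100 usable windows is an error, not a degraded estimate.

Waveform quality is peak-to-peak amplitude over the SD of the outer 10%
of the window (the MUAP energy is centered, so the edges approximate
residual noise); waveforms under SNR 5 are flagged for discard.
Near-duplicates (best-lag normalized cross-correlation ≥ 0.95 within a
2-fold amplitude band, grouped transitively) keep only the highest-SNR
member, mirroring the rule that one unit estimated from several
recordings contributes once.

Duration is the span of sustained (≥ 0.5 ms) excursion beyond
`3 ×` the edge-baseline SD, with a 1%-of-peak relative floor for
noise-free synthetic waveforms; the phase count is the number of
supra-threshold lobes of alternating sign within that span. These are
automated surrogates for cursor-based manual measurements; they
reproduce rank ordering and scaling properties (doubling the waveform
time scale doubles the measured duration) but are not calibrated to
match any particular human rater's absolute numbers.

## The simulator and its calibration

MUAP shapes are the first two Hermite–Rodriguez functions
(`h1(t) = A (t/λ) exp(−(t/λ)²)`, `h2(t) = A (1 − 2(t/λ)²) exp(−(t/λ)²)`),
drawn with equal probability; by Fourier scaling the MDF of either order
is proportional to `1/λ`. Discharge trains are Gaussian-interval renewal
processes (default rate 8–12 /s, interval CV 0.15, 2 ms interval floor,
random initial phase); parameter combinations that would push
non-negligible interval mass onto the floor are rejected. Contraction
intensity maps to recruitment plus rate coding: active units scale
proportionally with %MVC (n, 2n, 4n at 5/10/20%) and mean rates ramp
linearly 8 → 12 /s. Unit amplitudes are log-normal (σ = 0.3); additive
noise SD defaults to 0.02 against unit-scale amplitudes, small enough
that in-band noise shifts MDFs by well under a bin even at reduced
sampling rates.

Per-muscle λ means are calibrated once, by bisection against the
package's own periodogram/MDF code. Two statistics are distinguished.
For interference cohorts the calibration matches the median of the
equal-amplitude order-1/order-2 *mixture spectrum* (an interference
signal's spectrum is the energy-weighted sum of its units' spectra; at
equal amplitude the order-2 waveform carries about three times the
order-1 energy) to the intensity-pooled group means SO 124.0, MG 127.9,
LG 136.9, TA 98.0 Hz, giving λ = 2.511, 2.442, 2.281, 3.179 ms. For
isolated-MUAP populations the reported group summary is the *mean of
per-waveform MDFs, measured on the 75 ms window's 13.333 Hz bin grid*,
so the calibration evaluates exactly that statistic (balanced over the
two orders and, by quantile quadrature, over the generator's λ jitter)
against SO 147.6, MG 139.5, LG 140.9, TA 102.7 Hz, giving λ = 1.983,
2.084, 2.075, 2.827 ms. Both
constant sets are frozen in `synthetic_data` and can be refit with
`scripts/calibrate_lambdas.py`. Because a two-parameter waveform family
ties duration to MDF through the single scale λ, matching the MDF
targets fixes the implied durations (≈ 9–13 ms by the automated
measure, TA longest); they land near, but are not separately fitted to,
observed duration means.

Between-subject MDF spread (total λ CV 11% per muscle) is decomposed
into a factor shared across a subject's muscles (CV 10% — tissue
filtering between fibers and electrode slows all of a subject's surface
waveforms together) and a muscle-specific residual. This gives realistic
per-muscle MDF SDs (≈ 10–20 Hz at the calibrated means) while keeping
within-cohort muscle *contrasts* much less noisy than the marginal
spreads — which is also what makes the observed between-muscle ordering
detectable at n = 20.

What the simulator does **not** emulate: volume-conduction shape changes
with electrode position, motor-unit synchronization, recruitment
thresholds, fatigue dynamics (cohorts are stationary by construction),
and the heavy-tailed unit-amplitude distributions of real pools. Tests
passing on synthetic cohorts therefore validate the pipeline's
correctness and calibration, not the physiological fidelity of any
particular real recording.

## Statistics

ANOVAs are classical between-subject fixed-effects decompositions; the
two-way design must be balanced and fully crossed (the study design is,
at 20 subjects per cell), so type I/II/III sums of squares coincide and
unbalanced input is rejected rather than silently re-weighted. When the
two-way interaction is significant, follow-up one-way ANOVAs run within
each factor level. Post hoc muscle contrasts are all 6 pairwise t-tests,
Bonferroni-corrected (`p × 6`, capped at 1). Kruskal–Wallis (with tie
correction) is reported alongside as a non-parametric confirmation, not
as a gate; Shapiro–Wilk checks normality per muscle. Paired t-tests on
the half-split MDFs raise on zero-variance differences instead of
reporting a degenerate statistic. α = 0.05, two-sided, throughout.

## Problem sizes and numerical choices

Synthetic-cohort simulations in the tests and the acceptance script run
30 s signals at a 2.5 kHz sampling rate: the generated spectra lie
entirely below 1 kHz, so reducing the rate from the 20 kHz acquisition
default changes runtime and nothing else (filter/notch designs remain
valid against the 1.25 kHz Nyquist). Statistical calibration uses 200
replicates for the paired-t type-I rate and 20 cohort seeds for
power/ordering; the acceptance script uses 100 replicates and 10 seeds.
MUAP-level property checks (spike-triggered-average convergence,
Campbell variance, spectral scaling) run at the full 20 kHz.

Degenerate inputs fail loudly by design: constant signals have no
spectrum, zero total power has no median, all-tied samples have no rank
statistic. The only silent fallbacks are the ones a pipeline needs to
keep running: a zero-variance signal yields an empty trigger set (with a
warning), and a zero-noise baseline yields an infinite SNR sentinel.

## Known limitations

- The spike detector/clusterer is validated on synthetic data only and
  will not resolve superimposed MUAPs in dense real recordings.
- Automated duration/phase measurements are threshold-based surrogates;
  absolute agreement with manual measurements is not claimed.
- The discrete (no-interpolation) MDF convention can differ from
  interpolating implementations by up to one bin — 13.333 Hz for MUAP
  windows — which dominates the tolerance when comparing MUAP MDFs.
- Deposit loading auto-detects common layouts (CSV/HDF5, muscle labels
  in file or directory names) and may need extension for other
  arrangements of the published dataset.
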