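# Methods

This note documents the models, measurement definitions, numerical choices
and limitations behind `synaptofilter`. Conventions: time in seconds from
sweep start, currents in pA (inward negative at −70 mV), image indices
`(channel, z, y, x)` 0-based, pixel sizes in µm. Every results table
carries the configuration hash and RNG seed.

## Evoked EPSC measurement

Amplitude is the absolute difference between the mean over a 1 ms window
centred on the EPSC peak and a 1 s baseline window immediately before the
stimulus onset. The peak is the most negative deflection in a configurable
search window, by default 2–50 ms post-stimulus with the first 2 ms blanked
to exclude the stimulation artefact. Within paired/train stimulation the
first pulse uses the 1 s baseline; later pulses are referenced to the mean
over 1 ms immediately before each stimulus. This local baseline removes the
residual decay of the preceding EPSC without extrapolating a fit; with an
8 ms decay kernel the residual at 50 ms is <1%, and on noiseless synthetic
pairs the estimator agrees with the generative recursion to within 2% at
50, 80 and 100 ms inter-stimulus intervals (asserted in tests). Amplitudes
are reported as positive magnitudes; traces are stored signed.

Measurements below a configurable noise floor (default 1 pA) are returned
with a flag, not raised; ratios (PPR, train ratio) are refused with an
explicit error when the first-pulse amplitude is under the floor, because
a near-zero denominator makes the ratio meaningless.

Decay τ comes from a nonlinear least-squares fit of `A·exp(−t/τ) + c` from
the peak onward, initialised with the observed time-to-1/e and spanning
five rough time constants. Fits that fail to converge or land outside
(0.1, 500) ms are reported absent rather than fatal. Note the generative
kernel is a *double* exponential; the single-exponential fit recovers its
decay constant to within a few percent once the rise has completed, which
is also how the original measurement was defined.

Input resistance uses Ohm's law on the −5 mV, 100 ms test pulse: the
steady-state current is the mean of the last 20 ms of the pulse against a
50 ms pre-pulse baseline, so a membrane time constant of ~10 ms has fully
settled (error <0.1%).

Normalization divides each sweep's amplitude by the mean over the last
5 min of baseline-epoch sweeps; the baseline window therefore averages to
100% by construction. The per-cell summary is the mean normalized
amplitude over an epoch, and group tables carry n, mean and SEM (SEM is
absent for n < 2).

## Plasticity metrics

Train analysis measures all pulses with the local-baseline rule and
reports the full per-pulse vector plus the last/first ratio. LTD magnitude
is the mean normalized first-pulse amplitude over timestamps in
[induction end + 600 s, induction end + 1200 s]; timestamps, not sweep
indices, define the window, so irregular acquisition is handled correctly.
Induction-epoch sweeps are excluded from the normalized time course.

## Spontaneous-event detection

The detection signal is the negated residual after subtracting a
block-median baseline (50 ms blocks, linearly interpolated), smoothed with
a 1 ms Gaussian. The noise scale is the MAD-based robust SD of this
signal; candidate events must exceed `k`× that scale (default k = 3.5)
and be separated by a 5 ms refractory interval. Two shape criteria reject
noise excursions: the 10–90% rise must complete within 5 ms, and the
signal must stay above half its peak for at least 3.5 ms on the decay side
— real synaptic events decay over ~8 ms regardless of amplitude, while
smoothing-scale noise bumps collapse within 1–2 ms. The dwell default was
chosen on simulated traces as the smallest value holding both recall and
precision above 0.9 at SNR 4 (median 8 pA events over 2 pA noise); at
that regime the detector recovers a 2.33 Hz Poisson rate without
measurable bias. Amplitudes are measured on the raw trace against a local
pre-event median. Events closer than the refractory interval are merged
and counted once — a documented limitation that loses ~1% of events at
2.3 Hz.

## Synthetic electrophysiology

Evoked release uses the two-variable facilitation/depression recursion
described in the README. Stochastic sweeps track per-site availability:
each available site releases with probability uₖ at pulse k and recovers
with probability 1 − exp(−Δ/τ_rec) before the next pulse, so the expected
amplitude equals the deterministic recursion exactly — the recursion is
the oracle for every simulated protocol. A `deterministic=True` mode
replaces the binomial draw by its expectation for exact pass-through
tests. Defaults: n_sites = 200, U = 0.35, τ_facil = 0.2 s, τ_rec = 0.5 s,
q = 2 pA, kernel τ_rise = 1 ms / τ_decay = 8 ms (plausible AMPA kinetics
at −70 mV), Gaussian noise 5 pA, biphasic ±200 pA / 0.5 ms artefact,
10 kHz sampling, sweeps every 30 s. Calibration helpers invert the
recursion (by bracketing on U) so a requested PPR or train ratio becomes
the generative truth; recovery experiments use large n_sites (2000–5000)
so the per-sweep ratio estimator's small-sample bias (E[A₂/A₁] >
E[A₂]/E[A₁] for noisy denominators) stays below 2%.

Drug and plasticity effects scale either U (presynaptic: PPR and train
ratio change) or q (postsynaptic: both invariant), mirroring the
physiological dissociation and letting tests assert the pipeline
distinguishes the two. LTD experiments run a 5 min baseline of
paired-pulse probes, an induction gap (5 min at 10 Hz, or 4 × 1 s at
100 Hz with 10 s intervals), and ≥20 min of post-induction probes with
the injected post/pre fraction.

Spontaneous traces draw homogeneous-Poisson event times and log-normal
amplitudes (median 8 pA, σ_log = 0.4) on the same kernel, with Gaussian
noise; SNR is the median amplitude over the noise SD.

## Synthetic FISH scenes

Somata are non-overlapping disks (radius 13–16 px at ~0.3 µm/px, i.e.
~4–5 µm — the scale at which a 40× confocal field holds ~60 somata)
spanning 2–4 adjacent 1 µm z-slices in a 5-slice stack. Probe puncta are
unit-Gaussian spots (σ = 1.2 px, amplitude 80 over background 10) placed
only inside soma masks with a 4.5 px minimum spacing, at a z within the
cell's span; per-cell counts follow the mixture Poisson(1) for negative
and Poisson(25) for positive cells (70% positive). Bead-labelled cells
(50%) receive 4–8 brighter, broader aggregates. Optional extracellular
clutter stresses segmentation leakage. Noise is optional Poisson shot
noise plus Gaussian read noise; SNR 4 means read noise = 20.

Two geometric guarantees make noiseless end-to-end counting exact: spot
spacing (4.5 px) exceeds the detector's 3 px minimum separation even
after rounding to pixel maxima, and dart-throwing saturation at that
spacing caps per-cell counts at ~13–21 for the default radii — above the
>10 classification cutoff, so truncation of large Poisson draws never
flips a positive cell's class. The truth table records exactly what was
placed.

What the generator does not emulate: optical PSF physics and z-blur,
spectral bleed-through, autofluorescence texture, irregular soma shapes,
and overlapping cells. Passing tests therefore demonstrate correctness of
the counting pipeline's logic and its noise robustness, not performance
on real tissue, where thresholds and the segmentation scale must be
re-tuned (the cutoff calibrator against manual labels exists for exactly
that step).

## FISH quantification

Adjacent z-slices are combined in disjoint groups of 3 (~3 µm of tissue)
by maximum-intensity projection — the operator preserves punctum peaks;
sum projection is available by configuration. Channels are then
thresholded (Otsu by default, fixed value as override; a degenerate
constant image falls back to the fixed floor with a flag). The combine →
threshold order, and the projection operator, are implementation choices
documented here because the original description states neither.

Somata are segmented from the thresholded marker channel: seeds are local
maxima of the Gaussian-smoothed intensity (σ = 4 px) separated by at
least the expected soma diameter (10 px), de-duplicated greedily, then a
watershed on the inverted smoothed intensity constrained to the
foreground; segments under 100 px² are discarded. Puncta are local maxima
of the punctum-scale-smoothed image above a robust floor
(median + 4.5 × MAD-SD of the smoothed image — on a noiseless
thresholded image this collapses to zero so every placed spot is found),
with greedy Euclidean minimum-separation suppression (3 px, brightest
kept). Each punctum is assigned to the segment containing its rounded
coordinate; puncta outside all masks are uncounted. Cells appearing in
two z-groups are matched by centroid proximity (<5 px) and their counts
summed — exact, because disjoint grouping places each punctum in exactly
one group.

Classification is strictly `count > cutoff` (matching the published
">10 puncta" convention; default cutoffs: probe 10, bead 3). The cutoff
calibrator scans every integer threshold over the observed count range,
maximizes agreement with manual labels, and breaks ties toward the
smallest threshold; non-separable labelings return the best threshold
with its sub-unity accuracy. Co-expression tables report joint counts for
every channel combination and proportions with explicit denominators.

## Statistics

All tests are two-tailed at α = 0.05 and tie-aware. The signed-rank test
drops zero differences and mid-ranks tied |d|; for n ≤ 12 the p value is
exact by enumeration over all 2ⁿ sign patterns of the observed ranks,
otherwise a normal approximation with the standard tie correction is
used. Mann-Whitney enumerates all C(N, n₁) group assignments of the
pooled mid-ranks for N ≤ 14. Kruskal-Wallis applies the tie-corrected H
with a χ²(k−1) reference; Dunn's pairwise z statistics use pooled ranks
with tie-corrected variance and Bonferroni adjustment over all k(k−1)/2
comparisons (the conventional "Dunn's multiple comparison" default; the
adjustment is configurable to none). Friedman uses within-block mid-ranks
with the tie-corrected χ² form; an all-tied table returns statistic 0,
p = 1.

The type-I-error calibrator simulates Gaussian nulls and reports the
rejection rate at α. Exact rank tests are discrete, so their attainable
size is below the nominal level at very small n (e.g. the signed-rank
test at n = 8 can only achieve 0.0391); calibration checks therefore use
designs whose true size is close to nominal — signed rank at n = 10
(exact size 0.0488 by enumeration), Mann-Whitney 8/8 (0.0499),
Kruskal-Wallis 3 × 12 and Friedman 15 × 4 (≈0.048 by high-replicate
simulation). This is a property of discrete tests, not of the
implementation; the enumeration modes equal independent oracles exactly
at every size where they are enabled.

## Problem sizes

Recovery experiments run at the sample sizes of the study designs they
emulate: 15 cells × 20 sweeps for drug-epoch amplitude, 8 cells × 10
paired sweeps for PPR, 8 cells × 5 trains, 7 cells × 30 min LTD series,
and 50 × 120 s spontaneous traces; null calibration uses 5000 replicates.
These complete in seconds to a few minutes on a single CPU.

## Known limitations

- No series-resistance compensation modelling or NMDA/AMPA decomposition.
- Event detection merges events within the refractory interval and is not
  deconvolution-based; template matching is out of scope.
- Segmentation is 2D per z-group (no true 3D segmentation, no
  nuclear-channel support); spot intensities are not quantified beyond
  detection.
- The HDF5/CSV/TIFF readers cover the package's own formats only, not
  vendor acquisition formats.
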