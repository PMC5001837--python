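# Methods

`optomap` implements the analysis chain of single-cell-resolution optogenetic
connectivity mapping — sequential temporal-focusing (TF) two-photon
photostimulation of channelrhodopsin-expressing neurons, GCaMP6s calcium
imaging to verify evoked spiking, and whole-cell voltage-clamp recording of a
single postsynaptic cell — together with a seeded forward simulator that
generates complete experiments with ground truth, so every stage of the
analysis can be validated without experimental data.

## The mapping experiment and its analysis

One experiment stimulates each of N candidate presynaptic cells (identified
by a nuclear label) with a 150 ms TF pulse, one pulse at the onset of every
other imaging frame (1.5 Hz frames), repeated for four passes over the
target list. Three data streams result:

* per-cell fluorescence traces (ΔF/F against a 10-frame pre-stimulation
  baseline),
* 10 kHz current sweeps in the patched cell, one per (target, trial),
* the stimulation registry linking targets to frames and sweeps.

### Calcium analysis

ΔF/F uses per-cell F0 = mean of the first 10 (stimulus-free) frames.
A significant transient is a run of ≥ 2 consecutive frames exceeding the
cell's baseline mean by > 3 baseline SDs. The baseline window is the only
epoch guaranteed free of evoked activity, so both the mean and the SD of the
3-SD rule are computed there; a numerically zero SD (noise-free traces)
falls back to a configured noise floor of 0.05 ΔF/F. Cells whose baseline
fluorescence exceeds the across-cell mean by > 2 sample SDs are excluded
(indicator overexpression causes aberrant responsiveness); a
median/MAD-based variant is available (`robust=True`). A target is
**responsive** when a transient onsets within its own response window — the
stimulation frame plus one following frame — in ≥ 3 of 4 trials. The window
is two frames because targets are stimulated two frames apart; anything wider
would alias neighbouring targets. A transient in a different cell inside a
target's window, reproducible across ≥ 3 trials, is an **off-target event**;
off-target probability is reproducible events per stimulated target, and
off-target distance is the in-plane separation of the two cells.

Frames are 0-based in memory and 1-based in files and reports, so the first
stimulated target appears at "frame 2" in the registry JSON.

### Current analysis

Sweeps are low-pass filtered at 1 kHz (4th-order Butterworth, zero-phase).
Noise SD is a MAD-based estimate from the pre-stimulus window; events are
contiguous excursions beyond 4 noise SDs (inward = negative at −70 mV),
merged across sub-threshold gaps < 2 ms, split between inward peaks of
threshold-level prominence at the most-recovered intermediate sample, and
rejected if shorter than 1 ms (sub-millisecond crossings are noise). The
noise-SD estimate is floored at 0.5 pA so that noise-free synthetic sweeps do
not produce a degenerate threshold. Onsets extrapolate the crossing segment
back to baseline; 10–90% rise times interpolate linearly between samples;
decay constants come from a log-linear fit of the post-peak tail.

Classification: an event is **direct** (the patched cell's own photocurrent)
if its latency from light onset is < 2 ms and the current is sustained to the
light offset with decay commencing within 10 ms of it ("offset-locked"); it
is a **synaptic candidate** if latency ≥ 2 ms and rise < 10 ms; otherwise,
and always before light onset, it is spontaneous.

### Connection scoring

Per candidate target, the earliest synaptic candidate inside
[stimulus onset, offset + 50 ms] is matched per trial, and five criteria are
evaluated; all must pass:

1. every matched latency ≥ 2 ms;
2. matched events in ≥ 3 of 4 trials;
3. across-trial jitter (sample SD of matched latencies, n−1) < 14 ms;
4. mean 10–90% rise < 10 ms;
5. a calcium transient in the stimulated cell (criterion of verified firing).

Connectivity rate = connected pairs / responsive candidates. It is reported
both pooled (total counts) and as mean-of-experiments, which differ when
experiments have unequal sizes. Optical rates are compared against
paired-recording counts with a two-sided Fisher's exact test
(point-probability convention: the p-value sums all tables with fixed
margins no more probable than the observed one).

### Spatial profiles and resolution

Photocurrent-versus-distance profiles are fit with `I(x) = A·exp(−x/λ) + C`
(least squares, multi-start in λ at 1/10, 1/3 and 1× the x-span; a
zero-offset variant is available and flagged in the output). Two groups of
profiles are compared with an extra-sum-of-squares F-test: a single shared
curve fit to the pooled points (null) against separate per-group fits,
`F = ((RSS_sh − RSS_sep)/k) / (RSS_sep/(n − 2k))` with k parameters per
curve. Spike-probability resolution curves (proportion of 10 trials with a
spike, spot displaced at 9 µm lateral / 10 µm axial steps) are summarised by
their FWHM via linear interpolation of the sampled curve between the
half-maximum crossings; the convention is FWHM of the mean curve across
cells. Group comparisons of scalar measurements use the Mann-Whitney U test,
exact for two groups of ≤ 8 tie-free values, normal approximation with tie
correction otherwise. Power density is `P / (π(d/2)²)` for a flat disc of
diameter d (10 µm spot by default).

## The forward simulator

### Opsin response model

Two stock parameter sets describe soma-targeted ChR2 (Kv2.1 motif) and
conventional ChR2:

| parameter | targeted | nontargeted | units |
|---|---|---|---|
| dendritic length constant λ_d | 50/ln 10 ≈ 21.7 | 50/ln 2 ≈ 72.1 | µm |
| axonal length constant λ_a | 20/ln 5 ≈ 12.4 | 20/ln 2 ≈ 28.9 | µm |
| threshold power | 0.88 | 2.75 | mW/µm² |
| current at threshold | 222.7 | 261.1 | pA |
| current at 3.63 mW/µm² | 760.5 | 308.3 | pA |
| resolution FWHM lateral / axial | 11.1 / 23.3 | 19.6 / 36.2 | µm |

Photocurrent at distance d along a process is
`I_soma(P)·exp(−d/λ_compartment)`, so the targeted construct declines
exactly 10-fold 50 µm along a dendrite and 5-fold 20 µm down the axon, and
the nontargeted construct 2-fold at 50 µm. The nontargeted axonal constant
is set to a 2-fold decline at 20 µm (a qualitative choice: conventional ChR2
carries measurable axonal current tens of µm out). Amplitude versus power is
a Hill curve with coefficient 1 solved exactly through the two calibration
currents above; both constructs yield positive (I_max, K) solutions, and the
curve is concave (saturating) over the experimental power range.

Spiking: the probability of evoking ≥ 1 spike is
`min(1, (P/P_thr)^4) · G_lat(x) · G_ax(z)` with unit-peak Gaussians whose
FWHMs are the construct's resolution values. The on-soma probability reaches
1 exactly at threshold power, matching the operational 10/10-trials
definition of threshold; the quartic sub-threshold rise is a shape choice
(steep but finite). At half-FWHM offset the probability is exactly half the
on-soma value. First-spike latency is truncated-normal (> 0) with mean
shortening exponentially from 38.98 ms at threshold toward a 9.3 ms floor
(e-folding 1 mW/µm² above threshold) and SD scaling with the mean — 6.8 ms
at threshold, ≈ 1.6 ms at high power — because stronger drive initiates
spikes more deterministically. Pulses > 1.2× threshold evoke trains of 2–4
spikes (uniform), subsequent spikes 25–45 ms apart within the 150 ms pulse.

### Scene and protocol

A scene draws `n_cells` positions uniformly in a 200 × 300 µm usable field
(single axial plane), expression flags per cell (opsin 100% — targets are
selected by their nuclear label; indicator 80% — a separate viral construct;
high-baseline overexpression 2% of indicator-positive cells, baseline
inflated 3.5×), and Bernoulli(0.10) connectivity of opsin-expressing cells
onto the single patched neuron (the cell nearest the field centre).
Connected cells get log-normal EPSC amplitudes (median 25 pA, σ = 0.4, so
~95% exceed the detection threshold at the default 2 pA recording noise) and
truncated-normal synaptic delays (mean 3 ms, ≥ 2 ms, so every evoked EPSC
satisfies the 2 ms latency criterion by construction). Each neuron consumes
only its own substream of the experiment seed (numpy `SeedSequence` spawn
keys), so enlarging a scene never reshuffles existing cells, and identical
(config, seed) yields bit-identical experiments.

The default protocol stimulates every non-patched cell in id order: 150 ms
pulses at 2.29 mW/µm², one per alternate 1.5 Hz frame, 4 trials, preceded by
a 10-frame baseline block. The stimulation clock starts at the second frame
(frame 2, 1-based), so target k of trial t lands on clock frame
`2 + 2(k−1)` plus the trial offset; stored registries use absolute frames
(baseline block included). The frame rate is exposed as configuration: the
nominal 1.5 Hz frame rate and a 1.26 s inter-stimulus interval with
stimulation every other frame are mutually inconsistent by ~6%, and the
simulator does not resolve that tension — it uses whatever frame rate the
protocol specifies.

### Trace synthesis

Fluorescence: frames are sampled at their midpoints (a raster scan
integrates across the frame, and evoked spikes occur tens of ms after frame
onset, so the stimulation frame itself carries most of the transient). Each
spike adds a unit-peak difference-of-exponentials kernel (rise 180 ms, decay
1.0 s — typical GCaMP6s values, overridable) scaled by 0.4 ΔF/F per action
potential on the cell's baseline. Indicator-negative cells carry baseline
and noise only, whatever their spiking. Gaussian noise SD is 0.05 ΔF/F.

Currents: 500 ms sweeps per (target, trial) — 100 ms pre-stimulus, the
150 ms pulse, 250 ms tail — at 10 kHz. Components: (i) a direct photocurrent
when the stimulation spot falls within 15 µm of the patched soma (at larger
distances the bare exponential would still produce detectable current ~80 µm
out at mapping power, contradicting the observed confinement of significant
direct responses to the soma's immediate neighbourhood; the grid-map
analysis, which probes the exponential itself, is unaffected), with
activation/deactivation time constants 2/12 ms locked to the light epoch;
for the nontargeted construct an additional 28.75% of targets drive
dendritic direct responses of 10–80% somatic amplitude; (ii) one EPSC
(1 ms rise, 5 ms decay, difference of exponentials) per ground-truth
presynaptic spike of a connected target at spike time + delay, with 15%
amplitude CV and 0.2 ms delay jitter across trials; (iii) spontaneous EPSCs
as a 1.0 /s Poisson process with the same amplitude distribution —
a deliberately adversarial rate that exercises criteria 2–3, since a
spontaneous event inside the match window mimics an evoked one;
(iv) Gaussian noise of 2 pA SD.

Off-target activation is parametric: per target one Bernoulli draw
(probability 0.054 targeted / 0.152 nontargeted) decides whether an
off-target cell fires reproducibly on that target's trials. The victim must
express opsin and indicator (unobservable activations are not modelled) and
is drawn within a reach of 2× the construct's distance scale (18.9 µm
targeted / 40.6 µm nontargeted) with weight `exp(−d/λ_d)/d` — the chance of
a radial dendrite crossing the stimulation spot times the dendritic opsin
attenuation; if no cell is in reach (sparse fields), the nearest observable
cell is used. Generated mean distances land near 24 µm (targeted) and
36 µm (nontargeted): the construct contrast is reproduced, but the exact
means are bounded below by the field's nearest-neighbour spacing (~19 µm at
43 cells per field), a geometric floor the parametric mechanism cannot go
under.

## What the simulator does and does not emulate

It reproduces the statistical structure the analysis relies on: frame/sweep
timing, baseline windows, transient kinetics at the imaging frame rate,
latency/jitter structure of evoked EPSCs, spontaneous-event confounds,
direct-current confounds of the nontargeted construct, indicator-coverage
losses and high-baseline outliers. It does not emulate pixel-level image
formation (ROIs are given, not segmented), motion or neuropil contamination,
shutter blanking, dendritic morphology beyond straight radial segments,
conductance-based spike generation, inhibitory currents, or
series-resistance artefacts. Passing end-to-end tests therefore demonstrates
that the analysis correctly recovers what it claims from data with the
assumed structure — not that it is robust to imaging artefacts the simulator
does not produce.

## Numerical choices and edge cases

* Exponential fits: λ bounded > 0, multi-start, lowest-RSS solution kept;
  flat profiles flagged degenerate rather than fit.
* F-test: guards for non-positive residual dfs; convergence failure raises
  rather than returning a silent p-value.
* FWHM: requires an interior maximum and a below-half sample on each side;
  the failing side is named in the error.
* Fisher: degenerate margins return p = 1 with a warning.
* Threshold power: non-monotonic spike-count-versus-power outcomes are
  resolved by the strict minimum and flagged, mirroring the operational
  rule. Because sub-threshold powers have near-unity single-trial
  probability, a 10-trial ladder occasionally passes slightly below the true
  threshold; measured thresholds are accordingly biased a few percent low.
* Jitter with exactly 3 matched events uses n−1 = 2 denominators; trials
  without an event contribute no latency (no imputation).
* Detection on sweeps with direct + synaptic overlap: events are measured
  against a local (5 ms) pre-onset baseline, so an EPSC riding on a direct
  plateau keeps its own amplitude.

## Problem sizes used in bundled checks

Simulation-based checks run at the experiment scale the method targets:
mapping experiments of 40–43 cells × 4 trials; connectivity-rate recovery
over 20 seeded experiments (and 20 null experiments for the false-positive
bound); responsive-fraction calibration over ≥ 500 stimulated cells;
resolution-curve recovery over 20 cells × 10 trials per offset; F-test
type-I calibration over 1,000 null profile pairs. The acceptance script runs
12 fully scored mapping experiments plus 24 imaging-only experiments per
construct condition to keep Monte-Carlo error on the reported fractions
near one percentage point.
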