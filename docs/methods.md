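# Methods

`cosmofret` simulates and analyses single-molecule colocalization + FRET
records of eukaryotic replicative-helicase loading: an origin-recognition
complex (ORC) on surface-tethered origin DNA recruits two Cdt1-bound
Mcm2-7 helicases one at a time and loads them as a head-to-head double
hexamer.  The package implements (i) a continuous-time kinetic simulator
of the single-ORC "flip" pathway with its failure branches, loading-
defective mutants and alternative mechanistic hypotheses; (ii) a forward
model turning state trajectories into per-frame fluorescence traces under
alternating donor/acceptor excitation; (iii) the measurement pipeline
(background correction, presence intervals, intensity steps, apparent-
FRET series and high-FRET intervals); (iv) event classification; and
(v) censored dwell-time and counting statistics.

## Kinetic model

Each DNA is an independent renewal process of loading *attempts*:

1. ORC binds (exponential waiting time, default rate 0.005 /s) and a
   Cdt1-bound Mcm2-7 follows (default 0.01 /s).  Both rates are free
   parameters: the source experiments do not constrain them, and they
   only set how many attempts fit into a record.
2. The first **OM interaction** (C-terminal ORC-Mcm2-7 interface, the
   recruitment contact) begins exactly at the first Mcm2-7 arrival and
   ends exactly at the first Cdt1 release; its duration is exponential
   with mean 30 s.
3. With probability `p_mo_given_first_mcm = 0.23` the **MO complex**
   forms (ORC flips onto the N-terminal face of the first helicase) after
   an exponential lag of mean 8.3 s from Cdt1 release.  Otherwise ORC
   departs (free lag, mean 10 s) and the lone helicase leaves DNA with a
   median lifetime of 11 s (median-parameterised: rate ln2/11).
4. Given MO, a stable second Mcm2-7 is recruited with probability
   `p_second_given_mo = 0.79`; the second arrival waits exponentially
   (same Mcm arrival rate) after MO onset and never precedes it.  A
   second OM interaction runs from the second arrival for an exponential
   mean of 56 s, ending at the second Cdt1 release, when ORC also leaves.
   The MO interaction ends 9.7 s (exponential mean) after the second
   arrival — the onset of double-hexamer interactions — and therefore
   strictly brackets the second arrival.  The double hexamer occupies the
   DNA for the rest of the record.
5. Failure branches: abortive second associations (probability 0.1,
   dwell exponential mean 20 s conditioned below 48 s) and MO complexes
   that release the first helicase without recruiting a second one
   (lifetime mean 40 s, a free parameter).

ORC usage is a mixture: one ORC throughout (0.81), two sequential ORCs
(8/166), an extra overlapping-but-uninvolved ORC (14/166), and a
remainder class with two short nonspecific ORC visits (the "three ORC"
events).  Mechanism modes re-wire which molecule carries each
interaction: `re_fret` attaches both OM periods to the first helicase and
has no MO; `orc_exchange` hands the DNA off between two ORCs midway with
no visible gap; `two_orc_independent` forces the sequential two-ORC
pathway.  Mutants: `mcm5RA` blocks Cdt1 release, so the OM interaction
ends only through a composite fluorophore/protein-loss process
(exponential mean 156 s); `orc6dN119` reduces the MO probability to a
configured near-zero value (default 5/418).

## Trace synthesis

Acquisition alternates 1-s donor- and acceptor-excited exposures with
0.2-s dead times (2.4-s cycle, 600 cycles, ~24 min).  On donor-excited
frames an active donor emits total T = `unit_intensity` x PIFE, where
protein-induced fluorescence enhancement (PIFE, default factor 1.3, not
quantified in the source and therefore configurable) applies while an OM
interaction is engaged.  Emission is split I_Aem = E.T, I_Dem = (1-E).T
by the apparent-FRET set-point of the active state: 0.72 / 0.79 for the
first / second OM interaction, 0.73 for MO, 0.83 for OM with an
N-terminally acceptor-labeled Cdt1 still bound, 0.358 for a donor-ORC
with only acceptor-Cdt1 present, and a 0.08 "no-interaction" baseline
whenever a donor and an acceptor merely co-reside on the DNA.  With two
co-resident donors the contributions add, so the measured E blends the
engaged and baseline set-points — the reason the analysis restricts FRET
statistics to single-ORC events.  Acceptor-excited frames report direct
excitation only: one unit per present, unbleached acceptor, independent
of FRET state.  State occupancy is integrated over each exposure, so a
transition inside a frame scales emission by time-in-state.  Noise is
additive zero-mean Gaussian (records are modelled post background
correction).

Defaults: `unit_intensity` 1000, `background_sd` 150.  The noisier
channel used for presence detection is donor-excited *total* emission,
whose noise is sqrt(2) x 150 = 212, giving SNR ~ 4.7 per frame there and
a per-frame FRET noise sigma_E ~ 0.09-0.12 — the "paper-like" detection
regime the pipeline is designed for.  Photobleaching is Bernoulli per
illuminated exposure per dye, scaled by the laser-exposure factor; the
bleach/no-bleach pair of presets supports the rate decomposition
k_obs(f) = k_intrinsic + f.k_bleach.

## Measurement layer

* **Background**: per-channel baseline = median of frames outside
  presence, seeded by the minimum sliding-window median (so occupancy
  covering most of a record cannot drag the baseline onto an occupied
  level), iterated once; an all-occupied channel falls back to the global
  median and is flagged.
* **Presence**: hysteresis thresholding (on at 4 sigma, off at 2 sigma),
  right-censored at the record end.
* **Steps**: binary segmentation *within* each presence interval (a
  short interior dwell has almost no contrast in a whole-record split),
  with interval boundaries providing the entry/exit steps.  Candidate
  splits must pass a known-sigma z test on the segment-mean difference,
  Bonferroni-corrected for the number of candidates, at alpha = 1e-3;
  surviving splits are re-tested against their immediate neighbours and
  pruned (a top-level binary split can land between true changepoints).
  When the per-fluorophore unit is known from the configuration, segment
  means are quantised to integer fluorophore counts and steps are emitted
  only at level changes — this also removes PIFE-sized sub-unit steps
  from the donor record.  Down-steps of 0.35-0.65 of the preceding
  up-step are half-losses (one of two co-arrived dyes leaving, e.g. Cdt1
  release); a step returning the level to zero is always a departure.
* **Apparent FRET**: E = I_Aem/(I_Aem + I_Dem) on donor-excited frames,
  valid while a donor and >= 1 acceptor are present; no clamping, and
  histogram exports exclude |E| > 2.  High-FRET *onset detection* uses a
  donor-presence-only mask — the acceptor's arrival is confirmed
  separately (within 4.8 s) rather than gating the mask, otherwise the
  onset inherits the acceptor channel's half-cycle grid offset.
* **High-FRET intervals**: runs of frames with E >= 0.4 (midpoint
  between the 0.08 baseline and the ~0.72-0.79 interaction states),
  minimum two frames, bridging single valid-but-subthreshold frames (a
  lone noisy dip should not split a sustained interaction).  Intervals
  without a confirmed acceptor arrival within 4.8 s of onset are rejected
  for the OM reporter; the rule is switched off for the MO reporter,
  whose onset genuinely trails the first Cdt1 release.

## Event classification

Attempts are assembled from acceptor-channel arrivals/departures (LIFO
matching; half-losses do not change occupancy).  Success = exactly two
Mcm2-7 arrivals, both retained > 48 s (>= 20 acquisition frames); a
shorter second association is an unsuccessful event.  ORC usage is
counted from per-molecule donor intervals (level transitions >= 0.65
unit; which physical ORC leaves first in overlap events is not observable
and is resolved LIFO).  FRET-profile typing attributes a peak to the
arrival whose time is within +-4.8 s of its onset; under mixed-label
designs the profile maps to CC/CN/NC/NN.  For the MO reporter, all
high-FRET fragments inside the recruitment window are merged into the
single MO interval (gated to start no earlier than the first Cdt1
release when one is measured).  Coincidence calls use the +-2.4-s
experimental time resolution; the reported lag is time_a - time_b, so a
positive lag names the second argument as the earlier event.

## Statistics and estimator choices

* Product-limit survival curves with plain Greenwood 95% bands (the
  Matlab `ecdf` convention); lifelines serves as an independent
  cross-check in the tests, never as the implementation.
* Censored-exponential MLE: mean = (sum of all durations)/(number
  uncensored); SE from a nonparametric bootstrap over events (events,
  not frames, are the independent unit; B = 1000 by default, seeded).
* **Left truncation**: the interval detector cannot see dwells shorter
  than its minimum run length.  The effective cutoff is
  (min_frames - 0.5) cycles = 3.6 s: simulating the abstract exposure
  geometry (1-s exposures on a 2.4-s cycle, a frame counts as in-state
  above ~44% occupancy) gives E[measured | detected] - 3.6 = true mean
  for exponential dwells of any mean (checked at 30, 56 and 156 s).  The
  MLE subtracts this constant from every observation, restoring the
  plain closed form when the cutoff is zero.
* An interval ending because the complex dissolves (ORC departing as the
  second OM interaction ends; the 5RA composite loss) is an *observed*
  termination; right-censoring applies only at the record end (with
  photobleaching disabled there is no other censoring mechanism).
* **Window-mean FRET** (the 10-s window after the first arrival):
  per-event intensity-weighted (ratio-of-sums) E over interior window
  frames inside the detected first OM interval, averaged over events.
  Per-frame ratios carry a small-denominator bias of order
  (sigma/T)^2 ~ +0.007 that the ratio-of-sums estimator suppresses;
  boundary frames are excluded because the camera integrates across the
  transition.
* **Medians on lattice data**: frame-quantised dwells sit on a 2.4-s
  lattice, so the raw sample median jumps between adjacent lattice
  points; the grouped-data (interpolated-ECDF) median restores sub-frame
  resolution.
* Fractions use Wald binomial SEs (the "+- SE" convention on printed
  fractions), with Wilson intervals also available.  Event-fraction
  denominators exclude attempts starting within 250 s of the record end,
  which cannot be classified.
* Model discrimination uses the likelihood-ratio G statistic; for
  n <= 200 and <= 4 categories the p-value is the exact multinomial tail
  by composition enumeration.  A structural zero with a nonzero observed
  count rejects outright (p = 0, flagged).  Expected proportions can fold
  in a contamination channel for the rare unlabeled-second-ORC events.

## What the simulator does and does not establish

The generator reproduces the *statistical structure* the analysis
assumes: exponential dwells, exact coincidences (OM end = Cdt1 release),
Bernoulli labeling, FRET set-points with additive Gaussian noise, flat
illumination and a rigid field.  Real records additionally contain
spectral bleed-through, spatial excitation gradients, baseline drift,
dye blinking and non-exponential dwell mixtures — none of which are
modelled, so a green test certifies the pipeline's correctness *given*
the stated noise model, not robustness to those artifacts.  Detection
itself is imperfect in a way the tests quantify: dwells shorter than
~1.5 cycles are invisible (folded into expectations via the closed-form
miss rates 1 - exp(-3.6/tau)), and endpoint errors are about one frame.

## Known limitations

* Bleed-through/crosstalk matrices and dual-view registration are out of
  scope; the movie layer uses a rigid, flat field.
* Acceptor photophysics under donor excitation (FRET-mediated acceptor
  bleaching) is ignored; acceptors bleach only on their own exposures.
* Two-acceptor composites (Mcm2-7 + Cdt1) use a single effective
  set-point rather than explicit three-dye kinetics.
* The LIFO resolution of overlapping same-species molecules is a
  convention, not an inference.
* The binary "intervals" dialect of the original Matlab pipeline is not
  read; the deposited records for the source experiments live at
  Dryad (doi:10.5061/dryad.547d7wm8z) and would need that reader.
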