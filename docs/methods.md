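# Methods

## Signal model

All simulation and fitting is done at the level of prepared longitudinal
magnetization; RF pulse shapes, the bSSFP readout, slice profiles and
transverse dynamics are out of scope.  Preparations are instantaneous:
a saturation pulse maps Mz to `eff_sat * Mz` (ideal `eff_sat = 0`), an
inversion pulse maps Mz to `-eta * Mz` with completeness `eta` in [0, 1],
and between events Mz relaxes mono-exponentially toward equilibrium,
`Mz(t + dt) = M0 + (Mz(t) - M0) exp(-dt/T1)`.

For a frame whose readout is preceded by a saturation at delay TS and an
inversion at delay TI (`0 <= TI <= TS`), propagation gives the closed form

    Mz(TS, TI) = M0 [ 1 - (1 + eta) exp(-TI/T1) + eta exp(-TS/T1) ].

With `TI = TS` or `eta = 0` this degenerates to saturation recovery
`M0 (1 - exp(-TS/T1))`; with `TS -> inf`, `eta = 1` to ideal inversion
recovery.  `bloch_piecewise` implements the event-by-event propagation
directly and is kept as an independent brute-force oracle; the test suite
checks closed-form/oracle agreement to better than 1e-9 relative over
T1 ∈ [100, 3000] ms, TS ∈ [200, 10000] ms, TI ∈ (0, TS).

### Fit model

The 3-parameter estimate is (M0, T1, eta) with the saturation assumed ideal.
The parameter set is a modelling choice: the WET saturation module is
near-ideal in practice, while in the systolic variant TS varies from frame
to frame, so a fixed "apparent amplitude" parameterization would not absorb
the preparation history; an explicit inversion-efficiency parameter does.
Unprepared frames (nominal TI sentinel 10000 ms, far above every tissue T1)
are modelled as fully recovered, `s = M0`.

The model is linear in `(M0, M0*eta)` at fixed T1, so initialization scans a
12-node log-spaced T1 grid (50–4000 ms) solving the 2x2 linear problem per
node (variable projection) and keeps the best node; refinement uses bounded
trust-region least squares with an analytic Jacobian (`scipy.optimize.
least_squares`, ftol/xtol/gtol 1e-12, at most 400 evaluations).  Bounds:
T1 ∈ [1, 5000] ms, eta ∈ [0, 1], M0 ∈ [0, 10·max|s|].  Noiseless
round-trips recover T1 = 382/1578/2048 ms to ~1e-8 relative; the 0.1%
assertions in the tests are deliberately loose against this.

Pixel-wise map fitting deduplicates identical signal columns before fitting
(exact float match).  On noiseless phantoms this collapses the work to one
fit per compartment; on noisy data every column is unique and the path is a
no-op.

## Polarity restoration

Magnitude images lose the sign of Mz.  Two restorations are provided:

* **Flip-and-refit** (used for the fixed-TS diastolic variant): the
  inversion-prepared points are sorted by TI and, for every k, the first k
  are negated and refitted; the smallest SSR wins and ties go to fewer
  flips (the physically smoother choice).  With variable TS this sorting
  argument breaks down, which is exactly why the systolic variant needs the
  phase-sensitive route.
* **Phase-sensitive**: the phase of the unprepared reference image is
  subtracted (complex conjugate multiplication), the phase difference is
  spatially unwrapped (`skimage.restoration.unwrap_phase`), a global 2π
  offset is removed (median anchor over the foreground) and any residual
  local 2π multiple folded back; pixels with |Δφ| > π/2 get polarity −1,
  the rest +1.  Because smooth coil/B0 phase is common to all frames it
  cancels in the difference; only the π jump of inverted magnetization
  remains.

A practical caveat verified by simulation: when a tissue's recovery nulls
at (or within the noise of) one of the sampled TIs, that frame's sign is
not determined by the data, and the two restorations can legitimately
disagree there.  Method agreement is therefore assessed as *identical sign
decisions on frames whose magnitude exceeds 3x the noise SD*; at SNR 60 the
two routes agree on >99% of non-background pixels under that definition,
and the fitted T1s are identical wherever the decisions agree.

## Timing and arrhythmia model

RR intervals are i.i.d. Gaussian draws with configurable mean and SD,
clipped below at a 300 ms physiological floor (no truncation rule is
standard; clipping keeps the draw count deterministic and, with floor <
trigger delay, does not change the mis-trigger probability).  Arrhythmia
severity is parameterized either as an SD in ms or as a fraction of the
mean RR.

*Diastolic schedule*: saturation at the R-wave, readout at trigger delay
TD = 805 ms, inversion at TI before the readout, per-frame TI list
[10000; 805; 113; 211; 309; 407; 505; 603; 701; 799] ms.  TI above TD is a
full-recovery sentinel (unprepared frame); TI = TD degenerates to
saturation-only.

*Systolic schedule*: 1 unprepared + 4 saturation + 5 saturation+inversion
frames (7 + 7 in the 15-frame patient layout).  The saturation is played
directly after the previous readout, so the realized TS equals the RR
interval between consecutive readouts and varies with the heart rate; the
realized (TS, TI) of every frame is recorded in the timing sidecar and
consumed by the fit.  That bookkeeping is the entire mechanism behind
heart-rate independence.  The systolic trigger delay is not a published
quantity (it is set visually in practice); the default is 300 ms with the
five TIs spread linearly over 100–300 ms.  A frame whose realized TS falls
below its TI is dropped and logged.

*Mis-triggering*: a diastolic frame is relabeled systolic either by the
threshold rule (its beat's RR < TD — the mechanistic definition) or, to
mirror the randomized-replacement protocol of the numerical experiment, by
relabeling a seeded random subset whose size is the truncated-Gaussian
share P(RR < TD).  Note that with mean RR 667 ms and TD 805 ms this share
exceeds 50% even at zero variability; the threshold and share modes are
alternative conventions, both provided.

## Phantom

650 x 650 pixel mid-ventricular short-axis section; compartment T1s:
myocardium 1578 ms, LV+RV blood 2048 ms, epicardial fat 382 ms; M0 = 1
everywhere by default.  Only the grid size, the compartment T1s and the
systolic scaling (LV cavity diameter x0.70, wall thickness x1.40) are
prescribed quantities; the concrete radii are this package's choice:
cavity radius 130 px, wall 30 px, fat rim 8 px, RV disc radius 130 px
offset 110 px toward the septum (all at the 650 reference, scaled linearly
with grid size).  The diastolic (130, 30) and systolic (91, 42) radii are
integer-valued so that both phases quantize exactly onto the pixel grid and
the septal width ratio is exactly 140% along the central row — measured
FWHM ratios at other grids carry ±1-pixel quantization per edge.

The vial phantom is seven static discs with T1 log-spaced over
200–2000 ms (the vial values are not published; the range covers native
myocardium/blood and post-contrast values).

Series synthesis is per-pixel closed-form signal evaluation with the
frame's phase geometry (mis-triggered frames use the systolic maps), the
signed Mz embedded along the real axis times any smooth background phase
map, plus i.i.d. complex Gaussian noise.  SNR is defined as the unprepared
myocardial signal divided by the per-channel noise SD — the reference image
of the phase-sensitive fit — so `noise_sd = M0_myo / SNR`; noise is added to
the complex data (required for phase-sensitive fitting).

## What the generator does and does not emulate

It emulates: the TI/TD structure of both schedule variants, realized-timing
variability, mis-trigger frame substitution, compartment contrast and
complex noise at calibrated SNR.  It does not emulate: partial-volume
mixing at compartment borders (labels are crisp), coil sensitivities, B0/B1
inhomogeneity, banding, through-plane motion or contrast-agent washout.
Passing tests therefore demonstrate correctness of the timing model, the
estimator and the polarity logic — not in-vivo image quality.  In-vivo
quantities that depend on real anatomy (FWHM percent increases measured in
volunteers, patient T1 distributions) are outside what this phantom can
reproduce.

## Evaluation

* Accuracy/precision maps: per-pixel mean and sample SD (ddof 1) across
  repetitions.
* CoV: sample SD / mean, here applied to per-vial fitted T1 across
  RR-variability conditions.
* FWHM: bilinear line-profile sampling (8x oversampling); the plateau is
  the median of the outer 20% of samples on each end (robust to noise; no
  half-level convention is published), the extremum is the sample furthest
  from the plateau, crossings are sub-pixel by linear interpolation.
* ECV = (1 − Hct) ΔR1_myo / ΔR1_blood with R1 = 1/T1 — the standard
  definition, assumed rather than quoted.
* Sector segmentation: equal angular spans counterclockwise from the
  anterior RV insertion, 6 sectors (basal/mid) or 4 (apical); the phantom
  exercises a single slice of the 16-segment scheme.

## Problem sizes used in the shipped checks

The quantitative checks run the vial experiment at a 160-pixel grid
(ROI-level statistics are grid-independent well above the vial size), the
noiseless compartment-recovery and FWHM measurements at the full 650-pixel
grid, and the mis-trigger SD-map simulation at 128 pixels with 10
repetitions on a septal band — sizes chosen so the whole pipeline runs on a
laptop in minutes while leaving every quantity's expected value unchanged.

## Known limitations

* Saturation efficiency is fixed at ideal in the fit; a systematic
  saturation residual would alias into eta and M0.
* The magnitude flip-and-refit restoration is only offered for fixed-TS
  schedules; applying it to systolic data is possible but unsupported
  scientifically.
* The RR model is i.i.d. Gaussian; real arrhythmia (bigeminy, AF) has
  temporal structure that the share-mode mis-trigger only crudely mimics.
* `unwrap_phase` on piecewise-constant noiseless phase maps can choose
  either ±π representation of an inverted region; the sign decision is
  invariant to this, but unwrapped phase values themselves are not
  meaningful output.
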