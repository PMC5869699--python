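# sapphire-t1

Simulation and estimation toolkit for **systolic saturation-recovery
cardiac T1 mapping** (the SAPPHIRE hybrid saturation/inversion
preparation).

Myocardial T1 mapping quantifies diffuse fibrosis, but conventional
diastolic sequences are corrupted by partial-volume averaging at the
blood–myocardium interface and by mis-triggering when arrhythmia shortens
the diastole under the programmed trigger delay.  Imaging in systole —
thicker wall, a cardiac phase that common arrhythmias barely shorten —
avoids both, at the price of too little recovery time between the R-wave
and the readout for ordinary saturation-recovery.  The systolic SAPPHIRE
variant solves this by playing the saturation pulse in the *preceding*
heartbeat, directly after the previous readout, and feeding the *realized*
per-frame timing into the fit.

This package is for researchers who want to study that sequence logic
quantitatively without a scanner: it simulates numerical cardiac and vial
phantoms under realistic ECG triggering (Gaussian RR variability,
mis-trigger frame substitution, calibrated complex noise), reconstructs T1
maps, and evaluates them.

## Model

Each frame's prepared longitudinal magnetization follows the closed form

    Mz(TS, TI) = M0 [ 1 − (1 + η) e^(−TI/T1) + η e^(−TS/T1) ],

where TS and TI are the saturation- and inversion-to-readout delays and η
is the inversion completeness; unprepared frames give `M0` and
saturation-only frames `M0 (1 − e^(−TS/T1))`.  T1 maps come from a
3-parameter least-squares fit of (M0, T1, η) to the signed recovery data,
with polarity restored either by TI-sorted flip-and-refit (magnitude data,
fixed TS) or phase-sensitively, thresholding the unwrapped phase difference
to the unprepared reference image at π/2 (required in systole, where TS
varies per beat).  An event-by-event Bloch propagation of Mz is kept as an
independent oracle for every closed form.  See `docs/methods.md` for the
full account.

## Worked example

Heart-rate independence of the systolic variant — fit seven vials under a
steady versus a heavily irregular rhythm and compare:

```python
import numpy as np
from sapphire_t1 import (
    build_vial_phantom, generate_rr_series, schedule_systolic,
    synthesize_series, fit_region,
)

truth = build_vial_phantom(grid=160)          # seven vials, T1 200-2000 ms
for sd in (0.0, 500.0):                       # RR-interval SD in ms
    rr = generate_rr_series(mean_rr=1125.0, sd_rr=sd, n=11, seed=2)
    timings = schedule_systolic(rr, td_sys=300.0)
    series = synthesize_series(truth, timings, snr=60.0, seed=2)
    t1 = [fit_region(series, truth.label_map == v).t1 for v in (1, 4, 7)]
    print(f"RR SD {sd:3.0f} ms -> vial T1 = "
          + ", ".join(f"{x:7.1f}" for x in t1) + " ms")
```

prints

```
RR SD   0 ms -> vial T1 =   200.1,   631.9,  2006.3 ms
RR SD 500 ms -> vial T1 =   200.0,   632.6,  2006.5 ms
```

(true values 200.0, 632.5, 2000.0 ms).  Although a 500 ms RR standard
deviation changes every saturation delay in the series, the fit consumes
the realized (TS, TI) of each frame, so the estimates barely move — the
remaining ~0.3% spread at T1 = 2000 ms is noise (SNR 60), not heart rate.

## Command line

```sh
sapphire-t1 simulate --config run.yaml      # phantom series + manifest (NIfTI + CSV/JSON sidecars)
sapphire-t1 fit --series-dir out/series     # T1/M0/efficiency/polarity maps
sapphire-t1 report --maps-dir out/maps --labels out/series/cond0_rep000_labels.nii.gz
```

`simulate --dry-run` writes only the manifest; `fit` is resumable;
`report --acceptance` runs the built-in quantitative checks.  A config file
is a single YAML document validated against a schema (see
`sapphire_t1.config.RunConfig`); every random consumer receives an explicit
seed and reruns are byte-identical.

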