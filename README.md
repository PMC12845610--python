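# coilpilot

Markerless robot-assisted TMS coil targeting and contact sensing, as a
testable Python library.

Transcranial magnetic stimulation (TMS) only works when the coil sits over
the right piece of cortex, pressed tangentially against the scalp. Clinical
robots solve this with optical trackers and head markers; `coilpilot`
implements the computational core of a cheaper alternative: locate the C3
motor-cortex position of the 10-20 EEG system from three facial landmarks a
depth camera can see, and keep the coil flat on the head using two textile
capacitive sensors mounted one above the other behind the coil. It is aimed
at neuroengineering groups building or evaluating such systems, and at
anyone who needs a clean reference implementation of the individual pieces
(10-20 scalp geometry from partial landmarks, dual-sensor tilt estimation,
MEP measurement, motor-threshold staircases).

## The model

**Scalp target.** With the inion invisible to a front-facing camera, the
full 10-20 measurement is replaced by an angular model: the
preauricular-to-preauricular arc is taken as 180°, so C3 — 20% of the
transverse distance from the vertex — sits at an arc angle of
20% × 180° = 36°. In the camera's image plane (x right, y up), with
Ear = RightEar − LeftEar and MP the preauricular midpoint:

    θ = arctan(Ear_y / Ear_x)                  head roll in the image
    α = 100 · cos θ                            foreshortened 100 mm reach
    Target_x = MP_x − α · tan(36° + θ)
    Target_y = MP_y + α

Depth (z) passes through unchanged.

**Contact and tilt.** Each sensor channel n reports capacitance counts
proportional to suspension compression. After subtracting a 50-sample
baseline, `Adj_n = Raw_n − Baseline_n`, the normalized ratio
`Norm_n = Adj_n / (Adj_0 + Adj_1)` estimates tilt: 0.5/0.5 means both
sensors equally compressed, i.e. the coil face tangential to the scalp.
The total load `Adj_0 + Adj_1` proxies contact pressure; loads of
1500–4000 counts are classified optimal, below 800 or above 6000 poor.

**MEP measurement.** Raw EMG epochs (160 ms at 5000 Hz, 500× gain, 2.5 V
offset) are converted to µV, band-pass filtered 20–1000 Hz and notch
filtered at 50 Hz (both zero-phase), and the MEP amplitude is the
peak-to-peak value in the 20–40 ms post-stimulus window; amplitudes above
50 µV count as valid responses. The resting motor threshold (RMT) is the
lowest stimulator intensity at which ≥ 5 of 10 pulses are valid, found by
a bidirectional staircase; experiments run at 120% RMT (nearest integer
%MSO).

**Tilt experiments.** A sweep tilts the coil from 4° below to 5° above a
reference pitch in 1° steps, logging sensor ratios and one MEP per
condition; the analysis asks whether the peak MEP coincides with a
balanced (|Norm_0 − 0.5| ≤ 0.05) ratio and whether amplitude falls off as
the coil tilts past the peak.

A built-in simulator (ellipsoidal head, linear spring-suspension sensor
law, separable tilt × load × intensity MEP response) generates all of
these data with known ground truth.

## Worked example

Locate C3 for a head rolled ~7° in the image (ears at (−80, −10) and
(80, 10) mm, nasion straight ahead):

```
$ coilpilot localize --landmarks lm.json
{
  "target_x": -92.93701817865482,
  "target_y": 99.22778767136677,
  "target_z": 0.0,
  "ear_axis_angle_theta": 7.125016348901798,
  "offset_alpha": 99.22778767136677,
  ...
}
```

The ear axis is rotated θ = 7.13°, so the 100 mm reach foreshortens to
α = 99.23 mm and the target shifts to x = −92.9 mm (left of the midline,
toward the left ear — C3 is a left-hemisphere position), y = +99.2 mm up
from the preauricular midpoint.

Analyze the packaged example tilt sweep (ten conditions around a
25° robot-pitch reference):

```python
>>> from coilpilot.io import reference_trial
>>> from coilpilot.tilt_experiment import summarize_trial
>>> summarize_trial(reference_trial()).to_dict()
{'subject_id': 'A', 'trial_id': 'A3', 'peak_pitch': 24.0,
 'peak_mep': 1861.4, 'peak_norm0': 0.48,
 'balance_deviation_at_peak': 0.02, 'balanced_at_peak': True,
 'decreasing_trend': True}
```

The largest MEP (1861.4 µV) occurs at robot pitch 24°, where the sensor
ratio is 0.48/0.52 — within 0.02 of perfect balance — and amplitudes fall
off monotonically as the coil tilts further down: the peak response
coincides with the tangential orientation the sensors report.

The same pipelines are exposed as `coilpilot sensors`, `coilpilot mep`,
`coilpilot tilt-analyze` and `coilpilot simulate {trial,landmarks,emg}`.

## Layout

- `src/coilpilot/head_geometry.py` — landmarks → C3 target (angular model,
  pose estimation, vertex proxy)
- `src/coilpilot/contact_sensing.py` — counts → load / balance / safety
- `src/coilpilot/mep_analysis.py` — raw EMG → µV → filtered → MEP; RMT
- `src/coilpilot/tilt_experiment.py` — sweep construction and analysis
- `src/coilpilot/simulator.py` — ground-truth generators
- `src/coilpilot/io.py`, `src/coilpilot/cli.py` — file schemas and CLI

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
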