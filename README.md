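# rhesusear

A desk-scale virtual model of the rhesus macaque (*Macaca mulatta*) inner
ear for studying how cochlear implants affect residual acoustic hearing.
The package simulates harmonic sound transmission from the stapes into a
parametric two-chamber cochlea, computes the basilar-membrane (BM)
traveling-wave displacement at each drive frequency, calibrates the
membrane's property gradients against the Greenwood frequency–position map,
and quantifies how an electrode in the scala tympani — with or without a
scarred (ten-fold stiffened) round-window membrane — perturbs the
displacement pattern. It is intended for auditory-biomechanics researchers
who want a fast, fully scriptable passive cochlear model of the macaque, a
standard animal model for implant research.

## Model

The cochlea is uncoiled into a straight box of BM length L = 27 mm,
discretized into 82 longitudinal sections: two perilymph ducts (scala
vestibuli and scala tympani, treated as one-dimensional incompressible
acoustic lines) coupled section-by-section through a locally reacting BM
impedance

```
Z(x, ω) = iω·m(x) + s(x)·(1 + iω·β(x)) / (iω)
```

with areal mass m(x) = ρ_bm·t(x), areal plate stiffness
s(x) = k_geom·E(x)·t(x)³/w(x)⁴, and longitudinal property gradients

```
E(x)  = 10^5.7  · e^(−0.19·x)   [Pa]        (elastic modulus, decays base→apex)
β(x)  = 10^−5.91 · e^(0.1·x)    [unitless]  (stiffness-proportional damping, grows)
```

for x in mm from the base. The stapes footplate drives the scala vestibuli
through the oval window with the measured per-frequency displacement table
(8 nm at 1 kHz down to 0.05 nm at 10 kHz, with phases); the round window
terminates the scala tympani as a damped compliance; the helicotrema shunts
the two ducts at the apex; the membranous-labyrinth walls are damped
elastic shunts distributed along both ducts. Per frequency this yields one
sparse complex linear system (3 unknowns per section) solved directly.

The tonotopic map is anchored to the Greenwood frequency–position function
with rhesus constants,

```
F = A·(10^(a·x̂) − k),   A = 395 Hz, a = 2, k = 1,
```

where x̂ is the fractional distance from the apex. Calibration adjusts the
gradient coefficients (Nelder–Mead, deterministic) until simulated peak
locations match the Greenwood predictions at the six drive frequencies.

Scenarios: `healthy` (no electrode), `implanted` (tapered silicone
electrode occluding the basal 12 mm of the scala tympani) and
`implanted_stiffened` (electrode plus a ten-fold stiffer round-window
membrane, mimicking post-surgical scarring).

## Worked example

Calibrate the healthy model and compare the three scenarios:

```
$ rhesusear calibrate --out grad.yaml --report report.tsv
mean |peak - Greenwood| = 0.191 mm (initial 10.591 mm, 106 iterations, converged=True)

$ cat report.tsv
frequency_hz  peak_mm  greenwood_mm  deviation_mm
1000          19.6030  19.6023       0.0007
2000          15.8682  16.4334       0.5652
4000          12.6249  12.8741       0.2492
6000          10.7803  10.6752       0.1051
8000          9.2993   9.0798        0.2195
10000         7.8233   7.8269        0.0037
```

Starting from the printed gradient coefficients the simulated peaks sit
~10.6 mm from the Greenwood predictions; after calibration the mean
deviation is 0.19 mm, with the largest residuals at intermediate/extreme
frequencies. The fitted gradient is written to `grad.yaml` as a config
fragment.

```
$ rhesusear compare --calibrated-gradient grad.yaml --out cmp
$ cat cmp/scenario_rmse.tsv
frequency_hz  rmse_implanted  rmse_stiffened  peak_shift_mm  noise_healthy  noise_implanted  noise_stiffened
1000          0.00328         0.00978         0.00000        0.38594        0.38596          0.38597
2000          0.00028         0.00032         0.00000        0.44002        0.44065          0.44067
4000          0.00014         0.00014         0.00000        0.47983        0.48216          0.48216
6000          0.00007         0.00007         0.05058        0.52340        0.52498          0.52497
8000          0.00004         0.00004         0.04875        0.56135        0.56145          0.56144
10000         0.00002         0.00002         0.06487        0.59122        0.59083          0.59082
```

Reading the table: the RMSE columns compare stapes-normalized displacement
profiles against the healthy ear — the electrode alone perturbs the profile
least, stiffening the round window roughly triples the low-frequency error,
and both effects shrink rapidly with frequency. `peak_shift_mm` shows the
electrode never moves the place of maximal displacement by more than a
fifth of a section width (0.33 mm), i.e. tonotopic tuning is preserved; the
noise columns (fraction of displacement energy off the healthy peak) grow
slightly from healthy to implanted to stiffened at low frequencies.
`rhesusear simulate` writes raw per-frequency profiles, and
`rhesusear tonotopy` prints the Greenwood map.

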