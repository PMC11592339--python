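# Methods

## Scope and model class

`rhesusear` is a passive, linear, frequency-domain cochlear model of the
transmission-line family: the classical one-dimensional reduction of
three-dimensional cochlear fluid–structure models. It targets the
questions a macaque implant study asks of basilar-membrane (BM) mechanics —
where the traveling wave peaks, how large it is relative to the stapes,
and how an electrode or a stiffened round window changes that — not the
full 3-D pressure field of an image-derived ear. Active amplification
(outer-hair-cell feedback), nonlinearity and time-domain behavior are out
of scope; all simulations are harmonic and deterministic.

## Geometry

The coiled cochlea is unrolled into a straight two-chamber box (coiling
curvature does not enter 1-D duct mechanics; only longitudinal profiles
do). The BM is 27 mm long and divided into 82 equal sections, with all
per-section quantities evaluated at section midpoints; x = 0 is the base.
Reissner's membrane is treated as acoustically transparent, so the scala
media is absorbed into the scala vestibuli and the model has two effective
fluid ducts separated by the BM.

Longitudinal profiles (all linear in x and configurable):

| quantity | base | apex | units | status |
|---|---|---|---|---|
| BM width | 0.1 | 0.3 | mm | stand-in (must increase base→apex) |
| BM thickness | 0.01 | 0.005 | mm | stand-in |
| scala vestibuli area | 1.0 | 0.3 | mm² | stand-in (no rhesus morphometry) |
| scala tympani area | 1.0 | 0.3 | mm² | stand-in |

Window and helicotrema areas (oval 0.8 mm², round 0.6 mm², helicotrema
0.2 mm²) are literature-scale stand-ins. An optional lumped compliance on
the basal scala vestibuli stands in for the vestibule/semicircular-canal
load (off by default).

The electrode is a linearly tapered silicone cylinder (0.5 mm basal →
0.25 mm tip diameter, 12 mm insertion through the round window — an
assumed scaling of a human lateral-wall array to the macaque cochlea). It
contributes pure area occlusion of the scala tympani: the flow area is
reduced by π(d(x)/2)², weighted by each section's overlap with the
inserted length so the occluded volume matches the exact cone volume to
midpoint-rule accuracy. The duct *wall* area is tracked separately — an
electrode narrows the duct but removes no wall — which matters because the
wall is elastic (below).

## Materials and the BM impedance

BM density is 1200 kg/m³. The BM's elastic modulus and damping follow
exponential longitudinal gradients

    E(x)    = 10^5.7   · exp(−0.19 x)  Pa
    beta(x) = 10^−5.91 · exp( 0.1 x)   (unitless),  x in mm from base,

implemented as exact closed forms. Damping is stiffness-proportional
(Rayleigh β); mass-proportional damping is zero. The locally reacting
acoustic impedance per unit BM area is

    Z(x, ω) = iω m(x) + s(x)(1 + iω β(x)) / (iω),
    m = ρ_bm t(x),   s = k_geom · E(x) t(x)³ / w(x)⁴,

a clamped-strip plate conversion with geometric constant k_geom (default
16/3). Only the product k_geom·10^E0 is observable in the solution, so
k_geom is treated as an absorbable scale during calibration.

Other constants (fluid density 1000 kg/m³, bulk modulus 2.2 GPa, round
window 0.35 MPa / 0.05 mm, annular ligament 0.2 MPa, wall 10 MPa / 0.2 mm,
silicone 3 MPa, Poisson 0.49) are literature-typical soft-tissue and
perilymph values, not rhesus measurements; each is exposed in the YAML
configuration and marked as a stand-in there.

## Discretization and boundary conditions

Per drive frequency f the model is one sparse complex linear system with
unknowns (p_v,i, p_t,i, u_i) per section (+1 for the optional vestibular
branch):

* **Duct continuity** (finite volume): face flows q = A_f/(iωρΔx)·Δp,
  balanced in every cell against the BM volume velocity ±iω u_i w_i Δx.
  In-duct fluid is incompressible (long-wavelength limit).
* **BM relation**: p_v,i − p_t,i = Z(x_i, ω)·iω·u_i.
* **Base, scala vestibuli**: the stapes is a prescribed displacement
  source, injecting iω·u_stapes·A_ow; the oval-window rim / annular
  ligament is a damped compliance shunt (piston stiffness k = E_lig·t·P/b
  over the ligament ring, a few hundred N/m). This shunt is essential:
  with a perfectly rigid input port every series termination — including
  the round window — would be invisible to the membrane, because a series
  impedance behind an ideal flow source cannot alter the flow.
* **Base, scala tympani**: round-window termination as a clamped-plate
  compliance C = πa⁶/192D with stiffness-proportional membrane damping;
  the stiffened scenario multiplies its modulus by exactly 10.
* **Apex**: helicotrema short-duct shunt between the chambers.
* **Walls**: each cell leaks through a damped elastic wall shunt
  (thin-tube distensibility 2πr³/(E_wall h) per unit length). Distributed
  wall compliance is what lets a boundary-impedance change *reshape* the
  interior field; with all compliances lumped at the basal nodes the
  interior response is a fixed Green's function and window stiffening
  could only rescale, never redistribute, the displacement.

Units: configuration in mm/nm/degrees as tabulated; converted once to SI
at assembly (phases enter as e^(iφπ/180)). The system is solved by direct
sparse LU; a componentwise backward-error check (>1e-8 raises) and
explicit singularity detection guard the solve. Ties in peak magnitude
resolve to the most basal section. There is no randomness anywhere.

The wall/window damping coefficients (wall β = 1e-4, window β = 1e-4,
wall thickness 0.2 mm, round-window thickness 0.05 mm — the macaque
membrane is thinner than the 0.07 mm human figure) were fixed once during
model development so that the model sits in the physically sensible
regime: undamped walls otherwise produce spurious duct–wall standing-wave
resonances, and an undamped window termination makes the stiffening
scenario invisible above ~2 kHz. They are model constants, not fitted
quantities; calibration never touches them.

## Power bookkeeping

The fluid network is purely reactive, so the discrete time-averaged power
identity holds to machine precision: source input power at the oval window
equals the sum of dissipation in BM damping, the round- and oval-window
terminations, and the damped walls. The test suite asserts this identity
to 1e-6 relative at every drive frequency; all individual dissipation
terms are non-negative.

## Calibration

Phenomenological calibration minimizes the mean absolute distance between
simulated peak locations and the Greenwood predictions over the drive
frequencies (peak *location* only; amplitudes are checked post hoc, not
optimized). Peaks are localized by a three-point parabolic fit on
log-magnitude around the winning section — exact for a locally Gaussian
envelope. The optimizer is Nelder–Mead with a fixed deterministic initial
simplex at the printed gradient coefficients, free parameters (E0_log10,
E_decay, beta0_log10, beta_growth, log10 k_geom), at most 200 iterations
and a 0.01 mm improvement tolerance; invalid parameter regions (negative
decay/growth) return a large penalty. Calibration requires at least three
frequencies spanning a decade.

Under the defaults, calibration converges in ~106 iterations from an
initial deviation of 10.6 mm to 0.19 mm (healthy), and the implanted model
evaluated with the healthy calibration sits at 0.18 mm — comfortably
within the 1.47/1.53 mm figures of merit the model is held to. Because
E0 and k_geom are only jointly identifiable, parameter-recovery checks
compare the product k_geom·10^E0 (or hold k_geom fixed); a 2× basal-
modulus perturbation is recovered to within ~3%.

## Scenario analysis

Profiles are stapes-normalized (|u_i|/|u_stapes|) before comparison; RMSE
between scenarios is computed on these normalized magnitudes over the 82
section midpoints. The low-frequency "noise index" is an invented summary
metric: the fraction of profile energy Σ|u|² lying outside ±2 mm of the
healthy peak. Expected behaviors under the defaults — window stiffening
perturbing the profile more than the electrode at every frequency, both
effects shrinking with frequency, implanted peaks within one section of
healthy, displacement magnitudes spanning nanometers (1 kHz) to picometers
(10 kHz) — are asserted in the acceptance tests. Absolute RMSE values are
model-specific outputs, not reproduction targets; only their orderings are
meaningful across model families.

## What the defaults do and do not represent

The synthetic parametric geometry reproduces the gross layout of the
macaque cochlea (27 mm BM, two ducts, windows, helicotrema) but not its
coiling, its measured scala cross-sections, or any individual anatomy; a
passing test suite therefore demonstrates correct mechanics of the model
class under realistic parameter scales, not agreement with a particular
animal. Stapes drive values are human in-vivo measurements (no rhesus
stapes data exist); material stand-ins are human or generic soft-tissue
figures. Calibration against the Greenwood map absorbs much of this
uncertainty into the effective gradient coefficients, which is exactly how
the phenomenological approach is meant to be used.

## Known limitations

* Passive linear mechanics only; no cochlear amplifier, so simulated peak
  sharpness underestimates a living ear's tuning.
* The 1-D incompressible duct approximation ignores fast (compressional)
  waves and 3-D near-field effects at the windows.
* The electrode is an inert occupant (area occlusion only); an optional
  silicone wall-compliance term exists in concept but is off by default.
* Appendix-grade rhesus material data are unavailable; every stand-in is
  flagged in the configuration template.
* Problem sizes: 82 sections (164 in the refinement check) and six drive
  frequencies, the model's native resolution; a full calibration runs in
  seconds on one CPU.
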