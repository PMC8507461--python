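# Methods

This note documents the physical model, the numerical choices and the known
limitations of the `irscatter` dosimetry pipeline.

## Problem and scope

During an interventional-radiology procedure the operator is exposed almost
exclusively to photons scattered out of the patient. The machine logs every
irradiation event (technique factors, geometry, output) in its RDSR; an
indoor positioning system logs where the operator stands. The package
reconstructs the operational quantity Hp(10) — personal dose equivalent at
10 mm depth in the ICRU slab — at one or more dosemeter points that follow
the operator, event by event, and aggregates over the procedure. Organ
doses, eye-lens dose Hp(3), skin dose Hp(0.07) and patient dosimetry are
out of scope, as are skeleton extraction and camera calibration (traces are
ingested already expressed in the room frame).

## Coordinate frame and geometry

Right-handed frame, origin at the isocenter: +x patient left, +y cranial,
+z up; the tube is under the table, so the unrotated focal spot is at
(0, 0, −d_src) and the image receptor above. Primary angulation (+RAO
toward the patient's right) rotates the gantry about the patient axis,
secondary (cranio-caudal) about the lateral axis. Defaults
d_src = 0.75 m, d_iso→receptor = 0.35 m and the interventional reference
point 0.15 m from the isocenter toward the tube are standard C-arm values
and configuration-overridable; they are not clinic measurements.

The patient is a homogeneous ICRU-44 soft-tissue BOMAB-type phantom:
stacked elliptical cylinders (neck, trunk in three sections, arms, thighs,
calves) plus an ellipsoid head, nominal adult stature ≈1.7 m, abdomen
centred at the isocenter, with per-axis scale factors to match a real
patient. A rectangular prism (e.g. a 20 cm water slab) is available both as
a simplified patient model and for verification problems. Segments are
disjoint by construction, so the union volume equals the sum of segment
volumes (verified by Monte-Carlo point sampling in the tests).

The table is an attenuating slab (default 1.5 mm Al-equivalent) crossed
only by the primary beam; it contributes no scatter. The ceiling shield is
a rectangle of configurable lead equivalence; a ray crossing it is
attenuated by exp(−μ_Pb(E)·t), otherwise unaffected.

## Source term

The tube spectrum is a semi-empirical Birch–Marshall-type model: Kramers
production integrated over electron penetration depth (Thomson–Whiddington
constant 7.85·10⁵ keV²·cm²/g), self-attenuated through the anode along the
path set by the anode angle (default 12°), then filtered by inherent
(default 2.5 mm Al + 0.1 mm Cu equivalent, overridable — the real inherent
filtration of a given tube is rarely published) plus the per-event copper
and aluminium filtration from the log. Tungsten K lines (59.32, 57.98,
67.24, 69.07 keV) are added above the K edge with a yield scaling
(V/V_K − 1)^1.65; the line normalisation constant is calibrated once so
that line fractions at 100–120 kV are in the several-percent range typical
of this model class. Bins are 1 keV; photons below 10 keV are cut off —
they cannot reach an operator metres away through air and the
conversion-coefficient tables end there. The spectrum is relative: its
absolute magnitude cancels in the output normalisation.

The beam is a square pyramid whose apex is the focal spot and whose
projected area at the receptor plane equals the logged collimated field
area (flat field; heel effect not modelled). Field sizes logged at a
different reference plane can be accommodated through the configured
distances.

## Transport and scoring

Photons are tracked through the phantom by Woodcock (delta) tracking inside
its bounding box with the soft-tissue total attenuation as majorant —
exact for a homogeneous phantom and cheap to vectorise. Interaction
branches are sampled proportionally to the tabulated partial coefficients.
Compton scattering uses the free-electron Klein–Nishina distribution
(Kahn's sampling method) without the incoherent scattering function;
Rayleigh scattering is sampled from a Thomson-shaped angular kernel with
the tabulated coherent cross-section. Both simplifications are at the
few-percent level for scatter dosimetry at 60–90 keV and keep every kernel
closed-form and testable against quadrature oracles. Fluorescence after
photoabsorption in soft tissue is negligible and ignored. Russian roulette
(threshold 10⁻³, survival 1/10) bounds photon weights; no splitting.

At every Compton or Rayleigh interaction the attenuated probability of
scattering straight to each detector point is scored (next-event
estimation): pdf-per-steradian × exp(−optical depth through the remaining
phantom chord at the scattered energy) × shield transmission ÷ r². A
detector inside the beam additionally receives a deterministic primary
term. The operator's body is deliberately not modelled — the tally is
point fluence in air, and the backscatter a real dosemeter sees from the
wearer enters through the slab-phantom definition of the Hp(10)
conversion coefficients.

Statistical errors use 32 history groups (batch statistics), which absorb
the correlation of multiple scores per history; the per-bin variance is
propagated bin-wise through the conversion sum. An analog estimator
(weight entering a sphere, divided by πR² — exact for a convex body) is
implemented solely as an independent cross-check of the next-event
estimator and is exercised in the acceptance tests on a water-slab
problem.

Each event runs on its own generator seeded by (seed, SHA-256(event_id)),
so results are independent of event order and events can be simulated
concurrently without changing any number.

## Normalisation and uncertainty

Simulated doses are relative (per source photon). Simultaneously with the
tally, the code accumulates the kerma-area product per source photon
(Σ E·(μ_en/ρ)_air over sampled energies — plane-invariant in vacuum) and
the reference-point air kerma per photon (the same quantity divided by the
beam area at the reference plane). The absolute event dose is the relative
dose times the machine-reported P_KA (or K_air) over its simulated
counterpart. Consequently doses are exactly linear in the reported output,
and an event with zero reported output contributes exactly zero while
remaining in the report.

The reported expanded uncertainty is U = 2·Hp·√((u_stat/Hp)² + 0.05²):
Monte-Carlo statistics plus the 10 % (k=2) uncertainty of the machine-
reported output established by independent detector checks. Geometry and
positioning uncertainties are real but unquantified here and are listed as
such; the procedure mean over several points carries the standard error of
the per-point totals.

## Time synchronisation and movement

Events and traces are matched on timestamps after an explicit, user-
supplied clock offset (no automatic synchronisation). The operator
position is frozen at the latest valid sample at or before each event
start (hold-last-value, not interpolation — fidelity to the fixed-at-start
convention); if the nearest valid sample is older than `max_gap`
(default 5 s, a conservative choice for camera dropouts), the event is
flagged position-unknown, excluded from dose and counted in the report.
For acquisitions during which the operator demonstrably moves, an event
can be subdivided into n equal frames, each frame taking the trace
position at its own start and 1/n of the event output (the RDSR does not
resolve output within an event; acquisitions run at constant pulse rate).
Sub-frame output conservation is exact by construction. Detector points
are offsets from the tracked trunk reference, so multiple dosemeter
positions (chest, collar, …) ride along; when traces are planar, a
configured chest height completes the third coordinate.

## Physics data

Cross sections for air, water, ICRU-44 soft tissue, aluminium, copper,
lead and tungsten ship as plain-text tables (10–150 keV, 1 keV grid,
log-log interpolated): photoelectric from Cromer–Liberman f″, incoherent
from the free-electron Klein–Nishina closed form times electron density,
coherent from the Thomson kernel weighted by IT92 atomic form factors
(generator: `scripts/make_physics_tables.py`). Using the same
free-electron Compton in the tables and in the sampling keeps branch
probabilities and kernels mutually consistent. Against standard reference
tabulations the totals agree to within ~1–8 % (worst for the lead coherent
part, whose form-factor tail is overestimated); this is well inside the
needs of scatter dosimetry normalised to measured output. Air mass
energy-absorption coefficients and the Hp(10)/Φ slab coefficients (ICRP
74 / ISO 4037-style, normal incidence) are standard grid values with
provenance headers; the conversion-coefficient file is swappable. Angular
dependence of the conversion coefficients is ignored (broad scattered-
field incidence at the trunk) — a documented limitation.

## Synthetic study conditions

The generator reproduces the four study conditions as profiles: A — one
experimental exposure (79 kV, 0.3 mm Cu, 835 cm², P_KA 4.1 Gy·cm²); B —
abdominal procedure, 115 events / 17 acquisitions, 70–86 kV, 457–1091 cm²,
P_KA 163 Gy·cm², ceiling shield, operator stepping away during one
acquisition; C — extremity procedure, 19 events / 7 acquisitions, 66–82 kV,
P_KA 0.06 Gy·cm², operator beside the table; D — renal procedure, 186
events / 10 acquisitions, 54–630 cm², P_KA 10.5 Gy·cm², wandering operator.
Per-event P_KA is a log-normal shape rescaled to the exact case total,
with 60 % of the output assigned to acquisitions; traces are deterministic
waypoint scripts at 5 Hz with 3 cm Gaussian jitter and short dropout
bursts. Exact operator distances were not published; "close to the
patient" is realised as 0.7 m lateral of the isocenter at chest height.
What passing tests on these synthetic procedures demonstrate is the
correctness and stability of the pipeline — conservation, determinism,
estimator agreement, the direction and rough magnitude of the movement and
shield effects — not agreement with any clinical measurement, which would
require the original logs, traces and room survey.

## Problem sizes

Default history budgets are 10⁶ per procedure, allocated to events
proportionally to P_KA with a floor of 10⁴ (variance where the dose is);
unit tests run 10⁴–10⁵ histories per check and the acceptance checks
10⁵–4·10⁵, sizes at which the next-event estimator resolves chest-distance
doses to ~1 % statistics.

## Known limitations

- Homogeneous rigid phantom; no lungs/bone, no posture.
- Free-electron Compton and form-factor Rayleigh (few-percent level).
- No electron transport, no tube leakage or off-focal radiation, no room
  (wall/floor) scatter.
- Table attenuates the primary only; shield position must be supplied (it
  is not tracked).
- Normal-incidence conversion coefficients.
- Isocenter displacement during a procedure is accepted per event via the
  log dialect but not tracked automatically.
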