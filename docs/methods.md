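# Methods

## The model

`dlrflight` implements a phenomenological guidance model for insect
flight near a point light source, built around the dorsal light response
(DLR): the reflex that keeps an insect's dorsal side turned toward the
brightest region of its visual field. The agent is a point mass carrying
a right-handed orthonormal body triad (forward **b**<sub>x</sub>, left
**b**<sub>y</sub>, dorsal **b**<sub>z</sub>) in a world frame with z up
and gravity **g** = (0, 0, −9.81) m/s².

Three proportional controllers each command an angular speed equal to a
gain times an angular error:

| controller | error | gain | meaning |
|---|---|---|---|
| 1 | θ, dorsal axis vs line of sight (LOS) to the light | k₁ (1/s) | dorsal light response |
| 2 | γ, dorsal axis vs vertical | k₂ (1/s) | passive/active righting |
| 3 | β, forward axis vs velocity | k₃ (1/s) | weathercocking |

Each controller contributes an angular-velocity vector
ω<sub>i</sub> = k<sub>i</sub>·θ<sub>i</sub>·û<sub>i</sub>, where
û<sub>i</sub> is the unit normal of the plane spanned by the current and
target vectors (their normalised cross product) — the minimal rotation
nulling that error. The three vectors are summed within each time step
and applied as a single axis-angle rotation of the whole triad, followed
by Gram–Schmidt re-orthonormalisation. When a controller's current and
target vectors are exactly antiparallel the rotation plane is undefined;
a deterministic fallback axis is used — a body axis orthogonal to the
vector being steered (**b**<sub>x</sub> for the dorsal-axis controllers,
**b**<sub>y</sub> for the forward-axis controller).

Translational dynamics combine a body-fixed thrust, gravity, and
quadratic drag:

    a_b    = a_forw · b_x + a_dors · b_z
    a_net(t) = g − v̂(t−1) · c·|v(t−1)|² + a_b(t)
    v(t)   = v(t−1) + a_net(t)·Δt
    p(t)   = p(t−1) + v(t)·Δt

Integration is semi-implicit Euler exactly as indexed above (the
position update uses the already-updated velocity). The drag form factor
is pinned to the terminal velocity: c = g/v<sub>t</sub>², so a free-fall
from rest asymptotes to v<sub>t</sub> (a property test verifies this to
1%). The body-fixed thrust direction encodes the anatomical constraint
that flapping fliers produce net aerodynamic force in a roughly constant
orientation relative to the thorax; the model makes no attempt at
realistic flapping aerodynamics.

### Variants

* **dlr** — all three controllers active.
* **light_off** — controller 1 disabled; bit-identical to a dlr run with
  k₁ = 0 (tested).
* **compass** — controller 1 instead holds the LOS at a fixed egocentric
  direction, the body-frame LOS recorded at t = 0. This represents a
  celestial compass corrupted by a nearby source. The error is the angle
  between the current body-frame LOS and the stored reference; the
  rotation axis is their cross product mapped to the world frame. With
  the reference set dorsally the variant reduces exactly to dlr
  (tested bitwise).

### Default parameters

The fixed "motif" parameter set is k₁ = 15, k₂ = 1, k₃ = 15 s⁻¹,
v<sub>t</sub> = 3.5 m/s (giving c = 0.80 numerically, the deceleration
in m/s² per (m/s)² of airspeed), a_forw = 5, a_dors = 15 m/s²,
Δt = 10 ms.
The randomised batch experiment draws 300 parameter sets uniformly from
0 < k₁ < 20, 0 < k₂ < 20 s⁻¹ (k₃ fixed at 15), 0.5 < v<sub>t</sub> <
10.5 m/s, 0 < a_forw < 10, 9.81 < a_dors < 24.81 m/s², with start
positions uniform in the ±5 m cube about the light and level initial
attitude at a uniformly random horizontal bearing. The initial speed is
not constrained by the model description; the default is 2 m/s along
the initial bearing (configurable, recorded in output metadata). The
batch medians are insensitive to this choice (checked at 0, 2 and
4 m/s).

### What the sweeps show

Each run's dispersal is summarised by the mean rate of change of
distance to the light over the final 3 s of the 5-s simulation
(negative = approach). With the dorsal-light controller active the
median is ≈ 0 (entrapment: agents neither escape nor crash into the
light on net); with it disabled the median is strongly positive
(dispersal ≈ +1.1…1.3 m/s in this implementation). The compass variant
also disperses here (median ≈ +1.4…+2.0 m/s): holding the light at an
arbitrary egocentric direction is generally incompatible with the
upright-righting controller and the climb-inducing thrust envelope
(a_dors ≥ g), so most agents end up on outward paths, with a minority
spiralling into the light. Whether a compass-holding agent should
approach or escape on net is geometry-dependent (half the stored
references point "behind" the agent), and both servo sign conventions
were checked to give the same positive median.

## Kinematics and measurement pipeline

* **Orientation from markers.** The marker frame is a rigid L: origin
  marker plus two 4-mm arms along the body's forward and left axes (arm
  length configurable; the real frames' arm length is not documented, so
  4 mm is a fixture choice). Reconstruction is Gram–Schmidt on the two
  arms — exact for a rigid L. Collinear/degenerate triplets yield an
  invalid 3-DoF pose rather than an exception.
* **Attitude.** Bank = |arcsin(left·ẑ)| ∈ [0°, 90°], reflecting across
  the horizontal plane (a fully inverted body scores as upright). Pitch
  = arccos(forward·ẑ) ∈ [0°, 180°] from the global vertical; the
  complementary convention (elevation above horizon) is exposed as
  `pitch_from_horizontal` since plots in this literature use both.
* **Dorsal-tilt index.** Per frame, the dorsal axis and the LOS to the
  light are projected onto the ground plane, normalised and dotted:
  +1 = dorsum tilted straight at the light, −1 = straight away. Frames
  with a numerically zero projected dorsal axis (|proj| < 1e-8, i.e.
  exactly level or exactly inverted flight) are excluded.
* **Aerodynamic acceleration.** a_aero = d²p/dt² − g by central
  differences, expressed on the body axes. Level hover gives
  (0, 0, +9.81): the wings support the weight dorsally.
* **QC filters.** (1) frames whose reconstructed arm length deviates by
  more than 0.4 mm, or whose inter-arm angle deviates by more than 5°,
  from the per-track medians are removed (strict inequalities, medians
  over valid frames only); (2) tracks are split where the frame is
  missing for more than 0.5 s (short fragments are kept, with their
  span in metadata); (3) samples slower than 0.3 m/s are removed
  (walking/settled animals), speed from time-aware central differences
  on the unsubsampled track; (4) before statistics, tracks are
  subsampled to 10 Hz (every round(rate/10)-th sample, starting at the
  first) to limit pseudo-replication.
* **Trajectory metrics.** Tortuosity = path length / net displacement
  (undefined below 1 mm displacement — closed loops raise a degenerate
  -path error). The light-relative series gives the signed ground-plane
  bearing between velocity and LOS (0 = toward the light, ±90 =
  orthogonal; positive = light on the right), the signed horizontal turn
  rate (positive rightward/clockwise from above), the light side, and
  the range. The turn-bias table counts light-side × turn-direction over
  frames within 30° of orthogonality, dropping zero-turn-rate frames.
* **Circular statistics.** Rayleigh z = n·r̄² with the standard
  large-sample p approximation; axial (bimodal) bearing distributions
  are angle-doubled (a → 2a mod 360) first, collapsing
  clockwise/anticlockwise orbiting into one mode. Chi-square on the 2×2
  turn-bias table is Pearson without continuity correction, df = 1; a
  zero marginal is reported as undefined rather than 0. Rank tests
  delegate to scipy, reporting the normal-approximation z.

## Motif classification

The field labels (orbit / stall / invert) were assigned by eye in the
original observations; this package operationalises them with
configurable heuristics (`MotifThresholds`), defaults:

* **orbit** — cumulative unsigned smooth heading change ≥ 180° with
  range coefficient-of-variation < 0.3 about the light and mean speed
  > 0.3 m/s. "Smooth" excludes per-sample heading jumps ≥ 30°: a
  velocity reversal through zero horizontal speed otherwise contributes
  a spurious exact-180° turn.
* **stall** — a local speed peak followed by a trough below 50% of that
  peak while gaining ≥ 0.1 m of altitude, pitched nose-up on average
  (mean forward·ẑ > 0.2), with no inversion inside the window. The scan
  is local (peak→trough pairs) because a stalling flight typically
  re-accelerates afterwards; a global speed maximum would land on the
  later dive. The 50% fraction reflects the model's stall depth: with
  the motif parameter set the simulated stall collapses speed to
  ~15–60% of the entry peak before the agent is pulled back.
* **invert** — dorsal·ẑ < 0 sustained for ≥ 0.05 s.

Motifs can co-occur; in particular the simulated "flying away" entry
stalls and then inverts, matching the observed sequence in real insects
climbing over a light.

## Synthetic data

The generator produces closed-form motif trajectories so the entire
pipeline is testable without recordings:

* **orbit** — a circle of configurable radius about the light at the
  light's height, body banked toward the centre; for any constant bank
  the projected dorsal axis points exactly at the light (tilt index 1).
* **stall** — a straight nose-up climb with speed s₀·e^(−λt) (default
  λ = 1 s⁻¹, climb angle 60°). The field descriptions give no
  trajectory equations; the exponential decay is the simplest law with
  the described character.
* **invert** — a vertical half-loop over the light with the dorsal axis
  centripetal: fully inverted at the apex, diving afterwards.
* **cruise** — constant-speed level flight, by default perfectly
  straight (tortuosity exactly 1). For no-light control *batches* a
  smooth sinusoidal heading weave (amplitude parameter, frequency drawn
  from the seed in 0.3–0.8 Hz) emulates undisturbed searching flight.
  This matters for the control's bearing statistics: a straight segment
  spends most of its time moving radially toward/away from any fixed
  point (time per bearing bin scales as 1/sin²·bearing), so a pooled
  batch of straight chords is axially concentrated after angle doubling
  no matter how the geometry is randomised — it would wrongly reject
  uniformity. Real undisturbed flight meanders, decorrelating bearings
  within a track; `cruise_control_batch` (56 tracks of 3 s, ±180°
  weave) reproduces that and pools to a non-significant Rayleigh test.

The marker observation model places the three L-frame markers from each
pose, adds isotropic Gaussian noise per coordinate, and drops samples
with a given probability; defect injection (`corrupt_markers`) perturbs
an exact count of frames by an exact arm-length or inter-arm-angle
deviation so the QC thresholds can be tested sharply. All generators are
deterministic given their integer seed.

What the synthetic data does *not* emulate: wingbeat oscillations,
tracking spline smoothing artefacts, wind drift, marker mislabelling
(only geometric corruption), and arena-wall interactions. Tests passing
on these fixtures therefore demonstrate the pipeline's correctness on
idealised geometry, not robustness to every failure mode of real
capture data.

## Numerical choices

* Orthonormality is enforced to 1e-9 in the simulator (re-Gram–Schmidt
  each step) and checked to 1e-6 at I/O boundaries; triad columns
  failing the check downgrade the track to 3-DoF with a warning.
* Velocities/accelerations use `np.gradient` (central differences at
  interior samples, one-sided at the ends, actual time spacing). No
  smoothing is applied — spline smoothing belongs to the upstream
  digitisation stage, out of scope here.
* Angles are degrees at every API surface; radians internally.
* Strict inequalities implement all removal thresholds, so boundary
  samples (exactly 0.4 mm, exactly 5°, exactly 0.3 m/s) are kept.
* Per-run problem sizes follow the documented experiment (300 runs ×
  5 s × 10 ms); the full test suite and the acceptance script each run
  in about one to two minutes on a single core.

## Known limitations

* The compass variant disperses on net in this implementation under
  either servo orientation (see the discussion of servo geometry
  above); descriptions of compass-corrupted flight sometimes expect net
  approach instead, so treat that variant's dispersal sign as
  model-dependent.
* Motif thresholds are heuristics standing in for human judgement; they
  are validated against the generator's ground truth and the
  simulator's fixed-parameter runs, not against labelled field data.
* The flight-speed filter recomputes speeds after removal, so repeated
  application can in principle differ at segment boundaries; it is
  idempotent on the fixture classes tested (cruise + perch).
* No wind, no multiple light sources, no spectral/wavelength effects.
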