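# Methods

`cisim` simulates the insertion of a preformed, stylet-straightened cochlear-
implant electrode array into a 2D model of the cochlear lumen, grades the
geometric interference between implant and anatomy on a five-step
trauma-risk scale, and optimizes the insertion plan under the constraints of
an automatable insertion tool.  This note documents the models, their
assumptions, the parameters that matter, and what the synthetic study does
and does not show.

## Electrode model

The array is an inextensible planar curve of fixed total length (default
24 mm).  Two closed-form shapes define its kinematics:

* **Manufactured (relaxed) shape** — a logarithmic spiral
  `r(θ) = a·exp(bθ)` over the distal `spiral_span` (default 14.5 mm of arc
  from the tip), continued by a straight basal run.  Defaults: tip radius
  `a = 2.2/2.4/2.6 mm` for the pronounced/moderate/flat archetypes,
  growth rate `b = 0.10`.
* **Start configuration** — with the stylet fully inside, the array is not
  straight but bowed ("banana-shaped"); modelled as a circular arc of
  sagitta 0.6–3.0 mm over the full length (flat → pronounced archetypes).

Stylet extraction by `s` mm releases the distal `s` mm of arc, which reverts
immediately and completely to the manufactured shape; the unreleased
remainder keeps the start configuration; the pieces join with position and
tangent continuity.  This purely kinematic release rule is the model's core
assumption: no elastic deformation under wall contact is computed, so a
placed shape intersecting the anatomy simply overlaps it in the
visualization, exactly as the grading expects.

Landmarks: 22 contact centres between 0.7 and 14.3 mm of arc from the tip,
the tip itself, and the white marker 7.6 mm behind the tip (arc length is
assumed; the chord interpretation differs by < 0.1 mm at these curvatures).
The insertable portion (tip to the basal marker ribs) is 15.6 mm, so full
clinical insertion corresponds to a feed of 8.0 mm beyond the
marker-at-cochleostomy datum.

Profiles record states every 0.15 mm of extraction up to `s_max = 15.3 mm`
(102 steps), inside the 0.1–0.25 mm digitization range; the finer step also
keeps the insertion-tool rotation-rate cap (5°/step) compatible with the
~`Δs/r` rad/step of frame rotation that following the spiral demands.
Between stored states, queries are answered by per-vertex linear
interpolation after arc-length reparameterization (sub-resolution at these
step sizes).

Shape fitting (`fit_shape_model`) reverses the synthesis: an
orthogonal-distance least-squares fit of a logarithmic spiral (centre,
scale, growth rate, and per-point angles as free variables) plus up to
three connected straight segments over the basal points.  The segment count
is chosen by parsimony: counts are increased from zero and the smallest
count whose RMS improves by less than 10 % over the next is kept.
Collinear input degenerates to a straight-segment-only model.

## Cochlea model

The lumen is represented by inner (modiolar) and outer (lateral) wall
polylines in a canonical frame: cochleostomy at the origin, entry axis
(best-fit line through the basal 7.6 mm of the centerline) along −x, lumen
turning left.  Both the electrode and the lumen then share one curl
handedness by construction.

The synthetic generator builds both walls as radially offset logarithmic
spirals (`b = 0.12`, 2.0 turns), with a radial lumen width of 0.85 of the
inter-turn gap (clamped to 0.45–2.6 mm).  The width fraction is deliberately
generous: the imaging workflow the study emulates segments the whole bony
labyrinth, not the scala tympani, and therefore overestimates the channel;
a `LumenWidthProfile.scale < 1` emulates a tighter, scala-tympani-like
segmentation.  The geometry is rescaled once so the measured Escudé distance
A (greatest lateral dimension of the basal turn, longest chord from the
round-window end of the outer wall) hits the target exactly; presets
CS/CM/CL = 8.5/9.0/9.5 mm are configuration defaults within the human range,
chosen narrower than the arrays' shape spread so that implant variability —
not anatomy — dominates the outcome differences, consistent with the
study's qualitative finding.

For mesh input, a half-plane anchored on the modiolar axis is rotated in 5°
steps; per cut, the radially innermost and outermost intersection points of
each lumen loop are picked automatically (replacing manual clicks), loops of
deeper turns being assigned to virtual angles beyond 360°.  The point cloud
is projected onto its orthogonal-distance-regression plane (SVD) and
canonicalized as above.

**Overlap regions.** Penetration is scored against a bony shell: the lumen
polygon buffered by 2.5 mm, minus the lumen, minus the open half-space
beyond the entry plane (surgical access), minus a 0.35 mm neighbourhood of
the cochleostomy opening (drilled passage).  Without the last subtraction,
buffering the polygon's artificial mouth-closing edge creates a phantom
bone sliver exactly where the electrode must pass.

## Trauma-risk grading

Each insertion step produces an overlap report: exact polygon intersection
area with the shell, per-cross-section penetrated width (sections
perpendicular to the central path every 0.25 mm, endpoints on the inner and
outer outline offsets), tip-region overlap fraction, simultaneous
inner-and-outer-wall contact within a 2 mm path window (restraint), and
central-path excursions beyond the wall by more than the local width (far
outside).

The published scale is a subjective expert rating in which the rater's
mechanical experience compensates for the missing deformation simulation.
This package replaces it with a deterministic first-match cascade over the
scale's quantitative anchors, evaluated IV → 0:

| grade | predicate |
|---|---|
| IV | far outside, or restraint with ≥ 2 contact regions |
| III | tip overlap = its whole size, or body penetration = full cross section, or restraint |
| II | tip overlap > half its size, or body penetration > 0.25 of the cross section, or head-on tip incidence (< 45° between tip tangent and wall normal) |
| I | any remaining contact (≥ 10⁻⁶ mm² / fraction, below which geometry is treated as contact-free) |
| 0 | no contact |

"Size" of the tip is operationalized as its area, "cross section" as the
local outline width.  The cascade is monotone in both penetration
fractions; the I→II boundary sits exactly at a body-penetration fraction of
0.25.  The rejected objective alternative — depth of the first contact — is
carried as an optional report field but not used in summaries.  The grades
rate prospective geometric risk only; they are not a histological trauma
scale, and the determinism is a fidelity trade: a human rater would forgive
some grazes that the cascade counts as grade I.

## Insertion strategies

Poses are rigid: rotation `dphi` about the cochleostomy, then translation
`(−dx, +dy)`; feed `dx` is measured from the advance-off-stylet datum
(white marker at the cochleostomy).

* **autoAOS** — feed coupled 1:1 to extraction, `dy`/`dphi` frozen after
  initial positioning (drill-canal scenario; the canal is recorded as two
  guide lines of 2 mm bore and checked for violations by the unreleased
  portion, but exerts no straightening force).  Because the coupling runs to
  `s_max`, the automated plan over-inserts past the clinical full-insertion
  feed — a deliberate reproduction of the technique's known failure mode.
* **manAOS** — same feed; the surgeon's intuitive compensation is a greedy
  per-step rotation minimizing that step's overlap cost, capped at 5°/step,
  with the neutral orientation always available (relaxing compensation).
  The per-step candidate set therefore contains the automated choice, so the
  manual plan never scores worse than the automated one at any step.  The
  compensation magnitude has never been measured clinically; the greedy rule
  is a stand-in.
* **optIns** — full constrained optimization, below.

## Optimizer

Objective: summed step cost `area + 0.5·depth² + 0.05·contacts` (weights
configurable); the quadratic depth term punishes deep point contacts, the
contact-count term makes genuinely contact-free placements preferable to
slight grazes.  Constraints: monotone feed with per-step caps (0.5 mm
beyond the 1:1 coupling, 0.2 mm lateral, 5° rotation), free initial
positioning (up to 7 mm shallower, ±1 mm lateral, ±10°), and a terminal
condition: the final step must reach the full-insertion feed (8.0 mm) —
"full insertion with complete stylet removal".

Search: (1) seed feed schedules `dx(s) = clip(s + lag, …)` for lags −3/−5/−7
mm — lagging feed lets the array curl while shallow, and the clip holds full
insertion while extraction completes; (2) per schedule, an exact dynamic
program over a (dy, dphi) lattice (0.2 mm / 5° spacing — the rate caps
couple only consecutive steps, so the chain DP is the lattice optimum);
(3) two fine local DP passes jointly re-optimizing the whole trajectory
over small offsets of all three parameters; (4) coordinate-descent
polish; (5) exact-geometry comparison against the terminal-consistent
baselines, so the reported plan is never dominated.  All steps are
deterministic.  The inner loops use a rasterized signed-distance field of
the open region (0.05 mm cells, 11 samples across the width, sections every
0.4 mm, and a 0.05 mm safety margin treated as contact so that solver zeros
are exact-geometry zeros); every reported number is recomputed with exact
polygon clipping.

An exhaustive lattice search (same DP machinery at coarse levels, validated
against literal enumeration on tiny instances) serves as the optimizer's
oracle on reduced instances.

## Synthetic study and its limits

The packaged fixtures — two pronounced units (RE01, RE08, distinguished by
±5 % start-bow and ±2 % curl-radius unit variability), one moderate (RE06),
one flat (RE07), against small/medium/large cochleae — are constructed so
that a low-overlap plan exists for every pair: the moderate array's
manufactured spiral is fitted to the medium cochlea's mid-lumen curve at
full insertion (rigid-alignment residual < 0.1 mm), and the archetype and
size spreads perturb around that match.  With this construction the batch
reproduces the study's qualitative pattern: the automated technique is
dominated by grades III–IV (over-insertion plus the un-compensated start
bow), the manual technique improves on it at every step, and the optimized
insertion is dominated by grade 0 with the no-contact share the largest
histogram bin in all 12 cases.

What passing does **not** show: real arrays deviate from log-spiral + arc
shapes and deform elastically on contact; real lumens are not offset log
spirals (in particular, the basal turn of a log spiral is uniformly curved,
which makes the straight marker-depth insertion of the technique slightly
more interfering here than in real anatomy); and the deterministic cascade
is not a human rater.  Numbers produced on these fixtures characterize the
method, not any clinical population.

Problem sizes used by the packaged study: 102 extraction steps per profile,
~600-vertex outlines, 0.05 mm cost-field cells; the full 36-insertion batch
with optimization runs in minutes on one CPU.
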