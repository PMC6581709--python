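# Methods

## Problem and model

`handloc` analyzes tactile-localization (topesthesia) assessments in which
vibrotactile stimuli are delivered at 24 sites on the volar hand and the
subject indicates the perceived location on a schematic hand drawn on a
touchscreen. Because the hand is a non-convex shape, errors are measured
*geodesically*: the length of the shortest curve connecting two points that
stays inside the hand outline. An error from a fingertip to the neighboring
fingertip is therefore the path around the web space, not the chord across
it — the distance that is meaningful on the skin surface.

Three outcome measures are computed per stimulation site from the responses
reported for that site:

- **distance** — mean geodesic error of the individual responses from the
  site (accuracy at the trial level),
- **offset** — geodesic error of the response *center* from the site
  (systematic accuracy; the arrow of the distortion map),
- **spread** — mean geodesic distance of the responses from their center
  (precision; the circle of the distortion map).

Discretizing each response to its geodesically nearest site yields a 24×24
row-percentage confusion matrix; its diagonal is the correct localization
rate (CLR). A fingertip subset (sites 1, 5, 9, 13, 17 — the distal
phalanges of digits I–V) is supported for CLR because fingertip deficits are
clinically salient.

## Hand template

The schematic hand is a simple polygon with 24 labeled sites: digit I
carries distal phalanx, proximal phalanx, distal metacarpal and proximal
metacarpal (thenar) sites (1–4); digits II–V carry distal, intermediate and
proximal phalanx plus distal metacarpal sites (5–20); four further sites
cover the central palm (21–24). Coordinates use the origin at the
wrist-crease midpoint, y distal, x toward the thumb on a right hand; one
unit is 1 mm on the 17 cm reference hand (`units_per_cm = 10`). The shipped
outline is a versioned parametric fixture — rectangular finger lobes with
domed tips and web notches down to the knuckle line, an oblique thumb lobe,
and an 80 mm palm — with proportions of a standard adult hand. All metrics
are template-parametric: any template passing the validator (simple CCW
polygon, 24 sites inside it, positive hand length) can be substituted via
the JSON template format.

Palm sites need a `distal_rank` for the distal→proximal colormap; the upper
palm pair is rank 4 and the lower pair rank 5, continuing the 0–3 ranks of
the digit chains.

Left and right templates are exact mirror images, so geodesic distances
between corresponding site pairs agree to machine precision on both sides.

## Geodesic engine

Shortest paths are computed exactly with a visibility graph over
{endpoints} ∪ {polygon vertices}, with an edge wherever the connecting
segment lies within the closed polygon, followed by Dijkstra
(`scipy.sparse.csgraph`). Visibility is tested with `shapely` coverage on
the polygon dilated by 1e-9 template units, so segments grazing the
boundary (collinear with an edge, touching a vertex) count as visible;
points within 1e-9 of the boundary count as inside. Vertex–vertex distances
and per-site distance fields are cached per engine; caching reuses exact
intermediate results only and cannot change answers. Tests verify the
engine against an independent brute-force oracle: shortest paths on a fine
8-connected grid graph restricted to the polygon, which converge to the
true geodesic from above (octile overestimate ≤ 8.24 % plus snapping
error).

## Response center and degenerate inputs

The per-site response center is the arithmetic centroid, clamped to the
nearest boundary point when it falls outside the outline (responses split
across two fingers put the centroid in the web notch). The centroid was
chosen over a geodesic (Fréchet) mean for determinism and cost; the
discretization metric can be switched to Euclidean
(`discretize_response(..., metric="euclidean")`) for sensitivity analyses.
Ties in nearest-site assignment go to the lowest site ID. Sites with no
responses carry NaN (undefined) metrics and are excluded from across-site
means and SDs; missing trials are counted and reported but never imputed.
Note `distance ≥ offset` is a theorem only where geodesics are straight
lines (convex neighborhoods); it is asserted in tests only there.

## Units, normalization, rounding

Metrics are computed in template units, converted to centimeters on the
subject's physical hand using the measured hand length, and — when
normalized output is requested (the default) — multiplied by
17 / measured hand length so that subjects of different hand sizes are
comparable on the 17 cm reference hand. Report output rounds lengths and
percentages to one decimal using half-up rounding; raw double precision is
retained internally. Across-site ± values are population standard
deviations over the defined sites.

## Clinical cross-walk (NSA localization subscale)

The Nottingham Sensory Assessment localization subscale tests six
locations (distal phalanges of digits I, III and V, distal metacarpals of
digits II and V, thenar eminence) three times each, scoring 2 if all three
repetitions are localized within 2 cm, 1 if one or two are, 0 otherwise
(total 0–12). These six locations coincide with grid sites 1, 8, 9, 17, 20
and 4 by construction of the template. `nsa_from_session` emulates the
clinical rule on automated data: the first three responses at each mapped
site are scored correct iff their geodesic error on the subject's physical
hand is ≤ 2 cm.

## Virtual subjects

The simulator replaces the glove hardware with parametric distortion
fields: `identity`; `distoproximal_shift` (displacement of fixed length
proximally along the digit axis, derived from the line through the digit's
site chain, since no axis is otherwise defined); `palm_compression`
(perceived = attractor + c·(true − attractor), attractor defaulting to the
palm-site centroid); and `custom` per-site vectors. Isotropic Gaussian
noise (`noise_sd_cm`) is added before clamping into the outline — clamping
induces a small inward bias near boundaries, so parameter-recovery tests
use interior sites. Each attempt lapses independently with probability
`lapse_prob`; a trial is missing iff all three attempts lapse, giving a
missing fraction of `lapse_prob³`. Per-trial randomness is counter-based
(seeded by session seed and trial index), so sessions are bit-reproducible
regardless of evaluation order.

Archetype parameters (chosen once, as plausible magnitudes for the
phenotypes they emulate): `healthy` = identity + σ 0.4 cm;
`patient1_like` = 2.0 cm distoproximal shift + σ 0.8 cm (a 2 cm shift moves
each fingertip image within a few millimeters of the same digit's
intermediate-phalanx site, so noise-free responses discretize one segment
proximally); `patient2_like` = palm compression 0.25 toward the palm
centroid + σ 2.0 cm + lapse 0.25 (≈ 1.6 % missing, about two of 120
trials). What the simulator does **not** model: anisotropic or
digit-specific noise, response times, attention drift across the session,
touchscreen calibration error, and within-subject day-to-day variability —
passing recovery tests shows the metrics are correct for the programmed
field family, not that real patients follow it.

## Protocol

The default protocol is 24 sites × 5 repetitions = 120 trials in seeded
pseudo-random order with no site repeated back-to-back (rejection sampling
with a swap-repair fallback; infeasible constraint sets raise). The
original system's exact sequencing constraints are unknown, so the
no-immediate-repeat constraint is an explicit, documented choice that can
be disabled.

## Problem sizes used in the shipped checks

Grid-oracle equivalence uses a 2 mm grid (≈ 3.5 k nodes) and 100 random
interior pairs on the default template, and a 0.02-unit grid on the
L-polygon closed-form example. The spread closed form (E[spread] =
σ·√(π/2) for isotropic Gaussian responses in a convex neighborhood) is
checked at n = 5000 samples, σ = 0.5 cm, within 2 %; lapse calibration uses
10 000 simulated trials against the binomial 99 % interval; shift recovery
uses δ ∈ {0.5, 1, 2} cm at the intermediate-phalanx sites of digits II–V
(vertical finger segments where the shifted target is reachable in a
straight line), exact to 1e-6 noise-free and within 3σ/√5 at σ = 0.5 cm.

## Known limitations

- The outline is schematic; per-subject anatomical outlines (photographs,
  scans) and 3D hand surfaces are out of scope.
- Offsets computed with the clamped centroid differ from a true geodesic
  mean when responses straddle a web notch; the alternative center is not
  part of the validated surface.
- The published per-location worked example ships printed, already
  normalized values; raw response coordinates for those assessments are
  not available, so only the aggregation and scoring layers can be checked
  against them.
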