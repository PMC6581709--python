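# handloc

Automated tactile-localization (topesthesia) assessment on a schematic
hand, for researchers and clinicians quantifying somatosensory deficits —
e.g. after stroke — beyond what coarse clinical scales resolve.

A subject receives vibrotactile stimuli at 24 sites on the volar hand
(four per digit plus four palm sites) and indicates each perceived
location on a schematic hand; the standard protocol tests every site five
times in pseudo-random order (120 trials, up to three attempts per trial).
`handloc` provides the full analysis chain plus a virtual-subject
simulator standing in for the glove hardware.

For each site *s* with responses r₁…rₙ and response center c (clamped
centroid), with d_g the geodesic distance inside the hand polygon:

- distance(s) = (1/n) Σᵢ d_g(rᵢ, s)   — trial-level accuracy
- offset(s) = d_g(c, s)        — systematic accuracy (distortion-map arrow)
- spread(s) = (1/n) Σᵢ d_g(rᵢ, c)   — precision (distortion-map circle)

plus the 24×24 confusion matrix of nearest-site discretized responses,
whose diagonal is the correct localization rate (CLR), and a cross-walk to
the Nottingham Sensory Assessment localization subscale (6 locations ×
3 repetitions, 2 cm tolerance, scored 0–2 per location, total 0–12).
Lengths are reported in cm, normalized by default to a 17 cm reference
hand length (× 17 / measured hand length).

Geodesics are exact: a visibility graph over the polygon vertices plus
Dijkstra, so an error from one fingertip to the next is measured around
the web space, not across it.

## Worked example

Simulate a virtual subject with a 2 cm distal→proximal perceptual shift
(a common post-stroke distortion archetype), score the session, and apply
the clinical cross-walk:

```
$ handloc simulate --archetype patient1_like --seed 7 --side left --out p1.json
$ handloc score --in p1.json
n_trials=120  n_missing=0  normalized=True
mean offset   [cm] 2.0 ± 0.4
mean spread   [cm] 1.3 ± 0.8
mean distance [cm] 2.5 ± 1.0
mean CLR       [%] 20.0 ± 28.9
$ handloc nsa --in p1.json
digit_I_distal_phalanx       1
digit_II_metacarpal          0
digit_III_distal_phalanx     0
digit_V_distal_phalanx       1
digit_V_metacarpal           0
thenar_eminence              0
Total                        2
```

The mean offset recovers the programmed 2 cm shift; the low CLR (20 %)
reflects responses discretizing one segment proximally on every digit; and
the NSA total of 2/12 shows how such a distortion collapses the clinical
subscale, since most 2 cm-shifted responses fall at the edge of the 2 cm
clinical tolerance. `handloc plot map --in p1.json --out map.svg` renders
the distortion map (arrows site → response center, semitransparent spread
circles, yellow→blue distal→proximal site coloring) and
`handloc plot confusion ...` the confusion-matrix heatmap with grid lines
delimiting the digits.

The same analyses are available as a library (`handloc.summarize`,
`handloc.confusion_matrix`, `handloc.nsa_from_session`, ...) on session
JSON/CSV files documented in `src/handloc/session.py`.

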