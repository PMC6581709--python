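"""Published per-location values from two right-hemispheric stroke case
assessments, used as worked examples for the aggregation and NSA scoring
layers.

Values are normalized to a 17 cm hand length.  ``OFFSET_CM`` and
``SPREAD_CM`` hold the 24 per-location offset and spread values (cm, one
decimal) for each hand; ``NSA_SCORES`` holds the six clinical
localization-subscale scores (0-2) per hand, in the standard location
order (digit I distal phalanx, digit II metacarpal, digit III distal
phalanx, digit V distal phalanx, digit V metacarpal, thenar eminence).

Hands are keyed ``"<case>_<side>"``; for both cases the left hand is
contralesional.
"""

from __future__ import annotations

HANDS = ("case1_left", "case1_right", "case2_left", "case2_right")

# fmt: off
OFFSET_CM: dict[str, list[float]] = {
    "case1_left": [
        1.8, 0.2, 0.7, 4.1,   # digit I, sites 1-4
        2.3, 0.3, 0.7, 1.8,   # digit II, sites 5-8
        3.1, 1.7, 0.7, 0.9,   # digit III, sites 9-12
        2.8, 0.2, 3.6, 0.8,   # digit IV, sites 13-16
        3.0, 1.2, 0.4, 0.4,   # digit V, sites 17-20
        1.4, 1.7, 3.6, 2.5,   # palm, sites 21-24
    ],
    "case1_right": [
        0.8, 1.2, 0.7, 2.5,
        0.4, 0.2, 2.0, 1.2,
        2.6, 8.2, 1.6, 1.6,
        2.0, 0.3, 0.2, 0.7,
        1.6, 1.5, 0.6, 0.3,
        0.6, 2.4, 3.0, 1.3,
    ],
    "case2_left": [
        6.5, 4.2, 3.5, 4.1,
        9.8, 7.8, 5.0, 4.0,
        7.8, 5.7, 5.4, 4.7,
        8.4, 7.0, 2.3, 3.8,
        5.3, 6.9, 4.8, 2.7,
        3.1, 2.3, 2.2, 2.4,
    ],
    "case2_right": [
        0.4, 0.3, 1.2, 0.9,
        0.2, 2.1, 0.3, 2.3,
        0.2, 1.3, 2.6, 1.5,
        1.7, 2.6, 1.1, 2.7,
        2.6, 0.4, 1.2, 1.1,
        2.4, 3.4, 0.3, 1.7,
    ],
}

SPREAD_CM: dict[str, list[float]] = {
    "case1_left": [
        0.5, 0.6, 0.8, 2.5,
        1.1, 1.1, 0.4, 1.2,
        0.6, 2.7, 0.4, 0.7,
        0.8, 0.7, 2.1, 0.9,
        0.6, 0.4, 0.4, 0.3,
        1.0, 0.4, 1.3, 1.1,
    ],
    "case1_right": [
        0.5, 0.4, 0.7, 1.6,
        0.6, 2.2, 2.2, 1.0,
        2.3, 2.8, 1.5, 1.0,
        0.6, 0.9, 0.6, 1.1,
        0.6, 0.3, 0.9, 0.5,
        0.4, 1.0, 1.1, 0.5,
    ],
    "case2_left": [
        2.5, 2.5, 3.4, 2.5,
        2.2, 1.7, 2.0, 2.3,
        1.5, 2.7, 3.1, 1.5,
        2.1, 1.1, 1.6, 2.5,
        1.2, 2.0, 2.0, 1.7,
        2.5, 2.5, 2.0, 2.6,
    ],
    "case2_right": [
        0.8, 0.9, 0.9, 1.6,
        0.5, 2.3, 1.5, 1.3,
        1.6, 2.2, 2.8, 1.5,
        1.0, 3.5, 2.1, 1.1,
        1.8, 2.0, 1.0, 0.8,
        1.5, 1.4, 0.7, 2.6,
    ],
}
# fmt: on

NSA_SCORES: dict[str, list[int]] = {
    "case1_left": [2, 2, 2, 2, 2, 2],
    "case1_right": [2, 2, 2, 2, 2, 2],
    "case2_left": [1, 0, 0, 1, 1, 0],
    "case2_right": [2, 2, 1, 2, 1, 2],
}
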