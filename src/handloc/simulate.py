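"""Virtual subjects: parametric distortion fields standing in for the
glove hardware and a real responder.

A ``DistortionField`` maps each true stimulation site to a distribution of
perceived locations:

* ``identity`` — no systematic displacement;
* ``distoproximal_shift`` — displacement of a fixed length proximally
  along the site's digit axis (the distal-to-proximal shift archetype seen
  after somatosensory lesions);
* ``palm_compression`` — affine contraction of all sites toward an
  attractor point in the palm (perceived = attractor + c * (true -
  attractor)), emulating responses collapsing onto the palmar area;
* ``custom`` — explicit per-site displacement vectors.

Isotropic Gaussian response noise is added after the displacement, then
the point is clamped into the hand outline.  Each attempt lapses
independently with probability ``lapse_prob``; a trial is missing iff all
``max_attempts`` attempts lapse, so the missing fraction is
``lapse_prob ** max_attempts``.

Randomness is counter-based: every trial draws from a fresh
``numpy.random.Generator`` seeded by (session seed, trial index), so a
session is reproducible regardless of evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .hand_template import Digit, HandTemplate, Side, StimulationSite
from .protocol import ProtocolConfig, generate_sequence
from .session import Session, TrialRecord


@dataclass(frozen=True)
class DistortionField:
    kind: str = "identity"  # identity | distoproximal_shift | palm_compression | custom
    shift_cm: float = 0.0  # distoproximal_shift displacement length
    compression: float = 1.0  # palm_compression factor in [0, 1]
    attractor: Optional[tuple[float, float]] = None  # template units; default palm centroid
    displacement_table: Optional[dict[int, tuple[float, float]]] = None  # custom, units
    noise_sd_cm: float = 0.0
    lapse_prob: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in {"identity", "distoproximal_shift", "palm_compression", "custom"}:
            raise ValueError(f"unknown distortion kind {self.kind!r}")
        if self.noise_sd_cm < 0:
            raise ValueError("noise_sd_cm must be >= 0")
        if not 0.0 <= self.lapse_prob <= 1.0:
            raise ValueError("lapse_prob must be in [0, 1]")
        if self.kind == "palm_compression" and not 0.0 <= self.compression <= 1.0:
            raise ValueError("compression must be in [0, 1]")
        if self.kind == "custom" and self.displacement_table is None:
            raise ValueError("custom field requires a displacement_table")

    def to_doc(self) -> dict:
        return {
            "kind": self.kind,
            "shift_cm": self.shift_cm,
            "compression": self.compression,
            "attractor": None if self.attractor is None else list(self.attractor),
            "displacement_table": None
            if self.displacement_table is None
            else {str(k): list(v) for k, v in self.displacement_table.items()},
            "noise_sd_cm": self.noise_sd_cm,
            "lapse_prob": self.lapse_prob,
        }


@dataclass(frozen=True)
class VirtualSubject:
    field: DistortionField
    hand_length_cm: float = 17.0
    side: Side = Side.RIGHT
    subject_id: str = "virtual"

    def __post_init__(self) -> None:
        if self.hand_length_cm <= 0:
            raise ValueError("hand_length_cm must be positive")


# ---------------------------------------------------------------------------
# Displacement geometry
# ---------------------------------------------------------------------------


def digit_axis(template: HandTemplate, site: StimulationSite) -> np.ndarray:
    """Unit vector pointing proximally along the site's digit.

    Derived from the line through the digit's site chain (most distal to
    most proximal site position).  Palm sites use the straight-down
    (toward-wrist) direction.
    """
    if site.digit is Digit.PALM:
        return np.array([0.0, -1.0])
    chain = sorted(
        (s for s in template.sites if s.digit is site.digit),
        key=lambda s: s.distal_rank,
    )
    distal = np.asarray(chain[0].position, dtype=float)
    proximal = np.asarray(chain[-1].position, dtype=float)
    v = proximal - distal
    return v / np.linalg.norm(v)


def palm_centroid(template: HandTemplate) -> tuple[float, float]:
    """Centroid of the four central palm sites."""
    pts = [s.position for s in template.sites if s.digit is Digit.PALM]
    c = np.mean(np.asarray(pts, dtype=float), axis=0)
    return (float(c[0]), float(c[1]))


def displaced_position(
    field: DistortionField, template: HandTemplate, site: StimulationSite
) -> tuple[float, float]:
    """Noise-free perceived location of a site under the field, clamped."""
    p = np.asarray(site.position, dtype=float)
    units_per_cm = template.units_per_cm
    if field.kind == "identity":
        out = p
    elif field.kind == "distoproximal_shift":
        out = p + field.shift_cm * units_per_cm * digit_axis(template, site)
    elif field.kind == "palm_compression":
        a = np.asarray(
            field.attractor if field.attractor is not None else palm_centroid(template)
        )
        out = a + field.compression * (p - a)
    else:  # custom
        d = field.displacement_table.get(site.site_id, (0.0, 0.0))
        out = p + np.asarray(d, dtype=float)
    return template.clamp(out)


# ---------------------------------------------------------------------------
# Trial-level perception
# ---------------------------------------------------------------------------


def perceive(
    subject: VirtualSubject,
    template: HandTemplate,
    site: StimulationSite,
    rng: np.random.Generator,
    max_attempts: int = 3,
) -> tuple[Optional[tuple[float, float]], int]:
    """Simulate one trial: (response or None, attempts used).

    Each attempt lapses independently with probability ``lapse_prob``;
    attempts = lapsed attempts + 1, capped at ``max_attempts``; the
    response is missing iff every attempt lapsed.  Noise is applied before
    clamping, so responses always lie within the hand outline.
    """
    f = subject.field
    attempts = 1
    while rng.random() < f.lapse_prob:
        if attempts == max_attempts:
            return None, max_attempts
        attempts += 1
    base = np.asarray(displaced_position(f, template, site))
    noise = rng.normal(0.0, f.noise_sd_cm * template.units_per_cm, size=2)
    return template.clamp(base + noise), attempts


def simulate_session(
    subject: VirtualSubject,
    template: HandTemplate,
    config: ProtocolConfig = ProtocolConfig(),
) -> Session:
    """Run a full virtual assessment and return a valid ``Session``.

    The stimulation order comes from ``protocol.generate_sequence``; the
    simulator ground truth (field parameters) is embedded in the session
    metadata.
    """
    sequence = generate_sequence(config)
    trials = []
    for k, site_id in enumerate(sequence, start=1):
        rng = np.random.default_rng([config.seed % (2**31), k])
        response, attempts = perceive(
            subject, template, template.site(site_id), rng, config.max_attempts
        )
        trials.append(
            TrialRecord(
                trial_index=k,
                site_id=site_id,
                attempts=attempts,
                response=response,
            )
        )
    return Session(
        subject_id=subject.subject_id,
        side=subject.side,
        measured_hand_length_cm=subject.hand_length_cm,
        trials=tuple(trials),
        seed=config.seed,
        ground_truth={"field": subject.field.to_doc(), "protocol": config.to_doc()},
    )


# ---------------------------------------------------------------------------
# Archetypes
# ---------------------------------------------------------------------------

#: Documented archetype parameters.  ``healthy`` is an identity field with
#: small sensory noise; ``distal_shift`` reproduces a systematic
#: distal-to-proximal displacement on the fingers with moderate noise;
#: ``palm_collapse`` contracts all perceived locations toward the palm
#: centroid with large noise and occasional lapses.
ARCHETYPES: dict[str, DistortionField] = {
    "healthy": DistortionField(kind="identity", noise_sd_cm=0.4),
    "patient1_like": DistortionField(
        kind="distoproximal_shift", shift_cm=2.0, noise_sd_cm=0.8
    ),
    "patient2_like": DistortionField(
        kind="palm_compression", compression=0.25, noise_sd_cm=2.0, lapse_prob=0.25
    ),
}


def archetype(name: str, hand_length_cm: float = 17.0, side: Side | str = Side.LEFT) -> VirtualSubject:
    """A named virtual subject with documented distortion parameters."""
    try:
        f = ARCHETYPES[name]
    except KeyError:
        raise ValueError(
            f"unknown archetype {name!r}; choose from {sorted(ARCHETYPES)}"
        ) from None
    return VirtualSubject(field=f, hand_length_cm=hand_length_cm, side=Side(side), subject_id=name)
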