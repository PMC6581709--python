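"""Trial-sequence generation and the clinical NSA location set.

The automated protocol tests each of the 24 stimulation sites five times in
pseudo-random order (120 trials), with up to three attempts per trial
before the trial is marked missing.  "Pseudo-random" is implemented as a
seeded uniform shuffle with an optional (default on) constraint that no
site is stimulated twice in a row, since back-to-back identical
vibrotactile stimuli would be confusable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hand_template import Digit, HandTemplate, Segment, StimulationSite


@dataclass(frozen=True)
class ProtocolConfig:
    repetitions_per_site: int = 5
    sites: tuple[int, ...] = tuple(range(1, 25))
    max_attempts: int = 3
    no_immediate_repeat: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.repetitions_per_site < 1:
            raise ValueError("repetitions_per_site must be >= 1")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")
        if not self.sites:
            raise ValueError("sites must be non-empty")
        if len(set(self.sites)) != len(self.sites):
            raise ValueError("sites must be unique")

    def to_doc(self) -> dict:
        return {
            "repetitions_per_site": self.repetitions_per_site,
            "sites": list(self.sites),
            "max_attempts": self.max_attempts,
            "no_immediate_repeat": self.no_immediate_repeat,
            "seed": self.seed,
        }


class ConstraintInfeasibleError(ValueError):
    """The requested sequence constraints cannot be satisfied."""


def generate_sequence(config: ProtocolConfig) -> list[int]:
    """Pseudo-random stimulation order: every site exactly
    ``repetitions_per_site`` times, optionally with no immediate repeats.

    Deterministic for a given seed.  Infeasible constraint sets (a site
    majority too large to separate) raise ``ConstraintInfeasibleError``.
    """
    reps, sites = config.repetitions_per_site, config.sites
    total = reps * len(sites)
    if config.no_immediate_repeat and reps > (total + 1) // 2:
        # a single site holding a strict majority cannot be non-adjacent
        raise ConstraintInfeasibleError(
            f"cannot avoid immediate repeats with {reps} repetitions of"
            f" {len(sites)} site(s)"
        )
    rng = np.random.default_rng(config.seed)
    pool = np.repeat(np.asarray(sites, dtype=int), reps)
    for _ in range(10_000):
        seq = rng.permutation(pool)
        if not config.no_immediate_repeat or not np.any(seq[1:] == seq[:-1]):
            return seq.tolist()
    # feasible but unlucky: repair by swapping adjacent duplicates away
    seq = rng.permutation(pool).tolist()
    for _ in range(10_000):
        bad = [i for i in range(1, len(seq)) if seq[i] == seq[i - 1]]
        if not bad:
            return seq
        i = bad[0]
        for j in range(len(seq)):
            if seq[j] != seq[i] and (j == 0 or seq[j - 1] != seq[i]) and (
                j + 1 >= len(seq) or seq[j + 1] != seq[i]
            ) and abs(j - i) > 1:
                seq[i], seq[j] = seq[j], seq[i]
                break
        else:
            break
    if any(a == b for a, b in zip(seq, seq[1:])):
        raise ConstraintInfeasibleError("could not construct a repeat-free sequence")
    return seq


# ---------------------------------------------------------------------------
# Clinical NSA locations
# ---------------------------------------------------------------------------

#: The six locations of the NSA tactile-localization subscale, expressed as
#: (label, digit, segment).  Three coincide with the fingertip sites 1, 9
#: and 17; the metacarpal and thenar locations coincide with sites 8, 20
#: and 4 of the automated grid.
NSA_LOCATION_SPECS: tuple[tuple[str, Digit, Segment], ...] = (
    ("digit_I_distal_phalanx", Digit.I, Segment.DISTAL_PHALANX),
    ("digit_II_metacarpal", Digit.II, Segment.DISTAL_METACARPAL),
    ("digit_III_distal_phalanx", Digit.III, Segment.DISTAL_PHALANX),
    ("digit_V_distal_phalanx", Digit.V, Segment.DISTAL_PHALANX),
    ("digit_V_metacarpal", Digit.V, Segment.DISTAL_METACARPAL),
    ("thenar_eminence", Digit.I, Segment.PROXIMAL_METACARPAL),
)


@dataclass(frozen=True)
class NsaLocation:
    label: str
    site: StimulationSite  # the automated-grid site it maps onto

    @property
    def position(self) -> tuple[float, float]:
        return self.site.position


def nsa_locations(template: HandTemplate) -> list[NsaLocation]:
    """The six clinical NSA test locations mapped onto the template."""
    out = []
    for label, digit, segment in NSA_LOCATION_SPECS:
        matches = [s for s in template.sites if s.digit is digit and s.segment is segment]
        if len(matches) != 1:
            raise ValueError(f"template has no unique site for NSA location {label}")
        out.append(NsaLocation(label, matches[0]))
    return out
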