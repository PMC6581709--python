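"""Localization outcome measures.

Per stimulation site, three geodesic error measures are computed from the
responses a subject reported for that site:

* **distance** — mean geodesic error of the individual responses from the
  stimulation site (accuracy, trial level);
* **offset** — geodesic error of the response *center* from the
  stimulation site (accuracy, systematic component);
* **spread** — mean geodesic distance of the responses from their center
  (precision).

The response center is the arithmetic centroid, clamped onto the hand
outline if it falls outside (e.g. responses split across two fingers).
Discretizing each response to its geodesically nearest site yields a 24x24
confusion matrix whose diagonal is the correct localization rate (CLR).

Lengths are reported in centimeters on the subject's physical hand;
"normalized" output additionally rescales to the 17 cm reference hand
length (multiplication by 17 / measured hand length).  Report rounding is
one decimal for cm and percent values; raw double precision is retained.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .geodesic import engine_for
from .hand_template import REFERENCE_HAND_LENGTH_CM, HandTemplate
from .protocol import nsa_locations
from .session import ClinicalObservation, Session


class UndefinedMetricError(ValueError):
    """Raised when a metric is requested for a site with no responses."""


def round_report(value: float, decimals: int = 1) -> float:
    """Half-up rounding used for report output (0.05 -> 0.1)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Per-location primitives (template units unless stated otherwise)
# ---------------------------------------------------------------------------


def response_center(
    points: Sequence[Sequence[float]], template: HandTemplate
) -> tuple[float, float]:
    """Arithmetic centroid of the responses, clamped into the hand.

    The centroid of responses on two different fingers can land in a web
    notch outside the outline; clamping keeps the center a valid argument
    for geodesic distances.
    """
    if len(points) == 0:
        raise UndefinedMetricError("no responses: center undefined")
    c = np.mean(np.asarray(points, dtype=float), axis=0)
    return template.clamp(c)


def _scale(template: HandTemplate) -> float:
    return 1.0 / template.units_per_cm


def location_offset(
    responses: Sequence[Sequence[float]],
    site_position: Sequence[float],
    template: HandTemplate,
) -> float:
    """Geodesic error of the response center from the site, in cm."""
    if len(responses) == 0:
        raise UndefinedMetricError("no responses: offset undefined")
    eng = engine_for(template)
    center = response_center(responses, template)
    return eng.distance(site_position, center) * _scale(template)


def location_spread(
    responses: Sequence[Sequence[float]],
    template: HandTemplate,
) -> float:
    """Mean geodesic distance of responses from their center, in cm."""
    if len(responses) == 0:
        raise UndefinedMetricError("no responses: spread undefined")
    eng = engine_for(template)
    center = response_center(responses, template)
    clamped = [template.clamp(r) for r in responses]
    return float(np.mean([eng.distance(r, center) for r in clamped])) * _scale(template)


def location_distance(
    responses: Sequence[Sequence[float]],
    site_position: Sequence[float],
    template: HandTemplate,
) -> float:
    """Mean geodesic error of individual responses from the site, in cm."""
    if len(responses) == 0:
        raise UndefinedMetricError("no responses: distance undefined")
    eng = engine_for(template)
    clamped = [template.clamp(r) for r in responses]
    return float(
        np.mean([eng.distance(r, site_position) for r in clamped])
    ) * _scale(template)


# ---------------------------------------------------------------------------
# Confusion matrix and CLR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionMatrix:
    """Row-percentage confusion matrix over the 24 stimulation sites.

    ``matrix[i, j]`` is the percentage of non-missing responses to
    stimulated site i+1 that discretize to site j+1; rows with no
    responses are NaN.  ``row_n`` counts non-missing responses per row and
    ``row_missing`` the missing trials.
    """

    matrix: np.ndarray  # (24, 24) percentages
    row_n: np.ndarray  # (24,) ints
    row_missing: np.ndarray  # (24,) ints

    def diagonal(self) -> np.ndarray:
        return np.diagonal(self.matrix)

    def to_dataframe(self) -> pd.DataFrame:
        ids = list(range(1, 25))
        df = pd.DataFrame(self.matrix, index=ids, columns=ids)
        df.index.name = "stimulated_site"
        df["row_n"] = self.row_n
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)


def discretize_response(
    point: Sequence[float],
    template: HandTemplate,
    metric: str = "geodesic",
) -> int:
    """Nearest stimulation site to a response (ties -> lowest site_id).

    ``metric`` selects geodesic (default, consistent with the error
    measures) or Euclidean nearest-site assignment.
    """
    p = template.clamp(point)
    if metric == "geodesic":
        dists = engine_for(template).distances_to_sites(p)
    elif metric == "euclidean":
        dists = {
            s.site_id: math.hypot(p[0] - s.position[0], p[1] - s.position[1])
            for s in template.sites
        }
    else:
        raise ValueError(f"unknown discretization metric {metric!r}")
    # ties broken by lowest site_id: iterate in id order, strict improvement
    best_id, best_d = None, math.inf
    for sid in sorted(dists):
        if dists[sid] < best_d - 1e-12:
            best_id, best_d = sid, dists[sid]
    return best_id


def confusion_matrix(
    session: Session, template: HandTemplate, metric: str = "geodesic"
) -> ConfusionMatrix:
    """Discretize every non-missing response to its nearest site and
    tabulate row percentages per stimulated site."""
    counts = np.zeros((24, 24), dtype=float)
    row_missing = np.zeros(24, dtype=int)
    for t in session.trials:
        if t.missing:
            row_missing[t.site_id - 1] += 1
            continue
        j = discretize_response(t.response, template, metric=metric)
        counts[t.site_id - 1, j - 1] += 1
    row_n = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = 100.0 * counts / row_n[:, None]
    return ConfusionMatrix(matrix=pct, row_n=row_n.astype(int), row_missing=row_missing)


def correct_localization_rate(
    cm: ConfusionMatrix, subset: Optional[Sequence[int]] = None
) -> tuple[float, float]:
    """Mean and SD (across sites) of the confusion-matrix diagonal.

    ``subset`` restricts to a site list, e.g. the fingertips
    ``(1, 5, 9, 13, 17)``; sites without responses are excluded.
    """
    if subset is None:
        subset = range(1, 25)
    subset = list(subset)
    if not subset:
        raise ValueError("subset must be non-empty")
    diag = cm.diagonal()
    vals = np.array([diag[s - 1] for s in subset], dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return (math.nan, math.nan)
    return (float(np.mean(vals)), float(np.std(vals)))


# ---------------------------------------------------------------------------
# Session summary
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LocationOutcome:
    site_id: int
    n_responses: int
    center: Optional[tuple[float, float]]  # template units
    offset_cm: float  # NaN when undefined
    spread_cm: float
    distance_cm: float
    clr_pct: float

    @property
    def defined(self) -> bool:
        return self.n_responses > 0


@dataclass(frozen=True)
class AssessmentSummary:
    per_site: tuple[LocationOutcome, ...]
    mean_offset_cm: float
    sd_offset_cm: float
    mean_spread_cm: float
    sd_spread_cm: float
    mean_distance_cm: float
    sd_distance_cm: float
    mean_clr_pct: float
    sd_clr_pct: float
    n_trials: int
    n_missing: int
    normalized: bool

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "site_id": o.site_id,
                "n_responses": o.n_responses,
                "offset_cm": o.offset_cm,
                "spread_cm": o.spread_cm,
                "distance_cm": o.distance_cm,
                "clr_pct": o.clr_pct,
            }
            for o in self.per_site
        ]
        return pd.DataFrame(rows)

    def to_doc(self, rounded: bool = True) -> dict:
        r = round_report if rounded else (lambda v: v)

        def fmt(v: float):
            return None if math.isnan(v) else r(v)

        return {
            "per_site": [
                {
                    "site_id": o.site_id,
                    "n_responses": o.n_responses,
                    "offset_cm": fmt(o.offset_cm),
                    "spread_cm": fmt(o.spread_cm),
                    "distance_cm": fmt(o.distance_cm),
                    "clr_pct": fmt(o.clr_pct),
                }
                for o in self.per_site
            ],
            "mean_offset_cm": fmt(self.mean_offset_cm),
            "sd_offset_cm": fmt(self.sd_offset_cm),
            "mean_spread_cm": fmt(self.mean_spread_cm),
            "sd_spread_cm": fmt(self.sd_spread_cm),
            "mean_distance_cm": fmt(self.mean_distance_cm),
            "sd_distance_cm": fmt(self.sd_distance_cm),
            "mean_clr_pct": fmt(self.mean_clr_pct),
            "sd_clr_pct": fmt(self.sd_clr_pct),
            "n_trials": self.n_trials,
            "n_missing": self.n_missing,
            "normalized": self.normalized,
        }

    def to_json(self, path: str | Path, rounded: bool = True) -> None:
        Path(path).write_text(json.dumps(self.to_doc(rounded=rounded), indent=2) + "\n")

    def to_csv(self, path: str | Path) -> None:
        df = self.to_dataframe()
        mean_row = {
            "site_id": "mean",
            "n_responses": int(df["n_responses"].sum()),
            "offset_cm": self.mean_offset_cm,
            "spread_cm": self.mean_spread_cm,
            "distance_cm": self.mean_distance_cm,
            "clr_pct": self.mean_clr_pct,
        }
        sd_row = {
            "site_id": "sd",
            "n_responses": "",
            "offset_cm": self.sd_offset_cm,
            "spread_cm": self.sd_spread_cm,
            "distance_cm": self.sd_distance_cm,
            "clr_pct": self.sd_clr_pct,
        }
        pd.concat([df, pd.DataFrame([mean_row, sd_row])]).to_csv(path, index=False)


def aggregate_sites(values: Sequence[float]) -> tuple[float, float]:
    """Across-site mean and SD, skipping undefined (NaN) sites.

    The SD is the population standard deviation over the defined sites,
    matching the convention used for mean +/- SD report rows.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        return (math.nan, math.nan)
    return (float(np.mean(arr)), float(np.std(arr)))


def summarize(
    session: Session,
    template: HandTemplate,
    normalize: bool = True,
    discretization_metric: str = "geodesic",
) -> AssessmentSummary:
    """Per-site outcomes plus across-site means and SDs for one session.

    ``normalize=True`` rescales all lengths to the 17 cm reference hand
    (multiplication by 17 / measured hand length); CLR percentages are
    scale-free.  Sites without responses carry NaN metrics and are skipped
    in the aggregation.
    """
    cm = confusion_matrix(session, template, metric=discretization_metric)
    norm_factor = (
        REFERENCE_HAND_LENGTH_CM / session.measured_hand_length_cm if normalize else 1.0
    )
    # cm on the subject's physical hand: template cm * measured/17
    phys_factor = session.measured_hand_length_cm / template.hand_length_cm
    factor = phys_factor * norm_factor
    outcomes = []
    diag = cm.diagonal()
    for site in sorted(template.sites, key=lambda s: s.site_id):
        responses = session.responses_for_site(site.site_id)
        if not responses:
            outcomes.append(
                LocationOutcome(
                    site.site_id, 0, None, math.nan, math.nan, math.nan, math.nan
                )
            )
            continue
        clamped = [template.clamp(r) for r in responses]
        center = response_center(clamped, template)
        outcomes.append(
            LocationOutcome(
                site_id=site.site_id,
                n_responses=len(responses),
                center=center,
                offset_cm=location_offset(clamped, site.position, template) * factor,
                spread_cm=location_spread(clamped, template) * factor,
                distance_cm=location_distance(clamped, site.position, template) * factor,
                clr_pct=float(diag[site.site_id - 1]),
            )
        )
    mo, so = aggregate_sites([o.offset_cm for o in outcomes])
    ms, ss = aggregate_sites([o.spread_cm for o in outcomes])
    md, sd = aggregate_sites([o.distance_cm for o in outcomes])
    mc, sc = aggregate_sites([o.clr_pct for o in outcomes])
    return AssessmentSummary(
        per_site=tuple(outcomes),
        mean_offset_cm=mo,
        sd_offset_cm=so,
        mean_spread_cm=ms,
        sd_spread_cm=ss,
        mean_distance_cm=md,
        sd_distance_cm=sd,
        mean_clr_pct=mc,
        sd_clr_pct=sc,
        n_trials=len(session.trials),
        n_missing=session.n_missing,
        normalized=normalize,
    )


# ---------------------------------------------------------------------------
# Clinical NSA localization subscale
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NsaScore:
    """NSA tactile-localization subscale: 6 locations scored 0-2.

    2 = normal (correct on all three repetitions), 1 = impaired (correct on
    one or two), 0 = absent (incorrect on all three); total 0-12.
    """

    per_location: tuple[int, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.per_location) != 6 or len(self.labels) != 6:
            raise ValueError("NSA score requires exactly 6 locations")
        if any(s not in (0, 1, 2) for s in self.per_location):
            raise ValueError("per-location scores must be 0, 1 or 2")

    @property
    def total(self) -> int:
        return sum(self.per_location)


def score_repetitions(correct: Sequence[bool]) -> int:
    """0-2 score for one location from its three correct/incorrect
    repetitions."""
    n = sum(bool(c) for c in correct)
    if len(correct) != 3:
        raise ValueError("exactly 3 repetitions per location")
    return 2 if n == 3 else (1 if n >= 1 else 0)


def nsa_localization_score(observations: Sequence[ClinicalObservation]) -> NsaScore:
    if len(observations) != 6:
        raise ValueError(f"expected 6 NSA locations, got {len(observations)}")
    return NsaScore(
        per_location=tuple(score_repetitions(o.repetitions) for o in observations),
        labels=tuple(o.location_label for o in observations),
    )


def nsa_from_session(
    session: Session,
    template: HandTemplate,
    tolerance_cm: float = 2.0,
) -> NsaScore:
    """Cross-walk from automated coordinates to the clinical rule.

    For each of the six NSA-mapped sites, the first three responses are
    scored correct iff their geodesic error is within ``tolerance_cm`` on
    the subject's physical hand.
    """
    eng = engine_for(template)
    # physical cm per template unit for this subject
    phys = (session.measured_hand_length_cm / template.hand_length_cm) / template.units_per_cm
    observations = []
    short: list[str] = []
    for loc in nsa_locations(template):
        responses = session.responses_for_site(loc.site.site_id)[:3]
        if len(responses) < 3:
            short.append(loc.label)
            continue
        correct = tuple(
            eng.distance(template.clamp(r), loc.position) * phys <= tolerance_cm
            for r in responses
        )
        observations.append(ClinicalObservation(loc.label, correct))
    if short:
        raise ValueError(
            "insufficient responses (need 3) at NSA locations: " + ", ".join(short)
        )
    return nsa_localization_score(observations)
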