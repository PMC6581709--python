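"""Assessment-session data model and file I/O.

A session records one automated localization assessment of one hand:
ordered trials, each pairing a stimulated site (1-24) with the coordinates
the subject reported on the schematic hand, or a missing flag when all
three attempts lapsed.  Two on-disk formats are supported:

* a canonical JSON document (versioned, lossless round trip), and
* a flat CSV trial table for spreadsheet interoperability (one row per
  trial; empty response cells plus ``missing=1`` encode missing trials).

Coordinates in session files are template coordinates; touchscreen
calibration happens upstream of this package.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from .hand_template import HandTemplate, Side

SESSION_SCHEMA = "handloc-session/1"

DEFAULT_STIMULUS_PARAMS = {"duration_s": 1.5, "frequency_hz": 150.0}

_CSV_COLUMNS = [
    "trial_index",
    "site_id",
    "attempts",
    "resp_x",
    "resp_y",
    "missing",
    "response_time",
]


@dataclass(frozen=True)
class TrialRecord:
    trial_index: int  # 1-based, contiguous
    site_id: int
    attempts: int = 1  # 1..max_attempts
    response: Optional[tuple[float, float]] = None  # template coords; None = missing
    response_time: Optional[float] = None  # seconds

    def __post_init__(self) -> None:
        if self.trial_index < 1:
            raise ValueError(f"trial_index must be >= 1, got {self.trial_index}")
        if not 1 <= self.site_id <= 24:
            raise ValueError(f"site_id must be in 1..24, got {self.site_id}")
        if not 1 <= self.attempts <= 3:
            raise ValueError(f"attempts must be in 1..3, got {self.attempts}")
        if self.response_time is not None and self.response_time < 0:
            raise ValueError("response_time must be >= 0")

    @property
    def missing(self) -> bool:
        return self.response is None


@dataclass(frozen=True)
class Session:
    subject_id: str
    side: Side
    measured_hand_length_cm: float
    trials: tuple[TrialRecord, ...]
    laterality_label: Optional[str] = None  # contralesional / ipsilesional
    template_ref: str = "default/1.0"
    stimulus_params: dict = field(default_factory=lambda: dict(DEFAULT_STIMULUS_PARAMS))
    seed: Optional[int] = None
    ground_truth: Optional[dict] = None  # simulator field parameters, if simulated

    def __post_init__(self) -> None:
        if self.measured_hand_length_cm <= 0:
            raise ValueError("measured_hand_length_cm must be positive")
        for k, t in enumerate(self.trials, start=1):
            if t.trial_index != k:
                raise ValueError(
                    f"trial_index must be contiguous from 1; expected {k},"
                    f" got {t.trial_index}"
                )

    @property
    def n_missing(self) -> int:
        return sum(t.missing for t in self.trials)

    def responses_for_site(self, site_id: int) -> list[tuple[float, float]]:
        return [t.response for t in self.trials if t.site_id == site_id and not t.missing]


@dataclass(frozen=True)
class ClinicalObservation:
    """One clinical NSA location: three yes/no localization repetitions."""

    location_label: str
    repetitions: tuple[bool, bool, bool]

    def __post_init__(self) -> None:
        if len(self.repetitions) != 3:
            raise ValueError("exactly 3 repetitions per location")


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Finding:
    level: str  # "error" | "warning"
    message: str


def validate_session(
    session: Session,
    template: Optional[HandTemplate] = None,
    repetitions_per_site: int = 5,
    n_sites: int = 24,
) -> list[Finding]:
    """Check protocol invariants; errors for violations of the data model,
    warnings for partial sessions, missing trials and out-of-outline
    responses (all tolerated by the metrics layer)."""
    findings: list[Finding] = []
    counts: dict[int, int] = {}
    for t in session.trials:
        counts[t.site_id] = counts.get(t.site_id, 0) + 1
        if t.missing and t.attempts != 3:
            findings.append(
                Finding(
                    "error",
                    f"trial {t.trial_index}: missing response requires attempts=3,"
                    f" got {t.attempts}",
                )
            )
        if template is not None and not t.missing and not template.contains(t.response):
            findings.append(
                Finding(
                    "warning",
                    f"trial {t.trial_index}: response {t.response} outside the"
                    " hand outline (will be clamped)",
                )
            )
    expected_total = repetitions_per_site * n_sites
    if len(session.trials) != expected_total:
        findings.append(
            Finding(
                "warning",
                f"partial session: {len(session.trials)} trials,"
                f" expected {expected_total}",
            )
        )
    off = {s: c for s, c in sorted(counts.items()) if c != repetitions_per_site}
    if off and len(session.trials) == expected_total:
        findings.append(
            Finding("error", f"unbalanced repetitions per site: {off}")
        )
    if session.n_missing:
        findings.append(Finding("warning", f"{session.n_missing} missing"))
    return findings


# ---------------------------------------------------------------------------
# JSON I/O (canonical)
# ---------------------------------------------------------------------------


def _trial_to_doc(t: TrialRecord) -> dict:
    return {
        "trial_index": t.trial_index,
        "site_id": t.site_id,
        "attempts": t.attempts,
        "response": None if t.missing else [t.response[0], t.response[1]],
        "response_time": t.response_time,
    }


def write_session(session: Session, path: str | Path) -> None:
    doc = {
        "$schema": SESSION_SCHEMA,
        "subject_id": session.subject_id,
        "side": session.side.value,
        "laterality_label": session.laterality_label,
        "measured_hand_length_cm": session.measured_hand_length_cm,
        "template_ref": session.template_ref,
        "stimulus_params": session.stimulus_params,
        "seed": session.seed,
        "ground_truth": session.ground_truth,
        "trials": [_trial_to_doc(t) for t in session.trials],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_session(path: str | Path) -> Session:
    """Read a JSON session document, validating every invariant.

    All violations are collected and reported together, each addressed to
    its trial.
    """
    doc = json.loads(Path(path).read_text())
    if doc.get("$schema") != SESSION_SCHEMA:
        raise ValueError(
            f"{path}: unknown session schema {doc.get('$schema')!r},"
            f" expected {SESSION_SCHEMA!r}"
        )
    problems: list[str] = []
    trials: list[TrialRecord] = []
    for i, td in enumerate(doc.get("trials", [])):
        try:
            resp = td.get("response")
            trials.append(
                TrialRecord(
                    trial_index=int(td["trial_index"]),
                    site_id=int(td["site_id"]),
                    attempts=int(td.get("attempts", 1)),
                    response=None if resp is None else (float(resp[0]), float(resp[1])),
                    response_time=td.get("response_time"),
                )
            )
        except (KeyError, TypeError, ValueError) as exc:
            problems.append(f"trials[{i}]: {exc}")
    if problems:
        raise ValueError(f"{path}: invalid session:\n" + "\n".join(problems))
    try:
        return Session(
            subject_id=str(doc["subject_id"]),
            side=Side(doc["side"]),
            laterality_label=doc.get("laterality_label"),
            measured_hand_length_cm=float(doc["measured_hand_length_cm"]),
            template_ref=str(doc.get("template_ref", "default/1.0")),
            stimulus_params=doc.get("stimulus_params", dict(DEFAULT_STIMULUS_PARAMS)),
            seed=doc.get("seed"),
            ground_truth=doc.get("ground_truth"),
            trials=tuple(trials),
        )
    except (KeyError, TypeError, ValueError) as exc:
        raise ValueError(f"{path}: invalid session: {exc}") from exc


# ---------------------------------------------------------------------------
# CSV I/O (flat trial table)
# ---------------------------------------------------------------------------


def write_trials_csv(session: Session, path: str | Path) -> None:
    rows = []
    for t in session.trials:
        rows.append(
            {
                "trial_index": t.trial_index,
                "site_id": t.site_id,
                "attempts": t.attempts,
                "resp_x": "" if t.missing else t.response[0],
                "resp_y": "" if t.missing else t.response[1],
                "missing": int(t.missing),
                "response_time": "" if t.response_time is None else t.response_time,
            }
        )
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def read_trials_csv(path: str | Path, **session_fields) -> Session:
    """Read a flat CSV trial table.

    Session-level metadata is not stored in the CSV; pass it via keyword
    arguments (``subject_id``, ``side``, ``measured_hand_length_cm``, ...).
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in _CSV_COLUMNS[:6] if c not in df.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing columns {missing_cols}")
    trials = []
    for _, row in df.iterrows():
        is_missing = bool(int(row["missing"]))
        rt = row.get("response_time")
        trials.append(
            TrialRecord(
                trial_index=int(row["trial_index"]),
                site_id=int(row["site_id"]),
                attempts=int(row["attempts"]),
                response=None
                if is_missing
                else (float(row["resp_x"]), float(row["resp_y"])),
                response_time=None if rt is None or (isinstance(rt, float) and math.isnan(rt)) else float(rt),
            )
        )
    defaults = {
        "subject_id": "unknown",
        "side": Side.RIGHT,
        "measured_hand_length_cm": 17.0,
    }
    defaults.update(session_fields)
    defaults["side"] = Side(defaults["side"])
    return Session(trials=tuple(trials), **defaults)
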