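"""Steady-state 5-minute segment selection and PRE/POST/2H labelling.

A candidate window qualifies as steady state when every monitored vital
varies by no more than a fixed fraction (default 10%) of its window mean,
the artifact density is low, and the window stays clear of the exclusion
zones after anaesthesia induction (5 min) and after any substantial drug
change (2 min).  Segments are searched on a 1 s stride inside the label's
eligibility interval:

* PRE  — between anaesthesia induction and the first recanalization
  attempt; earliest admissible window.
* POST — between final reperfusion status and anaesthesia termination;
  earliest admissible window.
* 2H   — between anaesthesia termination and two hours after
  recanalization; latest admissible window ("as late as possible").
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import ArtifactParams, flag_artifacts
from .types import RawRecording

LABELS = ("PRE", "POST", "2H")


@dataclass
class SegmentCriteria:
    duration_s: float = 300.0
    ga_induction_exclusion_s: float = 300.0
    drug_change_exclusion_s: float = 120.0
    vital_variation_fraction: float = 0.10
    max_artifact_fraction: float = 0.05
    max_missing_fraction: float = 0.10
    monitored_vitals: tuple[str, ...] = ("hr", "mean_abp", "spo2", "etco2")
    stride_s: float = 1.0
    post_recanalization_horizon_s: float = 7200.0

    def __post_init__(self) -> None:
        if not 0 < self.vital_variation_fraction < 1:
            raise ValueError("vital_variation_fraction must be in (0, 1)")
        for v in (
            self.duration_s,
            self.ga_induction_exclusion_s,
            self.drug_change_exclusion_s,
            self.stride_s,
        ):
            if v <= 0:
                raise ValueError("criteria durations must be positive")


@dataclass
class SteadySegment:
    label: str
    start_s: float
    end_s: float
    qc: dict = field(default_factory=dict)


class EventOrderError(ValueError):
    """Raised when procedure markers are inconsistent in time."""


def _overlaps(start: float, end: float, zones: list[tuple[float, float]]) -> bool:
    return any(start < z1 and end > z0 for z0, z1 in zones)


def window_is_steady(
    vitals,
    vitals_fs: float,
    artifact_masks: dict[str, np.ndarray] | None,
    mask_fs: float,
    window: tuple[float, float],
    criteria: SegmentCriteria,
    exclusion_zones: list[tuple[float, float]] | None = None,
) -> tuple[bool, dict]:
    """Evaluate the steady-state rules on one window.

    Returns (steady, qc); qc reports per-vital relative variation
    ((max−min)/window mean), the worst artifact density, and the names of
    any violated rules.
    """
    start, end = window
    qc: dict = {"variation": {}, "artifact_density": 0.0, "violations": []}
    if exclusion_zones and _overlaps(start, end, exclusion_zones):
        qc["violations"].append("exclusion_zone")

    tv = vitals["time_s"].to_numpy()
    in_win = (tv >= start) & (tv < end)
    expected = criteria.duration_s * vitals_fs
    if in_win.sum() < (1 - criteria.max_missing_fraction) * expected:
        raise ValueError("vitals missing for too much of the window")
    for vital in criteria.monitored_vitals:
        if vital not in vitals.columns:
            continue
        v = vitals[vital].to_numpy()[in_win]
        v = v[np.isfinite(v)]
        if len(v) < (1 - criteria.max_missing_fraction) * expected:
            raise ValueError(f"vital {vital!r} missing for too much of the window")
        mean = float(np.mean(v))
        rel = float(np.ptp(v) / abs(mean)) if mean != 0 else np.inf
        qc["variation"][vital] = rel
        if rel > criteria.vital_variation_fraction:
            qc["violations"].append(f"vital:{vital}")

    if artifact_masks:
        for name, mask in artifact_masks.items():
            i0 = int(np.floor(start * mask_fs))
            i1 = int(np.ceil(end * mask_fs))
            frac = float(np.mean(mask[i0:i1])) if i1 > i0 else 0.0
            qc["artifact_density"] = max(qc["artifact_density"], frac)
            if frac > criteria.max_artifact_fraction:
                if f"artifacts:{name}" not in qc["violations"]:
                    qc["violations"].append(f"artifacts:{name}")

    return (not qc["violations"]), qc


def eligibility_intervals(
    recording: RawRecording, criteria: SegmentCriteria
) -> dict[str, tuple[float, float]]:
    """Label → (start, end) interval a segment of that label may occupy."""
    ga = recording.event_time("ga_induction")
    first = recording.event_time("first_attempt")
    recan = recording.event_time("reperfusion")
    term = recording.event_time("ga_termination")
    known = [(n, t) for n, t in
             [("ga_induction", ga), ("first_attempt", first),
              ("reperfusion", recan), ("ga_termination", term)]
             if t is not None]
    times = [t for _, t in known]
    if times != sorted(times):
        raise EventOrderError(f"event markers out of order: {known}")
    out: dict[str, tuple[float, float]] = {}
    if ga is not None and first is not None:
        out["PRE"] = (ga, first)
    if recan is not None and term is not None:
        out["POST"] = (recan, term)
    if term is not None and recan is not None:
        out["2H"] = (
            term,
            min(recan + criteria.post_recanalization_horizon_s, recording.duration_s),
        )
    return out


def exclusion_zones(
    recording: RawRecording, criteria: SegmentCriteria
) -> list[tuple[float, float]]:
    zones = []
    ga = recording.event_time("ga_induction")
    if ga is not None:
        zones.append((ga, ga + criteria.ga_induction_exclusion_s))
    for t in recording.event_times("drug_change"):
        zones.append((t, t + criteria.drug_change_exclusion_s))
    return zones


def compute_artifact_masks(
    recording: RawRecording, params: ArtifactParams | None = None
) -> dict[str, np.ndarray]:
    masks = {"abp": flag_artifacts(recording.abp, recording.fs_raw, params).mask}
    for ch in recording.channels:
        masks[ch.name] = flag_artifacts(ch.oxyhb, recording.fs_raw, params).mask
    return masks


def select_segments(
    recording: RawRecording,
    criteria: SegmentCriteria | None = None,
    artifact_masks: dict[str, np.ndarray] | None = None,
    labels: tuple[str, ...] = LABELS,
) -> list[SteadySegment]:
    """Best admissible window per label, or nothing for labels without one.

    Candidate starts advance on ``criteria.stride_s``; PRE and POST take the
    earliest admissible window, 2H the latest.  ``artifact_masks`` may be
    supplied (e.g. ground truth from the generator); by default they are
    computed from the raw signals.
    """
    criteria = criteria or SegmentCriteria()
    if artifact_masks is None:
        artifact_masks = compute_artifact_masks(recording)
    zones = exclusion_zones(recording, criteria)
    intervals = eligibility_intervals(recording, criteria)
    out: list[SteadySegment] = []
    for label in labels:
        if label not in intervals:
            continue
        lo, hi = intervals[label]
        starts = np.arange(
            np.ceil(lo), np.floor(hi - criteria.duration_s) + 1e-9, criteria.stride_s
        )
        if label == "2H":
            starts = starts[::-1]  # as late as possible
        for s in starts:
            ok, qc = window_is_steady(
                recording.vitals,
                recording.vitals_fs,
                artifact_masks,
                recording.fs_raw,
                (float(s), float(s) + criteria.duration_s),
                criteria,
                exclusion_zones=zones,
            )
            if ok:
                out.append(
                    SteadySegment(
                        label=label,
                        start_s=float(s),
                        end_s=float(s) + criteria.duration_s,
                        qc=qc,
                    )
                )
                break
    return out
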