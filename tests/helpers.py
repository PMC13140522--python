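"""Shared builders for synthetic scenarios used across the test suite."""
from __future__ import annotations

import numpy as np

import nirsdca as nd
from nirsdca.segments import (
    SegmentCriteria,
    eligibility_intervals,
    exclusion_zones,
    window_is_steady,
)
from nirsdca.synth import Excursion, default_vitals_spec

#: a tight event schedule leaving one long POST interval in a short record
TIGHT_EVENTS = {
    "ga_induction": 2.0,
    "first_attempt": 8.0,
    "reperfusion": 10.0,
    "ga_termination": 715.0,
}


def noiseless_config(
    lf_phase_deg: float = 40.0,
    lf_gain: float = 10.0,
    seed: int = 3,
    duration_s: float = 720.0,
    **overrides,
) -> nd.SynthConfig:
    """Noiseless, artifact-free, scalp-free config whose downstream TFA
    estimates should match the configured transfer exactly."""
    bt = {
        h: {
            "VLF": nd.BandTransfer(3.0, 10.0),
            "LF": nd.BandTransfer(lf_gain, lf_phase_deg),
            "HF": nd.BandTransfer(8.0, 5.0),
        }
        for h in ("ischaemic", "contralateral")
    }
    events = dict(TIGHT_EVENTS)
    events["ga_termination"] = duration_s - 5.0
    kw = dict(
        duration_s=duration_s,
        noise_sd_abp=0.0,
        noise_sd_nirs=0.0,
        nirs_drift_amp=0.0,
        extracerebral_fraction={"long": 0.0, "short": 0.0},
        artifact_spec=nd.ArtifactSpec(count=0),
        band_transfer=bt,
        event_times=events,
        seed=seed,
    )
    kw.update(overrides)
    return nd.SynthConfig(**kw)


def random_segment_recording(seed: int) -> nd.RawRecording:
    """Recording with randomized procedure timeline, vitals excursions,
    drug changes and artifacts — the stress input for segment selection."""
    rng = np.random.default_rng(seed)
    ga = rng.uniform(30, 90)
    first = ga + rng.uniform(500, 900)
    recan = first + rng.uniform(30, 120)
    term = recan + rng.uniform(600, 1200)
    dur = term + rng.uniform(400, 800)
    vs = default_vitals_spec()
    for name in vs:
        for _ in range(rng.integers(0, 3)):
            t0 = rng.uniform(0, dur - 200)
            vs[name].excursions.append(
                Excursion(
                    t0,
                    t0 + rng.uniform(60, 300),
                    rng.uniform(0.1, 0.2) * vs[name].baseline * rng.choice([-1, 1]),
                )
            )
    drugs = tuple(rng.uniform(ga, term, size=rng.integers(0, 3)))
    return nd.synthesize_recording(
        nd.SynthConfig(
            duration_s=dur,
            fs_raw=50.0,
            seed=seed,
            vitals_spec=vs,
            drug_change_times=drugs,
            artifact_spec=nd.ArtifactSpec(count=int(rng.integers(0, 4))),
            event_times={
                "ga_induction": ga,
                "first_attempt": first,
                "reperfusion": recan,
                "ga_termination": term,
            },
        )
    )


def brute_force_segments(
    rec: nd.RawRecording,
    criteria: SegmentCriteria,
    masks: dict[str, np.ndarray],
) -> dict[str, float]:
    """Exhaustive 1 s-stride scan: label → selected window start."""
    zones = exclusion_zones(rec, criteria)
    out: dict[str, float] = {}
    for label, (lo, hi) in eligibility_intervals(rec, criteria).items():
        found = []
        for s in np.arange(
            np.ceil(lo), np.floor(hi - criteria.duration_s) + 1e-9, 1.0
        ):
            ok, _ = window_is_steady(
                rec.vitals,
                rec.vitals_fs,
                masks,
                rec.fs_raw,
                (float(s), float(s) + criteria.duration_s),
                criteria,
                zones,
            )
            if ok:
                found.append(float(s))
        if found:
            out[label] = found[0] if label != "2H" else found[-1]
    return out


def brute_force_bh(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg from the definition: adj_i = min over j with
    p_(j) >= p_(i) of p_(j)·m/rank(j), capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return adj
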