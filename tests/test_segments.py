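"""Steady-state window rules and PRE/POST/2H selection."""
import numpy as np
import pandas as pd
import pytest

import nirsdca as nd
from nirsdca.segments import (
    EventOrderError,
    SegmentCriteria,
    eligibility_intervals,
    exclusion_zones,
    select_segments,
    window_is_steady,
)
from nirsdca.synth import Excursion, VitalSpec, default_vitals_spec
from helpers import brute_force_segments, random_segment_recording


def flat_vitals(duration_s: float, **baselines) -> pd.DataFrame:
    t = np.arange(int(duration_s))
    vals = {"hr": 60.0, "mean_abp": 100.0, "spo2": 98.0, "etco2": 4.5}
    vals.update(baselines)
    return pd.DataFrame({"time_s": t, **{k: np.full(len(t), v) for k, v in vals.items()}})


CRIT = SegmentCriteria()


class TestWindowIsSteady:
    def test_constant_vitals_steady(self):
        ok, qc = window_is_steady(
            flat_vitals(1000), 1.0, None, 100.0, (100, 400), CRIT
        )
        assert ok and not qc["violations"]

    def test_map_ramp_exceeding_ten_percent_fails(self):
        v = flat_vitals(1000)
        ramp = np.linspace(80, 95, 300)
        v.loc[100:399, "mean_abp"] = ramp  # ~17% of window mean
        ok, qc = window_is_steady(v, 1.0, None, 100.0, (100, 400), CRIT)
        assert not ok
        assert "vital:mean_abp" in qc["violations"]
        assert qc["variation"]["mean_abp"] > 0.10

    def test_ten_percent_rule_is_relative_to_window_mean(self):
        v = flat_vitals(1000)
        v.loc[100:399, "mean_abp"] = np.linspace(96, 104, 300)  # 8% of mean
        ok, _ = window_is_steady(v, 1.0, None, 100.0, (100, 400), CRIT)
        assert ok

    @pytest.mark.parametrize(
        "offset,admissible", [(240, False), (299, False), (301, True)]
    )
    def test_ga_induction_five_minute_exclusion(self, offset, admissible):
        ga = 50.0
        zones = [(ga, ga + 300.0)]
        ok, qc = window_is_steady(
            flat_vitals(1200), 1.0, None, 100.0,
            (ga + offset, ga + offset + 300), CRIT, zones,
        )
        assert ok is admissible

    @pytest.mark.parametrize(
        "offset,admissible", [(60, False), (119, False), (121, True)]
    )
    def test_drug_change_two_minute_exclusion(self, offset, admissible):
        t_drug = 400.0
        zones = [(t_drug, t_drug + 120.0)]
        ok, _ = window_is_steady(
            flat_vitals(1500), 1.0, None, 100.0,
            (t_drug + offset, t_drug + offset + 300), CRIT, zones,
        )
        assert ok is admissible

    def test_artifact_density_rule(self):
        mask = np.zeros(100_000, dtype=bool)
        mask[20_000:23_000] = True  # 30 s of 300 s window -> 10%
        ok, qc = window_is_steady(
            flat_vitals(1000), 1.0, {"abp": mask}, 100.0, (100, 400), CRIT
        )
        assert not ok and any(v.startswith("artifacts") for v in qc["violations"])

    def test_missing_vitals_rejected(self):
        v = flat_vitals(250)
        with pytest.raises(ValueError, match="missing"):
            window_is_steady(v, 1.0, None, 100.0, (100, 400), CRIT)


def _recording(duration=2400.0, events=None, vitals_spec=None, drug=(), seed=0):
    return nd.synthesize_recording(
        nd.SynthConfig(
            duration_s=duration,
            fs_raw=50.0,
            seed=seed,
            event_times=events,
            vitals_spec=vitals_spec,
            drug_change_times=drug,
            artifact_spec=nd.ArtifactSpec(count=0),
        )
    )


class TestSelectSegments:
    def test_all_three_labels_selected_once(self):
        rec = _recording(
            events={
                "ga_induction": 50,
                "first_attempt": 800,
                "reperfusion": 850,
                "ga_termination": 1800,
            }
        )
        segs = select_segments(rec)
        assert sorted(s.label for s in segs) == ["2H", "POST", "PRE"]
        by = {s.label: s for s in segs}
        # PRE earliest admissible: induction + 5 min exclusion
        assert by["PRE"].start_s == 350.0
        # POST earliest admissible = reperfusion
        assert by["POST"].start_s == 850.0
        # 2H latest admissible window ends at the end of its interval
        assert by["2H"].end_s == pytest.approx(2400.0, abs=1.5)

    def test_single_admissible_window_returned_exactly(self):
        vs = default_vitals_spec()
        # sharp-edged unrest leaves exactly one clean 300 s stretch of the
        # 1 Hz vitals trace (samples 1000..1299) inside the POST interval
        vs["etco2"].excursions = [
            Excursion(850, 1000, 1.5, ramp_s=1e-3),
            Excursion(1299.5, 1800, 1.5, ramp_s=1e-3),
        ]
        rec = _recording(
            events={
                "ga_induction": 50,
                "first_attempt": 800,
                "reperfusion": 850,
                "ga_termination": 1800,
            },
            vitals_spec=vs,
        )
        segs = [s for s in select_segments(rec, labels=("POST",))]
        assert len(segs) == 1
        assert segs[0].start_s == pytest.approx(1000.0, abs=0.1)

    def test_everything_unsteady_gives_empty_list(self):
        vs = default_vitals_spec()
        vs["mean_abp"] = VitalSpec(100.0, 8.0)  # 8 mmHg SD noise >> 10% rule
        rec = _recording(vitals_spec=vs)
        assert select_segments(rec) == []

    def test_event_order_validated(self):
        rec = _recording(
            events={
                "ga_induction": 50,
                "first_attempt": 900,
                "reperfusion": 800,
                "ga_termination": 1800,
            }
        )
        with pytest.raises(EventOrderError):
            select_segments(rec)

    def test_agrees_with_brute_force_scan(self):
        from nirsdca.segments import compute_artifact_masks

        for seed in range(3):
            rec = random_segment_recording(seed)
            masks = compute_artifact_masks(rec)
            got = {s.label: s.start_s for s in select_segments(rec, CRIT, masks)}
            assert got == brute_force_segments(rec, CRIT, masks)

    def test_tightening_variation_never_adds_windows(self):
        rec = random_segment_recording(12)
        masks = {"abp": np.zeros(len(rec.abp), dtype=bool)}
        loose = SegmentCriteria(vital_variation_fraction=0.10)
        tight = SegmentCriteria(vital_variation_fraction=0.03)
        zones = exclusion_zones(rec, loose)

        def admissible(crit):
            out = set()
            for label, (lo, hi) in eligibility_intervals(rec, crit).items():
                for s in np.arange(np.ceil(lo), np.floor(hi - 300) + 1e-9, 5.0):
                    ok, _ = window_is_steady(
                        rec.vitals, rec.vitals_fs, masks, rec.fs_raw,
                        (float(s), float(s) + 300.0), crit, zones,
                    )
                    if ok:
                        out.add((label, float(s)))
            return out

        assert admissible(tight) <= admissible(loose)

    def test_no_segment_overlaps_exclusion_zone(self):
        for seed in (20, 21):
            rec = random_segment_recording(seed)
            masks = {"abp": np.zeros(len(rec.abp), dtype=bool)}
            zones = exclusion_zones(rec, CRIT)
            for s in select_segments(rec, CRIT, masks):
                assert not any(s.start_s < z1 and s.end_s > z0 for z0, z1 in zones)
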