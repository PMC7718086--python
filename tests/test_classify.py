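import datetime as dt

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from passmon.classify import (
    ClassifierConfig,
    ExclusionReason,
    Label,
    LabeledInterval,
    classify_interval,
    classify_records,
    count_interruptions,
    exclusion_tally,
    filter_noise,
    filter_step_outliers,
)
from passmon.io import IntervalRecord
from tests.conftest import make_record


class TestClassifierConfig:
    def test_defaults(self, default_config):
        assert default_config.waking_start == dt.time(8, 0)
        assert default_config.waking_end == dt.time(22, 0)
        assert default_config.effective_pa_min == 2

    def test_three_way_mode_raises_threshold(self):
        cfg = ClassifierConfig(three_way_mode=True)
        assert cfg.effective_pa_min == 3

    def test_window_order_enforced(self):
        with pytest.raises(ValueError, match="waking_start"):
            ClassifierConfig(waking_start=dt.time(22, 0), waking_end=dt.time(8, 0))

    def test_threshold_bounds(self):
        with pytest.raises(ValueError, match="pa_min_sensors"):
            ClassifierConfig(pa_min_sensors=0)
        with pytest.raises(ValueError, match="outlier_step_threshold"):
            ClassifierConfig(outlier_step_threshold=0)

    def test_from_yaml_file(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("pa_min_sensors: 3\nwaking_start: '09:00'\n")
        cfg = ClassifierConfig.from_file(path)
        assert cfg.pa_min_sensors == 3
        assert cfg.waking_start == dt.time(9, 0)

    def test_from_json_file(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text('{"three_way_mode": true}')
        assert ClassifierConfig.from_file(path).three_way_mode is True

    def test_unknown_key_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ClassifierConfig.from_mapping({"pa_threshold": 2})

    def test_roundtrip_via_dict(self, default_config):
        assert ClassifierConfig.from_mapping(default_config.to_dict()) == default_config


class TestClassifyInterval:
    # the five canonical rule outcomes
    @pytest.mark.parametrize(
        "count,hour,expected",
        [
            (3, 14, Label.PHYSICAL_ACTIVITY),
            (2, 14, Label.PHYSICAL_ACTIVITY),
            (1, 14, Label.SEDENTARY),
            (0, 14, Label.AWAY),
            (0, 3, Label.SLEEP),
            (1, 3, Label.DISTURBED_SLEEP),
            (5, 3, Label.DISTURBED_SLEEP),
        ],
    )
    def test_rule_table(self, count, hour, expected, default_config):
        assert classify_interval(make_record(count, hour), default_config).label is expected

    @pytest.mark.parametrize(
        "count,expected",
        [
            (0, Label.AWAY),
            (1, Label.SEDENTARY),
            (2, Label.SEDENTARY),  # 1-2 sensors are sedentary in three-way mode
            (3, Label.PHYSICAL_ACTIVITY),
        ],
    )
    def test_three_way_mode(self, count, expected):
        cfg = ClassifierConfig(three_way_mode=True)
        assert classify_interval(make_record(count, 14), cfg).label is expected

    @pytest.mark.parametrize(
        "hour,minute,expected",
        [
            (7, 55, Label.SLEEP),   # last sleep-window slot of the morning
            (8, 0, Label.AWAY),     # waking window opens
            (21, 55, Label.AWAY),   # last waking slot
            (22, 0, Label.SLEEP),   # sleep window opens
        ],
    )
    def test_window_boundaries(self, hour, minute, expected, default_config):
        rec = make_record(0, hour, minute)
        assert classify_interval(rec, default_config).label is expected

    def test_missing_count_excluded(self, default_config):
        li = classify_interval(make_record(None, 14), default_config)
        assert li.label is Label.EXCLUDED
        assert li.exclusion_reason is ExclusionReason.MISSING

    def test_custom_windows(self):
        cfg = ClassifierConfig(waking_start=dt.time(6, 0), waking_end=dt.time(23, 0))
        assert classify_interval(make_record(0, 7), cfg).label is Label.AWAY
        assert classify_interval(make_record(0, 23), cfg).label is Label.SLEEP

    @given(count=st.integers(0, 30), slot=st.integers(0, 287), pa_min=st.integers(1, 6))
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_pa_threshold(self, count, slot, pa_min):
        # raising pa_min_sensors can only move labels out of PHYSICAL_ACTIVITY
        rec = make_record(count, slot * 5 // 60, slot * 5 % 60)
        low = classify_interval(rec, ClassifierConfig(pa_min_sensors=pa_min))
        high = classify_interval(rec, ClassifierConfig(pa_min_sensors=pa_min + 1))
        if high.label is Label.PHYSICAL_ACTIVITY:
            assert low.label is Label.PHYSICAL_ACTIVITY


class TestStepOutlierFilter:
    def run(self, steps, threshold=100):
        cfg = ClassifierConfig(outlier_step_threshold=threshold)
        labeled = [classify_interval(make_record(2, 14, steps=steps), cfg)]
        return filter_step_outliers(labeled, cfg)[0]

    def test_above_threshold_excluded(self):
        li = self.run(150)
        assert li.label is Label.EXCLUDED
        assert li.exclusion_reason is ExclusionReason.STEP_OUTLIER

    def test_boundary_value_retained(self):
        # the rule is strictly "more than", so exactly 100 steps survive
        assert self.run(100).label is Label.PHYSICAL_ACTIVITY

    def test_no_step_data_retained(self):
        assert self.run(None).label is Label.PHYSICAL_ACTIVITY

    def test_idempotent(self):
        cfg = ClassifierConfig()
        labeled = [classify_interval(make_record(2, 14, steps=s), cfg) for s in (5, 500, None)]
        once = filter_step_outliers(labeled, cfg)
        twice = filter_step_outliers(once, cfg)
        assert once == twice


def pattern_records(counts, steps=None, start_hour=10):
    steps = steps or [None] * len(counts)
    return [
        make_record(c, start_hour, 5 * i, steps=s)
        for i, (c, s) in enumerate(zip(counts, steps))
    ]


class TestNoiseFilter:
    def classify(self, counts, steps=None, **cfg_kwargs):
        cfg = ClassifierConfig(**cfg_kwargs)
        records = pattern_records(counts, steps)
        labeled = [classify_interval(r, cfg) for r in records]
        return filter_noise(labeled, cfg)

    def test_isolated_blip_excluded(self):
        out = self.classify([0, 1, 0], steps=[0, 0, 0])
        assert out[1].label is Label.EXCLUDED
        assert out[1].exclusion_reason is ExclusionReason.NOISE
        assert out[0].label is Label.AWAY and out[2].label is Label.AWAY

    def test_isolated_blip_without_step_data_excluded(self):
        out = self.classify([0, 1, 0])
        assert out[1].label is Label.EXCLUDED

    def test_blip_with_steps_is_real_movement(self):
        out = self.classify([0, 1, 0], steps=[0, 4, 0])
        assert out[1].label is Label.SEDENTARY

    def test_consecutive_activations_kept(self):
        out = self.classify([0, 1, 1])
        assert all(li.label is not Label.EXCLUDED for li in out)

    def test_multi_sensor_interval_kept(self):
        out = self.classify([0, 2, 0])
        assert out[1].label is Label.PHYSICAL_ACTIVITY

    def test_series_edges_kept(self):
        # no neighbor on one side -> isolation cannot be established
        out = self.classify([1, 0, 0, 1])
        assert out[0].label is Label.SEDENTARY
        assert out[3].label is Label.SEDENTARY

    def test_disabled_filter_is_identity(self):
        out = self.classify([0, 1, 0], noise_filter_enabled=False)
        assert [li.label for li in out] == [Label.AWAY, Label.SEDENTARY, Label.AWAY]

    def test_idempotent(self):
        cfg = ClassifierConfig()
        records = pattern_records([0, 1, 0, 1, 0, 1, 1, 0])
        labeled = [classify_interval(r, cfg) for r in records]
        once = filter_noise(labeled, cfg)
        twice = filter_noise(once, cfg)
        assert once == twice

    def test_neighbors_use_prefilter_counts(self):
        # two blips separated by one silent interval: both are isolated
        # against the ORIGINAL counts, so both go
        out = self.classify([0, 1, 0, 1, 0], steps=[0] * 5)
        assert out[1].label is Label.EXCLUDED
        assert out[3].label is Label.EXCLUDED

    def test_sleep_window_blip_excluded(self):
        cfg = ClassifierConfig()
        records = [make_record(c, 3, 5 * i, steps=0) for i, c in enumerate([0, 1, 0])]
        labeled = [classify_interval(r, cfg) for r in records]
        out = filter_noise(labeled, cfg)
        assert out[1].label is Label.EXCLUDED


class TestCountInterruptions:
    def build(self, pattern):
        labels = {"S": Label.SLEEP, "D": Label.DISTURBED_SLEEP}
        out = []
        for i, ch in enumerate(pattern):
            rec = make_record(0 if ch == "S" else 1, 1, 5 * i)
            out.append(LabeledInterval(rec, labels[ch]))
        return out

    def test_quiet_night(self):
        assert count_interruptions(self.build("SSSSSS")) == 0

    def test_two_runs(self):
        assert count_interruptions(self.build("SSDDSDS")) == 2

    def test_single_run_whole_night(self):
        assert count_interruptions(self.build("DDDDDD")) == 1

    def test_run_at_each_edge(self):
        assert count_interruptions(self.build("DSSSD")) == 2


class TestClassifyRecords:
    def test_pipeline_applies_all_filters(self):
        cfg = ClassifierConfig()
        records = pattern_records([0, 1, 0, 2, 2], steps=[0, 0, 0, 500, 30])
        labeled = classify_records(records, cfg)
        assert labeled[1].exclusion_reason is ExclusionReason.NOISE
        assert labeled[3].exclusion_reason is ExclusionReason.STEP_OUTLIER
        assert labeled[4].label is Label.PHYSICAL_ACTIVITY
        tally = exclusion_tally(labeled)
        assert tally == {"STEP_OUTLIER": 1, "NOISE": 1, "MISSING": 0}

    def test_away_min_intervals_merges_short_runs(self):
        cfg = ClassifierConfig(away_min_intervals=3, noise_filter_enabled=False)
        labeled = classify_records(pattern_records([1, 0, 0, 1, 0, 0, 0, 1]), cfg)
        assert [li.label for li in labeled[1:3]] == [Label.SEDENTARY, Label.SEDENTARY]
        assert [li.label for li in labeled[4:7]] == [Label.AWAY] * 3

    def test_exactly_one_label_each(self, default_config):
        labeled = classify_records(pattern_records([0, 1, 2, 0, 1]), default_config)
        assert len(labeled) == 5
        for li in labeled:
            assert isinstance(li.label, Label)
            assert (li.exclusion_reason is not None) == (li.label is Label.EXCLUDED)


class TestLabeledInterval:
    def test_reason_iff_excluded(self):
        rec = make_record(1, 12)
        with pytest.raises(ValueError, match="exclusion_reason"):
            LabeledInterval(rec, Label.SEDENTARY, ExclusionReason.NOISE)
        with pytest.raises(ValueError, match="exclusion_reason"):
            LabeledInterval(rec, Label.EXCLUDED, None)
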