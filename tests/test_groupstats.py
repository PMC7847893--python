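"""Sections, Kruskal-Wallis, SSMD and run-level comparison summaries."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from zfplate.formats import Section, SectionsSpec, parse_event_string
from zfplate.groupstats import (
    FishRecord,
    apply_sections,
    baseline_mixed_model,
    compare_groups,
    kruskal_wallis,
    metric_table,
    ssmd,
    ssmd_summary,
)
from zfplate.responses import ResponseEvent
from zfplate.synth import SyntheticSpec, simulate_fish_trace


def make_record(spec, seed, group="g1", duration=120.0):
    rng = np.random.default_rng(seed)
    motion, centroid, _ = simulate_fish_trace(spec, duration, rng)
    return FishRecord(well_id=f"W{seed}", group=group, motion=motion,
                      centroid=centroid, well_size=spec.well_size)


class TestApplySections:
    def test_full_section_equals_unsectioned(self, spec):
        rec = make_record(spec, 1)
        full = SectionsSpec([Section("all", 0, 120.0, "time")])
        apply_sections([rec], full)
        from zfplate import kinematics
        bouts = kinematics.detect_bouts(rec.motion, rec.centroid)
        expected = kinematics.bout_summary_metrics(
            bouts, 120.0, rec.centroid, rec.well_size)
        for k, v in expected.items():
            assert rec.processed["all"][k] == pytest.approx(v)

    def test_overlapping_sections_share_data(self, spec):
        rec = make_record(spec, 2)
        ev = parse_event_string("a0.3f625d20", 50.0)
        rec.responses = [(ev, ResponseEvent(responded=True, latency_frames=5,
                                            latency_ms=17.5))]
        secs = SectionsSpec([
            Section("first_half", 0, 60.0, "event"),
            Section("wide", 0, 120.0, "event"),
        ])
        apply_sections([rec], secs)
        assert rec.processed["first_half"]["n_events"] == 1
        assert rec.processed["wide"]["n_events"] == 1

    def test_empty_section_not_an_error(self, spec):
        rec = make_record(spec, 3)
        secs = SectionsSpec([Section("evts", 0, 120.0, "event")])
        apply_sections([rec], secs)
        assert rec.processed["evts"] == {}

    def test_metric_table_shape(self, spec):
        recs = [make_record(spec, s, group="g1" if s % 2 else "g2")
                for s in range(4)]
        apply_sections(recs, SectionsSpec([Section("all", 0, 120.0, "time")]))
        table = metric_table(recs)
        assert len(table) == 4
        assert "group" in table.columns
        assert any(c.startswith("all.") for c in table.columns)


class TestKruskalWallis:
    def test_closed_form_two_groups(self):
        h, p = kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert h == pytest.approx(3.857, abs=1e-3)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            kruskal_wallis([1.0, 2.0], [])

    def test_matches_permutation_oracle(self):
        """Chi-square p close to the exact permutation distribution."""
        a = [1.2, 3.4, 2.2, 5.0, 4.1]
        b = [2.0, 6.1, 7.3, 8.0, 6.6]
        h_obs, p_chi2 = kruskal_wallis(a, b)
        pooled = np.array(a + b)
        n = len(a)
        count = total = 0
        for idx in itertools.combinations(range(len(pooled)), n):
            mask = np.zeros(len(pooled), bool)
            mask[list(idx)] = True
            h, _ = kruskal_wallis(pooled[mask], pooled[~mask])
            count += h >= h_obs - 1e-12
            total += 1
        p_exact = count / total
        assert abs(p_chi2 - p_exact) < 0.05

    def test_null_p_uniform(self):
        """Under the null, p-values are approximately uniform (KS test)."""
        rng = np.random.default_rng(0)
        ps = []
        for _ in range(500):
            x = rng.normal(size=60)
            ps.append(kruskal_wallis(x[:30], x[30:])[1])
        stat, p = stats.kstest(ps, "uniform")
        assert p > 1e-3

    def test_identical_constant_groups(self):
        h, p = kruskal_wallis([1.0, 1.0], [1.0, 1.0])
        assert h == 0.0 and p == 1.0


class TestSsmd:
    def test_identical_samples_zero(self):
        assert ssmd([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0]) == 0.0

    def test_closed_form_unit_variances(self, rng):
        """Means 1 vs 0 with variances 1 each: SSMD = 1/sqrt(2)."""
        a = rng.normal(1.0, 1.0, 200_000)
        b = rng.normal(0.0, 1.0, 200_000)
        assert ssmd(a, b) == pytest.approx(1 / math.sqrt(2), abs=0.01)

    def test_exact_closed_form(self):
        # var([0,2]) = 2, var([-1,1]) = 2: (1-0)/sqrt(4) = 0.5
        assert ssmd([0.0, 2.0], [-1.0, 1.0]) == pytest.approx(0.5)

    def test_antisymmetry(self, rng):
        a, b = rng.normal(0, 1, 30), rng.normal(1, 2, 25)
        assert ssmd(a, b) == pytest.approx(-ssmd(b, a))

    def test_degenerate_zero_variance(self):
        assert ssmd([2.0, 2.0], [2.0, 2.0]) == 0.0
        assert ssmd([3.0, 3.0], [1.0, 1.0]) == math.inf
        assert ssmd([1.0, 1.0], [3.0, 3.0]) == -math.inf


class TestSsmdSummary:
    def test_all_zero_peak_at_zero(self):
        s = ssmd_summary([0.0] * 20)
        assert s.peak == 0.0

    def test_gaussian_sample_peak_near_mean(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0.5, 0.1, 3000)
        s = ssmd_summary(vals)
        assert abs(s.peak - 0.5) < 0.05

    def test_p_count(self):
        s = ssmd_summary([0.1, 0.2, 0.3], p_values=[0.01, 0.04, 0.2])
        assert s.n_p_below_05 == 2

    def test_reorder_invariance(self, rng):
        vals = rng.normal(0, 1, 500)
        s1 = ssmd_summary(vals)
        s2 = ssmd_summary(vals[rng.permutation(500)])
        # identical up to float summation order in the KDE grid limits
        assert s1.peak == pytest.approx(s2.peak, rel=1e-9)

    def test_infinite_ssmds_dropped(self):
        s = ssmd_summary([0.0, 0.1, math.inf, -math.inf])
        assert s.n_metrics == 4
        assert np.isfinite(s.peak)


class TestCompareGroups:
    def test_split_null_plate(self, spec):
        """Same generator both groups: KDE peak near 0, ~5% of p < 0.05."""
        recs = []
        for s in range(24):
            recs.append(make_record(spec, s, group="g1" if s < 12 else "g2",
                                    duration=300.0))
        secs = SectionsSpec([
            Section(f"t{i}", i * 60.0, (i + 1) * 60.0, "time")
            for i in range(5)
        ])
        apply_sections(recs, secs)
        result = compare_groups(metric_table(recs))
        assert abs(result.summary.peak) < 0.5
        assert result.summary.n_p_below_05 <= \
            0.05 * result.summary.n_metrics + \
            3 * math.sqrt(0.05 * 0.95 * result.summary.n_metrics) + 1

    def test_implanted_effect_detected(self, spec):
        fast = SyntheticSpec(seed=8, day_bout_rate_per_min=30.0)
        recs = [make_record(spec, s, group="wt", duration=300.0)
                for s in range(10)]
        recs += [make_record(fast, 100 + s, group="mut", duration=300.0)
                 for s in range(10)]
        apply_sections(recs, SectionsSpec([Section("all", 0, 300.0, "time")]))
        result = compare_groups(metric_table(recs))
        freq = result.table.loc["all.bout_frequency_per_min"]
        assert freq["p"] < 0.01
        assert abs(freq["ssmd"]) > 1.0

    def test_needs_two_groups(self, spec):
        recs = [make_record(spec, s) for s in range(4)]
        apply_sections(recs, SectionsSpec([Section("all", 0, 120.0, "time")]))
        with pytest.raises(ValueError):
            compare_groups(metric_table(recs))


class TestBaselineMixedModel:
    def make_binned(self, rng, n_fish=16, n_bins=6, effect=0.0):
        rows = []
        for f in range(n_fish):
            group = "g1" if f < n_fish // 2 else "g2"
            intercept = rng.normal(10.0, 1.0)
            for t in range(n_bins):
                v = intercept + 0.5 * t + rng.normal(0, 1.0)
                if group == "g2":
                    v += effect
                rows.append(dict(fish_id=f"f{f}", group=group,
                                 time_bin=t, value=v))
        return pd.DataFrame(rows)

    def test_null_effect_near_zero(self):
        """Null estimate small relative to noise in most replicates."""
        hits = 0
        n = 40
        for s in range(n):
            rng = np.random.default_rng(s)
            est, p = baseline_mixed_model(self.make_binned(rng))
            hits += p > 0.05
        assert hits / n >= 0.85

    def test_implanted_effect_detected(self):
        hits = 0
        n = 20
        for s in range(n):
            rng = np.random.default_rng(500 + s)
            est, p = baseline_mixed_model(
                self.make_binned(rng, effect=2.0))
            hits += (p < 0.05 and est > 0)
        assert hits / n >= 0.9

    def test_single_time_bin_collapses_to_group_comparison(self):
        rng = np.random.default_rng(3)
        df = self.make_binned(rng, n_bins=1, effect=1.0)
        est, p = baseline_mixed_model(df)
        diff = df[df.group == "g2"].value.mean() \
            - df[df.group == "g1"].value.mean()
        assert est == pytest.approx(diff, rel=1e-6)
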