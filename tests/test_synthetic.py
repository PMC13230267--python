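"""Synthetic-cohort generator: determinism, planted structure, validation."""

import numpy as np
import pandas as pd
import pytest

from netswitch.parcellation import detect_elbow, select_top_fraction
from netswitch.pipeline import subject_allegiance
from netswitch.synthetic import (
    Cohort,
    CohortSpec,
    SwitchSchedule,
    draw_schedule,
    generate_cohort,
    generate_density,
    generate_timeseries,
    make_region_table,
)


def no_switch_schedule(base, n_windows=74, width=27):
    return SwitchSchedule(transitions=[], base_allegiance=base,
                          n_windows=n_windows, width=width)


class TestGenerateTimeseries:
    def test_noiseless_within_rsn_correlation_is_one(self):
        base = {f"r{i}": 1 + i % 2 for i in range(6)}  # two RSNs, 3 regions each
        ts = generate_timeseries(no_switch_schedule(base), 60, 0.0, seed=5)
        same = [i for i, rid in enumerate(base) if base[rid] == 1]
        for a in same:
            for b in same:
                r = np.corrcoef(ts[a, 10:37], ts[b, 10:37])[0, 1]
                assert r == pytest.approx(1.0)

    def test_same_seed_bit_identical(self, base_allegiance_40):
        sched = no_switch_schedule(base_allegiance_40)
        a = generate_timeseries(sched, 100, 0.4, seed=9)
        b = generate_timeseries(sched, 100, 0.4, seed=9)
        assert np.array_equal(a, b)

    def test_different_seed_differs(self, base_allegiance_40):
        sched = no_switch_schedule(base_allegiance_40)
        a = generate_timeseries(sched, 100, 0.4, seed=9)
        b = generate_timeseries(sched, 100, 0.4, seed=10)
        assert not np.array_equal(a, b)

    @pytest.mark.parametrize("transitions, match", [
        ([(80, frozenset(["r0"]), 2, "disjoint")], "index outside"),
        ([(5, frozenset(["r0", "r1"]), 2, "disjoint")], "disjoint mode"),
        ([(5, frozenset(["r0"]), 2, "cohesive")], "cohesive mode"),
        ([(5, frozenset(["r0"]), 1, "disjoint")], "current allegiance"),
        ([(5, frozenset(["zz"]), 2, "disjoint")], "unknown region"),
    ])
    def test_inconsistent_schedule_rejected(self, transitions, match):
        base = {f"r{i}": 1 + i % 2 for i in range(6)}
        sched = SwitchSchedule(transitions=transitions, base_allegiance=base,
                               n_windows=40, width=27)
        with pytest.raises(ValueError, match=match):
            generate_timeseries(sched, 66, 0.0, seed=1)


class TestSwitchRealisation:
    def test_cohesive_event_recovered_across_boundary(self, region_table_40,
                                                      base_allegiance_40):
        """A planted 3-region wave at transition 10 changes exactly those
        regions' recovered labels between the last fully-pre window (10) and
        the first fully-post window (10 + width)."""
        ids = list(base_allegiance_40)
        movers = [ids[0], ids[8], ids[16]]  # homes 1, 2, 3 -> destination 5
        sched = SwitchSchedule(
            transitions=[(10, frozenset(movers), 5, "cohesive")],
            base_allegiance=base_allegiance_40, n_windows=74, width=27)
        ts = generate_timeseries(sched, 100, 0.0, seed=2)
        am = subject_allegiance(
            ts, region_table_40["rsn_label"].to_numpy(int),
            region_ids=ids, width=27)
        changed = am.labels[:, 37] != am.labels[:, 10]
        assert set(np.flatnonzero(changed)) == {0, 8, 16}
        for m in (0, 8, 16):
            assert am.labels[m, 10] == base_allegiance_40[ids[m]]
            assert am.labels[m, 37] == 5

    def test_window_and_volume_domains_consistent(self, base_allegiance_40):
        ids = list(base_allegiance_40)
        sched = SwitchSchedule(
            transitions=[(10, frozenset([ids[0]]), 5, "disjoint")],
            base_allegiance=base_allegiance_40, n_windows=74, width=27)
        wl = sched.window_allegiance()
        vl = sched.volume_allegiance(100)
        assert wl[0, 10] == vl[0, 36] == base_allegiance_40[ids[0]]
        assert wl[0, 11] == vl[0, 37] == 5
        # window 10 spans volumes [10, 37): fully pre-switch
        assert (vl[0, 10:37] == base_allegiance_40[ids[0]]).all()


class TestDrawSchedule:
    def test_per_region_event_separation(self, base_allegiance_40, rng):
        sched = draw_schedule(base_allegiance_40, 274, 0.023, rng, width=27)
        times = {}
        for t, members, _, _ in sorted(sched.transitions, key=lambda tr: tr[0]):
            for rid in members:
                times.setdefault(rid, []).append(t)
        assert any(len(v) > 1 for v in times.values())
        for v in times.values():
            assert all(b - a >= 27 for a, b in zip(v, v[1:]))

    def test_modes_well_formed_and_valid(self, base_allegiance_40, rng):
        sched = draw_schedule(base_allegiance_40, 274, 0.023, rng, width=27)
        sched.validate()
        modes = {m for _, _, _, m in sched.transitions}
        assert modes == {"cohesive", "disjoint"}
        for _, members, _, mode in sched.transitions:
            assert len(members) == (3 if mode == "cohesive" else 1)

    def test_rate_zero_gives_empty_schedule(self, base_allegiance_40, rng):
        sched = draw_schedule(base_allegiance_40, 274, 0.0, rng)
        assert sched.transitions == []

    def test_realised_rate_tracks_nominal(self, base_allegiance_40, rng):
        sched = draw_schedule(base_allegiance_40, 274, 0.010, rng, width=27)
        realised = sched.planted_flexibility().mean()
        assert 0.6 * 0.010 <= realised <= 1.1 * 0.010


class TestGenerateDensity:
    def test_planted_elbow_recovered(self):
        dv = generate_density(224, 12, elbow_sharpness=5, seed=1)
        res = detect_elbow(dv)
        assert not res.is_linear
        assert res.cutoff_rank == 12

    def test_linear_ramp_triggers_fallback(self):
        dv = generate_density(224, 12, elbow_sharpness=1, seed=1)
        assert detect_elbow(dv).is_linear
        assert len(select_top_fraction(dv, 0.05)) == 12

    def test_normalised_max_is_exactly_one(self):
        dv = generate_density(50, 5, elbow_sharpness=3, seed=7)
        assert dv.values.max() == 1.0
        assert (dv.values > 0).all()

    def test_invalid_n_top_rejected(self):
        with pytest.raises(ValueError):
            generate_density(10, 10, elbow_sharpness=2, seed=1)


@pytest.fixture(scope="module")
def small_spec():
    return CohortSpec(
        n_per_group={"HC": 3, "non-fatigued": 2, "mild/moderate": 0,
                     "severe": 3},
        n_regions=40, n_volumes=60, seed=11)


class TestGenerateCohort:

    def test_structure_and_fsmc_bands(self, small_spec):
        c = generate_cohort(small_spec)
        assert isinstance(c, Cohort)
        assert len(c.participants) == 8
        assert "mild/moderate" not in set(c.participants["group"])
        for _, row in c.participants.iterrows():
            lo, hi = small_spec.fsmc_ranges[row["group"]]
            assert lo <= row["fsmc_total"] <= hi
        assert set(c.timeseries) == set(c.participants["subject_id"])
        assert c.coverage.to_numpy().min() == 1.0

    def test_identical_seeds_identical_cohorts(self, small_spec):
        a, b = generate_cohort(small_spec), generate_cohort(small_spec)
        pd.testing.assert_frame_equal(a.participants, b.participants)
        for sid in a.timeseries:
            assert np.array_equal(a.timeseries[sid], b.timeseries[sid])
            assert a.truth[sid]["schedule"].transitions == \
                b.truth[sid]["schedule"].transitions

    def test_group_rates_ordered_in_truth(self, small_spec):
        c = generate_cohort(small_spec)
        by_group = {}
        for sid, rec in c.truth.items():
            by_group.setdefault(rec["group"], []).append(
                rec["schedule"].planted_flexibility().mean())
        assert np.mean(by_group["severe"]) > np.mean(by_group["HC"])

    def test_fsmc_range_straddling_cutoff_rejected(self):
        spec = CohortSpec(fsmc_ranges={
            "HC": (20, 42), "non-fatigued": (20, 50),
            "mild/moderate": (43, 62), "severe": (63, 85)})
        with pytest.raises(ValueError, match="straddles"):
            spec.validate()

    def test_volumes_shorter_than_window_rejected(self):
        with pytest.raises(ValueError, match="window width"):
            CohortSpec(n_volumes=20).validate()


def test_region_table_reference_configuration():
    regs = make_region_table(224, 8)
    assert (regs["source"] == "cortical").sum() == 210
    assert (regs["source"] == "deep-gray").sum() == 14
    assert regs["rsn_label"].nunique() == 8
    assert regs["rsn_label"].value_counts().min() >= 3
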