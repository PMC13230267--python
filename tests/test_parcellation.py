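"""Coverage QC, density normalisation, and circuit delineation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from netswitch.parcellation import (
    DensityVector,
    build_circuits,
    detect_elbow,
    exclude_participants,
    exclude_regions,
    normalize_density,
    select_top_fraction,
)
from netswitch.synthetic import generate_density


def coverage_frame(values):
    return pd.DataFrame(values).rename_axis("subject_id")


class TestExcludeParticipants:
    def test_boundary_strictly_greater(self):
        cov = coverage_frame({f"r{i}": [0.0 if i < 13 else 1.0,
                                        0.0 if i < 12 else 1.0]
                              for i in range(20)})
        cov.index = ["s13", "s12"]
        retained, log = exclude_participants(cov, zero_region_limit=12)
        assert retained == ["s12"]          # 12 zeros: retained, rule is '>'
        assert list(log["subject_id"]) == ["s13"]

    def test_crafted_fixture_matches_brute_force(self):
        rng = np.random.default_rng(3)
        n_zero = [0, 5, 13, 12, 30]
        cov = np.ones((5, 40))
        for s, k in enumerate(n_zero):
            cov[s, rng.choice(40, size=k, replace=False)] = 0.0
        df = coverage_frame(pd.DataFrame(cov, index=[f"s{i}" for i in range(5)]))
        retained, log = exclude_participants(df)
        brute = [f"s{i}" for i, k in enumerate(n_zero) if k <= 12]
        assert retained == brute
        assert set(log["subject_id"]) == {"s2", "s4"}

    def test_missing_entry_named(self):
        cov = coverage_frame({"rA": [1.0, np.nan]})
        cov.index = ["s0", "s1"]
        with pytest.raises(ValueError, match="s1.*rA"):
            exclude_participants(cov)


class TestExcludeRegions:
    def test_all_ones_is_identity(self):
        cov = coverage_frame(pd.DataFrame(np.ones((8, 30)),
                                          columns=[f"r{i}" for i in range(30)]))
        retained, log = exclude_regions(cov)
        assert retained == list(cov.columns)
        assert log.empty

    def test_boundary_strictly_greater(self):
        # 10 subjects; one region at 0.29 in exactly 1 subject (10%): retained
        cov = pd.DataFrame(np.ones((10, 3)), columns=["a", "b", "c"])
        cov.loc[0, "a"] = 0.29
        cov.loc[0:1, "b"] = 0.29           # 2 of 10 = 20% > 10%: excluded
        retained, _ = exclude_regions(coverage_frame(cov))
        assert retained == ["a", "c"]

    def test_empty_subject_set_rejected(self):
        cov = pd.DataFrame(columns=["a", "b"], dtype=float)
        with pytest.raises(ValueError, match="no subjects"):
            exclude_regions(coverage_frame(cov))


class TestNormalizeDensity:
    def test_simple_halving(self):
        dv = normalize_density({"A": 2.0, "B": 4.0}, map_name="m")
        assert dv.values["A"] == 0.5 and dv.values["B"] == 1.0

    @given(st.lists(st.floats(0.01, 1e6), min_size=2, max_size=30),
           st.floats(0.001, 1e3))
    def test_idempotent_and_scale_invariant(self, values, c):
        raw = pd.Series(values, index=[f"r{i}" for i in range(len(values))])
        once = normalize_density(raw).values
        twice = normalize_density(once).values
        scaled = normalize_density(raw * c).values
        assert np.allclose(once, twice)
        assert np.allclose(once, scaled)
        assert once.max() == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            normalize_density({"A": 0.0, "B": 0.0})
        with pytest.raises(ValueError):
            normalize_density({"A": -1.0, "B": -2.0})


class TestDetectElbow:
    def test_step_function_matches_brute_force(self):
        for n_top in (3, 7, 12):
            vals = np.where(np.arange(40) < n_top, 1.0, 0.1)
            dv = DensityVector("m", pd.Series(
                vals, index=[f"r{i:02d}" for i in range(40)]))
            res = detect_elbow(dv)
            # brute-force max perpendicular distance over the sorted curve;
            # the elbow point joins whichever side its value is nearer
            y = np.sort(vals)[::-1]
            n = len(y)
            best, best_d = None, -1.0
            for i in range(n):
                num = abs((y[-1] - y[0]) * i - (n - 1) * (y[i] - y[0]))
                d = num / np.hypot(n - 1, y[-1] - y[0])
                if d > best_d:
                    best, best_d = i, d
            cut = best + 1 if abs(y[best] - y[0]) <= abs(y[best] - y[-1]) else best
            assert res.cutoff_rank == cut == n_top
            assert not res.is_linear

    def test_exact_ramp_is_linear(self):
        dv = DensityVector("m", pd.Series(
            np.linspace(1, 0.1, 30), index=[f"r{i}" for i in range(30)]))
        assert detect_elbow(dv).is_linear

    def test_planted_elbow_recovered_over_replicates(self):
        for sharpness in (2, 5):
            for seed in range(25):
                dv = generate_density(224, 12, sharpness, seed=seed)
                res = detect_elbow(dv)
                assert res.cutoff_rank == 12 and not res.is_linear, \
                    f"sharpness={sharpness}, seed={seed}"

    def test_too_few_regions_rejected(self):
        with pytest.raises(ValueError):
            detect_elbow(DensityVector("m", pd.Series({"a": 1.0, "b": 0.5})))


class TestSelectTopFraction:
    @pytest.mark.parametrize("n, fraction, expected", [
        (224, 0.05, 12),   # ceil(11.2)
        (100, 0.05, 5),    # exact division
        (10, 0.25, 3),     # ceil(2.5)
    ])
    def test_ceiling_count(self, n, fraction, expected):
        dv = DensityVector("m", pd.Series(
            np.linspace(1, 0.01, n), index=[f"r{i:03d}" for i in range(n)]))
        assert len(select_top_fraction(dv, fraction)) == expected

    def test_tie_broken_by_region_id(self):
        vals = np.linspace(1, 0.5, 224)
        vals[11] = vals[12] = (vals[11] + vals[12]) / 2  # tie at the rank-12 cut
        dv = DensityVector("m", pd.Series(
            vals, index=[f"r{i:03d}" for i in range(224)]))
        top = select_top_fraction(dv, 0.05)
        assert len(top) == 12
        assert "r011" in top and "r012" not in top

    def test_invalid_fraction_rejected(self):
        dv = DensityVector("m", pd.Series({"a": 1.0, "b": 0.5}))
        with pytest.raises(ValueError):
            select_top_fraction(dv, 1.5)


class TestBuildCircuits:
    def planted(self, name, top_ids, n=60, seed=0):
        rng = np.random.default_rng(seed)
        ids = [f"r{i:02d}" for i in range(n)]
        vals = pd.Series(0.1 + 0.001 * rng.random(n), index=ids)
        vals[top_ids] = np.linspace(1.0, 0.9, len(top_ids))
        return DensityVector(name, vals)

    def test_identical_member_sets_merged_with_joint_name(self):
        top = [f"r{i:02d}" for i in range(5)]
        cs = build_circuits([self.planted("D2", top), self.planted("DAT", top)],
                            retained_regions=[f"r{i:02d}" for i in range(60)])
        assert list(cs.circuits) == ["D2/DAT"]
        assert set(cs.circuits["D2/DAT"]) == set(top)
        assert cs.merged_from["D2/DAT"] == ["D2", "DAT"]

    def test_disjoint_planted_tops_recovered(self):
        a = [f"r{i:02d}" for i in range(4)]
        b = [f"r{i:02d}" for i in range(10, 15)]
        cs = build_circuits([self.planted("A", a), self.planted("B", b)],
                            retained_regions=[f"r{i:02d}" for i in range(60)])
        assert set(cs.circuits["A"]) == set(a)
        assert set(cs.circuits["B"]) == set(b)

    def test_single_map(self):
        cs = build_circuits([self.planted("NAT", ["r00", "r01", "r02"])],
                            retained_regions=[f"r{i:02d}" for i in range(60)])
        assert len(cs) == 1

    def test_invariant_to_region_ordering(self):
        top = [f"r{i:02d}" for i in range(5)]
        dv = self.planted("A", top)
        shuffled = DensityVector("A", dv.values.sample(frac=1, random_state=4))
        retained = [f"r{i:02d}" for i in range(60)]
        cs1 = build_circuits([dv], retained)
        cs2 = build_circuits([shuffled], list(reversed(retained)))
        assert cs1.circuits == cs2.circuits

    def test_restriction_to_retained_regions(self):
        top = [f"r{i:02d}" for i in range(5)]
        cs = build_circuits([self.planted("A", top)],
                            retained_regions=[f"r{i:02d}" for i in range(1, 60)])
        assert "r00" not in cs.circuits["A"]
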