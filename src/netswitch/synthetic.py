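"""Synthetic cohorts with planted allegiance-switching structure.

No scan data ship with the package; every downstream stage is exercised on
synthetic region time series with known ground truth.  The generative model
is deliberately minimal: each resting-state network (RSN) has an independent
unit-variance white-noise latent signal, and a region's series is the latent
of its *current* RSN allegiance plus independent Gaussian noise.  That is
the weakest model under which within-RSN correlation exceeds between-RSN
correlation, which is all the allegiance-assignment step assumes.

Planted switching lives in a :class:`SwitchSchedule`: at chosen window
transitions, named regions change allegiance, either as a *cohesive* wave
(≥ 2 regions moving to one shared destination RSN) or as a *disjoint* solo
move.  A switch scheduled at window transition k is realised in the raw
series at volume index k + width, so that window k (half-open
[k, k + width)) is the last window lying fully before the change and
windows from k + width onward lie fully after it; the windows in between
straddle the change and are excluded from ground-truth comparisons.

Switching is drawn as *excursions* — a region, or a cohesive wave of
regions, departs to a destination RSN and returns home one window width
later — under structural constraints (per-region event separation, caps on
how many members of a network may be away at once, unique destinations per
transition) that keep every planted switch recoverable by the fixed-
membership argmax assignment; see :func:`draw_schedule`.  The realised
per-region switch rate can fall slightly below the nominal rate when those
caps bind, so recovery is always judged against the realised schedule,
which the cohort records as ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SwitchSchedule",
    "CohortSpec",
    "Cohort",
    "GROUPS",
    "make_region_table",
    "draw_schedule",
    "generate_timeseries",
    "generate_density",
    "generate_cohort",
]

GROUPS = ("HC", "non-fatigued", "mild/moderate", "severe")

#: FSMC-total severity cut-offs (mild, moderate, severe)
_FSMC_TOTAL_CUTS = (43, 53, 63)


@dataclass
class SwitchSchedule:
    """Planted allegiance switches for one subject.

    ``transitions`` holds (window-transition index, region ids, destination
    RSN label, mode) tuples with mode in {"cohesive", "disjoint"}; indices
    refer to the gap between windows k and k+1 and lie in [0, W−2].
    ``base_allegiance`` maps each region id to its starting RSN label.
    """

    transitions: list[tuple]
    base_allegiance: dict
    n_windows: int
    width: int = 27

    @property
    def region_ids(self) -> list:
        return list(self.base_allegiance)

    def validate(self) -> None:
        cur = dict(self.base_allegiance)
        for i, (t, members, dest, mode) in enumerate(sorted(self.transitions, key=lambda tr: tr[0])):
            where = f"transition #{i} (index {t})"
            if not 0 <= t <= self.n_windows - 2:
                raise ValueError(f"{where}: index outside [0, {self.n_windows - 2}]")
            members = set(members)
            if mode == "disjoint" and len(members) != 1:
                raise ValueError(f"{where}: disjoint mode names {len(members)} "
                                 "regions, expected exactly 1")
            if mode == "cohesive" and len(members) < 2:
                raise ValueError(f"{where}: cohesive mode needs >= 2 regions")
            if mode not in ("cohesive", "disjoint"):
                raise ValueError(f"{where}: unknown mode {mode!r}")
            for rid in members:
                if rid not in cur:
                    raise ValueError(f"{where}: unknown region {rid!r}")
                if cur[rid] == dest:
                    raise ValueError(
                        f"{where}: destination {dest} equals region {rid!r}'s "
                        "current allegiance")
                cur[rid] = dest

    def window_allegiance(self) -> np.ndarray:
        """Ground-truth (R, W) window-domain labels: windows ≤ k keep the
        pre-switch label, windows ≥ k+1 the destination."""
        ids = self.region_ids
        pos = {rid: i for i, rid in enumerate(ids)}
        lab = np.tile(np.array([self.base_allegiance[r] for r in ids],
                               dtype=int)[:, None], (1, self.n_windows))
        for t, members, dest, _ in sorted(self.transitions, key=lambda tr: tr[0]):
            for rid in members:
                lab[pos[rid], t + 1:] = dest
        return lab

    def volume_allegiance(self, n_volumes: int) -> np.ndarray:
        """(R, V) volume-domain labels; a switch at transition k takes
        effect at volume k + width."""
        ids = self.region_ids
        pos = {rid: i for i, rid in enumerate(ids)}
        lab = np.tile(np.array([self.base_allegiance[r] for r in ids],
                               dtype=int)[:, None], (1, n_volumes))
        for t, members, dest, _ in sorted(self.transitions, key=lambda tr: tr[0]):
            v = t + self.width
            for rid in members:
                if v < n_volumes:
                    lab[pos[rid], v:] = dest
        return lab

    def interior_mask(self) -> np.ndarray:
        """(R, W) boolean: True where a window's volume span lies entirely
        within one allegiance epoch of that region (False for the straddling
        windows k+1 .. k+width−1 around a switch at transition k)."""
        ids = self.region_ids
        pos = {rid: i for i, rid in enumerate(ids)}
        mask = np.ones((len(ids), self.n_windows), dtype=bool)
        w_idx = np.arange(self.n_windows)
        for t, members, _, _ in self.transitions:
            straddle = (w_idx > t) & (w_idx < t + self.width)
            for rid in members:
                mask[pos[rid], straddle] = False
        return mask

    def planted_flexibility(self) -> pd.Series:
        """Realised per-region switch fraction: events / (W − 1)."""
        counts = pd.Series(0.0, index=pd.Index(self.region_ids, name="region_id"))
        for _, members, _, _ in self.transitions:
            for rid in members:
                counts.loc[rid] += 1
        return counts / (self.n_windows - 1)

    def planted_rates(self) -> pd.DataFrame:
        """Realised per-region cohesive/disjoint switch fractions."""
        idx = pd.Index(self.region_ids, name="region_id")
        coh = pd.Series(0.0, index=idx)
        dis = pd.Series(0.0, index=idx)
        for _, members, _, mode in self.transitions:
            tgt = coh if mode == "cohesive" else dis
            for rid in members:
                tgt.loc[rid] += 1
        n = self.n_windows - 1
        return pd.DataFrame({"cohesion": coh / n, "disjointedness": dis / n})


def make_region_table(n_regions: int = 224, n_rsn: int = 8) -> pd.DataFrame:
    """A synthetic region table: cortical regions round-robin over the first
    n_rsn − 1 networks, plus a deep-gray block labelled with network n_rsn.

    The default emulates the reference configuration (210 cortical + 14
    deep-gray, 8 networks); smaller tables keep the 15:1 cortical:deep ratio
    with at least 3 regions per network so allegiance assignment is defined.
    """
    if n_rsn < 2:
        raise ValueError("need at least 2 networks")
    n_deep = max(3, round(n_regions / 16))
    n_cortical = n_regions - n_deep
    if n_cortical < 3 * (n_rsn - 1):
        raise ValueError(f"{n_regions} regions cannot give every one of "
                         f"{n_rsn} networks >= 3 members")
    rows = []
    for i in range(n_cortical):
        rows.append({"region_id": f"CTX{i:03d}", "name": f"cortical-{i}",
                     "source": "cortical", "rsn_label": (i % (n_rsn - 1)) + 1})
    for i in range(n_deep):
        rows.append({"region_id": f"DGM{i:03d}", "name": f"deep-gray-{i}",
                     "source": "deep-gray", "rsn_label": n_rsn})
    return pd.DataFrame(rows)


def draw_schedule(base_allegiance: dict, n_windows: int, rate: float,
                  rng: np.random.Generator, width: int = 27,
                  cohesive_fraction: float = 0.88, wave_size: int = 3,
                  n_rsn: int | None = None) -> SwitchSchedule:
    """Draw a random switch schedule at a nominal per-region, per-transition
    switch rate.

    Switching is planted as *excursions*: a region (or, for a cohesive
    event, a wave of ``wave_size`` regions with pairwise-distinct home
    networks) departs to a shared destination RSN and returns home one
    window width later, each leg counting as one switch.  Wave departures
    are cohesive; solo departures and all returns are disjoint (wave
    members return to different homes).  ``cohesive_fraction`` is the
    probability that an excursion is a wave.

    Three structural constraints keep every planted switch recoverable by
    the fixed-membership argmax assignment:

    * a region's successive switches are at least ``width`` transitions
      apart, so windows fully inside each allegiance epoch exist;
    * each RSN has a cap (``max(1, min(size − 3, size // 2))``) on members
      simultaneously *disturbed* — away from home or still inside the
      window-width transit zone around a switch — so at least half of
      every network is settled at home and home connectivity keeps the
      largest mean for every region's true allegiance;
    * destinations are unique within a transition, only a small quota of
      one home RSN's members (``max(1, size // 10)``) may visit the same
      destination at once, and networks smaller than 4 regions are never
      destinations; no foreign network then ever
      hosts enough same-latent signal to overtake a region's true RSN, and
      planted modes match what :func:`~netswitch.reconfiguration.classify_switches`
      reports on the ground-truth labels.

    A deficit scheduler launches excursions so the cumulative planted
    switch count tracks ``rate × R × t``; when the caps saturate the
    realised rate falls short of nominal, and recovery is always judged
    against the realised schedule.
    """
    if not 0 <= rate <= 1:
        raise ValueError("switch rate must lie in [0, 1]")
    n_trans = n_windows - 1
    ids = list(base_allegiance)
    R = len(ids)
    home = dict(base_allegiance)
    K = n_rsn if n_rsn is not None else max(home.values())
    sizes: dict[int, int] = {}
    for h in home.values():
        sizes[h] = sizes.get(h, 0) + 1
    cap = {h: max(1, min(s - 3, s // 2)) for h, s in sizes.items()}
    big_dests = [d for d in range(1, K + 1) if sizes.get(d, 0) >= 4] \
        or list(range(1, K + 1))
    pair_cap = {h: max(1, s // 10) for h, s in sizes.items()}

    cur = dict(home)
    disturbed = {h: 0 for h in sizes}      # away or within transit of a switch
    pair_count: dict[tuple, int] = {}      # (home RSN, destination) visits in use
    free_at = {rid: 0 for rid in ids}
    returns_due: dict[int, list] = {}
    release_due: dict[int, list] = {}      # resettle time -> (home, dest) slots
    dest_used: dict[int, set] = {}
    transitions: list[tuple] = []
    scheduled = 0.0
    dwell = width

    for t in range(n_trans):
        for h, d_old in release_due.pop(t, ()):
            disturbed[h] -= 1
            pair_count[(h, d_old)] -= 1
        for rid in returns_due.pop(t, ()):
            h = home[rid]
            transitions.append((t, frozenset([rid]), h, "disjoint"))
            release_due.setdefault(t + width, []).append((h, cur[rid]))
            cur[rid] = h
            free_at[rid] = t + width
        target = rate * R * (t + 1)
        while scheduled < target - 1e-9:
            is_wave = bool(rng.random() < cohesive_fraction) and wave_size >= 2
            m = wave_size if is_wave else 1
            elig = [rid for rid in ids
                    if free_at[rid] <= t and cur[rid] == home[rid]
                    and disturbed[home[rid]] < cap[home[rid]]]
            rng.shuffle(elig)
            members, used_homes = [], set()
            for rid in elig:
                if home[rid] not in used_homes:
                    members.append(rid)
                    used_homes.add(home[rid])
                if len(members) == m:
                    break
            if len(members) < m:
                break  # capacity exhausted at this transition
            used = dest_used.get(t, set())
            cand = [d for d in big_dests
                    if d not in used_homes and d not in used
                    and all(pair_count.get((home[r], d), 0) < pair_cap[home[r]]
                            for r in members)]
            if not cand:
                break
            d = int(cand[rng.integers(len(cand))])
            transitions.append((t, frozenset(members), d,
                                "cohesive" if m > 1 else "disjoint"))
            dest_used.setdefault(t, set()).add(d)
            n_switch = m
            for rid in members:
                cur[rid] = d
                disturbed[home[rid]] += 1
                pair_count[(home[rid], d)] = pair_count.get((home[rid], d), 0) + 1
                free_at[rid] = t + width
                tr = t + dwell
                while tr < n_trans and home[rid] in dest_used.get(tr, set()):
                    tr += 1
                if tr < n_trans:
                    returns_due.setdefault(tr, []).append(rid)
                    dest_used.setdefault(tr, set()).add(home[rid])
                    n_switch += 1
                # else: the region stays away through the end of the run
            scheduled += n_switch
    return SwitchSchedule(transitions=transitions,
                          base_allegiance=dict(home),
                          n_windows=n_windows, width=width)


def generate_timeseries(schedule: SwitchSchedule, n_volumes: int,
                        noise_sd: float, seed: int) -> np.ndarray:
    """Region-by-volume series realising a switch schedule.

    Each region's signal at volume t is the shared unit-variance white-noise
    latent of its current RSN allegiance plus independent N(0, noise_sd)
    noise; identical (schedule, n_volumes, noise_sd, seed) reproduce the
    matrix bit for bit.
    """
    if n_volumes < 2:
        raise ValueError("need at least 2 volumes")
    schedule.validate()
    rng = np.random.default_rng(seed)
    K = max(max(schedule.base_allegiance.values()),
            max((d for _, _, d, _ in schedule.transitions), default=0))
    latents = rng.standard_normal((K, n_volumes))
    lab = schedule.volume_allegiance(n_volumes)  # (R, V), labels 1..K
    ts = latents[lab - 1, np.arange(n_volumes)[None, :]]
    if noise_sd > 0:
        ts = ts + rng.normal(0.0, noise_sd, size=ts.shape)
    return ts


def generate_density(n_regions: int, n_top: int, elbow_sharpness: float,
                     seed: int, region_ids=None, map_name: str = "synthetic"):
    """A density vector whose sorted curve has a planted elbow at rank n_top.

    The sorted curve is two linear ramps: slope ``elbow_sharpness`` over the
    top ``n_top`` ranks and slope 1 over the tail, plus a small
    multiplicative jitter; ``elbow_sharpness = 1`` collapses the kink into a
    single linear ramp (no elbow, triggering the top-fraction fallback
    downstream).  Values are assigned to regions in shuffled order and
    normalised so the maximum is exactly 1.
    """
    from .parcellation import DensityVector

    if not 0 < n_top < n_regions:
        raise ValueError("need 0 < n_top < n_regions")
    if elbow_sharpness < 1:
        raise ValueError("elbow_sharpness must be >= 1")
    rng = np.random.default_rng(seed)
    i = np.arange(n_regions, dtype=float)
    tail_top = n_regions - n_top  # raw value at the kink (rank n_top)
    raw = np.where(i < n_top,
                   tail_top + (n_top - 1 - i) * elbow_sharpness,
                   n_regions - 1 - i)
    raw = raw + 1.0  # keep the smallest value strictly positive
    # jitter far below the unit tail step: the chord-distance profile falls
    # off by only ~(sharpness-1)*n_top/n per rank right of the kink, and the
    # planted elbow position must survive the perturbation
    raw = raw + rng.uniform(-0.01, 0.01, size=n_regions)
    if region_ids is None:
        region_ids = [f"R{j:03d}" for j in range(n_regions)]
    order = rng.permutation(n_regions)
    values = pd.Series(raw, index=pd.Index(np.asarray(region_ids, dtype=object)[order]))
    values = values / values.max()
    return DensityVector(map_name=map_name, values=values)


@dataclass
class CohortSpec:
    """Study conditions for a synthetic cohort.

    Defaults emulate the reference sample: four groups (healthy controls and
    people with MS who are non-fatigued, mildly/moderately fatigued, or
    severely fatigued) of sizes 60/87/77/53, 224 regions over 8 networks,
    300 volumes, and covariate distributions matching the sample table.
    Planted switch rates differ by group, with the severe − HC difference of
    0.015 per region per transition mimicking the order of magnitude of the
    reported group effects.
    """

    n_per_group: dict = field(default_factory=lambda: {
        "HC": 60, "non-fatigued": 87, "mild/moderate": 77, "severe": 53})
    n_regions: int = 224
    n_volumes: int = 300
    n_rsn: int = 8
    window_width: int = 27
    switch_rate_by_group: dict = field(default_factory=lambda: {
        "HC": 0.008, "non-fatigued": 0.010,
        "mild/moderate": 0.015, "severe": 0.023})
    cohesive_fraction: float = 0.88
    wave_size: int = 3
    noise_sd: float = 0.5
    age_by_group: dict = field(default_factory=lambda: {
        "HC": (30.5, 8.3), "non-fatigued": (38.1, 9.0),
        "mild/moderate": (40.6, 11.3), "severe": (40.7, 11.1)})
    female_prop_by_group: dict = field(default_factory=lambda: {
        "HC": 0.57, "non-fatigued": 0.54,
        "mild/moderate": 0.53, "severe": 0.67})
    education_by_group: dict = field(default_factory=lambda: {
        "HC": (17.4, 3.0), "non-fatigued": (15.2, 3.3),
        "mild/moderate": (14.5, 3.6), "severe": (14.1, 3.3)})
    fsmc_ranges: dict = field(default_factory=lambda: {
        "HC": (20, 42), "non-fatigued": (20, 42),
        "mild/moderate": (43, 62), "severe": (63, 85)})
    seed: int = 0

    def validate(self) -> None:
        if self.n_volumes < self.window_width:
            raise ValueError("n_volumes must be >= the window width")
        for g, r in self.switch_rate_by_group.items():
            if not 0 <= r <= 1:
                raise ValueError(f"group {g!r}: switch rate {r} outside [0, 1]")
        lo_c, mid_c, hi_c = _FSMC_TOTAL_CUTS
        bands = {"HC": (0, lo_c - 1), "non-fatigued": (0, lo_c - 1),
                 "mild/moderate": (lo_c, hi_c - 1), "severe": (hi_c, 100)}
        for g, (lo, hi) in self.fsmc_ranges.items():
            blo, bhi = bands[g]
            if lo > hi or lo < blo or hi > bhi:
                raise ValueError(
                    f"group {g!r}: fsmc range [{lo}, {hi}] straddles the "
                    f"severity cut-offs (allowed [{blo}, {bhi}])")


@dataclass
class Cohort:
    """A generated cohort: tables, per-subject series, and ground truth."""

    spec: CohortSpec
    regions: pd.DataFrame
    participants: pd.DataFrame
    timeseries: dict          # subject_id -> (R, V) ndarray
    coverage: pd.DataFrame    # subjects × regions, fractions in [0, 1]
    truth: dict               # subject_id -> {"schedule": SwitchSchedule, ...}

    @property
    def n_windows(self) -> int:
        return self.spec.n_volumes - self.spec.window_width + 1

    def region_rsn(self) -> np.ndarray:
        return self.regions["rsn_label"].to_numpy(dtype=int)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Draw a full synthetic cohort from a :class:`CohortSpec`.

    Per subject: a switch schedule at the group's planted rate, the
    corresponding noisy time series, full (1.0) voxel coverage, and a
    participant row whose FSMC total falls inside the group's configured
    band (so downstream severity classification reproduces group
    membership).  The spec's seed fully determines the output.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    regions = make_region_table(spec.n_regions, spec.n_rsn)
    base = dict(zip(regions["region_id"], regions["rsn_label"].astype(int)))
    n_windows = spec.n_volumes - spec.window_width + 1

    rows, series, truth = [], {}, {}
    for group in GROUPS:
        n = spec.n_per_group.get(group, 0)
        rate = spec.switch_rate_by_group[group]
        age_mu, age_sd = spec.age_by_group[group]
        edu_mu, edu_sd = spec.education_by_group[group]
        f_lo, f_hi = spec.fsmc_ranges[group]
        for j in range(n):
            sid = f"{'hc' if group == 'HC' else 'ms'}-{group.replace('/', '')[:4]}-{j:03d}"
            sched = draw_schedule(base, n_windows, rate, rng,
                                  width=spec.window_width,
                                  cohesive_fraction=spec.cohesive_fraction,
                                  wave_size=spec.wave_size, n_rsn=spec.n_rsn)
            ts_seed = int(rng.integers(0, 2**31 - 1))
            series[sid] = generate_timeseries(sched, spec.n_volumes,
                                              spec.noise_sd, ts_seed)
            fsmc = int(rng.integers(f_lo, f_hi + 1))
            fsmc_cog = fsmc // 2
            rows.append({
                "subject_id": sid,
                "cohort": "HC" if group == "HC" else "pwMS",
                "group": group,
                "sex": "F" if rng.random() < spec.female_prop_by_group[group] else "M",
                "age": round(float(np.clip(rng.normal(age_mu, age_sd), 18, 80)), 1),
                "education_years": round(float(np.clip(rng.normal(edu_mu, edu_sd), 8, 25)), 1),
                "fsmc_total": fsmc,
                "fsmc_cognitive": fsmc_cog,
                "fsmc_motor": fsmc - fsmc_cog,
                "hads_a": int(rng.integers(0, 11)),
                "hads_d": int(rng.integers(0, 9)),
                "ms_type": ("NA" if group == "HC" else
                            ["CIS", "RRMS", "PMS"][rng.choice(3, p=[0.032, 0.894, 0.074])]),
            })
            truth[sid] = {"schedule": sched, "group": group, "nominal_rate": rate}

    participants = pd.DataFrame(rows)
    subject_ids = participants["subject_id"] if len(participants) else pd.Series([], dtype=object)
    coverage = pd.DataFrame(1.0, index=pd.Index(subject_ids, name="subject_id"),
                            columns=regions["region_id"])
    return Cohort(spec=spec, regions=regions, participants=participants,
                  timeseries=series, coverage=coverage, truth=truth)
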