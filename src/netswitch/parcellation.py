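"""Region bookkeeping, coverage-based quality control, and circuit delineation.

The parcellation combines cortical atlas regions with deep gray matter, each
carrying one of K resting-state-network (RSN) labels (reference
configuration: 210 cortical + 14 deep-gray, K = 8).  Quality control drops
participants with too many zero-coverage regions, then regions with poor
coverage across the retained participants.  Monoaminergic circuits are the
highest-density regions of each normalised receptor/transporter map, cut at
the elbow of the sorted density curve — or, when the curve is effectively
linear, at the top 5%.  Circuits with identical membership are reported
jointly (e.g. D2/DAT).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DensityVector",
    "CircuitSet",
    "ElbowResult",
    "validate_region_table",
    "exclude_participants",
    "exclude_regions",
    "normalize_density",
    "detect_elbow",
    "select_top_fraction",
    "build_circuits",
]

REGION_COLUMNS = ("region_id", "name", "source", "rsn_label")

#: max chord distance below this fraction of the value range ⇒ linear slope
LINEARITY_THRESHOLD = 0.02


@dataclass
class DensityVector:
    """Per-region normalised density for one receptor/transporter map."""

    map_name: str
    values: pd.Series  # index: region_id, values in [0, 1] with max 1

    def restrict(self, region_ids) -> "DensityVector":
        keep = self.values.index.intersection(pd.Index(region_ids))
        return DensityVector(self.map_name, self.values.loc[keep])


@dataclass
class CircuitSet:
    """Named circuits as ordered region-id lists.

    Maps that select identical member sets are merged into one circuit with
    a joint "/"-separated name; ``merged_from`` records the joins and
    ``provenance`` how each source map was cut (elbow rank or top-fraction
    fallback).
    """

    circuits: dict[str, list] = field(default_factory=dict)
    merged_from: dict[str, list[str]] = field(default_factory=dict)
    provenance: dict[str, dict] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.circuits)

    def members(self, name: str) -> list:
        return self.circuits[name]


@dataclass(frozen=True)
class ElbowResult:
    cutoff_rank: int          # 1-based, inclusive: last region kept
    is_linear: bool
    max_distance: float       # max perpendicular distance from the chord
    value_range: float


def validate_region_table(regions: pd.DataFrame) -> pd.DataFrame:
    """Check the region table contract: required columns, unique ids,
    one RSN label per region."""
    missing = [c for c in REGION_COLUMNS if c not in regions.columns]
    if missing:
        raise ValueError(f"region table lacks columns: {missing}")
    if regions["region_id"].duplicated().any():
        dup = regions.loc[regions["region_id"].duplicated(), "region_id"].iloc[0]
        raise ValueError(f"duplicate region_id: {dup!r}")
    if regions["rsn_label"].isna().any():
        raise ValueError("every region needs exactly one rsn_label")
    return regions


def _check_coverage(coverage: pd.DataFrame) -> pd.DataFrame:
    if coverage.isna().any().any():
        col = coverage.columns[coverage.isna().any()][0]
        row = coverage.index[coverage[col].isna()][0]
        raise ValueError(f"missing coverage entry for subject {row!r}, region {col!r}")
    arr = coverage.to_numpy(dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("coverage fractions must lie in [0, 1]")
    return coverage


def exclude_participants(coverage: pd.DataFrame,
                         zero_region_limit: int = 12):
    """Drop subjects with more than ``zero_region_limit`` zero-coverage regions.

    ``coverage`` is subjects × regions.  The rule is a strict '>': a subject
    with exactly ``zero_region_limit`` zero regions is retained.  Returns
    (retained subject ids, exclusion log DataFrame).
    """
    _check_coverage(coverage)
    n_zero = (coverage.to_numpy(dtype=float) == 0.0).sum(axis=1)
    excluded = n_zero > zero_region_limit
    log = pd.DataFrame({
        "subject_id": coverage.index[excluded],
        "n_zero_regions": n_zero[excluded],
        "reason": [f"> {zero_region_limit} regions with zero coverage"] * int(excluded.sum()),
    })
    return list(coverage.index[~excluded]), log


def exclude_regions(coverage: pd.DataFrame,
                    min_coverage: float = 0.30,
                    max_subject_fraction: float = 0.10):
    """Drop regions with coverage below ``min_coverage`` in more than
    ``max_subject_fraction`` of the (already participant-screened) subjects.

    Both comparisons are strict, mirroring the printed rule
    ("< 30% voxel coverage in > 10% of participants").  Returns
    (retained region ids, exclusion log DataFrame).
    """
    _check_coverage(coverage)
    if len(coverage.index) == 0:
        raise ValueError("no subjects left to evaluate region coverage")
    frac_poor = (coverage.to_numpy(dtype=float) < min_coverage).mean(axis=0)
    excluded = frac_poor > max_subject_fraction
    log = pd.DataFrame({
        "region_id": coverage.columns[excluded],
        "fraction_poor_coverage": frac_poor[excluded],
        "reason": [f"< {min_coverage:.0%} coverage in > "
                   f"{max_subject_fraction:.0%} of participants"] * int(excluded.sum()),
    })
    return list(coverage.columns[~excluded]), log


def normalize_density(raw: pd.Series | dict, map_name: str = "") -> DensityVector:
    """Divide densities by their maximum so the largest value is exactly 1."""
    values = pd.Series(raw, dtype=float)
    peak = values.max()
    if not np.isfinite(peak) or peak <= 0:
        raise ValueError("density normalisation needs at least one strictly "
                         "positive value")
    return DensityVector(map_name=map_name, values=values / peak)


def detect_elbow(density: DensityVector,
                 linearity_threshold: float = LINEARITY_THRESHOLD) -> ElbowResult:
    """Locate the elbow of the sorted (descending) density curve.

    The elbow is the point of maximum perpendicular distance from the chord
    joining the first and last sorted values (kneedle-style); the cut-off is
    the rank of the last region on the high side of that elbow.  The elbow
    point itself is kept when its value lies nearer the top of the curve
    than the bottom (a kink ending a steep high segment) and dropped when it
    lies nearer the bottom (the first point after a cliff).  When the
    maximum distance is below ``linearity_threshold`` × value range the
    curve is declared linear and the caller should fall back to a
    top-fraction selection.
    """
    y = np.sort(density.values.to_numpy(dtype=float))[::-1]
    n = y.size
    if n < 3:
        raise ValueError("elbow detection needs at least 3 regions")
    x = np.arange(n, dtype=float)
    # chord from (0, y[0]) to (n-1, y[-1]); perpendicular point-line distance
    dx, dy = n - 1.0, y[-1] - y[0]
    dist = np.abs(dy * x - dx * (y - y[0])) / math.hypot(dx, dy)
    j = int(np.argmax(dist))
    keep_elbow = abs(y[j] - y[0]) <= abs(y[j] - y[-1])
    rank = max(1, j + 1 if keep_elbow else j)
    value_range = float(y[0] - y[-1])
    max_dist = float(dist.max())
    is_linear = max_dist < linearity_threshold * value_range or value_range == 0.0
    return ElbowResult(cutoff_rank=rank, is_linear=is_linear,
                       max_distance=max_dist, value_range=value_range)


def _ranked_ids(density: DensityVector) -> list:
    """Region ids sorted by descending density, ties broken by region_id."""
    s = density.values
    order = sorted(s.index, key=lambda rid: (-s.loc[rid], rid))
    return order


def select_top_fraction(density: DensityVector, fraction: float = 0.05) -> list:
    """The ceil(fraction × n) highest-density regions (ties by region_id).

    ceil rounding reproduces the reference count: top 5% of 224 regions
    is ceil(11.2) = 12.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    k = math.ceil(fraction * len(density.values))
    return _ranked_ids(density)[:k]


def build_circuits(densities: list[DensityVector],
                   retained_regions,
                   fraction: float = 0.05,
                   linearity_threshold: float = LINEARITY_THRESHOLD) -> CircuitSet:
    """Delineate one circuit per density map and merge identical member sets.

    Each map is first restricted to the QC-retained regions, then cut at the
    elbow of its sorted curve, or at the top ``fraction`` when the curve is
    linear.  Maps selecting exactly the same regions are merged into one
    jointly named circuit ("D2/DAT"-style).
    """
    retained = pd.Index(retained_regions)
    cut: dict[str, tuple[tuple, dict]] = {}
    for dv in densities:
        sub = dv.restrict(retained)
        if sub.values.empty:
            raise ValueError(f"map {dv.map_name!r}: no retained regions")
        elbow = detect_elbow(sub, linearity_threshold)
        if elbow.is_linear:
            members = select_top_fraction(sub, fraction)
            prov = {"rule": "top-fraction", "fraction": fraction,
                    "n_selected": len(members)}
        else:
            members = _ranked_ids(sub)[: elbow.cutoff_rank]
            prov = {"rule": "elbow", "cutoff_rank": elbow.cutoff_rank,
                    "max_distance": elbow.max_distance}
        if not members:
            raise ValueError(f"map {dv.map_name!r}: empty circuit after selection")
        cut[dv.map_name] = (tuple(sorted(members, key=str)), prov)

    out = CircuitSet()
    grouped: dict[tuple, list[str]] = {}
    for name, (members, _) in cut.items():
        grouped.setdefault(members, []).append(name)
    for members, names in grouped.items():
        joint = "/".join(names)
        # keep density-ranked order of the first contributing map
        first = names[0]
        ranked = [rid for rid in _ranked_ids(densities_by_name(densities)[first].restrict(retained))
                  if rid in set(members)]
        out.circuits[joint] = ranked
        if len(names) > 1:
            out.merged_from[joint] = list(names)
        out.provenance[joint] = {n: cut[n][1] for n in names}
    return out


def densities_by_name(densities: list[DensityVector]) -> dict[str, DensityVector]:
    return {dv.map_name: dv for dv in densities}
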