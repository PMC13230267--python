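"""Window-wise RSN allegiance and the four reconfiguration statistics.

A region's *allegiance* in a time window is the resting-state network (RSN)
to which it is most strongly connected in that window's FC matrix, with RSN
membership fixed by the parcellation.  Over the sequence of windows, four
per-region statistics summarise how allegiance changes:

* **flexibility** — fraction of window transitions at which the region
  switches RSN;
* **promiscuity** — fraction of the K RSNs the region is assigned to at
  least once;
* **cohesion** — fraction of transitions at which the region switches
  together with at least one other region to the same destination RSN;
* **disjointedness** — fraction of transitions at which it switches alone.

Per region, flexibility = cohesion + disjointedness exactly: every switch is
either cohesive (shared destination at the same transition) or disjoint.
Circuit and global values are unweighted means over member regions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .connectivity import FCMatrix
from .parcellation import CircuitSet

__all__ = [
    "AllegianceMatrix",
    "ReconfigProfile",
    "assign_allegiance",
    "flexibility",
    "promiscuity",
    "classify_switches",
    "cohesion_disjointedness",
    "aggregate",
    "SWITCH_NONE",
    "SWITCH_COHESIVE",
    "SWITCH_DISJOINT",
]

SWITCH_NONE = 0
SWITCH_COHESIVE = 1
SWITCH_DISJOINT = 2


@dataclass
class AllegianceMatrix:
    """Region-by-window integer RSN labels (1..K)."""

    labels: np.ndarray          # (R, W) int
    region_ids: list            # length R
    k_total: int = 8

    @property
    def n_windows(self) -> int:
        return self.labels.shape[1]

    @property
    def n_regions(self) -> int:
        return self.labels.shape[0]


@dataclass
class ReconfigProfile:
    """Per-region metrics plus circuit and global unweighted means.

    ``regions`` is indexed by region_id with columns flexibility,
    promiscuity, cohesion, disjointedness; ``circuits`` is indexed by
    circuit name (plus a ``global`` row) with the same columns.
    """

    regions: pd.DataFrame
    circuits: pd.DataFrame


def _as_stack(windowed) -> np.ndarray:
    if isinstance(windowed, np.ndarray):
        if windowed.ndim != 3:
            raise ValueError("windowed FC stack must be 3-D (windows, R, R)")
        return windowed
    return np.stack([fc.values if isinstance(fc, FCMatrix) else np.asarray(fc)
                     for fc in windowed])


def assign_allegiance(windowed, region_rsn: np.ndarray,
                      region_ids=None, k_total: int | None = None) -> AllegianceMatrix:
    """Assign each region, in each window, to its best-connected RSN.

    Parameters
    ----------
    windowed:
        List of window FC matrices, or a (W, R, R) stack.
    region_rsn:
        Integer RSN label (1..K) per region, aligned with the FC rows.
        Labels are the fixed parcellation, not a per-window community
        detection.

    For region *i* and window *w* the score of RSN *k* is the mean windowed
    FC between *i* and all members of *k* excluding *i* itself; the label is
    the argmax.  Ties keep the previous window's label when it is among the
    tied maxima, else the lowest label index — this avoids spurious switch
    counts from exact ties and is deterministic.
    """
    stack = _as_stack(windowed)
    W, R, _ = stack.shape
    rsn = np.asarray(region_rsn, dtype=int)
    if rsn.shape != (R,):
        raise ValueError("need one RSN label per region")
    K = int(k_total) if k_total is not None else int(rsn.max())
    if rsn.min() < 1 or rsn.max() > K:
        raise ValueError("RSN labels must lie in 1..K")
    sizes = np.bincount(rsn, minlength=K + 1)[1:]  # members per RSN
    own_short = sizes[rsn - 1] < 2
    if own_short.any():
        bad = int(np.flatnonzero(own_short)[0])
        raise ValueError(
            f"region index {bad}: its own RSN {rsn[bad]} has a single member, "
            "so no other-member connectivity exists")

    onehot = np.zeros((R, K))
    onehot[np.arange(R), rsn - 1] = 1.0
    sums = stack @ onehot                        # (W, R, K); diagonal is 0
    counts = sizes[None, :] - onehot             # (R, K), excludes self
    with np.errstate(divide="ignore", invalid="ignore"):
        means = sums / counts[None, :, :]
    means[:, counts == 0] = -np.inf              # foreign singleton-free RSNs never chosen
    # means[w, i, k]: mean FC of region i to RSN k+1 in window w

    labels = np.empty((R, W), dtype=int)
    best = means.max(axis=2)                     # (W, R)
    tied = means >= best[:, :, None]             # exact-tie mask
    labels[:, 0] = np.argmax(tied[0], axis=1) + 1
    for w in range(1, W):
        prev = labels[:, w - 1]
        keep = tied[w, np.arange(R), prev - 1]
        lab = np.argmax(tied[w], axis=1) + 1
        lab[keep] = prev[keep]
        labels[:, w] = lab
    if region_ids is None:
        region_ids = list(range(R))
    return AllegianceMatrix(labels=labels, region_ids=list(region_ids), k_total=K)


def _labels_of(labels) -> np.ndarray:
    arr = labels.labels if isinstance(labels, AllegianceMatrix) else np.asarray(labels)
    if arr.ndim != 2:
        raise ValueError("allegiance labels must be region × window")
    return arr


def flexibility(labels) -> np.ndarray:
    """Per-region fraction of the W−1 transitions with an RSN switch."""
    arr = _labels_of(labels)
    if arr.shape[1] < 2:
        raise ValueError("flexibility needs at least 2 windows")
    return (arr[:, 1:] != arr[:, :-1]).mean(axis=1)


def promiscuity(labels, k_total: int | None = None) -> np.ndarray:
    """Per-region fraction of the K RSNs visited at least once."""
    arr = _labels_of(labels)
    if k_total is None:
        k_total = labels.k_total if isinstance(labels, AllegianceMatrix) else int(arr.max())
    if k_total < arr.max():
        raise ValueError("k_total smaller than the largest observed label")
    R = arr.shape[0]
    distinct = np.array([np.unique(arr[i]).size for i in range(R)], dtype=float)
    return distinct / k_total


def classify_switches(labels) -> np.ndarray:
    """Per (region, transition) switch class: none / cohesive / disjoint.

    A switch at transition t is *cohesive* iff at least one other region
    also switches at t to the same destination label (source labels are
    irrelevant); a lone mover, or movers sharing a transition but not a
    destination, are *disjoint*.
    """
    arr = _labels_of(labels)
    if arr.shape[1] < 2:
        raise ValueError("switch classification needs at least 2 windows")
    R, W = arr.shape
    switched = arr[:, 1:] != arr[:, :-1]         # (R, W-1)
    dest = arr[:, 1:]
    out = np.full((R, W - 1), SWITCH_NONE, dtype=int)
    K = int(arr.max())
    for t in range(W - 1):
        movers = np.flatnonzero(switched[:, t])
        if movers.size == 0:
            continue
        counts = np.bincount(dest[movers, t], minlength=K + 1)
        shared = counts[dest[movers, t]] >= 2
        out[movers, t] = np.where(shared, SWITCH_COHESIVE, SWITCH_DISJOINT)
    return out


def cohesion_disjointedness(labels) -> tuple[np.ndarray, np.ndarray]:
    """Per-region (cohesion, disjointedness) fractions of the W−1 transitions.

    Their sum equals flexibility exactly for every region.
    """
    classes = classify_switches(labels)
    n_trans = classes.shape[1]
    coh = (classes == SWITCH_COHESIVE).sum(axis=1) / n_trans
    dis = (classes == SWITCH_DISJOINT).sum(axis=1) / n_trans
    return coh, dis


def aggregate(labels, circuits: CircuitSet | dict | None = None,
              retained_regions=None, k_total: int | None = None) -> ReconfigProfile:
    """All four region-level metrics plus circuit and global means.

    Circuit values are unweighted means over member regions; ``global`` is
    the unweighted mean over all retained regions (every row of the
    allegiance matrix by default).
    """
    arr = _labels_of(labels)
    ids = (labels.region_ids if isinstance(labels, AllegianceMatrix)
           else list(range(arr.shape[0])))
    flex = flexibility(labels)
    prom = promiscuity(labels, k_total=k_total)
    coh, dis = cohesion_disjointedness(labels)
    regions = pd.DataFrame(
        {"flexibility": flex, "promiscuity": prom,
         "cohesion": coh, "disjointedness": dis},
        index=pd.Index(ids, name="region_id"))

    if retained_regions is not None:
        keep = [rid for rid in ids if rid in set(retained_regions)]
        regions_kept = regions.loc[keep]
    else:
        regions_kept = regions

    circuit_map = circuits.circuits if isinstance(circuits, CircuitSet) else (circuits or {})
    rows = {}
    for name, members in circuit_map.items():
        missing = [m for m in members if m not in regions_kept.index]
        if missing or not members:
            raise ValueError(f"circuit {name!r}: empty or with regions outside "
                             f"the retained set: {missing}")
        rows[name] = regions_kept.loc[list(members)].mean()
    rows["global"] = regions_kept.mean()
    circuits_df = pd.DataFrame(rows).T
    circuits_df.index.name = "unit"
    return ReconfigProfile(regions=regions, circuits=circuits_df)
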