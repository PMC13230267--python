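"""Static and sliding-window functional connectivity.

Functional connectivity (FC) between two brain regions is the Pearson
correlation of their BOLD time series.  The static chain applies, in order,
Fisher r-to-z (arctanh, with |r| clipped just below 1 to stay finite), the
absolute value, and division by the off-diagonal maximum, producing a
symmetric matrix with off-diagonal entries in [0, 1] and maximum exactly 1.
The windowed chain applies the same transforms per overlapping window but
skips the max-normalisation: downstream allegiance assignment takes an
argmax of mean connectivity and is invariant to a global positive scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "FCMatrix",
    "WindowPlan",
    "make_windows",
    "static_fc",
    "windowed_fc",
    "windowed_fc_stack",
    "within_circuit_fc",
]

#: correlations are clipped to this magnitude before arctanh
R_CLIP = 1.0 - 1e-7


@dataclass
class FCMatrix:
    """A region-by-region symmetric connectivity matrix.

    The diagonal carries no information (self-connectivity is excluded from
    every summary) and is set to zero.  ``transform_log`` records the chain
    of transforms applied after the raw Pearson correlation.
    """

    values: np.ndarray
    kind: str = "static"  # "static" or "windowed"
    transform_log: list[str] = field(default_factory=list)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class WindowPlan:
    """Overlapping rectangular windows over a volume axis.

    Windows are half-open ``[start, start + width)`` intervals of volume
    indices at stride ``step``; their count is
    ``floor((n_volumes - width) / step) + 1``.
    """

    n_volumes: int
    width: int = 27
    step: int = 1

    @property
    def windows(self) -> list[tuple[int, int]]:
        return [(s, s + self.width) for s in
                range(0, self.n_volumes - self.width + 1, self.step)]

    @property
    def n_windows(self) -> int:
        return (self.n_volumes - self.width) // self.step + 1


def make_windows(n_volumes: int, width: int = 27, step: int = 1) -> WindowPlan:
    """Build a :class:`WindowPlan`; e.g. 300 volumes at width 27, step 1
    yield 274 windows."""
    if width > n_volumes:
        raise ValueError(
            f"window width {width} exceeds the {n_volumes} available volumes")
    if step < 1:
        raise ValueError("step must be >= 1")
    if width < 2:
        raise ValueError("window width must be >= 2")
    return WindowPlan(n_volumes=n_volumes, width=width, step=step)


def _check_timeseries(ts: np.ndarray) -> np.ndarray:
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValueError("time series must be a 2-D region-by-volume matrix")
    return ts


def static_fc(timeseries: np.ndarray) -> FCMatrix:
    """Whole-series FC with the full static transform chain.

    Pearson correlation over all volumes, then clipped arctanh, absolute
    value, and division by the off-diagonal maximum.  Raises if any region
    has zero variance (its correlation is undefined).
    """
    ts = _check_timeseries(timeseries)
    if ts.shape[1] < 3:
        raise ValueError("static FC needs at least 3 volumes")
    sd = ts.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"region {bad} has zero variance over the series")
    r = np.corrcoef(ts)
    z = np.abs(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))
    np.fill_diagonal(z, 0.0)
    peak = z.max()
    if peak > 0:
        z = z / peak
    np.fill_diagonal(z, 0.0)
    return FCMatrix(values=z, kind="static",
                    transform_log=["pearson", "arctanh(clip 1-1e-7)",
                                   "abs", "max-normalise (off-diagonal)"])


def windowed_fc_stack(timeseries: np.ndarray, plan: WindowPlan) -> np.ndarray:
    """Windowed FC as a (n_windows, R, R) array: per window, Pearson r
    followed by clipped arctanh and absolute value (no max-normalisation).

    Vectorised across windows; raises if a region is constant within any
    window.
    """
    ts = _check_timeseries(timeseries)
    if plan.n_volumes != ts.shape[1]:
        raise ValueError("window plan built for a different number of volumes")
    # view: (n_starts, R, width), subsampled at the plan's stride
    win = sliding_window_view(ts, plan.width, axis=1)  # (R, n_starts, width)
    win = win.transpose(1, 0, 2)[:: plan.step]
    mean = win.mean(axis=2, keepdims=True)
    centred = win - mean
    ss = np.einsum("wrt,wrt->wr", centred, centred)
    if np.any(ss == 0):
        w, r0 = map(int, np.argwhere(ss == 0)[0])
        raise ValueError(f"region {r0} is constant within window {w}")
    cov = np.einsum("wrt,wst->wrs", centred, centred)
    denom = np.sqrt(ss[:, :, None] * ss[:, None, :])
    r = cov / denom
    z = np.abs(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))
    idx = np.arange(z.shape[1])
    z[:, idx, idx] = 0.0
    return z


def windowed_fc(timeseries: np.ndarray, plan: WindowPlan) -> list[FCMatrix]:
    """Per-window FC matrices (views into one contiguous stack)."""
    stack = windowed_fc_stack(timeseries, plan)
    log = ["pearson", "arctanh(clip 1-1e-7)", "abs"]
    return [FCMatrix(values=stack[w], kind="windowed", transform_log=list(log))
            for w in range(stack.shape[0])]


def within_circuit_fc(fc: FCMatrix | np.ndarray, circuit: np.ndarray) -> float:
    """Mean connectivity over a circuit's unordered off-diagonal pairs.

    ``circuit`` holds integer row/column indices into the FC matrix; each of
    the C(n, 2) pairs is counted once.
    """
    values = fc.values if isinstance(fc, FCMatrix) else np.asarray(fc)
    idx = np.asarray(circuit, dtype=int)
    if idx.size < 2:
        raise ValueError("circuit must map to at least 2 regions in the matrix")
    sub = values[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].mean())
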