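"""Plain-text readers and writers for the pipeline's tables.

All formats are delimited text: per-subject time-series matrices (rows =
regions, first column the region id, header row of volume indices),
`participants.tsv`, `coverage.tsv`, `regions.tsv`, per-map density tables,
`circuits.json`, and `truth.json` holding the planted schedules of a
synthetic cohort.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .parcellation import CircuitSet, DensityVector
from .synthetic import Cohort, SwitchSchedule

__all__ = [
    "write_timeseries", "read_timeseries",
    "write_cohort", "read_regions", "read_participants", "read_coverage",
    "read_density", "write_density",
    "write_circuits", "read_circuits",
    "write_truth", "read_truth",
]


def write_timeseries(path, matrix: np.ndarray, region_ids) -> None:
    df = pd.DataFrame(matrix, index=pd.Index(region_ids, name="region_id"),
                      columns=[str(v) for v in range(matrix.shape[1])])
    df.to_csv(path, sep="\t", float_format="%.6f")


def read_timeseries(path):
    """Returns (region_ids, region-by-volume matrix)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return list(df.index), df.to_numpy(dtype=float)


def read_regions(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_participants(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_coverage(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_density(path, density: DensityVector) -> None:
    density.values.rename("density").rename_axis("region_id").to_csv(path, sep="\t")


def read_density(path, map_name: str) -> DensityVector:
    s = pd.read_csv(path, sep="\t", index_col=0)["density"]
    return DensityVector(map_name=map_name, values=s)


def write_circuits(path, circuits: CircuitSet) -> None:
    payload = {
        "circuits": {k: list(v) for k, v in circuits.circuits.items()},
        "merged_from": circuits.merged_from,
        "provenance": circuits.provenance,
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_circuits(path) -> CircuitSet:
    payload = json.loads(Path(path).read_text())
    return CircuitSet(circuits=payload["circuits"],
                      merged_from=payload.get("merged_from", {}),
                      provenance=payload.get("provenance", {}))


def _schedule_to_json(s: SwitchSchedule) -> dict:
    return {
        "n_windows": s.n_windows,
        "width": s.width,
        "base_allegiance": {str(k): int(v) for k, v in s.base_allegiance.items()},
        "transitions": [
            {"t": int(t), "regions": sorted(map(str, members)),
             "dest": int(dest), "mode": mode}
            for t, members, dest, mode in sorted(s.transitions, key=lambda tr: tr[0])
        ],
    }


def _schedule_from_json(d: dict) -> SwitchSchedule:
    return SwitchSchedule(
        transitions=[(tr["t"], frozenset(tr["regions"]), tr["dest"], tr["mode"])
                     for tr in d["transitions"]],
        base_allegiance=d["base_allegiance"],
        n_windows=d["n_windows"], width=d["width"])


def write_truth(path, truth: dict) -> None:
    payload = {
        sid: {"group": rec["group"], "nominal_rate": rec["nominal_rate"],
              "schedule": _schedule_to_json(rec["schedule"])}
        for sid, rec in truth.items()
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth(path) -> dict:
    payload = json.loads(Path(path).read_text())
    return {sid: {"group": rec["group"], "nominal_rate": rec["nominal_rate"],
                  "schedule": _schedule_from_json(rec["schedule"])}
            for sid, rec in payload.items()}


def write_cohort(cohort: Cohort, out_dir) -> Path:
    """Write a synthetic cohort as the pipeline's on-disk layout."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.regions.to_csv(out / "regions.tsv", sep="\t", index=False)
    cohort.participants.to_csv(out / "participants.tsv", sep="\t", index=False)
    cohort.coverage.to_csv(out / "coverage.tsv", sep="\t")
    for sid, ts in cohort.timeseries.items():
        write_timeseries(out / f"timeseries_{sid}.tsv", ts,
                         cohort.regions["region_id"])
    write_truth(out / "truth.json", cohort.truth)
    return out
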