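"""End-to-end glue: cohort → windowed FC → allegiance → metrics → statistics.

These helpers wire the modules together the way the analysis is meant to be
run: per subject, windowed FC matrices feed allegiance assignment, the four
reconfiguration metrics are averaged per circuit and globally, and the
resulting subject-by-outcome table goes into the covariate-adjusted group
comparison.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .connectivity import make_windows, static_fc, windowed_fc_stack, within_circuit_fc
from .parcellation import CircuitSet
from .reconfiguration import aggregate, assign_allegiance
from .stats import AnalysisPlan, default_plan, run_plan
from .synthetic import Cohort

__all__ = [
    "subject_allegiance",
    "subject_profile",
    "cohort_metrics",
    "cohort_static_fc",
    "analyze_cohort",
]


def subject_allegiance(timeseries: np.ndarray, region_rsn, region_ids=None,
                       width: int = 27, step: int = 1, k_total: int | None = None):
    """Windowed FC and allegiance assignment for one subject's series."""
    plan = make_windows(timeseries.shape[1], width=width, step=step)
    stack = windowed_fc_stack(timeseries, plan)
    return assign_allegiance(stack, region_rsn, region_ids=region_ids,
                             k_total=k_total)


def subject_profile(timeseries: np.ndarray, region_rsn, region_ids=None,
                    circuits: CircuitSet | dict | None = None,
                    width: int = 27, step: int = 1,
                    k_total: int | None = None):
    """Region/circuit/global reconfiguration metrics for one subject."""
    labels = subject_allegiance(timeseries, region_rsn, region_ids=region_ids,
                                width=width, step=step, k_total=k_total)
    return aggregate(labels, circuits=circuits, k_total=k_total)


def cohort_metrics(cohort: Cohort,
                   circuits: CircuitSet | dict | None = None,
                   step: int = 1) -> pd.DataFrame:
    """Subjects × outcome columns ("flexibility[global]", ...) for every
    unit (each circuit plus "global") and metric."""
    rsn = cohort.region_rsn()
    ids = list(cohort.regions["region_id"])
    rows = {}
    for sid, ts in cohort.timeseries.items():
        prof = subject_profile(ts, rsn, region_ids=ids, circuits=circuits,
                               width=cohort.spec.window_width, step=step,
                               k_total=cohort.spec.n_rsn)
        row = {}
        for unit, vals in prof.circuits.iterrows():
            for metric in ("flexibility", "promiscuity",
                           "cohesion", "disjointedness"):
                row[f"{metric}[{unit}]"] = vals[metric]
        rows[sid] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subject_id"
    return out


def cohort_static_fc(cohort: Cohort, circuits: CircuitSet | dict) -> pd.DataFrame:
    """Within-circuit static FC per subject ("static_fc[<circuit>]" columns)."""
    ids = list(cohort.regions["region_id"])
    pos = {rid: i for i, rid in enumerate(ids)}
    circuit_map = circuits.circuits if isinstance(circuits, CircuitSet) else circuits
    rows = {}
    for sid, ts in cohort.timeseries.items():
        fc = static_fc(ts)
        rows[sid] = {f"static_fc[{name}]":
                     within_circuit_fc(fc, [pos[r] for r in members])
                     for name, members in circuit_map.items()}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "subject_id"
    return out


def analyze_cohort(cohort: Cohort,
                   circuits: CircuitSet | dict | None = None,
                   plan: AnalysisPlan | None = None,
                   step: int = 1) -> pd.DataFrame:
    """Full run: metrics, then per-family ANCOVA + BH with the flexibility
    gate, using the cohort's own group labels and covariates."""
    metrics = cohort_metrics(cohort, circuits=circuits, step=step)
    parts = cohort.participants.set_index("subject_id").loc[metrics.index]
    if plan is None:
        units = (list(circuits.circuits) if isinstance(circuits, CircuitSet)
                 else list(circuits) if circuits else [])
        plan = default_plan(units + ["global"])
    covs = parts[["sex", "age", "education_years"]].reset_index(drop=True)
    return run_plan(metrics.reset_index(drop=True),
                    parts["group"].reset_index(drop=True), covs, plan)
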