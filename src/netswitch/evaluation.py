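"""Parameter-recovery and calibration experiments on synthetic cohorts.

These are the package's own quality checks, run both by the test suite and
by the acceptance script: does the windowed argmax pipeline recover planted
switch rates, does the planted group effect come out of the ANCOVA, and is
the ANCOVA calibrated under a null?

Switch-rate recovery compares boundary-corrected estimates with the
realised planted schedule.  Because a switch is spread over a window width
of straddling windows, the corrected estimator counts label changes on the
interior-window subsequence of each region (transitions inside a straddle
zone are excluded; the change across the zone counts once).  The same
count applied to the ground-truth labels gives the observable planted
switches — events too close to the end of the run have no fully-interior
post-switch window and are not observable by any windowed estimator.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pipeline import subject_allegiance
from .stats import ancova
from .synthetic import CohortSpec, generate_cohort

__all__ = [
    "interior_switch_rate",
    "recovery_study",
    "power_study",
    "null_calibration",
]


def interior_switch_rate(labels: np.ndarray, interior: np.ndarray) -> float:
    """Mean per-region switch fraction counted on interior windows only,
    on the all-transitions denominator (W − 1)."""
    R, W = labels.shape
    count = 0
    for row, mask in zip(labels, interior):
        seq = row[mask]
        count += int((seq[1:] != seq[:-1]).sum())
    return count / (R * (W - 1))


def recovery_study(n_subjects: int = 20, rate: float = 0.023,
                   n_regions: int = 224, n_volumes: int = 300,
                   noise_sd: float = 0.5, seed: int = 0) -> dict:
    """Estimate planted switch rates from one single-group cohort.

    Returns the cohort means of the boundary-corrected estimate, the
    observable planted rate, the raw (chatter-inclusive) estimate, and the
    Monte-Carlo standard error of the estimate over subjects.
    """
    spec = CohortSpec(
        n_per_group={"HC": 0, "non-fatigued": 0, "mild/moderate": 0,
                     "severe": n_subjects},
        n_regions=n_regions, n_volumes=n_volumes, noise_sd=noise_sd,
        switch_rate_by_group={"HC": 0.0, "non-fatigued": 0.0,
                              "mild/moderate": 0.0, "severe": rate},
        seed=seed)
    cohort = generate_cohort(spec)
    rsn = cohort.region_rsn()
    ids = list(cohort.regions["region_id"])
    est, planted, raw = [], [], []
    for sid, ts in cohort.timeseries.items():
        sched = cohort.truth[sid]["schedule"]
        am = subject_allegiance(ts, rsn, region_ids=ids,
                                width=spec.window_width)
        interior = sched.interior_mask()
        est.append(interior_switch_rate(am.labels, interior))
        planted.append(interior_switch_rate(sched.window_allegiance(), interior))
        raw.append(float((am.labels[:, 1:] != am.labels[:, :-1]).mean()))
    est, planted = np.asarray(est), np.asarray(planted)
    return {
        "estimated_mean": float(est.mean()),
        "planted_mean": float(planted.mean()),
        "raw_mean": float(np.mean(raw)),
        "mc_se": float(est.std(ddof=1) / np.sqrt(n_subjects)),
        "n_subjects": n_subjects,
    }


def _two_group_spec(n_per_group: int, n_regions: int, seed: int) -> CohortSpec:
    return CohortSpec(
        n_per_group={"HC": n_per_group, "non-fatigued": 0,
                     "mild/moderate": 0, "severe": n_per_group},
        n_regions=n_regions, n_volumes=300, seed=seed)


def power_study(n_replicates: int = 200, n_per_group: int = 10,
                n_regions: int = 40, seed_base: int = 1) -> dict:
    """Replicate HC-vs-severe cohorts at the default planted effect and
    count how often the planted ordering and the ANCOVA contrast come out.

    Per replicate: generate a two-group cohort, estimate global flexibility
    per subject through the full windowed pipeline, fit the
    sex/age/education-adjusted ANCOVA, and record (a) whether the severe
    group's mean estimated flexibility exceeds the HC mean and (b) whether
    the severe-vs-HC contrast is significant at 0.05.
    """
    from .pipeline import cohort_metrics

    ordered = 0
    significant = 0
    for rep in range(n_replicates):
        cohort = generate_cohort(
            _two_group_spec(n_per_group, n_regions, seed=seed_base + rep))
        metrics = cohort_metrics(cohort)
        parts = cohort.participants.set_index("subject_id").loc[metrics.index]
        flex = metrics["flexibility[global]"]
        groups = parts["group"]
        ordered += (flex[groups == "severe"].mean() >
                    flex[groups == "HC"].mean())
        res = ancova(flex.reset_index(drop=True),
                     groups.reset_index(drop=True),
                     parts[["sex", "age", "education_years"]].reset_index(drop=True),
                     name="flexibility[global]")
        con = res.contrasts.iloc[0]
        significant += (con["p"] < 0.05)
    return {
        "n_replicates": n_replicates,
        "ordering_fraction": ordered / n_replicates,
        "significant_fraction": significant / n_replicates,
    }


def null_calibration(n_sims: int = 1000, n_per_group: int = 12,
                     seed: int = 0, alpha: float = 0.05) -> dict:
    """Type-I-error rate of the ANCOVA group test under a planted null.

    All four groups share one outcome distribution; covariates are drawn
    independently of the outcome.  The rejection rate at ``alpha`` should
    fall inside the binomial sampling band around ``alpha``.
    """
    rng = np.random.default_rng(seed)
    groups = pd.Series(sum(([g] * n_per_group for g in
                            ("HC", "non-fatigued", "mild/moderate", "severe")),
                           []))
    n = len(groups)
    rejections = 0
    for _ in range(n_sims):
        cov = pd.DataFrame({
            "sex": rng.choice(["F", "M"], size=n),
            "age": rng.normal(40, 10, size=n),
            "education_years": rng.normal(15, 3, size=n),
        })
        while cov["sex"].nunique() < 2:
            cov["sex"] = rng.choice(["F", "M"], size=n)
        y = pd.Series(rng.normal(size=n))
        res = ancova(y, groups, cov)
        rejections += (res.p_uncorrected < alpha)
    return {"n_sims": n_sims, "rejection_rate": rejections / n_sims,
            "alpha": alpha}
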