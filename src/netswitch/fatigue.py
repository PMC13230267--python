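"""Participant screening and fatigue-severity grouping.

Fatigue is measured with the FSMC (Fatigue Scale for Motor and Cognitive
Functions; total score up to 100, with cognitive and motor subscales).
Severity cut-offs are scheme-specific and inclusive (">="):

==========  =====  =========  ======
scheme      mild   moderate   severe
==========  =====  =========  ======
total         43      53        63
cognitive     22      28        34
motor         22      27        32
==========  =====  =========  ======

For group analysis, mild and moderate are merged.  Screening removes any
participant with clinically relevant depression (HADS-D >= 11) and any
healthy control reporting at least mild fatigue.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd

__all__ = [
    "CUTOFFS",
    "GroupLabel",
    "screen_participants",
    "classify_fatigue",
    "assign_groups",
    "group_table",
    "subset_rrms",
]

CUTOFFS = {
    "total": (43, 53, 63),
    "cognitive": (22, 28, 34),
    "motor": (22, 27, 32),
}

HADS_D_EXCLUSION = 11

_REQUIRED = ("subject_id", "cohort", "fsmc_total", "hads_d")


@dataclass(frozen=True)
class GroupLabel:
    scheme: str
    label: str            # none / mild / moderate / severe
    analysis_label: str   # non-fatigued / mild/moderate / severe


def classify_fatigue(score: float, scheme: str = "total") -> GroupLabel:
    """Four-level severity label from a scale score, by inclusive cut-offs."""
    if scheme not in CUTOFFS:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {list(CUTOFFS)}")
    if score < 0:
        raise ValueError("FSMC scores are non-negative")
    if scheme == "total" and score > 100:
        raise ValueError("FSMC total has a maximum score of 100")
    mild, moderate, severe = CUTOFFS[scheme]
    if score >= severe:
        label = "severe"
    elif score >= moderate:
        label = "moderate"
    elif score >= mild:
        label = "mild"
    else:
        label = "none"
    analysis = {"none": "non-fatigued", "mild": "mild/moderate",
                "moderate": "mild/moderate", "severe": "severe"}[label]
    return GroupLabel(scheme=scheme, label=label, analysis_label=analysis)


def screen_participants(records: pd.DataFrame):
    """Apply the depression and HC-fatigue exclusion rules.

    Drops records with HADS-D >= 11 (clinically relevant depression), HC
    with FSMC total >= 43 (any reported fatigue), and records with missing
    screening scores.  Returns (retained records, exclusion log).
    """
    missing = [c for c in _REQUIRED if c not in records.columns]
    if missing:
        raise ValueError(f"participant table lacks columns: {missing}")
    reasons = []
    keep_idx = []
    for idx, row in records.iterrows():
        if pd.isna(row["hads_d"]) or pd.isna(row["fsmc_total"]):
            reasons.append((row["subject_id"], "incomplete screening scores"))
        elif row["hads_d"] >= HADS_D_EXCLUSION:
            reasons.append((row["subject_id"],
                            f"HADS-D {row['hads_d']:g} >= {HADS_D_EXCLUSION}"))
        elif row["cohort"] == "HC" and row["fsmc_total"] >= CUTOFFS["total"][0]:
            reasons.append((row["subject_id"],
                            f"HC reporting fatigue (FSMC {row['fsmc_total']:g})"))
        else:
            keep_idx.append(idx)
    log = pd.DataFrame(reasons, columns=["subject_id", "reason"])
    return records.loc[keep_idx].copy(), log


def assign_groups(records: pd.DataFrame, scheme: str = "total") -> pd.DataFrame:
    """Add a ``group`` column: "HC" for controls, the analysis-level fatigue
    label for pwMS (classified from the scheme's FSMC column)."""
    col = {"total": "fsmc_total", "cognitive": "fsmc_cognitive",
           "motor": "fsmc_motor"}[scheme]
    if col not in records.columns:
        raise ValueError(f"participant table lacks column {col!r}")
    out = records.copy()
    out["group"] = [
        "HC" if row["cohort"] == "HC"
        else classify_fatigue(row[col], scheme).analysis_label
        for _, row in records.iterrows()]
    return out


def _round1(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def group_table(records: pd.DataFrame, scheme: str = "total") -> pd.DataFrame:
    """Counts and percentages of pwMS per fatigue group.

    Percentages are 100 × count / total pwMS, rounded half-up to one
    decimal (87 of 217 -> 40.1).
    """
    if len(records) == 0:
        raise ValueError("empty participant table")
    classified = assign_groups(records, scheme)
    pwms = classified[classified["cohort"] == "pwMS"]
    total = len(pwms)
    if total == 0:
        raise ValueError("no pwMS records to tabulate")
    rows = []
    for label in ("non-fatigued", "mild/moderate", "severe"):
        n = int((pwms["group"] == label).sum())
        rows.append({"scheme": scheme, "group": label, "n": n,
                     "percent": _round1(100.0 * n / total)})
    return pd.DataFrame(rows)


def subset_rrms(records: pd.DataFrame) -> pd.DataFrame:
    """Sensitivity subset: healthy controls plus relapsing–remitting pwMS."""
    if "ms_type" not in records.columns:
        raise ValueError("participant table lacks column 'ms_type'")
    keep = (records["cohort"] == "HC") | (records["ms_type"] == "RRMS")
    return records.loc[keep].copy()
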