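"""Covariate-adjusted group comparison with per-family FDR control.

Every outcome (circuit volume, within-circuit static FC, reconfiguration
metric) is compared between groups by ANCOVA: an ordinary least-squares fit
of the outcome on sex, age and years of education followed by the group
factor, with the group F statistic taken from the sequential (covariates
first, Type I) sums of squares.  Pairwise group contrasts are t-tests on
adjusted group-mean differences using the full-model residual variance,
uncorrected across the group pairs.  p values are Benjamini–Hochberg
adjusted within outcome families (one family per measure class), and the
cohesion/disjointedness family is gated: those outcomes are analysed only
for units whose adjusted flexibility effect is significant, because the
nature of a switch is informative only where switching frequency differs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "AncovaResult",
    "AnalysisPlan",
    "ancova",
    "bh_adjust",
    "run_plan",
]

COVARIATES = ("sex", "age", "education_years")


@dataclass
class AncovaResult:
    outcome: str
    family: str
    f_group: float
    df_between: int
    df_resid: int
    p_uncorrected: float
    p_adjusted: float | None
    covariate_p: dict
    adjusted_means: dict
    contrasts: pd.DataFrame  # columns: group_a, group_b, estimate, t, p


@dataclass
class AnalysisPlan:
    """Outcome families, the flexibility gate, and the significance level.

    ``families`` maps a family name to its outcome columns (BH correction
    is applied within each family independently).  ``gate`` maps a
    flexibility outcome column to its (cohesion, disjointedness) columns;
    the latter are analysed, as a post-hoc family, only when the former's
    BH-adjusted p falls below ``alpha``.
    """

    families: dict = field(default_factory=dict)
    gate: dict = field(default_factory=dict)
    alpha: float = 0.05
    gated_family: str = "cohesion/disjointedness"


def _design(groups: pd.Series, covariates: pd.DataFrame):
    """Design matrix: intercept, sex (binary), age, education, then group
    dummies (first group level as reference).  Column order is fixed so the
    sequential sum of squares for the group block is the group effect
    adjusted for the covariates."""
    sex = covariates["sex"]
    if sex.dtype == object or str(sex.dtype) == "category":
        levels = sorted(sex.unique())
        if len(levels) > 2:
            raise ValueError("sex must be a two-level factor")
        sex = (sex == levels[-1]).astype(float)
    X_cov = pd.DataFrame({
        "intercept": 1.0,
        "sex": sex.astype(float),
        "age": covariates["age"].astype(float),
        "education_years": covariates["education_years"].astype(float),
    })
    for name in ("sex", "age", "education_years"):
        if X_cov[name].nunique() <= 1:
            raise ValueError(f"covariate {name!r} is constant: singular design")
    levels = list(pd.unique(groups))
    dummies = pd.DataFrame(
        {f"group[{g}]": (groups == g).astype(float).to_numpy() for g in levels[1:]},
        index=X_cov.index)
    X = pd.concat([X_cov, dummies], axis=1)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("singular design matrix (collinear columns)")
    return X, levels


def ancova(outcome: pd.Series, groups: pd.Series, covariates: pd.DataFrame,
           name: str = "outcome", family: str = "") -> AncovaResult:
    """Group comparison of one outcome adjusted for sex, age and education.

    The group F statistic is the sequential sum-of-squares F for the group
    block entered after the covariates (equivalently, the nested-model RSS
    comparison of covariates-only vs covariates+group).  Pairwise contrasts
    are adjusted-mean differences tested against the full-model residual
    variance.
    """
    y = np.asarray(outcome, dtype=float)
    groups = pd.Series(np.asarray(groups, dtype=object))
    counts = groups.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    covariates = covariates.reset_index(drop=True)
    X_full, levels = _design(groups, covariates)
    n_groups = len(levels)

    full = sm.OLS(y, X_full.to_numpy()).fit()
    reduced = sm.OLS(y, X_full.to_numpy()[:, :4]).fit()  # intercept + covariates
    df_between = n_groups - 1
    df_resid = int(full.df_resid)
    f_group = ((reduced.ssr - full.ssr) / df_between) / (full.ssr / df_resid)
    from scipy import stats as sps
    p_group = float(sps.f.sf(f_group, df_between, df_resid))

    cov_p = {nm: float(full.pvalues[i]) for i, nm in
             enumerate(X_full.columns) if nm in COVARIATES}

    # adjusted means: prediction at covariate means per group
    cov_means = X_full.to_numpy()[:, 1:4].mean(axis=0)
    adj = {}
    for g in levels:
        x = np.zeros(X_full.shape[1])
        x[0] = 1.0
        x[1:4] = cov_means
        if g != levels[0]:
            x[4 + levels[1:].index(g)] = 1.0
        adj[g] = float(x @ full.params)

    rows = []
    for ga, gb in itertools.combinations(levels, 2):
        c = np.zeros(X_full.shape[1])
        if ga != levels[0]:
            c[4 + levels[1:].index(ga)] = 1.0
        if gb != levels[0]:
            c[4 + levels[1:].index(gb)] -= 1.0
        est = float(c @ full.params)
        se = float(np.sqrt(c @ full.cov_params() @ c))
        tval = est / se
        rows.append({"group_a": ga, "group_b": gb, "estimate": est,
                     "t": tval, "p": float(2 * sps.t.sf(abs(tval), df_resid))})
    return AncovaResult(outcome=name, family=family, f_group=float(f_group),
                        df_between=df_between, df_resid=df_resid,
                        p_uncorrected=p_group, p_adjusted=None,
                        covariate_p=cov_p, adjusted_means=adj,
                        contrasts=pd.DataFrame(rows))


def bh_adjust(p_values, family: str = "") -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p values (within one family)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError(f"family {family!r}: p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_plan(outcomes: pd.DataFrame, groups: pd.Series,
             covariates: pd.DataFrame, plan: AnalysisPlan) -> pd.DataFrame:
    """Run every family's ANCOVAs with per-family BH correction and the
    flexibility gate.

    ``outcomes`` is subjects × outcome columns, aligned with ``groups`` and
    ``covariates``.  Gated cohesion/disjointedness outcomes are analysed
    (flagged ``post_hoc``) only for units whose flexibility column reached
    an adjusted p below ``plan.alpha``; with the gate closed everywhere,
    the result table contains no such rows.
    """
    results: list[AncovaResult] = []
    flex_adj: dict[str, float] = {}

    for fam, cols in plan.families.items():
        fam_res = []
        for col in cols:
            if col not in outcomes.columns:
                raise ValueError(f"family {fam!r}: outcome column {col!r} missing")
            fam_res.append(ancova(outcomes[col], groups, covariates,
                                  name=col, family=fam))
        adj = bh_adjust([r.p_uncorrected for r in fam_res], family=fam)
        for r, a in zip(fam_res, adj):
            r.p_adjusted = float(a)
            if r.outcome in plan.gate:
                flex_adj[r.outcome] = r.p_adjusted
        results.extend(fam_res)

    gated_cols = [c for flex_col, pair in plan.gate.items()
                  if flex_adj.get(flex_col, 1.0) < plan.alpha for c in pair]
    if gated_cols:
        fam_res = [ancova(outcomes[c], groups, covariates,
                          name=c, family=plan.gated_family) for c in gated_cols]
        adj = bh_adjust([r.p_uncorrected for r in fam_res],
                        family=plan.gated_family)
        for r, a in zip(fam_res, adj):
            r.p_adjusted = float(a)
        results.extend(fam_res)

    rows = []
    for r in results:
        rows.append({
            "family": r.family, "outcome": r.outcome,
            "post_hoc": r.family == plan.gated_family,
            "F": r.f_group, "df_between": r.df_between,
            "df_resid": r.df_resid, "p_uncorrected": r.p_uncorrected,
            "p_adjusted": r.p_adjusted,
            **{f"p[{c['group_a']} vs {c['group_b']}]": c["p"]
               for c in r.contrasts.to_dict("records")},
        })
    return pd.DataFrame(rows)


def default_plan(units, alpha: float = 0.05) -> AnalysisPlan:
    """The standard family layout over a set of units (circuit names plus
    "global"): one family per measure class, gates pairing each unit's
    flexibility with its cohesion/disjointedness columns."""
    units = list(units)
    return AnalysisPlan(
        families={
            "flexibility": [f"flexibility[{u}]" for u in units],
            "promiscuity": [f"promiscuity[{u}]" for u in units],
        },
        gate={f"flexibility[{u}]": (f"cohesion[{u}]", f"disjointedness[{u}]")
              for u in units},
        alpha=alpha,
    )
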