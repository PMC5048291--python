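"""Clinical outcome analysis of interface-defined sample groups.

Samples are joined to donor records (age, sex, vital and disease status,
survival time); interface- or cluster-defined groups are then compared by

* a two-tailed Fisher exact test on vital/disease status,
* a Mann–Whitney U test on survival-time distributions,
* Kaplan–Meier curves with a logrank test, and
* a Cox proportional-hazards model with age, sex and cancer type as
  covariates, whose group hazard ratio is the headline number.

Alive donors are treated as right-censored at last follow-up; times are
carried through in the input's units.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

logger = logging.getLogger(__name__)

REQUIRED_DONOR_FIELDS = [
    "donor_id", "sample_id", "age", "sex", "vital_status", "disease_status",
    "survival_time",
]


@dataclass
class SurvivalComparison:
    """Result bundle of a multi-group survival contrast."""

    groups: list
    km_curves: dict = field(default_factory=dict)  # group -> DataFrame(time, survival)
    logrank_stat: float | None = None
    logrank_p: float | None = None
    ranksum_p: float | None = None
    cox: pd.DataFrame | None = None


def match_donors(samples: pd.DataFrame, donors: pd.DataFrame) -> pd.DataFrame:
    """Inner-join samples to donors, keeping complete clinical records.

    Donor rows missing any required field are dropped with a logged count;
    two donor rows claiming the same sample with different content are an
    error.  Adds ``event_observed`` (deceased => True; alive => censored).
    """
    missing_cols = [c for c in REQUIRED_DONOR_FIELDS if c not in donors.columns]
    if missing_cols:
        raise ValueError(f"donor table lacks columns: {missing_cols}")
    dup = donors[donors.duplicated("sample_id", keep=False)]
    if len(dup):
        if dup.groupby("sample_id").nunique().gt(1).any().any():
            raise ValueError("conflicting duplicate sample->donor mappings")
        donors = donors.drop_duplicates("sample_id")
    complete = donors.dropna(subset=REQUIRED_DONOR_FIELDS)
    n_dropped = len(donors) - len(complete)
    if n_dropped:
        logger.warning("dropped %d donors with incomplete clinical information", n_dropped)
    joined = samples.merge(complete, on="sample_id", how="inner",
                           suffixes=("", "_donor"))
    logger.info("matched %d of %d samples to complete donor records",
                len(joined), len(samples))
    joined = joined[joined["survival_time"] >= 0].reset_index(drop=True)
    joined["event_observed"] = joined["vital_status"].eq("deceased")
    return joined


def status_association(groups: pd.Series, status: pd.Series) -> float:
    """Two-tailed Fisher exact p for a 2-group x 2-status association.

    Degenerate margins (an empty group or a constant status) return p = 1
    with a warning rather than failing.
    """
    table = pd.crosstab(pd.Series(groups).to_numpy(), pd.Series(status).to_numpy())
    if table.shape != (2, 2):
        if table.size == 0 or 1 in table.shape:
            logger.warning("degenerate status table %s; p = 1", tuple(table.shape))
            return 1.0
        raise ValueError(
            f"expected a 2x2 table, got {table.shape}; collapse groups/statuses first"
        )
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        logger.warning("degenerate margins in status table; p = 1")
        return 1.0
    return float(stats.fisher_exact(table.to_numpy(), alternative="two-sided")[1])


def survival_ranksum(times_a: Sequence[float], times_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann–Whitney U comparison of survival-time distributions.

    Returns (U, p); fully tied data yield p = 1 with a warning.
    """
    a = np.asarray(times_a, dtype=float)
    b = np.asarray(times_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if np.all(np.concatenate([a, b]) == a[0] if len(a) else True):
        logger.warning("all survival times tied; p = 1")
        return float(len(a) * len(b) / 2), 1.0
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def km_curve(times: Sequence[float], events: Sequence[bool]) -> pd.DataFrame:
    """Kaplan–Meier product-limit curve as a (time, survival) step table."""
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(times, dtype=float), np.asarray(events, dtype=bool))
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()})


def km_logrank(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence,
) -> SurvivalComparison:
    """Per-group Kaplan–Meier curves plus a logrank test (>= 2 groups).

    With a single group only the curve is returned; each group must be
    non-empty and at least one event must be observed overall for the test.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    labels = sorted(pd.unique(g).tolist())
    if any((g == lab).sum() == 0 for lab in labels) or len(t) == 0:
        raise ValueError("every group must contain at least one subject")
    curves = {lab: km_curve(t[g == lab], e[g == lab]) for lab in labels}
    comp = SurvivalComparison(groups=labels, km_curves=curves)
    if len(labels) >= 2:
        if not e.any():
            raise ValueError("logrank test requires at least one observed event")
        res = multivariate_logrank_test(t, g, e)
        comp.logrank_stat = float(res.test_statistic)
        comp.logrank_p = float(res.p_value)
    return comp


def cox_hazard(
    clinical: pd.DataFrame,
    group_col: str,
    covariates: Sequence[str] = ("age", "sex", "cancer_type"),
    duration_col: str = "survival_time",
    event_col: str = "event_observed",
) -> pd.DataFrame:
    """Cox proportional-hazards fit with the group term as headline.

    Categorical covariates (sex, cancer type, the group itself) are
    dummy-encoded against their first level.  Returns the lifelines summary
    frame (coef, exp(coef), CIs, p) with group terms first; convergence
    failures propagate as errors.
    """
    df = clinical.copy()
    if df[group_col].nunique() < 2:
        raise ValueError("Cox contrast needs at least two groups")
    cols = [duration_col, event_col]
    design = df[cols].copy()
    design[event_col] = design[event_col].astype(bool)
    cat_terms: list[str] = []
    for col in [group_col, *covariates]:
        if col == group_col or df[col].dtype == object or str(df[col].dtype) == "category":
            dummies = pd.get_dummies(df[col].astype(str), prefix=col, drop_first=True)
            # drop constant dummies (single-level covariates)
            dummies = dummies.loc[:, dummies.nunique() > 1]
            design = pd.concat([design, dummies.astype(float)], axis=1)
            if col == group_col:
                cat_terms = list(dummies.columns)
        else:
            if df[col].nunique() > 1:
                design[col] = df[col].astype(float)
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        cph.fit(design, duration_col=duration_col, event_col=event_col)
    summary = cph.summary.copy()
    order = cat_terms + [c for c in summary.index if c not in cat_terms]
    return summary.loc[order]


def perturbation_groups(
    perturbations: pd.DataFrame,
    interface_a: str,
    interface_b: str | None = None,
    all_samples: Sequence[str] | None = None,
) -> pd.Series:
    """Group labels for survival contrasts on interface perturbation.

    One interface: samples with >= 1 event on it vs the rest
    ('perturbed'/'rest').  Two interfaces (a mutually exclusive contrast):
    samples perturbed at A only vs B only; samples perturbed at both are
    dropped with a logged count, unperturbed samples are left out.
    """
    sa = set(perturbations.loc[perturbations["interface_id"] == interface_a, "sample_id"])
    if interface_b is None:
        if all_samples is None:
            raise ValueError("all_samples required for a one-interface contrast")
        return pd.Series(
            ["perturbed" if s in sa else "rest" for s in all_samples],
            index=pd.Index(all_samples, name="sample_id"),
            name="group",
        )
    sb = set(perturbations.loc[perturbations["interface_id"] == interface_b, "sample_id"])
    both = sa & sb
    if both:
        logger.info("dropping %d samples perturbed at both interfaces", len(both))
    labels = {s: interface_a for s in sa - both}
    labels.update({s: interface_b for s in sb - both})
    s = pd.Series(labels, name="group")
    s.index.name = "sample_id"
    return s.sort_index()
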