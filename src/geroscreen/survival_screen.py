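"""Age-cohort-stratified median-split Kaplan-Meier survival screening.

Patients with age and overall-survival metadata are split into young
(< 45 y), middle-aged (45-60 y, both ends inclusive) and senior (> 60 y)
cohorts. Within each cohort, each gene's median expression dichotomizes
patients into "high" (>= median) and "low" (< median) arms; the arms are
compared with the two-group log-rank test and oriented by comparing the
Kaplan-Meier median survival times (falling back to the survival probability
at the last common follow-up time when neither curve reaches 0.5). A gene
"stratifies by survival" when at least one cohort is significant at alpha.

KM fitting and the log-rank test are delegated to ``lifelines``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from ._stats import bh_adjust
from .datasets import COHORTS, CohortSpec, ExpressionDataset, ValidationError

logger = logging.getLogger("geroscreen")

SCREEN_COLUMNS = ["gene", "cohort", "n_high", "n_low", "logrank_chi2",
                  "logrank_p", "direction", "significant", "evaluable"]


def assign_cohorts(metadata: pd.DataFrame, spec: CohortSpec | None = None) -> pd.Series:
    """Map samples to age cohorts; samples without age or survival are excluded.

    age < young_max -> young; young_max <= age <= senior_min -> middle;
    age > senior_min -> senior.
    """
    spec = spec or CohortSpec()
    usable = (metadata["age"].notna() & metadata["os_time"].notna()
              & metadata["os_event"].notna())
    ages = metadata.loc[usable, "age"]
    labels = pd.Series("middle", index=ages.index, dtype=object)
    labels[ages < spec.young_max] = "young"
    labels[ages > spec.senior_min] = "senior"
    return labels


def median_split(values: pd.Series) -> tuple[pd.Index, pd.Index, bool]:
    """Partition samples into high (>= median) and low (< median) arms.

    Returns (high index, low index, indeterminate). A constant vector puts
    every sample in "high" and flags the split indeterminate.
    """
    if len(values) < 2:
        raise ValidationError("median split requires >= 2 samples")
    med = float(np.median(values.to_numpy(dtype=float)))
    high = values.index[values >= med]
    low = values.index[values < med]
    indeterminate = len(low) == 0
    return high, low, indeterminate


@dataclass
class KMCurve:
    """Product-limit survival curve summary.

    ``event_times`` are the distinct death times (ascending); the curve starts
    at 1 at time 0 and drops only at event times. ``median`` is the KM median
    survival time (inf when the curve never reaches 0.5); ``max_time`` the
    last follow-up (event or censoring).
    """

    event_times: np.ndarray
    survival_probs: np.ndarray
    at_risk: np.ndarray
    median: float
    max_time: float
    n: int

    def survival_at(self, t: float) -> float:
        idx = int(np.searchsorted(self.event_times, t, side="right"))
        return 1.0 if idx == 0 else float(self.survival_probs[idx - 1])


def km_estimate(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate (via lifelines)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValidationError("km_estimate requires at least one subject")
    if (times < 0).any():
        raise ValidationError("survival times must be nonnegative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    table = kmf.event_table
    is_event = table["observed"] > 0
    event_times = table.index.to_numpy(dtype=float)[is_event.to_numpy()]
    surv = kmf.survival_function_["KM_estimate"]
    survival_probs = np.array([float(surv.loc[t]) for t in event_times])
    at_risk = table.loc[is_event, "at_risk"].to_numpy(dtype=int)
    median = float(kmf.median_survival_time_)
    return KMCurve(event_times=event_times, survival_probs=survival_probs,
                   at_risk=at_risk, median=median,
                   max_time=float(times.max()), n=int(times.size))


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    With zero events in both groups the test is undefined; returns (0, 1)
    with a warning.
    """
    times_a = np.asarray(times_a, dtype=float)
    times_b = np.asarray(times_b, dtype=float)
    events_a = np.asarray(events_a, dtype=bool)
    events_b = np.asarray(events_b, dtype=bool)
    if times_a.size == 0 or times_b.size == 0:
        raise ValidationError("log-rank test requires both groups non-empty")
    if events_a.sum() + events_b.sum() == 0:
        logger.warning("log-rank: zero events in both groups; returning p = 1")
        return 0.0, 1.0
    res = _ll_logrank(times_a, times_b, event_observed_A=events_a,
                      event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def direction_of_harm(high: KMCurve, low: KMCurve) -> str:
    """Orient a survival split: which arm fares worse.

    The arm with the smaller KM median survival is "worse". When neither
    median is defined, the arm with the smaller survival probability at the
    last common follow-up time is worse; exact ties are indeterminate.
    """
    m_h, m_l = high.median, low.median
    if np.isinf(m_h) and np.isinf(m_l):
        t_star = min(high.max_time, low.max_time)
        s_h, s_l = high.survival_at(t_star), low.survival_at(t_star)
        if s_h < s_l:
            return "high_worse"
        if s_l < s_h:
            return "low_worse"
        return "indeterminate"
    if m_h < m_l:
        return "high_worse"
    if m_l < m_h:
        return "low_worse"
    return "indeterminate"


def _not_evaluable_row(gene: str, cohort: str, n_high: int, n_low: int) -> dict:
    return {"gene": gene, "cohort": cohort, "n_high": n_high, "n_low": n_low,
            "logrank_chi2": np.nan, "logrank_p": np.nan,
            "direction": "indeterminate", "significant": False,
            "evaluable": False}


def screen_survival(ds: ExpressionDataset, genes,
                    spec: CohortSpec | None = None,
                    alpha: float = 0.05,
                    min_cohort_n: int = 4,
                    bh: bool = False) -> pd.DataFrame:
    """Median-split log-rank screen of ``genes`` per age cohort.

    Returns one row per gene x cohort with columns gene, cohort, n_high,
    n_low, logrank_chi2, logrank_p, direction, significant, evaluable.
    Cohorts with fewer than ``min_cohort_n`` usable samples or zero events are
    marked not evaluable, as are constant-expression (indeterminate) splits.
    With ``bh=True`` significance is assessed on BH-adjusted p-values across
    all evaluable cells (off by default).
    """
    spec = spec or CohortSpec()
    cohort_map = assign_cohorts(ds.metadata, spec)
    genes = list(genes)
    missing = [g for g in genes if g not in ds.values.index]
    if missing:
        logger.warning("%s: %d requested genes absent from dataset",
                       ds.dataset_id, len(missing))
    genes = [g for g in genes if g in ds.values.index]
    rows = []
    for cohort in COHORTS:
        samples = cohort_map.index[cohort_map == cohort]
        times = ds.metadata.loc[samples, "os_time"].to_numpy(dtype=float)
        events = ds.metadata.loc[samples, "os_event"].to_numpy(dtype=float) == 1.0
        cohort_ok = len(samples) >= min_cohort_n and events.sum() >= 1
        for gene in genes:
            if not cohort_ok:
                rows.append(_not_evaluable_row(gene, cohort, 0, 0))
                continue
            expr = ds.values.loc[gene, samples]
            high, low, indet = median_split(expr)
            if indet:
                rows.append(_not_evaluable_row(gene, cohort, len(high), len(low)))
                continue
            hi_pos = samples.get_indexer(high)
            lo_pos = samples.get_indexer(low)
            chi2, p = logrank_test(times[hi_pos], events[hi_pos],
                                   times[lo_pos], events[lo_pos])
            direction = direction_of_harm(
                km_estimate(times[hi_pos], events[hi_pos]),
                km_estimate(times[lo_pos], events[lo_pos]))
            rows.append({"gene": gene, "cohort": cohort,
                         "n_high": len(high), "n_low": len(low),
                         "logrank_chi2": chi2, "logrank_p": p,
                         "direction": direction,
                         "significant": bool(p < alpha),
                         "evaluable": True})
    out = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
    if len(out):
        if bh:
            ev = out["evaluable"]
            out.loc[ev, "logrank_q"] = bh_adjust(out.loc[ev, "logrank_p"].to_numpy())
            out["significant"] = out.get("logrank_q", pd.Series(np.nan)) < alpha
            out["significant"] = out["significant"].fillna(False)
        out = out.sort_values(["gene", "cohort"], kind="mergesort").reset_index(drop=True)
    return out


def heatmap_table(results: pd.DataFrame) -> pd.DataFrame:
    """Genes x cohorts table of {red, blue, NA}.

    A cell is "red" when the cohort's high/low split is significantly
    different in survival, "blue" when evaluable but not significant, "NA"
    when not evaluable.
    """
    def _cell(row) -> str:
        if not row["evaluable"]:
            return "NA"
        return "red" if row["significant"] else "blue"

    if not len(results):
        return pd.DataFrame(columns=list(COHORTS))
    tmp = results.copy()
    tmp["cell"] = tmp.apply(_cell, axis=1)
    table = tmp.pivot(index="gene", columns="cohort", values="cell")
    return table.reindex(columns=list(COHORTS)).fillna("NA")


def stratifying_genes(results: pd.DataFrame) -> list[str]:
    """Genes significant in at least one cohort."""
    if not len(results):
        return []
    sig = results.loc[results["significant"], "gene"]
    return sorted(sig.unique())
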