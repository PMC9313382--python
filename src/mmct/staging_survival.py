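"""ISS / R-ISS staging, dynamic restaging and survival analysis.

Staging follows the published rules: ISS I iff beta2-microglobulin
< 3.5 mg/L with albumin >= 3.5 g/dL, ISS III iff beta2-microglobulin
>= 5.5 mg/L, else II.  R-ISS I requires ISS I with no high-risk
cytogenetics (del17p, t(4;14), t(14;16)) and normal LDH; R-ISS III requires
ISS III with high-risk cytogenetics or high LDH; everything else is II.
Missing inputs propagate to "not_reported" unless the stage is decidable
regardless (e.g. ISS II is R-ISS II whatever the cytogenetics).

Restaging at the paired (progression) sample — R-ISS'' — redistributes
patients across risk categories; the redistribution matrix and the survival
comparison of R-ISS'' groups (Kaplan-Meier, log-rank, Cox with Efron ties)
are the clinically load-bearing outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.stats import fisher_exact

STAGES = ("I", "II", "III", "not_reported")
HIGH_RISK_CA_FLAGS = ("del17p", "t_4_14", "t_14_16")


@dataclass(frozen=True)
class StagingResult:
    iss: str
    riss: str
    timepoint: str  # "first" or "paired"

    def __post_init__(self) -> None:
        if self.iss not in STAGES or self.riss not in STAGES:
            raise ValueError(f"unknown stage {self.iss}/{self.riss}")
        if self.riss == "I" and self.iss != "I":
            raise ValueError("R-ISS I requires ISS I")
        if self.riss == "III" and self.iss != "III":
            raise ValueError("R-ISS III requires ISS III")


def compute_iss(albumin_g_dl: Optional[float], b2m_mg_l: Optional[float]) -> str:
    """ISS stage from serum albumin (g/dL) and beta2-microglobulin (mg/L)."""
    if albumin_g_dl is None or b2m_mg_l is None:
        return "not_reported"
    if albumin_g_dl < 0 or b2m_mg_l < 0:
        raise ValueError("albumin and b2m must be non-negative")
    if b2m_mg_l >= 5.5:
        return "III"
    if b2m_mg_l < 3.5 and albumin_g_dl >= 3.5:
        return "I"
    return "II"


def high_risk_cytogenetics(fish: Mapping[str, Optional[bool]]) -> Optional[bool]:
    """Three-valued OR over del17p, t(4;14), t(14;16): True if any present,
    None if none present but at least one unassayed, else False."""
    flags = [fish.get(f) for f in HIGH_RISK_CA_FLAGS]
    if any(f is True for f in flags):
        return True
    if any(f is None for f in flags):
        return None
    return False


def compute_riss(iss: str, high_risk_ca: Optional[bool], ldh: str) -> str:
    """R-ISS from the ISS stage, high-risk cytogenetics and LDH status.

    Missing cytogenetics or LDH yield "not_reported" only when the stage
    actually depends on the missing value; ISS II, for instance, is R-ISS II
    regardless.
    """
    if iss == "not_reported":
        return "not_reported"
    ldh_high = {"high": True, "normal": False}.get(ldh)  # None when missing
    if iss == "II":
        return "II"
    if iss == "I":
        # R-ISS I needs both risk factors affirmatively absent.
        if high_risk_ca is False and ldh_high is False:
            return "I"
        if high_risk_ca or ldh_high:
            return "II"
        return "not_reported"
    # ISS III: III with any risk factor, II when both absent.
    if high_risk_ca or ldh_high:
        return "III"
    if high_risk_ca is False and ldh_high is False:
        return "II"
    return "not_reported"


def stage_patient(albumin: Optional[float], b2m: Optional[float],
                  fish: Mapping[str, Optional[bool]], ldh: str,
                  timepoint: str) -> StagingResult:
    iss = compute_iss(albumin, b2m)
    riss = compute_riss(iss, high_risk_cytogenetics(fish), ldh)
    return StagingResult(iss=iss, riss=riss, timepoint=timepoint)


def restaging_matrix(stage_pairs: Sequence[tuple[str, str]]) -> pd.DataFrame:
    """4x4 first-stage x paired-stage count matrix (I, II, III,
    not_reported), with marginals as the "total" row/column."""
    matrix = pd.DataFrame(0, index=list(STAGES), columns=list(STAGES))
    for first, paired in stage_pairs:
        matrix.loc[first, paired] += 1
    matrix["total"] = matrix.sum(axis=1)
    matrix.loc["total"] = matrix.sum(axis=0)
    return matrix


# --------------------------------------------------------------------------
# Survival


@dataclass(frozen=True)
class SurvivalSummary:
    group: str
    n: int
    n_events: int
    median_months: Optional[float]
    km_times: tuple[float, ...]
    km_survival: tuple[float, ...]
    km_ci_low: tuple[float, ...]
    km_ci_high: tuple[float, ...]
    km_at_risk: tuple[int, ...]


@dataclass(frozen=True)
class SurvivalComparison:
    groups: tuple[SurvivalSummary, ...]
    hr: Optional[float]
    ci95: Optional[tuple[float, float]]
    p_logrank: Optional[float]
    p_wald: Optional[float]


def _km_summary(times: np.ndarray, events: np.ndarray, label: str) -> SurvivalSummary:
    km = KaplanMeierFitter()
    km.fit(times, event_observed=events, label=label)
    sf = km.survival_function_[label]
    ci = km.confidence_interval_
    # median as first time the estimate drops to <= 0.5 (inf when never)
    median = km.median_survival_time_
    at_risk = km.event_table["at_risk"].reindex(sf.index).fillna(0).astype(int)
    return SurvivalSummary(
        group=label, n=len(times), n_events=int(events.sum()),
        median_months=None if math.isinf(median) else float(median),
        km_times=tuple(float(t) for t in sf.index),
        km_survival=tuple(float(v) for v in sf.values),
        km_ci_low=tuple(float(v) for v in ci.iloc[:, 0].values),
        km_ci_high=tuple(float(v) for v in ci.iloc[:, 1].values),
        km_at_risk=tuple(int(v) for v in at_risk.values))


def survival_compare(times: Sequence[float], events: Sequence[bool],
                     group_labels: Sequence[str]) -> SurvivalComparison:
    """Compare survival between groups.

    Kaplan-Meier per group (Greenwood CIs; median = first time the estimate
    is <= 0.5), a log-rank test across groups, and — for exactly two groups —
    a single-covariate Cox model with Efron tie handling giving the hazard
    ratio of the second group (sorted order) versus the first with a Wald
    95% CI.  A group without events leaves the HR undefined.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    labels = np.asarray(group_labels)
    if times.shape != events.shape or times.shape != labels.shape:
        raise ValueError("times, events and group_labels must have equal length")
    unique = sorted(set(labels.tolist()))
    if len(unique) < 2:
        raise ValueError("need at least two groups")

    summaries = tuple(_km_summary(times[labels == g], events[labels == g], g)
                      for g in unique)

    p_logrank: Optional[float] = None
    if all(s.n_events > 0 for s in summaries):
        lr = multivariate_logrank_test(times, labels, events)
        p_logrank = float(lr.p_value)

    hr = ci95 = p_wald = None
    if len(unique) == 2 and all(s.n_events > 0 for s in summaries):
        df = pd.DataFrame({
            "time": times, "event": events.astype(int),
            "group": (labels == unique[1]).astype(int)})
        cph = CoxPHFitter()  # lifelines uses the Efron partial likelihood
        cph.fit(df, duration_col="time", event_col="event")
        hr = float(np.exp(cph.params_["group"]))
        se = float(cph.standard_errors_["group"])
        log_hr = float(cph.params_["group"])
        ci95 = (float(np.exp(log_hr - 1.959963984540054 * se)),
                float(np.exp(log_hr + 1.959963984540054 * se)))
        p_wald = float(cph.summary.loc["group", "p"])
    return SurvivalComparison(groups=summaries, hr=hr, ci95=ci95,
                              p_logrank=p_logrank, p_wald=p_wald)


def km_median(times: Sequence[float], events: Sequence[bool]) -> Optional[float]:
    """Kaplan-Meier median: first time the survival estimate drops to <= 0.5."""
    km = KaplanMeierFitter()
    km.fit(np.asarray(times, dtype=float), event_observed=np.asarray(events, dtype=bool))
    median = km.median_survival_time_
    return None if math.isinf(median) else float(median)


# --------------------------------------------------------------------------
# Pattern vs response


def response_association(patterns: Sequence[str], responses: Sequence[str],
                         ) -> tuple[np.ndarray, Optional[float]]:
    """2x2 association of evolution pattern (loss vs acquisition) with
    treatment response dichotomized at >= VGPR.

    Rows: loss, acquisition; columns: >=VGPR (CR or VGPR), <VGPR.  Patients
    with other patterns or missing response are excluded.  Returns the table
    and a two-sided Fisher exact p (None when a margin is empty).
    """
    if len(patterns) != len(responses):
        raise ValueError("patterns and responses must have equal length")
    table = np.zeros((2, 2), dtype=int)
    for pattern, response in zip(patterns, responses):
        if pattern not in ("loss", "acquisition") or response in (None, "", "missing"):
            continue
        row = 0 if pattern == "loss" else 1
        col = 0 if response in ("CR", "VGPR") else 1
        table[row, col] += 1
    if table.sum(axis=1).min() == 0 or table.sum() == 0:
        return table, None
    _, p = fisher_exact(table, alternative="two-sided")
    return table, float(p)
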