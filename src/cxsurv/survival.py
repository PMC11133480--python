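"""Survival estimation and trial summary statistics.

Kaplan-Meier curves, log-rank tests and Cox proportional-hazards ratios are
computed with lifelines (Efron tie handling in Cox); Mann-Whitney U uses an
exact tie-aware enumeration for small samples and the tie-corrected normal
approximation otherwise.  Also implements adverse-event tabulation by CTCAE
grade and relationship, pharmacokinetic plateau summaries against the
1.5 uM pharmacologic threshold, and the modified 3+3 dose-escalation
decision rules (dose levels 200/400/600 mg/week).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats as sps

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = ["KMCurve", "CoxResult", "AESummary", "EscalationState",
           "km_estimate", "logrank_test", "cox_hr", "mann_whitney",
           "ae_summary", "pk_summary", "escalation_decision",
           "DOSE_LEVELS_MG", "PK_THRESHOLD_UM",
           "RELATIONSHIP_CATEGORIES"]

DOSE_LEVELS_MG = (200, 400, 600)
PK_THRESHOLD_UM = 1.5

RELATIONSHIP_CATEGORIES = ("none", "gbm", "rt", "rt_gbm", "drug", "drug_gbm",
                           "drug_rt", "drug_rt_gbm")
_DRUG_RELATED = {"drug", "drug_gbm", "drug_rt", "drug_rt_gbm"}


def _round1(x: float) -> float:
    """Round to one decimal, half away from zero (tabulation convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank / Cox


@dataclass
class KMCurve:
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float            # NaN when the curve never reaches 0.5
    query_day: float | None = None
    survival_at_query: float | None = None
    all_censored: bool = False

    def survival_at(self, day: float) -> float:
        """Right-continuous step-function evaluation of S(day)."""
        idx = np.searchsorted(self.times, day, side="right") - 1
        if idx < 0:
            return 1.0
        return float(self.survival[idx])


def km_estimate(records: pd.DataFrame, query_day: float | None = None) -> KMCurve:
    """Product-limit survival estimate from a survival table.

    ``records`` needs columns time_days and event.  Median survival is the
    first time at which S(t) <= 0.5 (NaN and flagged when all records are
    censored or the curve stays above 0.5).
    """
    if len(records) == 0:
        raise ValueError("no survival records")
    t = records["time_days"].to_numpy(dtype=float)
    e = records["event"].to_numpy(dtype=bool)
    if (t <= 0).any():
        raise ValueError("survival times must be > 0")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    at_risk = np.array([kmf.event_table.loc[x, "at_risk"] for x in sf.index])
    median = float(kmf.median_survival_time_)
    curve = KMCurve(times=times, survival=surv, at_risk=at_risk,
                    median=median, all_censored=not e.any())
    if query_day is not None:
        curve.query_day = query_day
        curve.survival_at_query = curve.survival_at(query_day)
    return curve


def logrank_test(group_a: pd.DataFrame, group_b: pd.DataFrame) -> tuple[float, float]:
    """Two-sided log-rank test between two survival tables; returns (chi2, p)."""
    if len(group_a) == 0 or len(group_b) == 0:
        raise ValueError("both groups must be non-empty")
    if not group_a["event"].any() or not group_b["event"].any():
        warnings.warn("a group has zero events; log-rank statistic is weakly "
                      "informative")
    res = _ll_logrank(group_a["time_days"], group_b["time_days"],
                      event_observed_A=group_a["event"].astype(bool),
                      event_observed_B=group_b["event"].astype(bool))
    return float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    hr: float
    ci_low: float
    ci_high: float
    p_wald: float
    logrank_p: float | None = None
    n: int = 0
    n_events: int = 0
    warnings: list[str] = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"hr": self.hr, "ci95": [self.ci_low, self.ci_high],
                "p_wald": self.p_wald, "logrank_p": self.logrank_p,
                "n": self.n, "n_events": self.n_events,
                "warnings": self.warnings}


def cox_hr(records: pd.DataFrame, group: pd.Series | np.ndarray) -> CoxResult:
    """Univariable Cox PH hazard ratio for a binary grouping.

    ``group`` is 0/1 (or boolean) aligned with ``records`` (columns time_days,
    event).  HR is for group 1 vs group 0, with Efron handling of ties and a
    Wald 95% CI.  Monotone-likelihood / separation is surfaced as a warning
    on the result, not an exception.
    """
    g = np.asarray(group).astype(float)
    if set(np.unique(g)) - {0.0, 1.0}:
        raise ValueError("group must be binary")
    df = pd.DataFrame({"time": records["time_days"].to_numpy(dtype=float),
                       "event": records["event"].to_numpy(dtype=bool),
                       "group": g})
    if not df["event"].any():
        raise ValueError("no events in pooled data")
    cph = CoxPHFitter()
    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(df, duration_col="time", event_col="event")
        except Exception:
            # monotone likelihood: retry with a light ridge penalty
            cph = CoxPHFitter(penalizer=0.1)
            cph.fit(df, duration_col="time", event_col="event")
            notes.append("separation: fitted with ridge penalizer 0.1")
        for w in caught:
            notes.append(str(w.message).splitlines()[0])
    beta = float(cph.params_["group"])
    ci = cph.confidence_intervals_.loc["group"]
    if abs(beta) > 15 or float(ci.iloc[1]) - float(ci.iloc[0]) > 30:
        notes.append("monotone likelihood suspected: HR/CI unstable at this "
                     "sample size")

    def _exp(v: float) -> float:
        return math.exp(min(max(v, -700.0), 700.0))
    lr = df.rename(columns={"time": "time_days"})
    if (df["group"] == 1).any() and (df["group"] == 0).any():
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, lr_p = logrank_test(lr[lr["group"] == 1], lr[lr["group"] == 0])
    else:
        lr_p = None
    return CoxResult(hr=_exp(beta),
                     ci_low=_exp(float(ci.iloc[0])),
                     ci_high=_exp(float(ci.iloc[1])),
                     p_wald=float(cph.summary.loc["group", "p"]),
                     logrank_p=lr_p, n=len(df),
                     n_events=int(df["event"].sum()),
                     warnings=notes)


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x via midranks (tie-aware)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[: len(x)].sum()
    return float(r1 - len(x) * (len(x) + 1) / 2.0)


def mann_whitney(x, y, *, method: str = "auto") -> tuple[float, float]:
    """Unpaired two-tailed Mann-Whitney U test; returns (U, p).

    'exact' enumerates every assignment of the pooled (tied) values to the
    two samples — feasible and used automatically for n+m <= 12; otherwise
    the tie-corrected normal approximation (scipy, no continuity correction)
    is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    n, m = len(x), len(y)
    u_obs = _u_statistic(x, y)
    if method == "auto":
        method = "exact" if n + m <= 12 else "asymptotic"
    if method == "exact":
        pooled = np.concatenate([x, y])
        mu = n * m / 2.0
        dev_obs = abs(u_obs - mu)
        hits = total = 0
        for comb in itertools.combinations(range(n + m), n):
            mask = np.zeros(n + m, dtype=bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= dev_obs - 1e-12:
                hits += 1
        return u_obs, hits / total
    _, p = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                            use_continuity=False)
    return u_obs, float(p)


# ---------------------------------------------------------------------------
# Adverse events


@dataclass
class AESummary:
    total: int
    by_grade: dict[int, int]
    by_relationship: dict[str, int]
    grade_ge2_total: int
    grade_ge2_drug_related: int

    def grade_pct(self, grade: int) -> float:
        if self.total == 0:
            return math.nan
        return _round1(100.0 * self.by_grade.get(grade, 0) / self.total)

    def relationship_pct(self, category: str) -> float:
        if self.total == 0:
            return math.nan
        return _round1(100.0 * self.by_relationship.get(category, 0) / self.total)

    def drug_related_sole_pct(self) -> float:
        return self.relationship_pct("drug")

    def grade_ge2_drug_related_pct(self) -> float:
        if self.grade_ge2_total == 0:
            return math.nan
        return _round1(100.0 * self.grade_ge2_drug_related / self.grade_ge2_total)

    def as_dict(self) -> dict:
        return {
            "total": self.total,
            "by_grade": {str(g): c for g, c in sorted(self.by_grade.items())},
            "grade_pct": {str(g): self.grade_pct(g) for g in range(1, 6)},
            "by_relationship": dict(self.by_relationship),
            "drug_related_sole_pct": self.drug_related_sole_pct(),
            "grade_ge2_total": self.grade_ge2_total,
            "grade_ge2_drug_related": self.grade_ge2_drug_related,
            "grade_ge2_drug_related_pct": self.grade_ge2_drug_related_pct(),
        }


def ae_summary(events: pd.DataFrame) -> AESummary:
    """Tabulate an adverse-event listing (columns: grade, relationship).

    Grades must be 1..5 and relationships members of
    ``RELATIONSHIP_CATEGORIES`` ('drug' alone means solely related to the
    study drug; combined categories list every attributed cause).
    Percentages are recomputed from counts at reporting time, one decimal,
    half away from zero.  Grade >= 2 events get a drug-related sub-summary.
    """
    grades = events["grade"].to_numpy() if len(events) else np.array([], dtype=int)
    bad = [g for g in grades if g not in (1, 2, 3, 4, 5)]
    if bad:
        raise ValueError(f"CTCAE grade outside 1..5: {sorted(set(bad))}")
    rels = events["relationship"].tolist() if len(events) else []
    unknown = sorted({r for r in rels if r not in RELATIONSHIP_CATEGORIES})
    if unknown:
        raise ValueError(f"unknown relationship categories: {unknown}")
    by_grade = {g: int((grades == g).sum()) for g in range(1, 6)}
    by_rel = {c: rels.count(c) for c in RELATIONSHIP_CATEGORIES}
    ge2 = events[events["grade"] >= 2] if len(events) else events
    ge2_drug = int(ge2["relationship"].isin(_DRUG_RELATED).sum()) if len(ge2) else 0
    return AESummary(total=int(len(events)), by_grade=by_grade,
                     by_relationship=by_rel, grade_ge2_total=int(len(ge2)),
                     grade_ge2_drug_related=ge2_drug)


# ---------------------------------------------------------------------------
# Pharmacokinetics


def pk_summary(series: pd.DataFrame, *, threshold_um: float = PK_THRESHOLD_UM) -> dict:
    """Summarize one drug-concentration time series against the PK targets.

    ``series`` columns: day, drug_um and (optionally) cxcl12_um.  The
    steady-state day is the first day whose concentration lies within 10% of
    the mean over the final 7 days of observation.
    """
    days = series["day"].to_numpy(dtype=float)
    if len(days) < 5 or days[-1] - days[0] < 14:
        raise ValueError("need >= 5 time points spanning >= 14 days")
    if not np.all(np.diff(days) > 0):
        raise ValueError("day grid must be strictly increasing")
    conc = series["drug_um"].to_numpy(dtype=float)
    final_week = conc[days >= days[-1] - 7]
    plateau = float(final_week.mean())
    if plateau > 0:
        within = np.abs(conc - plateau) <= 0.10 * plateau
    else:
        within = conc == 0
    ss_day = float(days[int(np.argmax(within))]) if within.any() else float(days[-1])
    out = {
        "steady_state_day": ss_day,
        "mean_plateau_um": plateau,
        "exceeds_threshold": bool(plateau > threshold_um),
        "threshold_um": threshold_um,
    }
    if "cxcl12_um" in series.columns:
        cx = series["cxcl12_um"].to_numpy(dtype=float)
        out["drug_over_target"] = bool(np.all(conc >= cx))
    return out


# ---------------------------------------------------------------------------
# Modified 3+3 dose escalation


@dataclass(frozen=True)
class EscalationState:
    dose_level_index: int      # 0-based into DOSE_LEVELS_MG
    patients_treated: int
    dlt_count: int

    def __post_init__(self) -> None:
        if not 0 <= self.dose_level_index < len(DOSE_LEVELS_MG):
            raise ValueError("dose level index out of range")
        if self.patients_treated > 6:
            raise ValueError("protocol violation: more than 6 patients at a "
                             "dose level")
        if not 0 <= self.dlt_count <= self.patients_treated:
            raise ValueError("DLT count must be within [0, patients treated]")


def escalation_decision(state: EscalationState) -> str:
    """Modified 3+3 decision for a dose level.

    Returns one of 'continue_enrollment', 'escalate', 'expand_same_level',
    'stop_declare_MTD', 'declare_RP2D'.  >= 2 DLTs among 3-6 patients stop
    escalation (MTD is the level below); a tolerated cohort at the top dose
    (600 mg/week) makes it the RP2D since escalation never goes beyond it.
    """
    top = state.dose_level_index == len(DOSE_LEVELS_MG) - 1
    n, d = state.patients_treated, state.dlt_count
    if d >= 2:
        return "stop_declare_MTD"
    if n < 3:
        return "continue_enrollment"
    if n == 3:
        if d == 0:
            return "declare_RP2D" if top else "escalate"
        return "expand_same_level"      # 1/3 DLT: treat three more
    if n < 6:
        return "continue_enrollment"    # expansion cohort incomplete
    # n == 6, d <= 1: dose tolerated
    return "declare_RP2D" if top else "escalate"
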