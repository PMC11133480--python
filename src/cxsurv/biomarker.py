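"""Composite EG12 biomarker: construction, median dichotomization, correlation.

The EG12 score combines the CXCL12+ frequency of endothelial cells (E12) and
of glioma cells (G12) with equal weights after centering each on its cohort
median:

    EG12_i = ((E12_i - med(E12)) + (G12_i - med(G12))) / 2

so a patient's score is positive when, on balance, their E12 and G12 sit
above the cohort's typical values.  Cohorts (treatment arms) are centered
and dichotomized independently; scores strictly above the cohort median are
"high", scores at or below it "low" (ties go to low).

E12/G12 are in percent (0-100), matching how such frequencies are plotted,
so EG12 is in percentage points.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["SpearmanResult", "eg12_scores", "median_split", "spearman",
           "correlate_with_pfs", "recompute_from_patient_table"]


@dataclass(frozen=True)
class SpearmanResult:
    r_s: float
    p: float
    n: int
    method: str = "t-approx"

    def as_dict(self) -> dict:
        return {"r_s": self.r_s, "p": self.p, "n": self.n, "method": self.method}


def eg12_scores(table: pd.DataFrame, *, cohort_col: str = "cohort",
                e_col: str = "E12", g_col: str = "G12") -> pd.DataFrame:
    """Add an ``EG12`` column: mean of per-cohort median-centered E12 and G12.

    Patients with an undefined component (NaN E12 or G12, e.g. no endothelial
    cells in the sample) are excluded from the median and get NaN EG12, with
    a warning naming them.
    """
    out = table.copy()
    if cohort_col not in out.columns:
        out[cohort_col] = "ALL"
    out["EG12"] = np.nan
    for cohort, sub in out.groupby(cohort_col):
        defined = sub[[e_col, g_col]].notna().all(axis=1)
        if (~defined).any():
            bad = sub.index[~defined].tolist()
            warnings.warn(f"cohort {cohort}: patients {bad} lack a defined "
                          f"{e_col}/{g_col}; excluded from EG12")
        d = sub.loc[defined]
        if len(d) < 2:
            raise ValueError(f"cohort {cohort}: need >= 2 patients with "
                             f"defined {e_col} and {g_col}")
        e_med = d[e_col].median()
        g_med = d[g_col].median()
        out.loc[d.index, "EG12"] = ((d[e_col] - e_med) + (d[g_col] - g_med)) / 2.0
    return out


def median_split(scores: pd.Series | np.ndarray,
                 by: pd.Series | None = None) -> pd.Series:
    """Dichotomize scores at the (per-cohort) median into 'high'/'low'.

    Strictly above the median -> 'high'; at or below -> 'low'.  With an even
    number of distinct scores this yields equal halves.  NaN scores stay NaN.
    """
    s = pd.Series(scores).astype(float)
    if len(s.dropna()) < 2:
        raise ValueError("need >= 2 defined scores to split")
    labels = pd.Series(index=s.index, dtype=object)
    groups = s.groupby(by) if by is not None else [("ALL", s)]
    for _, sub in groups:
        med = sub.median()
        lab = np.where(sub > med, "high", "low")
        lab = pd.Series(lab, index=sub.index, dtype=object)
        lab[sub.isna()] = np.nan
        labels.loc[sub.index] = lab
    return labels


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, r_obs: float) -> float:
    """Two-tailed permutation p-value for Spearman's r_s by full enumeration."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = _pearson(rx, ry[list(perm)])
        total += 1
        if abs(r) >= abs(r_obs) - 1e-12:
            count += 1
    return count / total


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return math.nan
    return float((a * b).sum() / denom)


def spearman(x, y, *, method: str = "auto") -> SpearmanResult:
    """Tie-corrected Spearman rank correlation with a two-tailed p-value.

    ``method``: 't-approx' (p from the t distribution with n-2 df, the common
    package default), 'exact' (full permutation enumeration, n <= 9), or
    'auto' (exact for n < 9, else t-approx).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3 for a Spearman p-value")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("Spearman correlation undefined for a constant vector")
    r = _pearson(stats.rankdata(x), stats.rankdata(y))
    if method == "auto":
        method = "exact" if n < 9 else "t-approx"
    if method == "exact":
        if n > 9:
            raise ValueError("exact enumeration limited to n <= 9")
        p = _exact_spearman_p(x, y, r)
    elif method == "t-approx":
        if abs(r) >= 1.0:
            p = 0.0
        else:
            t = r * math.sqrt((n - 2) / (1 - r * r))
            p = 2 * stats.t.sf(abs(t), df=n - 2)
    else:
        raise ValueError(f"unknown method {method!r}")
    return SpearmanResult(r_s=r, p=float(min(p, 1.0)), n=n, method=method)


def correlate_with_pfs(biomarker: pd.DataFrame, survival: pd.DataFrame,
                       variable: str, *, endpoint: str = "PFS",
                       method: str = "t-approx") -> SpearmanResult:
    """Spearman correlation between a biomarker column and event survival times.

    Only patients with an observed event contribute (censored patients carry
    no exact time, so a cohort of 10 with one patient censored yields n = 9).
    ``survival`` needs columns patient_id, endpoint, time_days, event.
    """
    surv = survival[(survival["endpoint"] == endpoint)
                    & (survival["event"].astype(bool))]
    merged = biomarker.merge(surv[["patient_id", "time_days"]], on="patient_id")
    merged = merged.dropna(subset=[variable, "time_days"])
    if len(merged) < 3:
        raise ValueError(f"fewer than 3 patients with an observed {endpoint} "
                         f"event and defined {variable}")
    return spearman(merged[variable].to_numpy(), merged["time_days"].to_numpy(),
                    method=method)


def recompute_from_patient_table(table: pd.DataFrame) -> dict:
    """Deterministic biomarker recomputation from a per-patient value table.

    Expects columns: patient_id, cohort, E12, G12 (percent), pfs_days,
    pfs_event (0/1).  Recomputes EG12, the per-cohort median split, and the
    Spearman correlation of each biomarker with event PFS — the full chain a
    per-patient source table supports — and returns a nested dict keyed by
    cohort.
    """
    scored = eg12_scores(table)
    scored["EG12_class"] = median_split(scored["EG12"], by=scored["cohort"])
    surv = pd.DataFrame({
        "patient_id": scored["patient_id"], "endpoint": "PFS",
        "time_days": scored["pfs_days"], "event": scored["pfs_event"].astype(bool),
    })
    report: dict = {}
    for cohort, sub in scored.groupby("cohort"):
        entry: dict = {"n": int(len(sub))}
        for var in ("E12", "G12", "EG12"):
            res = correlate_with_pfs(sub, surv, var)
            entry[f"spearman_{var}"] = res.as_dict()
        entry["classes"] = sub.set_index("patient_id")["EG12_class"].to_dict()
        report[str(cohort)] = entry
    report["table"] = scored
    return report
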