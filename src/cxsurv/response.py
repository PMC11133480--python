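"""Modified RANO (mRANO) response assessment and PFS/OS event derivation.

Works from bidimensional lesion measurements on serial contrast-enhanced MRI.
At baseline, lesions measurable in two perpendicular diameters (both >= 10 mm)
become target lesions (TL); the rest are non-target lesions (NTL).  Tumor
size per scan is the SPD: the sum over TLs of the products of the two longest
perpendicular diameters.  Timepoint response:

* CR  — all TLs and all enhancing NTLs absent
* PR  — SPD change vs baseline <= -50%
* PD  — SPD change vs nadir >= +25%, or a new measurable lesion; new
        non-measurable lesions and NTL changes count only against an
        otherwise complete response
* SD  — otherwise

Preliminary PR/CR/PD require confirmation in a successive scan (next scan at
least ``min_confirm_gap_days`` later, default 42 d for a q8w schedule with
jitter).  Histopathologically confirmed pseudo-progression voids a PD call.
PD is referenced to the nadir SPD (minimum of baseline and all prior scans);
PR/CR to baseline.  The PFS event day is the day of the first preliminary-PD
scan that was sequentially confirmed, a scan with simultaneous clinical
progression, or death before progression; an unconfirmed preliminary PD still
counts if treatment stopped for clinical progression, no further assessments
followed, or the patient died.  Without progression, PFS is censored at new
anticancer therapy or at the last assessment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = ["ClinicalEvents", "TimepointAssessment", "SurvivalRecord",
           "ImagingMetricSeries", "classify_lesions", "spd",
           "timepoint_response", "assess_series", "derive_pfs_os",
           "MEASURABLE_MIN_MM", "PR_THRESHOLD", "PD_THRESHOLD"]

MEASURABLE_MIN_MM = 10.0   # both diameters at least this for a target lesion
PR_THRESHOLD = -0.50       # SPD change vs baseline
PD_THRESHOLD = 0.25        # SPD change vs nadir

_ORDER = {"CR": 0, "PR": 1, "SD": 2, "PD": 3}


class ResponseInputError(ValueError):
    pass


class RecordConsistencyError(ValueError):
    pass


@dataclass(frozen=True)
class ClinicalEvents:
    """Per-patient clinical event dates (days from first treatment day)."""

    patient_id: str = ""
    clinical_pd_day: int | None = None
    death_day: int | None = None
    new_therapy_day: int | None = None
    #: protocol treatment stop reason, e.g. "clinical_progression", "eot",
    #: "patient_decision"
    treatment_stop_reason: str | None = None
    last_contact_day: int | None = None
    pseudo_progression_day: int | None = None


@dataclass
class TimepointAssessment:
    visit_day: int
    spd_mm2: float
    pct_change_baseline: float
    pct_change_nadir: float
    preliminary: str
    confirmed: str | None = None
    confirmation_pending: bool = False
    pseudo_progression: bool = False
    new_measurable_lesion: bool = False
    new_nonmeasurable_lesion: bool = False

    @property
    def effective(self) -> str:
        """Preliminary response with pseudo-progression PDs voided to SD."""
        if self.preliminary == "PD" and self.pseudo_progression:
            return "SD"
        return self.preliminary


@dataclass
class ImagingMetricSeries:
    """Scalar advanced-MRI summaries per visit (e.g. rCBV, FTB-high, ADC).

    Map computation happens upstream; this only tracks per-visit scalar
    values and their percent change from the baseline visit.
    """

    metric: str
    visit_days: list[int]
    values: list[float]

    def __post_init__(self) -> None:
        if len(self.visit_days) != len(self.values):
            raise ResponseInputError(f"{self.metric}: days/values length mismatch")
        if not self.visit_days:
            raise ResponseInputError(f"{self.metric}: empty series")
        if list(self.visit_days) != sorted(self.visit_days):
            raise ResponseInputError(f"{self.metric}: unordered visit days")

    def pct_change_from_baseline(self) -> list[float]:
        base = self.values[0]
        if base == 0:
            raise ResponseInputError(
                f"{self.metric}: zero baseline value, change undefined")
        return [100.0 * (v - base) / base for v in self.values]

    def best_change(self) -> float:
        """Largest-magnitude change from baseline over follow-up visits."""
        changes = self.pct_change_from_baseline()[1:]
        if not changes:
            return 0.0
        return max(changes, key=abs)


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    endpoint: str            # "PFS" | "OS"
    time_days: int
    event: bool
    reason: str

    def __post_init__(self) -> None:
        if self.time_days <= 0:
            raise RecordConsistencyError(
                f"{self.patient_id}: non-positive {self.endpoint} "
                f"time {self.time_days}")


def classify_lesions(baseline: pd.DataFrame) -> dict:
    """Assign TL/NTL roles from the baseline scan.

    A lesion is measurable — hence a target lesion — iff both perpendicular
    diameters are >= 10 mm (inclusive).  Returns ``{lesion_id: "TL"|"NTL"}``.
    """
    if len(baseline) == 0:
        raise ResponseInputError("no baseline scan")
    roles = {}
    for _, row in baseline.iterrows():
        measurable = (row["present_flag"]
                      and row["diam1_mm"] >= MEASURABLE_MIN_MM
                      and row["diam2_mm"] >= MEASURABLE_MIN_MM)
        roles[row["lesion_id"]] = "TL" if measurable else "NTL"
    return roles


def spd(lesions: pd.DataFrame) -> float:
    """SPD in mm^2 over target-lesion rows of one timepoint; absent rows add 0."""
    total = 0.0
    for _, row in lesions.iterrows():
        if not row["present_flag"]:
            if row["diam1_mm"] != 0 or row["diam2_mm"] != 0:
                raise ResponseInputError(
                    f"lesion {row['lesion_id']}: absent but non-zero diameters")
            continue
        if pd.isna(row["diam1_mm"]) or pd.isna(row["diam2_mm"]):
            raise ResponseInputError(
                f"lesion {row['lesion_id']}: missing measurement without "
                f"absent flag")
        total += float(row["diam1_mm"]) * float(row["diam2_mm"])
    return total


def timepoint_response(baseline_spd: float, nadir_spd: float, current_spd: float,
                       *, all_tl_absent: bool = False,
                       any_ntl_present: bool = True,
                       ntl_progression: bool = False,
                       new_measurable: bool = False,
                       new_nonmeasurable: bool = False,
                       has_tl: bool = True) -> str:
    """Classify one scan as CR / PR / SD / PD.

    ``nadir_spd`` is the minimum SPD up to (not including) this scan.
    NTL state and new non-measurable lesions matter only when the target
    lesions are completely resolved.
    """
    if new_measurable:
        return "PD"
    if not has_tl:
        # patient followed on NTLs only (no measurable disease at baseline)
        if not any_ntl_present:
            return "CR"
        return "PD" if ntl_progression else "SD"
    if baseline_spd <= 0:
        raise ResponseInputError("baseline SPD must be > 0 when TLs exist")
    if nadir_spd > 0 and (current_spd - nadir_spd) / nadir_spd >= PD_THRESHOLD:
        return "PD"
    if all_tl_absent:
        if not any_ntl_present:
            # complete response unless spoiled by a new non-measurable lesion
            return "PD" if new_nonmeasurable else "CR"
        if ntl_progression:
            return "PD"
    if (current_spd - baseline_spd) / baseline_spd <= PR_THRESHOLD:
        return "PR"
    return "SD"


def _visit_frame(lesions: pd.DataFrame, day: int) -> pd.DataFrame:
    return lesions[lesions["visit_day"] == day]


def assess_series(lesions: pd.DataFrame, *,
                  roles: dict | None = None,
                  pseudo_progression_days: Iterable[int] = (),
                  min_confirm_gap_days: int = 42) -> list[TimepointAssessment]:
    """Run the mRANO state machine over one patient's serial lesion table.

    ``lesions`` columns: visit_day, lesion_id, diam1_mm, diam2_mm,
    present_flag.  The earliest visit is the baseline.  Lesions first seen
    after baseline are new lesions (measurable if both diameters >= 10 mm).
    Returns one assessment per post-baseline visit, with confirmation
    resolved against later scans.
    """
    days = sorted(lesions["visit_day"].unique())
    if list(lesions["visit_day"]) != sorted(lesions["visit_day"]):
        lesions = lesions.sort_values(["visit_day", "lesion_id"])
    if len(days) == 0:
        raise ResponseInputError("empty lesion table")
    baseline_day = days[0]
    base = _visit_frame(lesions, baseline_day)
    if roles is None:
        roles = classify_lesions(base)
    tl_ids = {l for l, r in roles.items() if r == "TL"}
    has_tl = len(tl_ids) > 0
    pseudo_days = set(pseudo_progression_days)

    baseline_spd = spd(base[base["lesion_id"].isin(tl_ids)]) if has_tl else 0.0
    nadir = baseline_spd
    seen_cr = False
    assessments: list[TimepointAssessment] = []
    known = set(base["lesion_id"])

    for day in days[1:]:
        visit = _visit_frame(lesions, day)
        tl_rows = visit[visit["lesion_id"].isin(tl_ids)]
        missing_tl = tl_ids - set(tl_rows["lesion_id"])
        if missing_tl:
            raise ResponseInputError(
                f"day {day}: target lesions {sorted(missing_tl)} unreported "
                f"without absent flag")
        cur = spd(tl_rows) if has_tl else 0.0

        new_rows = visit[~visit["lesion_id"].isin(known) & visit["present_flag"]]
        new_measurable = bool(((new_rows["diam1_mm"] >= MEASURABLE_MIN_MM)
                               & (new_rows["diam2_mm"] >= MEASURABLE_MIN_MM)).any())
        new_nonmeasurable = bool(len(new_rows) > 0) and not new_measurable
        known |= set(visit["lesion_id"])

        ntl_rows = visit[visit["lesion_id"].isin(
            {l for l, r in roles.items() if r == "NTL"})]
        any_ntl_present = bool(ntl_rows["present_flag"].any())
        all_tl_absent = has_tl and bool(~tl_rows["present_flag"].any())

        prelim = timepoint_response(
            baseline_spd, nadir, cur,
            all_tl_absent=all_tl_absent, any_ntl_present=any_ntl_present,
            new_measurable=new_measurable, new_nonmeasurable=new_nonmeasurable,
            has_tl=has_tl)

        pct_base = (100.0 * (cur - baseline_spd) / baseline_spd
                    if baseline_spd > 0 else (0.0 if not has_tl else -100.0))
        pct_nadir = (100.0 * (cur - nadir) / nadir if nadir > 0 else 0.0)
        assessments.append(TimepointAssessment(
            visit_day=int(day), spd_mm2=cur,
            pct_change_baseline=pct_base, pct_change_nadir=pct_nadir,
            preliminary=prelim,
            pseudo_progression=(prelim == "PD" and day in pseudo_days),
            new_measurable_lesion=new_measurable,
            new_nonmeasurable_lesion=new_nonmeasurable))
        nadir = min(nadir, cur)

    _resolve_confirmation(assessments, min_confirm_gap_days)
    return assessments


def _resolve_confirmation(assessments: list[TimepointAssessment],
                          gap: int) -> None:
    """Confirm preliminary CR/PR/PD against the next qualifying scan."""
    for i, a in enumerate(assessments):
        state = a.effective
        if state not in ("CR", "PR", "PD"):
            continue
        confirmers = [b for b in assessments[i + 1:]
                      if b.visit_day >= a.visit_day + gap]
        if not confirmers:
            a.confirmation_pending = True
            continue
        nxt = confirmers[0].effective
        ok = {"PD": nxt == "PD",
              "PR": nxt in ("PR", "CR"),
              "CR": nxt == "CR"}[state]
        if ok:
            a.confirmed = state


def best_response(assessments: Sequence[TimepointAssessment]) -> dict:
    """Best on-treatment response: extreme SPD change vs baseline and the
    best confirmation-aware category reached (CR > PR > SD > PD)."""
    if not assessments:
        return {"best_pct_change": 0.0, "best_category": "SD"}
    best_pct = min(a.pct_change_baseline for a in assessments)
    cats = []
    for a in assessments:
        s = a.effective
        if s in ("CR", "PR") and a.confirmed != s:
            s = "SD"   # unconfirmed regression does not upgrade best response
        cats.append(s)
    non_pd = [c for c in cats if c != "PD"]
    best_cat = min(non_pd, key=_ORDER.get) if non_pd else "PD"
    return {"best_pct_change": best_pct, "best_category": best_cat}


def _validate_events(patient_id: str, assessments, ev: ClinicalEvents) -> None:
    days = [a.visit_day for a in assessments]
    if ev.death_day is not None:
        others = [d for d in (days + [ev.clinical_pd_day, ev.new_therapy_day])
                  if d is not None]
        bad = [d for d in others if d > ev.death_day]
        if bad:
            raise RecordConsistencyError(
                f"{patient_id}: events after death day {ev.death_day}: {bad}")


def derive_pfs_os(assessments: Sequence[TimepointAssessment],
                  events: ClinicalEvents) -> tuple[SurvivalRecord, SurvivalRecord]:
    """Derive the PFS and OS records for one patient.

    Returns ``(pfs, os)``.  See the module docstring for the rule set.
    """
    pid = events.patient_id
    _validate_events(pid, assessments, events)
    candidates: list[tuple[int, int, str]] = []   # (day, priority, reason)

    for i, a in enumerate(assessments):
        if a.effective != "PD":
            continue
        if a.confirmed == "PD":
            candidates.append((a.visit_day, 0, "confirmed_PD"))
        else:
            later = assessments[i + 1:]
            recovered = any(b.effective in ("SD", "PR", "CR") for b in later)
            if not recovered:
                qualifies = (events.treatment_stop_reason == "clinical_progression"
                             or not later
                             or events.death_day is not None)
                if qualifies:
                    candidates.append((a.visit_day, 3, "unconfirmed_PD_qualified"))

    if events.clinical_pd_day is not None:
        # clinical progression is tied to the simultaneous radiographic
        # assessment when one exists on that day
        day = events.clinical_pd_day
        candidates.append((day, 1, "clinical_PD"))

    if events.death_day is not None:
        candidates.append((events.death_day, 2, "death"))

    pfs: SurvivalRecord
    if candidates:
        day, _, reason = min(candidates)
        if events.new_therapy_day is not None and events.new_therapy_day < day:
            pfs = SurvivalRecord(pid, "PFS", int(events.new_therapy_day), False,
                                 "censor_new_therapy")
        else:
            pfs = SurvivalRecord(pid, "PFS", int(day), True, reason)
    elif events.new_therapy_day is not None:
        pfs = SurvivalRecord(pid, "PFS", int(events.new_therapy_day), False,
                             "censor_new_therapy")
    else:
        last = max([a.visit_day for a in assessments], default=None)
        if last is None:
            last = events.last_contact_day
        if last is None:
            raise RecordConsistencyError(f"{pid}: nothing to censor PFS at")
        pfs = SurvivalRecord(pid, "PFS", int(last), False, "censor_eot_followup")

    if events.death_day is not None:
        os_rec = SurvivalRecord(pid, "OS", int(events.death_day), True, "death")
    else:
        last = events.last_contact_day
        if last is None:
            last = max((a.visit_day for a in assessments), default=None)
        if last is None:
            raise RecordConsistencyError(f"{pid}: nothing to censor OS at")
        os_rec = SurvivalRecord(pid, "OS", int(last), False, "censor_alive")

    if pfs.time_days > os_rec.time_days:
        raise RecordConsistencyError(
            f"{pid}: PFS time {pfs.time_days} exceeds OS time {os_rec.time_days}")
    return pfs, os_rec
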