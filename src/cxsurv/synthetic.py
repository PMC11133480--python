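"""Synthetic trial-cohort generator.

Emulates the data a radiotherapy + CXCL12-aptamer dose-escalation cohort
produces, with the statistical structure the downstream analyses assume:

* segmented mIF cell tables whose type-specific CXCL12+ rates are ordered
  endothelial > pericyte > macrophage/microglia > glioma;
* an arm-dependent biomarker-outcome link: under the APTAMER arm the PFS
  log-hazard is ``log(h0) + eg12_beta * z`` where ``z`` is the patient's
  latent EG12 on the standard scale, under SOC PFS is independent of EG12;
* scripted piecewise-exponential lesion courses with multiplicative
  log-normal measurement noise, on a q8w scan schedule;
* dose-proportional drug plasma accumulation ``C(t) = C_ss (1 - e^{-kt})``
  to a steady state above the 1.5 uM pharmacologic threshold within about a
  week, in excess of the CXCL12 target level;
* adverse-event listings with realistic CTCAE grade / relationship mixtures.

Everything is deterministic given the config seed; per-patient substreams
are keyed by (seed, arm, patient index) so adding patients never perturbs
existing ones.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gating import MARKER_COLUMNS

__all__ = ["SynthConfig", "PatientTruth", "LesionScript", "CohortBundle",
           "generate_cohort", "generate_cell_table", "generate_lesion_series",
           "generate_pk_series", "generate_survival_truth"]

CELL_TYPES = ["endothelial", "pericyte", "mphi_microglia", "glioma", "other"]

#: marker column each cell type expresses strongly (besides DAPI)
_OWN_MARKER = {"endothelial": "cd31_nc", "pericyte": "asma_nc",
               "mphi_microglia": "cd68_nc", "glioma": "gfap_nc"}

_AE_TERMS = ["headache", "fatigue", "nausea", "alt_elevation", "seizure",
             "leukocytosis", "constipation", "dizziness", "pyrexia", "edema"]
# grade / relationship mixtures follow a typical RT + aptamer safety profile
_AE_GRADE_P = np.array([87, 59, 24, 1, 0], dtype=float) / 171.0
_AE_REL = ["none", "gbm", "rt", "rt_gbm", "drug", "drug_gbm", "drug_rt",
           "drug_rt_gbm"]
_AE_REL_P = np.array([81, 43, 20, 6, 13, 4, 2, 2], dtype=float) / 171.0


class ConfigurationError(ValueError):
    pass


def _beta_ab(mean: float, kappa: float) -> tuple[float, float]:
    return mean * kappa, (1.0 - mean) * kappa


@dataclass(frozen=True)
class SynthConfig:
    """Full parameterization of the synthetic cohort generator."""

    seed: int = 0
    n_patients: int = 10
    arm: str = "APTAMER"                       # "APTAMER" | "SOC"
    cell_type_mix: dict = field(default_factory=lambda: {
        "endothelial": 0.04, "pericyte": 0.04, "mphi_microglia": 0.24,
        "glioma": 0.48, "other": 0.20})
    cxcl12_rate: dict = field(default_factory=lambda: {
        "endothelial": 0.55, "pericyte": 0.35, "mphi_microglia": 0.20,
        "glioma": 0.10, "other": 0.08})
    n_cells: int = 10_000
    eg12_beta: float = -1.5                    # log-HR per SD latent EG12
    baseline_hazard: float = math.log(2) / 174.0   # events/day
    censor_rate: float = 0.10                  # new-therapy censoring for PFS
    visit_interval_days: int = 56
    n_visits: int = 7
    pk_dose_mg_per_week: int | None = None     # None: escalation blocks 3/3/rest
    pk_k_per_day: float = math.log(2) / 1.75
    pk_css_200mg_um: float = 2.0               # dose-proportional plateau
    pk_cxcl12_plateau_um: float = 0.5
    lesion_noise_sigma: float = 0.05
    pseudo_progression_rate: float = 0.10
    ntl_only_rate: float = 0.10                # patients with no measurable TL
    post_progression_median_days: float = 215.0
    rate_kappa: float = 150.0                  # patient-level Beta concentration

    def __post_init__(self) -> None:
        if abs(sum(self.cell_type_mix.values()) - 1.0) > 1e-9:
            raise ConfigurationError("cell_type_mix must sum to 1")
        if set(self.cell_type_mix) != set(CELL_TYPES):
            raise ConfigurationError(f"cell_type_mix keys must be {CELL_TYPES}")
        for name, val in list(self.cxcl12_rate.items()) + [
                ("censor_rate", self.censor_rate),
                ("pseudo_progression_rate", self.pseudo_progression_rate)]:
            if not 0.0 <= val <= 1.0:
                raise ConfigurationError(f"probability {name}={val} outside [0,1]")
        if any(not 0.0 <= v <= 1.0 for v in self.cell_type_mix.values()):
            raise ConfigurationError("mix fractions must lie in [0,1]")
        if self.visit_interval_days <= 0:
            raise ConfigurationError("visit_interval_days must be > 0")
        if self.arm not in ("APTAMER", "SOC"):
            raise ConfigurationError(f"unknown arm {self.arm!r}")
        if self.pk_dose_mg_per_week not in (None, 200, 400, 600):
            raise ConfigurationError("dose must be one of 200, 400, 600 mg/week")


@dataclass
class LesionScript:
    """Piecewise-exponential diameter course for one lesion.

    ``d(t) = d0 * exp(shrink_rate * min(t, regrow_day)
                      + grow_rate * max(0, t - regrow_day))``
    A lesion whose diameters fall below 1 mm is scripted as disappeared
    (absent record, zero diameters).
    """

    lesion_id: str
    d1_mm: float
    d2_mm: float
    shrink_rate: float        # per day, <= 0
    grow_rate: float          # per day, >= 0
    regrow_day: float
    bump_day: float | None = None   # transient pseudo-progression bump

    def diameters(self, day: float) -> tuple[float, float]:
        lg = (self.shrink_rate * min(day, self.regrow_day)
              + self.grow_rate * max(0.0, day - self.regrow_day))
        f = math.exp(lg)
        if self.bump_day is not None and abs(day - self.bump_day) < 1.0:
            f *= 1.30
        return self.d1_mm * f, self.d2_mm * f


@dataclass
class PatientTruth:
    """Ground truth for one simulated patient."""

    patient_id: str
    arm: str
    dose_mg: int
    e12_rate: float
    p12_rate: float
    m12_rate: float
    g12_rate: float
    other_rate: float
    latent_eg12_z: float
    pfs_true_days: float
    os_true_days: float
    censor_day: float | None
    pseudo_progression_day: float | None
    lesions: list[LesionScript] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.pfs_true_days > self.os_true_days:
            raise ConfigurationError(
                f"{self.patient_id}: true PFS exceeds true OS")

    def as_dict(self) -> dict:
        return {
            "patient_id": self.patient_id, "arm": self.arm,
            "dose_mg": self.dose_mg,
            "e12_rate": self.e12_rate, "p12_rate": self.p12_rate,
            "m12_rate": self.m12_rate, "g12_rate": self.g12_rate,
            "latent_eg12_z": self.latent_eg12_z,
            "pfs_true_days": self.pfs_true_days,
            "os_true_days": self.os_true_days,
            "censor_day": self.censor_day,
            "pseudo_progression_day": self.pseudo_progression_day,
        }


@dataclass
class CohortBundle:
    config: SynthConfig
    truths: list[PatientTruth]
    cells: pd.DataFrame
    lesions: pd.DataFrame
    clinical_events: pd.DataFrame
    pk: pd.DataFrame
    aes: pd.DataFrame
    survival: pd.DataFrame


def _stable_id(patient_id: str) -> int:
    """Process-independent integer key for a patient id."""
    return zlib.crc32(patient_id.encode()) % 2**31


def _patient_rng(config: SynthConfig, idx: int) -> np.random.Generator:
    arm_code = 0 if config.arm == "APTAMER" else 1
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(arm_code, idx)))


def _latent_sd(config: SynthConfig, cell_type: str) -> float:
    mean = config.cxcl12_rate[cell_type]
    a, b = _beta_ab(mean, config.rate_kappa)
    return math.sqrt(a * b / ((a + b) ** 2 * (a + b + 1)))


def _dose_for(config: SynthConfig, idx: int) -> int:
    if config.pk_dose_mg_per_week is not None:
        return config.pk_dose_mg_per_week
    return 200 if idx < 3 else (400 if idx < 6 else 600)


def generate_patient_truth(config: SynthConfig, idx: int) -> PatientTruth:
    rng = _patient_rng(config, idx)
    rates = {}
    for ct in CELL_TYPES:
        a, b = _beta_ab(config.cxcl12_rate[ct], config.rate_kappa)
        rates[ct] = float(rng.beta(a, b))
    z_e = (rates["endothelial"] - config.cxcl12_rate["endothelial"]) \
        / _latent_sd(config, "endothelial")
    z_g = (rates["glioma"] - config.cxcl12_rate["glioma"]) \
        / _latent_sd(config, "glioma")
    z = (z_e + z_g) / math.sqrt(2.0)

    log_h = math.log(config.baseline_hazard)
    if config.arm == "APTAMER":
        log_h += config.eg12_beta * z
    pfs = float(rng.exponential(1.0 / math.exp(log_h)))
    pfs = max(pfs, 30.0)      # progression before the first follow-up scan
    post = float(rng.exponential(
        config.post_progression_median_days / math.log(2)))
    os_days = pfs + max(post, 14.0)

    censor_day = None
    if rng.random() < config.censor_rate:
        censor_day = float(np.round(rng.uniform(0.3, 0.9) * pfs))
        censor_day = max(censor_day, 7.0)

    pseudo_day = None
    interval = config.visit_interval_days
    if rng.random() < config.pseudo_progression_rate and pfs > 3 * interval:
        pseudo_day = float(interval * 2)

    # lesion course: regrowth starts one scan interval before true progression
    # so the first >=+25%-above-nadir scan lands near pfs_true
    ntl_only = rng.random() < config.ntl_only_rate
    n_lesions = 1 if ntl_only else int(rng.integers(1, 4))
    regrow = max(pfs - interval, 1.0)
    lesions = []
    for j in range(n_lesions):
        if ntl_only:
            d1 = float(rng.uniform(4.0, 9.5))
            d2 = float(rng.uniform(4.0, 9.5))
        else:
            d1 = float(rng.uniform(12.0, 40.0))
            d2 = float(rng.uniform(10.0, d1))
        shrink = -float(rng.uniform(0.0, 0.006))
        grow = float(rng.uniform(0.004, 0.008))
        lesions.append(LesionScript(
            lesion_id=f"L{j + 1}", d1_mm=d1, d2_mm=d2,
            shrink_rate=shrink, grow_rate=grow, regrow_day=regrow,
            bump_day=pseudo_day))

    return PatientTruth(
        patient_id=f"{config.arm[:1]}{idx + 1:03d}", arm=config.arm,
        dose_mg=_dose_for(config, idx),
        e12_rate=rates["endothelial"], p12_rate=rates["pericyte"],
        m12_rate=rates["mphi_microglia"], g12_rate=rates["glioma"],
        other_rate=rates["other"], latent_eg12_z=z,
        pfs_true_days=pfs, os_true_days=os_days, censor_day=censor_day,
        pseudo_progression_day=pseudo_day, lesions=lesions)


def generate_cell_table(truth: PatientTruth, config: SynthConfig,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw a segmented cell table for one patient.

    Completeness fractions come from Beta distributions: Beta(8, 2) for a
    cell's own markers (passes its gate with probability > 0.95 at default
    thresholds) and Beta(1, 19) otherwise (gate leak < 2% per marker).
    CXCL12 positivity is Bernoulli with the patient's type-specific rate.
    A ``true_type`` column carries the ground truth.
    """
    if config.n_cells < 1:
        raise ConfigurationError("n_cells must be >= 1")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed,
                                   spawn_key=(2, _stable_id(truth.patient_id))))
    n = config.n_cells
    mix = np.array([config.cell_type_mix[ct] for ct in CELL_TYPES])
    types = rng.choice(len(CELL_TYPES), size=n, p=mix)
    type_names = np.array(CELL_TYPES)[types]

    area = np.exp(rng.normal(math.log(60.0), 0.8, size=n))
    data = {"patient_id": truth.patient_id,
            "cell_id": [f"{truth.patient_id}_c{i}" for i in range(n)],
            "nuclear_area_um2": area,
            "dapi_nuc": rng.beta(8, 2, size=n)}

    hi_a, hi_b = 8.0, 2.0
    lo_a, lo_b = 1.0, 19.0
    for marker in ("cd31_nc", "asma_nc", "cd68_nc", "gfap_nc"):
        own = np.array([_OWN_MARKER.get(ct) == marker for ct in type_names])
        vals = rng.beta(lo_a, lo_b, size=n)
        vals[own] = rng.beta(hi_a, hi_b, size=int(own.sum()))
        data[marker] = vals

    patient_rate = {"endothelial": truth.e12_rate, "pericyte": truth.p12_rate,
                    "mphi_microglia": truth.m12_rate, "glioma": truth.g12_rate,
                    "other": truth.other_rate}
    p_pos = np.array([patient_rate[ct] for ct in type_names])
    cx_pos = rng.random(n) < p_pos
    cx = rng.beta(lo_a, lo_b, size=n)
    cx[cx_pos] = rng.beta(hi_a, hi_b, size=int(cx_pos.sum()))
    data["cxcl12_nc"] = cx

    ki_pos = rng.random(n) < 0.20
    ki = rng.beta(lo_a, lo_b, size=n)
    ki[ki_pos] = rng.beta(hi_a, hi_b, size=int(ki_pos.sum()))
    data["ki67_nuc"] = ki

    df = pd.DataFrame(data)
    df["true_type"] = type_names
    return df


def generate_lesion_series(truth: PatientTruth, schedule,
                           config: SynthConfig | None = None,
                           rng: np.random.Generator | None = None
                           ) -> pd.DataFrame:
    """Evaluate the patient's scripted lesion course on a visit schedule.

    ``schedule`` must be strictly increasing and start at day 0 (baseline).
    Multiplicative log-normal noise (sigma = config.lesion_noise_sigma) is
    applied per measurement; diameters scripted below 1 mm give an absent
    record with zero diameters.
    """
    schedule = list(schedule)
    if schedule != sorted(set(schedule)):
        raise ValueError("visit schedule must be strictly increasing")
    if not schedule or schedule[0] != 0:
        raise ValueError("schedule must start at day 0 (baseline)")
    config = config or SynthConfig()
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed,
                                   spawn_key=(3, _stable_id(truth.patient_id))))
    sigma = config.lesion_noise_sigma
    rows = []
    for les in truth.lesions:
        for day in schedule:
            d1, d2 = les.diameters(day)
            if sigma > 0:
                d1 *= math.exp(rng.normal(0.0, sigma))
                d2 *= math.exp(rng.normal(0.0, sigma))
            present = min(d1, d2) >= 1.0
            rows.append({"patient_id": truth.patient_id, "visit_day": int(day),
                         "lesion_id": les.lesion_id,
                         "diam1_mm": round(d1, 1) if present else 0.0,
                         "diam2_mm": round(d2, 1) if present else 0.0,
                         "present_flag": present})
    return pd.DataFrame(rows)


def generate_pk_series(config: SynthConfig, days, dose_mg: int | None = None,
                       rng: np.random.Generator | None = None,
                       noise_sigma: float = 0.0) -> pd.DataFrame:
    """Drug and CXCL12 plasma series: saturating accumulation to a plateau.

    ``C(t) = C_ss(dose) * (1 - exp(-k t))`` with ``C_ss`` proportional to
    dose (``pk_css_200mg_um`` at 200 mg/week) and ``k = ln 2 / 1.75`` per
    day by default, i.e. within 10% of steady state after about a week.  The
    CXCL12 target accumulates to a plateau below the drug level.
    """
    days = np.asarray(list(days), dtype=float)
    if (days < 0).any():
        raise ValueError("days must be >= 0")
    dose = dose_mg if dose_mg is not None else (config.pk_dose_mg_per_week or 600)
    css = config.pk_css_200mg_um * dose / 200.0
    drug = css * (1.0 - np.exp(-config.pk_k_per_day * days))
    cx = config.pk_cxcl12_plateau_um * (1.0 - np.exp(-config.pk_k_per_day * days / 2.0))
    if noise_sigma > 0:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        drug = drug * np.exp(rng.normal(0.0, noise_sigma, size=len(days)))
        cx = cx * np.exp(rng.normal(0.0, noise_sigma, size=len(days)))
    return pd.DataFrame({"day": days, "drug_um": drug, "cxcl12_um": cx,
                         "dose_mg": dose})


def _survival_rows(truth: PatientTruth) -> list[dict]:
    if truth.censor_day is not None:
        pfs_time, pfs_event, reason = truth.censor_day, False, "censor_new_therapy"
    else:
        pfs_time, pfs_event, reason = truth.pfs_true_days, True, "confirmed_PD"
    return [
        {"patient_id": truth.patient_id, "endpoint": "PFS",
         "time_days": float(pfs_time), "event": pfs_event, "reason": reason},
        {"patient_id": truth.patient_id, "endpoint": "OS",
         "time_days": float(truth.os_true_days), "event": True,
         "reason": "death"},
    ]


def generate_survival_truth(config: SynthConfig) -> pd.DataFrame:
    """Survival truth table only (fast path for calibration studies)."""
    rows = []
    for i in range(config.n_patients):
        truth = generate_patient_truth(config, i)
        for r in _survival_rows(truth):
            r["latent_eg12_z"] = truth.latent_eg12_z
            r["arm"] = truth.arm
            rows.append(r)
    return pd.DataFrame(rows)


def _generate_aes(truth: PatientTruth, rng: np.random.Generator) -> list[dict]:
    n = int(rng.poisson(17))
    rows = []
    for _ in range(n):
        rows.append({
            "patient_id": truth.patient_id,
            "term": str(rng.choice(_AE_TERMS)),
            "grade": int(rng.choice(np.arange(1, 6), p=_AE_GRADE_P)),
            "relationship": str(rng.choice(_AE_REL, p=_AE_REL_P)),
        })
    return rows


def generate_cohort(config: SynthConfig) -> CohortBundle:
    """Generate a full cohort bundle (deterministic given config.seed)."""
    truths, cell_frames, lesion_frames = [], [], []
    event_rows, pk_frames, ae_rows, surv_rows = [], [], [], []
    interval = config.visit_interval_days

    for i in range(config.n_patients):
        truth = generate_patient_truth(config, i)
        truths.append(truth)
        # data stream independent of the truth stream
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(10, i)))

        if config.n_cells > 0:
            cell_frames.append(generate_cell_table(truth, config, rng))

        death = float(np.round(truth.os_true_days))
        follow_up = truth.censor_day if truth.censor_day is not None \
            else min(truth.os_true_days, truth.pfs_true_days + 2 * interval)
        schedule = [0] + [d for d in range(interval, config.n_visits * interval + 1,
                                           interval)
                          if d <= min(follow_up + interval, death - 1)]
        lesion_frames.append(generate_lesion_series(truth, schedule, config, rng))

        last_scan = schedule[-1] if len(schedule) > 1 else interval
        event_rows.append({
            "patient_id": truth.patient_id,
            "clinical_pd_day": None,
            "death_day": death,
            "new_therapy_day": truth.censor_day,
            "treatment_stop_reason": "eot",
            "last_contact_day": death,
            "pseudo_progression_day": truth.pseudo_progression_day,
        })

        pk_days = np.arange(0, min(float(last_scan), 180.0) + 1, 3.5)
        pk = generate_pk_series(config, pk_days, dose_mg=truth.dose_mg,
                                rng=rng, noise_sigma=0.02)
        pk.insert(0, "patient_id", truth.patient_id)
        pk_frames.append(pk)

        ae_rows.extend(_generate_aes(truth, rng))
        surv_rows.extend(_survival_rows(truth))

    cells = (pd.concat(cell_frames, ignore_index=True)
             if cell_frames else pd.DataFrame(
                 columns=["patient_id", "cell_id", "nuclear_area_um2",
                          *MARKER_COLUMNS, "true_type"]))
    return CohortBundle(
        config=config, truths=truths, cells=cells,
        lesions=pd.concat(lesion_frames, ignore_index=True),
        clinical_events=pd.DataFrame(event_rows),
        pk=pd.concat(pk_frames, ignore_index=True),
        aes=pd.DataFrame(ae_rows),
        survival=pd.DataFrame(surv_rows))
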