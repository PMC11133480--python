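"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written directly from the documented rules, with its own
literal constants and no imports from the package's logic, so agreement is
a genuine two-route check.
"""

from __future__ import annotations

import math


# --- gating: literal per-cell predicate ------------------------------------

def gate_cell_oracle(area, dapi, cxcl12, cd31, asma, cd68, gfap, ki67):
    """Return (kept, phenotype set, cxcl12_pos) per the documented settings."""
    kept = dapi >= 0.15 and 12.0 <= area <= 1000.0
    if not kept:
        return False, set(), False
    cd31_p = cd31 >= 0.30
    asma_p = asma >= 0.35
    cd68_p = cd68 >= 0.20
    gfap_p = gfap >= 0.30
    phenos = set()
    if cd31_p:
        phenos.add("endothelial")
    if asma_p and not cd31_p:
        phenos.add("pericyte")
    if cd68_p:
        phenos.add("mphi_microglia")
    if gfap_p and not cd68_p and not cd31_p and not asma_p:
        phenos.add("glioma")
    return True, phenos, cxcl12 >= 0.35


# --- Kaplan-Meier / log-rank by hand risk tables ---------------------------

def km_oracle(times, events):
    """Product-limit estimate; returns list of (time, S(time))."""
    s = 1.0
    out = []
    distinct = sorted({t for t, e in zip(times, events) if e})
    for t in distinct:
        n_at_risk = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ei and ti == t)
        s *= 1.0 - d / n_at_risk
        out.append((t, s))
    return out


def logrank_oracle(times_a, events_a, times_b, events_b):
    """Chi-square statistic from explicit per-event-time risk tables."""
    all_t = sorted({t for t, e in zip(list(times_a) + list(times_b),
                                      list(events_a) + list(events_b)) if e})
    o_minus_e = 0.0
    var = 0.0
    for t in all_t:
        n_a = sum(1 for ti in times_a if ti >= t)
        n_b = sum(1 for ti in times_b if ti >= t)
        d_a = sum(1 for ti, ei in zip(times_a, events_a) if ei and ti == t)
        d_b = sum(1 for ti, ei in zip(times_b, events_b) if ei and ti == t)
        n = n_a + n_b
        d = d_a + d_b
        if n < 2:
            continue
        e_a = d * n_a / n
        o_minus_e += d_a - e_a
        var += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1) if n > 1 else 0.0
    return o_minus_e ** 2 / var if var > 0 else 0.0


# --- Spearman by the rank-and-Pearson formula ------------------------------

def spearman_oracle(x, y):
    def ranks(v):
        order = sorted(range(len(v)), key=lambda i: v[i])
        r = [0.0] * len(v)
        i = 0
        while i < len(order):
            j = i
            while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
                j += 1
            avg = (i + j) / 2.0 + 1.0
            for k in range(i, j + 1):
                r[order[k]] = avg
            i = j + 1
        return r
    rx, ry = ranks(list(x)), ranks(list(y))
    mx = sum(rx) / len(rx)
    my = sum(ry) / len(ry)
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                    * sum((b - my) ** 2 for b in ry))
    return num / den


# --- mRANO rule list, transcribed literally --------------------------------

def mrano_states_oracle(spd_seq):
    """Preliminary states for a TL-only course given (day, spd) pairs.

    Baseline is the first entry; PD is >= +25% vs the nadir of strictly
    earlier scans, PR <= -50% vs baseline, computed by literal arithmetic.
    """
    base_day, base = spd_seq[0]
    states = []
    nadir = base
    for day, s in spd_seq[1:]:
        if nadir > 0 and (s - nadir) / nadir >= 0.25:
            st = "PD"
        elif (s - base) / base <= -0.50:
            st = "CR" if s == 0 else "PR"
        else:
            st = "SD"
        states.append((day, st))
        nadir = min(nadir, s)
    return states


def pfs_oracle(scan_states, *, clinical_pd_day=None, death_day=None,
               new_therapy_day=None, stop_for_clinical_progression=False,
               confirm_gap=42):
    """PFS (time, event, reason) from the written event-derivation rules.

    ``scan_states``: list of (day, state) post-baseline preliminary states.
    """
    candidates = []
    for i, (day, st) in enumerate(scan_states):
        if st != "PD":
            continue
        later = scan_states[i + 1:]
        confirmers = [(d, s) for d, s in later if d >= day + confirm_gap]
        confirmed = bool(confirmers) and confirmers[0][1] == "PD"
        if confirmed:
            candidates.append((day, 0, "confirmed_PD"))
        else:
            recovered = any(s in ("SD", "PR", "CR") for _, s in later)
            if not recovered and (stop_for_clinical_progression
                                  or not later or death_day is not None):
                candidates.append((day, 3, "unconfirmed_PD_qualified"))
    if clinical_pd_day is not None:
        candidates.append((clinical_pd_day, 1, "clinical_PD"))
    if death_day is not None:
        candidates.append((death_day, 2, "death"))
    if candidates:
        day, _, reason = min(candidates)
        if new_therapy_day is not None and new_therapy_day < day:
            return new_therapy_day, False, "censor_new_therapy"
        return day, True, reason
    if new_therapy_day is not None:
        return new_therapy_day, False, "censor_new_therapy"
    return scan_states[-1][0], False, "censor_eot_followup"


# --- modified 3+3 escalation, hand-enumerated ------------------------------

def escalation_oracle(level_index, n_levels, patients, dlts):
    """Literal protocol reading: >=2 DLT among 3-6 -> stop; 0/3 -> escalate
    (top dose tolerated -> RP2D); 1/3 -> expand to six; tolerated 6 ->
    escalate/RP2D; otherwise keep enrolling."""
    top = level_index == n_levels - 1
    if dlts >= 2:
        return "stop_declare_MTD"
    if patients == 3 and dlts == 0:
        return "declare_RP2D" if top else "escalate"
    if patients == 3 and dlts == 1:
        return "expand_same_level"
    if patients == 6 and dlts <= 1:
        return "declare_RP2D" if top else "escalate"
    return "continue_enrollment"
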