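import numpy as np
import pandas as pd
import pytest


def make_cell(cell_id="c0", area=50.0, dapi=0.9, cxcl12=0.0, cd31=0.0,
              asma=0.0, cd68=0.0, gfap=0.0, ki67=0.0, patient_id="P1"):
    return {"patient_id": patient_id, "cell_id": cell_id,
            "nuclear_area_um2": area, "dapi_nuc": dapi, "cxcl12_nc": cxcl12,
            "cd31_nc": cd31, "asma_nc": asma, "cd68_nc": cd68,
            "gfap_nc": gfap, "ki67_nuc": ki67}


def cells_df(rows):
    return pd.DataFrame(rows)


@pytest.fixture
def toy_cells():
    """Six cells: 2 endothelial (1 CXCL12+), 2 glioma (none +), 1 Mphi (+),
    1 ungated (+)."""
    return cells_df([
        make_cell("e1", cd31=0.8, cxcl12=0.9),
        make_cell("e2", cd31=0.8, cxcl12=0.0),
        make_cell("g1", gfap=0.8, cxcl12=0.0),
        make_cell("g2", gfap=0.8, cxcl12=0.1),
        make_cell("m1", cd68=0.8, cxcl12=0.9),
        make_cell("u1", cxcl12=0.9),
    ])


def random_cells(n, seed=0):
    """Valid random cell table exercising every threshold neighbourhood."""
    rng = np.random.default_rng(seed)
    return cells_df([
        make_cell(f"c{i}",
                  area=float(rng.uniform(5, 1100)),
                  dapi=float(rng.uniform(0, 1)),
                  cxcl12=float(rng.uniform(0, 1)),
                  cd31=float(rng.uniform(0, 1)),
                  asma=float(rng.uniform(0, 1)),
                  cd68=float(rng.uniform(0, 1)),
                  gfap=float(rng.uniform(0, 1)),
                  ki67=float(rng.uniform(0, 1)))
        for i in range(n)])


def lesion_rows(patient_id, course):
    """Build a one-lesion-per-entry lesion table.

    ``course``: {lesion_id: [(day, d1, d2), ...]}; d1 of None marks absent.
    """
    rows = []
    for lid, seq in course.items():
        for day, d1, d2 in seq:
            absent = d1 is None
            rows.append({"patient_id": patient_id, "visit_day": day,
                         "lesion_id": lid,
                         "diam1_mm": 0.0 if absent else d1,
                         "diam2_mm": 0.0 if absent else d2,
                         "present_flag": not absent})
    return pd.DataFrame(rows)


def survival_df(times, events, endpoint="PFS"):
    return pd.DataFrame({
        "patient_id": [f"p{i}" for i in range(len(times))],
        "endpoint": endpoint, "time_days": times, "event": events,
        "reason": ["confirmed_PD" if e else "censor_eot_followup"
                   for e in events]})
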