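"""Phenotype gating of segmented multiplexed-immunofluorescence cell tables.

Starts from per-cell records exported by a nuclear-segmentation pipeline
(one row per cell: nuclear area plus a nucleus/cytoplasm "% completeness"
fraction per marker) and produces per-sample CXCL12-positive frequency
profiles for four vascular/tumor phenotypes:

* endothelial cells  (DAPI+, CD31+)                       -> E12
* pericytes          (DAPI+, a-SMA+, CD31-)               -> P12
* macrophages/microglia (DAPI+, CD68+)                    -> M12
* glioma cells       (DAPI+, GFAP+, CD68-, CD31-, a-SMA-) -> G12

E12..G12 denote the percentage of CXCL12+ cells within each phenotype.
All threshold comparisons are inclusive (``>=``). A cell may satisfy both
the endothelial and the macrophage/microglia gate; pericytes exclude
endothelial by construction and glioma excludes the other three.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd

#: canonical marker column names for cell tables
MARKER_COLUMNS = ["dapi_nuc", "cxcl12_nc", "cd31_nc", "asma_nc", "cd68_nc",
                  "gfap_nc", "ki67_nuc"]

CELL_TABLE_COLUMNS = ["patient_id", "cell_id", "nuclear_area_um2"] + MARKER_COLUMNS

PHENOTYPES = ["endothelial", "pericyte", "mphi_microglia", "glioma"]

#: phenotype -> short frequency symbol
FREQ_SYMBOL = {"endothelial": "E12", "pericyte": "P12",
               "mphi_microglia": "M12", "glioma": "G12"}


class CellValidationError(ValueError):
    """A cell record violates the schema (negative area, fraction outside [0, 1])."""


@dataclass(frozen=True)
class MarkerThresholds:
    """Positivity thresholds (completeness fractions) and the nuclear-size window.

    Defaults are the image-analysis settings used for 7-plex CODEX panels of
    glioblastoma tissue: a marker is positive when its nucleus(/cytoplasm)
    completeness fraction is at least the threshold, and only cells whose
    nuclear area lies inside ``area_window_um2`` (inclusive) with DAPI
    completeness >= the DAPI threshold are analysed at all.
    """

    dapi: float = 0.15
    cxcl12: float = 0.35
    cd68: float = 0.20
    cd31: float = 0.30
    ki67: float = 0.30
    asma: float = 0.35
    gfap: float = 0.30
    area_window_um2: tuple[float, float] = (12.0, 1000.0)

    def __post_init__(self) -> None:
        for name in ("dapi", "cxcl12", "cd68", "cd31", "ki67", "asma", "gfap"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"threshold {name}={v} outside (0, 1)")
        lo, hi = self.area_window_um2
        if not lo < hi:
            raise ValueError(f"area window min {lo} must be < max {hi}")

    def as_dict(self) -> dict:
        d = asdict(self)
        d["area_window_um2"] = list(self.area_window_um2)
        return d


@dataclass
class PhenotypeFrequency:
    total: int
    cxcl12_pos: int

    @property
    def fraction_pct(self) -> float:
        """CXCL12+ share in percent; NaN when the phenotype has no members."""
        if self.total == 0:
            return math.nan
        return 100.0 * self.cxcl12_pos / self.total


@dataclass
class CxFrequencyProfile:
    """Per-sample phenotype counts and CXCL12+ frequencies (percent).

    ``by_phenotype`` maps phenotype name to counts; empty phenotypes report
    their fraction as NaN (missing), never as 0, so that downstream composite
    scores do not absorb spurious zeros.
    """

    n_cells: int
    cxcl12_pos_total: int
    ki67_pos_total: int
    by_phenotype: dict[str, PhenotypeFrequency] = field(default_factory=dict)
    #: cells gated simultaneously endothelial and macrophage/microglia
    endothelial_mphi_overlap: int = 0

    @property
    def total_fraction_pct(self) -> float:
        return 100.0 * self.cxcl12_pos_total / self.n_cells

    @property
    def ki67_fraction_pct(self) -> float:
        return 100.0 * self.ki67_pos_total / self.n_cells

    def symbol(self, sym: str) -> float:
        """Frequency in percent by field symbol: E12, P12, M12 or G12."""
        inv = {v: k for k, v in FREQ_SYMBOL.items()}
        return self.by_phenotype[inv[sym]].fraction_pct

    def as_dict(self) -> dict:
        d: dict = {
            "n_cells": self.n_cells,
            "total_cxcl12_pct": self.total_fraction_pct,
            "ki67_pct": self.ki67_fraction_pct,
            "endothelial_mphi_overlap": self.endothelial_mphi_overlap,
        }
        for ph, freq in self.by_phenotype.items():
            sym = FREQ_SYMBOL[ph]
            d[f"{ph}_total"] = freq.total
            d[f"{ph}_cxcl12_pos"] = freq.cxcl12_pos
            d[sym] = freq.fraction_pct
        return d


def _validate_cells(cells: pd.DataFrame) -> None:
    missing = [c for c in CELL_TABLE_COLUMNS[2:] if c not in cells.columns]
    if missing:
        raise CellValidationError(f"cell table missing columns: {missing}")
    bad_area = cells.index[cells["nuclear_area_um2"] <= 0]
    if len(bad_area):
        ids = _ids(cells, bad_area)
        raise CellValidationError(f"non-positive nuclear area for cells {ids}")
    for m in MARKER_COLUMNS:
        col = cells[m].to_numpy(dtype=float)
        bad = cells.index[(col < 0) | (col > 1) | ~np.isfinite(col)]
        if len(bad):
            raise CellValidationError(
                f"marker {m} outside [0, 1] for cells {_ids(cells, bad)}")


def _ids(cells: pd.DataFrame, idx) -> list:
    if "cell_id" in cells.columns:
        return cells.loc[idx, "cell_id"].tolist()[:5]
    return list(idx[:5])


def filter_cells(cells: pd.DataFrame,
                 thr: MarkerThresholds | None = None) -> pd.DataFrame:
    """Keep analysable cells: DAPI-positive nuclei inside the size window.

    Bounds are inclusive on both the DAPI threshold and the area window.
    Row order is preserved; the result is a copy.
    """
    thr = thr or MarkerThresholds()
    _validate_cells(cells)
    lo, hi = thr.area_window_um2
    keep = ((cells["dapi_nuc"] >= thr.dapi)
            & (cells["nuclear_area_um2"] >= lo)
            & (cells["nuclear_area_um2"] <= hi))
    return cells.loc[keep].copy()


def call_positivity(cells: pd.DataFrame,
                    thr: MarkerThresholds | None = None) -> pd.DataFrame:
    """Per-marker boolean positivity flags (inclusive thresholds).

    Accepts a table of filtered cells; returns a DataFrame of booleans with
    columns named after the markers and the same index.
    """
    thr = thr or MarkerThresholds()
    mapping = {"dapi_nuc": thr.dapi, "cxcl12_nc": thr.cxcl12, "cd31_nc": thr.cd31,
               "asma_nc": thr.asma, "cd68_nc": thr.cd68, "gfap_nc": thr.gfap,
               "ki67_nuc": thr.ki67}
    flags = {}
    for col, t in mapping.items():
        if col not in cells.columns:
            raise CellValidationError(f"unknown/missing marker column {col!r}")
        flags[col.split("_")[0]] = cells[col].to_numpy(dtype=float) >= t
    return pd.DataFrame(flags, index=cells.index)


def assign_phenotypes(flags: pd.DataFrame) -> pd.DataFrame:
    """Evaluate the phenotype gates on per-marker flags.

    Returns a boolean DataFrame with one column per phenotype.  Every gate a
    cell satisfies is reported (a CD31+CD68+ cell is both endothelial and
    macrophage/microglia); a cell may satisfy none.
    """
    cd31, asma, cd68, gfap = (flags["cd31"], flags["asma"], flags["cd68"],
                              flags["gfap"])
    return pd.DataFrame({
        "endothelial": cd31,
        "pericyte": asma & ~cd31,
        "mphi_microglia": cd68,
        "glioma": gfap & ~cd68 & ~cd31 & ~asma,
    }, index=flags.index)


def cxcl12_frequencies(cells: pd.DataFrame,
                       thr: MarkerThresholds | None = None,
                       *, prefiltered: bool = False) -> CxFrequencyProfile:
    """Compute the per-sample CXCL12+ frequency profile (E12, P12, M12, G12).

    Parameters
    ----------
    cells
        Cell table.  Unless ``prefiltered`` is True the DAPI/area filter is
        applied first.
    thr
        Marker thresholds; defaults to the panel defaults.

    The total CXCL12+ fraction uses all filtered cells as denominator,
    gated or not.  Phenotypes with zero members report NaN fractions.
    """
    thr = thr or MarkerThresholds()
    filt = cells if prefiltered else filter_cells(cells, thr)
    if len(filt) == 0:
        raise ValueError("no cells after filtering")
    flags = call_positivity(filt, thr)
    gates = assign_phenotypes(flags)
    cx = flags["cxcl12"].to_numpy()

    profile = CxFrequencyProfile(
        n_cells=int(len(filt)),
        cxcl12_pos_total=int(cx.sum()),
        ki67_pos_total=int(flags["ki67"].sum()),
        endothelial_mphi_overlap=int(
            (gates["endothelial"] & gates["mphi_microglia"]).sum()),
    )
    for ph in PHENOTYPES:
        g = gates[ph].to_numpy()
        profile.by_phenotype[ph] = PhenotypeFrequency(
            total=int(g.sum()), cxcl12_pos=int((g & cx).sum()))
    return profile


def profiles_by_patient(cells: pd.DataFrame,
                        thr: MarkerThresholds | None = None) -> pd.DataFrame:
    """Gate a multi-patient cell table; one profile row per ``patient_id``."""
    if "patient_id" not in cells.columns:
        raise CellValidationError("cell table lacks a patient_id column")
    rows = []
    for pid, sub in cells.groupby("patient_id", sort=True):
        prof = cxcl12_frequencies(sub, thr)
        row: dict = {"patient_id": pid}
        row.update(prof.as_dict())
        rows.append(row)
    return pd.DataFrame(rows)
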