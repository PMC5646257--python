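"""Founder-population back-calculation for biofilm reactors.

Given an areal protein measurement on the colonisable surfaces of a
CDC-style biofilm reactor, the chain

    areal protein (ug/cm2)
      -> total biofilm cells        (surface area, protein per cell)
      -> biofilm-producing cells    (subtract the non-producer fraction)
      -> founder cells              (divide by 2^doublings)

back-projects how many biofilm-competent cells the inoculum must have
contained, assuming exponential doubling at the measured generation
time and no loss of producers in the effluent (so the estimate is a
lower bound).  Also provides chemostat dilution-rate utilities and a
log-linear growth-rate fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import CensoredInputError, DataError

__all__ = [
    "ReactorGeometry",
    "ConversionConstants",
    "BackCalcInput",
    "BackCalcResult",
    "DilutionSpec",
    "total_area",
    "cells_from_protein",
    "producer_cells",
    "count_doublings",
    "back_calculate_founders",
    "dilution_rate",
    "infer_volume",
    "washout_expected",
    "fit_generation_time",
    "two_sig_figs",
]

UG_TO_FG = 1e9  # 1 ug = 1e9 fg


@dataclass(frozen=True)
class ReactorGeometry:
    """Colonisable surfaces: the vessel wall plus removable glass slides."""

    vessel_area: float = 231.0  # cm2
    slide_area: float = 15.0  # cm2 per slide
    n_slides: int = 7

    def __post_init__(self):
        if self.vessel_area <= 0 or self.slide_area <= 0 or self.n_slides < 0:
            raise DataError("reactor geometry must be positive")


@dataclass(frozen=True)
class ConversionConstants:
    protein_per_cell: float = 278.0  # fg/cell
    detection_limit: float = 1.3  # ug protein / cm2

    def __post_init__(self):
        if self.protein_per_cell <= 0 or self.detection_limit <= 0:
            raise DataError("conversion constants must be positive")


@dataclass(frozen=True)
class BackCalcInput:
    areal_protein: float  # ug/cm2
    elapsed_time: float  # h of total residence (continuous phase + batch lead)
    generation_time: float  # h
    non_producer_fraction: float = 0.0

    def __post_init__(self):
        if self.areal_protein <= 0 or self.elapsed_time < 0 or self.generation_time <= 0:
            raise DataError("back-calculation inputs must be positive")
        if not 0 <= self.non_producer_fraction < 1:
            raise DataError("non_producer_fraction must be in [0, 1)")


@dataclass(frozen=True)
class BackCalcResult:
    total_cells: float
    producer_cells: float
    doublings: float
    founder_cells: float
    rounding_mode: str

    def as_dict(self) -> dict:
        return {
            "total_cells": self.total_cells,
            "producer_cells": self.producer_cells,
            "doublings": self.doublings,
            "founder_cells": self.founder_cells,
            "rounding_mode": self.rounding_mode,
            "total_cells_2sf": two_sig_figs(self.total_cells),
            "producer_cells_2sf": two_sig_figs(self.producer_cells),
            "founder_cells_2sf": two_sig_figs(self.founder_cells),
        }


@dataclass(frozen=True)
class DilutionSpec:
    flow_rate: float  # ml/min
    working_volume: float  # ml

    @property
    def dilution_rate(self) -> float:
        return dilution_rate(self.flow_rate, self.working_volume)


def two_sig_figs(x: float) -> str:
    """Format a count the way reactor estimates are reported, e.g. '1.6e+04'."""
    return f"{float(f'{x:.1e}'):.1e}"


def total_area(geom: ReactorGeometry) -> float:
    return geom.vessel_area + geom.n_slides * geom.slide_area


def cells_from_protein(areal_protein: float, area: float, constants: ConversionConstants) -> float:
    """Cell count equivalent to an areal protein density over an area."""
    if areal_protein < 0 or area <= 0:
        raise DataError("areal protein and area must be positive")
    return areal_protein * area * UG_TO_FG / constants.protein_per_cell


def producer_cells(total: float, non_producer_fraction: float) -> float:
    if not 0 <= non_producer_fraction < 1:
        raise DataError("non_producer_fraction must be in [0, 1)")
    return total * (1.0 - non_producer_fraction)


def count_doublings(elapsed_time: float, generation_time: float, mode: str = "nearest") -> float:
    """Number of doublings in ``elapsed_time``.

    ``nearest`` (default) and ``floor`` give integers; ``continuous``
    returns the raw ratio.
    """
    if elapsed_time < 0 or generation_time <= 0:
        raise DataError("times must be positive")
    ratio = elapsed_time / generation_time
    if mode == "nearest":
        return float(round(ratio))
    if mode == "floor":
        return float(math.floor(ratio))
    if mode == "continuous":
        return ratio
    raise DataError(f"unknown rounding mode {mode!r}")


def back_calculate_founders(
    inp: BackCalcInput,
    geom: ReactorGeometry | None = None,
    constants: ConversionConstants | None = None,
    rounding: str = "nearest",
) -> BackCalcResult:
    """Full back-calculation chain with all intermediates reported.

    Refuses censored inputs (areal protein below the detection limit):
    a sub-detection measurement is not a quantified value and imputing
    one would silently bias the founder estimate.
    """
    geom = geom or ReactorGeometry()
    constants = constants or ConversionConstants()
    if inp.areal_protein < constants.detection_limit:
        raise CensoredInputError(
            f"areal protein {inp.areal_protein} ug/cm2 is below the detection limit "
            f"({constants.detection_limit} ug/cm2); censored observations cannot seed inference"
        )
    area = total_area(geom)
    total = cells_from_protein(inp.areal_protein, area, constants)
    producers = producer_cells(total, inp.non_producer_fraction)
    doublings = count_doublings(inp.elapsed_time, inp.generation_time, rounding)
    founders = producers / 2.0**doublings
    return BackCalcResult(total, producers, doublings, founders, rounding)


def dilution_rate(flow: float, volume: float) -> float:
    """D (1/h) from a flow in ml/min and a working volume in ml."""
    if flow <= 0 or volume <= 0:
        raise DataError("flow and volume must be positive")
    return flow * 60.0 / volume


def infer_volume(flow: float, D: float) -> float:
    if flow <= 0 or D <= 0:
        raise DataError("flow and dilution rate must be positive")
    return flow * 60.0 / D


def washout_expected(D: float, generation_time: float) -> bool:
    """Advisory: planktonic cells wash out when D exceeds their maximal
    specific growth rate ln(2)/generation_time."""
    if D <= 0 or generation_time <= 0:
        raise DataError("inputs must be positive")
    return D > math.log(2.0) / generation_time


def fit_generation_time(
    times: Sequence[float],
    od: Sequence[float],
    window: Optional[tuple[int, int]] = None,
    od_floor: float = 0.0,
    min_points: int = 3,
) -> float:
    """Generation time from a batch growth curve.

    Fits ln(OD) vs time on either a user-selected index window
    ``(start, stop)`` (half-open) or, by default, the contiguous window
    of at least ``min_points`` usable points maximising R^2 (longest
    window on ties).  Returns ln(2)/slope in hours.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise DataError("times and od must be equal-length 1-D sequences")
    usable = y > od_floor
    if window is not None:
        lo, hi = window
        idx = np.arange(lo, hi)
        if np.any(~usable[idx]):
            raise DataError("non-positive OD inside the selected window")
        if len(idx) < min_points:
            raise DataError(f"fewer than {min_points} points in the selected window")
        windows = [idx]
    else:
        if usable.sum() < min_points:
            raise DataError(f"fewer than {min_points} usable points")
        windows = []
        # contiguous runs of usable points, then every sub-window of each run
        run_start = None
        for i, ok in enumerate([*usable, False]):
            if ok and run_start is None:
                run_start = i
            elif not ok and run_start is not None:
                run = np.arange(run_start, i)
                for a in range(len(run)):
                    for b in range(a + min_points, len(run) + 1):
                        windows.append(run[a:b])
                run_start = None
        if not windows:
            raise DataError(f"fewer than {min_points} usable points")

    best = None
    for idx in windows:
        res = stats.linregress(t[idx], np.log(y[idx]))
        r2 = res.rvalue**2
        if np.isnan(r2):
            continue
        score = (r2, len(idx), -idx[0])
        if best is None or score > best[0]:
            best = (score, res.slope)
    if best is None:
        raise DataError("no window with measurable growth (flat or degenerate OD series)")
    slope = best[1]
    if slope <= 0:
        raise DataError("no growth detected (non-positive slope of ln OD vs time)")
    return math.log(2.0) / slope
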