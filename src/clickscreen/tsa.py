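"""Thermal shift assay (DSF) analysis: Tm extraction, per-plate shifts,
robust statistics and hit calling.

Ligand binding stabilises (or destabilises) a protein, shifting its melting
temperature Tm.  Per plate, each compound's shift is

    dTm = Tm(compound well) - Tm(reference),

with the reference taken as the median Tm of usable control wells on the
same plate.  A compound is a primary hit when

    |dTm| >= MED(dTm) + k * RSD(dTm)   and   |dTm| >= floor,

where MED and RSD are the median and robust standard deviation of the
sample shifts on that plate (controls excluded), k defaults to 3, and the
floor (default 0.5 degC) suppresses statistically-significant-but-tiny
shifts on very quiet plates.  RSD is the scaled median absolute deviation,
c * median(|x - median(x)|) with c = 1.4826 (the consistency constant that
makes the MAD estimate the standard deviation under normality); the
constant is configurable because "robust standard deviation" admits other
estimators.

Two Tm extraction methods are provided: the maximum of dF/dT on a
Savitzky-Golay-smoothed curve (fast, model-free) and a two-state Boltzmann
sigmoid fit F(T) = base + amp / (1 + exp((Tm - T)/slope)) (sub-grid
precision, the default).
"""

from __future__ import annotations


from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.signal import savgol_filter

__all__ = [
    "MeltCurve",
    "TmResult",
    "ShiftTable",
    "extract_tm",
    "compute_shifts",
    "robust_stats",
    "call_hits",
    "analyze_plate",
    "analyze_screen",
    "boltzmann",
]

MIN_POINTS = 20


@dataclass
class MeltCurve:
    plate_id: str
    well: str
    compound_id: str
    role: Literal["sample", "control"]
    temperatures: np.ndarray  # degC, strictly increasing
    fluorescence: np.ndarray
    concentration_uM: float | None = None

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.temperatures.size != self.fluorescence.size:
            raise ValueError(f"{self.well}: temperature/fluorescence length mismatch")
        if self.temperatures.size < MIN_POINTS:
            raise ValueError(
                f"{self.well}: {self.temperatures.size} points, need >= {MIN_POINTS}"
            )
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValueError(f"{self.well}: temperatures not strictly increasing")
        if np.any(~np.isfinite(self.fluorescence)):
            raise ValueError(f"{self.well}: missing fluorescence values")


@dataclass
class TmResult:
    tm: float
    method: str
    quality: float
    usable: bool
    reason: str = ""


@dataclass
class ShiftTable:
    plate_id: str
    delta_tm: dict[str, float]  # compound -> shift (degC), usable samples only
    excluded: dict[str, str] = field(default_factory=dict)
    med: float | None = None
    rsd: float | None = None
    k: float = 3.0
    floor: float = 0.5
    hits: dict[str, bool] = field(default_factory=dict)
    direction: dict[str, str] = field(default_factory=dict)

    @property
    def threshold(self) -> float:
        if self.med is None or self.rsd is None:
            raise ValueError("robust stats not yet computed")
        return max(self.med + self.k * self.rsd, self.floor)

    def hit_ids(self, direction: str | None = None) -> list[str]:
        ids = [c for c, h in self.hits.items() if h]
        if direction is not None:
            ids = [c for c in ids if self.direction[c] == direction]
        return sorted(ids)


def boltzmann(T, base, amp, tm, slope):
    """Two-state sigmoid melt model."""
    return base + amp / (1.0 + np.exp((tm - T) / slope))


def _derivative_tm(temps: np.ndarray, fluor: np.ndarray, window: int, order: int):
    smooth = savgol_filter(fluor, min(window, len(fluor) // 2 * 2 - 1), order)
    dfdt = np.gradient(smooth, temps)
    idx = int(np.argmax(dfdt))
    # signal-to-noise of the peak against the plate-free derivative baseline
    med = np.median(dfdt)
    mad = np.median(np.abs(dfdt - med))
    snr = (dfdt[idx] - med) / (1.4826 * mad + 1e-12)
    if idx in (0, len(temps) - 1):
        return temps[idx], snr, False, "derivative maximum on grid boundary"
    # parabolic refinement for sub-grid precision
    y0, y1, y2 = dfdt[idx - 1], dfdt[idx], dfdt[idx + 1]
    denom = y0 - 2 * y1 + y2
    shift = 0.5 * (y0 - y2) / denom if abs(denom) > 1e-15 else 0.0
    shift = float(np.clip(shift, -1, 1))
    step = temps[idx + 1] - temps[idx] if shift >= 0 else temps[idx] - temps[idx - 1]
    tm = float(temps[idx] + shift * step)
    if snr < 6.0:
        return tm, snr, False, "no resolvable transition (low derivative SNR)"
    return tm, snr, True, ""


def _boltzmann_tm(temps: np.ndarray, fluor: np.ndarray, window: int, order: int):
    lo, hi = float(np.min(fluor)), float(np.max(fluor))
    amp0 = hi - lo
    tm0, snr, _, _ = _derivative_tm(temps, fluor, window, order)
    if amp0 <= 0 or snr < 6.0:
        return float(tm0), 0.0, False, "no resolvable transition"
    p0 = (lo, amp0, tm0, 1.0)
    try:
        popt, _ = curve_fit(
            boltzmann,
            temps,
            fluor,
            p0=p0,
            bounds=(
                (-np.inf, 1e-12, temps[0], 1e-3),
                (np.inf, np.inf, temps[-1], (temps[-1] - temps[0]) / 2),
            ),
            maxfev=5000,
        )
    except RuntimeError:
        return float(tm0), 0.0, False, "sigmoid fit did not converge"
    base, amp, tm, slope = popt
    resid = fluor - boltzmann(temps, *popt)
    quality = float(amp / (np.std(resid) + 1e-12))
    usable = temps[0] < tm < temps[-1] and quality > 3.0
    reason = "" if usable else "fitted Tm at grid boundary or poor fit"
    return float(tm), quality, usable, reason


def extract_tm(
    curve: MeltCurve,
    method: Literal["derivative", "boltzmann"] = "boltzmann",
    *,
    smooth_window: int = 7,
    smooth_order: int = 3,
) -> TmResult:
    """Melting temperature of one well.

    ``derivative``: temperature of the maximum of dF/dT after smoothing
    (moving polynomial filter, window 7, order 3 by default), refined by
    parabolic interpolation.  ``boltzmann``: Tm parameter of the two-state
    sigmoid fit, seeded from the derivative estimate.  Curves whose
    transition sits on a grid boundary, or which show no transition at all,
    come back with ``usable=False``.
    """
    if method == "derivative":
        tm, q, usable, reason = _derivative_tm(
            curve.temperatures, curve.fluorescence, smooth_window, smooth_order
        )
    elif method == "boltzmann":
        tm, q, usable, reason = _boltzmann_tm(
            curve.temperatures, curve.fluorescence, smooth_window, smooth_order
        )
    else:
        raise ValueError(f"unknown method {method!r}")
    return TmResult(tm=tm, method=method, quality=float(q), usable=usable, reason=reason)


def robust_stats(shifts: Sequence[float], *, c: float = 1.4826) -> tuple[float, float]:
    """Median and scaled-MAD robust standard deviation of sample shifts.

    Requires at least 4 values: below that the MAD is too degenerate to set
    a plate threshold.
    """
    x = np.asarray(shifts, dtype=float)
    if x.size < 4:
        raise ValueError(f"robust_stats: {x.size} shifts, need >= 4 (plate too sparse)")
    med = float(np.median(x))
    rsd = float(c * np.median(np.abs(x - med)))
    return med, rsd


def compute_shifts(
    plate_id: str,
    sample_tms: dict[str, TmResult],
    control_tms: Sequence[TmResult],
) -> ShiftTable:
    """Per-compound dTm against the plate reference (median usable control Tm)."""
    usable_controls = [r.tm for r in control_tms if r.usable]
    if not usable_controls:
        raise ValueError(f"plate {plate_id}: no usable control wells")
    reference = float(np.median(usable_controls))
    table = ShiftTable(plate_id=plate_id, delta_tm={})
    for cid, res in sample_tms.items():
        if res.usable:
            table.delta_tm[cid] = res.tm - reference
        else:
            table.excluded[cid] = res.reason or "unusable melt curve"
    return table


def call_hits(
    table: ShiftTable,
    *,
    k: float = 3.0,
    floor: float = 0.5,
    c: float = 1.4826,
    on_absolute: bool = False,
) -> ShiftTable:
    """Flag hits with the robust per-plate rule.

    hit  <=>  |dTm| >= MED + k*RSD  and  |dTm| >= floor.  MED/RSD are taken
    over the signed sample shifts by default; ``on_absolute=True`` computes
    them over |dTm| instead (sensitivity analysis).  Controls never enter
    the statistics and are never flagged.
    """
    shifts = np.array(list(table.delta_tm.values()), dtype=float)
    basis = np.abs(shifts) if on_absolute else shifts
    med, rsd = robust_stats(basis, c=c)
    table.med, table.rsd, table.k, table.floor = med, rsd, k, floor
    cutoff = med + k * rsd
    for cid, d in table.delta_tm.items():
        table.hits[cid] = bool(abs(d) >= cutoff and abs(d) >= floor)
        table.direction[cid] = "positive" if d >= 0 else "negative"
    return table


def analyze_plate(
    curves: Sequence[MeltCurve],
    *,
    method: Literal["derivative", "boltzmann"] = "boltzmann",
    k: float = 3.0,
    floor: float = 0.5,
    c: float = 1.4826,
) -> ShiftTable:
    """Full single-plate reduction: Tm per well, shifts, robust threshold, hits."""
    plate_ids = {cv.plate_id for cv in curves}
    if len(plate_ids) != 1:
        raise ValueError(f"analyze_plate expects one plate, got {sorted(plate_ids)}")
    samples: dict[str, TmResult] = {}
    controls: list[TmResult] = []
    for cv in curves:
        res = extract_tm(cv, method)
        if cv.role == "control":
            controls.append(res)
        else:
            samples[cv.compound_id] = res
    table = compute_shifts(plate_ids.pop(), samples, controls)
    return call_hits(table, k=k, floor=floor, c=c)


def curves_from_frame(df: pd.DataFrame) -> list[MeltCurve]:
    """Build MeltCurve objects from a long-format table.

    Expected columns: plate, well, compound_id, role, temperature_C,
    fluorescence (concentration_uM optional).
    """
    curves = []
    keys = ["plate", "well", "compound_id", "role"]
    for (plate, well, cid, role), g in df.groupby(keys, sort=False):
        g = g.sort_values("temperature_C")
        conc = (
            float(g["concentration_uM"].iloc[0])
            if "concentration_uM" in g.columns
            else None
        )
        curves.append(
            MeltCurve(
                plate_id=str(plate),
                well=str(well),
                compound_id=str(cid),
                role=str(role),  # type: ignore[arg-type]
                temperatures=g["temperature_C"].to_numpy(),
                fluorescence=g["fluorescence"].to_numpy(),
                concentration_uM=conc,
            )
        )
    return curves


def analyze_screen(
    df: pd.DataFrame,
    *,
    method: Literal["derivative", "boltzmann"] = "boltzmann",
    k: float = 3.0,
    floor: float = 0.5,
    c: float = 1.4826,
) -> dict[str, ShiftTable]:
    """Analyze every plate in a long-format screen table independently."""
    out: dict[str, ShiftTable] = {}
    for plate, g in df.groupby("plate", sort=False):
        out[str(plate)] = analyze_plate(
            curves_from_frame(g), method=method, k=k, floor=floor, c=c
        )
    return out


def shift_table_frame(table: ShiftTable) -> pd.DataFrame:
    rows = [
        {
            "plate": table.plate_id,
            "compound_id": cid,
            "delta_tm_C": d,
            "hit": table.hits.get(cid, False),
            "direction": table.direction.get(cid, ""),
            "med_C": table.med,
            "rsd_C": table.rsd,
            "threshold_C": table.threshold,
        }
        for cid, d in sorted(table.delta_tm.items())
    ]
    return pd.DataFrame(rows)


def primary_hits(tables: Sequence[ShiftTable]) -> dict[str, str]:
    """Union hit calls over screening conditions (e.g. the two concentrations).

    A compound is a primary hit when flagged in at least one run; its
    direction is taken from the run with the largest |dTm|.
    """
    best: dict[str, tuple[float, str]] = {}
    for t in tables:
        for cid in t.hit_ids():
            d = t.delta_tm[cid]
            if cid not in best or abs(d) > abs(best[cid][0]):
                best[cid] = (d, t.direction[cid])
    return {cid: direction for cid, (_, direction) in sorted(best.items())}
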