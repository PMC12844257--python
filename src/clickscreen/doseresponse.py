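"""Esterase-assay reduction and four-parameter logistic (4PL) IC50 fitting.

Carbonic anhydrase activity is followed through the hydrolysis of
p-nitrophenyl acetate (absorbance vs. time); the initial linear rate of each
well is reduced to percent inhibition against no-inhibitor and background
controls, and the 10-point, 3-fold titration (200 uM down to 0.01 uM,
quadruplicate by default) is fitted with

    y(x) = bottom + (top - bottom) / (1 + (IC50 / x)^hill)

IC50 is optimised on the log10 scale for conditioning, with multi-start over
Hill slopes {0.5, 1, 2}.  Replicates are fitted as pooled points by default;
a mean-per-concentration option exists.  Compounds whose response never
rises are reported as non-inhibiting ("IC50 > top concentration") rather
than given a meaningless extrapolated fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

__all__ = [
    "KineticTrace",
    "DoseResponse",
    "PotencyFit",
    "serial_dilution",
    "initial_rate",
    "percent_inhibition",
    "fit_ic50",
    "four_pl",
]

CLAMP_RANGE = (-20.0, 120.0)


@dataclass
class KineticTrace:
    well: str
    compound_id: str
    concentration_uM: float
    times: np.ndarray  # seconds, strictly increasing
    absorbance: np.ndarray  # AU
    role: str = "sample"  # sample | no_inhibitor_control | background

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.size < 5:
            raise ValueError(f"{self.well}: {self.times.size} time points, need >= 5")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(f"{self.well}: times not strictly increasing")


@dataclass
class DoseResponse:
    compound_id: str
    concentrations_uM: np.ndarray  # one entry per measured point (pooled reps)
    inhibition_percent: np.ndarray
    n_replicates: int = 1
    clamped: int = 0

    def __post_init__(self) -> None:
        self.concentrations_uM = np.asarray(self.concentrations_uM, dtype=float)
        self.inhibition_percent = np.asarray(self.inhibition_percent, dtype=float)
        if self.concentrations_uM.size != self.inhibition_percent.size:
            raise ValueError("concentration/response length mismatch")

    def summary(self) -> "tuple[np.ndarray, np.ndarray, np.ndarray]":
        """(unique concentrations desc, mean, sd) per concentration."""
        concs = np.unique(self.concentrations_uM)[::-1]
        means = np.array(
            [self.inhibition_percent[self.concentrations_uM == c].mean() for c in concs]
        )
        sds = np.array(
            [self.inhibition_percent[self.concentrations_uM == c].std(ddof=0) for c in concs]
        )
        return concs, means, sds


@dataclass
class PotencyFit:
    compound_id: str
    ic50_uM: float | None
    hill: float | None
    top: float | None
    bottom: float | None
    converged: bool
    reason: str = ""
    ci95_uM: tuple[float, float] | None = None
    rmse: float | None = None

    def report_potency(self, top_concentration_uM: float | None = None) -> str:
        if self.converged and self.ic50_uM is not None:
            return f"IC50 = {self.ic50_uM:.3g} uM"
        if top_concentration_uM is not None:
            return f"IC50 > {top_concentration_uM:g} uM ({self.reason})"
        return f"not determined ({self.reason})"


def serial_dilution(top: float, factor: float, points: int) -> np.ndarray:
    """Geometric titration ladder [top, top/factor, ..., top/factor^(points-1)]."""
    if top <= 0:
        raise ValueError("top concentration must be positive")
    if factor <= 1:
        raise ValueError("dilution factor must exceed 1")
    if points < 2:
        raise ValueError("a titration needs at least 2 points")
    return top / factor ** np.arange(points, dtype=float)


def initial_rate(trace: KineticTrace, window_s: float = 120.0) -> float:
    """Least-squares slope (AU/s) of the initial linear window."""
    mask = trace.times <= trace.times[0] + window_s
    if mask.sum() < 3:
        raise ValueError(
            f"{trace.well}: {int(mask.sum())} points in the initial window, need >= 3"
        )
    res = linregress(trace.times[mask], trace.absorbance[mask])
    return float(res.slope)


def percent_inhibition(
    rate_sample: float, rate_control: float, rate_background: float
) -> tuple[float, bool]:
    """Percent inhibition with clamping to [-20, 120].

    Returns (value, clamped_flag).  The background-corrected control window
    must be positive.
    """
    if rate_control <= rate_background:
        raise ValueError("control rate must exceed background rate")
    raw = 100.0 * (1.0 - (rate_sample - rate_background) / (rate_control - rate_background))
    lo, hi = CLAMP_RANGE
    return float(min(max(raw, lo), hi)), not lo <= raw <= hi


def four_pl(x, top, bottom, log_ic50, hill):
    """4PL on log-scaled potency: y = bottom + (top-bottom)/(1+(ic50/x)^hill)."""
    return bottom + (top - bottom) / (1.0 + (10.0 ** log_ic50 / x) ** hill)


def reduce_traces(
    traces: Sequence[KineticTrace], *, window_s: float = 120.0
) -> dict[str, DoseResponse]:
    """Kinetic wells -> per-compound dose-response tables.

    Control and background rates are averaged over their wells; each sample
    well becomes one (concentration, inhibition) point.
    """
    controls = [initial_rate(t, window_s) for t in traces if t.role == "no_inhibitor_control"]
    backgrounds = [initial_rate(t, window_s) for t in traces if t.role == "background"]
    if not controls:
        raise ValueError("no no_inhibitor_control wells")
    r0 = float(np.mean(controls))
    rb = float(np.mean(backgrounds)) if backgrounds else 0.0
    per: dict[str, list[tuple[float, float, bool]]] = {}
    for t in traces:
        if t.role != "sample":
            continue
        inh, clamped = percent_inhibition(initial_rate(t, window_s), r0, rb)
        per.setdefault(t.compound_id, []).append((t.concentration_uM, inh, clamped))
    out = {}
    for cid, rows in per.items():
        concs = np.array([r[0] for r in rows])
        n_rep = int(np.max(np.unique(concs, return_counts=True)[1]))
        out[cid] = DoseResponse(
            compound_id=cid,
            concentrations_uM=concs,
            inhibition_percent=np.array([r[1] for r in rows]),
            n_replicates=n_rep,
            clamped=sum(r[2] for r in rows),
        )
    return out


def fit_ic50(
    dr: DoseResponse,
    *,
    use_means: bool = False,
    hill_starts: Sequence[float] = (0.5, 1.0, 2.0),
    min_span: float = 15.0,
    min_top_response: float = 25.0,
) -> PotencyFit:
    """Fit the 4PL and return the potency estimate.

    Requires >= 6 distinct concentrations.  Fits all replicate points pooled
    (``use_means=True`` fits per-concentration means instead).  The fit is
    declared non-converged when the response shows no dose dependence
    (range < ``min_span`` percentage points, or mean inhibition at the top
    concentration below ``min_top_response`` — an IC50 above the tested
    range cannot be read off the curve), when the optimiser fails from
    every start, or when the fitted IC50 escapes the guard band
    [min_conc/10, max_conc*10].
    """
    if np.unique(dr.concentrations_uM).size < 6:
        raise ValueError(
            f"{dr.compound_id}: {np.unique(dr.concentrations_uM).size} distinct "
            "concentrations, need >= 6"
        )
    if use_means:
        x, y, _ = dr.summary()
    else:
        x, y = dr.concentrations_uM, dr.inhibition_percent

    if float(np.ptp(y)) < min_span:
        return PotencyFit(
            dr.compound_id, None, None, None, None, False, reason="no dose dependence"
        )
    top_response = float(np.mean(y[x == x.max()]))
    if top_response < min_top_response:
        return PotencyFit(
            dr.compound_id, None, None, None, None, False,
            reason="no inhibition at the top concentration",
        )

    log_lo = math.log10(x.min()) - 1.0
    log_hi = math.log10(x.max()) + 1.0
    bounds = ((0.0, -50.0, log_lo, 0.1), (150.0, 60.0, log_hi, 10.0))
    # mid-response crossing as the IC50 seed
    half = (np.max(y) + np.min(y)) / 2.0
    order = np.argsort(x)
    crossing = np.interp(half, y[order], np.log10(x[order]), period=None) if np.all(
        np.diff(y[order]) >= 0
    ) else float(np.median(np.log10(x)))

    best = None
    for hill0 in hill_starts:
        p0 = (
            float(np.clip(np.max(y), 1.0, 149.0)),
            float(np.clip(np.min(y), -49.0, 59.0)),
            float(np.clip(crossing, log_lo, log_hi)),
            hill0,
        )
        try:
            popt, pcov = curve_fit(
                four_pl, x, y, p0=p0, bounds=bounds, maxfev=10000
            )
        except RuntimeError:
            continue
        rss = float(np.sum((y - four_pl(x, *popt)) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)

    if best is None:
        return PotencyFit(
            dr.compound_id, None, None, None, None, False, reason="optimiser failed"
        )
    (top, bottom, log_ic50, hill), pcov, rss = best
    ic50 = 10.0 ** log_ic50
    rmse = math.sqrt(rss / len(y))

    se_log = math.sqrt(max(pcov[2, 2], 0.0)) if np.all(np.isfinite(pcov)) else math.inf
    if math.isfinite(se_log):
        ci = (10.0 ** (log_ic50 - 1.96 * se_log), 10.0 ** (log_ic50 + 1.96 * se_log))
    else:
        ci = None

    guard_lo, guard_hi = x.min() / 10.0, x.max() * 10.0
    converged = guard_lo <= ic50 <= guard_hi and bottom < top
    reason = "" if converged else "IC50 outside the tested range (extrapolation)"
    return PotencyFit(
        compound_id=dr.compound_id,
        ic50_uM=float(ic50),
        hill=float(hill),
        top=float(top),
        bottom=float(bottom),
        converged=bool(converged),
        reason=reason,
        ci95_uM=ci,
        rmse=rmse,
    )
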