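"""Synthetic study-data generators with known ground truth.

Every input the pipeline consumes can be generated here: building-block
sets, parallel-synthesis outcomes, DSF melt plates and dose-response
kinetics.  The generators emulate the structure of a click-chemistry
library campaign — two-state melt curves with planted Tm shifts, Bernoulli
isolation at a true success rate, a geometric titration with 4PL-shaped
inhibition — so that each analysis stage can be tested against planted
truth without any external data.

Determinism contract: every generator takes an explicit seed (or an
``numpy.random.Generator``); the same seed reproduces byte-identical
outputs.  There is no module-level random state.

The building-block pools are built by combinatorially decorating a small
set of ring scaffolds with linkers, not shipped from any database.  Each
pool entry passes ``validate_building_block`` for its role.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd

from .chem import BuildingBlock, Role, validate_building_block
from .doseresponse import serial_dilution
from .synthesis import SynthesisOutcome
from .tsa import boltzmann

__all__ = [
    "ScenarioSpec",
    "building_block_pool",
    "gen_building_blocks",
    "gen_outcomes",
    "gen_melt_plate",
    "gen_dose_kinetics",
]

# ---------------------------------------------------------------------------
# Curated-by-construction SMILES pools

_RINGS = [
    "c1ccccc1",
    "c1ccc(F)cc1",
    "c1ccc(Cl)cc1",
    "c1ccc(Br)cc1",
    "c1ccc(C)cc1",
    "c1ccc(OC)cc1",
    "c1ccc(C(F)(F)F)cc1",
    "c1ccc(C#N)cc1",
    "c1ccncc1",
    "c1ccc2ccccc2c1",
    "c1ccsc1",
    "c1ccoc1",
    "C1CCCCC1",
    "C1CCCC1",
    "C1CCC1",
]

_LINKERS = ["", "C", "CC", "CCC", "CCCC", "C(C)", "CC(C)", "CCCCC"]

# Aliphatic linkers for the sulfonamide-capped series (no "" — the group
# needs a carbon anchor distinct from the triple bond).
_SULFO_LINKERS = ["C", "CC", "CCC", "CCCC", "C(C)", "CCCCC"]
_SULFO_RING = "c1ccc(S(N)(=O)=O)cc1"


def _validated(smiles_list: list[str], role: Role) -> list[str]:
    out = []
    for smi in smiles_list:
        bb = validate_building_block(smi, role)  # raises if a template is bad
        out.append(bb.smiles)
    return out


@lru_cache(maxsize=None)
def building_block_pool() -> dict[str, list[str]]:
    """Canonical-SMILES pools keyed by kind.

    kinds: ``azide`` (plain azides), ``azide_sulfonamide`` (azido
    sulfonamides), ``alkyne`` (plain terminal alkynes),
    ``alkyne_sulfonamide`` (alkynes carrying -SO2NH2), ``acid``.
    """
    azides = [f"[N-]=[N+]=N{link}{ring}" for ring in _RINGS for link in _LINKERS]
    alkynes = [f"C#C{link}{ring}" for ring in _RINGS for link in _LINKERS]
    acids = [f"OC(=O){link}{ring}" for ring in _RINGS for link in _LINKERS]
    alkyne_sulfo = [f"C#C{link}S(N)(=O)=O" for link in _SULFO_LINKERS] + [
        f"C#C{link}{_SULFO_RING}" for link in _LINKERS
    ]
    azide_sulfo = [f"[N-]=[N+]=N{link}S(N)(=O)=O" for link in _SULFO_LINKERS] + [
        f"[N-]=[N+]=N{link}{_SULFO_RING}" for link in _LINKERS
    ]
    return {
        "azide": _validated(azides, Role.AZIDE),
        "azide_sulfonamide": _validated(azide_sulfo, Role.AZIDE),
        "alkyne": _validated(alkynes, Role.ALKYNE),
        "alkyne_sulfonamide": _validated(alkyne_sulfo, Role.ALKYNE),
        "acid": _validated(acids, Role.ACID),
    }


# ---------------------------------------------------------------------------
# Scenario


@dataclass
class ScenarioSpec:
    """All knobs of a synthetic screening campaign, with the study defaults.

    Defaults mirror the campaign structure the pipeline targets: a
    three-set combinatorial library, a ~75% synthesis success rate with
    mid-50s% isolated yields, 100-compound DSF plates carrying 5 positive
    (+3 degC) and 10 negative (-2 degC) shifters over a quiet null
    background (sd 0.15 degC), melt transitions near 55 degC on a
    25-95 degC / 0.5 degC ramp, and a 10-point 3-fold titration from
    200 uM read in quadruplicate.
    """

    seed: int = 0
    # library sizes
    n_azide: int = 8
    n_alkyne: int = 8
    n_acid: int = 8
    sulfonamide_carrier: str = "alkyne"
    # synthesis
    ssr_true: float = 75.0
    yield_mean: float = 56.0
    yield_sd: float = 15.0
    # DSF plate layout
    n_controls: int = 8
    shifters: tuple[tuple[int, float], ...] = ((5, 3.0), (10, -2.0))
    n_null: int = 85
    null_sd: float = 0.15
    # melt-curve shape
    tm0: float = 55.0
    melt_amp: float = 1.0
    melt_base: float = 0.1
    melt_slope: float = 1.2
    melt_noise_pct: float = 2.0
    temp_lo: float = 25.0
    temp_hi: float = 95.0
    temp_step: float = 0.5
    # optional post-transition aggregation decay (off by default)
    decay_per_C: float = 0.0
    # dose-response
    ic50_uM: float = 1.0
    hill: float = 1.0
    top_pct: float = 100.0
    bottom_pct: float = 0.0
    dose_noise_pct: float = 5.0
    n_replicates: int = 4
    dilution_top_uM: float = 200.0
    dilution_factor: float = 3.0
    dilution_points: int = 10

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory: no implicit global randomness")
        for name in ("n_azide", "n_alkyne", "n_acid", "n_controls", "n_null",
                     "n_replicates", "dilution_points"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("yield_sd", "null_sd", "melt_noise_pct", "dose_noise_pct"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent integer-indexed RNG stream."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, stream]))


_STREAMS = {"blocks": 1, "outcomes": 2, "melt": 3, "dose": 4}


# ---------------------------------------------------------------------------
# Generators


def gen_building_blocks(spec: ScenarioSpec) -> tuple[
    list[BuildingBlock], list[BuildingBlock], list[BuildingBlock]
]:
    """Draw azide/alkyne/acid sets without replacement from the fixture pool.

    The sulfonamide-carrier set (alkynes by default, azides for the
    reversed-library layout) is drawn from the sulfonamide-bearing pool;
    the other two sets are sulfonamide-free.
    """
    pool = building_block_pool()
    rng = spec.rng(_STREAMS["blocks"])
    if spec.sulfonamide_carrier == "alkyne":
        az_pool, alk_pool = pool["azide"], pool["alkyne_sulfonamide"]
    elif spec.sulfonamide_carrier == "azide":
        az_pool, alk_pool = pool["azide_sulfonamide"], pool["alkyne"]
    else:
        raise ValueError("sulfonamide_carrier must be 'alkyne' or 'azide'")
    sizes = {"azide": spec.n_azide, "alkyne": spec.n_alkyne, "acid": spec.n_acid}
    pools = {"azide": az_pool, "alkyne": alk_pool, "acid": pool["acid"]}
    labels = {"azide": "1", "alkyne": "2", "acid": "3"}
    out = {}
    for kind in ("azide", "alkyne", "acid"):
        if sizes[kind] > len(pools[kind]):
            raise ValueError(
                f"requested {sizes[kind]} {kind}s but the pool holds {len(pools[kind])}"
            )
        picks = rng.choice(len(pools[kind]), size=sizes[kind], replace=False)
        out[kind] = [
            validate_building_block(
                pools[kind][p], Role(kind), set_label=labels[kind], index=i + 1
            )
            for i, p in enumerate(picks)
        ]
    return out["azide"], out["alkyne"], out["acid"]


def gen_outcomes(spec: ScenarioSpec, member_ids: list[str]) -> list[SynthesisOutcome]:
    """Bernoulli isolation at ssr_true with truncated-normal yields on (0, 100]."""
    if not member_ids:
        raise ValueError("gen_outcomes: no members")
    rng = spec.rng(_STREAMS["outcomes"])
    outcomes = []
    for mid in member_ids:
        isolated = bool(rng.random() < spec.ssr_true / 100.0)
        y = None
        if isolated:
            while True:  # truncated normal on (0, 100]
                y = rng.normal(spec.yield_mean, spec.yield_sd)
                if 0.0 < y <= 100.0:
                    break
            y = float(round(y, 1))
        outcomes.append(SynthesisOutcome(mid, isolated, y))
    return outcomes


def melt_plate_truth(spec: ScenarioSpec) -> dict[str, float]:
    """Planted dTm per compound id on the synthetic plate (controls excluded)."""
    truth: dict[str, float] = {}
    w = 1
    for count, shift in spec.shifters:
        for _ in range(count):
            truth[f"cmpd-{w:03d}"] = float(shift)
            w += 1
    for _ in range(spec.n_null):
        truth[f"cmpd-{w:03d}"] = 0.0
        w += 1
    return truth


def gen_melt_plate(
    spec: ScenarioSpec, *, plate_id: str = "P1", concentration_uM: float = 20.0
) -> tuple[pd.DataFrame, dict[str, float]]:
    """One synthetic DSF plate in long format plus the planted-shift truth.

    Controls melt at tm0 exactly; planted shifters at tm0 + dTm; nulls at
    tm0 + N(0, null_sd).  Each well is a two-state sigmoid with
    multiplicative Gaussian noise (sd = melt_noise_pct% per point); an
    optional linear post-transition decay emulates dye-aggregation droop.
    """
    rng = spec.rng(_STREAMS["melt"])
    temps = np.arange(spec.temp_lo, spec.temp_hi + spec.temp_step / 2, spec.temp_step)
    truth = melt_plate_truth(spec)

    rows = []
    well_no = 1

    def emit(compound_id: str, role: str, tm: float) -> None:
        nonlocal well_no
        f = boltzmann(temps, spec.melt_base, spec.melt_amp, tm, spec.melt_slope)
        if spec.decay_per_C > 0:
            f = f - spec.decay_per_C * np.clip(temps - tm, 0.0, None) * spec.melt_amp
        f = f * (1.0 + (spec.melt_noise_pct / 100.0) * rng.standard_normal(temps.size))
        well = f"W{well_no:03d}"
        well_no += 1
        rows.append(
            pd.DataFrame(
                {
                    "plate": plate_id,
                    "well": well,
                    "compound_id": compound_id,
                    "role": role,
                    "concentration_uM": 0.0 if role == "control" else concentration_uM,
                    "temperature_C": temps,
                    "fluorescence": f,
                }
            )
        )

    for _ in range(spec.n_controls):
        emit("control", "control", spec.tm0)
    for cid, shift in truth.items():
        tm = spec.tm0 + shift if shift != 0.0 else spec.tm0 + rng.normal(0.0, spec.null_sd)
        emit(cid, "sample", tm)

    return pd.concat(rows, ignore_index=True), truth


def gen_dose_kinetics(
    spec: ScenarioSpec,
    *,
    compound_id: str = "hit-1",
    r0: float = 2.0e-3,
    background: float = 1.0e-4,
    t_max: float = 300.0,
    n_times: int = 21,
    fit_window_s: float = 120.0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Kinetic traces for one titrated compound plus controls and background.

    The true fractional activity at concentration x follows the planted 4PL;
    per-point absorbance noise is scaled so that the sd of an initial rate
    fitted on ``fit_window_s`` equals dose_noise_pct% of the control window
    (r0 - background), i.e. percent-inhibition noise has sd of about
    dose_noise_pct points.
    """
    if background >= r0:
        raise ValueError("background rate must be below the control rate")
    rng = spec.rng(_STREAMS["dose"])
    times = np.linspace(0.0, t_max, n_times)
    tw = times[times <= fit_window_s]
    # least-squares slope se = sigma / sqrt(sum (t - tbar)^2) over the window
    spread = float(np.sqrt(np.sum((tw - tw.mean()) ** 2)))
    sd_abs = (spec.dose_noise_pct / 100.0) * (r0 - background) * spread
    concs = serial_dilution(spec.dilution_top_uM, spec.dilution_factor, spec.dilution_points)

    rows = []
    well_no = 1

    def make(compound: str, role: str, conc: float, rate: float) -> None:
        nonlocal well_no
        a = 0.05 + rate * times + sd_abs * rng.standard_normal(times.size)
        rows.append(
            pd.DataFrame(
                {
                    "well": f"D{well_no:03d}",
                    "compound_id": compound,
                    "role": role,
                    "concentration_uM": conc,
                    "time_s": times,
                    "absorbance": a,
                }
            )
        )
        well_no += 1

    for _ in range(spec.n_replicates):
        make("control", "no_inhibitor_control", 0.0, r0)
        make("background", "background", 0.0, background)
    for conc in concs:
        frac_inh = (
            spec.bottom_pct
            + (spec.top_pct - spec.bottom_pct)
            / (1.0 + (spec.ic50_uM / conc) ** spec.hill)
        ) / 100.0
        rate = background + (r0 - background) * (1.0 - frac_inh)
        for _ in range(spec.n_replicates):
            make(compound_id, "sample", float(conc), rate)

    truth = {
        "ic50_uM": spec.ic50_uM,
        "hill": spec.hill,
        "top_pct": spec.top_pct,
        "bottom_pct": spec.bottom_pct,
    }
    return pd.concat(rows, ignore_index=True), truth
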