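"""Parallel-synthesis outcome accounting.

The synthesis success rate (SSR) is the percentage of planned parallel
experiments that led to isolation of the target member; the mean isolated
yield averages over isolated members that report a yield.  Members isolated
without a reported yield count toward SSR but not toward the yield mean.

Printed percentages are rounded to the nearest integer, half away from
zero, matching common reporting practice (186/247 = 75.30 prints as 75,
76/89 = 85.39 prints as 85).  Unrounded values are kept alongside.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "SynthesisOutcome",
    "LibraryReport",
    "compute_ssr",
    "mean_yield",
    "build_report",
    "combined_report",
    "read_outcomes_csv",
    "write_outcomes_csv",
]


def round_half_away(x: float) -> int:
    """Round to nearest integer, ties away from zero (0.5 -> 1, -0.5 -> -1)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class SynthesisOutcome:
    member_id: str
    isolated: bool
    yield_percent: float | None = None

    def __post_init__(self) -> None:
        if self.yield_percent is not None:
            if not self.isolated:
                raise ValueError(
                    f"{self.member_id}: yield reported for a non-isolated member"
                )
            if not 0 < self.yield_percent <= 100:
                raise ValueError(
                    f"{self.member_id}: yield {self.yield_percent} outside (0, 100]"
                )


@dataclass
class LibraryReport:
    library_label: str
    planned_count: int
    isolated_count: int
    ssr_percent: int
    ssr_percent_exact: float
    mean_yield_percent: int | None
    mean_yield_percent_exact: float | None
    theoretical_space: int

    def __post_init__(self) -> None:
        if self.isolated_count > self.planned_count:
            raise ValueError("isolated_count exceeds planned_count")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    def to_text(self) -> str:
        lines = [
            f"Library {self.library_label}",
            f"  theoretical combinations : {self.theoretical_space:,}",
            f"  planned syntheses        : {self.planned_count}",
            f"  isolated members         : {self.isolated_count}",
            f"  synthesis success rate   : {self.ssr_percent}%"
            f" ({self.ssr_percent_exact:.2f}%)",
        ]
        if self.mean_yield_percent is not None:
            lines.append(
                f"  mean isolated yield      : {self.mean_yield_percent}%"
                " (over yield-reporting isolated members only)"
            )
        return "\n".join(lines)


def compute_ssr(outcomes: Sequence[SynthesisOutcome]) -> tuple[int, float]:
    """Synthesis success rate: 100 x isolated / planned, (rounded, exact)."""
    if not outcomes:
        raise ValueError("compute_ssr: no outcomes")
    exact = 100.0 * sum(o.isolated for o in outcomes) / len(outcomes)
    return round_half_away(exact), exact


def mean_yield(outcomes: Sequence[SynthesisOutcome]) -> tuple[int, float]:
    """Mean isolated yield over members reporting one, (rounded, exact)."""
    yields = [o.yield_percent for o in outcomes if o.yield_percent is not None]
    if not yields:
        raise ValueError("mean_yield: no isolated outcomes with reported yields")
    exact = sum(yields) / len(yields)
    return round_half_away(exact), exact


def build_report(
    library_label: str,
    outcomes: Sequence[SynthesisOutcome],
    theoretical_space: int,
) -> LibraryReport:
    ssr, ssr_exact = compute_ssr(outcomes)
    try:
        my, my_exact = mean_yield(outcomes)
    except ValueError:
        my, my_exact = None, None
    return LibraryReport(
        library_label=library_label,
        planned_count=len(outcomes),
        isolated_count=sum(o.isolated for o in outcomes),
        ssr_percent=ssr,
        ssr_percent_exact=ssr_exact,
        mean_yield_percent=my,
        mean_yield_percent_exact=my_exact,
        theoretical_space=theoretical_space,
    )


def combined_report(reports: Sequence[LibraryReport]) -> LibraryReport:
    """Pool libraries: counts and spaces add, SSR recomputed from the sums."""
    if not reports:
        raise ValueError("combined_report: no reports")
    planned = sum(r.planned_count for r in reports)
    isolated = sum(r.isolated_count for r in reports)
    ssr_exact = 100.0 * isolated / planned if planned else 0.0
    # Pool yield means weighted by each library's yield-reporting count when
    # available; exactness is secondary to the pooled counts.
    with_yield = [r for r in reports if r.mean_yield_percent_exact is not None]
    if with_yield:
        my_exact = sum(
            r.mean_yield_percent_exact * r.isolated_count for r in with_yield
        ) / sum(r.isolated_count for r in with_yield)
        my = round_half_away(my_exact)
    else:
        my, my_exact = None, None
    return LibraryReport(
        library_label="+".join(r.library_label for r in reports),
        planned_count=planned,
        isolated_count=isolated,
        ssr_percent=round_half_away(ssr_exact),
        ssr_percent_exact=ssr_exact,
        mean_yield_percent=my,
        mean_yield_percent_exact=my_exact,
        theoretical_space=sum(r.theoretical_space for r in reports),
    )


def read_outcomes_csv(path: str | Path) -> list[SynthesisOutcome]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            y = row.get("yield_percent", "")
            out.append(
                SynthesisOutcome(
                    member_id=row["member_id"],
                    isolated=str(row["isolated"]).strip().lower()
                    in ("1", "true", "yes"),
                    yield_percent=float(y) if y not in ("", None) else None,
                )
            )
    return out


def write_outcomes_csv(outcomes: Iterable[SynthesisOutcome], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["member_id", "isolated", "yield_percent"])
        for o in outcomes:
            w.writerow(
                [
                    o.member_id,
                    str(o.isolated).lower(),
                    "" if o.yield_percent is None else f"{o.yield_percent:.1f}",
                ]
            )
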