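"""Headline summary statistics with reporting-style rounding.

Percent declines, fold changes and shares as printed in epidemiological
abstracts: rounding is half-away-from-zero and applied only at formatting
time, never inside intermediate computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

__all__ = ["percent_decline", "fold_change", "share", "round_half_away",
           "SummaryReport"]


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (5 always rounds outward)."""
    factor = 10.0 ** ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percent_decline(rate_start: float, rate_end: float) -> int:
    """100 * (start - end) / start, to the nearest integer percent."""
    if rate_start <= 0:
        raise ValueError("rate_start must be positive")
    return int(round_half_away(100.0 * (rate_start - rate_end) / rate_start))


def fold_change(a: float, b: float, ndigits: int = 1) -> float:
    """a / b, rounded to ``ndigits`` decimals (default one)."""
    if b == 0:
        raise ValueError("zero denominator")
    return round_half_away(a / b, ndigits)


def share(numerator: float, denominator: float) -> float:
    """100 * num / den as a percent: two decimals below 1%, one otherwise."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= numerator <= denominator):
        raise ValueError("numerator must lie in [0, denominator]")
    pct = 100.0 * numerator / denominator
    return round_half_away(pct, 2 if pct < 1.0 else 1)


@dataclass
class SummaryReport:
    """Named scalar statistics with formatting metadata.

    Every statistic records the inputs it was computed from, so each number
    is traceable.
    """

    statistics: list = field(default_factory=list)

    def add(self, name: str, value: float, unit: str = "",
            inputs: tuple = ()) -> None:
        self.statistics.append({"name": name, "value": value, "unit": unit,
                                "inputs": tuple(inputs)})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{k: v for k, v in s.items() if k != "inputs"}
                             for s in self.statistics])

    def __getitem__(self, name: str) -> float:
        for s in self.statistics:
            if s["name"] == name:
                return s["value"]
        raise KeyError(name)

    def __str__(self) -> str:
        width = max((len(s["name"]) for s in self.statistics), default=0)
        return "\n".join(f"{s['name']:<{width}}  {s['value']:g} {s['unit']}".rstrip()
                         for s in self.statistics)
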