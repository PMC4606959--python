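"""ICD cause-of-death classification and multiple-cause tabulation.

Death certificates list one underlying cause and up to twenty mentioned
causes, coded under ICD-8, ICD-9 or ICD-10 depending on the data year.  A
death is condition-associated if any mentioned cause falls in the configured
code ranges — congenital anomalies of the heart and great vessels, excluding
anomalies of the peripheral circulatory system — and is additionally an
underlying-cause death if the underlying code itself is in range.

Default code maps (editable via :func:`read_code_map` files):

===========  =================  =================
ICD version  include            exclude
===========  =================  =================
8 and 9      745.0 - 747.49     747.5 - 747.9
10           Q20 - Q26          Q27 - Q28
===========  =================  =================

Codes are compared dot-stripped and uppercased with interval semantics that
tolerate 3/4/5-character codes: a code is at or above a range start when its
zero-padding to the start's length compares >=, and at or below a range end
when its truncation to the end's length compares <=.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd

__all__ = ["ICDCodeMap", "DeathRecord", "DEFAULT_CODE_MAPS", "normalize_code",
           "classify", "tabulate", "rates_from_counts", "read_records",
           "read_code_map", "records_from_frame"]

logger = logging.getLogger(__name__)


def normalize_code(code: str) -> str:
    """Uppercase, strip whitespace and remove dots from an ICD code."""
    return str(code).strip().upper().replace(".", "")


@dataclass(frozen=True)
class ICDCodeMap:
    """Include/exclude code intervals for one ICD revision."""

    version: int
    include_ranges: tuple
    exclude_ranges: tuple = ()

    def __post_init__(self) -> None:
        if self.version not in (8, 9, 10):
            raise ValueError(f"unsupported ICD version {self.version}")
        if not self.include_ranges:
            raise ValueError("code map needs at least one include range")
        norm = lambda ranges: tuple(
            (normalize_code(lo), normalize_code(hi)) for lo, hi in ranges)
        object.__setattr__(self, "include_ranges", norm(self.include_ranges))
        object.__setattr__(self, "exclude_ranges", norm(self.exclude_ranges))
        for lo, hi in self.include_ranges + self.exclude_ranges:
            # start <= end under padded semantics: compare start truncated to
            # the end's length (so ("7450", "74749") is a valid range)
            if not lo or not hi or (lo[: len(hi)] > hi and lo > hi):
                raise ValueError(f"bad code range ({lo!r}, {hi!r})")

    def contains(self, code: str) -> bool:
        code = normalize_code(code)
        if not any(_in_range(code, lo, hi) for lo, hi in self.include_ranges):
            return False
        return not any(_in_range(code, lo, hi) for lo, hi in self.exclude_ranges)


def _in_range(code: str, lo: str, hi: str) -> bool:
    padded = code.ljust(len(lo), "0")
    return padded >= lo and code[: len(hi)] <= hi


DEFAULT_CODE_MAPS: dict[int, ICDCodeMap] = {
    8: ICDCodeMap(8, (("7450", "74749"),), (("7475", "7479"),)),
    9: ICDCodeMap(9, (("7450", "74749"),), (("7475", "7479"),)),
    10: ICDCodeMap(10, (("Q20", "Q26"),), (("Q27", "Q28"),)),
}


def classify(code: str, version: int, code_maps: dict[int, ICDCodeMap] | None = None) -> bool:
    """True iff the code is condition-associated under the map for its revision."""
    code_maps = code_maps or DEFAULT_CODE_MAPS
    if version not in code_maps:
        raise KeyError(f"no code map configured for ICD version {version}")
    return code_maps[version].contains(code)


@dataclass
class DeathRecord:
    """One death certificate at CSV fidelity."""

    age: int | None
    sex: str | None
    year: int
    icd_version: int
    underlying_cause: str
    mentioned_causes: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.underlying_cause = normalize_code(self.underlying_cause)
        self.mentioned_causes = [normalize_code(c) for c in self.mentioned_causes
                                 if str(c).strip()]
        # the underlying cause is by definition a mentioned cause
        if self.underlying_cause and self.underlying_cause not in self.mentioned_causes:
            self.mentioned_causes.insert(0, self.underlying_cause)


def records_from_frame(df: pd.DataFrame) -> list[DeathRecord]:
    """Build DeathRecords from the multiple-cause CSV layout.

    Expected columns: age, sex, year, icd_version, underlying_cause and
    blank-padded cause_2 ... cause_20.
    """
    cause_cols = [c for c in df.columns if c.startswith("cause_")]
    records = []
    for row in df.itertuples(index=False):
        causes = [getattr(row, c) for c in cause_cols
                  if pd.notna(getattr(row, c)) and str(getattr(row, c)).strip()]
        age = None if pd.isna(row.age) else int(row.age)
        sex = None if pd.isna(row.sex) or not str(row.sex).strip() else str(row.sex)
        underlying = "" if pd.isna(row.underlying_cause) else str(row.underlying_cause)
        records.append(DeathRecord(age=age, sex=sex, year=int(row.year),
                                   icd_version=int(row.icd_version),
                                   underlying_cause=underlying,
                                   mentioned_causes=causes))
    return records


def read_records(path) -> list[DeathRecord]:
    """Read a records.csv multiple-cause file."""
    return records_from_frame(pd.read_csv(path, dtype={"underlying_cause": str}))


def read_code_map(path) -> dict[int, ICDCodeMap]:
    """Read a code-map CSV with columns version, start, end, action."""
    df = pd.read_csv(path, dtype={"start": str, "end": str})
    maps = {}
    for version, grp in df.groupby("version"):
        include = [(r.start, r.end) for r in grp.itertuples() if r.action == "include"]
        exclude = [(r.start, r.end) for r in grp.itertuples() if r.action == "exclude"]
        maps[int(version)] = ICDCodeMap(int(version), tuple(include), tuple(exclude))
    return maps


def tabulate(records: Iterable[DeathRecord],
             code_maps: dict[int, ICDCodeMap] | None = None) -> pd.DataFrame:
    """Any-mention and underlying-cause counts by age, sex and year.

    Records with no causes at all are excluded with a logged count, as are
    records missing age or sex.  Underlying-cause counts can never exceed
    any-mention counts, because an underlying hit implies a mention.
    """
    code_maps = code_maps or DEFAULT_CODE_MAPS
    rows = []
    n_empty = n_incomplete = 0
    for rec in records:
        if not rec.mentioned_causes:
            n_empty += 1
            continue
        if rec.age is None or rec.sex is None:
            n_incomplete += 1
            continue
        any_mention = any(classify(c, rec.icd_version, code_maps)
                          for c in rec.mentioned_causes)
        underlying = bool(rec.underlying_cause) and classify(
            rec.underlying_cause, rec.icd_version, code_maps)
        if any_mention or underlying:
            rows.append((rec.age, rec.sex, rec.year, any_mention, underlying))
    if n_empty:
        logger.warning("excluded %d records with an empty cause list", n_empty)
    if n_incomplete:
        logger.warning("dropped %d records missing age or sex", n_incomplete)
    out = pd.DataFrame(rows, columns=["age", "sex", "year", "any_mention", "underlying"])
    if out.empty:
        return pd.DataFrame(columns=["age", "sex", "year", "any_mention", "underlying"])
    return (out.groupby(["age", "sex", "year"], as_index=False)[["any_mention", "underlying"]]
               .sum())


def rates_from_counts(counts: pd.DataFrame, population: pd.DataFrame,
                      count_col: str | None = None) -> pd.DataFrame:
    """Cause-specific mortality-rate observations from counts and population.

    Rate = deaths / midyear population (person-years); the population carries
    through as the effective sample size for likelihood weighting.  Zero-count
    cells are retained.  A count cell with no matching population cell, or a
    zero population, is a hard error naming the cell.

    Returns an observation table with columns measure, age_lo, age_hi, sex,
    year, value, effective_n.
    """
    if count_col is None:
        count_col = "deaths" if "deaths" in counts.columns else "any_mention"
    merged = counts.merge(population[["age", "sex", "year", "population"]],
                          on=["age", "sex", "year"], how="left",
                          suffixes=("", "_pop"))
    pop_col = "population_pop" if "population_pop" in merged.columns else "population"
    missing = merged[merged[pop_col].isna() | (merged[pop_col] <= 0)]
    if not missing.empty:
        cell = missing.iloc[0]
        raise ValueError(
            f"no usable population for cell age={cell['age']} sex={cell['sex']} "
            f"year={cell['year']}")
    return pd.DataFrame({
        "measure": "csmr",
        "age_lo": merged["age"].astype(int),
        "age_hi": merged["age"].astype(int),
        "sex": merged["sex"],
        "year": merged["year"].astype(int),
        "value": merged[count_col] / merged[pop_col],
        "effective_n": merged[pop_col].astype(float),
    })
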