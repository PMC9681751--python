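"""Descriptive audit tabulations.

Categorical review/study characteristics are expressed as
``count (percent)`` cells and quantitative ones as median (Q1, Q3),
optionally stratified by review design (therapeutic intervention vs
pathophysiology). Denominator rules differ by variable — some
percentages are of the whole stratum, others of the "among those
reporting X" subset, and multi-select variables (e.g. several
risk-of-bias scales per study) may sum above 100% — so every cell
carries its own denominator explicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError

__all__ = [
    "SummaryCell",
    "tabulate_categorical",
    "summarize_numeric",
    "build_tables",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (the convention of printed
    clinical tables), unlike banker's rounding."""
    factor = 10.0**ndigits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


@dataclass(frozen=True)
class SummaryCell:
    """A count with its denominator; the percent is always recomputed,
    never stored."""

    count: int
    denominator: int

    def __post_init__(self) -> None:
        if self.count < 0 or self.denominator < self.count:
            raise ValidationError(
                f"invalid cell: {self.count}/{self.denominator}"
            )

    @property
    def percent(self) -> float:
        if self.denominator == 0:
            return float("nan")
        return round_half_up(100.0 * self.count / self.denominator, 1)

    def __str__(self) -> str:
        if self.denominator == 0:
            return f"{self.count} (—)"
        return f"{self.count} ({self.percent:.1f}%)"


def _strata_masks(records: pd.DataFrame, strata: str) -> dict[str, pd.Series]:
    masks = {"overall": pd.Series(True, index=records.index)}
    if strata == "overall":
        return masks
    if strata not in records.columns:
        raise ValidationError(f"stratum column {strata!r} not found")
    for level in sorted(records[strata].dropna().unique()):
        masks[str(level)] = records[strata] == level
    return masks


def tabulate_categorical(
    records: pd.DataFrame,
    variable: str | list[str],
    strata: str = "overall",
    denominator: str | None = None,
) -> pd.DataFrame:
    """Count/percent table for one categorical variable.

    Parameters
    ----------
    records : DataFrame
        One row per review (or study).
    variable : str or list of str
        A single column (one row per level) or a list of indicator
        columns (multi-select: one row per indicator, percentages may
        sum above 100).
    strata : str
        ``"overall"`` or a column name (e.g. ``"design"``); the overall
        column is always included.
    denominator : str, optional
        Column restricting the denominator to a nested subset ("among
        those reporting X"); rows falsy/missing there are excluded from
        both numerator and denominator. Default: all non-missing rows
        of the stratum.

    Returns a DataFrame of :class:`SummaryCell` objects indexed by
    level, one column per stratum.
    """
    masks = _strata_masks(records, strata)
    if denominator is not None:
        if denominator not in records.columns:
            raise ValidationError(f"denominator column {denominator!r} not found")
        denom_mask = records[denominator].fillna(False).astype(bool)
    else:
        denom_mask = pd.Series(True, index=records.index)

    multi = isinstance(variable, (list, tuple))
    columns = list(variable) if multi else [variable]
    for col in columns:
        if col not in records.columns:
            raise ValidationError(f"variable column {col!r} not found")

    out: dict[str, dict[str, SummaryCell]] = {}
    for stratum, smask in masks.items():
        base = smask & denom_mask
        if multi:
            denom = int(base.sum())
            cells = {
                col: SummaryCell(
                    int(records.loc[base, col].fillna(False).astype(bool).sum()),
                    denom,
                )
                for col in columns
            }
        else:
            col = columns[0]
            nonmiss = base & records[col].notna()
            denom = int(nonmiss.sum())
            counts = records.loc[nonmiss, col].value_counts()
            levels = sorted(records[col].dropna().unique())
            cells = {
                str(level): SummaryCell(int(counts.get(level, 0)), denom)
                for level in levels
            }
        out[stratum] = cells

    levels = list(out["overall"].keys())
    table = pd.DataFrame(
        {
            stratum: [
                cells.get(level, SummaryCell(0, 0)) for level in levels
            ]
            for stratum, cells in out.items()
        },
        index=levels,
    )
    return table


def summarize_numeric(
    records: pd.DataFrame,
    variable: str,
    strata: str = "overall",
) -> pd.DataFrame:
    """Median (Q1, Q3) of a quantitative variable per stratum.

    Quartiles use linear interpolation; missing values are dropped and
    counted. All-missing strata are reported as NaN.
    """
    if variable not in records.columns:
        raise ValidationError(f"variable column {variable!r} not found")
    masks = _strata_masks(records, strata)
    rows = []
    for stratum, smask in masks.items():
        vals = pd.to_numeric(
            records.loc[smask, variable], errors="coerce"
        ).dropna().to_numpy()
        if len(vals) == 0:
            rows.append(
                {"stratum": stratum, "median": np.nan, "q1": np.nan,
                 "q3": np.nan, "n": 0,
                 "n_missing": int(smask.sum())}
            )
            continue
        q1, med, q3 = np.quantile(vals, [0.25, 0.5, 0.75])
        rows.append(
            {"stratum": stratum, "median": float(med), "q1": float(q1),
             "q3": float(q3), "n": int(len(vals)),
             "n_missing": int(smask.sum() - len(vals))}
        )
    return pd.DataFrame(rows).set_index("stratum")


def build_tables(
    records: pd.DataFrame,
    table_spec: dict,
    strata: str = "overall",
) -> dict[str, pd.DataFrame]:
    """Assemble a set of descriptive tables from a declarative spec.

    ``table_spec`` maps table names to lists of variable entries:
    ``{"kind": "categorical"|"numeric"|"multiselect",
    "variable": str|list, "denominator": str|None}``. Returns one
    formatted DataFrame per table (cells stringified for categorical
    entries).
    """
    tables: dict[str, pd.DataFrame] = {}
    for name, entries in table_spec.items():
        blocks = []
        for entry in entries:
            kind = entry.get("kind", "categorical")
            var = entry["variable"]
            if kind in ("categorical", "multiselect"):
                tab = tabulate_categorical(
                    records, var, strata=strata,
                    denominator=entry.get("denominator"),
                )
                block = tab.map(str)
                label = var if isinstance(var, str) else "/".join(var)
                block.index = [f"{label}: {lv}" for lv in block.index]
            elif kind == "numeric":
                num = summarize_numeric(records, var, strata=strata)
                block = pd.DataFrame(
                    {
                        stratum: [
                            f"{row['median']:g} [{row['q1']:g}, {row['q3']:g}]"
                            if row["n"] > 0 else "NA"
                        ]
                        for stratum, row in num.iterrows()
                    },
                    index=[f"{var}: median [Q1, Q3]"],
                )
            else:
                raise ValidationError(f"unknown table entry kind {kind!r}")
            blocks.append(block)
        tables[name] = pd.concat(blocks)
    return tables
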