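"""Tidy phenotype-table I/O with validation.

The on-disk format is plain CSV: UTF-8, comma separated, header row, "NA"
for missing values.  Validation enforces the structural invariants of a
phenotype table: ANT = BT + INT and FRR = FLO/RP wherever all operands are
present, FITNESS ≥ 0, and RP/FRR missing under water-stress treatments.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .traits import FITNESS, is_water_stress

IDENTITY_TOL = 1e-6

_REQUIRED_ANY = ("line_id",)


def validate_phenotypes(table: pd.DataFrame, tol: float = IDENTITY_TOL) -> None:
    """Raise ValueError listing offending rows on invariant violations."""
    problems: list[str] = []
    for col in _REQUIRED_ANY:
        if col not in table.columns:
            problems.append(f"missing required column {col!r}")
    cols = set(table.columns)

    if {"ANT", "BT", "INT"} <= cols:
        full = table[["ANT", "BT", "INT"]].dropna()
        bad = full.index[(full["ANT"] - full["BT"] - full["INT"]).abs() > tol]
        if len(bad):
            problems.append(f"ANT ≠ BT + INT on rows {list(bad[:10])}")
    if {"FRR", "FLO", "RP"} <= cols:
        full = table[["FRR", "FLO", "RP"]].dropna()
        bad = full.index[(full["FRR"] * full["RP"] - full["FLO"]).abs() > tol]
        if len(bad):
            problems.append(f"FRR ≠ FLO / RP on rows {list(bad[:10])}")
    if FITNESS in cols:
        fit = table[FITNESS].dropna()
        bad = fit.index[fit < 0]
        if len(bad):
            problems.append(f"negative FITNESS on rows {list(bad[:10])}")
    treat_col = "treatment" if "treatment" in cols else (
        "treatment_intensity" if "treatment_intensity" in cols else None
    )
    if treat_col:
        ws = table[treat_col].fillna("").map(is_water_stress)
        for t in ("RP", "FRR"):
            if t in cols:
                bad = table.index[ws & table[t].notna()]
                if len(bad):
                    problems.append(
                        f"{t} present under water stress on rows {list(bad[:10])}"
                    )
    if problems:
        raise ValueError("invalid phenotype table:\n  " + "\n  ".join(problems))


def read_phenotypes(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    validate: bool = True,
) -> pd.DataFrame:
    """Read a tidy phenotype CSV ("NA" missing marker).

    *column_map* renames source columns to the package's names (useful for
    externally deposited tables with unknown headers).
    """
    table = pd.read_csv(path, na_values=["NA"], keep_default_na=False)
    if column_map:
        table = table.rename(columns=column_map)
    if validate:
        validate_phenotypes(table)
    return table


def write_phenotypes(table: pd.DataFrame, path: str | Path) -> None:
    """Write a phenotype table as CSV with "NA" for missing values."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False, na_rep="NA")
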