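"""CSV dialects for panel inputs and outputs.

All files are UTF-8, comma-separated, "." decimal, with a header row.

* measurements: accession, stage (H/P), fruit (replicate index), L, a, b
* DUS notes:    accession, ACH, ACS, ILG, ACL, FC, FPC, FSCH, IFC, FG, FSCP
  (IFC empty for accessions where it is not evaluated)
* genotypes:    accession, then two integer allele-size columns per
  marker ("<marker>_1", "<marker>_2"); empty cells are missing calls
* structure runs: K, run, LnPD

Row-level validation errors are collected and raised together with
1-based data line numbers.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .traits import DUS_TRAITS

__all__ = [
    "ValidationError",
    "read_measurements",
    "read_dus",
    "read_genotypes",
    "read_structure_runs",
    "read_q_matrix",
    "write_q_matrix",
]


class ValidationError(ValueError):
    """Input-table validation failure; carries per-row messages."""

    def __init__(self, path, problems: list[str]):
        self.problems = problems
        head = "; ".join(problems[:10])
        more = f" (+{len(problems) - 10} more)" if len(problems) > 10 else ""
        super().__init__(f"{path}: {head}{more}")


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValidationError(path, [f"missing columns {missing}"])


def _warn_if_empty(df: pd.DataFrame, path) -> None:
    if df.empty:
        warnings.warn(f"{path}: empty data section", stacklevel=3)


def read_measurements(path) -> pd.DataFrame:
    """Fruit-level colorimeter readings, validated."""
    df = pd.read_csv(path)
    _require_columns(df, ["accession", "stage", "fruit", "L", "a", "b"], path)
    _warn_if_empty(df, path)
    problems = []
    for col in ("L", "a", "b"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        if row["stage"] not in ("H", "P"):
            problems.append(f"line {line}: stage must be 'H' or 'P', got {row['stage']!r}")
        if any(pd.isna(row[c]) for c in ("L", "a", "b")):
            problems.append(f"line {line}: malformed numeric L/a/b")
        elif not 0 <= row["L"] <= 100:
            problems.append(f"line {line}: L*={row['L']} outside [0, 100]")
    dup = df.duplicated(subset=["accession", "stage", "fruit"])
    for i in df.index[dup]:
        problems.append(f"line {i + 2}: duplicate (accession, stage, fruit) key")
    if problems:
        raise ValidationError(path, problems)
    return df


def read_dus(path) -> pd.DataFrame:
    """DUS trait-note table; notes numeric, IFC may be missing."""
    df = pd.read_csv(path)
    _require_columns(df, ["accession"], path)
    _warn_if_empty(df, path)
    problems = []
    for tr in DUS_TRAITS:
        if tr not in df.columns:
            continue
        bad = df[tr].notna() & pd.to_numeric(df[tr], errors="coerce").isna()
        for i in df.index[bad]:
            problems.append(f"line {i + 2}: malformed note in {tr}")
        df[tr] = pd.to_numeric(df[tr], errors="coerce")
    for i in df.index[df.duplicated(subset=["accession"])]:
        problems.append(f"line {i + 2}: duplicate accession")
    if problems:
        raise ValidationError(path, problems)
    return df


def read_genotypes(path) -> pd.DataFrame:
    """SSR allele-size pairs; empty cells become missing calls (NaN)."""
    df = pd.read_csv(path)
    _require_columns(df, ["accession"], path)
    _warn_if_empty(df, path)
    problems = []
    size_cols = [c for c in df.columns if c.endswith(("_1", "_2"))]
    if not size_cols:
        problems.append("no '<marker>_1'/'<marker>_2' allele columns found")
    for c in size_cols:
        coerced = pd.to_numeric(df[c], errors="coerce")
        bad = df[c].notna() & coerced.isna()
        for i in df.index[bad]:
            problems.append(f"line {i + 2}: malformed allele size in {c}")
        neg = coerced.notna() & (coerced <= 0)
        for i in df.index[neg]:
            problems.append(f"line {i + 2}: non-positive allele size in {c}")
        df[c] = coerced
    if problems:
        raise ValidationError(path, problems)
    return df


def read_structure_runs(path) -> pd.DataFrame:
    """Bayesian-clustering run summaries (K, run, LnPD)."""
    df = pd.read_csv(path)
    _require_columns(df, ["K", "run", "LnPD"], path)
    _warn_if_empty(df, path)
    problems = []
    for col in ("K", "run", "LnPD"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[df[col].notna() & coerced.isna()]:
            problems.append(f"line {i + 2}: malformed {col}")
        df[col] = coerced
    if problems:
        raise ValidationError(path, problems)
    df["K"] = df["K"].astype(int)
    df["run"] = df["run"].astype(int)
    return df


def read_q_matrix(path) -> pd.DataFrame:
    """Membership proportions; rows must sum to 1."""
    df = pd.read_csv(path).set_index("accession")
    bad = (df.sum(axis=1) - 1.0).abs() > 1e-6
    if bad.any():
        raise ValidationError(path, [f"row {a}: memberships do not sum to 1" for a in df.index[bad]])
    return df


def write_q_matrix(q: pd.DataFrame, path) -> None:
    q.to_csv(path, index=True)
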