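"""Reading, validating and writing the pipeline's tabular formats.

All tables are tidy long-format CSV (comma-separated, UTF-8, "." decimal),
one measurement per row. Validation never mutates a value: offending rows
are dropped or flagged and every exclusion is listed in the returned
:class:`~alascan.datamodel.ValidationReport`.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Tuple, Union

import numpy as np
import pandas as pd

from .datamodel import ValidationReport

PathLike = Union[str, Path]

#: required columns per table kind
SCHEMAS = {
    "response": [
        "construct_id", "ligand_id", "pathway_id",
        "experiment_id", "replicate_id", "concentration", "response",
    ],
    "binding": [
        "construct_id", "ligand_id", "experiment_id",
        "log_conc", "specific_binding",
    ],
    "expression": ["construct_id", "expression_fraction", "sem"],
}

_FLOAT_FORMAT = "%.12g"


class SchemaError(ValueError):
    """A table is missing required columns or has an unparseable dtype."""


def read_tables(path: PathLike, kind: str) -> Tuple[pd.DataFrame, ValidationReport]:
    """Read one input CSV and validate it against its schema.

    Parameters
    ----------
    path : file path to a CSV
    kind : one of ``"response"``, ``"binding"``, ``"expression"``

    Returns
    -------
    (DataFrame, ValidationReport)
        Typed records (invalid rows removed) and a report listing every
        dropped or flagged row. The frame preserves input row order.
    """
    if kind not in SCHEMAS:
        raise ValueError(f"unknown table kind {kind!r}; expected one of {sorted(SCHEMAS)}")
    df = pd.read_csv(path)
    return validate_table(df, kind)


def validate_table(df: pd.DataFrame, kind: str) -> Tuple[pd.DataFrame, ValidationReport]:
    """Schema- and row-level validation of an in-memory table."""
    required = SCHEMAS[kind]
    report = ValidationReport(table_kind=kind, n_rows_in=len(df))
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{kind} table is missing required column(s): {', '.join(missing)}")

    df = df.copy()
    bad = np.zeros(len(df), dtype=bool)

    def _numeric(col: str) -> pd.Series:
        s = pd.to_numeric(df[col], errors="coerce")
        for i in df.index[s.isna() & df[col].notna()]:
            report.add(int(i), col, f"non-numeric value {df.at[i, col]!r}", "dropped")
        return s

    if kind == "response":
        conc = _numeric("concentration")
        resp = _numeric("response")
        df["concentration"] = conc
        df["response"] = resp
        neg = conc < 0
        for i in df.index[neg.fillna(False)]:
            report.add(int(i), "concentration",
                       f"non-positive concentration {conc[i]:g} in a non-basal row", "dropped")
        nonfinite = ~np.isfinite(resp.to_numpy(dtype=float))
        for i in df.index[nonfinite & resp.notna()]:
            report.add(int(i), "response", "non-finite response", "dropped")
        bad |= (neg.fillna(True) | conc.isna() | resp.isna() | nonfinite).to_numpy()
    elif kind == "binding":
        lc = _numeric("log_conc")
        sb = _numeric("specific_binding")
        df["log_conc"] = lc
        df["specific_binding"] = sb
        # nonspecific-subtracted values may legitimately stray outside [0, 100]
        bad |= (lc.isna() | sb.isna()).to_numpy()
    elif kind == "expression":
        ef = _numeric("expression_fraction")
        sem = _numeric("sem")
        df["expression_fraction"] = ef
        df["sem"] = sem
        nonpos = ef <= 0
        for i in df.index[nonpos.fillna(False)]:
            report.add(int(i), "expression_fraction",
                       "non-positive expression fraction; construct must be "
                       "flagged not_determined instead", "dropped")
        bad |= (ef.isna() | nonpos.fillna(True)).to_numpy()
        if "status" not in df.columns:
            df["status"] = "ok"
        # not_determined rows carry no usable fraction and are kept as flags
        nd = df["status"].astype(str) == "not_determined"
        bad &= ~nd.to_numpy()

    out = df.loc[~bad].reset_index(drop=True)
    report.n_rows_out = len(out)
    return out, report


def write_results(results: pd.DataFrame, path: PathLike) -> Path:
    """Write a result table to CSV; numeric round-trip stable to <1e-9 rel."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    results.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
    return path


def read_results(path: PathLike) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path: PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
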