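"""Reading labeled CSV datasets and writing selection outputs.

Datasets are rectangular CSV tables with samples as rows, features as
columns and exactly one label column (by default the last).  Features must
be numeric and complete; impute missing values upstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .exceptions import InputError
from .linalg import FeatureMatrix
from .relevance import LabeledDataset
from .selection import SVFSParams, SelectionResult

__all__ = ["RunConfig", "read_dataset", "write_selection"]

log = logging.getLogger("svfs")


@dataclass(frozen=True)
class RunConfig:
    """Resolved configuration of one CLI run (flags merged over YAML)."""

    input: Optional[str] = None
    label_col: Union[str, int] = "last"
    delimiter: str = ","
    params: SVFSParams = field(default_factory=SVFSParams)
    out_dir: str = "svfs_out"
    log_level: str = "INFO"
    export_graph: bool = False
    folds: int = 5
    repeats: int = 2
    stratified: bool = True
    classifier: str = "random_forest"


def _has_header(first_line: str, delimiter: str) -> bool:
    for tok in first_line.rstrip("\n").split(delimiter):
        try:
            float(tok)
            return False
        except ValueError:
            continue
    return True


def read_dataset(
    path,
    label_col: Union[str, int] = "last",
    delimiter: str = ",",
) -> LabeledDataset:
    """Read ``D = [A | b]`` from CSV.

    ``label_col`` is a column name, a 0-based position, or ``"last"``.
    A header row is auto-detected (any non-numeric token in the first line);
    without one, features are named F1..Fn.  Numeric label columns are kept
    as-is; categorical labels are integer-encoded in order of first
    appearance (mapping logged).
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"input file not found: {path}")
    with open(path) as fh:
        first = fh.readline()
    header = 0 if _has_header(first, delimiter) else None
    df = pd.read_csv(path, sep=delimiter, header=header)
    if header is None:
        df.columns = [f"F{j + 1}" for j in range(df.shape[1])]
    if df.shape[1] < 2:
        raise InputError(f"need at least one feature and one label column, got {df.shape[1]}")

    if label_col == "last":
        label_name = df.columns[-1]
    elif isinstance(label_col, int):
        try:
            label_name = df.columns[label_col]
        except IndexError:
            raise InputError(f"label position {label_col} out of range") from None
    else:
        if label_col not in df.columns:
            raise InputError(f"label column {label_col!r} not in header {list(df.columns)}")
        label_name = label_col

    features = df.drop(columns=[label_name])
    na = features.isna()
    if na.to_numpy().any():
        i = int(np.argwhere(na.to_numpy())[0][0])
        j = na.columns[int(np.argwhere(na.to_numpy())[0][1])]
        raise InputError(
            f"missing value at sample row {i}, feature {j!r}: impute before "
            "running selection"
        )
    for cname in features.columns:
        col = pd.to_numeric(features[cname], errors="coerce")
        if col.isna().any():
            i = int(col.isna().idxmax())
            raise InputError(
                f"non-numeric feature cell at row {i}, column {cname!r}: "
                f"{features[cname].iloc[i]!r}"
            )
        features[cname] = col

    raw_b = df[label_name]
    if raw_b.isna().any():
        i = int(raw_b.isna().idxmax())
        raise InputError(f"missing label at sample row {i}")
    b_num = pd.to_numeric(raw_b, errors="coerce")
    if b_num.isna().any():
        codes, uniques = pd.factorize(raw_b)  # order of first appearance
        log.info("label encoding: %s", {str(u): i for i, u in enumerate(uniques)})
        b = codes.astype(float)
    else:
        b = b_num.to_numpy(dtype=float)

    A = FeatureMatrix(
        values=features.to_numpy(dtype=float),
        feature_ids=[str(c) for c in features.columns],
    )
    return LabeledDataset(A=A, b=b, label_name=str(label_name))


def write_selection(
    result: SelectionResult,
    out_dir,
    diagnostics_extra: Optional[dict] = None,
) -> Path:
    """Write ``selection.tsv`` and ``diagnostics.json``; returns the dir."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(result.to_rows()).to_csv(out_dir / "selection.tsv", sep="\t", index=False)
    diag = result.to_dict()
    diag.pop("relevance_score_of", None)
    diag.pop("cluster_of", None)
    if diagnostics_extra:
        diag.update(diagnostics_extra)
    (out_dir / "diagnostics.json").write_text(json.dumps(diag, indent=2) + "\n")
    return out_dir
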