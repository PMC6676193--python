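"""Table and gene-set file handling.

All tabular artifacts are TSV with a header row, UTF-8, ``.`` decimal and
``NA`` for missing values. Gene sets use the GMT convention: one set per
line, ``term<TAB>description<TAB>gene1<TAB>gene2...``.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from methylink.errors import DataIntegrityError

NA_REP = "NA"


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    """Write a DataFrame as canonical TSV (header, NA for missing)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", na_rep=NA_REP, index=index)
    return path


def read_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    """Read a canonical TSV back into a DataFrame."""
    return pd.read_csv(path, sep="\t", index_col=index_col, na_values=[NA_REP])


def read_beta_table(path: str | Path) -> pd.DataFrame:
    """Read a probes x samples beta-value table, enforcing the [0, 1] bound.

    Raises
    ------
    DataIntegrityError
        If a cell is outside [0, 1]; the message names the offending probe
        and sample.
    """
    df = read_table(path)
    values = df.to_numpy(dtype=float)
    bad = np.argwhere((values < 0) | (values > 1))
    if bad.size:
        r, c = bad[0]
        raise DataIntegrityError(
            f"beta value {values[r, c]!r} out of [0,1] at probe "
            f"{df.index[r]!r}, sample {df.columns[c]!r} in {path}"
        )
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise DataIntegrityError(f"duplicate probe id {dup!r} in {path}")
    return df


def write_gmt(sets: Mapping[str, tuple], path: str | Path) -> Path:
    """Write term -> (item set, description) mappings as a GMT file.

    ``sets`` maps term -> iterable of items, or term -> (items, description).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for term, payload in sets.items():
            if isinstance(payload, tuple) and len(payload) == 2 and isinstance(payload[1], str):
                items, desc = payload
            else:
                items, desc = payload, ""
            fh.write("\t".join([term, desc, *sorted(map(str, items))]) + "\n")
    return path


def read_gmt(path: str | Path) -> dict[str, frozenset]:
    """Read a GMT file into term -> frozenset of items."""
    out: dict[str, frozenset] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataIntegrityError(
                    f"GMT line {lineno} in {path} has {len(fields)} fields; "
                    "expected term, description and at least one item"
                )
            out[fields[0]] = frozenset(f for f in fields[2:] if f)
    return out


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, (set, frozenset)):
            return sorted(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=_default))
    return path


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
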