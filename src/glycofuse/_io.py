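"""Plain-text tabular interchange helpers.

Every stage communicates through TSV/CSV written with a fixed float
format so a rerun from the same config is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

FLOAT_FORMAT = "%.10g"


def write_tsv(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FORMAT, index_label=index_label)


def read_tsv(path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_csv(df: pd.DataFrame, path, index_label: str | None = None) -> None:
    # missing cells serialize as empty fields
    df.to_csv(path, float_format=FLOAT_FORMAT, index_label=index_label)


def read_csv(path, index_col: int = 0) -> pd.DataFrame:
    return pd.read_csv(path, index_col=index_col)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def sha256_text(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
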