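"""Plain-text interchange: commented TSV tables, event CSVs, layouts.

Stage outputs are tab-separated tables with ``# key=value`` header
comments, so every intermediate is diff-able and loadable from any
language.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Mapping

import pandas as pd

__all__ = [
    "write_tsv",
    "read_tsv",
    "write_events_csv",
    "read_events_csv",
    "read_layout",
    "file_sha256",
]


def write_tsv(df: pd.DataFrame, path: str | Path, meta: Mapping[str, str] | None = None) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return df


def write_events_csv(events: pd.DataFrame, path: str | Path) -> None:
    events.to_csv(path, index=False)


def read_events_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_layout(path: str | Path) -> pd.DataFrame:
    layout = pd.read_csv(path)
    required = {"well", "strain", "reporter", "role"}
    missing = required - set(layout.columns)
    if missing:
        raise ValueError(f"plate layout missing column(s): {sorted(missing)}")
    return layout


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
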