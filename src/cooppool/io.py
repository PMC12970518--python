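"""File-format round-tripping: libraries, designs, logs and peak tables."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import pandas as pd

from .deconvolution import SignatureDesign
from .gcms_diff import PeakTable
from .pool_design import Library, PoolDesign

__all__ = [
    "read_library",
    "write_library",
    "read_design",
    "write_design",
    "write_platemap",
    "read_peak_table",
    "write_peak_table",
    "append_session_log",
    "read_session_log",
]


def read_library(path: str | Path) -> Library:
    """Load a library from CSV/TSV with columns ``id,label``."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    if "id" not in df.columns:
        raise ValueError(f"{path}: expected an 'id' column")
    ids = df["id"].astype(int).tolist()
    if sorted(ids) != list(range(len(ids))):
        raise ValueError(f"{path}: ids must be 0..n-1")
    if "label" in df.columns:
        labels = tuple(df.sort_values("id")["label"].astype(str))
    else:
        labels = None
    return Library(n=len(ids), labels=labels)


def write_library(library: Library, path: str | Path) -> None:
    df = pd.DataFrame(
        {"id": range(library.n), "label": [library.label(i) for i in range(library.n)]}
    )
    df.to_csv(path, index=False)


def read_design(path: str | Path) -> PoolDesign:
    with open(path) as fh:
        return PoolDesign.from_dict(json.load(fh))


def write_design(design: PoolDesign, path: str | Path, seed: int | None = None) -> None:
    d = design.to_dict()
    if seed is not None:
        d["seed"] = seed
    with open(path, "w") as fh:
        json.dump(d, fh, indent=1)
        fh.write("\n")


def write_platemap(
    design: PoolDesign, path: str | Path, library: Library | None = None
) -> None:
    """Bench-facing CSV: one row per (block, position, compound)."""
    lib = library or Library(n=design.n)
    rows = [
        {"block": bi, "position": pos, "id": idx, "label": lib.label(idx)}
        for bi, block in enumerate(design.blocks)
        for pos, idx in enumerate(sorted(block))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_peak_table(path: str | Path, run_id: str | None = None) -> PeakTable:
    df = pd.read_csv(path)
    if run_id is None:
        run_id = str(df["run_id"].iloc[0]) if "run_id" in df.columns else Path(path).stem
    return PeakTable.from_dataframe(run_id, df)


def write_peak_table(table: PeakTable, path: str | Path) -> None:
    table.to_dataframe().to_csv(path, index=False)


def append_session_log(records: Sequence[dict], path: str | Path) -> None:
    """Append deconvolution query records as JSON lines."""
    with open(path, "a") as fh:
        for rec in records:
            fh.write(json.dumps(rec) + "\n")


def read_session_log(path: str | Path) -> list[dict]:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(json.loads(line))
    return out


def write_signature_design(design: SignatureDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(design.to_dict(), fh, indent=1)
        fh.write("\n")


def read_signature_design(path: str | Path) -> SignatureDesign:
    with open(path) as fh:
        d = json.load(fh)
    return SignatureDesign.from_subsets(int(d["group_size"]), d["subsets"])
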