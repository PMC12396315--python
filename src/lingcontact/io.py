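"""Readers and writers for the pipeline's on-disk formats.

Ancestry tables use the ADMIXTURE .Q layout: one whitespace-delimited file
per K with one row per population and K fraction columns, row order given by
a companion ``populations.txt``.  Everything else is delimiter-separated
(tab by default) or JSON (truth records, manifests).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError

POPLIST_NAME = "populations.txt"


def write_q_dir(q_tables: dict[int, pd.DataFrame], metadata: pd.DataFrame, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pops = list(q_tables[next(iter(q_tables))].index)
    for k, table in q_tables.items():
        if list(table.index) != pops:
            raise InvalidInputError("all K tables must share one population order")
        np.savetxt(outdir / f"K{k}.Q", table.to_numpy(), fmt="%.6f")
    (outdir / POPLIST_NAME).write_text("\n".join(str(p) for p in pops) + "\n")
    metadata.to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    return outdir


def read_q_dir(qdir: str | Path, poplist: str | Path | None = None) -> dict[int, pd.DataFrame]:
    qdir = Path(qdir)
    poplist = Path(poplist) if poplist else qdir / POPLIST_NAME
    if not poplist.exists():
        raise InvalidInputError(f"population list not found: {poplist}")
    pops = [l.strip() for l in poplist.read_text().splitlines() if l.strip()]
    tables: dict[int, pd.DataFrame] = {}
    for f in sorted(qdir.glob("*.Q")):
        m = re.search(r"(\d+)", f.stem)
        if not m:
            raise InvalidInputError(f"cannot infer K from file name {f.name}")
        k = int(m.group(1))
        arr = np.loadtxt(f, ndmin=2)
        if arr.shape != (len(pops), k):
            raise InvalidInputError(
                f"{f.name}: shape {arr.shape} does not match {len(pops)} populations x K={k}"
            )
        sums = arr.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-4) or np.any(arr < -1e-9):
            raise InvalidInputError(f"{f.name}: rows are not ancestry fractions")
        arr = arr / sums[:, None]  # absorb fixed-precision rounding
        tables[k] = pd.DataFrame(arr, index=pops, columns=[f"C{c}" for c in range(k)])
    if not tables:
        raise InvalidInputError(f"no .Q files in {qdir}")
    return tables


def read_metadata(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)
    return path


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(obj, indent=2, default=default, sort_keys=True))
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
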