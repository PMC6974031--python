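"""Result-table output with provenance sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

__all__ = ["write_results", "read_results"]


def write_results(table: pd.DataFrame, path: str | Path,
                  meta: dict | None = None) -> Path:
    """Write a stage's result table as TSV plus a ``.json`` sidecar.

    The sidecar records whatever provenance the caller supplies
    (configuration, seed, package version). Column order is preserved,
    floats are written with full precision, so output bytes are a pure
    function of the input.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False, na_rep="")
    sidecar = path.with_suffix(path.suffix + ".json")
    from precon_mvpa import __version__
    payload = {"version": __version__}
    payload.update(meta or {})
    with open(sidecar, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return path


def read_results(path: str | Path) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    table = pd.read_csv(path, sep="\t")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar.exists():
        with open(sidecar) as fh:
            meta = json.load(fh)
    return table, meta
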