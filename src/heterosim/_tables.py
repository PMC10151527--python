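"""Tab-delimited table output with a small metadata header."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__


def config_hash(config_dict: dict) -> str:
    payload = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, seed=None, extra: dict | None = None) -> None:
    """Write a DataFrame as TSV with '#'-prefixed metadata header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    meta = {"version": __version__}
    if seed is not None:
        meta["seed"] = seed
    if extra:
        meta.update(extra)
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
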