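"""Shared file I/O: SMILES files, CSV tables, configs, run manifests.

All formats are plain text (UTF-8).  SMILES files are whitespace
separated ``SMILES<TAB>ID`` lines; ``#`` starts a comment.  Tables are
CSV with documented headers and deterministic column order.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml


def read_smiles(path: str | Path) -> list[tuple[str, str]]:
    """Read ``(smiles, id)`` pairs from a .smi file.

    Lines are whitespace-split; blank lines and ``#`` comments are
    skipped.  Records missing an identifier raise with the line number.
    """
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected 'SMILES<TAB>ID', got {line!r}")
        out.append((parts[0], parts[1]))
    return out


def write_smiles(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    """Write ``(smiles, id)`` pairs as a .smi file."""
    with open(path, "w") as fh:
        for smiles, cid in records:
            fh.write(f"{smiles}\t{cid}\n")


def read_table(path: str | Path, required: Sequence[str] = ()) -> pd.DataFrame:
    """Read a CSV table, checking for required columns by name."""
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns: {missing}")
    return df


def write_table(path: str | Path, df: pd.DataFrame) -> None:
    """Write a CSV table without the index, deterministically."""
    df.to_csv(path, index=False)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a dict."""
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        return json.loads(text)
    out = yaml.safe_load(text)
    if not isinstance(out, dict):
        raise ValueError(f"{path}: expected a mapping at the top level")
    return out


def write_manifest(path: str | Path, payload: dict) -> None:
    """Write a JSON run manifest with stable key order."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
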