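"""File round-tripping and run manifests.

Formats: BIDS-style events TSV, CSV results tables (12 significant
digits), YAML/JSON configs, PNG images, and compressed ``.npz`` array
containers (full precision).  Every pipeline run writes a manifest
listing its inputs, seeds and the SHA-256 checksum of each output file,
so identical configs can be verified to produce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "read_config",
    "write_config",
    "read_table",
    "write_table",
    "read_array",
    "write_array",
    "sha256_file",
    "write_manifest",
    "ParseError",
]


class ParseError(ValueError):
    """Malformed input file."""


def read_config(path: str | Path) -> dict:
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix in (".yaml", ".yml"):
            cfg = yaml.safe_load(text)
        else:
            cfg = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        line = getattr(exc, "lineno", None) or getattr(
            getattr(exc, "problem_mark", None), "line", "?"
        )
        raise ParseError(f"{path}: parse error at line {line}: {exc}") from exc
    if not isinstance(cfg, dict):
        raise ParseError(f"{path}: config must be a mapping")
    return cfg


def write_config(cfg: dict, path: str | Path) -> None:
    path = Path(path)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(cfg, sort_keys=True))
    else:
        path.write_text(json.dumps(cfg, indent=2, sort_keys=True))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")


def read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "\t" if path.suffix == ".tsv" else ","
    try:
        return pd.read_csv(path, sep=sep)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_array(arrays: dict[str, np.ndarray], path: str | Path) -> None:
    np.savez_compressed(Path(path), **arrays)


def read_array(path: str | Path) -> dict[str, np.ndarray]:
    with np.load(Path(path)) as data:
        return {k: data[k] for k in data.files}


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    output_dir: str | Path,
    command: str,
    config: dict,
    files: list[str | Path],
    status: str = "complete",
) -> dict:
    manifest = {
        "command": command,
        "config": config,
        "status": status,
        "outputs": {
            str(Path(f).relative_to(output_dir)): sha256_file(f) for f in files
        },
    }
    Path(output_dir, "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True)
    )
    return manifest
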