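"""Deterministic output writing: atomic CSV/JSON, run manifests, logging."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__

__all__ = [
    "atomic_write_text",
    "write_csv",
    "write_json",
    "sha256_file",
    "write_manifest",
    "get_logger",
]


def get_logger(name: str = "refutesim") -> logging.Logger:
    logger = logging.getLogger(name)
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    return logger


def atomic_write_text(path: Path, text: str) -> None:
    """Write-then-rename so no output file is ever partially written."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    tmp.replace(path)


def write_csv(frame: pd.DataFrame, path: Path) -> None:
    atomic_write_text(Path(path), frame.to_csv(index=False))


def write_json(obj, path: Path) -> None:
    atomic_write_text(Path(path), json.dumps(obj, indent=2, default=str) + "\n")


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: Path,
    command: str,
    config_snapshot: dict | None,
    seeds,
    outputs: list[Path],
) -> Path:
    """Write a run manifest: config snapshot, seeds, artifact version and
    the checksums of every output file — enough to re-execute the run
    bit-identically (the timestamp is informational only)."""
    out_dir = Path(out_dir)
    manifest = {
        "command": command,
        "refutesim_version": __version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "config": config_snapshot,
        "seeds": list(seeds) if seeds is not None else None,
        "outputs": {
            str(p.relative_to(out_dir)): sha256_file(p) for p in outputs
        },
    }
    path = out_dir / "manifest.json"
    write_json(manifest, path)
    return path
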