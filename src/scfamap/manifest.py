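"""Run manifests: provenance metadata stamped into every output directory."""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping

from importlib.metadata import PackageNotFoundError, version as _pkg_version

__all__ = ["tool_version", "write_manifest", "load_manifest", "manifests_equivalent"]

MANIFEST_NAME = "manifest.json"


def tool_version() -> str:
    try:
        return _pkg_version("scfamap")
    except PackageNotFoundError:  # pragma: no cover - source tree without install
        return "0+unknown"


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    command: str,
    seed: int | None = None,
    config: Mapping | None = None,
    inputs: Iterable[str | Path] = (),
) -> Path:
    """Write ``manifest.json`` into ``out_dir``.

    Records the tool version, the invoked command, the seed, a hash of the
    effective configuration, one hash per input file, and a UTC creation
    timestamp. Reruns with identical inputs differ only in the timestamp.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config_hash = None
    if config is not None:
        config_hash = hashlib.sha256(
            json.dumps(config, sort_keys=True, default=str).encode()
        ).hexdigest()
    manifest = {
        "tool": "scfamap",
        "version": tool_version(),
        "command": command,
        "seed": seed,
        "config_hash": config_hash,
        "input_hashes": {str(Path(p).name): _sha256(Path(p)) for p in inputs},
        "created_utc": _dt.datetime.now(_dt.timezone.utc).isoformat(),
    }
    path = out_dir / MANIFEST_NAME
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path


def load_manifest(out_dir: str | Path) -> dict:
    return json.loads((Path(out_dir) / MANIFEST_NAME).read_text())


def manifests_equivalent(a: Mapping, b: Mapping) -> bool:
    """Equality of two manifests up to their creation timestamps."""
    strip = lambda m: {k: v for k, v in m.items() if k != "created_utc"}
    return strip(dict(a)) == strip(dict(b))
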