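"""Deterministic JSON output helpers shared by the CLI subcommands.

Every quantitative result is written as sorted-key, indented JSON so that
reruns with identical configurations and seeds are byte-identical.  A
run manifest (the resolved configuration plus the package version) is
written next to each output; wall-clock time is deliberately kept out of
the manifest to preserve byte-level reproducibility.
"""

from __future__ import annotations

import json
from pathlib import Path

from . import __version__


def write_json(obj: dict, path) -> None:
    Path(path).write_text(
        json.dumps(obj, sort_keys=True, indent=2) + "\n", encoding="utf-8"
    )


def write_manifest(out_path, subcommand: str, params: dict) -> None:
    manifest = {
        "subcommand": subcommand,
        "parameters": {k: _jsonable(v) for k, v in params.items()},
        "version": __version__,
    }
    write_json(manifest, str(out_path) + ".manifest.json")


def _jsonable(v):
    if isinstance(v, Path):
        return str(v)
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v
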