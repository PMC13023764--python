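"""Deterministic run manifests: config snapshot, seeds, digests of every
output file, and verification of a finished run directory."""

from __future__ import annotations

import datetime
import hashlib
import json
import pathlib

__all__ = ["RunManifest", "write_manifest", "load_manifest", "verify_manifest"]

MANIFEST_NAME = "manifest.json"


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Everything needed to re-execute and verify a pipeline run."""

    def __init__(self, config: dict, seed: int, version: str,
                 outputs: dict | None = None, created: str | None = None):
        self.config = config
        self.seed = seed
        self.version = version
        self.outputs = outputs or {}  # relative path -> sha256
        self.created = created or datetime.datetime.now(datetime.timezone.utc).isoformat()

    def record_output(self, out_dir, path) -> None:
        rel = str(pathlib.Path(path).relative_to(out_dir))
        self.outputs[rel] = _sha256(path)

    def to_dict(self) -> dict:
        return {"format": "xpdtsim-manifest", "version": self.version,
                "created": self.created, "seed": self.seed,
                "config": self.config, "outputs": self.outputs}


def write_manifest(manifest: RunManifest, out_dir) -> pathlib.Path:
    path = pathlib.Path(out_dir) / MANIFEST_NAME
    with open(path, "w") as fh:
        json.dump(manifest.to_dict(), fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def load_manifest(out_dir) -> RunManifest:
    path = pathlib.Path(out_dir) / MANIFEST_NAME
    with open(path) as fh:
        d = json.load(fh)
    if d.get("format") != "xpdtsim-manifest":
        raise ValueError(f"{path}: not an xpdtsim manifest")
    return RunManifest(config=d["config"], seed=d["seed"], version=d["version"],
                       outputs=d["outputs"], created=d["created"])


def verify_manifest(out_dir) -> list:
    """Check every declared output against its digest.

    Returns a list of problems (empty = verified)."""
    out_dir = pathlib.Path(out_dir)
    manifest = load_manifest(out_dir)
    problems = []
    for rel, digest in sorted(manifest.outputs.items()):
        p = out_dir / rel
        if not p.exists():
            problems.append(f"missing output {rel}")
        elif _sha256(p) != digest:
            problems.append(f"digest mismatch for {rel}")
    return problems
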