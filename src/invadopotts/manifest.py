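"""Run manifests: config hash, seeds and output inventory for reproducibility."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(cfg) -> str:
    payload = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(cfg, out_dir, outputs: list[str], counters: dict) -> Path:
    """Write manifest.json next to the run outputs; hashes every output file."""
    out_dir = Path(out_dir)
    man = {
        "config": asdict(cfg),
        "config_hash": config_hash(cfg),
        "base_seed": cfg.base_seed,
        "outputs": {
            name: _sha256(out_dir / name) for name in outputs
        },
        "counters": counters,
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(man, fh, indent=2, default=str)
    return path


def verify_manifest(path) -> bool:
    """Re-hash the listed outputs; True iff everything matches."""
    path = Path(path)
    with open(path) as fh:
        man = json.load(fh)
    for name, digest in man["outputs"].items():
        f = path.parent / name
        if not f.exists() or _sha256(f) != digest:
            return False
    return True
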