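"""Run provenance: config hashes, seeds, and output checksums."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def hash_parameters(ps) -> str:
    """Stable hash of a ParameterSet's canonical JSON serialisation."""
    payload = json.dumps(ps.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()


@dataclass
class RunManifest:
    """Everything needed to reproduce a run byte-for-byte."""

    config_hash: str
    seed: int
    code_version: str = __version__
    scenarios: list = field(default_factory=list)
    population_size: int = 0
    start_year: int = 2020
    end_year: int = 2040
    wall_time_s: float = 0.0
    output_checksums: dict = field(default_factory=dict)
    created: str = ""

    def write(self, path) -> None:
        data = asdict(self)
        data["created"] = data["created"] or time.strftime("%Y-%m-%dT%H:%M:%S")
        Path(path).write_text(json.dumps(data, indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))
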