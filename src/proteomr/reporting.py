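"""Run manifests and structured exclusion accounting.

The manifest records the effective configuration, input checksums, seeds,
and stage-by-stage inclusion/exclusion counts, so that a run can be
audited (flow-diagram style: in = retained + excluded at every stage) and
reproduced. It is written as a deterministic key-value text file; the one
wall-clock field (``timestamp``) sits on its own line so byte comparisons
can exclude it.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Auditable record of one pipeline run."""

    command: str
    config: dict = field(default_factory=dict)
    input_checksums: dict = field(default_factory=dict)
    stage_counts: list = field(default_factory=list)  # dicts: stage, n_in, n_retained, n_excluded
    seeds: dict = field(default_factory=dict)
    timestamp: str = field(default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def add_stage(self, stage: str, n_in: int, n_retained: int, detail: str = "") -> None:
        n_excluded = n_in - n_retained
        if n_excluded < 0:
            raise ValueError(f"stage {stage}: retained more than entered")
        self.stage_counts.append({"stage": stage, "n_in": int(n_in),
                                  "n_retained": int(n_retained),
                                  "n_excluded": int(n_excluded), "detail": detail})

    def checksum_inputs(self, paths: dict) -> None:
        for key, p in sorted(paths.items()):
            if isinstance(p, dict):
                for sub, sp in sorted(p.items()):
                    self.input_checksums[f"{key}:{sub}"] = sha256_file(sp)
            else:
                self.input_checksums[key] = sha256_file(p)

    def conservation_holds(self) -> bool:
        """in = retained + excluded at every stage (enforced by add_stage, re-checked here)."""
        return all(s["n_in"] == s["n_retained"] + s["n_excluded"] for s in self.stage_counts)

    def to_text(self) -> str:
        lines = [f"command\t{self.command}", f"timestamp\t{self.timestamp}"]
        for key in sorted(self.config):
            lines.append(f"config.{key}\t{self.config[key]}")
        for key in sorted(self.seeds):
            lines.append(f"seed.{key}\t{self.seeds[key]}")
        for key in sorted(self.input_checksums):
            lines.append(f"input_sha256.{key}\t{self.input_checksums[key]}")
        for s in self.stage_counts:
            lines.append("stage\t{stage}\tin={n_in}\tretained={n_retained}"
                         "\texcluded={n_excluded}\t{detail}".format(**s))
        return "\n".join(lines) + "\n"

    def write(self, path) -> None:
        Path(path).write_text(self.to_text())


def manifest_lines_without_timestamp(path) -> list[str]:
    """Manifest content for byte-level comparison across reruns."""
    return [ln for ln in Path(path).read_text().splitlines()
            if not ln.startswith("timestamp\t")]
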