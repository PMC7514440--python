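"""Sample files, checkpoints and run manifests.

Samples are stored as tab-separated text with a header row: ``D`` coordinate
columns ``x0..x{D-1}`` plus optional ``log_q_flow`` and ``log_target_unnorm``
columns.  Checkpoints are a single JSON document holding the flow weights and
the structural hyperparameters (epsilon, Langevin steps, layer count,
conditioner shapes, seed), so a run can be rebuilt exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

from .flow import FlowStack, SampleBatch, load_flow

__all__ = ["write_samples", "read_samples", "SampleFileError",
           "save_checkpoint", "load_checkpoint", "RunManifest"]

_FMT = "%.17g"


class SampleFileError(ValueError):
    """Malformed sample file; the message reports the offending line."""


def write_samples(path, batch: SampleBatch):
    d = batch.points.shape[1]
    header = "\t".join([f"x{i}" for i in range(d)]
                       + ["log_q_flow", "log_target_unnorm"])
    body = np.column_stack([batch.points, batch.log_q_flow,
                            batch.log_target_unnorm])
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for row in body:
            fh.write("\t".join(_FMT % v for v in row) + "\n")


def read_samples(path) -> SampleBatch:
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise SampleFileError(f"{path}: empty file")
    cols = lines[0].split("\t")
    try:
        d = cols.index("log_q_flow")
    except ValueError:
        raise SampleFileError(f"{path}: line 1: missing log-density columns")
    rows = []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(cols):
            raise SampleFileError(
                f"{path}: line {lineno}: expected {len(cols)} columns, "
                f"got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise SampleFileError(f"{path}: line {lineno}: {exc}") from None
    arr = np.asarray(rows)
    return SampleBatch(points=arr[:, :d], log_q_flow=arr[:, d],
                       log_target_unnorm=arr[:, d + 1])


def save_checkpoint(path, stack: FlowStack, extra=None):
    doc = {"flow": stack.state_dict(), "target": stack.target.name,
           "dim": stack.dim}
    if extra:
        doc["extra"] = extra
    with open(path, "w") as fh:
        json.dump(doc, fh)


def load_checkpoint(path, target):
    with open(path) as fh:
        doc = json.load(fh)
    if doc["dim"] != target.dim:
        raise ValueError(
            f"checkpoint dimension {doc['dim']} != target dimension {target.dim}")
    return load_flow(doc["flow"], target)


@dataclass
class RunManifest:
    """Everything needed to reproduce a training run bit-for-bit."""

    config: dict
    seed: int
    version: str
    final_loss: Optional[float] = None
    wall_time_s: Optional[float] = None
    outputs: dict = field(default_factory=dict)

    def to_json(self, path):
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path):
        with open(path) as fh:
            return cls(**json.load(fh))
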