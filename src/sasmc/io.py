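"""Curve files, run configuration and provenance stamping.

Curves travel as whitespace-delimited text with 2 or 3 columns
(q [1/Angstrom], intensity [, sigma]) and '#' comment lines carrying
metadata -- the common SAS ``.dat`` dialect.  Run configuration is a YAML
file mirroring the engine/model/sampler dataclasses; a SHA-256 hash of
its canonical serialization is stamped into every output artifact.

Unit convention (easy to get wrong, so stated twice): q in files is in
inverse Angstroms; all real-space lengths in the config (radius, Debye
length, box, displacements) are nanometres.  ``units_nm_inv=True``
converts a q column given in 1/nm on read.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .inference import SamplerConfig
from .mc import SimulationConfig
from .models import TrainingConfig
from .potentials import InteractionParams
from .scattering import SAXSCurve

__all__ = [
    "read_saxs_curve",
    "write_saxs_curve",
    "RunConfig",
    "load_config",
]


def read_saxs_curve(path, units_nm_inv: bool = False) -> SAXSCurve:
    """Parse a 2- or 3-column .dat curve; '#' lines may carry metadata.

    Metadata comments of the form ``# key: value`` are collected; a
    ``# labels: z k`` line populates the ground-truth labels of synthetic
    curves.  Errors name the offending line.
    """
    path = Path(path)
    rows, metadata, labels = [], {}, None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if ":" in body:
                    key, _, value = body.partition(":")
                    metadata[key.strip()] = value.strip()
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected at least 2 columns, "
                    f"got {len(parts)}")
            try:
                rows.append([float(p) for p in parts[:3]])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric value") from exc
    if not rows:
        raise ValueError(f"{path}: no data rows")
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise ValueError(f"{path}: inconsistent column counts {sorted(widths)}")
    data = np.asarray(rows)
    q = data[:, 0] / 10.0 if units_nm_inv else data[:, 0]
    if np.any(np.diff(q) <= 0):
        bad = int(np.argmax(np.diff(q) <= 0)) + 2
        raise ValueError(f"{path}:{bad}: q must be strictly increasing")
    if np.any(data[:, 1] <= 0):
        bad = int(np.argmax(data[:, 1] <= 0)) + 1
        raise ValueError(f"{path}:{bad}: nonpositive intensity")
    sigma = data[:, 2] if data.shape[1] == 3 else None
    if "labels" in metadata:
        z, k = metadata["labels"].split()
        labels = (float(z), float(k))
    return SAXSCurve(q, data[:, 1], sigma=sigma, labels=labels,
                     metadata=metadata)


def write_saxs_curve(curve: SAXSCurve, path) -> None:
    """Write a curve as q / I [/ sigma] columns with metadata comments."""
    with open(path, "w") as fh:
        fh.write("# columns: q[1/A] intensity" +
                 (" sigma\n" if curve.sigma is not None else "\n"))
        if curve.labels is not None:
            fh.write(f"# labels: {curve.labels[0]:.8g} {curve.labels[1]:.8g}\n")
        for key, value in curve.metadata.items():
            if key in ("labels", "columns"):
                continue
            fh.write(f"# {key}: {value}\n")
        for i in range(len(curve)):
            row = f"{curve.q[i]:.8e} {curve.intensity[i]:.8e}"
            if curve.sigma is not None:
                row += f" {curve.sigma[i]:.8e}"
            fh.write(row + "\n")


@dataclasses.dataclass
class RunConfig:
    """Nested configuration for a full workflow run."""

    params: InteractionParams = dataclasses.field(
        default_factory=lambda: InteractionParams(z_eff=40.0, kappa_inv=5.0))
    simulation: SimulationConfig = dataclasses.field(
        default_factory=SimulationConfig)
    training: TrainingConfig = dataclasses.field(default_factory=TrainingConfig)
    sampler: SamplerConfig = dataclasses.field(default_factory=SamplerConfig)
    n_curves: int = 200
    q_cutoff: float | None = None
    output_dir: str = "sasmc_output"
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        for key, klass in (("params", InteractionParams),
                           ("simulation", SimulationConfig),
                           ("training", TrainingConfig),
                           ("sampler", SamplerConfig)):
            if key in kwargs and isinstance(kwargs[key], dict):
                kwargs[key] = klass(**kwargs[key])
        return cls(**kwargs)

    def config_hash(self) -> str:
        """SHA-256 of the canonical JSON serialization (first 12 hex chars)."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(raw)
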