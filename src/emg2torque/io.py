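"""Structured-text I/O: parameter sets, geometry, manifests, run records."""

from __future__ import annotations

import hashlib
import json
import platform
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .exceptions import TrialFormatError
from .geometry import GeometryPoly
from .hill import MuscleParams

__all__ = [
    "write_params",
    "read_params",
    "write_geometry",
    "read_geometry",
    "write_manifest",
    "read_manifest",
    "write_run_record",
]


def write_params(muscles: Mapping[str, MuscleParams], path) -> None:
    """Write a muscle parameter set as YAML (one block per muscle)."""
    data = {
        "muscles": {
            m: {
                "F0m": float(p.F0m),
                "l0m": float(p.l0m),
                "lst": float(p.lst),
                "phi0_deg": float(p.phi0_deg),
                "v0m": float(p.v0m),
            }
            for m, p in muscles.items()
        }
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_params(path) -> dict[str, MuscleParams]:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "muscles" not in data:
        raise TrialFormatError(f"{path}: not a muscle parameter file")
    return {
        m: MuscleParams(name=m, **fields) for m, fields in data["muscles"].items()
    }


def write_geometry(geometry: Mapping[str, Mapping[str, GeometryPoly]], path) -> None:
    data = {
        dof: {
            m: {
                "mu0": g.mu0,
                "mu1": g.mu1,
                "mu2": g.mu2,
                "mu3": g.mu3,
                "rom_deg": list(g.rom_deg),
            }
            for m, g in per_dof.items()
        }
        for dof, per_dof in geometry.items()
    }
    Path(path).write_text(yaml.safe_dump({"geometry": data}, sort_keys=True))


def read_geometry(path) -> dict[str, dict[str, GeometryPoly]]:
    data = yaml.safe_load(Path(path).read_text())["geometry"]
    return {
        dof: {
            m: GeometryPoly(
                muscle=m,
                dof=dof,
                mu0=g["mu0"],
                mu1=g["mu1"],
                mu2=g.get("mu2", 0.0),
                mu3=g.get("mu3", 0.0),
                rom_deg=tuple(g.get("rom_deg", (-45.0, 45.0))),
            )
            for m, g in per_dof.items()
        }
        for dof, per_dof in data.items()
    }


def write_manifest(trial_files: Sequence[tuple[str, str]], path, extra: dict | None = None) -> None:
    """Write a manifest listing (relative trial path, role) pairs."""
    data = {"trials": [{"path": str(p), "role": role} for p, role in trial_files]}
    if extra:
        data.update(extra)
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def read_manifest(path) -> dict:
    data = yaml.safe_load(Path(path).read_text())
    if not isinstance(data, dict) or "trials" not in data:
        raise TrialFormatError(f"{path}: not a trial manifest")
    return data


def _hash_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def write_run_record(out_dir, command: str, seed: int | None, configs: dict, inputs: Sequence = ()) -> Path:
    """Write a machine-readable record of one CLI run."""
    record = {
        "command": command,
        "seed": seed,
        "version": __version__,
        "python": platform.python_version(),
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "configs": configs,
        "input_hashes": {str(p): _hash_file(p) for p in inputs},
    }
    out = Path(out_dir) / f"run_record_{command}.json"
    out.write_text(json.dumps(record, indent=2, default=str))
    return out
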