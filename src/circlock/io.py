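"""Result writers: trajectory CSVs, scan tables, JSON run metadata."""

from __future__ import annotations

import hashlib
import importlib.resources
import json
from pathlib import Path

import pandas as pd

from .simulate import Trajectory

__all__ = [
    "write_trajectory_csv",
    "read_trajectory_csv",
    "write_run_metadata",
    "parameter_file_hash",
]


def parameter_file_hash() -> str:
    """SHA-256 of the shipped parameter table (for provenance sidecars)."""
    data = (
        importlib.resources.files("circlock")
        .joinpath("data/parameters.tsv")
        .read_bytes()
    )
    return hashlib.sha256(data).hexdigest()


def write_trajectory_csv(traj: Trajectory, path, tidy: bool = False) -> None:
    """Wide (time x species) or tidy (time, species, value) CSV."""
    traj.to_frame(tidy=tidy).to_csv(path, index=False)


def read_trajectory_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_run_metadata(
    path, settings=None, perturbations=(), extra: dict | None = None
) -> None:
    """JSON sidecar describing one run (settings, perturbations, versions)."""
    from . import __version__

    meta = {
        "package": "circlock",
        "version": __version__,
        "parameter_file_sha256": parameter_file_hash(),
        "perturbations": [
            {"kind": p.kind, "target": p.target, "value": p.value}
            for p in perturbations
        ],
    }
    if settings is not None:
        meta["settings"] = {
            "t_end": settings.t_end,
            "output_step": settings.output_step,
            "rtol": settings.rtol,
            "atol": settings.atol,
            "transient_discard": settings.transient_discard,
            "method": settings.method,
        }
    if extra:
        meta.update(extra)
    Path(path).write_text(json.dumps(meta, indent=2, default=str) + "\n")
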