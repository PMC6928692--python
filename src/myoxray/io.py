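"""Readers/writers for the on-disk formats: two-column meridional profiles
with '#'-header metadata, tabular traces, and JSON run manifests."""
from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .diffraction import MeridionalProfile
from .kinetics import SimulationTrace

__all__ = [
    "read_profile",
    "write_profile",
    "write_trace_table",
    "write_manifest",
    "file_digest",
]

_FMT = "%.8g"


def write_profile(profile: MeridionalProfile, path: str | Path) -> None:
    """Two-column text table (Z_nm_inv, intensity_au) with '# key: value'
    header lines carrying the metadata; numbers at %.8g."""
    path = Path(path)
    lines = []
    for k, v in profile.metadata.items():
        lines.append(f"# {k}: {json.dumps(v)}")
    lines.append("# columns: Z_nm_inv\tintensity_au")
    for z, i in zip(profile.Z, profile.intensity):
        lines.append(f"{z:.8g}\t{i:.8g}")
    path.write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path) -> MeridionalProfile:
    """Read a profile written by write_profile; malformed rows are reported
    with their line numbers."""
    path = Path(path)
    meta: dict = {}
    zs: list[float] = []
    Is: list[float] = []
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty profile file")
    for ln, line in enumerate(text.splitlines(), start=1):
        s = line.strip()
        if not s:
            continue
        if s.startswith("#"):
            body = s[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                k, v = k.strip(), v.strip()
                if k == "columns":
                    continue
                try:
                    meta[k] = json.loads(v)
                except json.JSONDecodeError:
                    meta[k] = v
            continue
        parts = s.split()
        if len(parts) != 2:
            raise ValueError(f"{path}:{ln}: expected two columns, got {len(parts)}")
        try:
            zs.append(float(parts[0]))
            Is.append(float(parts[1]))
        except ValueError as exc:
            raise ValueError(f"{path}:{ln}: non-numeric value ({exc})") from None
    if not zs:
        raise ValueError(f"{path}: no data rows")
    # metadata segments come back as lists of lists; restore tuples
    if "segments" in meta:
        meta["segments"] = [tuple(seg) for seg in meta["segments"]]
    return MeridionalProfile(np.asarray(zs), np.asarray(Is), meta)


def write_trace_table(trace: SimulationTrace, path: str | Path) -> None:
    """Long-format trace table: t_s, filament_id, force_pN plus the
    per-thick bound-head counts in companion columns (filament_id indexes
    thin filaments; thick counts are broadcast by integer division)."""
    n_rec, F = trace.thin_force.shape
    t = np.repeat(trace.t, F)
    fid = np.tile(np.arange(F), n_rec)
    force = trace.thin_force.ravel()
    n2 = np.repeat(trace.n2.sum(axis=1), F)
    n3 = np.repeat(trace.n3.sum(axis=1), F)
    df = pd.DataFrame({
        "t_s": t, "filament_id": fid, "force_pN": force,
        "n_state2_total": n2, "n_state3_total": n3,
    })
    df.to_csv(path, sep="\t", index=False, float_format=_FMT)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, config: dict, seed: int,
                   inputs: dict | None = None, outputs: dict | None = None) -> dict:
    """JSON run manifest: config snapshot, seed, timestamps, file digests."""
    from . import __version__

    manifest = {
        "package": "myoxray",
        "version": __version__,
        "seed": int(seed),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "config": config,
        "inputs": {k: file_digest(v) for k, v in (inputs or {}).items()},
        "outputs": {k: file_digest(v) for k, v in (outputs or {}).items()},
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return manifest
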