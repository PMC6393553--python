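"""Plain-text file formats, run configuration and provenance.

All artifacts are inspectable text: relaxation traces as two-column CSV
with a JSON metadata sidecar, simulation snapshots as extended-XYZ or
LAMMPS-style dump frames, run configuration as YAML, results as JSON.
Every run can record a provenance log (config hash, seed, package
version) so any result regenerates from its recorded inputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .md import SPECIES, ParticleSystem
from .tensiometry import RelaxationTrace

logger = logging.getLogger(__name__)

__all__ = [
    "read_trace_csv", "write_trace_csv", "write_xyz", "read_xyz",
    "write_lammps_dump", "read_lammps_dump", "RunConfig", "load_config",
    "write_provenance",
]

TIME_COL = "time_s"
GAMMA_COL = "gamma_mN_per_m"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_trace_csv(trace: RelaxationTrace, path, metadata: dict | None = None) -> None:
    """Write a trace as two-column CSV plus a JSON sidecar with protocol
    metadata (and optionally the generation truth parameters)."""
    path = Path(path)
    df = pd.DataFrame({TIME_COL: trace.t, GAMMA_COL: trace.gamma})
    df.to_csv(path, index=False, float_format="%.10g")
    meta = dict(step_time=trace.step_time, step_fraction=trace.step_fraction,
                step_duration=trace.step_duration, phase_label=trace.phase_label)
    if metadata:
        meta.update(metadata)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_trace_csv(path) -> RelaxationTrace:
    """Read a trace CSV (+ sidecar if present) back into a RelaxationTrace.

    The time column must be strictly increasing; a violation is reported
    with the first offending row number (1-based, excluding the header).
    """
    path = Path(path)
    df = pd.read_csv(path)
    if TIME_COL not in df.columns or GAMMA_COL not in df.columns:
        raise ValueError(f"{path}: expected columns {TIME_COL!r}, {GAMMA_COL!r}")
    t = df[TIME_COL].to_numpy(dtype=float)
    bad = np.flatnonzero(np.diff(t) <= 0)
    if bad.size:
        raise ValueError(
            f"{path}: time not strictly increasing at data row {bad[0] + 2}")
    meta: dict = {}
    sc = _sidecar_path(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return RelaxationTrace(
        t=t, gamma=df[GAMMA_COL].to_numpy(dtype=float),
        step_time=float(meta.get("step_time", t[0])),
        step_fraction=float(meta.get("step_fraction", 0.1)),
        step_duration=float(meta.get("step_duration", 2.0)),
        phase_label=meta.get("phase_label", "expansion"),
    )


# ---------------------------------------------------------------------------
# simulation snapshots
# ---------------------------------------------------------------------------


def write_xyz(system: ParticleSystem, path, append: bool = False,
              comment: str = "") -> None:
    """Append one extended-XYZ frame (species, positions, velocities)."""
    lx, ly, lz = system.box
    lattice = f"{lx:.8g} 0 0 0 {ly:.8g} 0 {system.tilt_xz:.8g} 0 {lz:.8g}"
    lines = [str(system.n),
             f'Lattice="{lattice}" Properties=species:S:1:pos:R:3:vel:R:3'
             + (f" {comment}" if comment else "")]
    for s, p, v in zip(system.species, system.positions, system.velocities):
        lines.append(f"{SPECIES[s]} {p[0]:.10g} {p[1]:.10g} {p[2]:.10g} "
                     f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}")
    mode = "a" if append else "w"
    with open(path, mode) as fh:
        fh.write("\n".join(lines) + "\n")


def read_xyz(path, frame: int = 0) -> ParticleSystem:
    """Read one frame of an extended-XYZ trajectory."""
    text = Path(path).read_text().splitlines()
    pos = 0
    for _ in range(frame + 1):
        if pos >= len(text):
            raise ValueError(f"{path}: frame {frame} not present")
        n = int(text[pos])
        header = text[pos + 1]
        body = text[pos + 2:pos + 2 + n]
        pos += 2 + n
    lat = header.split('Lattice="')[1].split('"')[0].split()
    lat = [float(x) for x in lat]
    box = np.array([lat[0], lat[4], lat[8]])
    tilt = lat[6]
    species = np.array([SPECIES.index(l.split()[0]) for l in body])
    vals = np.array([[float(x) for x in l.split()[1:7]] for l in body])
    return ParticleSystem(vals[:, :3], vals[:, 3:], species, box, tilt_xz=tilt)


def write_lammps_dump(system: ParticleSystem, path, step: int = 0,
                      append: bool = False) -> None:
    """Append one LAMMPS-dump-style text frame (id type x y z vx vy vz)."""
    lx, ly, lz = system.box
    lines = ["ITEM: TIMESTEP", str(step), "ITEM: NUMBER OF ATOMS",
             str(system.n), "ITEM: BOX BOUNDS pp pp pp",
             f"0 {lx:.8g}", f"0 {ly:.8g}", f"0 {lz:.8g}",
             "ITEM: ATOMS id type x y z vx vy vz"]
    for i, (s, p, v) in enumerate(zip(system.species, system.positions,
                                      system.velocities), start=1):
        lines.append(f"{i} {s + 1} {p[0]:.10g} {p[1]:.10g} {p[2]:.10g} "
                     f"{v[0]:.10g} {v[1]:.10g} {v[2]:.10g}")
    with open(path, "a" if append else "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_lammps_dump(path, frame: int = 0) -> ParticleSystem:
    """Read one frame of a LAMMPS-dump-style text trajectory."""
    text = Path(path).read_text().splitlines()
    pos = 0
    for _ in range(frame + 1):
        if pos >= len(text):
            raise ValueError(f"{path}: frame {frame} not present")
        assert text[pos].startswith("ITEM: TIMESTEP")
        n = int(text[pos + 3])
        bounds = [text[pos + 5 + k].split() for k in range(3)]
        body = text[pos + 9:pos + 9 + n]
        pos += 9 + n
    box = np.array([float(b[1]) - float(b[0]) for b in bounds])
    rows = sorted((l.split() for l in body), key=lambda r: int(r[0]))
    species = np.array([int(r[1]) - 1 for r in rows])
    vals = np.array([[float(x) for x in r[2:8]] for r in rows])
    return ParticleSystem(vals[:, :3], vals[:, 3:], species, box)


# ---------------------------------------------------------------------------
# configuration and provenance
# ---------------------------------------------------------------------------

STAGES = ("fit", "simulate-trace", "md-equilibrate", "nemd-shear",
          "friction", "morphology")


@dataclass
class RunConfig:
    """One reproducible pipeline run: a stage, its parameters and a seed."""

    stage: str
    params: dict = field(default_factory=dict)
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; one of {STAGES}")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path) -> RunConfig:
    """Load a YAML run configuration."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig(**data)


def write_provenance(config: RunConfig, outdir=None, extra: dict | None = None) -> Path:
    """Write the provenance log (config hash, seed, version) for a run."""
    outdir = Path(outdir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    record = dict(config=asdict(config), config_hash=config.config_hash(),
                  seed=config.seed, package_version=__version__)
    if extra:
        record.update(extra)
    path = outdir / "provenance.json"
    path.write_text(json.dumps(record, indent=1))
    logger.info("provenance written to %s (hash %s)", path, record["config_hash"])
    return path
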