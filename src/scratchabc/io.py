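"""File formats: cell tables (CSV), dataset directories, particles, summaries.

Cell tables are plain CSV with header ``cell_id,x,y``; units are microns
unless a pixel scale is supplied, in which case coordinates are converted
on read.  A dataset directory holds one ``<label>_initial.csv`` /
``<label>_final.csv`` pair per observation plus a ``manifest.yaml`` with
the shared metadata (pixel scale, field of view, cell diameter, per-
observation counts and wound areas, and any ground-truth parameters).
Particle populations go to CSV with columns
``m,p,d,gamma_m,gamma_p,gamma_b,weight,distance``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .ibm import FOV_PX, UM_PER_PX, CellPopulation, Domain
from .inference import PARAM_NAMES, ParticlePopulation
from .summaries import SummaryVector
from .synthetic import ScratchObservation

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "write_dataset",
    "read_dataset",
    "write_particles",
    "read_particles",
    "write_summary_json",
    "read_summary_json",
]


def read_cell_table(path, um_per_px: Optional[float] = None,
                    domain: Optional[Domain] = None,
                    time: float = 0.0) -> CellPopulation:
    """Read a ``cell_id,x,y`` CSV into a population.

    Coordinates are microns, or pixels if ``um_per_px`` is given.  When a
    domain is supplied, out-of-bounds coordinates raise a validation error
    naming the offending rows (a coordinate exactly at the upper edge is
    wrapped to 0).  An empty table is a valid, empty population.
    """
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"cell_id", "x", "y"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    for col in ("x", "y"):
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"{path}: non-numeric {col!r} in rows "
                             f"{[int(b) + 2 for b in bad[:5]]} (1-based incl. header)")
    pos = df[["x", "y"]].to_numpy(dtype=float)
    if um_per_px is not None:
        pos = pos * um_per_px
    domain = domain or Domain()
    widths = domain.widths
    bad = np.where((pos < 0) | (pos > widths))[0]
    if bad.size:
        rows = sorted({int(b) + 2 for b in bad})[:5]
        raise ValueError(f"{path}: coordinates outside the field of view in "
                         f"rows {rows} (1-based incl. header)")
    return CellPopulation(pos, time=time, domain=domain)


def write_cell_table(pop: CellPopulation, path) -> None:
    """Write a population as a ``cell_id,x,y`` CSV (microns)."""
    df = pd.DataFrame({
        "cell_id": np.arange(pop.size),
        "x": pop.positions[:, 0],
        "y": pop.positions[:, 1],
    })
    df.to_csv(path, index=False, float_format="%.17g")


def write_dataset(observations: Sequence[ScratchObservation], outdir,
                  seed: Optional[int] = None, extra: Optional[dict] = None,
                  ) -> Path:
    """Write observations + manifest.yaml to a directory; returns its path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for k, obs in enumerate(observations):
        label = obs.label or f"obs_{k:03d}"
        fi, ff = f"{label}_initial.csv", f"{label}_final.csv"
        write_cell_table(obs.initial, outdir / fi)
        write_cell_table(obs.final, outdir / ff)
        entries.append({
            "label": label, "initial": fi, "final": ff,
            "c0": int(obs.c0), "c24": int(obs.c24),
            "w0": float(obs.w0), "w24": float(obs.w24),
            "t0": float(obs.initial.time), "t_final": float(obs.final.time),
            "phi_um": float(obs.phi),
            "meta": _plain(obs.meta),
        })
    dom = observations[0].initial.domain if observations else Domain()
    manifest = {
        "um_per_px": observations[0].um_per_px if observations else UM_PER_PX,
        "fov_px": list(FOV_PX),
        "domain_um": {"width_x": dom.width_x, "width_y": dom.width_y},
        "seed": seed,
        "observations": entries,
    }
    if extra:
        manifest.update(_plain(extra))
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return outdir


def read_dataset(path) -> List[ScratchObservation]:
    """Read a dataset directory written by :func:`write_dataset`."""
    path = Path(path)
    with open(path / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    dom = Domain(**manifest["domain_um"])
    out = []
    for e in manifest["observations"]:
        initial = read_cell_table(path / e["initial"], domain=dom,
                                  time=e.get("t0", 0.0))
        final = read_cell_table(path / e["final"], domain=dom,
                                time=e.get("t_final", 24.0))
        out.append(ScratchObservation(
            initial=initial, final=final,
            w0=e["w0"], w24=e["w24"],
            um_per_px=manifest.get("um_per_px", UM_PER_PX),
            phi=e.get("phi_um", 24.0),
            label=e["label"], meta=e.get("meta") or {},
        ))
    return out


def write_particles(pop: ParticlePopulation, path) -> None:
    """Particle population to CSV (one row per particle)."""
    df = pd.DataFrame(pop.thetas, columns=list(PARAM_NAMES))
    df["weight"] = pop.weights
    df["distance"] = pop.distances
    df.to_csv(path, index=False, float_format="%.17g")


def read_particles(path, generation: int = 1) -> ParticlePopulation:
    df = pd.read_csv(path, float_precision="round_trip")
    return ParticlePopulation(
        thetas=df[list(PARAM_NAMES)].to_numpy(),
        weights=df["weight"].to_numpy(),
        distances=df["distance"].to_numpy(),
        generation=generation,
    )


def write_summary_json(sv: SummaryVector, path) -> None:
    with open(path, "w") as fh:
        json.dump({
            "n_final": int(sv.n_final),
            "pair_corr": [float(v) for v in sv.pair_corr],
            "density": [int(v) for v in sv.density],
        }, fh, indent=1)


def read_summary_json(path) -> SummaryVector:
    with open(path) as fh:
        d = json.load(fh)
    return SummaryVector(d["n_final"], np.array(d["pair_corr"]),
                         np.array(d["density"], dtype=int))


def _plain(obj):
    """Recursively convert numpy scalars/arrays for YAML serialisation."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
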