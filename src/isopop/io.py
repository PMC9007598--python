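"""Delimited-text serialization of isoboles, surfaces and run logs.

All files are plain CSV with ``#``-prefixed provenance comment lines before
the header. Floats are written with 17 significant digits so that every
file round-trips bit-exactly through the package readers.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .aggregate import ConfidenceSurface
from .fastisoboles import EffectiveIsobole, FastIsobolesResult
from .geometry import Polyline

__all__ = [
    "write_polyline", "read_polyline",
    "write_isobole", "read_isobole",
    "write_surface", "read_surface",
    "write_evaluation_log", "write_cache_table",
    "write_manifest",
]

def _write_header(fh, provenance: dict | None):
    for key, val in (provenance or {}).items():
        fh.write(f"# {key}: {val}\n")


def _read_comments(path) -> tuple[dict, int]:
    meta = {}
    n_skip = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n_skip += 1
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
    return meta, n_skip


def write_polyline(path, polylines, provenance: dict | None = None) -> None:
    """Write one or more polylines as two-column CSV.

    Multiple contour components are separated by a NaN,NaN row.
    """
    if isinstance(polylines, Polyline):
        polylines = [polylines]
    with open(path, "w") as fh:
        _write_header(fh, provenance)
        fh.write("amt1,amt2\n")
        for k, pl in enumerate(polylines):
            if k > 0:
                fh.write("nan,nan\n")
            for x, y in pl.points:
                fh.write(f"{x:.17g},{y:.17g}\n")


def read_polyline(path) -> tuple[list[Polyline], dict]:
    """Read polyline file; returns (components, provenance)."""
    meta, n_skip = _read_comments(path)
    df = pd.read_csv(path, skiprows=n_skip, float_precision="round_trip")
    pts = df.to_numpy(dtype=float)
    components = []
    breaks = np.where(np.isnan(pts).any(axis=1))[0]
    start = 0
    for b in list(breaks) + [len(pts)]:
        chunk = pts[start:b]
        if len(chunk) >= 2:
            components.append(Polyline(chunk))
        start = b + 1
    return components, meta


def write_isobole(path, iso: EffectiveIsobole,
                  extra: dict | None = None) -> None:
    """Serialize one population's effective isobole with its provenance."""
    prov = {
        "population_id": iso.population_id,
        "target_rate": repr(iso.target_rate),
        "bounds": f"{iso.bounds[0]:.17g},{iso.bounds[1]:.17g}",
    }
    if iso.classification:
        prov["classification"] = iso.classification
    prov.update(extra or {})
    polylines = [] if iso.degenerate else [iso.polyline]
    write_polyline(path, polylines, prov)


def read_isobole(path) -> EffectiveIsobole:
    components, meta = read_polyline(path)
    bounds = tuple(float(v) for v in meta["bounds"].split(","))
    return EffectiveIsobole(
        polyline=components[0] if components else Polyline(),
        target_rate=float(meta["target_rate"]),
        bounds=bounds,
        population_id=int(meta.get("population_id", -1)),
        classification=meta.get("classification"),
    )


def write_surface(path, surface: ConfidenceSurface,
                  provenance: dict | None = None) -> None:
    """Confidence surface as long-format (amt1, amt2, confidence) CSV."""
    prov = {
        "target_rate": repr(surface.target_rate),
        "n_pop": surface.n_pop,
        "resolution": f"{len(surface.axis1)},{len(surface.axis2)}",
    }
    prov.update(provenance or {})
    with open(path, "w") as fh:
        _write_header(fh, prov)
        fh.write("amt1,amt2,confidence\n")
        for i, a in enumerate(surface.axis1):
            for j, b in enumerate(surface.axis2):
                fh.write(f"{a:.17g},{b:.17g},{surface.values[i, j]:.17g}\n")


def read_surface(path) -> ConfidenceSurface:
    meta, n_skip = _read_comments(path)
    df = pd.read_csv(path, skiprows=n_skip, float_precision="round_trip")
    ax1 = np.unique(df.amt1.to_numpy())
    ax2 = np.unique(df.amt2.to_numpy())
    values = df.confidence.to_numpy().reshape(len(ax1), len(ax2))
    return ConfidenceSurface(ax1, ax2, values,
                             target_rate=float(meta["target_rate"]),
                             n_pop=int(meta["n_pop"]))


def write_evaluation_log(path, result: FastIsobolesResult,
                         provenance: dict | None = None) -> None:
    """Per-iteration log: nodes evaluated and Fréchet step distances."""
    with open(path, "w") as fh:
        _write_header(fh, provenance)
        fh.write("iteration,resolution,n_new_evaluations,"
                 "n_total_evaluations,frechet_step\n")
        for rec in result.iterations:
            fh.write(f"{rec.iteration},{rec.resolution},"
                     f"{rec.n_new_evaluations},{rec.n_total_evaluations},"
                     f"{rec.frechet_step:.17g}\n")


def write_cache_table(path, result: FastIsobolesResult,
                      provenance: dict | None = None) -> None:
    """Evaluated dose combinations as a long-format table."""
    with open(path, "w") as fh:
        _write_header(fh, provenance)
        fh.write("amt1,amt2,success_rate,iteration_first_evaluated\n")
        rows = sorted(result.grid.nodes_dose_units())
        for a, b, v, it in rows:
            fh.write(f"{a:.17g},{b:.17g},{v:.17g},{it}\n")


def write_manifest(path, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
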