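"""Plain-text format plumbing: rasters, code tables, envelopes, points.

Rasters travel as ESRI ASCII grid (``.asc``), a plain-text single-band
format any GIS reads.  Categorical layers (ERU, zone, masks) are written
as integer codes with a sidecar CSV code table; envelopes, profiles and
result tables are CSV; point sets are GeoJSON.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .landscape import Landscape, HabitatMap
from .projection import ClimateEnvelope
from .synthetic import OccurrenceRecord, Territory
from .taxonomy import Taxonomy

__all__ = [
    "write_ascii_grid", "read_ascii_grid",
    "write_landscape", "read_landscape",
    "write_mask", "read_mask",
    "write_envelopes", "read_envelopes",
    "write_points_geojson", "read_points_geojson",
]


def write_ascii_grid(path, array: np.ndarray, cell_size: float,
                     nodata: float = -9999) -> None:
    """Write a single-band raster as ESRI ASCII grid (origin lower-left)."""
    a = np.asarray(array)
    nr, nc = a.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {nc}\nnrows {nr}\nxllcorner 0\nyllcorner 0\n"
                 f"cellsize {cell_size}\nNODATA_value {nodata}\n")
        for row in a:
            fh.write(" ".join(format(v, "g") for v in row) + "\n")


def read_ascii_grid(path) -> tuple[np.ndarray, float]:
    """Read an ESRI ASCII grid; returns (array, cell_size)."""
    with open(path) as fh:
        header = {}
        pos = fh.tell()
        for _ in range(6):
            pos = fh.tell()
            parts = fh.readline().split()
            if len(parts) != 2 or not parts[0][0].isalpha():
                fh.seek(pos)
                break
            header[parts[0].lower()] = float(parts[1])
        data = np.loadtxt(fh)
    nr, nc = int(header["nrows"]), int(header["ncols"])
    return data.reshape(nr, nc), header.get("cellsize", 1.0)


def _codes(values: np.ndarray) -> tuple[np.ndarray, list[str]]:
    uniq = sorted(np.unique(values).tolist())
    lut = {v: i + 1 for i, v in enumerate(uniq)}
    coded = np.vectorize(lut.get)(values)
    return coded, uniq


def write_landscape(outdir, landscape: Landscape, taxonomy: Taxonomy) -> None:
    """Write ERU/zone/elevation rasters plus the ERU code table CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    eru_codes, eru_ids = _codes(landscape.eru)
    zone_codes, zone_ids = _codes(landscape.zone)
    write_ascii_grid(outdir / "eru.asc", eru_codes, landscape.cell_size)
    write_ascii_grid(outdir / "zone.asc", zone_codes, landscape.cell_size)
    write_ascii_grid(outdir / "elevation.asc", landscape.elevation,
                     landscape.cell_size)
    with open(outdir / "eru_codes.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["code", "eru_id", "name", "zone", "lifeform",
                    "is_forest_or_woodland"])
        for i, eid in enumerate(eru_ids, start=1):
            e = taxonomy[eid]
            w.writerow([i, e.id, e.name, e.zone, e.lifeform,
                        int(e.is_forest_or_woodland)])
    with open(outdir / "zone_codes.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["code", "zone_id"])
        for i, z in enumerate(zone_ids, start=1):
            w.writerow([i, z])


def read_landscape(indir) -> Landscape:
    indir = Path(indir)
    eru_codes, cs = read_ascii_grid(indir / "eru.asc")
    zone_codes, _ = read_ascii_grid(indir / "zone.asc")
    elev, _ = read_ascii_grid(indir / "elevation.asc")
    eru_lut = {}
    with open(indir / "eru_codes.csv", newline="") as fh:
        for r in csv.DictReader(fh):
            eru_lut[int(r["code"])] = r["eru_id"]
    zone_lut = {}
    with open(indir / "zone_codes.csv", newline="") as fh:
        for r in csv.DictReader(fh):
            zone_lut[int(r["code"])] = r["zone_id"]
    eru = np.vectorize(eru_lut.get)(eru_codes.astype(int))
    zone = np.vectorize(zone_lut.get)(zone_codes.astype(int))
    return Landscape(eru=eru, zone=zone, elevation=elev, cell_size=cs)


def write_mask(path, habitat: HabitatMap) -> None:
    write_ascii_grid(path, habitat.mask.astype(int), habitat.landscape.cell_size)


def read_mask(path, landscape: Landscape, **kw) -> HabitatMap:
    arr, _ = read_ascii_grid(path)
    return HabitatMap(landscape, arr.astype(bool), **kw)


def write_envelopes(path, envelopes: list[ClimateEnvelope]) -> None:
    """Long-format envelope CSV: eru_id, variable, mean, sd."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["eru_id", "variable", "mean", "sd"])
        for env in envelopes:
            for v, m, s in zip(env.variables, env.means, env.sds):
                w.writerow([env.eru_id, v, repr(m), repr(s)])


def read_envelopes(path) -> list[ClimateEnvelope]:
    rows: dict[str, list[tuple[str, float, float]]] = {}
    order: list[str] = []
    with open(path, newline="") as fh:
        for r in csv.DictReader(fh):
            if r["eru_id"] not in rows:
                rows[r["eru_id"]] = []
                order.append(r["eru_id"])
            rows[r["eru_id"]].append((r["variable"], float(r["mean"]),
                                      float(r["sd"])))
    out = []
    for eid in order:
        vs, ms, ss = zip(*rows[eid])
        out.append(ClimateEnvelope(eid, tuple(vs), tuple(ms), tuple(ss)))
    return out


def write_points_geojson(path, points) -> None:
    """Write occurrence records or territories as a GeoJSON FeatureCollection."""
    feats = []
    for p in points:
        props = {k: v for k, v in vars(p).items() if k not in ("x", "y")}
        feats.append({
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [p.x, p.y]},
            "properties": props,
        })
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh, indent=1)


def read_points_geojson(path, kind: str = "occurrence"):
    with open(path) as fh:
        gj = json.load(fh)
    out = []
    for f in gj["features"]:
        x, y = f["geometry"]["coordinates"]
        props = f["properties"]
        if kind == "occurrence":
            out.append(OccurrenceRecord(x=x, y=y, **props))
        else:
            out.append(Territory(x=x, y=y, **props))
    return out
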