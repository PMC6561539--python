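"""Readers and writers for the plain-text interchange formats.

Formats:
  * capture histories — CSV with header session,individual,occasion,
    detector[,sex]; occasions are 1-based in files, 0-based in memory.
  * trap layouts — CSV with header detector,x,y,d2river,d2boundary,
    camera_type,usage where usage is a binary string, one digit per
    occasion ("110" = off on occasion 3).
  * rasters — ESRI ASCII grid (ncols, nrows, xllcorner, yllcorner,
    cellsize, NODATA_value, then row-major values from the north row).
  * prey tables — long CSV species,station,array,count,effort
    [,d2boundary].

Coordinates in files are projected metres; no CRS handling.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .types import (CaptureSession, FittedModel, ModelSpec,
                    PreyDetectionTable, StateSpace, TrapLayout)

logger = logging.getLogger(__name__)

RASTER_NODATA = -9999.0


# ---------------------------------------------------------------------
# capture histories

def write_capthist(sessions: list[CaptureSession], path) -> None:
    rows = []
    for s in sessions:
        for r in s.detections.itertuples():
            rows.append({"session": s.array, "individual": r.individual,
                         "occasion": r.occasion + 1, "detector": r.detector,
                         "sex": s.sex_of(r.individual)})
    pd.DataFrame(rows, columns=["session", "individual", "occasion",
                                "detector", "sex"]).to_csv(path, index=False)


def read_capthist(path, traps: dict[str, TrapLayout]
                  ) -> list[CaptureSession]:
    """Read and validate capture histories against the trap layouts.

    Duplicate (individual, detector, occasion) rows collapse to one
    detection with a logged count; invalid rows are rejected with their
    file row number.
    """
    df = pd.read_csv(path, dtype={"session": str, "individual": str,
                                  "detector": str})
    required = {"session", "individual", "occasion", "detector"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"capture file missing columns: {sorted(missing)}")
    sessions = []
    for array, grp in df.groupby("session", sort=True):
        layout = traps.get(array)
        if layout is None:
            row = grp.index[0] + 2
            raise ValueError(f"row {row}: unknown session {array!r}")
        jidx = {d: j for j, d in enumerate(layout.ids)}
        for i, r in grp.iterrows():
            row = i + 2  # header + 1-based
            if r["detector"] not in jidx:
                raise ValueError(f"row {row}: unknown detector "
                                 f"{r['detector']!r} in session {array}")
            occ = int(r["occasion"])
            if not 1 <= occ <= layout.n_occasions:
                raise ValueError(f"row {row}: occasion {occ} out of range "
                                 f"1..{layout.n_occasions}")
            if layout.usage[jidx[r["detector"]], occ - 1] == 0:
                raise ValueError(f"row {row}: detection at detector "
                                 f"{r['detector']!r} occasion {occ} during "
                                 "usage=0")
        n_raw = len(grp)
        dedup = grp.drop_duplicates(
            subset=["individual", "detector", "occasion"])
        if len(dedup) < n_raw:
            logger.warning("session %s: collapsed %d duplicate detection "
                           "row(s)", array, n_raw - len(dedup))
        det = pd.DataFrame({
            "individual": dedup["individual"].to_numpy(),
            "detector": dedup["detector"].to_numpy(),
            "occasion": dedup["occasion"].astype(int).to_numpy() - 1,
        })
        sex = {}
        if "sex" in dedup.columns:
            for ind, sgrp in dedup.groupby("individual"):
                vals = set(sgrp["sex"].dropna().astype(str))
                sex[ind] = vals.pop() if len(vals) == 1 else "U"
        sessions.append(CaptureSession(array=array, detections=det, sex=sex))
    return sessions


# ---------------------------------------------------------------------
# trap layouts

def write_traps(layout: TrapLayout, path) -> None:
    usage = ["".join(str(int(u)) for u in row) for row in layout.usage]
    df = pd.DataFrame({
        "detector": layout.ids,
        "x": layout.xy[:, 0], "y": layout.xy[:, 1],
        "d2river": layout.covariates["d2river"].to_numpy(),
        "d2boundary": layout.covariates["d2boundary"].to_numpy(),
        "camera_type": layout.covariates["camera_type"].to_numpy(),
        "usage": usage,
    })
    df.to_csv(path, index=False)


def read_traps(path, array: str) -> TrapLayout:
    df = pd.read_csv(path, dtype={"detector": str, "usage": str})
    lengths = df["usage"].str.len().unique()
    if len(lengths) != 1:
        raise ValueError(f"ragged usage strings in {path}: lengths {sorted(lengths)}")
    usage = np.array([[int(c) for c in u] for u in df["usage"]])
    cov = df[["d2river", "d2boundary", "camera_type"]].reset_index(drop=True)
    return TrapLayout(array=array, ids=df["detector"].tolist(),
                      xy=df[["x", "y"]].to_numpy(float),
                      usage=usage, covariates=cov)


# ---------------------------------------------------------------------
# ESRI ASCII rasters

def write_raster(path, values: np.ndarray, xll: float, yll: float,
                 cellsize: float, nodata: float = RASTER_NODATA) -> None:
    """Write a 2-D grid (first row = northernmost) as ESRI ASCII."""
    values = np.asarray(values, dtype=float)
    nrows, ncols = values.shape
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xll:.6f}\n")
        fh.write(f"yllcorner {yll:.6f}\n")
        fh.write(f"cellsize {cellsize:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for row in values:
            fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")


def read_raster(path, expected_cellsize: Optional[float] = None
                ) -> tuple[np.ndarray, float, float, float, float]:
    """Read an ESRI ASCII grid → (values, xll, yll, cellsize, nodata)."""
    header = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if parts[0].lower() in ("ncols", "nrows", "xllcorner",
                                    "yllcorner", "cellsize", "nodata_value"):
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    for key in ("ncols", "nrows", "xllcorner", "yllcorner", "cellsize"):
        if key not in header:
            raise ValueError(f"raster {path} missing header field {key}")
    values = np.asarray(rows, dtype=float)
    if values.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"raster {path}: data shape {values.shape} does not "
                         "match header")
    cs = header["cellsize"]
    if expected_cellsize is not None and abs(cs - expected_cellsize) > 1e-9:
        raise ValueError(f"raster {path}: cellsize {cs} does not match "
                         f"configured pixel size {expected_cellsize}")
    nodata = header.get("nodata_value", RASTER_NODATA)
    return values, header["xllcorner"], header["yllcorner"], cs, nodata


def state_space_to_rasters(space: StateSpace) -> dict[str, dict]:
    """Per-covariate grids plus georeferencing for a rectangular mask."""
    xs = np.unique(space.xy[:, 0])
    ys = np.unique(space.xy[:, 1])
    ncols, nrows = len(xs), len(ys)
    if ncols * nrows != space.n_pixels:
        raise ValueError("state space is not a full rectangular grid")
    out = {}
    px = space.pixel_size
    for name in space.covariates.columns:
        grid = space.covariates[name].to_numpy(float).reshape(nrows, ncols)
        out[name] = {"values": grid, "xll": float(xs.min() - px / 2),
                     "yll": float(ys.min() - px / 2), "cellsize": px}
    return out


def write_state_space(space: StateSpace, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name, r in state_space_to_rasters(space).items():
        write_raster(directory / f"{name}.asc", r["values"], r["xll"],
                     r["yll"], r["cellsize"])
    meta = {"array": space.array, "pixel_size": space.pixel_size,
            "region_covariates": space.region_covariates}
    (directory / "region.json").write_text(json.dumps(meta, indent=2))


def read_state_space(directory, expected_pixel_size: Optional[float] = None
                     ) -> StateSpace:
    directory = Path(directory)
    meta = json.loads((directory / "region.json").read_text())
    px = meta["pixel_size"]
    if expected_pixel_size is not None and abs(px - expected_pixel_size) > 1e-9:
        raise ValueError(f"state space pixel size {px} does not match "
                         f"configured {expected_pixel_size}")
    cols = {}
    geo = None
    for f in sorted(directory.glob("*.asc")):
        values, xll, yll, cs, nodata = read_raster(f, px)
        if np.any(values == nodata):
            raise ValueError(f"raster {f} has NODATA inside the state space")
        cols[f.stem] = values
        geo = (xll, yll, cs, values.shape)
    if geo is None:
        raise ValueError(f"no rasters found in {directory}")
    xll, yll, cs, (nrows, ncols) = geo
    xs = xll + cs / 2 + cs * np.arange(ncols)
    ys = (yll + cs / 2 + cs * np.arange(nrows))[::-1]
    gx, gy = np.meshgrid(xs, ys)
    xy = np.column_stack([gx.ravel(), gy.ravel()])
    cov = pd.DataFrame({k: v.ravel() for k, v in cols.items()})
    return StateSpace(array=meta["array"], xy=xy, pixel_size=px,
                      covariates=cov,
                      region_covariates=meta.get("region_covariates", {}))


# ---------------------------------------------------------------------
# prey tables

def write_prey_table(table: PreyDetectionTable, path) -> None:
    rows = []
    for i, sp in enumerate(table.species):
        for j, st in enumerate(table.stations):
            rows.append({
                "species": sp, "station": st, "array": table.array[j],
                "count": int(table.y[i, j]), "effort": int(table.k[j]),
                "d2boundary": (float(table.d2boundary[j])
                               if table.d2boundary is not None else ""),
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_prey_table(path) -> PreyDetectionTable:
    df = pd.read_csv(path, dtype={"species": str, "station": str,
                                  "array": str})
    species = sorted(df["species"].unique())
    stations = sorted(df["station"].unique())
    sidx = {s: i for i, s in enumerate(species)}
    jidx = {s: j for j, s in enumerate(stations)}
    y = np.zeros((len(species), len(stations)), dtype=int)
    k = np.zeros(len(stations), dtype=int)
    arr = np.empty(len(stations), dtype=object)
    d2b = np.full(len(stations), np.nan)
    for r in df.itertuples():
        i, j = sidx[r.species], jidx[r.station]
        y[i, j] = int(r.count)
        k[j] = int(r.effort)
        arr[j] = r.array
        if hasattr(r, "d2boundary") and r.d2boundary not in ("", None):
            try:
                d2b[j] = float(r.d2boundary)
            except (TypeError, ValueError):
                pass
    d2boundary = None if np.isnan(d2b).all() else d2b
    return PreyDetectionTable(y=y, k=k, array=arr.astype(str),
                              species=species, stations=stations,
                              d2boundary=d2boundary)


# ---------------------------------------------------------------------
# fitted models

def fitted_to_dict(fit: FittedModel) -> dict:
    return {
        "spec": {"density": list(fit.spec.density), "p0": list(fit.spec.p0),
                 "sigma": list(fit.spec.sigma), "name": fit.spec.name},
        "estimates": fit.estimates.tolist(),
        "names": fit.names,
        "se": None if fit.se is None else fit.se.tolist(),
        "vcov": None if fit.vcov is None else fit.vcov.tolist(),
        "loglik": fit.loglik,
        "n_params": fit.n_params,
        "convergence": fit.convergence,
        "standardization": {k: list(v)
                            for k, v in fit.standardization.items()},
        "slices": {k: [v.start, v.stop] for k, v in fit.slices.items()},
        "array_levels": fit.array_levels,
    }


def fitted_from_dict(d: dict) -> FittedModel:
    spec = ModelSpec(density=tuple(d["spec"]["density"]),
                     p0=tuple(d["spec"]["p0"]),
                     sigma=tuple(d["spec"]["sigma"]),
                     name=d["spec"].get("name", ""))
    return FittedModel(
        spec=spec,
        estimates=np.asarray(d["estimates"], float),
        names=list(d["names"]),
        se=None if d["se"] is None else np.asarray(d["se"], float),
        vcov=None if d["vcov"] is None else np.asarray(d["vcov"], float),
        loglik=float(d["loglik"]),
        n_params=int(d["n_params"]),
        convergence=bool(d["convergence"]),
        standardization={k: tuple(v)
                         for k, v in d["standardization"].items()},
        slices={k: slice(v[0], v[1]) for k, v in d["slices"].items()},
        array_levels=list(d["array_levels"]),
    )


def write_fits(fits: list[FittedModel], path) -> None:
    Path(path).write_text(json.dumps([fitted_to_dict(f) for f in fits],
                                     indent=1))


def read_fits(path) -> list[FittedModel]:
    return [fitted_from_dict(d) for d in json.loads(Path(path).read_text())]
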