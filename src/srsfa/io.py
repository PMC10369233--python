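"""Readers and writers for the on-disk formats.

Formats (all plain, uncompressed by default):

* hyperspectral stack — multi-page 32-bit float TIFF, one page per
  wavenumber, plus a JSON sidecar ``{"wavenumbers_cm1": [...]}``;
* reference library — CSV with a ``wavenumber_cm1`` column and one column
  per component (``protein``, ``C14:0``, ..., ``unsat``);
* GC-MS table — CSV with ``species`` (Cn:u) and ``concentration`` columns,
  ``#`` comment lines allowed;
* label masks — integer TIFF;
* chain-length calibration — JSON;
* region tables / distributions / trajectories — tidy CSV.

Coordinates are 0-based row-major everywhere; the first TIFF page is the
lowest wavenumber after sorting.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile

from .cells import CellTrajectory
from .errors import FormatError, ValidationError
from .spectra import (
    ChainLengthCalibration,
    Component,
    GCMSProfile,
    ReferenceLibrary,
    Spectrum,
    WavenumberAxis,
    parse_species,
)
from .unmix import ChemicalMaps, HyperspectralStack


# --- hyperspectral stacks --------------------------------------------------

def write_hyperstack(stack: HyperspectralStack, tiff_path, sidecar_path) -> None:
    """Write a stack as multi-page float32 TIFF plus wavenumber sidecar."""
    pages = np.moveaxis(stack.data.astype(np.float32), 2, 0)
    tifffile.imwrite(tiff_path, pages)
    Path(sidecar_path).write_text(
        json.dumps({"wavenumbers_cm1": stack.axis.values.tolist()})
    )


def read_hyperstack(tiff_path, sidecar_path) -> HyperspectralStack:
    """Read a stack, validating the page count against the sidecar.

    A non-monotone sidecar axis is sorted (pages reordered accordingly)
    with a warning.
    """
    sidecar = json.loads(Path(sidecar_path).read_text())
    try:
        wn = np.asarray(sidecar["wavenumbers_cm1"], dtype=float)
    except KeyError:
        raise FormatError("sidecar is missing the 'wavenumbers_cm1' key") from None
    pages = tifffile.imread(tiff_path)
    if pages.ndim == 2:
        pages = pages[None]
    if pages.shape[0] != wn.size:
        raise FormatError(
            f"sidecar lists {wn.size} wavenumbers but TIFF has {pages.shape[0]} pages"
        )
    if not np.all(np.diff(wn) > 0):
        warnings.warn("sidecar axis not strictly increasing; sorting", stacklevel=2)
        order = np.argsort(wn, kind="stable")
        wn = wn[order]
        pages = pages[order]
    data = np.moveaxis(pages, 0, 2).astype(float)
    return HyperspectralStack(WavenumberAxis(wn), data)


# --- reference libraries ---------------------------------------------------

def _component_from_column(name: str, spectrum: Spectrum) -> Component:
    if name == "protein":
        return Component("protein", "protein", spectrum)
    if name in ("unsat", "unsaturated"):
        return Component(name, "unsaturated_composite", spectrum)
    n, u = parse_species(name)
    if u != 0:
        raise ValidationError(
            f"column {name!r}: individual unsaturated species are not valid "
            "library components; use a single 'unsat' column"
        )
    return Component(name, "saturated", spectrum, chain_length=n)


def read_reference_csv(path) -> ReferenceLibrary:
    """Read a reference library CSV (see module docstring for the schema)."""
    df = pd.read_csv(path, comment="#")
    if "wavenumber_cm1" not in df.columns:
        raise FormatError(f"{path}: first column must be 'wavenumber_cm1'")
    axis = WavenumberAxis(df["wavenumber_cm1"].to_numpy(dtype=float))
    comps = []
    for col in df.columns:
        if col == "wavenumber_cm1":
            continue
        comps.append(
            _component_from_column(col, Spectrum(axis, df[col].to_numpy(dtype=float)))
        )
    if not comps:
        raise FormatError(f"{path}: no component columns found")
    return ReferenceLibrary(tuple(comps))


def write_reference_csv(lib: ReferenceLibrary, path) -> None:
    df = pd.DataFrame({"wavenumber_cm1": lib.axis.values})
    for c in lib.components:
        df[c.name] = c.spectrum.intensity
    df.to_csv(path, index=False)


# --- GC-MS profiles --------------------------------------------------------

def read_gcms_csv(path) -> GCMSProfile:
    """Read a GC-MS table; malformed species labels are reported by row."""
    df = pd.read_csv(path, comment="#")
    for col in ("species", "concentration"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    bad_rows = []
    entries: dict[str, float] = {}
    for i, row in df.iterrows():
        label = str(row["species"]).strip()
        try:
            parse_species(label)
            conc = float(row["concentration"])
            if conc < 0 or not np.isfinite(conc):
                raise ValidationError("negative or non-finite concentration")
            entries[label] = entries.get(label, 0.0) + conc
        except (ValidationError, ValueError) as exc:
            bad_rows.append(f"row {i + 2}: {label!r} ({exc})")  # +2: header + 1-based
    if bad_rows:
        raise ValidationError(f"{path}: invalid rows: " + "; ".join(bad_rows))
    return GCMSProfile(entries)


def write_gcms_csv(profile: GCMSProfile, path, units: str = "relative fraction") -> None:
    lines = [f"# concentration units: {units}", "species,concentration"]
    lines += [f"{k},{v!r}" for k, v in profile.entries.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# --- calibration -----------------------------------------------------------

def write_calibration_json(cal: ChainLengthCalibration, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "slope": cal.slope,
                "intercept": cal.intercept,
                "r_squared": cal.r_squared,
                "ch2_window": list(cal.ch2_window),
                "ch3_window": list(cal.ch3_window),
            },
            indent=2,
        )
    )


def read_calibration_json(path) -> ChainLengthCalibration:
    d = json.loads(Path(path).read_text())
    try:
        return ChainLengthCalibration(
            slope=float(d["slope"]),
            intercept=float(d["intercept"]),
            r_squared=float(d["r_squared"]),
            ch2_window=tuple(d["ch2_window"]),
            ch3_window=tuple(d["ch3_window"]),
        )
    except KeyError as exc:
        raise FormatError(f"{path}: missing calibration key {exc}") from None


# --- masks -----------------------------------------------------------------

def write_mask_tiff(mask: np.ndarray, path) -> None:
    mask = np.asarray(mask)
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValidationError("mask must be an integer label image")
    tifffile.imwrite(path, mask.astype(np.int32))


def read_mask_tiff(path) -> np.ndarray:
    mask = tifffile.imread(path)
    if mask.ndim != 2:
        raise FormatError(f"{path}: mask must be a single 2D page")
    if not np.issubdtype(mask.dtype, np.integer):
        raise FormatError(f"{path}: mask must be integer-typed, got {mask.dtype}")
    return mask.astype(np.int32)


# --- chemical maps ---------------------------------------------------------

def write_chemical_maps(maps: ChemicalMaps, out_dir, manifest_extra: dict | None = None) -> None:
    """One float32 TIFF per component plus residual.tif and a JSON manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, name in enumerate(maps.names):
        tifffile.imwrite(
            out / f"{name.replace(':', '_')}.tif", maps.maps[..., i].astype(np.float32)
        )
    if maps.residual is not None:
        tifffile.imwrite(out / "residual.tif", maps.residual.astype(np.float32))
    manifest = {
        "components": [
            {
                "name": n,
                "category": c,
                "chain_length": cl,
                "area": float(a),
                "file": f"{n.replace(':', '_')}.tif",
            }
            for n, c, cl, a in zip(
                maps.names, maps.categories, maps.chain_lengths, maps.areas
            )
        ],
        "has_residual": maps.residual is not None,
    }
    manifest.update(manifest_extra or {})
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))


def read_chemical_maps(out_dir) -> ChemicalMaps:
    out = Path(out_dir)
    manifest = json.loads((out / "manifest.json").read_text())
    names, cats, cls, areas, planes = [], [], [], [], []
    for comp in manifest["components"]:
        names.append(comp["name"])
        cats.append(comp["category"])
        cls.append(comp["chain_length"])
        areas.append(comp["area"])
        planes.append(tifffile.imread(out / comp["file"]).astype(float))
    residual = None
    if manifest.get("has_residual") and (out / "residual.tif").exists():
        residual = tifffile.imread(out / "residual.tif").astype(float)
    return ChemicalMaps(
        names=tuple(names),
        categories=tuple(cats),
        chain_lengths=tuple(cls),
        areas=np.asarray(areas),
        maps=np.stack(planes, axis=-1),
        residual=residual,
    )


# --- tables ----------------------------------------------------------------

def write_region_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def write_distribution_csv(dist, path) -> None:
    pd.DataFrame({"bin": list(dist.bins), "fraction": dist.fractions}).to_csv(
        path, index=False
    )


def read_trajectories_csv(path) -> list[CellTrajectory]:
    """Read cell-length trajectories: cell_id, time_min, length_um[, parent_id]."""
    df = pd.read_csv(path, comment="#")
    for col in ("cell_id", "time_min", "length_um"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    out = []
    for cid, group in df.groupby("cell_id", sort=True):
        group = group.sort_values("time_min")
        parent = None
        if "parent_id" in group.columns:
            vals = group["parent_id"].dropna().unique()
            if vals.size:
                parent = int(vals[0])
        out.append(
            CellTrajectory(
                cell_id=int(cid),
                times_min=group["time_min"].to_numpy(dtype=float),
                lengths_um=group["length_um"].to_numpy(dtype=float),
                parent_id=parent,
            )
        )
    return out


def write_trajectories_csv(trajectories: Sequence[CellTrajectory], path) -> None:
    rows = []
    for tr in trajectories:
        for t, length in zip(tr.times_min, tr.lengths_um):
            rows.append(
                {
                    "cell_id": tr.cell_id,
                    "time_min": t,
                    "length_um": length,
                    "parent_id": tr.parent_id,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)
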