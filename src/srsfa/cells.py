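"""Single-cell, colony and droplet quantification plus growth rates.

Works on integer label masks produced by an external segmentation pipeline
(e.g. CellProfiler on the protein channel, or DeLTA on phase contrast).
Label 0 is background; region ids need not be contiguous. Masks and maps
share the same pixel-index space: row-major, origin top-left, 0-based.

Two normalization conventions are supported, mirroring how single cells
and microcolonies are reported: fatty-acid mass per cell *area* for single
cells (robust when cells grow on top of each other is not a concern) and
per *protein* mass at the microcolony level (which accounts for stacked
cells). Growth rate is the centered logarithmic derivative of cell length,

    mu_k = (1 / 2 dt) * ln(L_{k+1} / L_{k-1}),

exact for exponential elongation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NoRegionsError, SpacingError
from .composition import (
    DEFAULT_BINS,
    chain_length_distribution,
    unsaturation_ratio,
)
from .errors import EmptySelectionError, UndefinedRatioError
from .unmix import ChemicalMaps, combined_fatty_acid_map

#: Default physical pixel pitch, micrometres (the endpoint imaging step size).
DEFAULT_PIXEL_SIZE_UM = 0.15

#: Fractional length drop between consecutive frames that marks a division.
DIVISION_DROP = 0.30


@dataclass(frozen=True)
class CellTrajectory:
    """Time-stamped single-cell length series (minutes, micrometres)."""

    cell_id: int
    times_min: np.ndarray
    lengths_um: np.ndarray
    parent_id: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times_min, dtype=float)
        ln = np.asarray(self.lengths_um, dtype=float)
        if t.ndim != 1 or t.shape != ln.shape:
            raise ValueError("times and lengths must be matching 1D arrays")
        if t.size >= 2 and not np.all(np.diff(t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if np.any(ln <= 0):
            raise ValueError("lengths must be positive")
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "lengths_um", ln)

    def __len__(self) -> int:
        return self.times_min.size


def _region_sums(values: np.ndarray, labels: np.ndarray, ids: np.ndarray) -> np.ndarray:
    flat = np.bincount(
        labels.ravel(), weights=values.ravel(), minlength=int(labels.max()) + 1
    )
    return flat[ids]


def quantify_regions(
    maps: ChemicalMaps,
    mask: np.ndarray,
    mode: str = "per_area",
    include_composition: bool = False,
    bins=DEFAULT_BINS,
) -> pd.DataFrame:
    """Per-region protein and fatty-acid totals from a label mask.

    Returns a tidy DataFrame with one row per region id: ``area_px``,
    ``protein_total``, ``fa_total``, ``fa_per_area``, ``fa_per_protein``
    and a ``production`` column selected by ``mode`` ("per_area" or
    "per_protein"). Background (label 0) is excluded from every total.
    Regions with zero protein get NaN ``fa_per_protein``. With
    ``include_composition`` the per-region chain-length fractions and
    unsaturation ratio are appended where defined.
    """
    if mode not in ("per_area", "per_protein"):
        raise ValueError(f"unknown mode {mode!r}")
    mask = np.asarray(mask)
    if mask.shape != maps.shape:
        raise ValueError(f"mask shape {mask.shape} does not match maps {maps.shape}")
    if not np.issubdtype(mask.dtype, np.integer):
        raise ValueError("mask must be an integer label image")
    if mask.min() < 0:
        raise ValueError("labels must be non-negative")
    ids = np.unique(mask)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise NoRegionsError("mask contains no labeled regions")

    protein_idx = [i for i, c in enumerate(maps.categories) if c == "protein"]
    protein_mass = (
        (maps.maps[..., protein_idx] * maps.areas[protein_idx]).sum(axis=2)
        if protein_idx
        else np.zeros(maps.shape)
    )
    fa_mass = combined_fatty_acid_map(maps)

    area = _region_sums(np.ones(mask.shape), mask, ids)
    protein_total = _region_sums(protein_mass, mask, ids)
    fa_total = _region_sums(fa_mass, mask, ids)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa_per_protein = np.where(protein_total > 0, fa_total / protein_total, np.nan)
    table = pd.DataFrame(
        {
            "id": ids.astype(int),
            "area_px": area.astype(int),
            "protein_total": protein_total,
            "fa_total": fa_total,
            "fa_per_area": fa_total / area,
            "fa_per_protein": fa_per_protein,
        }
    )
    table["production"] = (
        table["fa_per_area"] if mode == "per_area" else table["fa_per_protein"]
    )

    if include_composition:
        fracs, unsats = [], []
        for rid in table["id"]:
            region = mask == rid
            try:
                dist = chain_length_distribution(maps, region=region, bins=bins)
                fracs.append(dist.fractions)
            except EmptySelectionError:
                fracs.append(np.full(len(bins), np.nan))
            try:
                unsats.append(unsaturation_ratio(maps, region=region))
            except (EmptySelectionError, UndefinedRatioError):
                unsats.append(np.nan)
        fr = np.asarray(fracs)
        for j, b in enumerate(bins):
            table[f"frac_C{int(b)}"] = fr[:, j]
        table["unsat_ratio"] = unsats
    return table


def classify_high_producers(
    table: pd.DataFrame, fraction: float = 0.15, column: str = "production"
) -> pd.Series:
    """Flag the top-``fraction`` producing regions.

    The cut is the empirical (1 - fraction) quantile with linear
    interpolation; ties at the quantile are included. When every region
    produces identically the distribution is degenerate: all regions are
    flagged and a warning is emitted.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    values = table[column].to_numpy(dtype=float)
    if values.size == 0:
        raise NoRegionsError("empty region table")
    if np.any(np.isnan(values)):
        raise ValueError(f"column {column!r} contains NaN; cannot rank")
    if np.ptp(values) == 0:
        warnings.warn(
            "all regions produce identically; flagging every region", stacklevel=2
        )
        return pd.Series(True, index=table.index, name="high_producer")
    cut = float(np.quantile(values, 1.0 - fraction))
    return pd.Series(values >= cut, index=table.index, name="high_producer")


def growth_rate(
    traj: CellTrajectory,
    spacing_rtol: float = 1e-3,
    mask_divisions: bool = False,
) -> pd.DataFrame:
    """Centered log-derivative growth rate at each interior frame.

    Returns a DataFrame with ``frame``, ``time_min`` and ``mu_per_min``;
    endpoint frames have no rate (no extrapolation). Requires uniform
    frame spacing within ``spacing_rtol``. With ``mask_divisions`` frames
    within +-1 of a division event (length drop > 30% between consecutive
    frames) get NaN rates, since the raw formula produces a negative spike
    there.
    """
    if len(traj) < 3:
        raise ValueError("need at least 3 frames for a centered derivative")
    dt = np.diff(traj.times_min)
    if np.ptp(dt) > spacing_rtol * float(np.mean(dt)):
        raise SpacingError(
            f"frame spacing varies by {np.ptp(dt):g} min "
            f"(mean {np.mean(dt):g} min); uniform spacing required"
        )
    step = float(np.mean(dt))
    L = traj.lengths_um
    mu = np.log(L[2:] / L[:-2]) / (2.0 * step)
    frames = np.arange(1, len(traj) - 1)
    out = pd.DataFrame(
        {
            "frame": frames,
            "time_min": traj.times_min[1:-1],
            "mu_per_min": mu,
        }
    )
    if mask_divisions:
        drops = np.flatnonzero(L[1:] < (1.0 - DIVISION_DROP) * L[:-1]) + 1
        bad = set()
        for d in drops:
            bad.update((d - 1, d, d + 1))
        out.loc[out["frame"].isin(bad), "mu_per_min"] = np.nan
    return out


def detect_divisions(traj: CellTrajectory, drop: float = DIVISION_DROP) -> np.ndarray:
    """Frame indices where length fell by more than ``drop`` from the previous frame."""
    L = traj.lengths_um
    return np.flatnonzero(L[1:] < (1.0 - drop) * L[:-1]) + 1


def colony_time_series(
    times: np.ndarray,
    maps_sequence,
    masks_sequence,
) -> pd.DataFrame:
    """Protein and fatty-acid totals of a colony across timepoints.

    ``maps_sequence`` and ``masks_sequence`` are parallel sequences; a
    ``None`` mask marks a missing timepoint, which is recorded as a gap
    (NaN row), never interpolated. Totals sum over all labeled pixels.
    """
    times = np.asarray(times, dtype=float)
    if not (len(times) == len(maps_sequence) == len(masks_sequence)):
        raise ValueError("times, maps and masks must have equal length")
    if len(times) < 2:
        raise ValueError("need at least 2 timepoints")
    rows = []
    for t, maps, mask in zip(times, maps_sequence, masks_sequence):
        if mask is None or maps is None:
            rows.append(
                {"time_min": t, "protein_total": np.nan, "fa_total": np.nan,
                 "fa_per_protein": np.nan, "missing": True}
            )
            continue
        table = quantify_regions(maps, np.asarray(mask), mode="per_protein")
        protein = float(table["protein_total"].sum())
        fa = float(table["fa_total"].sum())
        rows.append(
            {
                "time_min": t,
                "protein_total": protein,
                "fa_total": fa,
                "fa_per_protein": fa / protein if protein > 0 else np.nan,
                "missing": False,
            }
        )
    return pd.DataFrame(rows)
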