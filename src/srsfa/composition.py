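"""Chain-length and unsaturation analytics on unmixed chemical maps.

Two complementary readouts come out of the saturated fatty-acid maps:

* a per-pixel *average chain length* image, obtained by reconstructing the
  saturated-only spectrum at each pixel, taking the CH2/CH3 band-area
  ratio, and applying the linear calibration from pure standards;
* a *chain-length distribution* over even carbons, either from the
  per-component concentration mass directly (default) or by binning the
  per-pixel averages weighted by saturated mass.

Distributions are compared with bulk GC-MS tables via the base-2
Jensen-Shannon divergence, which is symmetric and bounded in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import EmptySelectionError, UndefinedRatioError
from .spectra import (
    CHAIN_LENGTH_RANGE,
    ChainLengthCalibration,
    ReferenceLibrary,
    predict_chain_length,
)
from .unmix import ChemicalMaps, combined_fatty_acid_map

#: Even-carbon bins matching what the GC-MS assay reports.
DEFAULT_BINS = (8, 10, 12, 14, 16, 18)


@dataclass(frozen=True)
class ChainLengthMap:
    """Per-pixel average saturated chain length.

    ``values`` is a float32 image (matching the 32-bit on-disk dialect)
    quantized to 0.01 carbons; pixels whose saturated mass fell below
    ``threshold`` are NaN, never a numeric placeholder.
    """

    values: np.ndarray
    threshold: float
    calibration: ChainLengthCalibration

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float32)
        if v.ndim != 2:
            raise ValueError("chain-length map must be 2D")
        finite = v[np.isfinite(v)]
        if finite.size and (
            finite.min() < CHAIN_LENGTH_RANGE[0] - 1e-3
            or finite.max() > CHAIN_LENGTH_RANGE[1] + 1e-3
        ):
            raise ValueError("defined chain lengths must lie in the clip range")
        object.__setattr__(self, "values", v)

    def defined_mask(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass(frozen=True)
class ChainLengthDistribution:
    """Fraction of saturated fatty-acid mass per even-carbon bin."""

    bins: tuple[int, ...]
    fractions: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fractions, dtype=float)
        if f.shape != (len(self.bins),):
            raise ValueError("one fraction per bin required")
        if np.any(f < 0):
            raise ValueError("fractions must be non-negative")
        if abs(f.sum() - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {f.sum()!r}")
        object.__setattr__(self, "fractions", f)

    def as_dict(self) -> dict[int, float]:
        return {b: float(v) for b, v in zip(self.bins, self.fractions)}


def _saturated_indices(maps: ChemicalMaps) -> list[int]:
    idx = [i for i, cat in enumerate(maps.categories) if cat == "saturated"]
    if not idx:
        raise EmptySelectionError("maps contain no saturated components")
    return idx


def estimate_noise_sigma(maps: ChemicalMaps) -> float:
    """Robust scale of the combined fatty-acid map's background.

    Uses 1.4826 * MAD around the median, which ignores the sparse
    high-signal foreground; used for the default chain-length threshold.
    """
    fa = combined_fatty_acid_map(maps)
    med = np.median(fa)
    return float(1.4826 * np.median(np.abs(fa - med)))


def chain_length_map(
    maps: ChemicalMaps,
    lib: ReferenceLibrary,
    cal: ChainLengthCalibration,
    threshold: float | None = None,
) -> ChainLengthMap:
    """Average saturated chain length per pixel.

    The saturated-only spectrum at a pixel is ``sum_k C_k S_k`` over the
    saturated components; its CH2/CH3 AUC ratio is a linear functional of
    the maps, so the whole image reduces to two matrix products. Pixels
    whose saturated mass is at or below ``threshold`` (default: 5x the
    background noise scale from :func:`estimate_noise_sigma`, where
    low-signal predictions fluctuate strongly) are left undefined (NaN).
    """
    idx = _saturated_indices(maps)
    names = [maps.names[i] for i in idx]
    S = np.stack([lib[name].spectrum.intensity for name in names])
    w2 = lib.axis.window_weights(*cal.ch2_window)
    w3 = lib.axis.window_weights(*cal.ch3_window)
    ch2_per_comp = S @ w2  # (K_sat,)
    ch3_per_comp = S @ w3
    sat_maps = maps.maps[..., idx]
    ch2 = sat_maps @ ch2_per_comp
    ch3 = sat_maps @ ch3_per_comp

    sat_mass = (sat_maps * maps.areas[idx]).sum(axis=2)
    if threshold is None:
        threshold = 5.0 * estimate_noise_sigma(maps)
    defined = (sat_mass > threshold) & (ch3 > 0)

    values = np.full(maps.shape, np.nan, dtype=float)
    ratio = np.divide(ch2, ch3, out=np.zeros_like(ch2), where=defined)
    pred = predict_chain_length(ratio, cal, clip=True)
    values[defined] = np.asarray(pred)[defined]
    # Chain lengths are reported at 0.01-carbon resolution: the band-ratio
    # estimate carries no physical meaning beyond that, and the rounding
    # keeps maps stable against solver-path jitter in flat directions.
    values = np.round(values, 2)
    return ChainLengthMap(
        values=values.astype(np.float32), threshold=float(threshold), calibration=cal
    )


def bin_chain_length(value):
    """Round a continuous chain length to the nearest even carbon.

    Odd-integer midpoints round *down* (15.0 -> 14), so a prediction like
    14.9 lands in the C14 bin. NaN propagates. Accepts scalars or arrays.
    """
    v = np.asarray(value, dtype=float)
    lower = 2.0 * np.floor(v / 2.0)
    frac = v - lower
    binned = np.where(frac <= 1.0, lower, lower + 2.0)
    binned = np.clip(binned, *CHAIN_LENGTH_RANGE)
    binned = np.where(np.isnan(v), np.nan, binned)
    if np.isscalar(value) or np.asarray(value).ndim == 0:
        return float(binned)
    return binned


def chain_length_distribution(
    maps: ChemicalMaps,
    region: np.ndarray | None = None,
    bins: Sequence[int] = DEFAULT_BINS,
    method: str = "component_mass",
    lib: ReferenceLibrary | None = None,
    cal: ChainLengthCalibration | None = None,
    threshold: float | None = None,
) -> ChainLengthDistribution:
    """Distribution of saturated fatty-acid mass over even-carbon bins.

    method="component_mass" (default): each saturated component's summed
    concentration mass over the region is assigned to its chain-length
    bin. method="pixel_binned": per-pixel average chain lengths (from
    :func:`chain_length_map`, which requires ``lib`` and ``cal``) are
    binned, weighting each pixel by its saturated mass.

    Mass outside the bin range is clipped into the terminal bins with a
    warning; fractions always sum to 1.
    """
    bins = tuple(int(b) for b in bins)
    if list(bins) != sorted(bins) or len(set(bins)) != len(bins) or any(b % 2 for b in bins):
        raise ValueError("bins must be strictly increasing even carbons")
    idx = _saturated_indices(maps)
    sat_maps = maps.maps[..., idx]
    if region is not None:
        region = np.asarray(region, dtype=bool)
        if region.shape != maps.shape:
            raise ValueError("region mask shape does not match maps")
        sat_maps = sat_maps[region]
    else:
        sat_maps = sat_maps.reshape(-1, len(idx))

    mass_per_bin = dict.fromkeys(bins, 0.0)
    clipped = 0.0

    def deposit(n: float, mass: float) -> None:
        nonlocal clipped
        if mass <= 0:
            return
        b = int(bin_chain_length(n))
        if b < bins[0]:
            clipped += mass
            b = bins[0]
        elif b > bins[-1]:
            clipped += mass
            b = bins[-1]
        elif b not in mass_per_bin:
            b = min(bins, key=lambda x: abs(x - b))
        mass_per_bin[b] += mass

    if method == "component_mass":
        comp_mass = (sat_maps * maps.areas[idx]).sum(axis=0)
        comp_mass = np.maximum(comp_mass, 0.0)
        for i, m in zip(idx, comp_mass):
            deposit(float(maps.chain_lengths[i]), float(m))
    elif method == "pixel_binned":
        if lib is None or cal is None:
            raise ValueError("pixel_binned route requires lib and cal")
        clm = chain_length_map(maps, lib, cal, threshold=threshold)
        sat_mass = (maps.maps[..., idx] * maps.areas[idx]).sum(axis=2)
        sel = clm.defined_mask()
        if region is not None:
            sel = sel & region
        for n, m in zip(clm.values[sel].tolist(), sat_mass[sel].tolist()):
            deposit(n, m)
    else:
        raise ValueError(f"unknown method {method!r}")

    total = sum(mass_per_bin.values())
    if total <= 0:
        raise EmptySelectionError("zero saturated mass in region")
    if clipped > 0:
        warnings.warn(
            f"{clipped / total:.1%} of saturated mass fell outside the bin range "
            "and was clipped into the terminal bins",
            stacklevel=2,
        )
    fractions = np.array([mass_per_bin[b] for b in bins]) / total
    return ChainLengthDistribution(bins=bins, fractions=fractions)


def unsaturation_ratio(
    maps: ChemicalMaps,
    region: np.ndarray | None = None,
    eps: float = 1e-12,
) -> float:
    """Unsaturated over saturated fatty-acid mass in a region.

    Masses are concentration maps weighted by each reference's spectral
    area, so with unit-area references this is the plain concentration
    ratio and with GC-MS-scaled references the shares fold in correctly.
    """
    sat_idx = _saturated_indices(maps)
    unsat_idx = [
        i for i, cat in enumerate(maps.categories) if cat == "unsaturated_composite"
    ]
    if not unsat_idx:
        raise EmptySelectionError("maps contain no unsaturated_composite component")
    m = maps.maps
    if region is not None:
        region = np.asarray(region, dtype=bool)
        m = m[region]
    else:
        m = m.reshape(-1, m.shape[-1])
    sat_total = float((m[:, sat_idx] * maps.areas[sat_idx]).sum())
    unsat_total = float((m[:, unsat_idx] * maps.areas[unsat_idx]).sum())
    if sat_total <= eps:
        raise UndefinedRatioError("zero saturated mass; unsaturation ratio undefined")
    return max(unsat_total, 0.0) / sat_total


def js_divergence(p: ChainLengthDistribution, q: ChainLengthDistribution) -> float:
    """Base-2 Jensen-Shannon divergence between two binned distributions.

    JSD(p, q) = 1/2 KL(p || m) + 1/2 KL(q || m) with m = (p + q)/2 and
    logarithms base 2; symmetric, bounded in [0, 1], zero iff p == q.
    The convention 0 * log 0 = 0 applies.
    """
    if p.bins != q.bins:
        raise ValueError(f"bin sets differ: {p.bins} vs {q.bins}")
    pv, qv = p.fractions, q.fractions
    m = 0.5 * (pv + qv)

    def kl(a: np.ndarray, b: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / b[mask])))

    return 0.5 * kl(pv, m) + 0.5 * kl(qv, m)


def distribution_from_profile(
    profile, bins: Sequence[int] = DEFAULT_BINS
) -> ChainLengthDistribution:
    """Saturated chain-length distribution implied by a GC-MS profile."""
    bins = tuple(int(b) for b in bins)
    fracs = profile.saturated_fractions()
    mass = dict.fromkeys(bins, 0.0)
    for n, f in fracs.items():
        b = min(max(n, bins[0]), bins[-1])
        mass[b] += f
    total = sum(mass.values())
    return ChainLengthDistribution(
        bins=bins, fractions=np.array([mass[b] for b in bins]) / total
    )
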