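"""Synthetic reference spectra, hyperspectral scenes and growth trajectories.

Every stage of the pipeline is testable without instrument data: this
module builds C-H-region reference spectra from a Gaussian band model
(parameters in ``band_model.yaml``), paints rod-shaped cells and
extracellular droplets into a ground-truth concentration cube, mixes the
cube with the references, and adds Gaussian noise at a stated SNR.

The band model is a fixture that reproduces the *qualitative* structure of
measured standards — CH2 bands in 2832-2888 cm^-1 whose amplitude grows
with chain length, fixed CH3 bands in 2909-2967 cm^-1, and the ~3000 cm^-1
=C-H marker unique to unsaturated fatty acids — not their instrument
lineshapes. All generators are pure functions of (parameters, seed).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import yaml

from .cells import CellTrajectory
from .errors import PackingError, ValidationError
from .spectra import (
    Component,
    GCMSProfile,
    ReferenceLibrary,
    Spectrum,
    WavenumberAxis,
    normalize_spectrum,
    parse_species,
)
from .unmix import HyperspectralStack

#: Signal-to-noise ratio used throughout the bundled study conditions:
#: mean in-cell peak signal divided by the additive noise sigma.
DEFAULT_SNR = 20.0

#: Fraction of cells carrying the high-producer phenotype in intra-colony
#: scenes (a small percentage of cells produces the vast majority).
DEFAULT_HIGH_PRODUCER_FRACTION = 0.1


def load_band_model() -> dict:
    """Band-model parameters from the packaged ``band_model.yaml``."""
    text = (resources.files("srsfa") / "band_model.yaml").read_text()
    return yaml.safe_load(text)


def default_axis(params: Mapping | None = None) -> WavenumberAxis:
    """The default synthetic axis: 2800-3050 cm^-1, 40 uniform samples."""
    params = params or load_band_model()
    ax = params["axis"]
    return WavenumberAxis(np.linspace(ax["start"], ax["stop"], int(ax["n"])))


def _gaussian_sum(x: np.ndarray, bands: Sequence[Mapping], scale: float = 1.0) -> np.ndarray:
    y = np.zeros_like(x)
    for b in bands:
        y += (
            scale
            * b["amplitude"]
            * np.exp(-0.5 * ((x - b["center"]) / b["width"]) ** 2)
        )
    return y


def model_spectrum(
    species: str, axis: WavenumberAxis | None = None, params: Mapping | None = None
) -> Spectrum:
    """Model spectrum for ``protein``, ``unsat`` or a saturated ``Cn:0``.

    Saturated spectra: sum of CH2 bands scaled by (n - 2) plus fixed CH3
    bands, so the CH2/CH3 area ratio grows linearly with chain length by
    construction.
    """
    params = params or load_band_model()
    axis = axis or default_axis(params)
    x = axis.values
    if species == "protein":
        y = _gaussian_sum(x, params["protein_bands"])
    elif species in ("unsat", "unsaturated"):
        y = _gaussian_sum(x, params["unsaturated_bands"])
    else:
        n, u = parse_species(species)
        if u != 0:
            raise ValidationError(
                f"individual unsaturated species {species!r} have no distinct "
                "model spectrum; use the composite 'unsat' channel"
            )
        shifts = params.get("saturated_center_shift_per_carbon", {})
        wslope = float(params.get("saturated_width_slope_per_carbon", 0.0))
        dn = float(n - 12)  # centered so C12 keeps the nominal band table

        def chain_bands(bands, kind: str):
            shift = float(shifts.get(kind, 0.0)) * dn
            return [
                {
                    "center": b["center"] + shift,
                    "width": b["width"] * (1.0 + wslope * dn),
                    "amplitude": b["amplitude"],
                }
                for b in bands
            ]

        y = _gaussian_sum(
            x, chain_bands(params["ch2_bands"], "ch2"), scale=float(n - 2)
        ) + _gaussian_sum(x, chain_bands(params["ch3_bands"], "ch3"))
    return Spectrum(axis, y)


def make_reference_spectra(
    species: Sequence[str],
    axis: WavenumberAxis | None = None,
    params: Mapping | None = None,
    normalized: bool = False,
) -> ReferenceLibrary:
    """Build a reference library of model spectra for the listed species.

    ``species`` mixes "protein", "unsat" and saturated labels like
    "C14:0". Chain lengths outside C6-C20 raise a range error. With
    ``normalized`` each spectrum is rescaled to unit trapezoidal area.
    """
    params = params or load_band_model()
    axis = axis or default_axis(params)
    comps = []
    for sp in species:
        s = model_spectrum(sp, axis=axis, params=params)
        if normalized:
            s = normalize_spectrum(s)
        if sp == "protein":
            comps.append(Component("protein", "protein", s))
        elif sp in ("unsat", "unsaturated"):
            comps.append(Component("unsat", "unsaturated_composite", s))
        else:
            n, _ = parse_species(sp)
            comps.append(Component(sp, "saturated", s, chain_length=n))
    return ReferenceLibrary(tuple(comps))


def noisy_standards(
    species: Sequence[str],
    snr: float = DEFAULT_SNR,
    n_replicates: int = 6,
    seed: int = 0,
    axis: WavenumberAxis | None = None,
    params: Mapping | None = None,
) -> list[tuple[int, Spectrum]]:
    """Noise replicates of normalized saturated standards for calibration.

    Each replicate is the unit-area model spectrum plus i.i.d. Gaussian
    noise with sigma = (spectrum peak) / snr, emulating repeated
    measurements of pure standards. Returns (chain_length, spectrum)
    pairs, ``n_replicates`` per species, deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    out: list[tuple[int, Spectrum]] = []
    for sp in species:
        n, u = parse_species(sp)
        if u != 0:
            raise ValidationError("calibration standards must be saturated")
        base = normalize_spectrum(model_spectrum(sp, axis=axis, params=params))
        sigma = float(base.intensity.max()) / snr
        for _ in range(n_replicates):
            y = base.intensity + rng.normal(0.0, sigma, base.intensity.size)
            out.append((n, Spectrum(base.axis, y)))
    return out


_PRESETS: dict[str, dict[str, float]] = {
    # Invented fixture numbers shaped after the three thioesterase
    # phenotypes: a short-chain producer dominated by C8:0, a mixed
    # producer peaking at C14:0, and a long-chain producer with large
    # C14:0/C16:0 contributions. Not measured values.
    "short_chain_producer": {
        "C8:0": 66.0, "C10:0": 14.0, "C12:0": 8.0, "C14:0": 5.0,
        "C16:0": 3.0, "C16:1": 4.0,
    },
    "mixed_producer": {
        "C8:0": 8.0, "C10:0": 10.0, "C12:0": 16.0, "C14:0": 30.0,
        "C16:0": 16.0, "C18:0": 5.0, "C12:1": 3.0, "C14:1": 5.0, "C16:1": 7.0,
    },
    "long_chain_producer": {
        "C12:0": 7.0, "C14:0": 30.0, "C16:0": 28.0, "C18:0": 12.0,
        "C16:1": 13.0, "C18:1": 10.0,
    },
}

PRESET_NAMES = tuple(_PRESETS)


def make_gcms_profile(
    preset: str, custom: Mapping[str, float] | None = None
) -> GCMSProfile:
    """A GC-MS composition table for a named producer preset.

    Presets: ``short_chain_producer`` (argmax C8:0), ``mixed_producer``
    (argmax C14:0), ``long_chain_producer`` (C14:0/C16:0 heavy), or
    ``custom`` with an explicit species -> concentration mapping.
    Entries are normalized to fractions summing to 1.
    """
    if preset == "custom":
        if custom is None:
            raise ValueError("custom preset requires a species mapping")
        entries = dict(custom)
    else:
        try:
            entries = dict(_PRESETS[preset])
        except KeyError:
            raise ValueError(
                f"unknown preset {preset!r}; choose from {PRESET_NAMES + ('custom',)}"
            ) from None
    total = float(sum(entries.values()))
    if total <= 0:
        raise ValidationError("profile concentrations are all zero")
    return GCMSProfile({k: v / total for k, v in entries.items()})


@dataclass(frozen=True)
class SceneSpec:
    """Study conditions for one synthetic microcolony scene.

    Geometry is in physical units (micrometres) converted through
    ``pixel_size_um``; rod dimensions bracket E. coli (1-2 um long,
    ~0.7 um wide). Baseline cells contain protein with a low fatty-acid
    level; high-producer cells and extracellular droplets carry the
    fatty-acid mixture given by ``profile``.
    """

    profile: GCMSProfile
    shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.15
    n_cells: int = 40
    cell_length_um: tuple[float, float] = (1.0, 2.0)
    cell_width_um: tuple[float, float] = (0.55, 0.8)
    n_droplets: int = 24
    droplet_radius_um: tuple[float, float] = (0.3, 0.9)
    protein_level: float = 1.0
    cell_fa_level: float = 0.15
    high_producer_fa_level: float = 1.0
    droplet_fa_level: float = 1.5
    high_producer_fraction: float = DEFAULT_HIGH_PRODUCER_FRACTION
    snr: float = DEFAULT_SNR
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("SNR must be positive")
        if not 0 <= self.high_producer_fraction <= 1:
            raise ValueError("high_producer_fraction must be in [0, 1]")
        for level in (
            self.protein_level, self.cell_fa_level,
            self.high_producer_fa_level, self.droplet_fa_level,
        ):
            if level < 0:
                raise ValueError("composition levels must be non-negative")
        max_len_px = self.cell_length_um[1] / self.pixel_size_um
        if max_len_px > min(self.shape):
            raise ValueError("cells do not fit in the image")


@dataclass(frozen=True)
class SceneGroundTruth:
    """Everything the generator knows about a scene.

    ``concentrations`` is the true (Nx, Ny, K) cube aligned with
    ``component_names``; ``cell_labels`` / ``droplet_labels`` are integer
    masks (0 = background); ``high_producer_ids`` lists the cell labels
    given the producer phenotype; ``noise_sigma`` is the additive noise
    scale actually applied.
    """

    component_names: tuple[str, ...]
    concentrations: np.ndarray
    cell_labels: np.ndarray
    droplet_labels: np.ndarray
    high_producer_ids: tuple[int, ...]
    profile: GCMSProfile
    noise_sigma: float

    def combined_mask(self) -> np.ndarray:
        """Cells and droplets in one label image (droplets offset past cells)."""
        out = self.cell_labels.copy()
        offset = int(self.cell_labels.max())
        drop = self.droplet_labels > 0
        out[drop] = self.droplet_labels[drop] + offset
        return out


def _paint_rod(
    shape: tuple[int, int],
    center: tuple[float, float],
    angle: float,
    length_px: float,
    width_px: float,
) -> np.ndarray:
    """Boolean capsule (rod with hemispherical caps) raster."""
    cy, cx = center
    half = max(length_px / 2.0 - width_px / 2.0, 0.0)
    dy, dx = np.sin(angle) * half, np.cos(angle) * half
    y0, x0 = cy - dy, cx - dx
    y1, x1 = cy + dy, cx + dx
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    # distance from each pixel to the segment (y0,x0)-(y1,x1)
    vy, vx = y1 - y0, x1 - x0
    seg2 = vy * vy + vx * vx
    if seg2 == 0:
        t = np.zeros(shape)
    else:
        t = np.clip(((yy - y0) * vy + (xx - x0) * vx) / seg2, 0.0, 1.0)
    py, px = y0 + t * vy, x0 + t * vx
    dist2 = (yy - py) ** 2 + (xx - px) ** 2
    return dist2 <= (width_px / 2.0) ** 2


def _paint_disk(
    shape: tuple[int, int], center: tuple[float, float], radius_px: float
) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius_px**2


def make_scene(
    spec: SceneSpec, lib: ReferenceLibrary
) -> tuple[HyperspectralStack, SceneGroundTruth]:
    """Generate a hyperspectral scene and its ground truth.

    Rod-shaped cells are placed by rejection sampling without overlap
    (1000 attempts per cell, then a packing error); droplets may touch
    cells, in which case concentrations add. The stack is the ground-truth
    cube mixed with *unit-area* references plus Gaussian noise with
    sigma = (mean in-cell peak signal) / snr, then quantized to float32
    (the on-disk dialect). Deterministic per ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    nlib = lib.normalized()
    names = nlib.names
    k_index = {name: i for i, name in enumerate(names)}
    shape = spec.shape
    px = spec.pixel_size_um

    # fatty-acid shares over library components, from the profile
    sat_fracs = spec.profile.fractions()
    fa_share: dict[str, float] = {}
    for label, frac in sat_fracs.items():
        n, u = parse_species(label)
        if u == 0:
            name = f"C{n}:0"
            if name in k_index:
                fa_share[name] = fa_share.get(name, 0.0) + frac
        else:
            if "unsat" in k_index:
                fa_share["unsat"] = fa_share.get("unsat", 0.0) + frac
    total_share = sum(fa_share.values())
    if total_share <= 0:
        raise ValidationError("profile has no species representable in the library")
    fa_share = {k: v / total_share for k, v in fa_share.items()}

    cell_labels = np.zeros(shape, dtype=np.int32)
    occupied = np.zeros(shape, dtype=bool)
    for cid in range(1, spec.n_cells + 1):
        for _ in range(1000):
            length = rng.uniform(*spec.cell_length_um) / px
            width = rng.uniform(*spec.cell_width_um) / px
            margin = length / 2.0 + 1.0
            cy = rng.uniform(margin, shape[0] - margin)
            cx = rng.uniform(margin, shape[1] - margin)
            angle = rng.uniform(0.0, np.pi)
            rod = _paint_rod(shape, (cy, cx), angle, length, width)
            if not rod.any() or (rod & occupied).any():
                continue
            cell_labels[rod] = cid
            occupied |= rod
            break
        else:
            raise PackingError(
                f"could not place cell {cid} of {spec.n_cells} in 1000 attempts"
            )

    n_high = int(round(spec.high_producer_fraction * spec.n_cells))
    high_ids = tuple(
        sorted(rng.choice(np.arange(1, spec.n_cells + 1), size=n_high, replace=False).tolist())
    ) if n_high else ()

    droplet_labels = np.zeros(shape, dtype=np.int32)
    for did in range(1, spec.n_droplets + 1):
        radius = rng.uniform(*spec.droplet_radius_um) / px
        cy = rng.uniform(radius + 1, shape[0] - radius - 1)
        cx = rng.uniform(radius + 1, shape[1] - radius - 1)
        disk = _paint_disk(shape, (cy, cx), radius)
        droplet_labels[disk & (droplet_labels == 0)] = did

    truth = np.zeros(shape + (len(nlib),), dtype=float)
    if "protein" in k_index:
        truth[..., k_index["protein"]] += spec.protein_level * (cell_labels > 0)

    # Baseline cells carry the shared profile mixture at a low level
    # (membrane-lipid-like background).
    baseline = cell_labels > 0
    for name, share in fa_share.items():
        truth[..., k_index[name]] += spec.cell_fa_level * baseline * share

    # Droplets and high-producer cells are each enriched in a single
    # fatty-acid species, allocated greedily (largest compartment first,
    # species with the largest remaining mass deficit) so the scene's
    # aggregate fatty-acid composition matches the profile up to
    # compartment quantization. This reproduces the observed spatial
    # variation of composition between droplets, which is also the regime
    # in which per-pixel sparse unmixing can recover the distribution.
    compartments: list[tuple[np.ndarray, float]] = []
    for cid in high_ids:
        m = cell_labels == cid
        if m.any():
            compartments.append((m, spec.high_producer_fa_level))
    for did in np.unique(droplet_labels[droplet_labels > 0]):
        m = droplet_labels == did
        compartments.append((m, spec.droplet_fa_level))
    if compartments:
        masses = np.array([level * m.sum() for m, level in compartments])
        total_mass = float(masses.sum())
        targets = {name: share * total_mass for name, share in fa_share.items()}
        assigned = dict.fromkeys(fa_share, 0.0)
        for j in np.argsort(masses)[::-1]:
            name = max(fa_share, key=lambda k: targets[k] - assigned[k])
            assigned[name] += float(masses[j])
            m, level = compartments[j]
            truth[..., k_index[name]] += level * m

    clean = np.einsum("xyk,kl->xyl", truth, nlib.matrix)
    in_cell = cell_labels > 0
    if in_cell.any():
        peak = clean[in_cell].max(axis=1).mean()
    else:
        peak = clean.max()
    sigma = float(peak) / spec.snr
    data = clean + rng.normal(0.0, sigma, clean.shape)
    data = data.astype(np.float32).astype(float)

    stack = HyperspectralStack(nlib.axis, data)
    gt = SceneGroundTruth(
        component_names=names,
        concentrations=truth,
        cell_labels=cell_labels,
        droplet_labels=droplet_labels,
        high_producer_ids=high_ids,
        profile=spec.profile,
        noise_sigma=sigma,
    )
    return stack, gt


def make_growth_trajectories(
    n_cells: int,
    mu_true: float,
    dt_min: float = 20.0,
    noise_sigma: float = 0.0,
    division_threshold_um: float | None = 4.0,
    n_frames: int = 24,
    initial_length_um: tuple[float, float] = (1.5, 2.5),
    seed: int = 0,
) -> list[CellTrajectory]:
    """Exponential single-cell length trajectories with optional divisions.

    True length elongates as L * exp(mu_true * dt) each frame and halves
    when it crosses ``division_threshold_um`` (None disables divisions).
    Observed lengths carry multiplicative lognormal noise
    ``L * exp(noise_sigma * z)``. Deterministic per seed.
    """
    if mu_true < 0:
        raise ValueError("mu_true must be >= 0")
    if n_frames < 3:
        raise ValueError("need at least 3 frames")
    rng = np.random.default_rng(seed)
    times = np.arange(n_frames) * dt_min
    out = []
    for cid in range(n_cells):
        L = rng.uniform(*initial_length_um)
        true_lengths = []
        for _ in range(n_frames):
            true_lengths.append(L)
            L = L * np.exp(mu_true * dt_min)
            if division_threshold_um is not None and L > division_threshold_um:
                L = L / 2.0
        true_lengths = np.asarray(true_lengths)
        if noise_sigma > 0:
            obs = true_lengths * np.exp(
                rng.normal(0.0, noise_sigma, n_frames)
            )
        else:
            obs = true_lengths
        out.append(CellTrajectory(cell_id=cid, times_min=times, lengths_um=obs))
    return out
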