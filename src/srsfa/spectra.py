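"""Pure-component reference spectra and CH2/CH3 chain-length calibration.

This module holds the spectral side of the compositional analysis:

* :class:`WavenumberAxis`, :class:`Spectrum` — a Raman spectrum sampled on a
  strictly increasing wavenumber grid (cm^-1) in the C-H stretch region.
* :class:`ReferenceLibrary` — the matrix ``S`` of named pure-component
  spectra (protein, saturated fatty acids Cn:0, and a single composite
  unsaturated channel) that the per-pixel regression decomposes against.
* :class:`GCMSProfile` — a bulk-culture fatty-acid composition table used to
  rescale the normalized references so the regression starts from
  strain-level priors.
* :class:`ChainLengthCalibration` — the linear map from the CH2/CH3
  band-area ratio to saturated chain length, fitted on pure standards.

The chain-length idea: a saturated fatty acid of chain length ``n`` has
``n - 2`` internal methylene (CH2) groups but always one terminal methyl
(CH3), so the ratio of integrated band intensity in the CH2 window
(2832-2888 cm^-1) to the CH3 window (2909-2967 cm^-1) grows approximately
linearly with ``n``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (
    AugmentationDegenerateError,
    AxisMismatchError,
    CalibrationError,
    DegenerateWeightsError,
    InvalidSpectrumError,
    ValidationError,
)

#: Methylene (CH2) integration window, cm^-1.
CH2_WINDOW = (2832.0, 2888.0)
#: Methyl (CH3) integration window, cm^-1.
CH3_WINDOW = (2909.0, 2967.0)

#: Saturated standards span C6:0-C20:0; predictions are clipped to this range.
CHAIN_LENGTH_RANGE = (6, 20)

Category = Literal["protein", "saturated", "unsaturated_composite"]

_SPECIES_RE = re.compile(r"^C(\d+):(\d+)$")


def parse_species(label: str) -> tuple[int, int]:
    """Parse a fatty-acid species label ``Cn:u`` into ``(n, u)``.

    ``n`` must be an even carbon number in [6, 20] and ``u`` (number of
    double bonds) must be 0 or 1, matching what the gas-chromatography
    tables report for these strains.
    """
    m = _SPECIES_RE.match(label.strip())
    if m is None:
        raise ValidationError(f"malformed species label {label!r}; expected 'Cn:u'")
    n, u = int(m.group(1)), int(m.group(2))
    if n % 2 or not (CHAIN_LENGTH_RANGE[0] <= n <= CHAIN_LENGTH_RANGE[1]):
        raise ValidationError(
            f"species {label!r}: chain length must be even and within "
            f"{CHAIN_LENGTH_RANGE}, got {n}"
        )
    if u not in (0, 1):
        raise ValidationError(f"species {label!r}: unsaturation must be 0 or 1, got {u}")
    return n, u


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing wavenumber grid in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("axis must be a 1D array with at least 2 points")
        if not np.all(np.diff(v) > 0):
            raise ValueError("wavenumber axis must be strictly increasing")
        if not np.all(v > 0):
            raise ValueError("wavenumbers must be positive")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other: object) -> bool:
        return isinstance(other, WavenumberAxis) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.values.size, float(self.values[0]), float(self.values[-1])))

    @property
    def span(self) -> tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])

    def covers(self, window: tuple[float, float]) -> bool:
        lo, hi = self.span
        return lo <= window[0] and window[1] <= hi

    def window_weights(self, lo: float, hi: float) -> np.ndarray:
        """Quadrature weights ``w`` such that ``w @ y`` is the trapezoidal
        integral of the linear interpolant of ``y`` over ``[lo, hi]``.

        Window endpoints that fall between grid points are handled by
        linear interpolation, so the weights are exact for the trapezoid
        rule on the refined grid that includes ``lo`` and ``hi``.
        """
        if not lo < hi:
            raise ValueError(f"empty window [{lo}, {hi}]")
        if not self.covers((lo, hi)):
            raise ValueError(
                f"window [{lo}, {hi}] not inside axis span {self.span}"
            )
        x = self.values
        inner = x[(x > lo) & (x < hi)]
        pts = np.concatenate([[lo], inner, [hi]])
        # trapezoid coefficients on the refined grid
        seg = np.diff(pts)
        coef = np.zeros_like(pts)
        coef[:-1] += seg / 2.0
        coef[1:] += seg / 2.0
        w = np.zeros(x.size)
        for t, c in zip(pts, coef):
            i = int(np.searchsorted(x, t, side="right")) - 1
            if i == x.size - 1 or x[i] == t:
                w[i] += c
            else:
                frac = (t - x[i]) / (x[i + 1] - x[i])
                w[i] += c * (1.0 - frac)
                w[i + 1] += c * frac
        return w


@dataclass(frozen=True)
class Spectrum:
    """Intensity sampled on a :class:`WavenumberAxis` (arbitrary SRS units)."""

    axis: WavenumberAxis
    intensity: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.intensity, dtype=float)
        if y.shape != (len(self.axis),):
            raise ValueError(
                f"intensity length {y.shape} does not match axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("intensity must be finite")
        object.__setattr__(self, "intensity", y)

    def area(self) -> float:
        """Trapezoidal integral over the full axis."""
        return float(np.trapezoid(self.intensity, self.axis.values))

    def window_auc(self, window: tuple[float, float]) -> float:
        """Trapezoidal area under the curve inside ``window``."""
        return float(self.axis.window_weights(*window) @ self.intensity)


@dataclass(frozen=True)
class Component:
    """A named library entry: spectrum plus its chemical category."""

    name: str
    category: Category
    spectrum: Spectrum
    chain_length: int | None = None

    def __post_init__(self) -> None:
        if self.category == "saturated":
            if self.chain_length is None:
                raise ValueError(f"saturated component {self.name!r} needs a chain length")
            n = self.chain_length
            if n % 2 or not (CHAIN_LENGTH_RANGE[0] <= n <= CHAIN_LENGTH_RANGE[1]):
                raise ValueError(f"chain length {n} must be even and in {CHAIN_LENGTH_RANGE}")
        elif self.chain_length is not None:
            raise ValueError(f"{self.category} component must not carry a chain length")


@dataclass(frozen=True)
class ReferenceLibrary:
    """Ordered collection of pure-component spectra on one shared axis."""

    components: tuple[Component, ...]

    def __post_init__(self) -> None:
        comps = tuple(self.components)
        if not comps:
            raise ValueError("library needs at least one component")
        names = [c.name for c in comps]
        if len(set(names)) != len(names):
            raise ValueError("component names must be unique")
        axis = comps[0].spectrum.axis
        for c in comps[1:]:
            if c.spectrum.axis != axis:
                raise AxisMismatchError(
                    f"component {c.name!r} is not on the shared axis"
                )
        for cat in ("protein", "unsaturated_composite"):
            if sum(c.category == cat for c in comps) > 1:
                raise ValueError(f"at most one {cat} component allowed")
        object.__setattr__(self, "components", comps)

    @property
    def axis(self) -> WavenumberAxis:
        return self.components[0].spectrum.axis

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    @property
    def categories(self) -> tuple[Category, ...]:
        return tuple(c.category for c in self.components)

    @property
    def chain_lengths(self) -> tuple[int | None, ...]:
        return tuple(c.chain_length for c in self.components)

    def __len__(self) -> int:
        return len(self.components)

    def __getitem__(self, name: str) -> Component:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(name)

    @property
    def matrix(self) -> np.ndarray:
        """Reference matrix ``S`` of shape (K, n_wavenumbers)."""
        return np.stack([c.spectrum.intensity for c in self.components])

    @property
    def areas(self) -> np.ndarray:
        """Trapezoidal area of each reference (mass per unit concentration)."""
        return np.array([c.spectrum.area() for c in self.components])

    def saturated(self) -> tuple[Component, ...]:
        return tuple(c for c in self.components if c.category == "saturated")

    def fatty_acid_indices(self) -> np.ndarray:
        return np.array(
            [i for i, c in enumerate(self.components) if c.category != "protein"],
            dtype=int,
        )

    def normalized(self, skip_protein: bool = False) -> "ReferenceLibrary":
        """Library with each spectrum rescaled to unit trapezoidal area."""
        out = []
        for c in self.components:
            if skip_protein and c.category == "protein":
                out.append(c)
            else:
                out.append(replace(c, spectrum=normalize_spectrum(c.spectrum)))
        return ReferenceLibrary(tuple(out))

    def resampled(self, axis: WavenumberAxis) -> "ReferenceLibrary":
        """Linearly interpolate every reference onto ``axis``.

        Extrapolation is forbidden: ``axis`` must lie inside the library span.
        """
        lo, hi = self.axis.span
        if axis.values[0] < lo or axis.values[-1] > hi:
            raise AxisMismatchError(
                f"target axis {axis.span} extends beyond library span {(lo, hi)}"
            )
        out = []
        for c in self.components:
            y = np.interp(axis.values, self.axis.values, c.spectrum.intensity)
            out.append(replace(c, spectrum=Spectrum(axis, y)))
        return ReferenceLibrary(tuple(out))


@dataclass(frozen=True)
class GCMSProfile:
    """Bulk-culture fatty-acid composition: species label ``Cn:u`` -> amount.

    Amounts may be absolute concentrations (mg/L) or relative fractions;
    only ratios matter downstream.
    """

    entries: Mapping[str, float]

    def __post_init__(self) -> None:
        items = {}
        for label, conc in dict(self.entries).items():
            parse_species(label)  # validates
            c = float(conc)
            if c < 0 or not np.isfinite(c):
                raise ValidationError(f"species {label!r}: concentration {conc!r} invalid")
            items[label] = c
        if not any(v > 0 for v in items.values()):
            raise ValidationError("profile needs at least one positive concentration")
        object.__setattr__(self, "entries", items)

    def saturated_items(self) -> dict[int, float]:
        """Chain length -> concentration for the saturated species."""
        out: dict[int, float] = {}
        for label, conc in self.entries.items():
            n, u = parse_species(label)
            if u == 0:
                out[n] = out.get(n, 0.0) + conc
        return out

    def unsaturated_items(self) -> dict[str, float]:
        return {
            label: conc
            for label, conc in self.entries.items()
            if parse_species(label)[1] == 1
        }

    def unsaturated_total(self) -> float:
        return float(sum(self.unsaturated_items().values()))

    def fractions(self) -> dict[str, float]:
        """Entries normalized to sum to 1."""
        total = sum(self.entries.values())
        return {k: v / total for k, v in self.entries.items()}

    def saturated_fractions(self) -> dict[int, float]:
        """Chain length -> fraction of the *saturated* mass (sums to 1)."""
        sat = self.saturated_items()
        total = sum(sat.values())
        if total <= 0:
            raise AugmentationDegenerateError("profile has no saturated mass")
        return {n: v / total for n, v in sat.items()}


@dataclass(frozen=True)
class ChainLengthCalibration:
    """Linear calibration: chain length = slope * (CH2/CH3 AUC ratio) + intercept."""

    slope: float
    intercept: float
    r_squared: float
    ch2_window: tuple[float, float] = CH2_WINDOW
    ch3_window: tuple[float, float] = CH3_WINDOW

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise CalibrationError(f"slope must be positive, got {self.slope}")
        a, b = self.ch2_window, self.ch3_window
        if a[1] > b[0] and b[1] > a[0]:
            raise CalibrationError("CH2 and CH3 windows must not overlap")


# ---------------------------------------------------------------------------
# operations


def normalize_spectrum(s: Spectrum) -> Spectrum:
    """Rescale a spectrum to unit trapezoidal area over its axis.

    Unit-area references make the GC-MS scaling constants act on comparable
    magnitudes and let fitted concentrations read directly as mass.
    """
    area = s.area()
    if not np.any(s.intensity > 0) or area <= 0:
        raise InvalidSpectrumError(
            f"cannot normalize spectrum with area {area:g} and no positive intensity"
            if not np.any(s.intensity > 0)
            else f"cannot normalize spectrum with non-positive area {area:g}"
        )
    return Spectrum(s.axis, s.intensity / area)


def composite_unsaturated_reference(
    specs: Sequence[Spectrum], weights: Sequence[float]
) -> Spectrum:
    """Convex combination of normalized unsaturated spectra.

    Individual unsaturated chain lengths cannot be resolved spectrally, so
    a single composite channel is formed; ``weights`` are proportional to
    the GC-MS concentrations of the corresponding unsaturated species.
    """
    if len(specs) == 0:
        raise ValueError("need at least one spectrum")
    w = np.asarray(list(weights), dtype=float)
    if w.shape != (len(specs),):
        raise ValueError("one weight per spectrum required")
    if np.any(w < 0):
        raise DegenerateWeightsError("weights must be non-negative")
    total = w.sum()
    if total <= 0:
        raise DegenerateWeightsError("all weights are zero")
    axis = specs[0].axis
    for s in specs[1:]:
        if s.axis != axis:
            raise AxisMismatchError("unsaturated spectra are not on a shared axis")
    w = w / total
    y = np.zeros(len(axis))
    for s, wk in zip(specs, w):
        y += wk * normalize_spectrum(s).intensity
    return Spectrum(axis, y)


def unsaturated_weights_from_profile(
    profile: GCMSProfile, species: Sequence[str]
) -> np.ndarray:
    """GC-MS concentrations of the listed unsaturated species (0 if absent)."""
    return np.array([profile.entries.get(sp, 0.0) for sp in species])


def scale_references_by_gcms(
    lib: ReferenceLibrary, profile: GCMSProfile
) -> ReferenceLibrary:
    """Rescale normalized fatty-acid references by their GC-MS shares.

    Shares are computed over fatty-acid species only (protein passes through
    untouched): each saturated reference is multiplied by its species'
    share of total fatty-acid mass, and the composite unsaturated reference
    by the summed unsaturated share. Shares sum to 1 over the fatty-acid
    components, so the per-pixel regression still estimates an absolute
    scale while being steered toward the strain's bulk composition.

    Profile species with no matching library component are dropped with a
    warning (their mass is reassigned proportionally by renormalization).
    Library species missing from the profile are treated as concentration
    zero: the component is kept, scaled to zero, so map indices stay stable
    across strains.
    """
    sat_conc = profile.saturated_items()
    lib_chain_lengths = {c.chain_length for c in lib.saturated()}
    has_unsat = any(c.category == "unsaturated_composite" for c in lib.components)

    orphan_sat = {n: v for n, v in sat_conc.items() if n not in lib_chain_lengths and v > 0}
    if orphan_sat:
        warnings.warn(
            "profile species absent from library, mass reassigned proportionally: "
            + ", ".join(f"C{n}:0" for n in sorted(orphan_sat)),
            stacklevel=2,
        )
    unsat_total = profile.unsaturated_total()
    if unsat_total > 0 and not has_unsat:
        warnings.warn(
            "profile has unsaturated mass but library has no unsaturated_composite "
            "component; mass reassigned proportionally",
            stacklevel=2,
        )
        unsat_total = 0.0

    missing = sorted(n for n in lib_chain_lengths if n not in sat_conc)
    if missing:
        warnings.warn(
            "library species missing from profile, treated as zero concentration: "
            + ", ".join(f"C{n}:0" for n in missing),
            stacklevel=2,
        )

    total = sum(v for n, v in sat_conc.items() if n in lib_chain_lengths) + unsat_total
    if total <= 0:
        raise AugmentationDegenerateError("all fatty-acid shares are zero")

    out = []
    for c in lib.components:
        if c.category == "protein":
            out.append(c)
            continue
        if c.category == "saturated":
            share = sat_conc.get(c.chain_length, 0.0) / total
        else:  # unsaturated_composite
            share = unsat_total / total
        base = normalize_spectrum(c.spectrum) if np.any(c.spectrum.intensity > 0) else c.spectrum
        out.append(replace(c, spectrum=Spectrum(base.axis, base.intensity * share)))
    return ReferenceLibrary(tuple(out))


def ch2_ch3_auc_ratio(
    s: Spectrum, cal: ChainLengthCalibration | None = None, eps: float = 1e-12
) -> float:
    """Ratio of trapezoidal band areas, CH2 window over CH3 window.

    Invariant to global rescaling of the spectrum. Returns NaN when the
    CH3-window area is at or below ``eps`` (the caller decides whether to
    propagate NaN or skip the pixel).
    """
    ch2_win = cal.ch2_window if cal is not None else CH2_WINDOW
    ch3_win = cal.ch3_window if cal is not None else CH3_WINDOW
    ch2 = s.window_auc(ch2_win)
    ch3 = s.window_auc(ch3_win)
    if ch3 <= eps:
        return float("nan")
    return ch2 / ch3


def fit_chain_length_calibration(
    standards: Iterable[tuple[int, Spectrum]],
    ch2_window: tuple[float, float] = CH2_WINDOW,
    ch3_window: tuple[float, float] = CH3_WINDOW,
) -> ChainLengthCalibration:
    """Ordinary least squares of chain length on CH2/CH3 AUC ratio.

    ``standards`` holds (chain_length, spectrum) pairs for pure saturated
    standards; replicates (repeated chain lengths) are allowed and all
    points enter the fit. At least 3 distinct chain lengths are required.
    """
    pairs = list(standards)
    ns = np.array([float(n) for n, _ in pairs])
    ratios = np.array(
        [s.window_auc(ch2_window) / s.window_auc(ch3_window) for _, s in pairs]
    )
    if len(set(ns.tolist())) < 3:
        raise CalibrationError("need standards at >= 3 distinct chain lengths")
    if np.ptp(ratios) <= 0 or not np.all(np.isfinite(ratios)):
        raise CalibrationError("AUC ratios carry no variance; calibration underdetermined")
    res = stats.linregress(ratios, ns)
    return ChainLengthCalibration(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        ch2_window=ch2_window,
        ch3_window=ch3_window,
    )


def predict_chain_length(
    ratio: float | np.ndarray,
    cal: ChainLengthCalibration,
    clip: bool = True,
) -> float | np.ndarray:
    """Map a CH2/CH3 AUC ratio to a (continuous) chain length.

    Predictions are clipped to the span of the standards, C6-C20, unless
    ``clip=False``; NaN inputs propagate.
    """
    value = cal.slope * np.asarray(ratio, dtype=float) + cal.intercept
    if clip:
        value = np.clip(value, *CHAIN_LENGTH_RANGE)
    if np.isscalar(ratio) or np.asarray(ratio).ndim == 0:
        return float(value)
    return value
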