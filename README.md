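# srsfa

Compositional analysis of hyperspectral stimulated Raman scattering (SRS)
images of fatty-acid-producing bacteria.

Metabolic engineers screen *E. coli* strains that secrete free fatty acids,
and need to know not just *how much* each cell produces but *what*: the
saturated chain-length distribution and the degree of unsaturation.
Bulk GC-MS gives exact chemistry but destroys the sample and averages away
single-cell heterogeneity; label-free SRS imaging in the C–H stretch region
(~2800–3050 cm⁻¹) sees every cell alive, but the Raman bands of proteins
and fatty acids overlap heavily. This package implements the analysis that
bridges the two: it decomposes hyperspectral SRS stacks into per-component
chemical maps and turns them into chain-length and unsaturation readouts at
single-cell resolution, validated against GC-MS-style composition tables.

## The method

**Pixel-wise sparse unmixing.** With the stack reshaped to
D ∈ ℝ^(NxNy×Nλ), pure-component reference spectra S ∈ ℝ^(K×Nλ) and
concentration maps C, the model is D = C·S + E. Each pixel *i* is solved as
a non-negative LASSO problem,

    ĉᵢ = argmin_c ½‖Dᵢ,: − c S‖² + β‖c‖₁   (c ≥ 0),

whose L1 penalty suppresses crosstalk between spectrally similar
components. The solver is cyclic coordinate descent, vectorized across all
pixels, with deterministic sweep order.

**GC-MS augmentation.** With many saturated references the regression is
underdetermined; each normalized fatty-acid reference is therefore rescaled
by its species' share of the strain's bulk GC-MS composition, so the
per-pixel fit starts from strain-level priors while still estimating an
absolute scale.

**Chain length from the CH₂/CH₃ band ratio.** A saturated fatty acid of
chain length *n* has *n* − 2 internal methylene groups but one terminal
methyl, so the ratio of integrated band area in the CH₂ window
(2832–2888 cm⁻¹) to the CH₃ window (2909–2967 cm⁻¹) grows linearly with
*n*. A linear calibration fitted on pure C6:0–C20:0 standards converts the
per-pixel ratio of the reconstructed saturated-only spectrum into an
average chain length (e.g. 14.9), binned to even carbons (C8–C18) for
comparison with GC-MS. Distribution similarity is scored with the base-2
Jensen–Shannon divergence (0 = identical, 1 = disjoint).

**Unsaturation.** All unsaturated fatty acids share a =C–H marker band
near 3000 cm⁻¹; they enter the library as a single GC-MS-weighted
composite, and the unsaturation ratio is unsaturated over saturated mass.

**Single cells and growth.** Integer label masks (from an external
segmentation such as CellProfiler or DeLTA) turn maps into per-cell
production tables (per-area or per-protein normalization), top-15 %
high-producer calls, colony time series, and growth rates from the centered
logarithmic derivative of cell length, μₖ = ln(L₍ₖ₊₁₎/L₍ₖ₋₁₎)/(2Δt).

Because no instrument data ship with the package, `srsfa.synthetic`
generates everything needed to exercise the pipeline end to end: Gaussian
band-model reference spectra, rod-shaped cells and secreted droplets with
known per-pixel composition, GC-MS producer presets, and cell-length
trajectories — all pure functions of (parameters, seed).

## Worked example

```python
import srsfa
from srsfa.pipeline import DEFAULT_COMPONENTS

# 1. reference library + chain-length calibration from noisy standards
lib = srsfa.make_reference_spectra(DEFAULT_COMPONENTS)
standards = srsfa.noisy_standards([f"C{n}:0" for n in range(6, 21, 2)],
                                  snr=20, n_replicates=6, seed=1)
cal = srsfa.fit_chain_length_calibration(standards)
print(f"calibration: n = {cal.slope:.2f} * ratio + {cal.intercept:.2f}"
      f"  (R^2 = {cal.r_squared:.3f})")

# 2. synthetic mixed-producer scene and GC-MS-augmented unmixing
profile = srsfa.make_gcms_profile("mixed_producer")
stack, truth = srsfa.make_scene(srsfa.SceneSpec(profile=profile, seed=1), lib)
maps = srsfa.augmented_unmix(stack, lib, profile=profile)

# 3. compositional readouts
recovered = srsfa.chain_length_distribution(
    maps, method="pixel_binned", lib=lib.normalized(), cal=cal)
target = srsfa.distribution_from_profile(profile)
print(f"JSD = {srsfa.js_divergence(recovered, target):.4f}")

# 4. single-cell production
table = srsfa.quantify_regions(maps, truth.cell_labels, mode="per_area")
flags = srsfa.classify_high_producers(table, fraction=0.15)
print(f"{len(table)} cells, {int(flags.sum())} high producers")
```

Output:

```
calibration: n = 8.49 * ratio + 1.25  (R^2 = 0.980)
bin   recovered  gc-ms
C8       0.113    0.094
C10      0.117    0.118
C12      0.178    0.188
C14      0.356    0.353
C16      0.193    0.188
C18      0.044    0.059
JSD = 0.0016
unsaturation ratio = 0.174
40 cells, 6 high producers
```

The calibration is tight (R² = 0.98 at SNR 20); the recovered chain-length
distribution matches the generating GC-MS profile with a Jensen–Shannon
divergence of 0.002 (well inside the < 0.1 band that marks "highly
similar" distributions); and 6 of 40 cells (the top 15 %) are flagged as
high producers.

## Command line

The same pipeline is scriptable from the shell; each command logs its
effective configuration (seed, β, library hash) for reproducibility:

```
srsfa simulate --preset mixed_producer --seed 1 --out scene/
srsfa calibrate --seed 1 --out scene/cal.json
srsfa unmix --stack scene/stack.tif --axis scene/stack.json \
    --library scene/refs.csv --gcms scene/profile.csv --out scene/maps/
srsfa composition --maps scene/maps/ --library scene/refs.csv \
    --calibration scene/cal.json --mask scene/mask.tif --out scene/
srsfa cells --maps scene/maps/ --mask scene/cell_mask.tif --out scene/cells.csv
srsfa growth --trajectories traj.csv --out rates.csv
```

Formats: multi-page 32-bit float TIFF stacks with a JSON wavenumber
sidecar, CSV reference libraries and GC-MS tables, integer TIFF label
masks, tidy CSV outputs. See the module docstring of `srsfa.io`.

## Documentation

`docs/methods.md` describes the model, the synthetic data generator and
its limits, numerical choices, and known limitations.
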