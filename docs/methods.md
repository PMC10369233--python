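# Methods

This note records the models behind `srsfa`, the choices made where the
design was genuinely open, and what the synthetic emulation does and does
not establish about real instrument data.

## Measurement model and unmixing

A hyperspectral SRS stack is a cube D(x, y, λ) of intensities on a strictly
increasing wavenumber axis (cm⁻¹). SRS intensity is linear in molecular
concentration, so with K pure-component reference spectra S (protein, a set
of saturated fatty acids Cn:0, and one composite unsaturated channel) the
stack is modeled as D = C·S + E per pixel. The per-pixel estimator is the
L1-regularized least-squares (LASSO) problem

    ĉ = argmin_{c ≥ 0} ½‖d − cS‖² + β‖c‖₁,

solved by cyclic coordinate descent over components in fixed library
order. Non-negativity is the default because concentrations are physical;
`nonnegative=False` reproduces the unconstrained regression exactly.

Solver details that matter:

* **Reparametrization.** Internally each reference row is rescaled to unit
  Euclidean norm and the penalty becomes per-coordinate (β/‖sₖ‖). This is
  an exact change of variables — the minimizer is unchanged — but it
  decouples convergence speed from reference scaling, which matters when
  GC-MS shares spanning two orders of magnitude are folded into the rows.
* **Warm start.** Coordinate descent starts from the clipped unpenalized
  least-squares solution. The problem is convex, so the result does not
  depend on the start; the warm start only cuts sweep counts.
* **Stopping.** A pixel is frozen when its objective decrease over one
  sweep falls below `tolerance` (default 1e-8) times the larger of its
  objective magnitude and 1 % of its data energy ‖d‖². The data-energy
  floor exists because near-perfect-fit pixels compute their objective by
  cancellation of large terms and cannot resolve smaller decreases in
  float64. Exceeding `max_iterations` (default 50 000 sweeps) raises a
  convergence error carrying the last iterate.
* **Intensity normalization.** By default the stack is scaled so the
  median per-pixel spectrum norm is 1 before solving and the maps are
  rescaled back. β therefore refers to a fixed intensity scale and
  transfers across acquisitions. In scenes dominated by background the
  median norm is the background noise norm; that is intentional — it makes
  β effectively a multiple of the noise scale.
* **β default = 1e-4.** Chosen by the bundled benchmark sweep
  (`beta_sweep`): it is the largest value at which the synthetic
  benchmark's ground-truth support and distributions are recovered; larger
  values progressively collapse mass onto the dominant components (the
  share-scaled references make L1 cost inversely proportional to a
  species' prior share, which is the intended prior but must stay gentle).
* **Degenerate minimizers.** The C–H-region references are heavily
  correlated (adjacent chain lengths correlate > 0.99), so at small β the
  minimizer set is numerically flat: solutions with equal objective can
  differ visibly in coefficients. Quantities derived from the *fit*
  (reconstructed spectra, band ratios) are stable; per-component
  coefficients at a single pixel are not, and should be interpreted only
  in aggregate. Tests compare objectives, not coefficients, against
  scikit-learn and brute-force oracles for this reason.

Zero reference rows (species scaled to zero concentration by augmentation)
are kept in the library with coefficients pinned to zero, so map indices
are stable across strains.

## GC-MS augmentation

References are first normalized to unit trapezoidal area over the axis, so
a fitted coefficient reads directly as mass. (The normalization scheme —
area vs maximum vs Euclidean — is not dictated by the physics; unit area
was chosen because it makes the GC-MS scaling constants act on comparable
magnitudes and downstream AUC arithmetic unit-consistent.) Each saturated
reference is then multiplied by its species' share of total fatty-acid
mass in the strain's bulk GC-MS table, and the composite unsaturated
reference by the summed unsaturated share; shares sum to 1 over fatty-acid
components and the protein reference passes through untouched. Profile
species with no library component are dropped with a warning (their mass
reassigned proportionally); library species missing from the profile are
treated as zero concentration rather than rejected.

With scaled references the coefficient times the reference area is the
physical mass, which is how `ChemicalMaps` stores and aggregates
everything (`areas` per component).

## Chain length and unsaturation

The CH₂ window is 2832–2888 cm⁻¹ and the CH₃ window 2909–2967 cm⁻¹; both
integrals use the trapezoid rule on the native axis with window endpoints
interpolated linearly when off-grid. The calibration is an ordinary
least-squares fit of chain length on the CH₂/CH₃ area ratio of pure
saturated standards C6:0–C20:0; predictions are clipped to [6, 20], the
span of the standards. Binning to even carbons uses nearest-even with
odd-integer midpoints rounding down (14.9 → C14, 15.0 → C14, 15.1 → C16).

Two distribution routes exist:

* `component_mass` (default): each saturated component's summed
  concentration mass is assigned to its bin. This is the right readout
  when per-species maps are trustworthy (strong signal, identifiable
  references) and is what per-cell tables use.
* `pixel_binned`: the saturated-only stack is reconstructed (Σ Cₖ·Sₖ over
  saturated components), each pixel's CH₂/CH₃ ratio is converted to an
  average chain length and binned, weighting pixels by saturated mass.
  This route depends only on the fit, not on how mass is split between
  correlated components, and is therefore the more robust validation
  readout against bulk tables.

Chain-length maps leave pixels undefined (NaN) when saturated mass is at
or below a threshold, by default 5× a robust background scale
(1.4826 × MAD of the combined fatty-acid map): low-signal ratio estimates
fluctuate strongly. Values are reported at 0.01-carbon resolution in
float32 — the estimate carries no meaning beyond that, and the quantization
keeps maps bit-stable under global intensity rescaling of the input.

The unsaturation ratio is unsaturated over saturated mass
(Σ c·area, i.e. AUC-weighted concentrations) over a region. Whole-image
ratios are biased upward by non-negative-clamped background noise, which
adds a small positive mass floor to every component — one unsaturated
channel versus several saturated ones does not cancel. Evaluate over a
cell/droplet mask (the `region` argument) for quantitative work; the CLI
`composition --mask` does exactly that.

The Jensen–Shannon divergence uses base-2 logarithms (bounded [0, 1]) with
0·log 0 = 0, over matching even-carbon bins (C8–C18 by default; mass
outside is clipped into the terminal bins with a warning).

## Single-cell quantification

Masks and maps share pixel-index space (row-major, origin top-left,
0-based); areas are in pixels with a default physical pitch of 150 nm for
µm conversions. Per-region tables report protein and fatty-acid mass
totals and both normalizations — per area (single-cell readout) and per
protein (microcolony readout, robust to stacked cells); `mode` picks the
headline column. High producers are regions at or above the empirical
(1 − f) quantile (linear interpolation, ties included, f = 0.15 by
default); an all-identical table flags everyone with a warning.

Growth rate is the centered logarithmic derivative of length, exact for
exponential elongation; endpoint frames get no rate. Division events
(length drop > 30 % between frames) produce a negative spike at adjacent
frames; `mask_divisions=True` blanks frames within ±1 of a division, since
the raw trajectories are otherwise reported as measured.

## Synthetic data: what it emulates and what it does not

The generator exists so every stage is testable without instrument data.
Reference spectra are sums of Gaussian bands (`band_model.yaml`): two CH₂
bands (~2850/2880 cm⁻¹) whose amplitude scales with n − 2, two fixed CH₃
bands (~2935/2960 cm⁻¹), a broad unsaturated band at 2900 cm⁻¹ plus the
~3000 cm⁻¹ =C–H marker, and a broad protein envelope. Widths (σ ≈ 9–40
cm⁻¹) emulate the ~25 cm⁻¹ effective resolution of chirped femtosecond
SRS. Band centers and widths drift slightly with chain length
(0.8/−0.5 cm⁻¹ per carbon, 2 %/carbon width growth), as acyl-chain packing
does in real spectra; without this the saturated series would be an exact
two-dimensional family and per-species unmixing would be degenerate by
construction. The default axis is 2800–3050 cm⁻¹ at 40 uniform samples.

Scenes place non-overlapping rod-shaped cells (capsules, 1–2 µm long,
rejection-sampled; > 1000 failed attempts raise a packing error) and
circular secreted droplets on a 256×256 grid at 150 nm/pixel. Baseline
cells carry protein (level 1) and a low shared fatty-acid mixture
(level 0.15, membrane-lipid-like). Droplets (level 1.5) and a 10 % subset
of high-producer cells (level 1) are each enriched in a single fatty-acid
species, allocated largest-compartment-first against the profile's
fractions so the scene's aggregate composition matches the GC-MS table up
to compartment quantization. This spatial segregation mirrors the
observed compartment-to-compartment composition variation in real scenes
and is, importantly, the regime in which a per-pixel method can recover a
distribution at all: if every pixel held the identical mixture, every
pixel average would collapse into one bin and no pixel-wise analysis could
reconstruct the spread.

Noise is additive Gaussian per pixel-wavenumber with
σ = (mean in-cell peak signal)/SNR, SNR 20 by default; stacks are
quantized to float32, the on-disk dialect. Measured intensities may dip
slightly below zero in the background, as lock-in detected signals do;
they are kept as-is because clipping would bias the background. Standards
replicates add the same noise model to unit-area pure spectra
(σ = peak/SNR).

What passing tests therefore show: the pipeline inverts its own forward
model at realistic noise, conditioning and geometry. What they do not
show: robustness to instrument effects absent from the model — baseline
drift, chirp-induced lineshape asymmetry, point-spread blurring, shot
noise, focus drift, or segmentation errors (masks here are exact by
construction).

Growth trajectories elongate exponentially (default Δt = 20 min), halve at
a division threshold, and carry multiplicative lognormal length noise.

## Known limitations

* Individual unsaturated chain lengths are not resolved (their spectra
  differ too little); only the composite unsaturated channel is reported.
* Per-pixel per-species coefficients are aggregate-trustworthy only
  (see degenerate minimizers above).
* The 3000 cm⁻¹ marker region overlaps the protein envelope tail; in very
  protein-rich, fatty-acid-poor pixels the unsaturated channel can pick up
  protein crosstalk.
* The quantile definition of "top 15 %" (linear interpolation, ties
  included) is one of several defensible conventions; counts can differ by
  one region from other definitions at small n.
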