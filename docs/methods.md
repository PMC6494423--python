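# Methods

## The generative model

`mpskit.synthetic` models one axon's spectrin localizations as a quasi-1D
marked point process:

- The number of localizations is Poisson with mean
  `density_per_um × axon_length_um`.
- With probability `periodic_fraction` (f) a localization belongs to the ring
  comb: its axial coordinate is `k·period_nm + phase_nm + N(0, jitter_nm²)`,
  with the ring index k uniform over the `floor(L/period)` complete rings.
  Otherwise the axial coordinate is uniform on the axon length (disassembled /
  nonspecific signal).
- Transverse (y) and depth (z) coordinates are uniform across the axon
  diameter: ring occupancy around the circumference is collapsed, because the
  analysis is strictly 1D after projection.
- Independent Gaussian localization error is added to every coordinate
  (`loc_precision_xy_nm` laterally, `loc_precision_z_nm` in depth).

Lattice disassembly is emulated by lowering f (and optionally raising
`jitter_nm`). The two knobs are deliberately minimal: f spans the amplitude
range from fully ordered to spatially random, and jitter degrades order
within the periodic component, which is exactly what the downstream statistic
is supposed to detect.

Defaults (all exposed in `LatticeParams`): period 190 nm (the actin-ring
spacing of the MPS), phase 0, jitter 10 nm, f 1.0, density 500/µm, lateral
precision 10 nm, z precision 20 nm, length 38 µm (twenty full 1900 nm
segments), diameter 300 nm. Labeling density and localization precision are
not published quantities for this preparation; the defaults are typical of
good dSTORM on a densely labeled epitope and are stated in every output's
metadata. The diameter is validated against the ≤ 700 nm selection criterion
used for unbundled distal axons.

The trophic-deprivation preset (`td_timecourse`) uses four conditions — NGF,
TD_3h, TD_6h, TD_12h — with f = 1.0, 0.7, 0.45, 0.2 and shared remaining
parameters: a monotone, roughly even decline whose endpoints span the ordered
and mostly-disassembled regimes.

Per-axon seeds are derived from the condition seed through
`numpy.random.SeedSequence(seed).generate_state(n_axons)` — a counter-based
scheme, so cohorts are reproducible and independent of iteration order.

What the generator does **not** emulate: frame-level blinking and repeated
localizations of one fluorophore, drift, astigmatic 3D PSFs, epitope
clustering within a ring (per-localization ring assignment is independent),
axon curvature, and background from neighboring cells. Tests passing on this
generator therefore validate the statistical machinery, not the full
messiness of real acquisitions.

Wide-field image pairs (`simulate_widefield_pair`): the axon is a filled
ribbon; the spectrin channel carries signal on an exact count of randomly
chosen 2 µm blocks matching the requested coverage (realized coverage is
recorded). Both channels are blurred with a Gaussian PSF (default σ 250 nm)
on a 160 nm pixel grid and Poisson noise is added (signal 1000, background 10
expected counts). These are conventional-microscope scales; the paper-style
occupancy procedure only needs the two channels to share geometry.

## Projection and binning

The 1D profile is built from the (x, y) coordinates only; z is ignored (the
lattice period is axial, and including depth would only mix in the axis
estimate's largest error direction). Two axis modes:

- `principal-axis` (default): project onto the first principal component of
  the cloud. The sign is fixed (positive correlation with +x, ties toward +y)
  so output is deterministic; positions are shifted so the smallest retained
  coordinate is 0.
- `polyline`: arc length of the nearest point on a user-supplied centerline
  (for curved axons), computed with shapely.

Localizations farther than `corridor_nm` (default 500 nm, covering the
≤700 nm diameter criterion with margin) from the axis are dropped and
counted. Binning uses half-open 10 nm bins anchored at 0.

## The autocorrelation estimator

Per 1900 nm segment (190 bins), with c the bin counts and c̄ their mean:

    g(k) = Σᵢ (cᵢ − c̄)(c₍ᵢ₊ₖ₎ ₘₒd ₙ − c̄) / Σᵢ (cᵢ − c̄)²

i.e. **circular** autocorrelation with full-segment mean and variance. This
is the default for a specific reason. The segment length is an exact
multiple of the lattice period (10 × 190 nm), so a periodic profile is
circularly stationary within a segment: the estimator is phase-invariant and
its expected curve inherits the half-period symmetry
g(T/2 − x) = g(T/2 + x) of a periodic signal, which places the inter-peak
minimum symmetrically about 95 nm. The alternative linear estimator
(`acf_estimator="linear"`: numerator over the overlapping range only) is
provided for comparison, but its finite-window mean-subtraction bias tilts
the inter-peak trough by a few parts in 10³ per 100 nm of lag — enough to
drag the trough minimum of a sharply peaked lattice 30–40 nm away from the
half-period — so it is not the default.

Normalization choices: variance normalization makes g dimensionless,
density-invariant and g(0) = 1, so amplitudes are comparable across axons
with different labeling density. Flat segments (zero count variance) are
degenerate and dropped with bookkeeping; segments with fewer than
`min_locs_per_segment` (default 50) localizations are dropped likewise, to
keep near-empty segments from contributing pure noise curves.

Per-segment curves are averaged lag-wise (unweighted); the per-axon
**amplitude** is the averaged curve's maximum over [150, 230] nm minus its
minimum over [50, 150] nm. Window extrema are window-global; exact ties
resolve toward the lag nearest the window center, then toward the smaller
lag. Amplitudes are reported as-is (they can exceed 1; with non-touching
windows they could be negative — no clamping). The variant that averages
per-segment amplitudes instead of reading the averaged curve is available
(`amplitude_from="per-segment"`) but not default: the averaged-curve reading
is less noisy at the segment counts typical of one axon.

A reporting helper (`lag_min_midpoint`) localizes the half-period more finely
than the 10 nm grid: the two adjacent lags bracketing the window minimum are
symmetric about the half-period for a periodic curve, so their midpoint
(e.g. 90 and 100 → 95 nm) recovers it. For sharply peaked lattices the
trough is a plateau whose lags are tied to within ~1e-6; pair-sum ties within
that tolerance resolve toward the window center, mirroring the extremum
convention.

### Known biases of the amplitude

- **Positive null bias.** The default extremum windows touch at 150 nm, so
  the amplitude (max over one window minus min over the other) is
  non-negative for every axon, and scanning for extrema over ~10 noisy lags
  inflates it further: under complete spatial randomness the per-axon
  amplitude concentrates around a small positive value (≈0.1–0.15 at the
  densities used in the tests) rather than 0. The amplitude is therefore an
  ordinal score — ideal for comparing conditions, as in the KS contrasts —
  not an unbiased "excess periodicity" estimate. The acceptance suite
  contains a deliberately strict null-mean check that documents this bias by
  failing.
- **Non-monotonicity at sub-bin ring widths.** For ring widths below about
  two bins (≲20 nm), narrowing the rings inflates the profile variance (the
  g(0) = 1 normalizer) faster than the 190 nm cross-correlation, so the
  normalized amplitude *rises* slightly as jitter grows from 0 to ~20 nm and
  only then enters the expected decreasing regime. The monotonicity property
  test runs on the disorder-dominated grid {20, 40, 80} nm.

## Occupancy ratio

Both channels are binarized (Otsu by default; fixed and percentile
thresholds available — the threshold used is always recorded in the result).
The tubulin mask is thinned to a one-pixel skeleton with a topology-preserving
3D-safe thinning (Lee's method as implemented in scikit-image) and dilated by
2 px into a thin corridor ("strokes"), so that the denominator measures axon
length rather than apparent width. Registration of the spectrin channel to
the tubulin channel is translation-only by default (integer shift maximizing
cross-correlation; drift is the stated purpose), with an opt-in affine model
(sub-pixel translation initialization via upsampled cross-correlation, then
least-squares refinement of all six parameters on lightly smoothed
intensities). The ratio is |aligned spectrin mask ∩ strokes| / |strokes|;
spectrin signal outside the strokes never contributes. An empty spectrin
mask under a fixed threshold yields ratio 0 with an explicit flag instead of
an error, so cohort runs keep going.

Caveats: dilation can merge strokes of distinct axons closer than twice the
dilation radius; the component-count preservation contract assumes separated
axons. Otsu thresholding misbehaves on images with no real foreground — use
a fixed threshold for near-empty channels.

## Group statistics

Per condition: mean, SEM (sample standard deviation with n−1, divided by
√n), and n. Pairwise contrasts use the two-sided two-sample
Kolmogorov–Smirnov test: exact D over the pooled sample, asymptotic p-value
(appropriate at ≥ ~20 axons per condition; at the cohort sizes used the
asymptotic test is mildly conservative, with a measured type-I rate of
~3–4% at α = 0.05). Raw p-values per contrast, no multiplicity correction,
starred p ≤ 0.05 / 0.01 / 0.001. Extremely small p-values are clipped to the
smallest positive float so they remain valid probabilities in (0, 1].

## Pipeline determinism

`run_pipeline` echoes the fully expanded configuration (no silent defaults)
and its SHA-256 into the manifest, derives every random stream from the
configured seeds, logs and excludes unquantifiable axons with per-condition
counts, and produces byte-identical summary tables on rerun.

## Problem sizes in the test suite

The tests simulate axons at reduced scale where the check does not need the
default geometry (e.g. 3.8–7.6 µm axons at 300/µm for null-calibration and
monotonicity sweeps, 20 axons per condition for the time-course check);
these sizes give standard errors comfortably below the effect sizes being
asserted while keeping the whole suite at around a minute.
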