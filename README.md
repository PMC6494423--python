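# mpskit

Quantification of the axonal **membrane-associated periodic skeleton (MPS)**
from single-molecule localization microscopy (STORM/SMLM) data.

The MPS is a quasi-1D lattice beneath the axonal membrane: actin rings spaced
~190 nm apart, connected by spectrin tetramers. Super-resolution imaging of a
spectrin subunit yields a list of fluorophore coordinates; when the lattice is
intact the axial positions of those localizations are periodic, and as the
lattice disassembles (for example after trophic deprivation of sensory
neurons) the periodicity fades. `mpskit` turns that qualitative picture into
numbers, for microscopists and quantitative biologists analyzing axon
degeneration or MPS perturbations.

## The statistic

For one axon, with localization positions projected onto the axon axis:

1. Bin the axial positions into a 10 nm histogram.
2. Cut the histogram into adjacent, non-overlapping 1900 nm segments
   (trailing remainder discarded, near-empty segments dropped).
3. For each segment compute the mean-subtracted, variance-normalized 1D
   spatial autocorrelation (circular over the segment by default; since
   1900 nm = 10 × 190 nm, a periodic profile is circularly stationary, which
   keeps the curve's half-period symmetry intact):

       g(k) = Σᵢ (cᵢ − c̄)(c₍ᵢ₊ₖ₎ mod n − c̄) / Σᵢ (cᵢ − c̄)²,   g(0) = 1

4. Average the per-segment curves.
5. Report the **autocorrelation amplitude**: the averaged curve's maximum in
   a window around the 190 nm ring spacing ([150, 230] nm) minus its minimum
   in a window around the 95 nm half-period ([50, 150] nm). Ordered lattices
   give amplitudes near 1; spatially random localizations give small values.

Conditions are compared the way such experiments are reported: per-condition
mean ± SEM with axon counts, and a two-sided two-sample Kolmogorov–Smirnov
test per contrast.

The package also implements the complementary **occupancy ratio** on
two-channel wide-field images (spectrin + tubulin): binarize both channels,
thin the tubulin mask into topology-preserving "strokes", register the
channels (translation or affine), and report the fraction of stroke pixels
covered by spectrin signal.

Because raw localization data for published disassembly time courses are not
deposited, the package ships a first-class synthetic generator
(`mpskit.synthetic`): a ring-comb mixture model with tunable period, phase
jitter, periodic fraction, labeling density and localization precision, plus
matching diffraction-limited image pairs. Every analysis stage is tested
against this generator's ground truth.

## Worked example

```python
from mpskit import simulate_cohort, quantify_axon, summarize, td_timecourse

groups = {}
for cond in td_timecourse(seed=7, n_axons=20):   # NGF, TD_3h, TD_6h, TD_12h
    tables, _ = simulate_cohort(cond)
    groups[cond.label] = [quantify_axon(t).amplitude for t in tables]

summaries, comparisons = summarize(groups, contrasts=[("NGF", "TD_12h")])
for s in summaries:
    print(f"{s.label}: {s.mean:.3f} +/- {s.sem:.3f} (n={s.n})")
```

This prints:

```
NGF:    1.276 +/- 0.001 (n=20)
TD_3h:  1.194 +/- 0.002 (n=20)
TD_6h:  1.012 +/- 0.003 (n=20)
TD_12h: 0.496 +/- 0.005 (n=20)
```

The preset lowers the periodic fraction from 1.0 (NGF) to 0.2 (12 h of
trophic deprivation), and the mean amplitude declines accordingly; the
NGF vs TD_12h KS contrast has D = 1.0 (the asymptotic p underflows and is
reported as the smallest positive float, starred `***`). A single clean-lattice
axon (periodic fraction 1, 5 nm jitter, 10 nm precision, 38 µm, 500
localizations/µm) gives amplitude ≈ 1.21 with the curve maximum at lag
190 nm — the recovered ring spacing — and the half-period minimum bracketed
symmetrically about 95 nm.

There is also a CLI:

```bash
mps simulate --out sim/ --seed 1            # TD time-course preset
mps quantify --locs sim/NGF/NGF_axon000.csv --out result.json
mps run --config run.yaml --out out/        # simulate -> quantify -> compare
mps occupancy --spectrin a.tif --tubulin b.tif --out occ.json
```

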