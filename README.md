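# msi2lmd

Mass spectrometry imaging (MSI) can map hundreds of lipids across a tissue
section and reveal, e.g., molecularly distinct tumor subpopulations — but it
cannot by itself isolate those regions for deeper molecular analysis.
Laser microdissection (LMD) can cut arbitrary shapes out of a section, but
needs to be told *where*. `msi2lmd` implements the computational bridge: it
co-registers the MSI pixel grid, the high-resolution optical image of the
measured section, the H&E-stained image of the same section, and the LMD
stage coordinates; segments the tumor-associated spectra into molecular
subpopulations; and exports the segment outlines as an LMD-importable XML
file, so that each MSI-defined region can be microdissected and profiled
(e.g. by microproteomics). It is aimed at MSI/imaging-MS groups running
MSI-guided microdissection workflows.

## Method

**Registration.** Each hop between coordinate frames is a 2-D affine
transform `x' = a·x + b·y + tx`, `y' = c·x + d·y + ty` fitted to ≥ 3 manually
picked landmark pairs (laser-shot marks for MSI→optical, Tipp-Ex fiducial
spots for optical→H&E and optical→LMD). Three pairs give the exact
interpolant; more give the least-squares fit. Per-hop errors are summarized
per axis as mean ± SD of the absolute landmark deviations (μm) and
propagated assuming additive worst-case effects: means add, SDs combine in
quadrature. Scanner resolution converts to physical pixel size as
`25400 / dpi` μm.

**Segmentation.** TIC-normalized tumor spectra `X` (pixels × m/z channels)
are factorized by non-negative matrix factorization, `X ≈ W H` with
`W, H ≥ 0` (multiplicative Frobenius updates, seeded restarts), and each
pixel is labeled by its arg-max score. The number of segments `k` is scanned
over 2..5 and chosen to maximize the mean silhouette coefficient
`s(i) = (b(i) − a(i)) / max(a(i), b(i))` of the labeling.

**ROI processing.** The label image is smoothed by a 2×2 grayscale opening,
split into per-segment binary masks, cleaned (4-connected components ≤ 30
pixels removed, 8-connected holes filled), warped to the H&E frame by
nearest-pixel inverse mapping, and the external boundary of every region is
traced (Moore-neighbor tracing) into a closed polygon. Boundaries are
re-expressed relative to an origin teaching point and written as LMD XML.

**Microproteomics statistics.** Post-LMD label-free protein tables are
filtered for QC flags, log2-transformed and z-scored per protein across
segments; a protein is called exclusively over- (under-) expressed in a
segment when only that segment's z-score reaches +1 (−1); protein ordering
comes from complete-linkage Euclidean clustering over a k-means
pre-clustering (300 clusters, 10 iterations, 1 restart).

Because no public dataset accompanies this workflow, the `phantom` module
generates complete synthetic studies (MSI grids with planted contiguous
clusters, fiducial-marked image pairs under known affines, protein tables
with planted markers) that every test runs against.

## Worked example

```python
import numpy as np
from msi2lmd import (PhantomSpec, make_msi_phantom, tic_normalize, select_k,
                     RegistrationError, propagate_errors)

# per-step registration errors measured on the instrument chain (um)
steps = [RegistrationError(7.89, 3.96, 4.06, 4.32, 3),
         RegistrationError(1.39, 1.39, 0.33, 0.50, 5),
         RegistrationError(3.46, 7.39, 2.62, 3.78, 3)]
total = propagate_errors(steps)
print(f"worst-case error: x {total.mean_x:.2f}±{total.sd_x:.2f} um, "
      f"y {total.mean_y:.2f}±{total.sd_y:.2f} um")

ds, truth = make_msi_phantom(PhantomSpec(grid_shape=(40, 40), k_true=3, seed=1))
result = select_k(tic_normalize(ds).spectra, k_range=range(2, 6), seed=1)
print("chosen k =", result.chosen_k)
print({k: round(v, 3) for k, v in result.silhouette_by_k.items()})
```

prints

```
worst-case error: x 12.74±4.84 um, y 12.74±5.76 um
chosen k = 3
{2: 0.512, 3: 0.733, 4: 0.523, 5: 0.238}
```

The combined error bound (12.74 μm in both axes) is the additive worst case
over the three co-registration hops — below one 70 μm MSI pixel, i.e. the
chain is accurate enough to cut what MSI sees. On the synthetic 3-cluster
tissue, the silhouette curve peaks at `k = 3`, recovering the planted number
of molecular subpopulations.

The same steps are available from the shell (`msi2lmd register | normalize |
mask | segment | process-roi | export-lmd | proteomics | phantom | run`);
`msi2lmd phantom --out demo/` writes a full synthetic study and
`msi2lmd run --config pipeline.yaml` executes the whole chain to an LMD XML.

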