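# symseg

Symmetry- and edge-constrained level-set segmentation of bilaterally
symmetric blobs in 2-D grayscale images.

The motivating application is tongue-body segmentation for computer-aided
tongue diagnosis: the tongue is low-contrast against lips and surrounding
tissue, speckled, sometimes cracked down the middle — but it is reliably
*mirror-symmetric about an axis running to a single pointed tip*. `symseg`
exploits that geometry three ways:

1. **Automatic initialization.** The symmetry axis is detected from the
   edge-probability map (centroid of the thinned edge ridge) and a Harris
   corner search for the tip; the level-set function starts as a circular
   signed distance function centred on the axis, inside the target.
2. **Symmetry detection constraint (SCT).** The evolution energy is
   augmented with the squared asymmetry of the edge-weighted inside
   indicator, `S(φ) = η ∫ (H_ε(−φ)g − reflect(H_ε(−φ)g))² dx`, where the
   reflection is across the detected axis. When the contour stalls or leaks
   on one side (weak edges, noise, cracks), the mirror image of the
   healthy side pulls it back.
3. **Edge-probability stop function.** The contour's motion is gated by
   `g = 1/(1 + (gain·E)²)` where `E ∈ [0,1]` is per-pixel boundary
   probability — either loaded from file (e.g. the output of a learned edge
   detector) or computed as a normalized smoothed image gradient.

The evolution itself is distance-regularized level-set evolution (DRLSE):

```
∂φ/∂t = μ div(d_p(|∇φ|)∇φ) + λ δ_ε(φ) div(g ∇φ/|∇φ|) + α g δ_ε(φ) + 2η δ_ε(φ) g (w − ŵ)
```

with the double-well potential `p` keeping `|∇φ| ≈ 1` near the interface
(no reinitialization), `w = H_ε(−φ)g`, and `ŵ` its mirror. Defaults:
`Δt = 1, ε = 1.5, λ = 2, α = −2, μ = 0.2, σ = 1, η = 1`.

A seeded phantom generator produces tongue-like test images with ground
truth (mask, apex, axis, edge map) covering the hard cases: low contrast,
speckle, median crack, and one-sided edge attenuation. Metrics are the
usual reference-normalised TP/FN/FP fractions plus precision, recall, F1
and IoU.

## Worked example

```sh
# make 1 clean phantom (image/mask/edges PNGs + manifest)
symseg synthesize --preset clean --n 1 --seed 7 --out demo

# segment it, using the shipped ground-truth edge map as the edge prior
symseg segment demo/phantom_clean_000_seed2029167940_image.png \
    --edge-map demo/phantom_clean_000_seed2029167940_edges.png --out demo/out

# score the result against the ground-truth mask
mkdir -p demo/pred demo/ref
cp demo/out/*_mask.png demo/pred/m.png
cp demo/phantom_clean_000_seed2029167940_mask.png demo/ref/m.png
symseg evaluate demo/pred demo/ref
```

The `segment` step prints the detected axis and the run summary:

```
axis: A=-36.435 B=-0.252 C=2273.401 (angle 0.40 deg from vertical)
iterations: 600 (max_iters)
final energies: regularization=728.4, length=23.41, area=2661, sct=26.59, total=-5103
mask: demo/out/phantom_clean_000_seed2029167940_image_mask.png
```

and `evaluate` reports per-image and mean scores:

```
file                                         prec     reca       F1      IoU
m.png                                      0.9888   0.9818   0.9853   0.9710
mean                                       0.9888   0.9818   0.9853   0.9710
```

i.e. the detected axis is within half a degree of vertical, the contour ran
its 600-iteration budget, and the recovered mask overlaps the ground truth
at IoU 0.97 (the quantisation of the edge map to 8-bit PNG costs a little
versus the in-memory pipeline).
`--mode drlse` runs the same pipeline without the symmetry term —
on this clean, symmetric phantom the two agree; on the `weak-side` preset
(one side's edge evidence attenuated to 20 %) the symmetry term is worth
roughly +0.05…+0.1 IoU per image.

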