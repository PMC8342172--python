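# Methods

## Model

A closed contour is represented implicitly as the zero level of a scalar
field φ(x, y) (negative inside) and evolved by forward Euler on the gradient
descent flow of

E(φ) = μ·R_p(φ) + λ·L_g(φ) + α·A_g(φ) + η·S_g(φ)

* **R_p = ∫ p(|∇φ|) dx** — distance regularization. `p` is the double-well
  potential, `p(s) = (1/(2π)²)(1 − cos 2πs)` for `s ≤ 1` and `(s−1)²/2` for
  `s ≥ 1`, whose wells at `s = 0` and `s = 1` drive the field toward the
  signed-distance slope near the interface and toward flatness far away, so
  no periodic reinitialization is needed.
* **L_g = ∫ g δ_ε(φ)|∇φ| dx** — edge-weighted contour length. `δ_ε` is the
  cosine-bump smoothed Dirac of half-width ε, so the term acts only in a
  band around the zero level.
* **A_g = ∫ g H_ε(−φ) dx** — edge-weighted inside area. With α < 0 an
  interior seed grows; growth stalls where g is small.
* **S_g = η ∫ (w − ŵ)² dx**, with `w = H_ε(−φ)·g` and `ŵ` the reflection of
  w across the symmetry axis — the symmetry detection constraint. It is
  zero for a mirror-symmetric contour-and-evidence configuration and
  penalizes one-sided deviations.

The flow is

∂φ/∂t = μ div(d_p(|∇φ|)∇φ) + λ δ_ε(φ) div(g∇φ/|∇φ|) + α g δ_ε(φ) + 2η δ_ε(φ) g (w − ŵ)

where `d_p(s) = p′(s)/s` and the last term treats the reflected field ŵ as
frozen within a step (a standard "frozen mirror" approximation; a forward
Euler step along it strictly decreases S_g on fixed g). An optional
`sct_literal` variant replaces the last term by `2η δ_ε(φ)(H_ε(φ) − Ĥ_ε(φ̂))`,
a simplified g-less form sometimes written for this constraint; it is not
the descent direction of S_g (the sign of its interior difference is
opposite), so the consistent form is the default.

The smoothed step functions are `H_ε(x) = ½(1 + x/ε + sin(πx/ε)/π)` on
|x| ≤ ε (0/1 outside) and its derivative `δ_ε(x) = (1+cos(πx/ε))/(2ε)`.

## Edge prior and stop function

Edge evidence E ∈ [0,1] per pixel comes from an external boundary-probability
image (e.g. a learned edge detector's output, loaded from PNG/TIFF and
Gaussian-smoothed with the configured σ) or from the classical fallback
|∇(G_σ∗I)| normalized by its maximum. The stop function is

g = 1 / (1 + (gain·E)²) ∈ (0, 1].

The gain (default 4) sets where on the probability scale evidence starts to
act as a barrier: g = 0.5 at E = 1/gain. Two considerations fix the
default. With Δt = 1 the front advances only a few hundredths of a pixel
per iteration, and its speed is proportional to g; a high gain (say 10)
turns even the broad low-probability skirt of a band-limited edge ridge
into a brake, and the contour spends its entire iteration budget crawling
the last two pixels. Gain 4 leaves evidence below ~0.25 nearly transparent
while a confident edge (E ≈ 1) still yields g ≈ 0.06, a barrier two orders
of magnitude below free space. The gain is exposed in the configuration.

## Automatic axis detection and initialization

* **Anchor.** The centroid of the *skeletonized support* of the edge map
  (pixels above 10 % of the maximum, thinned to one-pixel ridge lines,
  equally weighted). A value-weighted centroid — the naive reading — is
  dragged several pixels toward the side with stronger evidence whenever
  the detector is locally less confident on one side, and an off-axis
  mirror turns the symmetry constraint from corrective to harmful; thinning
  also removes the residual bias of the support band being wider where
  evidence is stronger. The module still exposes the plain value-weighted
  `gradient_centroid` as its own operation.
* **Tip.** Harris corner response `det(S) − k·trace(S)²` of the
  Gaussian-windowed structure tensor (window σ = 2, k = 0.05, replicate
  boundaries), thresholded at 10 % of its maximum; candidates are restricted
  to a vertical strip of half-width 10 % of the image width around the
  mid-column and to the lower 40 % of rows (the pole of a tongue sits
  low-centre), and their mean coordinate is the tip. If no corner survives
  (smooth, corner-free poles) the fallback takes the lowest strong-edge
  pixel in the strip.
* **Axis.** The line through anchor and tip, A = y₁−y₂, B = x₂−x₁,
  C = x₁y₂−x₂y₁; its midpoint O is the midpoint of the two intersections
  with the image rectangle. Reflection across it is the homogeneous matrix
  involution; fields are reflected by bilinear resampling with replicate
  out-of-bounds policy (a constant-background policy is selectable).
* **Seed circle.** φ₀ is the exact SDF of a circle centred on O with radius
  0.9 × the distance from O to the nearest *strong* edge pixel (above half
  the edge-map maximum), clamped to [5 px, 0.45·min(h,w)]. Rationale: the
  front's travel is the budget-limiting resource (see below), so the seed
  should hug the boundary from inside; using only confident edges means an
  undetected (weak) boundary section does not shrink the seed — the contour
  will run through it and the symmetry term pulls it back, which is the
  designed division of labour. By construction the symmetry energy of the
  seed is ~0, so the constraint is inert until the contour becomes
  asymmetric.
* The axis is fixed after initialization by default; `axis_refresh_every N`
  re-anchors it on the centroid of H_ε(−φ) every N iterations for users who
  want the reflection to track the evolving contour.

## Parameters

| name | default | meaning |
|------|---------|---------|
| μ | 0.2 | distance-regularization weight; stability needs μ·Δt < ¼ |
| λ | 2 | length (edge-attraction) weight |
| α | −2 | area weight; negative = outward growth of the seed |
| η | 1 | symmetry-constraint weight |
| ε | 1.5 px | half-width of H_ε/δ_ε transition band |
| Δt | 1 | forward-Euler step |
| σ | 1 px | Gaussian smoothing of images / external edge maps |
| gain | 4 | edge-evidence gain in g |
| max_iters | 600 | iteration budget; early stop when mean |Δφ| < 1e−4 |

The PDE weights are the method's standard operating point and are kept as
shipped defaults; gain and the detection parameters (Harris window,
thresholds, search band) are package choices, exposed in the config.

## Discretization

Spatial derivatives are central differences with one-sided borders
(replicate/Neumann); a border ring is re-mirrored from the interior each
step. The regularization divergence is computed in the split form
div((d_p−1)∇φ) + Δφ with a compact 5-point Laplacian, and the length term
by the product rule ∇g·n + g·div(n): nesting wide-stencil first differences
instead visibly under-damps the moving interface and halves the front
speed (verified against an independent transliteration of the canonical
update). |∇φ| is floored at 1e−10 before normalization. The standalone
curvature operator uses the direct second-derivative formula
(φ_xx φ_y² − 2φ_xφ_yφ_xy + φ_yy φ_x²)/(φ_x²+φ_y²)^{3/2}, whose tight
stencil is ~1 % more accurate on small circles than nested divergences.

Two discrete facts worth knowing:

* **Front speed.** With Δt = 1 the expanding front moves at roughly
  0.02–0.05 px/iteration in free space (the δ_ε band truncates the driving
  force one pixel ahead of the interface), slowing further inside the edge
  valley. 600 iterations therefore buy ~10–20 px of travel; the seed-radius
  rule above exists to spend that budget on the final approach.
* **Swept-region profile.** Pixels the front has passed over settle near
  φ ≈ −(ε + ½) and stay flat (the s = 0 well); |∇φ| ≈ 1 holds only in the
  recently visited neighbourhood of the zero level, and the interface
  compresses to |∇φ| ≈ 1.2–1.3 where it rests against a stiff edge
  barrier. Both effects are shared by the reference update and are visible
  in any truncated-SDF profile this family of methods produces. Energy
  descent holds at checkpoint granularity (default every 10 iterations);
  at single-step granularity the barrier-landing transient can produce
  upticks of order 1e−4 of the total energy (forward Euler plus
  discrete-sum ripple).

## Synthetic phantoms

A phantom is a mirror-symmetric blob: half-width rises parabolically from 0
at the apex (a genuine wedge corner for the Harris detector) to W over a
taper length L, closed above by a half-ellipse cap; defaults W ≈ 30–36,
L ≈ 42–50, cap 16–20 on a 128² grid, apex near (w/2, 0.78h), axis tilt
within ±6°. The proportions mimic a frontal tongue filling most of the
frame and keep the true boundary within the front's travel budget of the
inscribed seed circle. The image is background + contrast·(Gaussian-soft
mask) with optional speckle dots, a dark median crack along the axis, and
i.i.d. Gaussian noise; the ground-truth edge map is the gradient-magnitude
ridge of the soft mask (it peaks *on* the boundary; a feathered
inner-boundary ring would sit half a pixel inside and bias the converged
contour inward by ~1 px). The `weak-side` preset multiplies one side of the
edge map by 0.2, emulating a locally unreliable detector.

Presets: `clean` (contrast 0.6), `low-contrast` (0.08), `speckle` (density
0.05, amplitude 0.3), `crack` (width 3 px), `weak-side` (attenuation 0.2).
All randomness flows from one seeded generator per phantom; suites derive
per-item seeds from a master seed, so everything is bit-reproducible.

What the phantoms do **not** emulate: colour and texture of real tissue,
specular highlights, lips/teeth structures with their own symmetry, and a
learned detector's correlated (non-multiplicative) failure modes. Passing
the synthetic suites shows the machinery behaves as designed — that the
symmetry term repairs one-sided evidence loss, that initialization and
detection are accurate on this geometry — not that clinical-grade accuracy
transfers to real images, which additionally depends on the quality of the
supplied edge map.

## Degenerate inputs and conventions

All-zero edge maps, coincident centroid/tip, empty reference masks and
both-empty mask pairs raise typed errors; an empty prediction against a
nonempty reference scores 0 with an `empty-prediction` flag. Masks are
φ ≤ 0; the coordinate convention is x = column, y = row, origin top-left.
Images are 8/16-bit PNG/TIFF, rescaled linearly to [0,1], RGB collapsed to
luma. The CLI exits 0 on success, 2 on usage errors, 3 on input errors,
4 on numeric failure (non-finite φ, reported with the iteration index).

## Known limitations

* Single axis, single blob: no multi-object or rotational symmetry support.
* The frozen-mirror symmetry gradient ignores the dependence of ŵ on φ;
  it is a descent direction but not the exact functional derivative.
* Dense updates on the full grid (no narrow band); fine for ≤ 512² images.
* The stop function never reaches 0, so an unbounded run would eventually
  leak through any finite barrier; the iteration budget is part of the
  method's operating point.
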