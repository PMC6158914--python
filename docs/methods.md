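# Methods

`cupseg` segments the optic cup — the bright central depression of the
optic disc — in colour fundus photographs, and reports the vertical
cup-to-disc ratio (CDR) used to grade glaucoma risk.  The hard part of
cup segmentation is that retinal blood vessels cross the cup boundary
and locally destroy the intensity transition a region-based segmenter
relies on.  The pipeline therefore removes the vessels *before*
segmenting:

1. green-channel extraction (best cup contrast of the three channels);
2. morphological contrast enhancement;
3. vessel extraction by median differencing;
4. vessel inpainting with an improved BSCB PDE scheme;
5. cup segmentation with a local Chan–Vese (LCV) level set.

All images are carried as float grids in [0, 255] indexed `(row, col)`;
quantization happens only when writing files.

## Contrast enhancement

With a flat 5×5 square structuring element `SE`,

    U = (U_G + TopHat(U_G)) − BottomHat(U_G),

where the top-hat `U_G − open(U_G, SE)` collects small bright detail and
the bottom-hat `close(U_G, SE) − U_G` small dark detail (mostly
vessels).  Borders are reflect-padded so both hats vanish on constant
images; the result is clipped back to [0, 255] by default (`clamp`).
The SE side is the main tunable; the sweep harness reproduces the
classic size study (2…15 px, even sizes permitted there only).

## Vessel extraction

Vessels are darker than their surroundings, so the 9×9 median filter
raises them: `U_sub = U_med − U` is positive on vessel pixels and the
mask is `U_sub > τ` with τ = 0 by default (the strict positive rule).
A zero threshold also fires on noise — on the default noisy phantom
roughly half of all pixels are marked — so two cleanup steps follow:
8-connected components smaller than `min_component` (10 px) are
dropped, and the mask Ω is dilated by a Euclidean disc of radius
`band_radius` (2 px) into the band Ω^ε the diffusion stage works on.
The disc is a metric ball (pixel included iff its centre is within the
radius), so radius 1 is the 4-neighbour cross — fixed so tests are
bit-exact.

## BSCB inpainting

The Bertalmio–Sapiro–Caselles–Ballester model alternates two explicit
updates at rate Δt = 0.1 (15 transport + 2 diffusion updates per
cycle):

    transport:  U ← U + Δt (∇L̄ · T),   in Ω
    diffusion:  U ← U + Δt g_ε κ |∇U|,  in Ω^ε

`T` is the unit isophote direction `(−U_y, U_x)/|∇U|`, κ the isophote
curvature `div(∇U/|∇U|)` (magnitude regularized by 1e-8), `g_ε` the
Gaussian-smoothed band indicator renormalized to [0, 1] and zero
outside the band.  The propagation information L̄ is the *improvement*
of the scheme: the second differences `u_xx`, `u_yy` are averaged over
a 3×3 neighbourhood before being combined, which suppresses the effect
of pixel noise on what gets transported.  `nbhd=1` recovers the classic
single-pixel scheme; `laplacian_mode` chooses between the sum
`ū_xx + ū_yy` (the discrete Laplacian, default) and the product
`ū_xx · ū_yy`.

**Stabilization.**  The continuous model satisfies a maximum principle,
but the central-difference transport term does not: on large noisy
regions the raw explicit scheme diverges (measured: values of order
1e30 after 3000 updates on the default phantom).  Each update is
therefore followed by a local extremum-diminishing limiter — changed
pixels are clipped to the 3×3 min/max of the previous iterate.  The
limiter leaves small in-range updates untouched (the transport-oracle
tests pass unchanged), lets fill fronts advance one pixel per step, and
bounds the output by the input range.  It can be disabled
(`limiter=False`) to study the raw scheme.

An important honesty note on the improved-vs-classic comparison: in the
*raw* scheme the neighbourhood-mean variant reconstructs noisy phantoms
far better than the single-pixel variant (it is the difference between
slow and fast divergence of the transported information; 20/20 paired
wins at σ = 8).  With the production limiter enabled, both variants are
stabilized and the paired difference disappears.  The acceptance test
for this claim runs both arms with the limiter off, because that is the
configuration in which the choice of propagation information — the
modelling claim — is actually load-bearing.

**Stopping.**  Iteration ends at `total_iters` (3000), when the mean
absolute change per Ω pixel per elementary update over a cycle drops
below `stop_tol` (1e-4), or when that cycle residual has improved by
less than 1% over the last 12 cycles (`plateau_cycles`/`plateau_ratio`)
— the latter catches noise-dominated regions whose residual floors well
above `stop_tol`.  Pixels outside Ω^ε are bit-identical to the input,
always.  Internally the iteration runs on the band's bounding box
padded by 6 px (beyond the stencil reach), which is exactly equivalent
to full-frame iteration.

## LCV segmentation

The energy is a two-phase Chan–Vese fit plus an α-weighted local term
on the difference image `Id = boxmean(I, w) − I` (w = 15):

    E(φ) = μ·Length(φ) + ∫_in (I−c1)² + ∫_out (I−c2)²
         + α [ ∫_in (Id−d1)² + ∫_out (Id−d2)² ]

with α = 0.1 and μ = 0.1·255², the standard weights for a single bright
target with intensity inhomogeneity.  In/out are defined by the
arctan-smoothed Heaviside of width 1.5 px; `Length` uses the matching
Dirac.  `c1, c2, d1, d2` are the exact minimizing region means given φ.

Seeding is automatic: threshold at the 97th intensity percentile, keep
the largest component, take its centroid; φ starts as the signed
distance to a circle of radius 0.15·min(H, W).

**Evolution.**  Descent moves φ along the Dirac-localized negative
gradient normalized to unit maximum, so `dt` (default 1.0) is a
per-iteration movement cap in pixels — the CFL-style choice.  (A 0.1 px
cap cannot traverse the ~50 px seed-to-boundary distances of the
phantom suite within any reasonable iteration budget; that is why the
default is 1.0.)  Each step is accepted only if the energy does not
increase, halving up to 8 times otherwise, so the energy trace is
non-increasing by construction between redistancings.  Every 50
iterations φ is redistanced via the signed Euclidean distance transform
of {φ > 0}; redistancing may raise the recorded energy (it
reparametrizes φ) and in practice frees descents stuck in shallow local
minima — which is why the stall-based early stop only fires after the
mask has been static for a full redistancing period plus `stall_iters`.
The iteration cap is 1500; converged runs stop far earlier, the largest
cups (CDR ≈ 0.8) genuinely need ~1000 capped steps.

The result is the largest 8-connected component of {φ > 0}, holes
filled, with the boundary traced by marching squares at the 0.5 level.

## Metrics

* **Precision / recall / F-score**: pixel counts; `F = 2PR/(P+R)`,
  defined as 0 when TP = 0.
* **Boundary distance D**: rays from the centroid of the reference
  contour at n = 360 equally spaced angles; per angle, the absolute
  difference of the distances to the *farthest* intersection with each
  contour (robust to slight non-convexity); D is the mean.  Both curves
  are probed from the same origin.
* **Vertical CDR**: ratio of inclusive vertical pixel extents
  (`max_row − min_row + 1`) of cup and disc, so identical masks give
  exactly 1.  The disc mask is an input (expert-delineated in practice,
  analytic truth on phantoms).

## Phantom generator

The generator renders what the method needs to be tested against, not a
photorealistic retina: a background at level 60, an elliptical disc at
140, a cup at 210 with a 6 px smooth rim ramp centred on the analytic
cup ellipse, 3-px-wide quadratic-Bézier vessels (depth 70) that start
outside the disc and end inside the cup — guaranteeing each crosses the
cup boundary, the failure mode the method addresses — and i.i.d.
Gaussian noise (σ = 4).  The default frame is 480×480 with disc
semi-axes (110, 125) and cup semi-axes (55, 62) (CDR ≈ 0.5).  The green
channel carries the signal; red/blue are fixed 0.8×/0.4× copies, since
only green is consumed.  Truth masks come from the analytic ellipses
and the rendered vessel strips, and `true_cdr` is *computed* with the
package's own `vertical_cdr`, so the identity holds exactly by
construction.

`make_suite` jitters disc axes (±10%), centre (±10 px) and sweeps the
target CDR across [0.3, 0.8] with per-phantom seeds derived by a fixed
counter scheme (`seed·100003 + i mod 2³¹`), so suites are reproducible
bit-for-bit.

What a green phantom test does **not** establish: performance on real
fundus photographs — the phantom has no vignetting, no peripapillary
atrophy, no colour-channel bleed, piecewise-elliptic geometry, and
spatially white noise (real sensor noise is correlated).  The phantom
closes the loop on contracts and on the method's internal logic (e.g.
inpainting improves segmentation), not on clinical accuracy.

## Pipeline, ROI and determinism

When a disc mask is supplied, processing is restricted to its bounding
box (+`roi_margin`); the filtering stages additionally see an 8 px halo
so morphology/median stencils read true pixels rather than crop-border
reflections, while the level set runs on the tight window.  Everything
is deterministic: identical input and configuration give byte-identical
masks, contours and reports (no stage draws random numbers).

The ablation harness runs the pipeline with and without the inpainting
stage and reports paired F-scores; the sweep harness varies
`enhance.se_size` or `vessels.median_size` and reports mean ± sd of
precision and F over a suite.

## Known limitations

* The optic disc is an input, not segmented.
* The raw (unlimited) BSCB scheme is only usable on small, clean
  inpainting domains; production use relies on the limiter.
* Backtracking descent can park the level set in shallow local minima
  for up to one redistancing period; pathological images could in
  principle stall it permanently (it then stops and reports the
  current mask).
* The extended-structure-tensor LCV variant and ellipse fitting of the
  cup boundary are out of scope.
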