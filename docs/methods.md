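# Methods

## Helix model and landmark arithmetic

A thread centerline is modelled as an ideal circular helix
`c(t) = (P t / 2π) û + (D/2)(cos t v̂ + sin t ŵ)` in an orthonormal frame
with `û` the helix axis and `ŵ` the optical axis; a left-handed helix
mirrors the `ŵ` component.  Digitization places one landmark pair per
projection extremum `t_k = kπ`, offset `±φ/2` along `v̂` (in-image,
perpendicular to the projected tangent), so the pair distance is exactly
the thread diameter `φ` and the pair midpoint is exactly the centerline
extremum.

Analysis proceeds from the pair midpoints `p_c = (p_i + p_j)/2`:

* the **mean direction of increase** `v_inc` is the unit vector from the
  first to the last midpoint;
* each consecutive midpoint pair is one **half loop**; its displacement `d`
  splits into an axial part `a = (d·v_inc)v_inc` and lateral part
  `l = d − a`;
* the **pitch angle** is `θ = atan2(|a|, |l|)` — the angle between the
  half-loop displacement and the plane normal to `v_inc`.  The phrase
  "angle between the centerline and a vector normal to the direction of
  increase" admits several normal vectors; this operationalization is the
  one under which `D = |a| / tan θ` recovers the true helical diameter
  exactly on ideal data (it reduces algebraically to `|l|`), so it is
  adopted.  The chord length `|d|` is also reported as a diagnostic.
* the half-loop displacement of the ideal helix is `(P/2) û ± D v̂`, so the
  recovered angle satisfies `θ = atan(P/(2D))`.  This is the *chord* pitch
  angle of the half-loop secant, not the tangent pitch angle
  `atan(P/(πD))`; the landmark construction is followed literally, and all
  downstream uses (`R_ext = 1 − sin θ`, `L_T' = L_T sin θ`) are consistent
  with it.

**Degenerate half loops** (zero chord, or zero axial component, where `D`
is undefined) are flagged, excluded from per-thread means, and reported
with a warning rather than propagating NaN.  Per-thread summaries are
unweighted means over pairs / non-degenerate half loops; no weighting
scheme is imposed because none is implied by the measurement design.

**Exactness caveat:** `v_inc` equals the true axis only when the series
spans an even number of half loops (an odd count leaves a residual lateral
offset `D v̂` between the endpoints).  Oracle tests therefore use even
counts; with measured data the residual shrinks as 1/n and is part of
ordinary measurement error.

**Handedness** cannot be recovered from extremum-only landmarks (consecutive
lateral components are antiparallel), so the generator offers a separate
dense mode (quarter-loop centerline samples) and the detector returns
`undetermined` — never a guess — when the mean triple product
`(l_k × l_{k+1})·v_inc` of mean-centred lateral components is below 10 % of
the squared mean lateral norm.  A positive mean rotation is right-handed.

**Angles** are degrees at every public surface, radians internally; lengths
are µm at the cell scale and mm at the body/gland scale, with explicit
conversions (`units.py`).

## Census model

Counts along ~1 mm skin-section transects give a linear density
`λ = N/L`; the area density is `σ = λ²`, which assumes an isotropic cell
arrangement (mean linear spacing = inverse square root of planar
intensity).  Under Poisson counts `λ²` is biased upward by `λ/L`; an
optional bias-corrected estimator `(N² − N)/L²` is provided (default off,
since the plain estimator is the field convention and the bias is < 3 % at
the section lengths used here).  Counts must be integers; fractional counts
are rejected.  Aggregation over transects is an unweighted mean.

The whole animal is a cylinder (default 450 mm long, 20 mm diameter; skin
area `π·d·L`).  A 20 *cm* diameter sometimes appears in print for animals
this size, but it is inconsistent with the measured density and whole-body
total by an order of magnitude; a configured diameter ≥ 100 mm therefore
triggers a warning rather than a silent fix.

## Gland, exudate and fibrosity models

Slime glands are ellipsoids with one major and two minor semi-axes,
`V_G = (4/3)π(Φ_a/2)(Φ_b/2)²`.  With gland thread cells (GTCs) distributed
evenly, a cross-sectional area density `σ_GTC` (mm⁻²) implies a number
density `σ_GTC^{3/2}` (mm⁻³) — the only dimensionally consistent reading —
so `N_GTC = σ_GTC^{1.5} V_G`.  Direct count overrides are accepted because
the cross-sectional density is a supplementary measurement usually reported
only through the resulting counts (defaults 19,300 full / 4,100 remaining,
hence 15,200 ejected).

Exudate bookkeeping conserves volume exactly:
`V_ejected = V_full − V_emptied`, exudate weight `W = ρ V_ejected`
(default ρ = 1 g/ml, conservative), seawater volume `V_SW = W / c_wv`
(default w/v concentration 0.004 % = 4×10⁻⁵ g/ml), total deployed volume
`V_S = V_SW + V_ejected`.  The default profile carries the *reported*
ejected volume 9.37 mm³, which does not follow from the mean printed axes
(those give 7.25 mm³ — presumably the underlying per-gland data differ from
the axis means); the report shows both values rather than reconciling them.

Fibrosity is total thread length per slime volume.  For epidermal slime a
unit skin area `A` of ruptured epidermis (thickness `D_epi`, default
100 µm) yields `N = σ_ETC A` threads of length `L_T` in a volume `A·D_epi`,
so `r_F = L_T σ_ETC / D_epi`.  The default uses the straightened single
thread length `L_T = 2.2 mm` (not the helical centerline length 1.97 mm),
matching how the index is conventionally evaluated.  Seawater swelling
divides `r_F` by the swelling factor.  For defensive slime,
`r_F = L_T,slime · N_GTC,ejected / V_S`, with the single slime-thread
length defaulting to 180 mm (15,200 threads × 180 mm = 2,736 m per gland).
The fibrosity of raw, undiluted exudate (default 6.5×10⁵ mm/mm³) is a
configuration input from upstream literature, not derivable from the other
defaults; the dilution factor is that value over the deployed fibrosity.

The swelling factor is 1 plus the difference of group-mean water contents
in percentage points / 100 (93.9 % vs 74.7 % → 1.192; the default profile
ships the conventionally rounded 1.19).  This is a volume proxy assuming
near-seawater density, not a mass-balance swelling model.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the *statistical structure the analysis assumes*,
at the measured study conditions as defaults: helices at φ = 0.5 µm,
D = 0.35 µm, pitch chosen so θ = 63.5°, with i.i.d. Gaussian digitization
noise added to every coordinate after an arbitrary rigid motion; Poisson
transect counts with `λ_true = √σ_true` so the `σ = λ²` pipeline is
consistent in expectation (negative-binomial over-dispersion available,
default off); independent truncated-normal gland axes (resampling, max
1000 attempts) at full 3.51/2.45 mm and emptied 2.47/1.71 mm; water
contents 93.9 ± 1.2 % (swollen) and 74.7 ± 6.8 % (unswollen) converted to
consistent wet/dry masses with wet mass in the observed 2–10 mg scrape
range.  Distributional choices (normal, Poisson) are modelling conventions
— the measurements themselves carry no distributional claim.

What the generators do **not** emulate: real threads deviate from ideal
helices (variable pitch, curvature of the helix axis, switchback packing),
digitization error is likely anisotropic (worse along the optical axis),
cell counts may cluster by body region, and gland axes are correlated
within animals.  Passing recovery tests therefore demonstrates correctness
of the arithmetic and robustness to idealized noise, not field accuracy on
real images.

## Numerical and testing choices

* All randomness flows from integer seeds through `numpy.random.default_rng`;
  identical spec + seed gives bit-identical output.
* Truncated normals truncate at 0 (axes) or (0, 1) (water contents) by
  resampling; a degenerate request errors after 1000 attempts.
* `θ = 90°` (straight axial segment) is well-defined with `D = 0`;
  `θ = 0` flags the half loop degenerate.
* OLS trend tests (e.g. thread diameter against pitch angle) use the
  standard two-sided t-test on the slope; a constant predictor is an error.
* Test problem sizes: parameter-recovery tests use 200 replicate threads
  (noise 0.02 µm, 10 half loops, median θ error < 2°), transect sets with
  ≳10⁴ expected cells (σ recovered within 5 %; per-section expected count
  ~42 keeps the λ² bias near 2 %), and 10⁴ sections for count-mean checks.
  The whole suite runs in a few seconds.

## Known limitations

* The pipeline reports, but cannot reconcile, two printed inconsistencies:
  the ejected-volume discrepancy (9.37 vs 7.25 mm³ above), and the fact
  that ~3.15 cm² of skin at σ_T ≈ 95.5 cm/mm² stores ~300 m of thread, not
  the ~2736 m a single gland ejects.
* No continuous helix fitting (least-squares helix regression) — analysis
  is deliberately restricted to the landmark arithmetic used to produce the
  measurements it mirrors.
* No image processing: landmarks and counts are inputs, not outputs.
* No rheology, mucin swelling kinetics, or thread unraveling dynamics.
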