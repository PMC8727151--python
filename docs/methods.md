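# Methods

## Model and assumptions

The reinforcement model treats each root crossing the shear plane of a
direct-shear specimen as an independent, linear-elastic fibre, initially
perpendicular to the shear zone. Its assumptions, inherited from the
classical fibre treatment, are: roots never break, never pull out (the
bond stress τ′ can always be transferred over sufficient embedded
length), and deform into an idealised tri-linear shape — straight and
undisplaced outside the zone, a straight inclined segment across it.
Per root, at displacement u and local zone thickness Z:

- inclination β = arctan(u / Z);
- bond factor k = (4 τ′ Z E / D)^0.5 (a stress; τ′ in kPa, E converted
  MPa → kPa, Z/D dimensionless);
- added resistance ΔS_i = a_r,i · k · (sec β − 1)^0.5
  (sin β + cos β · tan φ′), additive over roots and exactly linear in the
  per-root area ratio a_r,i;
- extension Δl = Z (sec β − 1), axial stress σ = (Δl / l) E with l the
  stressed length l = k (sec β − 1)^0.5 D / (2 τ′).

Total stress is assembled as fallow baseline plus ΔS. The baseline is
supplied as data — a measured fallow curve or a fitted hyperbola
S = S_ult·u/(u_ref + u) tabulated to a piecewise-linear map — and its
source is recorded in the prediction metadata, since the model itself
says nothing about the unrooted soil.

Two shear-zone treatments extend the constant-thickness idealisation:

- **Positional**: thickness interpolates linearly from Z_max at the tube
  axis to Z_min (the physical gap between the tube halves, 2 mm in the
  reference geometry) at the sidewall. Z_max is taken from a thickness
  map when one is available.
- **Growth**: thickness scales with a piecewise-linear factor f(u):
  f(0) = 0, f(u_step3) = 0.8, f(u_final) = 1.0, clamped beyond. β is
  evaluated pointwise at the current grown thickness. Because f(0) = 0
  would make β singular, the grown thickness is floored at Z_min — the
  tube gap exists at every displacement, so the floor is physical, not a
  numerical fudge.

### A non-obvious property of the reinforcement equation

ΔS is *not* globally decreasing in Z. For u/Z ≳ 6 (β ≳ 80°) the friction
term cos β · tan φ′ dies off while k ∝ √Z keeps growing, and ΔS(Z)
develops an interior maximum: at u = 20 mm, ΔS(Z = 4 mm) exceeds
ΔS(Z = 2 mm) for every τ′ (the ordering is τ′-independent because
ΔS ∝ √τ′ uniformly). The monotonicity tests therefore assert the
decrease on the moderate-inclination range u/Z ≤ 5 and the reversal is
accepted as model behaviour, not suppressed. τ′-monotonicity holds
everywhere and is asserted on the full sweep grid.

### Numerical choices

- sec β − 1 is evaluated as 2 sin²(β/2) / cos β. The naive 1/cos β − 1
  cancels catastrophically at small β (four significant digits lost at
  β ≈ 3·10⁻⁶) and broke the small-angle limit ΔS → a_r k (β²/2)^0.5
  (β + tan φ′) before the rewrite.
- σ is defined as 0 at u = 0, where Δl and l vanish together.
- Angles: β in radians internally; φ′ accepted in degrees at the API
  surface and converted once. All file I/O uses mm / kPa / MPa / degrees.

## Shear-zone thickness estimation

Each (x, y) column of a displacement field yields a profile of
x-displacement vs depth. The estimator fits the continuous tri-linear
model (plateau u_below for z ≤ z_lower, plateau u_above for z ≥ z_upper,
linear ramp between, continuity enforced at both knees) by least squares
and reports thickness = z_upper − z_lower.

Solver: a deterministic two-stage scheme. Stage one searches all knee
pairs on the profile's own z-levels; for each candidate the plateaus are
a 2-parameter linear least-squares problem solved in closed form, so the
search is exhaustive and global. Ties in residual break toward the
smallest thickness. Stage two refines the knees continuously with a
bounded trust-region least-squares start from the best candidate (the
residual is continuous and piecewise smooth in the knees, so the refiner
converges to the continuous optimum; recovery of noiseless generator
profiles is exact to < 10⁻⁶ mm even when the true knees fall between grid
levels). On very fine grids the candidate lattice is strided automatically
to bound memory; refinement restores sub-stride resolution. No randomness
enters anywhere, so maps are bit-reproducible.

Quality flags (`ok = False`) rather than exceptions mark columns with:
fewer than 6 valid nodes, a constant profile, plateau separation below
3× the configured noise sigma (an unresolvable band), or a knee pinned to
the profile boundary. One bad column never aborts a map. The configured
noise sigma should be the per-correlation-step displacement noise times
the number of accumulated steps, because profiles are cumulative
displacement relative to the undeformed state and successive-scan
correlation accumulates noise linearly.

Whether the plateaus should be free constants or the fit should allow
jumps at the knees was genuinely open; continuity at both knees and
zero-strain plateaus ("vertical lines" in a depth-displacement plot) were
chosen as the physically meaningful reading and are enforced exactly.

## Synthetic data

The generator emulates the structure — not the pixel-level realism — of
volume-correlation output from an in-scanner direct shear test:

- **Field**: lower half translated by the step's cumulative displacement,
  upper half fixed, transition across a band of local thickness
  Z(x, y) = max(Z_min + (Z_max − Z_min)(1 − 2r/D_tube) + Σ Gaussian root
  bumps, Z_min) — the double-cone observed in sheared columns. Ramp shape
  is tri-linear (exactly recoverable) or tanh ("smooth", emulating root
  bending); the tanh width is calibrated once, numerically, so its
  tri-linear best fit returns the requested thickness on a well-sampled
  profile. Truncated plateaus bias the smooth-ramp estimate low by up to
  ~1 mm, which the tests treat as expected. Noise is i.i.d. Gaussian per
  displacement component, σ = (per-step σ) × step index; spatial noise
  correlation is out of scope. Defaults: 80 mm window, 0.37 mm pitch,
  103 mm tube, 2→30 mm band, 5.4 µm per-step noise.
- **Root maps**: lognormal diameters truncated to [0.1, 4] mm (a few
  coarse roots, many fine ones), positions area-uniform with 60% of the
  probability mass within 20 mm of the sidewall (pot-grown systems
  deflect roots outward). In draw-until-RAR mode the final root's
  diameter is resized so the achieved area ratio equals the target
  exactly, which keeps RAR accounting exact at the cost of one
  off-distribution diameter.
- **Stress records**: the forward model plus i.i.d. Gaussian stress
  noise.
- **Root paths**: the tri-linear deformed shape, or a variant whose
  knees are replaced by circular arcs tangent to both limbs — strictly
  shorter, so the idealised extension Z(sec β − 1) upper-bounds the
  measured one. Bend radii comparable to the zone thickness put the
  overshoot in the 10–30% range.

Everything is deterministic per seed. What passing these tests shows:
the estimator and the fitting loop are correct against known ground
truth at realistic noise levels. What they do not show: behaviour under
spatially correlated correlation error, partial decorrelation near
moving boundaries, real root-architecture geometry, or soil
heterogeneity (peds) — all absent from the generator.

## Back-analysis of τ′

τ′ is identified from a record either by solving
total(u_target; τ′) = S_measured(u_target) with bracketed scalar
root-finding on τ′ ∈ [0.01, 50] kPa (total stress is strictly increasing
in τ′ at fixed displacement, so the root is unique; the default target is
the record's final displacement) or by bounded scalar least squares over
the full curve. The model is evaluated directly on the record's
displacement grid — equivalent to interpolating the record onto a model
grid for a pointwise model, without the extra interpolation error.
Joint (τ′, Z_max) fitting is deliberately not offered as a default path:
from a single curve the pair is weakly identified, and Z_max is better
fixed from a thickness map. Fallow records raise (τ′ unidentifiable).

Assumption diagnostics report, per root at peak load, σ as a fraction of
tensile strength (flag above 0.8) and stressed length against available
root length. Missing strength/length inputs leave fractions as NaN and
the summary booleans as None — unavailable, never silently zero.

## Parameters that matter

| parameter | units | default | rationale |
|---|---|---|---|
| Z_min | mm | 2.0 | tube-gap clearance; hard floor on thickness |
| Z_max | mm | 30.0 | upper band-thickness bound from displacement maps |
| D_tube | mm | 103 | specimen tube inner diameter |
| φ′ | deg | 36 | soil internal friction angle |
| E (willow / gorse) | MPa | 200 / 500 | species-level root stiffness |
| τ′ | kPa | fitted (≈1.25) | interface bond + anchorage; the one fitted parameter |
| growth (u_step3, u_final, f_step3) | mm, mm, – | per specimen schedule, 0.8 | band reaches 80% of peak by step 3, 100% by the final step |
| grid pitch | mm | 0.37 | 32-voxel subsets at 46 µm voxels, 75% overlap |
| per-step noise σ | mm | 0.0054 | correlation displacement noise per step |
| plateau SNR flag | – | 3 | band unresolvable below 3σ plateau separation |

## Problem sizes

Test and pipeline fixtures use reduced windows (24–42 mm at 0.9–1.8 mm
pitch, ~10³ columns) rather than the instrument's full 80 mm / 0.37 mm
grid (~47 000 columns): the estimator is resolution-agnostic, and the
reduced sizes exercise every code path while keeping the default suite
fast. Monte-Carlo suites use 50–100 seeds.

## Known limitations

- Root breakage and pull-out are diagnosed, not modelled; predictions
  beyond the flagged regime overstate reinforcement.
- The stressed-length closed form, evaluated with dimensionally
  consistent mm/kPa inputs, yields lengths of order 10²–10³ mm for
  realistic parameters; it is reported as computed and the pull-out flag
  simply compares it to whatever available length the user supplies.
- The growth schedule is a two-segment idealisation of measured band
  growth; it is specimen-schedule-specific, not a constitutive law.
- The smooth-ramp generator biases thickness low when the field window
  leaves little plateau on either side of the band.
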