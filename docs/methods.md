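# Methods

## System and model

The package models a millifluidic device used to study how microscale
advection alters microbial growth inside a gelatinous microenvironment: a
3 mm agarose disc seeded homogeneously with aerobic bacteria sits in an
8 mm circular flow chamber connected to 5 mm wide inlet/outlet
connectors. A straight channel (a "macropore") of width `w` (200–600 µm)
bisects the disc at an angle `θ` (0–90°) to the bulk-flow axis. The model
is 2-D plan-view; the 1 mm device height never enters the equations.

Three coupled pieces:

1. **Steady Stokes flow.** Creeping flow (Re ≈ 10⁻³) with no-slip on all
   walls and on the disc surfaces, a plug velocity `U` on the inlet face
   and a do-nothing outlet. The gel is impermeable to flow (matrix
   permeation contributes ~10⁻⁷ % of the collection efficiency and is
   neglected). Because the problem is linear in `U`, normalised channel
   summaries are velocity-invariant.

2. **Oxygen transport.** `∂C/∂t = ∇·(D∇C) − u·∇C − v_ox`, with
   `D = 1.0×10⁻⁹ m² s⁻¹` in both fluid and gel, `u = 0` inside the gel,
   `C = C_sat = 0.258 mol m⁻³` on the inlet and on the gas-permeable
   chamber walls, and purely advective outflow (zero diffusive flux) at
   the outlet. Initial condition: saturation everywhere.

3. **Monod growth with a carrying capacity.** Immobilised cells
   (`B`, cells m⁻³) grow as
   `dB/dt = µ_max · C/(K_ox+C) · (1 − B/B_max) · B` and consume oxygen as
   `v_ox = Y · dB/dt`. Defaults: `µ_max = 3.85×10⁻⁴ s⁻¹` (30 min doubling
   time), `K_ox = 6.3×10⁻³ mol m⁻³`, `B_0 = 10¹¹ cells m⁻³`
   (10⁵ cells mL⁻¹), `Y = 2.29×10⁻¹⁷ mol cell⁻¹`,
   `B_max = 10¹⁸ cells m⁻³` (1 µm⁻³, space filling). Cells neither
   diffuse nor advect; the horizon is 24 h.

As printed, the transport equation would make growth a *source* of
oxygen; consumption is of course a sink, and the sign is fixed
accordingly.

## The carrying capacity cannot bind on this horizon

This is the one place where the implementation deviates from the face
value of the model above, and the deviation is forced by the system's own
observables. With a strictly growth-linked sink and `B_max = 10¹⁸ m⁻³`,
the disc rim reaches the cap after ~23 doublings (~12 h), uptake there
shuts off, and oxygen then floods back: by 24 h a solid disc is ~60%
oxic and a channel is oxygen-filled along its entire length. We verified
this against an independent fine-grid 1-D radial integration (BDF,
rtol 10⁻⁶) — it is a property of the equations, not of our solver. It is
also flatly incompatible with how these discs actually behave at 24 h:
persistent anoxia over ~90% of the disc, diffusion-limited channel
penetration of a few hundred micrometres, and oxic-area plateaus of a few
percent.

Those observables *are* reproduced when the oxygen sink does not saturate
within 24 h. The reference configuration (`reference_params()`) therefore
keeps the growth-linked sink but treats the space-filling cap as
non-binding on this horizon (`B_max = 10²⁴ m⁻³`); a cells-per-mL versus
cells-per-m³ slip in a twin implementation would produce exactly this
behaviour. Two alternatives were evaluated and kept available:

* `GrowthParams()` — the literal parameter set (cap at 10¹⁸), for
  studying the capacity-limited regime;
* `maintenance_uptake=True` — uptake proportional to total Monod-limited
  activity (`v_ox = Y µ_max C/(K+C) B`), which sustains consumption at
  the cap. It reproduces the solid-disc anoxia but over-predicts channel
  penetration (the crowded gel stops adding absorbers, so fronts are
  softer).

All reported numbers use the reference configuration.

## Numerics

**Meshing.** Boundary loops are sampled at `h_boundary` (20 µm reference,
40 µm test scale); interior points come from deterministically jittered
hexagonal grids, one per size band, with the local target edge length
grading linearly (rate 0.55) up to `h_max = 1 mm`; a Delaunay
triangulation is filtered to the domain and classified fluid/gel by
centroid. The gel is meshed conformally with the fluid. Region areas
converge to the closed-form circle-minus-slab values (<0.05% at test
scale).

**Stokes.** Taylor–Hood (P2 velocity / P1 pressure), exact edge-midpoint
quadrature, sparse LU. An equal-order stabilised pair was tried first and
rejected: its local mass-conservation error (~2–3% across cross-
sections) exceeded the 1% budget; Taylor–Hood holds every cross-section
flux to <0.5%. Inlet plug values are rescaled by `W/(W − Σℓ/6)` so the
discrete inlet influx equals `U·W` exactly despite the no-slip corners.

**Transport/growth stepping.** Implicit Euler on advection–diffusion with
streamline-upwind (SUPG-type) stabilisation on fluid elements (element
Péclet numbers reach ~10² on coarse far-field cells at 1150 µm s⁻¹). The
consumption front at a crowded gel boundary is micrometres thick —
unresolvable at any practical mesh — so the sink must be visible to the
transport operator: it is linearised in C (Patankar form,
`σ = Y µ_max B_eff/(K_ox + Cⁿ)`) and added to the system diagonal, which
preserves positivity and lets the anoxic core actually block diffusion.
(An operator-split scheme with a sink-free transport step was tried
first and leaks √(D·dt) ≈ 110 µm of oxygen past the front per step,
eventually saturating the whole disc.) The LU factorisation is refreshed
only when a node's per-step absorption number drifts >10%, at most every
10 steps (a few hundred refactorisations per run), and the absorption
number is capped at 10⁴ — beyond that a node already removes all of its
oxygen each step. Biomass then advances by the exact logistic map at the
oxygen-limited rate, with the oxygen ledger corrected so that exactly
`Y·ΔB` is consumed; the oxygen removed can never exceed the nodal
control volume's content. Oxygen is clamped to `[0, C_sat]` with event
counting (clamp magnitudes are at round-off level).

At gel-interface nodes the sink is weighted by the gel-side share of the
lumped nodal mass, so disc-integrated consumption is exact.

**Fluxes.** Oxygen influx into the gel per boundary tag (channel walls
vs. disc arcs) uses consistent (residual-based) flux extraction on the
gel subdomain; nodes at chord/arc junctions split half-and-half. The
channel-flux share is reported instantaneously at 24 h; the Sherwood
flux ratio uses the time-integrated fluxes of a with-flow and a no-flow
solid-disc pair. The global oxygen balance check integrates an
independent, gradient-based boundary influx and closes within 2% for
diffusive supply.

**Conventions.** The channel Péclet number uses `L = w` and the *mean*
channel velocity (net mid-chord flux / width); back-checking both
candidate definitions against the known triplet for
(200 µm, 75°, 1150 µm s⁻¹), (400 µm, 75°, 115 µm s⁻¹) and
(600 µm, 45°, 11.5 µm s⁻¹) puts the mean-velocity values ~10–20% low and
the peak-velocity values ~20–30% high; the mean is kept (the
documented convention) and `channel_peak_velocity` is exposed as a
diagnostic. Penetration depth is the first centreline crossing below
1 µmol L⁻¹ measured from the *mouth plane* — the plane through the
windward chord-face corners, half a chord from the centre — and the
channel length is correspondingly the chord length (2.97–2.98 mm for
these widths); "full penetration" is reported as that length. The
oxic-area plateaus are means of (100 − anoxic%) over sweep rows with
channel Pe below/above 1.

**Problem sizes.** The documented test scale (40 µm boundary mesh →
~3.6k nodes, 12 s step → 7200 steps) runs one 24 h case in ~5–10 s and
is the configuration behind every reported number; the reference scale
(20 µm, 2.4 s) is available via `--scale full`. Halving the reference
step changes 24 h biomass by <0.2%.

## Synthetic micrographs

The generator emulates 16-bit brightfield tile scans: a brighter gel disc
on a dark chamber background, colonies as steep-edged super-Gaussian
blobs (exponent 16, so the measured area is threshold-insensitive),
additive Gaussian background noise plus signal-dependent shot noise.
Colony mean area decays exponentially with distance from the nearest
nutrient-exposed boundary (decay length 300 µm, ~40 colonies mm⁻²,
lognormal scatter σ=0.25); channel walls count as exposed only when the
emulated angle supports through-flow. An entrance-skew factor emulates
advective enhancement at the windward mouth, and anomalous colonies of
known excess area can be implanted. Default pixel size is 2.6 µm px⁻¹
(a 4× binning of the microscope's 0.65 µm px⁻¹) so a disc fits in a
~1400 px frame.

What the generator does **not** emulate: tile-stitching seams, uneven
illumination, focal-plane blur across the 1 mm depth, overlapping or
merging colonies, and real colony texture. Passing the imaging suite
therefore demonstrates correctness of the morphology/segmentation logic
against known truth, not robustness to every artefact of real microscope
data.

The biomass-increase estimator fits the solid-disc size-versus-depth
trend (150 µm bins), flags semi-disc colonies above a stretched per-depth
quantile envelope (q=0.995, margin 1.15 — an outlier rule, not a fixed
percentile, so ordinary scatter is almost never flagged), and attributes
their excess over the trend to advective supply. Disc classification
thresholds (circularity ≥ 0.93, elongation shape factor ≤ 1.10) were
calibrated on the synthetic fixtures and are configurable.

## Known limitations

* One chamber unit is modelled, not the five-disc train of the physical
  device; in the train, upstream discs partially deplete the stream,
  which plausibly explains why simulated penetration depths here run
  ~15–25% deeper than the reference values.
* The Sherwood number is a confined-chamber flux ratio, not a free-stream
  correlation; it tracks the correlation value at the lowest velocity
  (2.7 vs 2.2) but grows faster with velocity.
* The oxic rim at 24 h is one element thick at the test resolution, so
  the oxic-area fraction there carries a resolution dependence of a few
  percentage points.
* 2-D plan view: vertical oxygen supply through the device top/bottom is
  absent (the real top/bottom are glass, so this is mild).
* The continuum biomass field ignores colony discreteness; the
  synthetic-micrograph pathway exists precisely because the continuum
  field and the colony statistics are linked only qualitatively.
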