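# Methods

`evapollps` models how evaporation drives segregative liquid–liquid phase
separation (LLPS) inside a sessile droplet of a PEG/dextran aqueous two-phase
system (ATPS), and how the resulting dextran-rich compartments enhance a
ribozyme cleavage reaction. Four physical models are chained together; each is
described below with its assumptions, parameters and numerical choices.

## 1. Diffusion-limited evaporation of a spherical-cap droplet

A small sessile droplet is a spherical cap set by its contact radius `a` and
contact angle `θ`. Evaporation is limited by diffusion of water vapor from the
liquid–air interface into the surroundings, giving the total mass-loss rate

    dM/dt = −π a D (n_s − n_∞) f(θ),

with `D` the vapor diffusivity (default 2.5e-5 m²/s), `n_s` the saturated
vapor concentration (default 2.3e-2 kg/m³ near 22 °C) and `n_∞ = RH·n_s`. The
contact-angle factor `f(θ)` has an integral representation evaluated by
adaptive quadrature. The integrand is rewritten in an overflow-safe
exponential form (it decays like `exp(−2(π−θ)τ)`, so the integral is truncated
at `τ = 20/(π−θ)` where it is below ~1e-16 of its `τ→0` limit `(π−θ)/π`,
which is substituted analytically to avoid 0/0). Two closed forms anchor the
implementation: `f(π/2) = 2` (hemisphere) and `f(θ→0) = 4/π` (flat disk).

The local evaporation flux diverges towards a pinned contact line. We adopt
the asymptotic edge scaling `J(r) ∝ (R0 − r)^(−1/2)` over the whole footprint
and fix the prefactor so the disk integral of `J` reproduces the total rate;
the annulus integrals of this integrable singularity are evaluated in closed
form. The approximation is crudest at the droplet center, but every
downstream use is confined to the edge annulus where the scaling is exact
asymptotically.

Drying is integrated in **pinned mode**: the footprint stays fixed and each
time step removes `(dM/dt)·Δt` of water from the cap volume, after which the
cap relation is re-inverted for the new contact angle (bracketed root-find;
the relation is monotone in θ). Integration truncates at a configurable
contact-angle floor (default 5°). The default world — a 0.5 µL droplet at 45°
and 60 % RH — has a ~0.90 mm contact radius, loses ~1 µg/s initially and
passes through the experimentally relevant 45°→25° band within a few minutes.

Not modeled: evaporative cooling, substrate conduction, thermal Marangoni
effects, contact-line depinning, θ ≥ 90°.

## 2. Phase plane and the kinetic pathway of LLPS

Compositions live in the `(w_dex, w_peg)` mass-fraction plane. The binodal is
represented by the standard four-parameter Merchuk-type empirical curve

    w_peg = a·exp(b·√w_dex + c·w_dex + d·w_dex³),

fitted by linear least squares in log space (the form is log-linear in its
coefficients, and multiplicative measurement noise is the natural error model
there). A monotone tabulated alternative (PCHIP) is available. Compositions
exactly on the curve count as single-phase (strict inequality above the curve
means two-phase).

Tie lines use a constant slope `dw_peg/dw_dex` supplied in configuration
(default −0.55); the line through a two-phase composition is intersected with
the binodal by bracketed root-finding on a scan grid, taking on each side the
intersection nearest the bulk point. The lever rule converts distances along
the tie line into phase mass fractions: the dextran-rich : PEG-rich mass
ratio equals the ratio of distances from the bulk composition to the PEG-rich
and dextran-rich endpoints. Tie-line length (TLL), the Euclidean distance
between endpoints, measures quench depth.

The **kinetic pathway** tracks the composition of the thin edge annulus
(width 0.05·R0) over 5 s time steps: the analytic annulus flux integral gives
the water mass evaporated per step; dividing by the current annulus liquid
mass gives the water-loss fraction; removing that water scales both polymer
fractions by `1/(1−fraction)`, preserving their ratio exactly. The annulus is
treated as closed for polymers (its liquid mass decreases only by the
evaporated water), which conserves annulus polymer mass identically. Under
default conditions the annulus loses ~29 % of its mass per step and therefore
dries out after ~3–4 steps — consistent with the model's intended two-step
(initial → first split → second split) depth; deeper requests raise a
dry-out error naming the step (or truncate, for callers that only need the
first split). The whole-droplet geometry advances in pinned mode alongside,
so later steps see the flatter, slower-evaporating cap.

**Regime classification.** Two morphological regimes are distinguished: in
regime 1 the dextran-rich and PEG-rich phases form with comparable mass
fractions, so the dextran-rich droplets coalesce into lobe-shaped domains; in
regime 2 the dextran-rich phase is a small minority and stays dispersed.
`classify_regime` offers (i) an *empirical* composition map — below 4 wt%
dextran the dispersed regime requires PEG more than twice dextran; at or
above 4 wt% dextran, PEG above the ~7 wt% critical value — and (ii) a
*lever-ratio* mode that runs the pathway and thresholds the first split's
dextran:PEG mass ratio at 0.5 (a tunable calibrated so near-even splits
classify as regime 1 and order-0.1 splits as regime 2). On the packaged
synthetic phase diagram the 5/10 wt% composition gives a first-split ratio of
0.85 (regime 1) and 9/4 wt% gives 0.13 (regime 2).

## 3. Flow scaling: capillary vs Marangoni

Three dimensionless/scaling quantities summarize the hydrodynamics:

* **Bond number** `Bo = ρgR²/γ` ≈ 0.13 for the default droplet (ρ = 1030
  kg/m³, γ = 64 mN/m): surface tension controls the shape.
* **Capillary (coffee-ring) velocity**: depth-averaged outward radial flow
  from liquid mass conservation under the edge-peaked flux,
  `u(r) = (1/ρ r h)·∫₀ʳ [J − ρ ∂h/∂t] r′ dr′`, with `∂h/∂t` the pinned-cap
  thinning rate (analytic `∂h/∂θ` times `dθ/dt`). Evaluated at 0.95·R0
  (default), u ≈ 7 µm/s — the same order as the ~6 µm/s phase-separation
  front speed.
* **Marangoni scale**: in the lubrication approximation a surface-tension
  difference Δγ acting over length L drives `u_M = ½·Δγ·h/(µL)` (the O(1)
  coefficient is exposed in configuration).

`required_delta_gamma` answers "how large a Δγ does it take for Marangoni
flow to rival capillarity?" Two balances are provided. The default
(`balance="pressure"`) balances the Marangoni stress `Δγ/L` against the
capillary-pressure-driven film stress, `Δγ = ½·h·ΔP` with
`ΔP = 2γ sinθ / a` the spherical-cap Laplace pressure: ~2.2 mN/m for the
default droplet. The alternative (`balance="velocity"`) inverts the velocity
scales exactly (`u_M = u_cap`), giving ~0.003 mN/m — small because the
depth-averaged evaporative outflow is slow. The pressure balance is the one
that sets the millinewton-per-metre magnitude relevant to reversing the
coffee-ring flow; the velocity balance is kept because it is the exact
round-trip inverse of `marangoni_velocity_scale`. Whether a given Δγ is
*achievable* is judged from a linear surface-tension model γ(w_peg)
(defaults: 64 mN/m at 5 wt% PEG, slope −70 mN/m per unit mass fraction; PEG
is surface active): the jump between the initial mixture (5 wt% PEG) and the
nearly PEG-free dextran-rich phase affords ~3.5 mN/m, exceeding the ~2 mN/m
requirement.

**Front kinematics.** The phase-separation front radius `R2(t)` retreats
linearly (flow-driven, `L ∝ t`, unlike diffusive `t^1/2` spreading), so
`psf_linear_fit` is an ordinary least-squares line. `detect_front` locates
the front on a radial intensity profile: moving-average smoothing, candidate
at the outermost maximum-gradient sample, then (default) refinement to the
interpolated crossing of the midpoint between the two plateau levels flanking
the candidate. The plateau levels are medians over *fixed-length* windows so
that any residual localization bias is independent of where the front sits
and cancels from the linear fit. Two gates return a no-front signal instead
of a spurious location: the smoothed amplitude must exceed 3× the point-noise
scale (estimated from raw first differences), and the plateau jump must
explain ≥ 70 % of the amplitude (a featureless linear ramp scores exactly
50 %). The raw max-gradient location is available as `mode="gradient"`; the
refined threshold mode is the default because at realistic noise (5 %
multiplicative) and front width (20 µm on a 200-sample profile) it localizes
to ≲1.5 sample spacings where the raw gradient peak wanders by ~5.

## 4. Compartmentalized ribozyme cleavage (reaction–diffusion)

A hammerhead ribozyme E (43 nt) cleaves substrate S into two short products
(lumped as P). Binding and cleavage are fast, so kinetics reduce to the
single Michaelis–Menten step S →(E) P. Inside a spherical domain of radius
R_d = 10 µm, S and P diffuse with equal diffusivity D while E is uniform
(its much larger size makes its diffusion negligible):

    ∂s/∂t = D∇²s − k_cat·e·s/(K_M + s),
    ∂p/∂t = D∇²p + k_cat·e·s/(K_M + s).

Length-dependent RNA partitioning enters only through boundary data. In the
`dextran_compartment` scenario the ribozyme is enriched (`e = K_E·e_bulk`),
the substrate boundary value is pinned at `K_S·s_bulk` (constant supply), and
the products see a perfect sink (`p = 0`: short chains escape freely). The
`water_droplet` scenario is identical with no enrichment. A `closed`
(reflecting) configuration exists for verification only.

Default parameters (configuration defaults, literature-typical, not fitted):
k_cat = 0.017 s⁻¹ (~1 min⁻¹), K_M = 0.1 µM, D = 1e-10 m²/s, e_bulk = 10 nM,
s_bulk = 0.1 µM, K_E = 50, K_S = 5, K_P = 1 (ordering K_E ≥ K_S ≥ K_P is
enforced — partitioning strengthens with chain length).

**Numerics.** Method of lines on a uniform radial grid (default 200 nodes)
with a conservative finite-volume discretization of the spherical Laplacian:
cells are node-centered with interfaces at midpoints, the center cell is a
half-sphere (regularity at r = 0 is automatic in flux form), and with
reflecting boundaries the scheme conserves total moles exactly, so the
closed-configuration conservation check is limited only by the stiff BDF
integrator's tolerance (default rtol 1e-8). The analytic sparse Jacobian is
supplied. The cumulative converted substrate is integrated as an extra,
nondimensionalized ODE state, so productivities are solver-accurate rather
than post-hoc quadrature. Verified against (i) the implicit integrated
Michaelis–Menten closed form `K_M ln(s0/s) + (s0−s) = k_cat e t` in the
well-mixed (large-D, closed) limit to better than 1e-6 relative, and (ii)
grid self-convergence (200→400 nodes moves the productivity plateau by
< 0.5 %).

**Productivity.** `m_p(t′)` is the cumulative converted substrate normalized
by `V·s_bulk`, against diffusive time `t′ = Dt/R_d²`. With a constant supply
at the boundary the cumulative curve grows linearly once the fields are
steady, so the "plateau" is the final value with a convergence flag (tail
slope < 5 % of the mean slope), and `time_to_plateau` is the first `t′`
reaching 95 % of it. Consequence worth knowing: under this normalization the
time-to-plateau of *both* scenarios lands near 0.95·t_end, so their ratio is
≈ 1 and carries no information — the informative comparison surfaces are the
plateau (conversion) ratio, which is > 1 whenever the compartment is enriched
and grows monotonically with K_E, and the exact symmetry
`K_E = K_S = K_P = 1 ⇒ both ratios = 1`.

## What the synthetic generators do and do not establish

The generators emulate the three external inputs with known ground truth:
a coexistence table (exact Merchuk curve + multiplicative noise on w_peg +
exact tie-line endpoint pairs), droplet mass vs time (pinned-mode trajectory
+ additive weighing noise), and radial intensity profiles (sigmoidal front at
`R2(t) = R0 − vt`, default v = 6 µm/s, multiplicative noise). Green recovery
tests establish that the estimators are unbiased at the stated noise levels
(means over ≥100 seeded replicates within 3 standard errors of truth) — they
do not establish that the synthetic phase diagram matches any measured
PEG/dextran system, that real fronts are sigmoidal, or that real weighing
noise is Gaussian. The synthetic binodal's coefficients
(a, b, c, d) = (0.35, −5.8, 2.0, −200.0) and tie slope −0.55 were frozen once
to place the two canonical starting compositions (5/10 and 9/4 wt%
PEG/dextran) below the curve with first-step crossings under default
evaporation; they are package fixtures, not measurements.

## Known limitations

* The global `(R0−r)^(−1/2)` flux profile is an edge asymptote; center fluxes
  are approximate (unused downstream).
* The closed-annulus pathway ignores replenishment by the capillary inflow,
  so its concentration rate is an upper bound and the annulus dries within a
  few steps.
* Tie-line slope is constant per configuration; real ATPS tie lines rotate
  slightly with quench depth.
* The two Marangoni balances bracket, not resolve, the exact lubrication
  constant; the pressure-balance coefficient (default ½) is exposed.
* The reaction–diffusion model has a stationary domain with constant
  substrate supply and free product escape: no coupling to droplet
  evaporation, compartment growth, coalescence or RNase degradation, and the
  enrichment of productivity it predicts is accordingly an upper bound.
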