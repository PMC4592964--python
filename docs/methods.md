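# Methods

## Scope and coordinate conventions

`rolltank` models the interior hydrodynamics of rolling-tank incubators —
horizontal cylinders of inner radius R = 4.5 cm rotating slowly about
their axis — and the transport of spherical aggregate-like particles
through them. Three designs are covered: a sealed (closed) tank, a
flow-through tank whose inlet/outlet holes sit in two co-rotating wall
channels 90° apart (six holes each, "design 1"), and a flow-through tank
fed through 20 stationary peripheral holes at each end cap ("design 2").

Coordinates are fixed project-wide: origin at the inlet-end interior face
on the axis, z along the axis, y opposite gravity, x completing a
right-handed frame. All internal computation is SI; configuration files
use bench units (cm, rpm, ml/min, mm) converted once at the boundary.

The wetted interior length defaults to L = 27 cm. The devices are 30 cm
long overall, but particles are conventionally released at the mid-plane
z = 13.5 cm, which identifies 27 cm as the interior span between the end
faces; the value is configurable.

## Flow fields

All fields are reduced-order, evaluated in the lab frame, and exactly or
numerically divergence-free. The full no-slip boundary-value problem
(pressure and velocity) is deliberately out of scope; a gridded import
path (`GriddedField`, trilinear interpolation of `x y z u v w` tables)
admits externally computed solutions when wall-layer fidelity matters.

**Closed tank.** The long-time interior state of a slowly rotating sealed
cylinder is solid-body rotation, v = (−ωy, ωx, 0). At ω = 1.8 rpm the
Ekman/spin-up transient is not modelled.

**Design 2.** Solid-body rotation plus an axial through-flow profile. The
true profile between the peripheral hole rings is unknown; the default is
plug flow u_z = Q/(πR²) (2.36 × 10⁻⁵ m/s at Q = 9 ml/min), with a
parabolic (Poiseuille) option u_z(r) = 2Q/(πR²)(1 − r²/R²). The ports are
stationary, so the field is steady in the lab frame; azimuthal and axial
components decouple, and a tracer keeps its cylindrical radius while
advancing axially at the plug speed.

**Design 1.** Three superposed parts:

1. solid-body rotation;
2. a free-space monopole q_i/(4π) · (x − x_i(t))/|x − x_i(t)|³ per wall
   hole, with strengths ±Q/6 and positions rotating with the cylinder
   (the field is unsteady in the lab frame and satisfies the
   frame-consistency identity v(x, t) = R(ωt) v(R(−ωt) x, 0));
3. an axisymmetric through-flow correction.

The correction exists because free-space monopoles do not see the wall: a
source on the wall radius radiates most of its volume flux radially
through the (absent) wall, and the bare monopole superposition carries
only ~15% of Q across the mid cross-section, which would violate the
constant-flow-rate boundary contract the devices are operated under. The
correction has the stream-function form

    u_z = f(z)/(πR²),    u_r = −(r/2) f′(z)/(πR²),

which is exactly divergence-free for any differentiable f. f is built at
field construction: the target cumulative flux profile (the sum of port
strengths below z, smoothed over a 5 mm ramp) minus the monopole disc
flux, computed by midpoint polar quadrature on an 81-point z grid and
interpolated with a monotone (PCHIP) spline. Between the inlet and outlet
bands the total cross-section flux then equals Q to quadrature error
(measured < 0.1% at the mid plane). The radial part of the correction is
confined to the port bands, mirroring where water actually enters and
leaves. Wall impermeability is still violated within roughly one
port-spacing of a hole; default seeding regions keep particles ≥ 5 mm
away. Queries within 2 mm of a hole raise a singularity error instead of
returning unbounded velocities.

## Particle models

Spheres of diameter d (default 1 mm) and density ρ_p (default
1005 kg/m³ — aggregate excess density 5 kg/m³ over water) in a fluid of
density ρ_f = 1000 kg/m³ and kinematic viscosity ν = 10⁻⁶ m²/s.

* **massless** — dx/dt = u(x, t): streamlines of steady fields, pathlines
  otherwise.
* **overdamped** — dx/dt = u + w_s(−ŷ): valid when τ_p ω ≪ 1 (here
  τ_p ω ≈ 0.01).
* **inertial** — dv/dt = f(Re_p)(u − v)/τ_p + (1 − β) g(−ŷ) + β Du/Dt,
  with β = ρ_f/ρ_p and τ_p = ρ_p d²/(18μ) ≈ 0.056 s.

The force budget is drag, buoyancy-corrected gravity and (by default) the
fluid pressure-gradient force β Du/Dt. The last term matters more than
its size suggests: a nearly neutrally buoyant sphere on a circular orbit
must be accelerated centripetally, and in a rotating tank that
acceleration is supplied almost entirely by the fluid pressure gradient.
Without the term the entire centripetal force must come from drag slip,
and the outward drift of the orbit radius is τ_p ω² r — about
1.3 × 10⁻⁵ m/s at the reference point, which would spiral a particle into
the wall within the 1000-s observation window. With the term the drift is
the physically expected τ_p (1 − β) ω² r ≈ 5 × 10⁻⁸ m/s: a slow,
circular approach to the wall, matching observed aggregate behaviour.
`pressure_gradient=False` recovers the drag + gravity model. Added mass,
Basset history and Saffman lift are neglected throughout (relative
corrections O(β τ_p ω) and smaller at this operating point); particle
feedback on the fluid and particle–particle coagulation are out of scope.

Du/Dt is analytic (−ω²(x, y, 0)) for the three built-in fields — for
design 1 the through-flow contribution to Du/Dt is O(ω·Q/πR²) ≈ 10⁻⁶ of
the centripetal term and is dropped — and a central-difference fallback
serves gridded fields.

**Drag law.** `stokes` (f = 1) is the default per-particle contract, but
at the reference parameters the terminal Reynolds number is
Re_p = w_s d/ν ≈ 2.7, outside the Stokes regime, so a warning suggests
`schiller_naumann` (f = 1 + 0.15 Re_p^0.687, the standard correlation up
to Re_p ≈ 800 and the default of commercial particle-tracing codes). The
Schiller–Naumann settling velocity is the fixed point of
w = w_St/(1 + 0.15 Re_p^0.687), solved by damped iteration to 1e−10
relative: 2.17 mm/s versus 2.73 mm/s for Stokes. The scenario presets use
Schiller–Naumann; the distinction is consequential, because the orbit
centre offset w_s/ω (1.15 cm vs 1.45 cm) decides whether the outermost
particles of a 2 cm mid-plane ring clear the wall.

**Integration.** Fixed-step classical RK4, chosen over adaptive schemes
for bitwise reproducibility and trivial convergence testing at desk
scale. dt defaults: 0.01 s for 30-s validation runs, 0.02 s for 1000-s
scenario runs (both well below the stability and accuracy limits;
halving dt moves 30–1000 s endpoints by < 10⁻⁴·R). Under the inertial
model a dt ≥ τ_p/2 is halved automatically with a warning. Trajectories
terminate at t_max, on wall contact (centre within one particle radius of
any wall; no restitution or sticking model), or within 3 mm of an outlet
hole (the hole diameter is not otherwise modelled). An RK stage that
leaves the domain is likewise classified as wall contact at the last
interior state.

## Validation statistics

**Axial stationarity.** Each particle's axial coordinate W_i(t) (from the
inlet-end face — the experimental analogue references a line on the
cylinder surface, which differs by a constant that cancels in deviations
but does enter the W_max normalisation) is sampled on a regular grid over
a window (default 30 samples at 1 s), scaled by the ensemble-time maximum
W_max, and reduced to std_t[w_i(t) − w_i(0)] (population std). The
reported figure is the maximum across particles, in percent; a pooled
variant is available. At the reference operating point the simulated
15-particle ensemble gives ≈ 0.16%, i.e. axial motion is a fraction of a
percent of the reference displacement over half a rotation period.

**Orbit fits.** Per-rotation-period least-squares circle fits (algebraic
Kasa initialisation refined by geometric least squares) give centre,
radius and the linear drift rate of the per-period radius. The closed
overdamped orbit centre recovers (w_s/ω, 0) and hence w_s to < 1%.

**Retention.** Ensembles are summarised by termination-status fractions
and residence-time quantiles; with through-flow the full-volume exchange
time V/Q (≈ 1.15 × 10⁴ s at 9 ml/min) is attached, which is also the
scale of the axial traverse time — two orders above the 1000-s
observation window, hence zero outlet losses there.

## Synthetic tracking loop

The frame renderer projects trajectories onto the y–z (axial analysis) or
x–y (spiral path) plane as Gaussian spots (σ = 2 px, peak 200, background
10) at 0.2 mm/px on 512×768 frames, optionally with Gaussian pixel noise.
These camera parameters are synthetic stand-ins — no real optics are
modelled — sized so the mid-tank region fills the frame. Detection
thresholds the frame, labels 8-connected components (scikit-image) and
takes intensity-weighted centroids of the above-threshold excess, which
cancels a uniform background and is sub-pixel for symmetric spots.
Linking is greedy nearest-neighbour between consecutive frames, globally
ordered by pair distance with deterministic tie-breaks and a hard
displacement gate.

The closed loop (simulate → render → detect → link → statistic)
reproduces the trajectory-based axial positions to well under half a
pixel and the stationarity statistic to under 0.05 percentage points.
This validates the pipeline, not real footage: rendered scenes are
sparse, spots are identical Gaussians, and there is no optical
distortion, depth blur or illumination drift. Greedy linking has no gap
closing and can swap identities when projected tracks cross within the
displacement gate — the closed-loop fixtures therefore stagger particles
axially, which is also the regime (well-separated slow particles) where
the experimental procedure operates. Stereo reconstruction of the third
coordinate is out of scope.

## Scenario presets and defaults

* `closed_reference`, `design1_reference`, `design2_reference` (and
  `*_streamline` tracer variants): ω = 1.8 rpm, Q = 9 ml/min (0 when
  closed), single particle released at (2 cm, 0, 13.5 cm), 1000 s at
  dt = 0.02 s.
* `bottle_effect`: design 1 at ω = 2 rpm, Q = 5 ml/min — the operating
  point used when comparing closed and flow-through incubations.
* `displacement_validation`: design 1 at the reference point, 15
  particles on the r = 2 cm mid-plane ring, 30 s at dt = 0.01 s, 1-s
  sampling — the protocol behind the headline stationarity number.

Design-1 hole stations are evenly spaced over each half-cylinder with 5%
end margins (the as-built stations are not published to this precision;
they are configurable per hole), inlet channel at angle 0, outlet at
+90°; the sign of the 90° offset is configurable since the handedness of
the as-built arrangement depends on viewing direction. Port strengths are
uniform per channel (Q/6, design 1) and per ring (Q/20, design 2).

## Known limitations

* Through-flow components do not satisfy no-slip at the wall; near-wall
  and near-port transport is qualitative. The pressure field is not
  represented at all.
* Spin-up transients, free-surface/bubble effects, thermal effects and
  turbulence are absent.
* Wall contact ends a trajectory; aggregate–wall adhesion or re-suspension
  is not modelled.
* The tracking module handles 2-D projections of sparse scenes only.
* Synthetic tests exercise the model's internal consistency and its
  analytic limits; they cannot certify the reduced-order fields against a
  full CFD solution — the gridded import path exists for that comparison.
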