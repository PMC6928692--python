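# Methods

`myoxray` connects three layers: a spatially explicit Monte Carlo model of
isometric contraction in a half sarcomere, a meridional X-ray diffraction
calculator for the actin monomer positions that the simulation produces, and
a metrology/estimation chain that inverts observed first- and second-order
actin meridional reflections into per-filament forces and muscle tension.

## Half-sarcomere model

**Geometry.** One half sarcomere from the Z-disc (z = 0) to the M-band
(z = SL/2), default sarcomere length 2.3 um.  Thin filaments carry 364
monomers at s0 = 2.73 nm axial rise (length 0.994 um), anchored at the
Z-disc.  Each half-thick filament carries 50 crowns of 3 heads at 14.3 nm
spacing and hangs from the M-band through a bare-zone segment.  The bare
zone defaults to 156.3 nm, chosen so that at SL 2.3 um the distal crown
coincides with the thin-filament tip: the thick-thin overlap then equals the
full crown span of 0.70 um (the maximum), leaving a 0.29 um I-band.  The
hexagonal lattice (each thick filament surrounded by six thin, each thin
shared by three thick, n_thin = 2 n_thick) enters through adjacency only —
meridional diffraction and axial mechanics need axial coordinates and
head-to-filament wiring, not transverse positions.  A periodic circulant
rule supplies the 6:3 wiring for any filament count; head h of crown c
targets neighbour (c + 2h) mod 6, a deterministic stand-in for azimuthal
matching that spreads the 150 heads of a filament evenly over its six
neighbours.

**Elasticity.** Filaments are extensible chains: actin segment stiffness
Ka/s0 with Ka = 0.65e5 pN (65 pN/nm per um), myosin Km/14.3 nm with
Km = 1.32e5 pN.  Attached crossbridges are linear springs of stiffness
kappa = 1.3 pN/nm.  An optional titin spring (default stiffness 0) connects
the thick-filament tip to the Z-disc.  Strain coordinate of a bound head:
x = z_crown − z_site; the post-stroke state is unstrained at x = −d
(site one stroke length d = 10.5 nm beyond the crown), so a freshly stroked
head pulls actin toward the M-band — the sign convention that makes the
I-band tension positive and the spacing plateau sit next to the Z-disc.

**Crossbridge cycle.** Three states: detached (1), weakly attached /
pre-stroke (2), post-stroke (3), with free energies (kBT units,
kBT = 3.96 pN nm at 287 K)

    G1 = 0,   G2 = dG_bind + kappa x^2/(2 kBT),
    G3 = dG_bind + dG_stroke + kappa (x+d)^2/(2 kBT),

dG_bind = −3 (binding constant ~20), dG_stroke = −15.  Rates are
Duke-style: Gaussian-weighted attachment k12 = k_bind exp(−kappa x²/2kBT)
with k_bind = 134 s⁻¹ at the reference activation level; constant
k21 = k_bind e^{dG_bind}; sigmoidal stroke rate
k23 = k23cap/(1 + e^{dG23(x)}) capped at 1000 s⁻¹; ADP release k31 = 70 s⁻¹,
strain-accelerated (with the 1 nm second stroke delta as the transition
distance) only for negatively strained post-stroke heads and capped at
1e4 s⁻¹.  Whenever a cap engages, the partner rate is recomputed from the
equilibrium constant, so detailed balance k_ij/k_ji = e^{−dG_ij} holds at
every strain — this is asserted on a dense strain grid in the tests.  The
exact strain dependences of the original multiscale platform are published
only by reference; these forms reproduce every printed constraint
(equilibrium constants, caps, transition distances) and live in one place
(`kinetics.transition_rates` mirrored by the compiled kernel) so model-form
changes are localised.

**Monte Carlo.** Fixed time step dt = 1 us (k·dt <= 0.01 for every capped
rate, validated at run start).  Per step, each head's transition is a
first-order event with probability 1 − e^{−k dt} at the rates frozen at the
step start.  The implementation draws the number of events per step from
Poisson(R_tot·dt) with R_tot the summed head rates and picks firing heads
proportionally to their rates — identical to independent per-head tests to
O((k dt)^2) ~ 1e-4 per head, and exact for a single head.  Detached heads
bind one unoccupied monomer of their target filament within a reach of 8 nm
(beyond which the Gaussian binding weight is < 1e-3 of peak), chosen with
probability proportional to k12 at the site's current offset; one head per
monomer.  Identical (config, seed) gives bit-identical event logs; the RNG
is the compiled kernel's generator seeded once per run.

**Mechanics.** Between events the isometric elastic configuration is
constant, so the spring network is re-equilibrated only when something
fires.  The solver does exact tridiagonal (Thomas) solves per filament
chain inside a block Gauss-Seidel iteration.  Because the summed crossbridge
stiffness of a filament (~75 x 1.3 ~ 100 pN/nm) is comparable to its
end-to-end stiffness, the global thin-thick force-exchange mode contracts
only geometrically per sweep; the engine therefore splits the work:

* per event, a residual-driven local front re-solves the event's chains and
  their neighbours until further changes are below 1e-4 nm;
* every 200 steps a global sweep polishes the whole network to 1e-5 nm;
* before any recorded sample or snapshot (and at the final step) the polish
  runs to the full force tolerance (default 1e-6 pN on every free node), so
  every reported configuration satisfies the stated force balance.

Between polishes the far field of an event is stale by < 1e-4 nm, a rate
error of order 0.01%.  Rate caches are rebuilt for heads on chains that
moved more than 1e-3 nm (rate error < 0.3%) and fully after every polish.
The public `solve_equilibrium` always solves to the requested tolerance; a
dense brute-force linear solve is the test oracle (agreement 1e-10).

**Traces.** Every 1 ms the engine records per-thin-filament Z-disc tension,
attached-head counts by state per thick filament, and the summed crossbridge
force; monomer-position snapshots are stored every 20 ms after 0.2 s.
Plateau detection: first time from which the 50 ms windowed mean force
drifts < 1% relative.

## Diffraction

On the meridian (R = 0) the azimuth of the actin helix contributes a
constant phase, so only axial positions matter.  Per filament the amplitude
is the coherent sum A(Z) = sum_j f(Z) e^{2 pi i Z z_j} over monomer centres
(point scatterers by default; a uniform-sphere form factor is available);
filaments add incoherently — no axial register across the lattice is
assumed, and simulation snapshots taken at different times add incoherently
too, emulating a time-integrated exposure.  A uniform 364-monomer filament
reproduces the finite-lattice (Dirichlet kernel) closed form to 1e-8
relative; orders n of the 2.73 nm repeat appear at Z = n/2.73 nm^-1.
Reflection windows default to ±2% around n/s0 with >= 2000 grid points per
1% of window; on a uniform grid the computation uses a per-monomer phasor
rotation recurrence (exact to rounding).  Beam smearing is a unit-area
Gaussian kernel of configurable FWHM in Z (no universal instrument value
exists; it is a required input when emulating camera data), applied
per order window; integrated intensity is conserved to 1e-6.

## Metrology and force estimation

Peak positions use the centroid of the top half: points with
I >= Imax/2 weighted by I − Imax/2; FWHM by linear interpolation at half
height.  The estimator is invariant to intensity scale and to the removed
background (linear through the window endpoints by default, polynomial
optional), and errs by far less than 0.05% of the spacing on noiseless
uniform-helix profiles.  `PeakMetrics.spacing` is the reflection's Bragg
spacing 1/Z_center (2.73, 1.365, 0.91 nm for the first three actin orders).
The order-1 window is clamped above 1/2.80 nm^-1 to exclude the 2.86 nm
myosin meridional reflection.

The estimation chain:

1. mean inter-monomer spacing of relaxed and contracted states from the
   order-1 centroid; mean strain = Δs/s_relaxed;
2. conversion to the I-band plateau strain with the mean-to-plateau ratio
   g.  For tension decaying linearly across the overlap the monomer-average
   is g = (L_I + L_ov/2)/L_thin ≈ 0.647, but the *observed* centroid sits a
   few percent above the monomer mean because the uniformly stretched
   I-band diffracts coherently and dominates the peak.  The default g is
   therefore calibrated on the forward model (`effective_g` ≈ 0.68 for the
   reference geometry: stepwise overlap-distributed loads -> diffraction ->
   centroid), and in simulation-coupled mode it is recomputed from the
   matched ensemble with the same observable;
3. plateau force per thin filament F = Ka x plateau strain;
4. (optional, `g_mode="simulate"`) the binding rate is titrated —
   seed-averaged bisection in log k_bind — until the simulated plateau
   per-thin-filament force matches F within 3%, and g is refined once from
   the matched ensemble;
5. the matched ensemble supplies the per-filament force histogram, its SD,
   and a beam-convolved overlay residual against the input reflections;
   tension = F x actin areal density, with
   density = occupancy x 1e6 / ((2/sqrt(3)) d10²) thick filaments per um²
   at the slack-length d10 = 37 nm and 80% myofibril occupancy
   (506 thick / 1012 actin per um²; 297 pN ↔ ~300 kPa).

## Synthetic data

The generator emulates the relaxed/contracted profile pairs of classic
frog-sartorius meridional experiments with known ground truth.  Contracted
filaments carry n_loads = 54 equal point loads (the expected number of
attached crossbridges per thin filament at ~72% duty ratio) at
uniform-random monomer indices inside the overlap; per-filament total force
is Normal(mean, sd) truncated at zero — the simulated force histograms are
unimodal and near-symmetric, and no distribution family is implied by the
data.  Defaults: 1000 filaments (the production simulation scale), beam
FWHM as supplied, multiplicative Gaussian intensity noise of relative SD
5e-4 (the scale of sub-0.05% spacing metrology).  The relaxed and
contracted profiles share one noise realisation per seed so paired
comparisons remain exact in the zero-force limit.

What the generator does **not** emulate: activation-dependent thin-filament
twisting/shortening, myosin-based reflections (only the window clamp
acknowledges the 2.86 nm neighbour), detector geometry, radial integration
bands, and counting statistics that scale with exposure.  Closed-loop tests
therefore validate the estimation chain under the model's own assumptions,
not the full complexity of camera data.

## Numerical choices and limitations

* Default run scale for validation is 20 thick filaments x 0.5 s x 3 seeds
  (~3000 heads), the smallest ensemble with stable plateau statistics on a
  single CPU; production scale is 500 thick filaments.  Observables are
  per-filament averages and are unbiased in filament count; their sampling
  noise shrinks as 1/sqrt(n_thick).
* With the documented rate forms the reference activation (k_bind = 134
  s⁻¹) develops ~75% bound heads but a per-thin-filament force of ~225 pN,
  below the ~297 pN the original multiscale platform reports there; the
  ~300 kPa operating point is reached by titrating k_bind (step 4), at
  which the mean crossbridge force is ~4.5 pN.  The difference traces to
  the unpublished strain-dependence details of the original rate
  expressions; all printed constraints are honoured.
* Mechanics tolerances: force residual 1e-6 pN (configurable); event-local
  front 1e-4 nm; mid-polish 1e-5 nm; rate-refresh threshold 1e-3 nm.
* Degenerate inputs: zero overlap (overlong sarcomere) is rejected at
  construction and by the estimator; a flat-topped peak exactly at half
  height falls back to the midpoint of the plateau; titration refuses
  unbracketable targets rather than extrapolating.
* Calcium regulation is outside the model: activation level is represented
  solely by the effective binding rate.  Radial (lattice-spacing)
  mechanics, filament bending, multi-sarcomere chains and 2D detector
  images are likewise out of scope.
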