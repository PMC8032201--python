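# Methods

## Models and conventions

Both bundled epilepsy models are planar slow-fast systems with a cubic fast
nullcline and a linear (or effectively linear) slow nullcline.  The
*phenomenor* couples a firing rate v to an excitability a,

    v' = -tau_x (v^3 + v^2 - a),
    a' = tau_a (tanh(c (hm a - hn - v)) - a0),

with `P_pheno = {tau_x=1, tau_a=0.001, c=1000, hn=0.86, hm=1.6, a0=0.5}`.
The `tanh` with c = 1000 acts as a near-step threshold; the offset
a0 = 0.5 makes the response asymmetric by design (the excitability grows at
rate ~ +0.5 tau_a below threshold and decays at ~ -1.5 tau_a above it).
The reduced epileptor couples the firing rate to a permittivity z,

    v' = 1 + I_app - v^3 - 2 v^2 - z,
    z' = tau_z s (c (v - v0) + z),

with tau_z stored as the exact quotient 1/2857 and three canonical rows
P+ (v0=-2, c=-4, s=-1), P0 (v0=-1.5, c=-16, s=-1), P- (v0=-0.1, c=2.4,
s=1), all with I_app = 3.1.  The rows differ only in the slope and position
of the slow nullcline; their unperturbed cycles are qualitatively
identical, which is exactly what makes them a controlled comparison of the
slow vector field's role.  The small time constants are *absorbed* in these
models (the `epsilon_absorbed` flag); the generic interface also supports
an explicit epsilon, used by the cubic Liénard test oscillator
(`x' = x - x^3/3 - y`, `y' = x/mu`).

Delta pulses act along +v in both models.  All times are model (fast) time
units; no unit conversions exist anywhere.

## Limit cycles

Cycles are located as fixed points of a Poincaré map on a vertical section
(constant fast coordinate, fixed crossing direction) by a Newton iteration
with a finite-difference map derivative; integration uses DOP853 at
rtol 1e-12 (atol 1e-14) by default.  For slow-fast cycles the nontrivial
characteristic multiplier is O(exp(-k/eps)) — numerically zero — so the
iteration lands on the cycle after a single return; the Newton form is kept
for mildly stiff systems such as the fixture at moderate mu.  Phase zero is
anchored at the section crossing, the phase chart is proportional to time
(theta = t/T), and the cycle is stored as 2048 equispaced snapshots;
gamma(theta) between snapshots is evaluated by a short integration from the
nearest snapshot rather than spline interpolation, because the phenomenor's
threshold layer makes high-order interpolants locally inaccurate.  The
rotation sense is measured from the signed loop area, not assumed — the two
bundled models rotate oppositely.

## Phase readout

Asymptotic phases are read at the upward zero crossing of the fast variable
(the seizure-transition event).  Converting a crossing time into a phase
divides the integrator's position error by the local speed, so anchoring
the readout where the flow is fast (the jump) keeps phases accurate to
~1e-10, whereas a slow-branch section would lose four orders of magnitude.
The estimate uses the last crossing in the window and requires the last two
crossings to agree to 1e-6, which certifies convergence to the cycle.

## Phase response curves

The primary method is continuation: solve
`F_A(gamma(theta)) = gamma(f_A(theta))` with
`F_A(z) = phi_{T_rel}(z + A d)` by projecting the residual onto the cycle
tangent `T Z(gamma(f))`, stepping the amplitude from 0 (where f is exact)
to the target in steps of A/20 by default, with adaptive halving.  The
relaxation time T_rel defaults to the smallest whole number of periods
after which an off-cycle probe is period-map stationary to the working
tolerance.  Newton steps are capped at a quarter turn; stagnation with a
small residual is accepted (the residual then equals the target's own
transverse distance from the cycle, which no phase change can remove),
while stagnation with a large residual means the iteration found a
nearest-point projection on the wrong arc and triggers re-seeding from the
nearest stored cycle snapshot.  A brute-force direct method (kick, relax,
read the asymptotic phase) provides the independent cross-check; the two
agree to better than 1e-6 in phase on 64-phase grids for both models.

Phase shifts are wrapped to (-0.5, 0.5].  The discontinuity phase theta* is
located by bisection on the geometric event "the kicked point lands beyond
the repelling branch", not by thresholding jumps in the sampled curve.
Each sample also carries a crossing flag, for two reasons: advances larger
than half a cycle (kicks just past theta* that skip most of a turn) fold
into apparent large delays under the wrap, and the maximal-delay statistic
that sets the locking boundary must be taken over the genuinely delaying
(non-crossing) samples only.  The maximal delay concentrates in a narrow
spike just below theta*; `refine_near_discontinuity` adds samples on a
geometric ladder down to 3e-4 cycles below theta* so the limiting delay is
resolved (without it a uniform 32-sample grid understates T_s* by ~20% for
the phenomenor at A = 0.2).

Interpolation of a sampled PRC never crosses the discontinuity: the grid is
unrolled to start just after theta* and interpolated piecewise.

## Infinitesimal PRC and isochrons

The phase gradient along the cycle is computed from small-amplitude PRCs in
each basis direction with three-point Richardson extrapolation
(A, A/2, A/4; default A = 2e-4), which cancels the O(A) and O(A^2)
curvature bias; the two finest first-order extrapolations must agree to the
requested tolerance or A is halved.  Forward variational and adjoint
integration are avoided as the primary path — the cycle's multiplier
underflows — but a *backward* adjoint solve along the stored forward cycle
is provided as an independent oracle: backward in time the nontrivial
adjoint mode decays, so two backward periods converge to the gradient with
conservation of `<w, Z>` as a built-in error monitor.  The adjoint solver
caps its step at T/8192 because the phenomenor's threshold layer is so
narrow in time that an uncapped adaptive step can jump over it without
noticing.  The finite-amplitude and adjoint gradients agree to ~1e-5
relative; the normalization `<grad Theta, Z> T = 1` holds to a few 1e-7.

The isochron tangent N(theta) is the kernel of the gradient.  Isochrons are
globalized by seeding the linearization of I_{theta + t/T} at a small
offset (1e-4 of the cycle diameter) and flowing backward for time t: the
image lies on I_theta, and sweeping t traces the curve outward with only
short backward legs — mapping a fixed segment backward by whole periods is
impossible here because the transverse expansion exp(+k/eps) leaves any
bounded box in a fraction of a period.  Phase errors are invariant under
the flow, so the seed's O(s^2) linearization error does not grow; however,
isochron curvature diverges near the folds, so every candidate point is
verified with the asymptotic-phase membership test (tolerance 1e-4 cycles)
and each side of the curve is truncated at the first failure.

## The slow field shapes the isochrons

With the slow variable frozen, a kicked point converges to the slow
manifold under the layer dynamics in a measured time t_h (defined by
|f| <= eps); during that time the matching cycle point and the kicked point
accumulate different slow displacements, and their difference is the
leading-order offset of the isochron from a constant-slow line.
`predict_isochron_offset` evaluates both quadratures numerically (t_h is
measured, not taken from the asymptotic O(eps log eps) bound, which is
order-of-magnitude only).  When the slow rate is monotone in the fast
variable the offset's sign is uniform: `isochron_slope_sign` samples
dg/dx along the layer trajectory and returns -sign(dg/dx), 0 when the slow
field is insensitive to the fast variable, or "indeterminate" (None) when
the derivative changes sign.  Slope reporting is restricted to normally
hyperbolic points; near the folds the construction is undefined and the
globalizer's membership test is the only guard.

## Pulse trains and sweeps

Pulses are exact state jumps between integration segments (a delta pulse
has no width).  Seizures are upward crossings of v = 0 — the fast variable
value of the upper fold in both models — located by the integrator's event
detection with a refractory window of 1% of T against grazing double
counts; a pulse that itself carries v across zero is also counted, since no
integration step sees that crossing.  The seizure-rate change is
Delta = count / (duration/T), the unperturbed rate being one seizure per
period.  Sweep cells run 20 periods by default starting on-cycle at the
lower-branch landing point (the down-jump target), so there is no transient
to discard and the unperturbed count is exact; jittered cells draw
intervals from N(T_s, (0.05 T_s)^2) with per-cell seeds derived from a
single SeedSequence, negative draws clipped at 1e-3 T_s (clips are logged),
and 3 replicates by default.  Sweeps integrate at rtol 1e-9; cycle and PRC
work at 1e-12.

## Locking predictions

Fixed points of the stroboscopic map solve PRC(theta) = -T_s/T on each
continuous piece of the PRC; stability uses the standard circle-map
criterion |1 + PRC'| < 1 with PRC' from central differences, never across
the discontinuity (the criterion is an editorial choice — no canonical one
exists for discontinuous PRCs).  Roots on the advancing piece are reported
but flagged non-suppressing: a lock near T_s ≈ T entrains the rhythm while
letting every cycle complete.  The locking boundary is
T_s*(A) = T |max delay|, with the maximal delay over delaying samples as
above; on the phenomenor it tracks the simulated Delta = 0 wedge to within
one 5-unit grid cell at A = 0.2 and 0.25.  Robustness to timing jitter is
summarized by the exceedance probability P(t_s > T_s*) under
N(T_s, sigma^2) — 0.5 exactly at the boundary.  At matched sigma the P+
and P0 epileptor variants are orders of magnitude more fragile than P-:
the three PRCs have similar delay ranges, but the much longer P- period
converts them into a much longer critical interval.

## Test-fixture realism and scope

The cubic Liénard fixture reproduces the geometry the theory assumes
(cubic fast nullcline, linear slow nullcline, point symmetry) at moderate
stiffness (mu = 20 in most tests), where attraction is strong but not
machine-degenerate — exercising code paths (multi-period relaxation,
Newton with nonzero map derivative) that the bundled models' extreme
contraction hides.  What passing tests show is internal consistency of the
methods and agreement with the bundled models' published behaviour; they do
not show that any of these planar models describes real epileptic tissue,
and none of the machinery addresses non-planar dynamics, continuous
stimulation, or stochastic vector fields.

## Problem sizes

Default problem sizes were chosen so a full analysis runs interactively on
one CPU: 2048 cycle snapshots, 64-phase PRC grids (with 6 refinement
samples at the discontinuity), 20-period sweep cells, and coarse (A, T_s)
grids with 0.02-0.03 amplitude resolution.  The onset amplitude reported by
the acceptance script is therefore resolved to the grid step, and
sweep-based quantities are exact for periodic trains (no replication
needed) and averaged over 3 seeds for jittered ones.

## Known limitations

* The Poincaré section default (vertical line through the initial guess)
  assumes the guess's fast coordinate is actually crossed by the cycle.
* Near-fold PRC samples sit in the transition zone between delay and
  advance; their values are correct but no sign law applies there.
* `predict_isochron_offset` raises in the repelling region and loses
  meaning within O(eps) of the folds.
* Backward-time operations (isochron globalization) are limited to a
  bounded box; isochron tails approaching the repelling manifold are
  truncated by the membership test rather than followed.
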