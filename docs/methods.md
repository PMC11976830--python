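# Methods

## Model and assumptions

The sphere is a homogeneous continuum of Lennard-Jones 12-6 material points
(number density `rho_s`, radius `a`); the rod is a one-dimensional material
line (line density `lambda`, length `L`, possibly infinite) with **no
cross-sectional radius**.  The pair interaction is strictly additive
(Hamaker superposition): no many-body screening, no retardation (the
attraction is the nonretarded 1/r^6 van der Waals form), and both bodies
are rigid.  All results are therefore exact consequences of integrating
`U(r) = 4 eps [(sigma/r)^12 - (sigma/r)^6]` over the two bodies, valid
whenever the rod lies strictly outside the sphere.

Configurations live in the rod's polar frame: origin at rod end O, x-axis
along the rod, sphere center at `(rho, theta)` with `theta` in `[0, pi]`.
The derived coordinates `x_c = rho cos(theta)` (axial projection of the
center) and `h = rho sin(theta)` (center-to-axis distance) parametrize
everything; the rod endpoints sit at `y0 = -x_c`, `yL = L - x_c` in the
axial coordinate centered on the projection.

## Parameters

| parameter | meaning | default | units |
|---|---|---|---|
| `epsilon` | LJ well depth | 1 | energy |
| `sigma` | LJ zero-crossing length | 1 | length |
| `a` | sphere radius | — | sigma |
| `rho_s` | sphere number density | 1 | sigma^-3 |
| `L` | rod length (`inf` allowed) | — | sigma |
| `lambda_lin` | rod line density | 1 | sigma^-1 |

`A_cs = 24 pi epsilon` is always recomputed from `epsilon`.  The density
defaults `lambda = 1/sigma`, `rho_s = 1/sigma^3` are the convention under
which the adhesion coefficient `4.48 eps` is quoted; both potentials and
forces are linear in `lambda * rho_s`, so other densities rescale all
energies trivially.

## Branch dispatch and numerical precision

The closed-form axial primitives have three branches around axis tangency
(`h` vs `a`).  Dispatch uses `tau_b = 1e-6 sigma` on `|h - a|`: inside the
band the dedicated tangent primitive (exact at `h = a`) is evaluated at the
actual endpoints, which introduces a relative error of order
`|h - a| * dlnW/dh`, comfortably below 1e-6 away from near-contact.  If the
rod crosses the grazing point while `|h - a| <= tau_b` the configuration is
within 1e-6 sigma of contact; it is then evaluated with the exact
off-tangent branch in extended precision instead.

Away from tangency the individual branch terms scale like
`(h^2 - a^2)^{-8}` while the bracketed endpoint difference is of the order
of the result, so double precision loses roughly 8.5 digits per decade of
`u = |h^2 - a^2|` below the scale `(a + sigma)^2`.  Evaluation therefore
escalates to mpmath whenever `u < 0.05 (a + sigma)^2`, with the working
precision set adaptively to `30 + 9 log10((a + sigma)^2 / u)` digits
(capped at 300).  This band is wider than a fixed `|h - a| < 0.01 sigma`
window on purpose: for a 10-sigma sphere, double precision already fails
the 1e-8 oracle-agreement target at `|h - a| ~ 0.1 sigma`.  A non-finite
double-precision result escalates the same way regardless of the band.

The infinite-rod potential has only two terms and no cancellation; it is
evaluated in log space with radius-scaled variables (`t = h/a`,
`v = t^2 - 1`) so intermediates like `(h^2 - a^2)^{17/2}` cannot overflow
for any sphere radius.

## Derivatives, force, and torque

`dW/dx_c` is exact: moving the sphere axially only slides the integration
endpoints, so the derivative is the closed-form sphere-point integrand
evaluated at the two rod ends.  `dW/dh` uses complex-step differentiation
of the branch primitives (step `1e-80 i`; no subtractive cancellation,
machine-accurate), with an mpmath complex step inside the
extended-precision band and a Richardson finite difference across the
tangent band, where the closed form is h-independent.  The polar partials
`dW/drho`, `dW/dtheta` follow from the chain rule.  Cross-checks against
arbitrary-precision numerical differentiation agree to better than 1e-7
relative.

Forces are assembled in the `(x_c, h)` parametrization, so the removable
`1/(rho sin theta)` factor of the polar-gradient expression never appears
and collinear configurations (`sin theta = 0`) are regular.  The torque on
the rod uses the center- or O-end-referenced closed forms along
`n_z = (n_x x n_rho)/sin(theta)`; infinite rods are rejected rather than
assigned zero torque.  The torque on the continuum sphere about its own
center is exactly zero (central pair forces have no lever about the
center); this is asserted as a property of the model.

Global-frame wrenches rotate the local components through the orthonormal
basis `(n_x, n_h, n_z)` reconstructed from the Cartesian endpoints; when
the center lies on the rod axis the perpendicular directions are chosen
deterministically (smallest-magnitude axis component, orthogonalized) so
outputs are reproducible.

## Quadrature oracle

Every closed form is validated against adaptive Gauss–Kronrod quadrature of
the defining integral (`scipy.integrate.quad`, relative tolerance 1e-12),
with the interval split at the point of closest approach where the
integrand peaks.  Torques are cross-checked by an independent *vector*
quadrature of the segment force density (lever arm times the analytic
radial derivative of the sphere-point potential), and the sphere-point
closed form itself is checked against a two-dimensional quadrature of the
bare pair potential over the sphere volume.  Near tangency the oracle
integrates in arbitrary precision so the reference is at least as accurate
as the analytic path.  Pseudo-infinite rods truncate at 1e4 sigma
half-length; doubling the truncation changes results below the tolerance.

## Adhesion analysis

The bisector family (`x_c = L/2`) maximizes attraction by symmetry; the
minimum of `W(L, h)` over `h` is found by bracketing the analytic
`dW/dh` in `[a + 0.3 sigma, a + 3 sigma]` (expanded geometrically if
needed) and Brent root finding to `1e-12 sigma`.  The convergence
certificate bounds the derivative residual by `1e-8 eps/sigma` plus a
curvature-times-resolution floor, because for very large spheres
(`a ~ 1e4 sigma`) the root cannot be localized below the floating-point
spacing of `h0` itself.  The substitution solutions of the stationarity
conditions ((2/5)^{1/6} sigma for the sphere-point limit; the h0 = a and
h0 = 2a substitutions 0.787/0.824 sigma for the infinite rod) are
evaluated exactly; fixed-point iteration of the same conditions converges
in a handful of steps and agrees with direct minimization to 1e-8 sigma.

The `sqrt(a)` adhesion coefficient is reported at finite radius as
computed; the large-a asymptote is estimated by Richardson extrapolation in
`1/a` over the two largest radii (the finite-a coefficients approach the
asymptote from below: 4.43 at a = 100, 4.4838 at a = 10^4).

## Test design and problem sizes

The suite validates each operation against an independent oracle rather
than frozen constants wherever an oracle exists: quadrature for potentials
(1e-8 relative away from tangency, 1e-6 inside the `|h - a| < 0.01 sigma`
band, over ~1e3 random configurations spanning all three branches),
Richardson finite differences for partial derivatives and forces, vector
quadrature for torques, and closed-form limits (short rod to sphere–point,
vanishing sphere to pair and point–rod forms, long rod to infinite rod).
Finite-difference oracles sample the potential through the
extended-precision path and keep a 0.6-sigma clearance from the repulsive
wall: closer in, the oracle's own truncation/roundoff — not the analytic
derivatives — dominates the comparison.  Random configurations draw radii
from 2–15 sigma and rod lengths from 1–20 sigma, which spans all branch
and sign structures the formulas distinguish; the closed forms contain no
scale that would require larger systems to exercise.

Known limitations: no finite rod cross-section (the thin-rod line density
is not a good model for thick cylinders near contact), no retarded vdW
regime, no thermal/entropic contributions to adhesion, and single
sphere–rod pairs only (no neighbor lists or periodic boundaries).
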