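# rodsphere

Closed-form Lennard-Jones 12-6 interaction between a **continuum sphere**
and a **thin rod** (a material line of LJ points), in arbitrary 3-D
configurations — the integrated potential, the resultant force and torque,
and the adhesion analysis built on them.  A slow, independent
numerical-quadrature oracle validates every closed form.

Sphere–rod pairs of this kind appear throughout soft matter and biophysics:
colloidal particles against nanorods, nanowires or carbon nanotubes,
spherical inclusions against biofilaments such as microtubules, or
spherical colloids mixed with rod-like viruses and bacteria.  Simulating
such mixtures as rigid bodies requires the *integrated* (Hamaker-style)
pair interaction rather than a sum over atoms; this package provides it in
exact closed form for the sphere/thin-rod geometry.

## The model

Material points interact through the LJ 12-6 potential
`U(r) = 4 eps [ (sigma/r)^12 - (sigma/r)^6 ]`.  Integrating over a sphere of
radius `a` and density `rho_s` gives the sphere–point potential `U_SP(r)`
(valid for `r > a`), with the Hamaker-style constant `A_cs = 24 pi eps`.
Integrating `U_SP` along a rod of length `L` and line density `lambda`
gives the sphere–rod potential `W(rho, theta)` in the rod's polar frame.
The axial integral has three closed-form branches, dispatched on the
perpendicular center-to-axis distance `h = rho sin(theta)`:

* `h > a`: primitive with arctangent terms in `y / sqrt(h^2 - a^2)`;
* `h < a` (axis pierces the sphere, rod outside): the arctangents become a
  logarithm whose end-to-end argument is provably positive, so `W` stays
  real and finite;
* `h = a` (tangent axis): a separate, simpler primitive.

Near tangency the branch terms cancel catastrophically in double precision;
the package escalates to arbitrary-precision arithmetic automatically and
reports it (`precision_mode="extended"`).  Forces come from the exact
endpoint derivative in the axial direction plus a complex-step derivative
in `h`; the torque on the rod about its center is
`tau_z = -(L/2) sin(theta) dW/drho + (1 - L cos(theta) / (2 rho)) dW/dtheta`.

For an infinite rod `W` depends on `h` only and has a two-term closed form;
its minimum defines the equilibrium gap `delta_h = h0 - a` and adhesion
depth `DeltaW = |W(h0)|`.  Closed-form stationarity conditions bound the
infinite-rod gap between `0.787 sigma` and `0.824 sigma`, and for large
spheres the adhesion scales as `DeltaW ~ 4.48 eps sqrt(a/sigma)`
(for `lambda = 1/sigma`, `rho_s = 1/sigma^3`).

## Worked example

```python
import math
from rodsphere import (LJParams, Sphere, Rod, finite_rod_potential,
                       find_h0, torque_on_rod, bisector_config)
from rodsphere.mechanics import config_from_xc_h

p = LJParams()                      # eps = sigma = 1 (reduced units)
s = Sphere(a=10.0)                  # sphere radius 10 sigma
rod = Rod(L=5.0)                    # rod of length 5 sigma, lambda = 1

# sphere center 12 sigma above a point 2 sigma along the rod
c = config_from_xc_h(2.0, 12.0, rod.L)
res = finite_rod_potential(c, s, rod, p)
print(res.W, res.branch.value)      # -0.852770484116719 h>a

# equilibrium gap and adhesion for an infinite rod
eq = find_h0(Sphere(a=50.0), Rod(L=math.inf), p)
print(round(eq.delta_h, 3), round(eq.DeltaW, 2))   # 0.787 30.97

# torque vanishes when the center sits on the perpendicular bisector
tau = torque_on_rod(bisector_config(20.0, 10.0), Sphere(a=5.0), Rod(L=20.0), p)
print(abs(tau.torque[2]) < 1e-8)    # True
```

The first number is the interaction energy in `eps` (attractive, the rod
axis clears the sphere, so the `h > a` branch was used).  The equilibrium
gap `0.787 sigma` is the long-rod/large-sphere plateau; `30.97 eps` is the
corresponding adhesion depth — a coefficient `4.38 eps sqrt(a/sigma)` at
this radius, still below the large-sphere asymptote `4.48`.

A CLI mirrors the library:

```sh
rodsphere potential --a 10 --L 5 --theta 0.5236 --rho-min 22 --rho-max 30 --n 100 --verify
rodsphere adhesion  --a-values 5,10,20,50 --L-values 0.01,10,inf
rodsphere wrench    --a 3 --configs configs.csv
rodsphere verify    --a 6 --L 5 --n 200 --seed 0
```

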