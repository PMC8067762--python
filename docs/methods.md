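# Methods

`nfvisco` characterizes the viscoelasticity of neurofilament (NF) sidearms
— the intrinsically disordered C-terminal tails of axonal intermediate
filaments — from steered-pulling MD output. The pipeline has four stages:
stress/strain extraction from per-atom trajectory frames, relaxation-modulus
construction, Prony-series fitting, and correspondence-principle conversion
to shear and bulk moduli. A synthetic-data module generates every input
with known ground truth so the whole chain runs, and is tested, at desk
scale.

## Stress and strain extraction

Per-atom virial stress is reported in pressure×volume form (atm·Å³ in the
"real" unit convention). The stress of an atom group is

σ = −(Σᵢ sᵢ) / (Σᵢ vᵢ) · 1.01325×10⁻⁴ GPa/atm,

where sᵢ is the per-atom stress·volume tensor and vᵢ the atom's Voronoi
cell volume. Voronoi volumes use the periodic tessellation of the box
(positions wrapped, surrounded by their 26 lattice images, cell volumes
from the convex hull of each central cell), so the volumes partition the
box exactly; a non-periodic fallback clips cells at the box faces via
mirror images and is an approximation for non-periodic snapshots.
Coincident positions are jittered by 10⁻⁶ Å with a fixed seed and a
warning instead of failing. The virial sign is flipped so tensile stress
is positive, and the reported scalar is the normal tensor component along
the pulling axis (a von Mises invariant is available as an alternative).
Engineering strain is the mean displacement of the pulled group along the
pulling axis since the first frame, divided by a reference length; the
axis sign encodes the pulling direction. Dump files are the standard
ITEM:-delimited text dialect; column order is taken from the ATOMS header,
indexed compute names (`c_stress[1..6]`) are accepted, image flags unwrap
wrapped coordinates, and a malformed trailing frame is dropped with a
warning while prior frames are kept.

## Relaxation model and fitting

After a step stretch to hold strain ε₀ (default 0.8), the relaxation
modulus is E(t) = σ_axial(t)/ε₀ with time re-zeroed at the hold start;
loading-phase samples are excluded, which is accurate when loading is fast
against the hold. E(t) is fitted to the generalized-Maxwell (Prony) form

E(t) = E₁ + Σᵢ Eᵢ e^(−t/τᵢ)    (E in GPa, τ in ps),

the one-branch case being the three-parameter model (E₁, E₂, τ). Fitting
minimizes the L2 norm of the residual by Nelder-Mead simplex search with
multi-start. Constraints are structural: the search runs over √Eᵢ and
log τᵢ, so every visited point maps to non-negative moduli and positive
times. The deterministic start uses E₁⁰ = mean of the last 10% of the
trace, E₂⁰ = E(0) − E₁⁰, and τ⁰ = the first time the trace falls to
E₁⁰ + E₂⁰/e; 8 additional starts jitter each packed parameter by
independent U(0.5, 2) factors drawn from the run seed. Convergence uses
10⁻⁸ tolerances on objective and parameters with at most 10⁴ evaluations
per start; the best converged start is returned, and per-start diagnostics
accompany a failure. If the fitted long-term modulus falls below a
threshold fraction (default 1%) of E(0), the material is classified as a
two-parameter (pure Maxwell) solid and refitted with E₁ pinned to zero —
the form observed at the higher pulling rate, where the stretched chain
relaxes to zero stress. N-branch fitting is implemented (branch count is a
parameter) but one branch is the default and is sufficient for these
traces. A constant trace is a degenerate case: the branch modulus fits to
~0 and τ is then unidentifiable; the fitted E(t) is still correct, which is
what the tests assert.

## Correspondence conversion

With a constant Poisson's ratio ν, the Laplace-domain relations
G\*(s) = E\*(s)/(2(1+ν)) and K\*(s) = E\*(s)/(3(1−2ν)) invert in closed
form: every Prony modulus scales by 1/(2(1+ν)) (shear) or 1/(3(1−2ν))
(bulk) and the relaxation times are unchanged. Defaults are ν ∈ {0.33,
0.48} — a compressible and a nearly incompressible assumption; measured
values for comparable cytoskeletal components fall around 0.3–0.4, and no
measured value exists for NF sidearms. K diverges as ν → 0.5 and the
conversion raises an error saying so. An independent oracle
(`inverse_laplace_check`) numerically inverts the Laplace-domain
expressions with mpmath's Talbot contour at 30 digits of working
precision, reporting unstable points as NaN rather than smoothing; tests
require agreement with the closed form to 10⁻⁶ relative on t ∈ [1, 1000]
ps. The constant-ν closed form is the primary path; a time-dependent ν(s)
is representable only through the numerical oracle.

Reference parameter sets used throughout the tests and drivers are the
fitted sidearm models at the two nominal pulling rates: (E₁=0.103 GPa,
E₂=0.827 GPa, τ=87.866 ps) at 10⁸ s⁻¹ and (E₁=0, E₂=2 GPa, τ=100 ps) at
10⁹ s⁻¹. Published tabulations of the converted parameters contain two
internal inconsistencies worth documenting: shear/bulk τ values of
90.909 ps accompany a source τ of 87.866 ps, although a constant-ν
conversion cannot alter τ; and the tabulated G₂ at ν=0.33 (0.314, 0.76)
and one G₂ at ν=0.48 (0.281) differ slightly from the closed-form
arithmetic (0.311, 0.752, 0.279). This package reproduces the arithmetic,
not those cells.

## Tensile stiffness

Unfolding and stretching of the sidearm overlap throughout pulling, so no
changepoint detection is attempted; stiffness is an OLS slope over a
user-chosen strain window, with intercept and residual RMS reported.
Default reporting windows extend to strain 2.17 at 10⁸ s⁻¹ and 3.6 at
10⁹ s⁻¹, matching the recorded extents at each rate. `compare_rates` fits
a common window across curves, sorts by nominal rate, and flags any
violation of the expected monotone rate→stiffness ordering; curves sharing
a rate are kept as separate labeled rows.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *structure* of the MD output, not its
physics:

- **Relaxation traces**: exact Prony decays plus additive i.i.d. Gaussian
  noise on the sampled modulus. Default duration 1 ns at 1 ps sampling
  (1001 points) and hold strain 0.8, matching the relaxation protocol.
  The noise level is not reported anywhere; the default sd = 0.05 GPa
  (≈5% of a ~1 GPa instantaneous modulus) is this package's documented
  choice. Real E(t) fluctuations are time-correlated and
  heteroscedastic; passing tests show the fitter recovers parameters
  under iid noise, not under MD noise.
- **Tensile curves**: piecewise-linear two-stage curves (low unfolding
  slope, then a stiffer stretching slope, continuous at the breakpoint)
  with additive Gaussian fluctuation. Rate dependence enters only through
  the prescribed stretch slope (0.3 GPa at 10⁸ s⁻¹, 0.5 GPa at 10⁹ s⁻¹ in
  the drivers, putting the high-rate stiffness at the observed ~0.5 GPa
  scale). No entropic elasticity, no rupture.
- **Toy frames**: static uniformly placed atoms whose per-atom
  stress·volume entries are an exact volume-weighted split of a prescribed
  group stress history plus a zero-sum random perturbation, so extraction
  must recover the prescription to rounding error. They validate the
  bookkeeping (units, signs, Voronoi normalization), not any force field.

## Numerical choices and limitations

- Seeds: every stochastic component takes an explicit integer seed
  (numpy `default_rng`); pipelines embed the seed and a config hash in
  each artifact, and identical (config, seed) runs are byte-identical.
- Monte-Carlo cross-check of Voronoi volumes (tests) uses 10⁶
  nearest-site samples under the minimum-image metric at 1% tolerance.
- Degenerate inputs: empty member sets, non-positive hold strain or
  reference length, disjoint time grids, and sub-minimal sample counts
  raise typed errors before any computation.
- The strain-rate dependence of stiffness is emulated, not derived: the
  qualitative claim tested is that fitted stiffness ordering follows the
  generating slopes. Quantities that require the original all-atom
  trajectories (the fitted parameter values themselves, absolute
  stress-strain magnitudes) are outside what synthetic data can
  establish.
- Problem sizes in the drivers and tests (40-atom frames, 20-frame
  histories, 1001-point traces, 100-seed noise studies) were chosen as the
  smallest sizes at which every invariant is sharply testable.
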