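# Methods and conventions

This note fixes the conventions every module shares and records the exact
statements of the estimators, so that results from the flow pipeline, the
Einstein-crystal chain and the synthetic fixtures are directly comparable.

## Units and reference state

- Length: nanometers. Angles: radians. Temperature: kelvin
  (`celsius_to_kelvin` is the single Celsius entry point).
- Energies in kJ/mol; `KB = 0.008314462618 kJ mol⁻¹ K⁻¹`; all free energies
  are *reduced*: `f = -ln Z` in units of k_BT per supercell.
- Coordinates are nm everywhere in memory; the only unit conversion boundary
  is file I/O (PDB files are ångströms on disk).

## Measure and the centroid constraint

All densities and free energies refer to the ensemble with the **oxygen
centroid constrained to zero**, with orthonormal (Lebesgue) measure on that
`3(N_O - 1)`-dimensional hyperplane of oxygen coordinates plus the full
hydrogen coordinates. This is the natural convention for crystal supercells
(overall translation is not a fluctuation of interest) and it makes three
components agree exactly:

- the whitening layer drops the three null directions of the oxygen
  covariance and accounts for the basis change in its log-volume;
- the Einstein tether with an isotropic scalar spring and a reference
  structure inside the hyperplane has the closed-form constrained free
  energy `f0 = -(3(N-1)/2) ln(2π/(βk))` with `N` the real atom count;
- the synthetic fixtures sample the centroid-conditioned Gaussian exactly
  and normalize on the same hyperplane.

An alternative "standard" three-term bookkeeping (free Einstein crystal,
mass-weighted-COM fixing correction, physical `-ln V` term) is implemented
in `analytic_f0(..., convention="standard")` for cross-checks against the
conventional unconstrained formulation.

## Molecular representation

A molecule is `(O, H1, H2)` with an optional massless virtual site `M`
reconstructed deterministically as a fixed affine combination of the real
atoms (for a TIP4P/Ice-like geometry the hydrogen weight is
`w_H = d_OM / (2 d_OH cos(θ/2))`). Virtual sites are dropped on input and
rebuilt on output; they carry no degrees of freedom.

Internal coordinates are `(d1, d2, θ, q)`: the two O–H bond lengths, the
H–O–H angle, and the orientation as a unit quaternion. The Cartesian →
internal log-volume is closed-form,

```
ln γ = ln 8 + 2 ln d1 + 2 ln d2 + ln sin θ,
```

verified against the numerical Jacobian spectrum (`√det JᵀJ` over the
6-dimensional tangent including the quaternion's S³ tangent space).

### Hemisphere chart

Rotations are represented on the `q0 ≥ 0` hemisphere of S³ (since
`R(q) = R(-q)`), with `sign(0) = +1` as the deterministic tie-break.
Hyperspherical angles:

```
q0 = cos θ0,  q1 = sin θ0 cos θ1,
q2 = sin θ0 sin θ1 cos θ2,  q3 = sin θ0 sin θ1 sin θ2,
θ0 ∈ [0, π/2], θ1 ∈ [0, π], θ2 ∈ [0, 2π)
```

with area element `sin²θ0 sin θ1` (clipped at 1e-8 inside logs). Data
rotations are pre-rotated by per-molecule reference offsets (chordal means)
so that the angle distribution is centered in the chart, away from the
singular edges; the offsets are exact rotations, hence measure-preserving.

## Flow models

Model **C**: whitened oxygen block + raw hydrogen Cartesians. Model **H**:
whitened oxygen block + `(d1, d2, θ)` per molecule + hyperspherical angles.
Fixed layers (centroid removal, whitening, internal-coordinate map, angle
chart, shift-scale into the spline working range) all report exact
log-volumes. Trainable layers are monotone rational-quadratic spline
couplings with identity tails (`θ2` dimensions use periodic/circular
splines), conditioned by small MLPs whose final layers are zero-initialized
— a freshly built flow is exactly the identity, so `log_prob` is normalized
from the start.

The base distribution is flat: uniform `[-1, 1]` per dimension for model C;
for model H, uniform on the hemisphere per molecule (area π²) times flat
intervals for the rest. Because the hemisphere base is uniform *on the
sphere* and not in the angle chart, the base log-density in the latent
coordinates carries the output-side area element; gradients flow through it.

## Estimators

The central quantity is the generalized work `φ(r) = βU(r) + ln q(r)`.

- **Absolute free energy (`bar_v`).** Two-state Bennett acceptance ratio
  between the normalized model (reduced potential `-ln q`, free energy 0)
  and the physical state (`βU`): forward work `+φ` on model samples,
  reverse work `-φ` on data frames. The self-consistent solution with
  `M = ln(n_F/n_R)` is found by bracketed root-finding; the standard error
  is the asymptotic sandwich estimate from the self-consistency equation.
- **Overlap diagnostics.** Per side, the effective sample size is
  `min(Kish ESS of the Fermi factors, n · mean Fermi factor)` — the first
  catches a few dominant acceptance weights, the second uniformly
  negligible acceptance. If either side drops to ≤ 10 the estimate is
  flagged and its standard error reported as infinite.
- **ML lower bound.** `f_ML = <φ>` over validation frames satisfies
  `E_p[φ] = f - KL(p‖q) ≤ f` (Gibbs), tight when the model matches the
  Boltzmann density. It rises as training improves and decays on
  overfitting.
- **Weighted running average.** Per-evaluation `f_BAR` values are combined
  with cumulative weights `softmax(f_ML)`; standard errors are averaged
  with the same weights (conservative: no √n shrinkage is claimed).
  Flagged evaluations (infinite SE) are excluded.

The loss `-<βU + ln q>` differs from plain negative log-likelihood by the
parameter-independent `βU` term only; it keeps the training curve on the
`-f` scale so that convergence toward the free energy is visible directly.

## Einstein-crystal chain

`f = f0 + Σᵢ Δfᵢ` over a 20-window schedule `λ = 1 - (1 - t)²` (denser near
the interacting end). Each neighboring pair is bridged by BAR on
`Δλ · β(U - U_EC)` evaluated on both windows' samples. Pairwise standard
errors are **summed linearly** — a deliberate conservative convention.
When the λ = 1 window is sampled 4× longer than each other window, the
physical ensemble receives exactly `4/23 ≈ 17.4%` of the sampling effort.

## Synthetic fixtures

`HarmonicCrystalSpec` defines an exactly solvable water-like crystal:
harmonic oxygen site springs (centroid-constrained), truncated-Gaussian
bonds/angle, truncated-Gaussian hyperspherical angles about chart-centered
reference orientations. The reduced potential includes the internal-
coordinate Jacobian and the hemisphere area element, so the density is an
exact product of truncated Gaussians in the internal chart and `f` is
closed-form (Gaussian normalizers × truncation masses, restricted
determinant for the oxygen block).

Analytic moments used by the tests: the *quadratic* modes contribute
`(9n - 3)/2` to `<βU>` by equipartition — equipartition applies to the
quadratic forms only, not to the full reduced potential, whose log-measure
terms (`ln γ` and the area element) are instead evaluated by 1-D
quadrature per mode. The per-molecule entropy follows from
`s = (<βU> - f)/n`.

The default bond stiffness is softer than a real water force field so that
the default Einstein-crystal chain (spring 6·10³ kJ mol⁻¹ nm⁻², 20
windows) bridges the fixture with comfortable window overlap while keeping
bond-length fluctuations far (13σ) from zero.

## MD adapter

Real-ice inputs require an MD engine (optional dependency). The full
simulation protocol — PME tolerance 1e-5, 0.31 nm cutoff with switching
from 0.279 nm, Langevin middle integrator (20 ps⁻¹, 2 fs), frames every
100 fs, 20 ns production for ≤ 32 molecules / 40 ns above, anisotropic NPT
pre-equilibration at 1 atm with closest-to-average box selection, rigid
4-site water — is encoded as a plain `MDProtocol` descriptor that is
testable arithmetic without an engine.
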