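# Methods

## The model and the objective

A structure is a unit cell (a, b, c in Å; α, β, γ in degrees), an explicit
list of symmetry operators x' = Rx + t on fractional coordinates, atomic
sites (fractional coordinates, occupancy, isotropic u or six anisotropic
Uij in the CIF U convention, Å²), optional non-atomic shape scatterers,
and one overall scale K.  Refinement minimises

    M = Σ w (Yo − Yc)²

over observed intensities (Y = F², the default) or amplitudes (Y = F),
with w = 1/σ²(Yo) or unit weights.  Restraint equations share the same
objective: each contributes ((current − target)/σ)², i.e. enters the
normal equations with weight 1/σ² on a common scale with the data.  The
choice of a single augmented objective (rather than a separately scaled
restraint block) is the standard practice for small-molecule work; the
restraint-to-data balance is therefore controlled entirely by the σ
values.

Calculated structure factors are

    Fc(h) = K · Σ_sym Σ_sites occ · f(s) · T(h) · S(q) · exp(2πi h·(Rx+t))

plus an optional per-reflection complex solvent term added *before* the
modulus: |Fc| = |Fc_molecule + Fc_solvent|.  Adding the solvent estimate to
the calculated side (instead of correcting |Yo|) keeps its phase
information and lets model and solvent estimates be improved alternately.
No anomalous dispersion, extinction or absorption terms are included, so
Friedel symmetry Fc(−h) = conj(Fc(h)) holds exactly.

Form factors f(s) are 4-Gaussian + constant fits (International Tables
coefficients, sourced from gemmi at run time, overridable per element).
Debye-Waller factors: exp(−8π²u s²) isotropic, exp(−2π² Σ Uij hi hj ai*aj*)
anisotropic, evaluated with the symmetry-rotated index Rᵗh per operator.

## Orthogonal frame

One convention is used everywhere: x along **a**, y in the **a**-**b**
plane, z completing the right-handed set.  M maps fractional to Cartesian
(MᵗM = G, the metric tensor).  Shape orientations are declination (angle
from z) and azimuth (angle of the x-y projection from x), in degrees, and
the convention is written into every CIF the package emits
(`_microrefine_orthogonal_frame`).  Any program using a different frame
must re-express the angles; nothing in the refinement depends on the
choice beyond this bookkeeping.

## Special shapes

Severely disordered groups are modelled as uniform densities with closed
Fourier transforms, each multiplied by multiplicity, occupancy, the
element form factor and the isotropic Debye-Waller factor of the shape's
u_iso:

* spherical shell, radius R:  S = sin(qR)/(qR)  (spherical Bessel j₀);
* line, length L, axis n:     S = sinc((q·n)L/2);
* torus (ideal ring), radius R, normal n:  S = J₀(R|q − (q·n)n|).

The torus is an ideal circle; finite tube thickness is represented only
through the u_iso smearing.  All three transforms are validated against a
brute-force average of exp(iq·r) over 10⁴ points placed uniformly on the
shape (a Gauss-Legendre × azimuth grid for the shell), agreeing to better
than 1e-4 over random q up to ~6 Å⁻¹.  A multiplicity-6 torus reproduces
six discrete ring carbons to an R-factor-style aggregate difference of
0.8 % at d ≥ 2.5 Å; the residual is the sixth-order azimuthal harmonic
(J₆ terms) that a continuous ring necessarily lacks, so individual
reflections can differ by several percent even when the aggregate
agreement is well under 1 % — the smeared model is a low-resolution
equivalence, not an identity.

## Parameters, constraints and derivatives

A `ParameterMap` is a bijection between refinable quantities and the
refinement vector.  Every model quantity owns a linear gather
[(index, coeff), …] over the free vector: a free parameter one (i, 1)
entry, a fixed parameter none, a riding hydrogen its parent's positional
indices with coefficient 1, a shared-ADP member its group leader's
indices, and an eliminated occupancy (occupancy-sum constraint) minus its
partners' indices.  The same chain is used in both directions — folding
derivative contributions onto leader columns and distributing solved
shifts back onto followers — so constraints are exact, not penalised.

Derivatives of Yc are analytic for coordinates (2πi·Rᵗh phase factors),
u_iso, the six Uij, occupancies and the scale.  Shape magnitude,
declination and azimuth use a five-point central difference on the shape
factor only (steps 1e-5 Å / degrees): hand-deriving Bessel-term
derivatives buys nothing measurable and is error-prone; the finite
difference is itself validated against an independent two-point stencil of
the full Yc to a relative 1e-5.

In P1 (and other polar directions) the phase origin is undetermined and
uniform translation is an exact null direction of the normal matrix; the
engine surfaces this as a singular-pivot error naming the coordinates
involved.  Fixing one atom's coordinates (`--fix-origin`, or a `Fix`
constraint) is the supported anchor.

## Restraints

* DISTANCE/ANGLE: absolute targets; a distance involves at most six
  parameters, an angle nine.
* SAME: the first group is the target; its connectivity determines the
  restrained pairs — every 1-2 bond and every 1-3 (angle-defining,
  non-bonded) pair — and each mapped group contributes one equivalence per
  pair, tying its value to the target's.  Angle equivalences are realised
  as 1-3 distance equivalences, which are uniquely determined once the 1-2
  equivalences are present.  Mirror mappings are expressed by listing the
  mirror-permuted atom order as a mapped group, and duplicates arising
  from mirror self-maps are retained (one equation each).  For the
  two-pyridine fixture the scheme is four mapping lines — second ring onto
  the first, mirrored first onto the first, mirrored second onto the
  first, and mirrored second onto itself — each contributing 6 + 6
  equations for the 6-ring: 48 in total.  This counting convention is
  asserted by test.
* SIMU: component-wise Uij differences (six equations per pair; isotropic
  members are promoted to their equivalent tensor, with the chain rule
  back to u_iso).  One group restrains all pairs within it; two paired
  groups restrain corresponding members.
* DELU: the rigid-bond equation Δ = z̄ᵗU_A^cart z̄ − z̄ᵗU_B^cart z̄ with
  target 0, where z̄ is the unit Cartesian bond vector.  Both the ADP and
  the positional dependence (through the bond direction) carry analytic
  Jacobians.
* Asymmetric behaviour: the reference group's Jacobian entries are masked
  to zero before accumulation.  The reference's *current* values are
  re-read every cycle, so it guides the dependent group without ever being
  pulled itself.  This is a masking formulation chosen for its simplicity
  and exact one-sidedness; it makes the least-squares problem mildly
  inconsistent (the masked rows no longer derive from a single objective),
  which is harmless in practice because the reference is well determined
  by the data.
* Shift-limiting (LIMIT σ): one equation per free parameter with residual
  0 and weight 1/σ², exactly additive Levenberg-style damping of the
  normal-matrix diagonal; σ→∞ is a no-op.  Damping is off by default —
  shift limiting is the sanctioned brake for oscillating refinements, not
  a hidden default.

Default σ values: distances 0.01 Å, 1-3 equivalences 0.02 Å, angles 1°,
SIMU 0.04 Å², DELU 0.01 Å² — conventional small-molecule values, all
overridable per line in the restraint file.

## Hydrogens

Geometric placement covers sp¹ (linear continuation), sp² (external
bisector in the substituent plane; terminal CH₂ at ±60° about the bond),
and sp³ (tetrahedral completion for CH; staggered CH₂ about the
bisector-normal plane; CH₃ staggered at 60° + k·120° from a reference
substituent, falling back to a documented default torsion with a warning
when no reference exists).  Default X-H lengths are 0.95 Å (sp¹/sp²) and
0.98 Å (sp³); u_iso multipliers 1.2, or 1.5 for methyl.  An optional
separate pass refines only H positions against the data under soft X-H
distance restraints (default σ 0.02 Å) and 1-3 distance restraints to the
parent's neighbours (σ 0.04 Å) frozen at the placed geometry; afterwards
the riding model takes over.  Riding chains are refused (an H cannot ride
on a rider).  Heteroatom H placement from difference maps is not
implemented.

## The engine

Per cycle: structure factors and design rows are computed for reflection
batches (default 256); each batch block B updates N += BᵗWB and
g += BᵗW(Yo−Yc) in double precision, making the result independent of the
batch size to 1e-10.  Restraint rows are so sparse that they are
accumulated one by one as rank-1 updates of the touched sub-block only.

Before solving, N is scaled to unit diagonal: Cᵢᵢ = 1/√Nᵢᵢ, N' = CNC,
recovery N⁻¹ = C N'⁻¹ C.  Zero-diagonal parameters are flagged
undetermined and excluded with zero shift.  The solve is scipy's LDLᵗ
(Bunch-Kaufman diagonal pivoting); a pivot block below 1e-10 of the
largest raises a singular-matrix error naming the offending parameters.
The alternative `eigen_filter` solver discards eigenvalue contributions
below 1e-8 × λ_max (a pseudo-inverse), always returns finite shifts, and
leaves exactly-null combinations unshifted.

Shifts are applied through the constraint chains; riding u_iso values are
re-derived.  Convergence: max |shift|/esd < 0.01 (default) within 20
cycles, or all shifts absolutely negligible (< 1e-8), which covers
noiseless data where M reaches the numerical floor and the shift/esd
ratio becomes ill-posed.  Divergence is declared after three consecutive
relative rises of M.  esd(pᵢ) = GoF·√((N⁻¹)ᵢᵢ) with GoF computed over
data and restraints jointly; with w = 1/σ² and well-calibrated σ this
makes the esds directly interpretable (the noisy-recovery test finds
≥95 % of parameters within 3 esd of truth across 20 seeds).

Condition diagnostics report λ_max/λ_min of N' (∞ if λ_min ≤ 0) and, for
the k smallest eigenvectors, the largest-|component| parameter labels —
the near-collinear combination.  On the two-same-site-occupancy fixture
the flattest direction is the occupancy *transfer* mode (opposite-sign
loadings on the two occupancies: raising one while lowering the other
leaves Fc almost unchanged), and adding the occupancy-sum constraint
improves the condition number by about four orders of magnitude.

## Synthetic data

The generator emulates an idealised diffraction experiment: a full hkl
sphere to d_min, Yo = |Fc|²(1 + ν·ε) with ε ~ N(0,1) at a fixed seed, and
σ = ν|Fc|² floored at 1e-6.  ν = 0.02 (2 % intensity noise) is the default
"realistic" quality for the recovery experiments, with d_min = 0.9 Å;
ν = 0 gives exact data for convergence and identity tests.  The GoF of the
true model against generated data is 1 within χ² sampling error, which is
what makes the esd-calibration test meaningful.  Deliberately absent:
Poisson counting statistics, absorption, extinction, twinning, scan
profiles, and any resolution-dependent error model — so passing tests
demonstrate the correctness of the estimator and its error model under
Gaussian multiplicative noise, not robustness to real diffractometer
systematics.  Fixtures use P1 cells so that symmetry handling stays
orthogonal to the numerics tests; one P2₁/c random-structure fixture
exercises the symmetry summation (verified through its 0k0, k odd
absences).

Problem sizes used by the test suite and the acceptance script — six-atom
random structures (~25-30 free parameters, 2-3.5×10³ reflections), 20
noise seeds for the calibration experiment — were chosen so the whole
pipeline re-runs from scratch in seconds while keeping every statistic
comfortably away from small-sample ambiguity.

## Known limitations

* The minimal CIF dialect has no save frames or multi-block support; it is
  sufficient for the package's own round trips, and gemmi reads its output.
* Occupancy-sum and shared-ADP constraints are linear eliminations; no
  general linear-combination constraint language is exposed.
* The asymmetric-restraint masking is one specific formulation of
  one-sidedness (see above).
* Torsional (rotating-methyl) riding refinement and difference-Fourier H
  location are out of scope.
* Condition diagnostics use a full eigendecomposition — fine at small-
  molecule sizes, not tuned for thousands of parameters.
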