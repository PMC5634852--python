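# Methods

## The model

`wntemt` implements a three-variable ordinary-differential-equation model of
the epithelial–mesenchymal transition (EMT) driven by canonical Wnt
signaling.  The state is the concentration of membrane-bound E-cadherin
(`E`), free cytosolic β-catenin (`B`) and the transcription factor Slug
(`S`); the input is the level of membrane-bound Dishevelled (`D`, written
`Dvl`), which rises when Wnt ligand binds Frizzled and which inactivates the
GSK-3β/Axin degradation complex.  In nM and minutes:

    dE/dt = α₁ / (1 + (S/IC_S)^n₁) − β₁·E
    dB/dt = α₂ − k₁·h(E/IC_E, n₂) − (β₂·B − k₀·h(D/IC_D, n₄))
    dS/dt = α₃ + k₂·h(B/IC_B, n₃) − β₃·S

with the Hill activation `h(x, n) = xⁿ/(1+xⁿ)`.  Slug represses E-cadherin
transcription; E-cadherin sequesters β-catenin at the membrane; β-catenin
translocates to the nucleus and induces Slug.  The loop's sign product
(S ⊣ E)·(E ⊣ B)·(B → S) is positive, and together with the ultrasensitive
Hill exponents (n₁ = 3, n₂ = n₃ = 2, n₄ = 5) this makes the circuit a
candidate bistable switch: an epithelial attractor (high E, low B and S) and
a mesenchymal attractor (low E, high B and S) can coexist.

Model simplifications worth keeping in mind: sequestration and degradation
of β-catenin are single lumped first-order-style terms (binding is assumed
much faster than unbinding in both the adhesion and the degradation
complex); Dvl enters only as a level, not via receptor dynamics; there is no
cell–cell coupling, no transcriptional delay, and no intermediate (partial)
EMT state.

Nondimensionalization divides each species by its half-maximal constant
(ε = IC_E, λ = IC_B, σ = IC_S, δ = IC_D) and time by T = IC_B/k₁ — the time
to accumulate half the Slug-activating β-catenin level at the
sequestration-limited rate.  This collapses the 13 kinetic constants to 8
grouped ones:

    de/dτ = A₁/(1+s^n₁) − C₁·e
    db/dτ = A₂ − h(e, n₂) − (C₂·b − F₁·h(d, n₄))
    ds/dτ = A₃ + F₂·h(b, n₃) − C₃·s

with A₁ = α₁·IC_B/(k₁·IC_E), A₂ = α₂/k₁, A₃ = α₃·IC_B/(k₁·IC_S),
Cᵢ = βᵢ·IC_B/k₁, F₁ = k₀/k₁, F₂ = k₂·IC_B/(k₁·IC_S).

## Reference parameters and the rounding question

The package ships the reference constants as YAML fixtures.  The dimensional
set (`table1.yaml`) maps exactly to loss rates C₁ = C₂ = C₃ = 0.99, while
the published nondimensional set rounds these to 1.  Both are shipped
(`table2_exact.yaml` and `table2.yaml`); all headline results (steady
states, the switching threshold, region maps) use the rounded `table2`
values, which is what the reported numbers correspond to.  The
frame-equivalence tests use `table2_exact`, for which dimensional and
nondimensional trajectories coincide to integration tolerance after
rescaling.

Negative concentrations: the β-catenin equation's sequestration term is not
proportional to B, so db/dτ < 0 is possible at b = 0 and the equations admit
fixed points with b < 0 (this happens for A₂ < 1, which is why the
sensitivity ranges start at A₂ = 1 / α₂ = 0.01).  The right-hand sides are
evaluated verbatim — no clamping — and every state, trajectory and
equilibrium carries a `nonphysical` flag when a component is negative.
The analytic Jacobian refuses negative states (x^(n−1) is not meaningful
there for the model's intent); stability of flagged nonphysical fixed
points falls back to a central-difference Jacobian of the verbatim
equations.

## Equilibria: the scalar reduction

At a fixed Dvl level the E-cadherin and Slug equations give their steady
values explicitly in terms of b:

    s*(b) = (A₃ + F₂·h(b, n₃)) / C₃,   e*(b) = A₁ / (C₁·(1 + s*(b)^n₁)),

leaving the scalar residual

    g(b) = A₂ − h(e*(b), n₂) − C₂·b + F₁·h(d, n₄)

whose zeros are exactly the system's fixed points.  `find_equilibria` scans
g on a dense grid (default 10,001 points over [−0.5, A₂/C₂ + F₁/C₂ + 0.5];
the lower bound deliberately extends below 0 so nonphysical fixed points are
found and flagged, never dropped), bisects every sign change to
|g| < 10⁻¹² with one Newton polish, reconstructs (e, b, s), and classifies
stability from Jacobian eigenvalues.  Roots closer than 10⁻⁶ in b are merged
and flagged `near_fold`.  Because both saturating terms vary on the
b-scale ~1 (IC_B dimensionally), the dense grid covers 25 such scales and a
coarse 512-point tail extends to the bracket edge, where g is strictly
decreasing and can hold at most one further root — this matters for sampled
parameter sets with very small loss rates, whose brackets stretch far out.

The same reduction applies verbatim to the dimensional frame and is what
makes the sensitivity analysis cheap.  It is cross-checked in the test suite
against an independent multi-start damped-Newton search of the full 3-D
system (100 random parameter draws from the published sampling ranges;
identical equilibrium counts and states to 10⁻⁸).

Phenotype labels: when two stable states coexist, the higher-e one is
epithelial and the lower-e one mesenchymal.  A unique stable state is left
unlabeled at a single Dvl level; branch continuation (below) labels it.
An exact E-cadherin tie raises an error rather than guessing.

## Time integration

Trajectories use SciPy's LSODA (stiff-capable, adaptive) with relative
tolerance 10⁻¹⁰ and absolute 10⁻¹² by default; the system is only mildly
stiff near the fold, and these settings keep the hysteresis-memory checks
(return to the epithelial point within 10⁻⁶ after a sub-threshold pulse)
well inside tolerance.  Dvl protocols are piecewise constant and
right-continuous; the integrator restarts at every switch time so the
discontinuity never crosses a solver step.  Output is sampled on a uniform
grid (2,000 points by default).

`steady_state` integrates in growing chunks until ‖rhs‖∞ < 10⁻⁹, with a
time cap of 10⁴ τ-units (scaled by T in the dimensional frame), an error on
non-convergence, and a distinct error if the residual plateaus while the
state keeps moving (a periodic orbit — not expected for this monotone
circuit, but detected rather than silently looped on).

## Bifurcation analysis

Branches against d are traced by grid scanning with nearest-state linkage
(relative metric, so the e ≈ 10 and e ≈ 0.08 branches both weigh in),
ambiguous linkages resolved by local grid refinement, and identities
assigned from the d = 0 ordering.  Folds are located by bisection on the
equilibrium count to |Δd| < 10⁻⁴ and cross-checked by requiring a merging
root pair (g′ → 0) just inside the bistable side.  This is deliberately not
pseudo-arclength continuation: with an exact scalar reduction the
grid-plus-bisection approach is simpler, robust, and accurate to the stated
tolerance.  For the reference parameters the bistable window is one-sided:
the mesenchymal state survives down to d = 0 (L1 absent, window clipped at
0) and the epithelial branch is lost at L2 ≈ 1.333.

Region maps vary one nondimensional parameter against d and label each grid
cell by the count of stable physical (b ≥ 0) equilibria: two = Region II
(bistable).  Monostable cells in a row that has a bistable interval are
labeled I or III by which side of the interval they lie on.  Rows with no
bistable cell are labeled by branch continuation — the cell's unique stable
state is matched (relative state-space distance) against the
epithelial/mesenchymal pair of the nearest bistable cell, preferring the
same d column — so labels stay consistent where the absolute E-cadherin
scale changes with the parameter; no fixed concentration threshold is ever
applied.  A map with no bistable cell anywhere and no bistable anchor at
the unvaried parameters raises an error rather than guessing.  Default
grids are 400 d-points over [0, 6] and 200 y-points over the published
sampling range of the varied parameter; Hill-coefficient panels use [1, 8].
More than two coexisting stable states would violate this model class and
raise an error with the offending parameters.

## Sensitivity analysis

Latin hypercube sampling draws each parameter uniformly from its published
range (one draw per equal-probability stratum, columns independently
permuted; built on `scipy.stats.qmc.LatinHypercube`), under the constraint
N > (4/3)·K — for the 13 dimensional parameters at least 18 strata.  The
default is N = 10⁴ strata, a deliberate scale-down from the 10⁵ used for
the published analysis; the halving test (10⁴ → 5·10³) shows the strong
coefficients stable to < 0.05, so 10⁴ is comfortably converged for the
questions asked here.  Hill coefficients are never sampled (they are the
ultrasensitivity knobs, explored separately in the region maps) and Dvl is
fixed per analysis (D ∈ {0, 4} dimensionally, d ∈ {0, 6} nondimensionally).

Each sample row is solved with the scalar reduction; when the row is
bistable the epithelial-basin state is selected by a short integration from
epithelial initial conditions (e = 10 equivalent, i.e. E = 10·IC_E) and
nearest-in-b assignment.  Rows with negative components are flagged, not
dropped (the range restrictions α₂ ≥ 0.01, A₂ ≥ 1 are what keep them rare);
rows that fail to resolve are excluded from the correlation step with a
logged count.

Two rank statistics are provided:

* `method="partial"` (default): the partial rank correlation coefficient
  (PRCC) — rank-transform all columns, regress out the other parameters'
  ranks from both the parameter and the output, and correlate the
  residuals.  p-values use the large-sample t statistic
  ρ·√((N−2−g)/(1−ρ²)) with g controlled parameters.  No multiple-testing
  correction is applied; the fixed effect-size threshold |ρ| > 0.45 (with
  p < 0.05) does that job.
* `method="simple"`: the plain rank (Spearman) correlation with the same
  significance rule.

The distinction matters for the Wnt-on/Wnt-off contrast.  Partial
correlations concentrate essentially all of a monotone dependence into the
responsible parameter, so with these ranges the Slug-induction rate is
already far above the 0.45 threshold at zero Dvl (the baseline
epithelial-basin β-catenin is not small for most draws: b* ≥ (A₂−1)/C₂ with
C₂ allowed near 0).  Under the simple rank statistic, which dilutes each
parameter's signal by all the others' variance, the induction-rate
coefficients sit just below the threshold at zero Dvl and cross it when Dvl
turns on — the "gains significance upon Wnt activation" structure.  The
acceptance suite therefore checks the headline negative coefficients
(β₂ → B, β₃ → S) with standard PRCC and the on/off significance-set
contrast with the simple statistic; both tables are one keyword apart.

The monotonicity screen (binned-median monotonicity per parameter–output
pair, 20 quantile bins, 2% noise tolerance) verifies the precondition of
rank-correlation analysis; extending the A₂ range into [0, 1) demonstrably
breaks it for e and s, which is the documented reason that range starts
at 1.  The input-independence check computes all pairwise partial rank
correlations among sampled columns (< 0.05 at N = 10⁴; a null simulation at
N = 20, K = 4 puts the small-design spread an order of magnitude wider,
so small designs cannot certify independence).

## What the fixtures emulate — and what they do not

There are no external datasets: every input is either a published constant
(the parameter tables, the sampling ranges, the pulse protocols d = 1.2 and
d = 5.4 switching at τ = 20 and 50) or generated by the toolkit.  Passing
tests therefore demonstrate internal correctness and reproduction of the
model's reported behavior — bistability, the ≈1.33 switching threshold,
one-sided hysteresis, the sensitivity structure — not agreement with
measured biology.  In particular the parameter values are order-of-magnitude
estimates, concentrations are well-mixed single-cell averages, and nothing
here constrains spatial organization, cell–cell adhesion dynamics or
partial-EMT states.

## Problem sizes

Defaults were chosen so the whole suite runs on a laptop in a few minutes:
equilibrium scans 10,001 points (4,001 inside the sensitivity loop, where
roots are re-polished to 10⁻¹² anyway), branch sweeps 150–300 d-points,
region-map tests ~30×60 grids, sensitivity N = 10⁴.  All are arguments, not
constants.

## Known limitations

* The fold locator assumes the count changes by a simple saddle-node; a
  codimension-2 degeneracy inside a bracket would be reported as a failed
  cross-check, not resolved.
* Basin selection integrates for a finite horizon (200/min(C) capped, with
  three extensions); a draw sitting almost exactly on the separatrix can in
  principle be mis-assigned, which for rank statistics at N = 10⁴ is
  inconsequential but would matter for per-row guarantees.
* Rank-based sensitivity only detects monotone effects — the monotonicity
  screen is a precondition, not a formality.
* `label_phenotype` relies on E-cadherin ordering between coexisting stable
  states; circuits with a different reporter ordering would need a
  different rule.
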