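# Methods

## Model

The structural connectome of each subject enters as a symmetric, weighted,
zero-diagonal adjacency matrix **A** (90 nodes in the reference atlas;
weights on a dimensionless 0–1, quantitative-anisotropy-like scale, with
edges below a configurable threshold, default 0.001, set to zero). Regional
activity is modelled by a noise-free linear time-invariant system

    x(t+1) = A x(t) + B_K u_K(t)

with control inputs injected at the node set K. The raw matrix generally
has spectral radius ≥ 1, so all controllability computations use the
stabilized matrix **A**/(c + σ_max(**A**)) with offset c = 1 (configurable).
This scaling is the standard convention in the network-control literature;
it guarantees convergence of the controllability Gramian and makes the
modal bounds provable. For continuous-time energy computations the
identity is subtracted, placing all eigenvalues strictly in the left half
plane.

### Controllability metrics

*Average controllability* of node k is Trace(**W**_k) of the single-node
Gramian **W**_k = Σ_τ **A**^τ e_k e_kᵀ **A**^τ. Because Trace(**W**_k) =
Σ_τ ‖**A**^τ e_k‖², the vector of all per-node traces is the diagonal of
the solution X of one discrete Lyapunov equation X = **A**ᵀX**A** + I,
which we solve directly (Bartels–Stewart via SciPy) rather than by series
truncation: exact to linear-algebra tolerance and one solve for all nodes.
The truncated series survives in the test suite as an independent oracle.
Every value is ≥ 1 (the τ = 0 term), with equality for an isolated node.

*Modal controllability* is φ_i = Σ_j (1 − λ_j²) v_ij² over the eigenmodes
of the stabilized matrix (symmetry gives a real eigensystem with
orthonormal eigenvectors, hence 0 < φ_i ≤ 1). The eigenvalues in this
formula are taken from the *stabilized* matrix: with raw eigenvalues the
weights 1 − λ² could go negative and the quantity loses its
interpretation.

Whole-brain values are arithmetic means of the regional vectors, and
regional normalization ("z-scoring" across nodes) uses the sample (n−1)
standard deviation.

### Control energy

Transitions start at the resting baseline x(0) = 0 and end at the
activation state of one functional network (1 on member nodes, 0
elsewhere). The cost is the Hamiltonian H = xᵀx + uᵀu + pᵀ(**A**x + **B**u);
stationarity in u gives u* = −½**B**ᵀp and the state/costate pair evolves
as the linear system

    d/dt [x; p] = [[A, -BBᵀ/2], [-2I, -Aᵀ]] [x; p]

(the −2I block is absent when the state cost is toggled off, reducing the
problem to the classical minimum-energy transition, for which the
closed-form Gramian solution exists and is used as a validation oracle).
The boundary conditions are imposed through the block matrix exponential
over [0, T]: p(0) comes from a single linear solve, so the solver is
deterministic — no shooting iteration. A singular boundary map (target
unreachable from the chosen control set) raises a solvability error, and
the reported endpoint error must stay below 1e−6.

Per-node energies E_k = ∫₀ᵀ u_k(t)² dt are computed by the trapezoidal
rule on a uniform grid. The quadrature error is O(Δt²): at the default
n_grid = 1001 the energies agree with closed forms to ~1e−6 relative,
which is why validation tests against exact Gramian values use a 1e−5
tolerance rather than machine precision.

Defaults: horizon T = 1 (dimensionless), n_grid = 1001, all nodes
controlled (**B** = I, matching per-node energy maps), state cost on. The
horizon, grid, relative weighting of state and input costs, and control
set are genuinely open modelling choices — no published value constrains
them — so all are configurable and the validation properties are checked
at multiple horizons.

### Null models

Surrogates preserve the binary degree sequence exactly (Maslov–Sneppen
double-edge swaps, default 10 swaps per edge) and the edge-weight multiset
exactly; node strengths are approximated by reassigning weights in
descending order to the free rewired edge whose endpoints have the largest
residual original strength. On sparse modular networks the surrogate
strength sequence rank-correlates with the original above 0.9. Real
versus null activation energy is summarized both by a paired two-sided
t-test across surrogates and by the empirical percentile of the real value
in the surrogate distribution — small ensembles make the t-test fragile,
so both are always reported. The direction of the difference (real brains
cheaper to drive than nulls) is a data finding, reported but never
asserted by the test suite.

### Statistics

Group comparisons residualize the outcome on an intercept plus the
confound design — sex, brain volume, and three motion summaries by
default; network strength and density can be added for sensitivity
analyses — then apply a pooled-variance two-sample t-test
(df = n₁ + n₂ − 2) to the residuals, with Benjamini–Hochberg FDR across
regions. Development rates are Pearson correlations between a metric and
postmenstrual age within a scan window. Two rates are compared with the
Fisher r-to-z statistic for *independent* correlations; this is the
default even for the birth-vs-TEA comparison within the longitudinal
preterm group, because arithmetic on published summary statistics matches
that formula, and the one-sided normal tail reproduces published p-values
(e.g. z = 2.92 → p = 0.0017). A dependent-correlation variant
(Raghunathan–Rosenthal–Rubin/Pearson–Filon) is provided for users with
raw data; it needs the cross-correlations among all four variables. Note
that published energy group tests carry df = 518 where the controllability
tests carry 519 at the same group sizes — one subject or degree of freedom
is unexplained there; this package always reports the exact df of the data
it is given.

## Synthetic cohorts

The generator emulates the gross features of neonatal connectomes:
8 contiguous modules aligned with the canonical functional networks
(p_within = 0.7, p_between = 0.15, overall density ≈ 0.2), log-normal
weights (log-mean −2.3, log-sd 0.5, clipped to ≤ 1), ~15% hub nodes with
gain 2.0 spread across modules, multiplicative log-normal weight noise
(sd 0.2), and two injected effects:

- **age trend** — hub gain scales by (1 + 0.05·(PMA − 28)) per week; all
  random draws happen before this deterministic scaling, so for a fixed
  seed the injected trend is monotone in age;
- **preterm deficit** — edge weights incident to 10 designated non-hub
  nodes are attenuated by a factor 0.7 for preterm subjects at both scans.

The deficit magnitude was fixed at design time so that the injected effect
sits at a clearly detectable operating point for the recovery suite
(10 affected nodes, 60 subjects per group, FDR q = 0.05): a 30% attenuation
of regional connectivity, within the range of white-matter alterations
reported for preterm cohorts, yields near-ceiling sensitivity, whereas a
20% attenuation is marginal at that sample size.

Cohorts mirror the reference study design: term subjects scanned once in
the 37–44-week window, preterm subjects scanned at 28–36 weeks (birth,
GA = PMA − 3) and again at 37–44 weeks. Motion summaries, brain volume
(≈ −600 + 25·PMA mL), and optional 18-month developmental outcome scores
are drawn from group-level distributions. Defaults are *not* calibrated to
any real dataset — edge-level summaries of the reference cohort are not
public — so passing recovery tests demonstrates that the pipeline detects
effects of this kind and size under these noise assumptions, not that it
would reach the same sensitivity on real data. The generator also does not
emulate spatial embedding, distance-dependent connectivity, or
subject-level topological fingerprints.

## Pipeline and problem sizes

`run_all` executes: profiles → development rates (windows and Fisher-z
comparisons, whole-brain and regional) → group tests → network energies →
energy group tests → null comparisons → outcome correlations, writing one
TSV/JSON per table plus a manifest of config, version, and output hashes.
All randomness flows from the config seed, and reruns are byte-identical.
Null-model comparisons are run on the first `nulls.n_subjects` records
(default 5): each surrogate costs a full set of eight boundary-value
solves, and an ensemble per subject is rarely informative beyond a sample
of subjects. The test suite and the acceptance script use cohorts of
60–120 records with 4–20 surrogates, sizes at which the full pipeline
completes in about a minute on one CPU; the defaults scale linearly in
records × surrogates.

## Known limitations

- Linear dynamics only; no nonlinear neural-mass models.
- Single-node control sets for the controllability metrics (the model's
  B_K(t) generality is not exercised); full control set for energy.
- No spatially embedded null models (distance-preserving surrogates).
- The independent-correlation z-test applied to longitudinal windows
  ignores within-subject dependence; the dependent variant is available
  when raw paired data exist.
- Asymmetric matrices are rejected, never auto-symmetrized; an explicit
  `symmetrize` utility exists for users who accept the repair.
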