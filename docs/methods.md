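# Methods

## Model and assumptions

`dimernet` treats a protein family as a competitive dimerization network:
`m` monomer species, a set of pairwise association edges (homodimers
allowed), and one dimensionless equilibrium constant `K_ij` per edge.
Only monomers and dimers exist — no trimers or higher-order complexes, no
DNA binding, localization, or post-translational modification. Binding is
detailed-balanced, so the equilibrium is unique and there is no
multistability. Concentrations are dimensionless; the system is invariant
under rescaling all totals by `k` and all affinities by `1/k`, and the
convention throughout is that one dimensionless unit corresponds to 1000
molecules in a 3 pL cell (so the floor 1e-3 is one molecule per cell, and
1 molecule ≈ 5.5e-13 M).

## Equilibrium solver

The equilibrium conditions — mass action `D_ij = K_ij M_i M_j` plus
conservation of each monomer's total — reduce to an `m`-dimensional root
problem in log free-monomer coordinates `x_i = log M_i`:

    r_i(x) = e^{x_i} + 2 K_ii e^{2 x_i} + Σ_{j≠i} K_ij e^{x_i + x_j} − T_i = 0.

`r` is the gradient of the strictly convex potential
`Φ(x) = Σ e^{x_i} + Σ K_ii e^{2x_i} + Σ_{i<j} K_ij e^{x_i+x_j} − Σ T_i x_i`,
so a damped Newton iteration with a backtracking Armijo line search on `Φ`
converges globally to the unique minimum; once the relative residual drops
below 1e-2 the iteration switches to undamped Newton steps (the quadratic
convergence region), because near the optimum `Φ` differences fall below
float resolution and an Armijo test would stall. Newton steps are capped
at 10 log units per component to keep `exp` in range. Defaults: start at
`x_i = log T_i`, relative conservation tolerance 1e-9, 200 iterations.
Monomers with total exactly zero are removed from the solve and reported
as exactly zero together with their dimers, avoiding log-domain
singularities. The kernel is numba-compiled; titrations warm-start each
grid point from the previous solution.

The single-edge closed forms used as oracles are written in cancellation-
free form: the pair discriminant is expanded as
`(T_A−T_B)² + q² + 2q(T_A+T_B)` with `q = 1/K` (the naive `b² − 4T_AT_B`
loses all precision when `T_A ≈ T_B` and `q` is tiny), and each free
concentration is taken from its own quadratic on the branch that avoids
subtraction, which matters when >99% of a monomer is sequestered.

An independent cross-check used by the tests minimizes `Φ` directly with
scipy's `trust-exact` trust-region method (analytic gradient and Hessian,
followed by a short Newton polish); solver and minimizer agree to a
relative 1e-6 on random networks up to m = 6.

## Random networks and parameter screens

Random topologies are connected Erdős–Rényi draws: `n_hetero` heterodimer
edges (admissible range `m−1 .. m(m−1)/2`), redrawn until connected
(retry cap 1e5), plus an independent homodimer loop per monomer with
probability 0.75 — the fraction observed in natural bZIP/nuclear-receptor
networks. Affinities are log-uniform Latin-hypercube samples, one stratum
per edge along the exponent axis (default screen range 1e-5..1e7, chosen
so the strongest affinity dimerizes ≥99% of monomers at the lowest
expression level and the weakest ≤1% at the highest; a restricted range
1e-3..1e1 and a versatility range 1e-7..1e5 are also provided). Expression
levels are LHS log-uniform on 1e-3..1e3. Screens stratify evenly over the
admissible edge counts of each size — the allocation that makes a nominal
1e6-network screen of 8-monomer networks actually 22 × 45,455 = 1,000,010.
By convention the input monomers are the lowest indices; their sampled
totals are placeholders overridden by the titration.

## Responses, discretization, expressivity

One-input responses are equilibria over 30 log-spaced input totals on
1e-3..1e3; two-input responses use 12 points per axis. Outputs are floored
at 1e-3 and dimers whose floored max/min ratio is not strictly greater
than 10 are discarded as non-responsive. Surviving responses are
discretized on decade bins with edges 1e-3, 1e-2, ..., 1e3: within each
input decade (5 titration points, or 2×2 for two inputs) the floored
response is averaged in log space and the mean assigned to an output
decade. Bins are half-open `[10^k, 10^{k+1})` with the top edge closed;
means landing exactly on an edge go to the upper bin. On the default
grids no titration point falls on an interior bin edge (the 30-point
exponents `−3 + 6k/29` are never integers for interior `k`), so the tie
rule never fires in practice. Local extrema of a one-input response are
counted as strict sign changes of successive differences of the floored
log response after merging equal-value plateaus.

Expressivity is the number of distinct codes across a screen. The
two-output census counts distinct unordered code pairs co-occurring
within a network and compares them to a scrambled control that draws the
same number of pairs, with replacement, from the pooled codes.

Target libraries group screened responses by code and average each group
pointwise in log space; because every member's per-bin log mean lies in
the same output decade, each library target re-discretizes exactly to the
code it represents.

## Optimization

**Dual annealing** (scipy `dual_annealing`, seeded) asks whether *any*
network of size `m` can perform a target. The candidate topology is fully
connected including homodimers — `m(m+1)/2` affinities plus the accessory
totals, all in log10 space (affinities 1e-5..1e7, totals 1e-3..1e3).
For function targets the objective is the best dimer's sum of squared log
residuals, and success means a Chebyshev loss `L_inf ≤ 1` — within
10-fold of the target at every titration point, the same 10-fold
tolerance used for versatility. For Boolean targets the gates are
evaluated on four levels per input (1e-3, 1e-1 "off"; 1e1, 1e3 "on");
the objective maximizes the log margin `min(on) − max(off)` of the best
dimer, while success is judged by the strict criterion that the highest
"off" response lies below the lowest "on" response. The margin surrogate
is a package choice: the strict rule itself is a 0/1 criterion with no
gradient signal, and the margin is the quantity the rule thresholds.
Equilibria that fail to converge score a large finite loss rather than
raising. Minimal network size is found by scanning sizes downward,
several seeds per size, stopping at the first size where every attempt
fails; with the default budget (5000 objective evaluations) the
four-monomer inverted-bump exemplar is recovered at m = 4 while m = 3
fails across all seeds.

**Genetic algorithm.** Versatility fixes the affinities and tunes only
accessory expression levels (log10 box 1e-3..1e3), minimizing the mean
squared log error; fit quality is then judged by `L_inf ≤ γ = 1` for
one-input targets or a Pearson correlation ≥ 0.85 for two-input targets
(the Chebyshev rule is needlessly strict in two dimensions, where a
one-bin shift can exceed the tolerance everywhere). The GA is implemented
in-package and seeded: binary tournament selection, simulated binary
crossover (probability 0.9, η = 15), polynomial mutation (rate 1/d,
η = 20), elitist (μ+λ) truncation survival; defaults are population 100 ×
20 generations for one-input targets and 1000 × 200 for two-input
targets. Per-dimer versatility `V_m(j, K)` is the fraction of library
targets dimer `j` achieves; any-dimer versatility `ν_m(K)` frees the
choice of output dimer per target, so `ν_m ≥ max_j V_m` by construction.

The named two-input target set renders seven Boolean gates (AND, OR,
NAND, NOR, XOR, XNOR, NIMPLY) as two-level log surfaces (+1 / −2 decades,
inputs "on" above 1), a ratiometric surface proportional to
`log(x1/x2)`, an equality band within one decade of the diagonal, and a
two-input bump high only when both inputs are mid-range. Because
two-input achievement is judged by Pearson correlation, which is affine
invariant, only the shapes of these idealized surfaces matter.

## Elementary network catalog

The fixture catalog holds minimal exemplars — switch-off (m=2), switch-on
(m=3), bump (m=3), inverted bump (m=4), NIMPLY (m=3), NAND (m=4),
two-input bump (m=5), XOR (m=6) — each with parameters derived here:
the switches, bumps and small gates from sequestration reasoning with
decade-rounded affinities, the XOR by annealing on its fixed
seven-edge topology (two input-sequestration edges, an M3–M4 pair, both
binding M5, an M5–M6 pair, and the D66 output homodimer). Expected
behavior is stored as a discretized code or truth table — never as exact
concentrations — and re-verified by simulation in the test suite.

## Kinetics

All associations share `kon = 5e5 M⁻¹s⁻¹` (single-transition-state
assumption, typical of designed coiled coils), i.e. 2.77e-7 per molecule
per second at 3 pL; dissociation rates are log-uniform on 1e-4..1 s⁻¹,
implying `K = kon/koff` and spanning K_D ≈ 200 pM – 2 µM. Abundances are
log-uniform on 1..1e6 molecules per cell. ODEs are integrated with
scipy's LSODA at rtol 1e-8 / atol 1e-6 molecules; fixed 10 s increments
are the *sampling* grid, not the integration step. Relaxation runs start
from the equilibrium at input = 1 molecule, jump the input's free pool to
1e6 molecules, and record per-species equilibration as the first sample
time after which the species stays within 1 molecule of the exact new
equilibrium (cap 1e7 s).

Oscillating inputs follow a sinusoid in log10 of the total (1..1e6
molecules); the log-space sinusoid is a package choice matching the
multiplicative concentration scale. At each sampling step the input's
free pool is adjusted instantaneously to meet the prescribed total
(removal is limited to the available free molecules), then the ODEs are
integrated to the next step. The sampling step is `period/200`, floored
at 10 s — so fast oscillations are sampled at the 10 s increments, while
a 27 h period uses ~8 min steps (0.5% of the period). A dimer counts as
*changing* when its instantaneous-equilibrium concentration spans more
than 0.5 log units over the run, and as at quasi-equilibrium when its
dynamic trajectory stays within 0.5 log units (≈3-fold) of the
instantaneous equilibrium at every sample; both comparisons floor
concentrations at 1 molecule. Integration failures are counted and
reported, never silently dropped.

## Noise

Intrinsic noise uses an exact numba-compiled Gillespie kernel in molecule
counts. Propensities: heterodimer association `kon·n_i·n_j`, homodimer
association `kon·n_i·(n_i−1)` — the convention whose large-count limit
matches the deterministic rate `kon·M_i²` in these ODEs — and
dissociation `koff·n_D` (homodimer dissociation returns two monomers).
Trajectories start from the deterministic equilibrium rounded to integers
(no burn-in needed) and are sampled 100 times at 10 s intervals; the
noise coefficient is the temporal CV `η = std(n)/mean(n)` per species,
undefined (NaN) for zero-mean species. Integer conservation of every
monomer's total is exact along trajectories.

Extrinsic expression noise multiplies totals by gamma factors with mean 1
and CV `η` (shape `1/η²`, scale `η²`): independent draws per monomer
(η = 0.4) model gene-intrinsic noise, a single shared draw (η = 0.6)
models concerted extrinsic noise. In the robustness screen only accessory
totals are perturbed — the input totals are the scripted titration
variable, so perturbing them would conflate the function's argument with
its parameters. Robustness of a function is the log-space RMSD between
the original and perturbed floored responses over the titration grid; a
network per unique screened function is chosen at random and perturbed 50
times.

## Problem sizes

Full-scale screens (1e6 networks) and versatility matrices (50 networks ×
all dimers × full libraries) are cluster-scale; this package's tests and
acceptance script use reduced ensembles chosen to keep everything on one
CPU in minutes while preserving the qualitative regime: screens of
~100–1500 networks per size, quasi-equilibrium surveys of 10 networks per
size for m = 2..6, Gillespie surveys of ~2 networks per size for
m = 2..12, and robustness screens over the unique functions of a
~10,500-network screen. The expressivity census at this depth already
shows the strict growth with network size; absolute unique-function
counts, of course, grow with sampling depth and are not comparable across
scales.

## What the generator does and does not emulate

Random networks reproduce the *sampling design* of large-scale screens —
connectivity-stratified connected topologies, 75% homodimer incidence,
log-uniform LHS affinities and expression levels — not any measured
interactome: real dimerization families have correlated, structurally
constrained affinity matrices, expression levels far from log-uniform,
and shared-partner biases. Passing tests therefore certify the
computational framework (solver correctness, discretization, optimizer
behavior, noise statistics) under the stated random ensembles, not
quantitative predictions for a specific protein family.

## Known limitations

* Two-input discretization (2×2 points per cell) is a convention; other
  binnings would shift absolute expressivity counts.
* Dual-annealing success depends on the evaluation budget; the defaults
  reliably separate m = 3 from m = 4 on the inverted bump but harder
  targets may need larger budgets.
* The oscillation driver's instantaneous free-pool adjustment cannot
  remove more input than is free; during rapid downswings of a strongly
  sequestered input the realized total briefly lags the prescribed one.
* The gamma model is a stand-in for bursty expression; it reproduces the
  stationary CV, not temporal correlations of expression noise.
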