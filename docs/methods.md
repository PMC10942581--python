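# Methods

## The model

A signaling network is treated as a family of discrete memoryless
channels indexed by the cell state θ — the vector of per-cell biochemical
parameters (rate constants, protein totals) assumed stable on signaling
time scales.  For a finite dose grid u ∈ {L₁ … L_n} with input weights
p(u) and a parametric dose-conditioned response p(x|u,θ):

- **I(θ)** — the cell-state-dependent mutual information of one cell's
  conditional channel, in bits.
- **I_Cee = Σ_θ p(θ) I(θ)** — the conditional mutual information, the
  population mean of single-cell fidelities.
- **I_CSA** — the cell-state-agnostic MI of the pooled mixture channel
  p(x|u) = Σ_θ p(θ) p(x|u,θ).
- **p_CeeMI(I)** — the distribution of I(θ) across the population, and
  p_CeeMI(I, χ) its joint with a biochemical covariate χ(θ).
- **Interaction information** I_CSA − I_Cee ≤ 0 whenever cell states are
  statistically independent of the input (the experimenter chooses the
  doses; the states are intrinsic), so conditioning on the cell state can
  only reveal information hidden by population averaging.

Channel capacities of either objective are maxima over the input
probability simplex on the fixed dose grid.

## Numerical mutual information

Responses are modeled by two-moment parametric families — gamma for
protein abundances (shape = μ²/σ², scale = σ²/μ), Poisson for elementary
birth–death outputs, negative binomial for overdispersed mixtures — and
discretized onto a constant-width bin grid:

- bin width = 5% (`bin_frac`) of the smallest interquartile range across
  the dose-conditioned models;
- support = union of the central 99.95% (`coverage`) intervals of every
  model, anchored at the global lower truncation point (widened by half a
  count for discrete families so boundary integers fall inside);
- per-bin probabilities from CDF differences; rows renormalized after
  verifying the captured mass meets the coverage requirement.

Terms with p(x|u) = 0 or p(u) = 0 contribute zero to the MI sum; logs
are floored at 1e-300 inside the logarithm only.  On smooth gamma
channels halving the bin width moves MI by < 0.02 bits (tested), and the
binned toy-cell MI agrees with an unbinned Poisson pmf summation to
0.01 bits.

## Capacity optimization

Capacity is maximized with a trust-region constrained optimizer on the
simplex (Σp = 1, p ≥ 0) with the analytic gradient ∂I/∂p_u =
D(p(x|u) ‖ p(x)) − 1/ln 2, started from the uniform input plus five
Dirichlet(1) restarts (seeded), keeping the best optimum.  The same
routine maximizes any convex combination of per-channel MIs, which
covers both the pooled I_CSA objective and the per-cell-average I_Cee
objective (the latter is not a Blahut–Arimoto problem).  Blahut–Arimoto
serves as an independent test oracle for single-channel capacities
(agreement within 1e-4 bits on random channels; closed-form binary
symmetric channels within 1e-6).  Convergence is certified when the
optimizer reports success and the optimum is no worse than the uniform
input minus 1e-6; otherwise the result carries a diagnostic flag.

## Toy receptor population

Receptors are produced, degraded (kdeg) and bound reversibly (kbind,
kunbind) by ligand at concentration L; the bound count at steady state
is Poisson with mean μ_B = R0·L·kbind / (L·kbind + kdeg + kunbind).
Defaults follow the study conditions: kbind = 1 s⁻¹a.u.⁻¹,
kunbind = 10 s⁻¹; population 1 varies R0 (⟨R0⟩ = 500, kdeg = 5 s⁻¹
fixed), population 2 varies kdeg (⟨kdeg⟩ = 5 s⁻¹, R0 = 50 fixed), the
variable parameter gamma distributed with CV swept over
[10⁻¹·⁵, 10⁻⁰·⁵].  The ligand input is a discretized gamma (mean 10,
CV 1, 25 equal-mass slices).  Each slice is represented by its
conditional mean (centroid), which preserves the distribution mean
exactly; quantile-midpoint representatives are available as an option.
The pooled population response is a negative binomial carrying the exact
Poisson-mixture moments (closed form for variable R0, dense equal-mass
quadrature over the kdeg law otherwise).  Deterministic ensembles use
equal-weight gamma-quantile grids; sampled ensembles default to 500
seeded draws per CV.

At the lowest CV of the sweep the I_Cee − I_CSA gap is ≈ 0.10 bits, not
zero: with σ_R0 = 16 the between-cell variance is already comparable to
the Poisson noise at high doses.  An exact mixture-of-Poissons summation
oracle reproduces this value, and the unit tests assert it.

## Pathway models and moment closure

Both networks share a receptor core (production, reversible ligand
binding, reversible phosphorylation, degradation with preferential
endocytosis of the phosphorylated form at kdeg*); the FoxO network adds
receptor-catalyzed Akt phosphorylation and pAkt-catalyzed cytoplasmic
FoxO phosphorylation, with Akt and FoxO totals conserved.  The output is
total surface receptors (R+B+P) for EGFR and nuclear FoxO for IGF/FoxO;
without stimulation the nuclear fraction is kin/(kin+kef), calibrated to
2/3 of a 710-molecule total.  Unit conversion rescales fluorescence so
the zero-ligand surface-receptor mean is 2.5e5 (EGFR) or the
unstimulated nuclear FoxO mean is (2/3)·710 after background subtraction
and per-experiment offset equalization.

Per-cell response moments come from Gaussian moment closure: the
first/second-moment ODEs with third central moments set to zero.
Bilinear propensities retain the covariance term in the mean equation
(E[k x_i x_j] = k(μ_i μ_j + C_ij)).  The equations integrate from the
deterministic zero-ligand steady state (zero covariances except
Poisson-level variance on free receptors) in growing chunks until the
maximum relative derivative falls below 1e-8, capped at a 1e4 s horizon;
non-convergence or negative variances raise a diagnostic error rather
than returning silently.  p(x|u,θ) is the moment-matched gamma.  Exact
Gillespie simulation (numba-compiled direct SSA, seeded, at most
bimolecular propensities) is the accuracy reference: closure means agree
within 3 SEM of 1000 replicates and variances within 20% across a
3-dose × 3-state grid for both networks, and the fitted gamma's
Kolmogorov–Smirnov distance to SSA samples is < 0.1 at mid-dose.

## Maximum-entropy inference of p(θ)

Per experimental condition (each dose/time pair is its own condition) a
gamma is moment-matched to the single-cell snapshot histogram and its
deciles become ten percentile windows with target mass R_em = 0.1 (outer
edges 0 and ∞).  The maxent density subject to ⟨ψ_em⟩ = R_em, where
ψ_em(θ) is the model-predicted window mass of the cell's gamma response,
is the Gibbs form exp(−Σ λ_em ψ_em(θ)) on a parameter box, uniform in
log10 rates (default ±1 decade around literature-scale midpoints).
Multipliers are tuned by ADAM (step 0.1, β₁ = 0.8, β₂ = 0.999) on the
dual gradient R_m − ⟨ψ_m⟩, the average estimated by parallel Metropolis
chains (proposals perturb 1–5 coordinates by ≤ 10% of the box width,
reflecting at the edges; chains warm-start from the previous ensemble).
Desk-scale defaults are 20 chains × 2000 steps per iteration with
burn-in 1000 and thinning 50; the study-scale configuration (150 chains,
1e4–2.5e5 steps) is reachable through the same arguments.  Iteration
stops at a mean absolute relative error of 0.05 or on a patience
plateau.  Because the per-iteration error estimate carries Monte-Carlo
noise of comparable size at desk scale, final fits should be assessed by
a longer evaluation chain at the fitted λ.

Known limitation: decile constraints leave the response profile inside
each window — in particular beyond the outermost deciles — to the
log-uniform base measure.  Cells whose responses sit entirely above the
pooled 90th percentile at every dose share one ψ vector, so the fitted
ensemble spreads across that region of the box and the pushed-forward
pooled response variance is substantially inflated relative to a
sharply-peaked ground truth even when every window constraint is met.
Pushed-forward means recover to within ~10%; pushed-forward variances do
not, and tests document this rather than hiding it.

## Cell-state dynamics

The dynamics study uses an mRNA → receptor → bound-receptor cascade with
kmprod/kmdeg = 5 copies, kprod = 50 s⁻¹, kdeg = 0.5 s⁻¹,
kunbind = 1 s⁻¹; the mRNA turnover time τ = 1/kmdeg sweeps five
log-spaced values in [10², 10⁴] s with kmprod co-scaled to hold the mean
copy number, and 20 log-spaced doses span L·kbind ∈ [10⁻², 10³] s⁻¹.
The cell state is the exact initial pair (R0, mRNA0); the study cells
are (300, 3) and (700, 7).  Measurement protocol: the state propagates
ligand-free for 1000 s (the geometric mean of the τ grid), then the
ligand is applied for 10 s and the bound count B is read at the end;
receptor turnover (2 s lifetime) makes B report the state at measurement
time.  A single 10 s exposure alone cannot separate the τ regimes —
every τ on the grid is much longer than 10 s, so conditioning would
persist everywhere; the wait period is what lets fast mRNA turnover
ergodically erase the conditioning while slow turnover leaves cells
frozen near their endowment.  Responses are moment-matched gammas from
250 seeded SSA replicates per condition (2500 at study scale), and the
conditioned MI uses a uniform input over the non-degenerate doses.

## Repeated-stimulation pipeline

Long-format trajectories (cell, dose, time, value) are reduced to
per-cell, per-dose gamma models from the sample moments inside the
steady-state window (60–90 min; ≥ 3 points required, degenerate windows
drop the whole cell so the channel stays square).  The experimental
p_CeeMI(I) reports each cell's MI at the input p*(u) that maximizes the
across-cell mean MI.  Pooling averages first and second moments exactly
(mixture variance = mean of (σ²+μ²) minus squared pooled mean).
Repeatability contrasts within-cell response differences δ = x₁ − x₂
against between-cell differences δ₀ built from 10 seeded random
derangements of the cell labels.

## Synthetic data

The generator draws θ from a gamma law in one toy parameter (defaults:
R0, mean 500, CV 0.3), pushes it through the forward model, and samples
one value per cell and dose (snapshot mode: 500 cells) or a full
relaxation trajectory per dose epoch (trajectory mode: 90 min epochs
sampled every 3 min, exponential relaxation with a 10 min time scale,
stationary gamma fluctuations at the model Fano factor, states held
fixed across epochs or redrawn for the unstable null).  Measurement
noise is multiplicative log-normal with CV 0.05 by default, exposed
separately from the response model for robustness tests.  Every table
ships with a ground-truth sidecar.  What the generator does not emulate:
imaging artifacts (segmentation error, bleaching, drift), cell division,
and non-gamma state laws — so passing recovery tests demonstrate
correctness of the estimation machinery under the model's own
assumptions, not robustness to real-microscopy systematics.

## Problem sizes

Default test-suite scales are chosen for a laptop-class run: 21–200 cell
ensembles for information quantities, 1000 SSA replicates for closure
checks, 20 × 2000-step MCMC per ADAM iteration, 250 SSA replicates per
dynamics condition.  All are configuration parameters; study-scale runs
change only those numbers.
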