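# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `pmfrelease`. The package studies one question at desk
scale: how the free-energy landscape a hydrophobic drug experiences on its
way out of a polymer matrix controls its release kinetics, and how the
standard free-energy machinery (umbrella sampling + WHAM, alchemical
multistate estimation, coarse-grained parametrisation, power-law release
fitting, contact clustering) behaves when every ground truth is known.

## The toy sampling engine

Real studies of this kind generate their data with a molecular-dynamics
engine; here a one-dimensional overdamped Langevin integrator on analytic
potentials plays that role, so that every downstream estimator can be tested
against a planted truth. The update is position-only Euler–Maruyama,

    z ← z − βD U′(z) Δt + √(2DΔt) ξ,   ξ ~ N(0,1),

with β = 1/k_BT, k_B = 0.008314462618 kJ·mol⁻¹·K⁻¹ and T = 310 K by default
(300 K for the alchemical examples). An inertial stochastic-dynamics
integrator would add nothing here: the estimators only need correctly
distributed samples, and the overdamped chain has the exact Boltzmann
stationary law in the Δt → 0 limit.

Two numbers control the quality of that stand-in and were chosen once, from
the stationary analysis of the Ornstein–Uhlenbeck discretisation rather than
from any test outcome. For local stiffness k (potential curvature plus bias
spring) the discrete chain has stationary variance (k_BT/k)·1/(1 − a/2) with
a = βDkΔt, i.e. a relative variance bias of a/2, and a relaxation time of
1/a steps. Defaults D = 2×10⁻³ nm²/ps and Δt = 2×10⁻³ ps keep a ≈ 1.6×10⁻³
for the stiffest springs used (k ≈ 1000–1500 kJ·mol⁻¹·nm⁻²), so the
systematic energy distortion is ≈0.1% — far below sampling noise — at the
price of ≈600-step decorrelation. Umbrella datasets therefore record strided
samples (typically every 500–1000 steps, i.e. roughly one to two relaxation
times) so that bootstrap error estimates, which treat samples as
independent, stay honest. Generators that need faster mixing on soft
landscapes (the double-well protocol, the light demo) raise D instead of Δt,
which leaves a unchanged per unit stiffness.

Each umbrella window runs as an independent walker seeded from
`SeedSequence(seed).spawn(window_index)`; a chunked, numba-compiled kernel
advances all windows simultaneously, and a pure-numpy fallback produces
bit-identical trajectories when numba is absent. A domain guard aborts with
the offending step index if a walker leaves its configured interval or turns
non-finite.

The translocation landscape is an analytic stand-in for a drug's potential
of mean force across a polymer–water interface: a Gaussian-envelope well of
depth ΔG (≤ 0, width `well_sigma` = 1.5 nm) inside the matrix, multiplied by
a compact-support smoothstep that rises across `interface_center ±
interface_width` to an exactly flat aqueous plateau. The profile is
renormalised at construction so its minimum is exactly the requested depth.
The functional form is a modelling choice — a real PMF is simulation output,
not analytic — but it reproduces the features that matter: a deep preferred
location, a sigmoidal interfacial rise, and a flat solvent reference.

Other generators: bonded ensembles are drawn exactly from exp(−βV) (Gaussian
sampling for harmonic terms; rejection sampling with a uniform envelope on
[0°, 180°] for harmonic-cosine terms, acceptance exp(−βV) ≤ 1); alchemical
states sample a particle in a harmonic restraint with a λ-scaled attractive
Gaussian well by exact rejection, with the end-to-end free energy from
quadrature as planted truth; release curves are K·tⁿ plus clipped Gaussian
noise; cluster configurations chain particles at fixed spacing around grid
points whose pitch guarantees the planted partition under any cutoff between
the intra- and inter-cluster distances.

## WHAM

The profile estimator is standard binned WHAM: with per-window histograms
nᵢ(z), counts Nⱼ and bias wⱼ(z) = ½kⱼ(z−cⱼ)²,

    p(z) ∝ Σᵢ nᵢ(z) / Σⱼ Nⱼ exp(β(Fⱼ − wⱼ(z))),
    Fⱼ = −k_BT ln Σ_z p(z) exp(−βwⱼ(z)),

iterated to self-consistency and converted to G(z) = −k_BT ln p(z), shifted
so the aqueous reference region (caller-specified; default the outermost 10%
of the sampled range on the solvent side) averages zero. Plain fixed-point
iteration converges geometrically with a rate set by window overlap, and at
60 windows with ~5% neighbour overlap the tail is punishingly slow (residual
errors of order 1 kJ/mol after 10⁵ sweeps). The default solver therefore
first minimises the equivalent convex negative log-likelihood in the window
free energies by damped Newton iteration (the Hessian is K×K and explicit),
then finishes with self-consistent sweeps until max|ΔF| < tol — the two
share a fixed point, so the converged result is the WHAM solution at
tol = 10⁻⁸ kJ/mol. `method="scf"` runs the pure iteration.

Defaults: bin width 0.05 nm; max 10⁵ sweeps; optional decorrelation stride.
Empty bins are flagged and excluded, never interpolated; a disconnected
window-overlap graph is an error, and adjacent-pair histogram intersections
below 0.03 raise a warning (`check_overlap` reports them all). Errors come
from a seeded bootstrap: windows are resampled with replacement, WHAM is
re-solved on the shared grid (warm-started from the full-data solution), and
the per-bin standard deviation across replicates is the error bar. The
replicate profiles are kept so that derived quantities — in particular the
translocation barrier ΔG_t* = min G − ⟨G⟩_reference — take their standard
error from the replicate distribution of the *derived* quantity rather than
from naive per-bin propagation.

Sign convention: ΔG_t* ≤ 0 measures the depth of the compound's preferred
location (matrix interior or interface — the extractor simply takes the
deepest populated bin) below bulk water; a larger magnitude means slower
release.

The dominant reconstruction error under the 60-window / 0.2 nm / 1000
kJ·mol⁻¹·nm⁻² protocol is not per-bin noise but the random walk of
window-to-window stitching errors across ~4.6% neighbour overlaps; with
5×10⁴ effectively independent samples per window it contributes ~0.3–0.5
kJ/mol RMSE over the full range. The bootstrap captures exactly this mode.

## MBAR

Multistate free energies solve fᵢ = −ln Σₙ exp(−uᵢₙ)/Σₖ Nₖ exp(fₖ − uₖₙ)
over all pooled samples (reduced energies uₖₙ = βUₖ(xₙ)), anchored at
f₀ = 0, by log-sum-exp fixed-point iteration to max|Δf| < 10⁻¹⁰. The
uncertainty is the standard asymptotic covariance of the estimator, computed
from the N×K weight matrix via its SVD,
Θ = V S (I − S Vᵀ diag(N) V S)⁺ S Vᵀ; a 50-replicate calibration puts the
empirical scatter at 0.95× the reported standard error. State connectivity
is checked on the converged overlap matrix Oᵢⱼ = Σₙ Nᵢ Wₙᵢ Wₙⱼ; a
disconnected pair is reported by index rather than returning an
unidentifiable answer.

The soft-core interaction uses the Beutler form with α = 0.5 and linear λ
scaling (V ∝ λ·[σ¹²/(ασ⁶(1−λ)+r⁶)² − σ⁶/(ασ⁶(1−λ)+r⁶)]): exactly 12-6
Lennard–Jones at λ = 1, identically zero at λ = 0, finite at r = 0 for
λ < 1. The constants are conventional choices; nothing downstream is
sensitive to them. The `coulomb_then_lj` schedule mode is bookkeeping for
the charged-solute protocol (electrostatics off first, then dispersion);
the toy engine computes no electrostatics.

Solvation free energies are k_BT(f_{λ=1} − f_{λ=0}); transfer free energies
subtract two solvation legs with errors in quadrature, and
log P_ow = ΔG_{O→W}/(ln 10·RT), positive for hydrophobic solutes.

## Coarse-grained bonded fitting

Bead positions are mass-weighted centres of their member atoms. Bond
lengths, angles (arccos of normalised dot product) and signed dihedrals
(atan2 convention, (−180°, 180°], matching mdtraj's sign) are histogrammed
with Freedman–Diaconis bins; dihedral means and widths are circular, so
distributions peaked at ±180° fit cleanly. Degenerate frames (zero-length
vectors) are excluded per term with a count.

Fitting is Boltzmann inversion by moment matching: the equilibrium value is
the distribution (circular) mean and the force constant k = k_BT/var, with
angular variances in rad². Harmonic-cosine terms match the mean and variance
of cos θ instead. Moment matching in cos-space ignores the dθ → d(cos θ)
Jacobian, so for very soft angular terms (spread in cos θ ≳ 0.25) the
recovered equilibrium carries a small systematic offset; the round-trip
self-consistency test quantifies the stiffness regime where this is
negligible. Zero-width distributions raise an error advising a rigid
constraint — no spring reproduces a delta function.

Iterative refinement mirrors the trial-and-error width matching used in
bottom-up parametrisation: per iteration, resample each term from the
current parameters, rescale k by (width_current/width_target)², shift the
equilibrium by the mean residual, and stop when the Jensen–Shannon distance
between model and target histograms falls below tol (default 0.05, roughly
the finite-sample JSD floor at the default 10⁵ model samples). If the total
mismatch rises twice in a row, later updates are damped by half and the
event is recorded. The JSD metric is this module's choice; any metric on
normalised histograms would serve.

## Release kinetics

With equal diffusion coefficients the solubility–diffusion picture makes the
release-rate ratio of two compounds exp(β(ΔG_a − ΔG_b)); only ratios are
exposed because the absolute prefactor (geometry, diffusivity) cancels and
is not identifiable from barriers alone. Ranking is descending ΔG_t*
(shallowest well releases fastest), ties broken alphabetically and reported.

Release curves follow the Ritger–Peppas law M_t/M_∞ = K·tⁿ, fitted by
nonlinear least squares on points with fraction ≤ 0.6 — the standard
validity ceiling of the power law — initialised from a log-log linear
regression, inverse-variance weighted when the curve carries error bars. The
exponent n diagnoses the transport mechanism (n ≈ 0.43–0.5 is Fickian for
common geometries); K absorbs geometry and interaction strength and is not
decomposed.

## Cluster analysis

Molecules aggregate when bead contacts form; the analysis takes contacts as
minimum-image pairs within a cutoff (0.6 nm in the standard protocol) in an
orthorhombic periodic box, builds the contact graph with a periodic k-d
tree, and labels connected components (single linkage) by their smallest
member index. The cutoff must stay below half the smallest box edge or the
minimum image is ambiguous (error). Average cluster size is reported both as
number average N/(number of clusters), monomers included, and mass average
Σsᵢ²/Σsᵢ; the trace keeps both because published "average cluster size"
curves rarely state which was plotted.

## The demo pipeline

`run_demo` wires the stages together on synthetic data: four named
compounds with planted well depths (−69.8, −75.3, −76.9, −90.7 kJ/mol — the
drug/prodrug series the package's examples use throughout) → umbrella
sampling → bootstrap WHAM → barrier extraction → ranking, pairwise rate
ratios and relative differences → noisy power-law release curves and their
fits → a planted-cluster configuration trace. Demo-scale sampling (2000
samples/window by default) keeps the run to minutes; every stage writes its
artifact and every seed (derived deterministically from the master seed) is
recorded, so reports are byte-identical across reruns and every number is
traceable to a stage file. The demo's release-curve parameters are
illustrative inputs, not predictions: mapping a 21 kJ/mol barrier difference
through exp(βΔΔG) would change rates by four orders of magnitude, while real
matrix-release experiments differ far more modestly — a reminder that the
exponential rate model ranks compounds well but should not be read as a
quantitative release-time predictor.

## Problem sizes used by the recovery checks

The protocol-scale checks run 60 windows × 5×10⁴ strided samples for the
double-well reconstruction (RMSE ≤ 0.5 kJ/mol against the analytic truth;
across seeds the typical value is ≈0.4) and 60 windows × 8×10³ samples with
24 bootstrap replicates per compound for the planted-barrier series —
roughly 10⁸ integrator steps in total, a few minutes on one core. The
remaining checks (MBAR vs quadrature, bonded and power-law recovery,
brute-force cluster validation at 200 random configurations) run in
seconds.

## What passing these tests does and does not show

The synthetic engine emulates correctly distributed biased samples,
separable bonded degrees of freedom, uncorrelated release-curve noise and
geometrically clean clusters. It does not emulate the hard parts of real
data: slow orthogonal degrees of freedom (polymer relaxation far slower
than the pulling coordinate), hidden hysteresis in window starting
structures, force-field error, correlated experimental noise, or matrix
degradation beyond the diffusion-dominated window. Passing recovery here
validates the estimators and their error bars, not the molecular models
those estimators would be fed in a real study.
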