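# Methods

## The model

`pdtbind` works with probability densities of the alchemical perturbation
energy u = U₁(x) − U₀(x), in kcal/mol throughout, at a fixed Boltzmann
constant k_B = 0.0019872041 kcal/(mol·K) and default temperature 300 K.
The initial-state density p₀(u) is a mixture over conformational modes.
Each mode has a Gaussian background component N(u; ū₀, σ) — the aggregate
of many long-ranged interactions, Gaussian by central-limit and
linear-response arguments — and, with probability 1 − b, an additive
collisional energy drawn from the max-statistics family

    G(u) = [1 − √((1 + x_c)/(1 + x))]^{n_l},  u ≥ 0,
    x(u) = √(1 + (u + ũ)/ε),   x_c = √(1 + ũ/ε),

whose density F = dG/du is

    F(u) = n_l [1 − √((1+x_c)/(1+x))]^{n_l − 1} √(1 + x_c)
           / (4 ε x (1 + x)^{3/2}),   u ≥ 0.

This is the exact derivative pair: the density integrates to one by
construction and the CDF (and its closed-form quantile) are available for
high-accuracy quadrature and sampling.  The form follows from a
Lennard-Jones r⁻¹² repulsion probed by a uniformly distributed particle:
the survival probability of a single contact scales as u^(−1/4), and n_l
statistically independent contacts give the max-statistics power.  Two
consequences shape all numerics downstream:

* the collisional tail is extremely heavy — no moments exist, and the CDF
  approaches 1 only at ~10¹⁵·ε — so raw-u quadrature over a finite window
  never "converges" to full mass;
* all integration is therefore performed in the soft-core variable u_sc,
  whose domain is bounded above by u_max and where the tail mass is
  compressed into a thin, numerically benign layer under the cap.

Mode parameters: weight w ∈ [0, 1] (weights sum to 1), ū₀ and σ (kcal/mol),
clash-free probability b ∈ [0, 1], ε > 0 (kcal/mol, collisional energy
scale), ũ ≥ 0 (kcal/mol, onset), n_l ≥ 1 (dimensionless, scales with solute
size; fractional values allowed).  −k_B T ln b is the cavity-formation free
energy of the solute-shaped cavity.

## Soft core and alchemical potential

The soft-core transform is the identity below u_cut and caps smoothly at
u_max with exponent a (default 0.0625); defaults are u_cut = 0, u_max = 50
kcal/mol for coupling legs and u_cut = 100, u_max = 200 kcal/mol for
host–guest transfer legs.  Its inverse and derivative are closed-form,
making the change of measure p₀(u_sc) = p₀(u)/u_sc′(u) exact.  The softplus
alchemical function

    W(u_sc) = ((λ₂ − λ₁)/α) ln(1 + e^{−α(u_sc − u₀)}) + λ₂ u_sc

is evaluated through the overflow-safe identity
ln(1+eˣ) = max(x, 0) + log1p(e^{−|x|}); it reduces to λ·u_sc on linear
schedules (λ₁ = λ₂ = λ) and the schedule validator enforces W ≡ 0 at λ = 0
and W = u_sc at λ = 1 numerically on a grid.  Nonlinear schedules are read
from TSV tables (λ, λ₁, λ₂, α, u₀); the p₀ parameters are independent of the
schedule, so the bundled linear schedule is the default.

## PDT propagation and quadrature

K(λ) and all state densities are computed on a composite trapezoid grid in
u_sc spanning [min(ū₀ᵢ − 12σᵢ), u_max − 10⁻⁶(u_max − u_cut)] with 4001
nodes by default; integrands are assembled in the log domain with a
max-shift to avoid underflow.  Measured normalization error |K(0) − 1| is
≤ 4·10⁻⁶ at 4001 nodes across all bundled models and scales as h² (the
property suite uses 16001 nodes where 10⁻⁶ accuracy is asserted; choosing
resolution by this convergence law is the intended knob).  An optional
self-convergence check re-evaluates on a doubled grid and raises with
diagnostics on disagreement.

The mode convolution (N ⊛ F)(u) uses 19-node Gauss–Hermite quadrature over
the Gaussian factor by default.  Its accuracy is not uniform: relative
error is ≤ 10⁻³ near the density peak and the mass-weighted L1 error is
~2·10⁻⁵, but the deep tails (density below ~10% of peak) can be off by a
few percent because the Heaviside edge of F sits inside the Gaussian mass.
A second route integrates over the closed-form collisional quantile with
Gauss–Legendre nodes (`method="quantile"`); it converges to ≤ 10⁻⁵
everywhere by ~4000 nodes and serves as the high-accuracy reference in the
oracle tests.  The fast rule is used in fitting (where mass-weighted
accuracy is what matters); the quantile rule wherever pointwise tail
accuracy is needed.

Coupled-state means: the linear-response closed form ū₁ = ū₀ − βσ² per mode
is the default and is what the transfer parameter-combination rules use —
it matches the printed transfer means to their precision.  The quadrature
route also reports ⟨u_sc⟩ under p₁; note ⟨u⟩ in the raw variable is
divergent for any mode with b < 1 (the u^(−1/4) tail times the bounded
soft-core weight), so the capped mean is the physically meaningful one and
the returned raw-u value is explicitly grid-truncated.

## Transfer models

The transfer density is the convolution of the gaining-environment coupling
density with the (sign-flipped) coupled-state density of the losing
environment, which is Gaussian because the coupled state is clash-free.
Each of the m_h × m_s mode pairs yields a transfer mode with weight
w_h·w_s, mean ū₀(gain) − ū₁(lose), standard deviation √(σ_h² + σ_s²), and
the gaining model's collisional parameters (receptor for binding, solvent
for unbinding).  The literal product rule is implemented; published
transfer tables refit the weights slightly (e.g. 0.462 vs the product
0.446) and such refit shifts are deliberately not reproduced.  Two caveats
that the test suite encodes:

* for the symmetric water-in-water system the binding- and unbinding-leg
  models coincide exactly and the two-leg free-energy difference is
  identically zero;
* the λ = ½ mirror symmetry between the legs holds only where the
  soft-core is inactive in the populated range (the transfer setting,
  u_cut = 100).  Under a u_cut = 0 soft-core the capped clash penalty
  e^{−βu_sc/2} re-weights the heavy collisional tail and the two capped
  leg ensembles are genuinely inequivalent — the sampled distributions are
  then far from mirror images.  The mirror test therefore runs under the
  transfer soft-core and allows a KS distance of 0.1 for the few-percent
  residual asymmetry the mixture model retains.

Bookkeeping helpers implement ΔG_b = ΔG⁺ − ΔG⁻, the ideal term
−k_B T ln(C°V_site) with C° = 1/1660.539 Å⁻³ and a spherical flat-bottom
site, the cavity term −k_B T ln b, and ΔG°_b = ΔG°_id + ΔG_b.

## Inference

UWHAM (unbinned multistate reweighting) runs on reduced energies
βW_{λ_k}(u_sc,i): an L-BFGS minimization of the convex objective provides
the start, and self-consistent iteration polishes to max|Δf| < 10⁻⁸ with
f₀ ≡ 0.  Per-sample λ = 0 weights come from the standard mixture
denominator; an effective-sample-size floor triggers a warning in the
result metadata rather than an error.  Standard errors are by within-state
bootstrap, warm-started from the full-data solution (samples are i.i.d. by
construction here; on correlated trajectory data a block bootstrap would be
required).

Kernel diagnostics use weighted Gaussian kernels with σ = 1 kcal/mol by
default: p₀(u_sc) = Σ W₀ᵢ N(u_sc; u_i, σ) and the λ-function
k_B T d log p₀/du_sc via the analytic kernel derivative, masked (NaN) where
the density falls below a floor.  Kernel smoothing inflates the apparent
variance by the bandwidth squared; the initializer subtracts it back out.

The maximum-likelihood cost is −Σᵢ log p_{λᵢ}(u_sc,i | θ) with the
change-of-measure Jacobian; samples where the model density underflows contribute a
large finite penalty (log floor −690) instead of NaN.  Parameters are
optimized unconstrained via transforms — simplex logits for weights
(first mode anchored), log for σ, ε, ũ, n_l − 1, logit for b — with
L-BFGS-B and finite-difference gradients, optional seeded multi-starts, and
a descent guarantee (the initial model is returned if no improvement is
found).  By default the per-sample log-density is linearly interpolated
from the 2001-node quadrature grid (relative cost error ~5·10⁻⁶, ~25×
faster); `negative_log_likelihood` keeps the direct evaluation.

Automated initialization exploits linear response: the most-coupled state's
samples are clash-free and Gaussian, so a 1-d k-means split into the
requested number of modes gives per-mode (mean, σ) that are back-shifted by
λβσ² to decoupled means; decoupled weights come from the UWHAM λ = 0 mass
nearest each core, and b from the kernel-density mass in the Gaussian core.
With one requested mode on clearly bimodal data (cluster separation above
3.2 pooled widths — a k = 2 split of a single Gaussian yields ~2.7) the
dominant component is returned.  Collisional parameters start at
order-of-magnitude defaults (ε = ũ = 1 kcal/mol, n_l from a size hint).
This replaces an inherently interactive, graphically guided initialization
workflow and is not expected to reproduce hand-tuned fits from raw samples;
it is validated by recovery experiments instead.

Identifiability: different (ε, ũ, n_l) combinations fit multi-state data
almost equally well, and b trades off against the mode weights.  Recovery
is therefore asserted at the level of the Gaussian parameters (tight) and
of the full density in L1 (tight), never at the level of individual
collisional parameters.

## Synthetic data

The sampler draws i.i.d. u_sc values from p_λ(u_sc) by inverse-CDF lookup:
the state density is tabulated on 20001 points over the same u_sc window as
the quadrature, integrated cumulatively, and inverted with monotone cubic
(PCHIP) interpolation.  Rejection sampling is deliberately avoided because
of the thin high-density layer under the soft-core cap.  A mass-deficit
guard raises if the tabulation window truncates more than 10⁻⁴ of the
state's mass.  A master seed spawns one child stream per state
(`numpy` SeedSequence), so adding states never perturbs existing ones.
Samples are exact up to grid interpolation (two-sided KS against the
tabulated CDF passes at the 1% level in ≥95/100 seeded repetitions); no
replica-exchange autocorrelation or equilibration transients are emulated,
which means recovery results here bound what real, correlated trajectory
data would give from below in difficulty — equilibration trimming
(`discard_fraction`, customarily 1/3) is applied by the sample reader, not
the generator.

## Experiment sizes

The recovery experiments use 11 evenly spaced λ states: 5000 samples/state
for free-energy and single-mode parameter recovery, 10000/state for
two-mode density-level recovery (L1 < 0.05).  These sizes give UWHAM
standard errors of ~0.015 kcal/mol and leave the whole suite comfortably
within a few minutes on one CPU core.

## Known limitations

* The collisional density's literal printed grouping is ambiguous; the
  implemented form is the unique one that is the exact derivative of the
  max-statistics CDF and reproduces the 1/(4εx(1+x)^{3/2}) prefactor.
* Raw-u means and higher moments of collisional modes do not exist; use
  soft-core-variable moments.
* The Gauss–Hermite convolution default trades tail accuracy for speed;
  switch to the quantile rule for tail-sensitive work.
* Printed parameter tables carry 3 significant figures; the model reader
  renormalizes weight sums within 2·10⁻³ and rejects worse.
* Transfer-model weights follow the exact product rule, not the refitted
  published weights.
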