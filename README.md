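# pdtbind

Analytical potential-distribution-theory (PDT) models of alchemical coupling
and alchemical transfer for molecular binding.

Alchemical binding free-energy calculations estimate the excess binding free
energy ΔG_b = −k_B T ln ⟨e^(−βu)⟩₀, where u = U₁(x) − U₀(x) is the
perturbation energy and the average runs over the decoupled ensemble.  The
central object of PDT is the probability density p₀(u) of the perturbation
energy at the initial state: it determines every intermediate state of any
alchemical path through

    p_λ(u) = e^(−β W_λ(u)) p₀(u) / K(λ),     K(λ) = ∫ e^(−β W_λ(u)) p₀(u) du,

and the free-energy profile ΔG(λ) = −k_B T ln K(λ).  `pdtbind` implements
the analytical model family for p₀(u) used in host–guest alchemical work —
a multimodal mixture of a Gaussian "background" component (long-ranged
interactions, by linear response / central-limit arguments) and a
"collisional" component following max statistics of the most repulsive
atomic contact:

    p₀(u) = Σᵢ wᵢ [ bᵢ N(u; ū₀ᵢ, σᵢ) + (1 − bᵢ) (N ⊛ F)ᵢ(u) ],

where b is the probability of a clash-free configuration (so −k_B T ln b is
a cavity-formation free energy) and F(u_c) is the closed-form max-statistics
density with parameters (ε, ũ, n_l).  On top of this the package provides:

* the soft-core capping transform u_sc(u) and the softplus alchemical
  potential W_λ(u_sc) with per-state (λ₁, λ₂, α, u₀) schedules;
* **transfer models by convolution**: the density of the transfer
  perturbation energy u_t = u_h − u_s is built from a receptor-coupling and
  a solvent-coupling model — each mode pair combines with weight w_h·w_s,
  mean ū₀t = ū₀h − ū₁s (ū₁ = ū₀ − βσ² by linear response),
  σ_t = √(σ_h² + σ_s²), and collisional parameters inherited from the
  receptor (binding) or solvent (unbinding) model;
* UWHAM multistate reweighting, weighted kernel estimates of log p₀(u_sc)
  and the λ-function k_B T · d log p₀/du_sc, and maximum-likelihood fitting
  of the mixture to multi-state perturbation-energy samples;
* an exact synthetic sampler that draws i.i.d. samples from p_λ(u_sc) by
  inverse-CDF lookup, standing in for replica-exchange simulation output;
* double-decoupling bookkeeping: two-leg differences, the ideal term
  −k_B T ln C°V_site, and standard binding free energies.

Bundled parameter tables cover water-in-water coupling/transfer and the
TEMOA (tetramethyl octa-acid) host with water and five SAMPL8 guests.

## Worked example

Build the transfer model for moving a water molecule from bulk solvent into
the TEMOA cavity, from its host-coupling and hydration models:

```python
import pdtbind as pb

th = pb.ThermoSpec(300.0)
host = pb.datasets.load_model("temoa-h2o-coupling")
hyd = pb.datasets.load_model("hydration-h2o")
transfer = pb.build_transfer_model(host, hyd, "binding", th)
for i, m in enumerate(transfer.modes, 1):
    print(f"mode {i}: w={m.weight:.3f}  u0t={m.gaussian.mean_u0:.1f}  "
          f"sigma_t={m.gaussian.sigma:.2f}  b={m.collision.b_no_collision:.2e}")

sched = pb.linear_schedule(11, pb.DEFAULT_COUPLING_SOFTCORE)
prof = pb.free_energy_profile(pb.datasets.load_model("h2o-coupling"), sched, th)
print(f"water solvation excess dG(1) = {prof.excess_dg:.2f} kcal/mol")
print(f"ideal term (4.5 A site)     = {pb.ideal_binding_term(pb.SiteSpec(4.5), th):.2f} kcal/mol")
print(f"cavity dG (b=5.77e-3)       = {pb.cavity_free_energy(5.77e-3, th):.2f} kcal/mol")
```

prints

```
mode 1: w=0.446  u0t=17.2  sigma_t=4.36  b=1.40e-02
mode 2: w=0.554  u0t=17.7  sigma_t=4.66  b=6.90e-04
water solvation excess dG(1) = -4.56 kcal/mol
ideal term (4.5 A site)     = 0.88 kcal/mol
cavity dG (b=5.77e-3)       = 3.07 kcal/mol
```

The two transfer modes combine the two host-coupling modes with the single
hydration mode: the means are the host decoupled means minus the
linear-response coupled-state solvent mean (ū₁s ≈ −17.7 kcal/mol at 300 K),
and the widths add in quadrature (√(2.66² + 3.46²) = 4.36,
√(3.12² + 3.46²) = 4.66).  The water solvation free energy from the fitted
model's PDT quadrature (−4.56 kcal/mol) sits within a quarter kcal/mol of
the multistate-reweighting estimate from the underlying simulation data
(−4.50 kcal/mol).

Fitting a model to multi-state samples uses the statsmodels-style front end:

```python
ds = pb.generate_dataset(pb.SimSpec(model, sched, n_per_state=5000, seed=1), th)
res = pb.AlchemicalDensityModel(ds, n_modes=1, thermo=th).fit()
print(res.summary())
```

A `pdtbind` console script exposes the same functionality
(`simulate`, `fit`, `predict`, `transfer`, `free-energy`, `diagnose`);
every run writes a JSON provenance log with the seed and a configuration
hash.

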