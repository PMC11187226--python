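# intronkit

Quantitative analysis of small-molecule inhibition of group II intron
self-splicing.  Group II introns are self-splicing ribozymes whose
excision proceeds through two sequential chemical steps: hydrolysis at
the 5′ splice junction (precursor 5e-I-3e → intermediate I-3e, rate
constant k₁) followed by exon ligation and intron release
(I-3e → linear intron I, rate constant k₂).  Inhibitors that bind the
conserved, metal-aided active site slow these steps to different degrees,
and quantifying that selectivity requires a consistent chain of kinetic
and thermodynamic inference.  `intronkit` implements that chain for
researchers analyzing splicing gels, FRET activity assays, calorimetry,
biosensor kinetics, and relative binding free energies.

## What it computes

* **Two-step kinetics** — the irreversible sequential first-order
  (Bateman) model with unit initial precursor:
  `P(t) = e^(−k₁t)`, `I(t) = k₁/(k₂−k₁)·(e^(−k₁t) − e^(−k₂t))`,
  `prod(t) = 1 − P − I`, including the k₁ = k₂ degenerate limit, the
  intermediate peak time `t* = ln(k₁/k₂)/(k₁−k₂)`, and joint or
  sequential least-squares fits of (k₁, k₂) to replicate time courses.
* **Inhibition constants** — `k_obs = k_max/(1 + [I]/K_i)` fits
  (optionally weighted by per-point standard errors), the
  percent-reacted-precursor normalization of the 15-min gel readout, the
  dose-response hyperbola `% = 100/(1 + [I]/IC50)` fitted in log(IC50),
  FRET initial-slope %activity, and per-step fold-changes.
* **Binding thermodynamics** — `ΔG = RT·ln(K_D/c°)`, `−TΔS = ΔG − ΔH`,
  `ΔΔG = RT·ln(K_i,B/K_i,A)` with delta-method errors, a single-site ITC
  forward model with perfusion-cell dilution bookkeeping and its fit
  (N, K_D, ΔH, blank offset), and a globally fitted biphasic ("2:1
  heterogeneous") BLI model with `K_D = k_off/k_on` per phase.
* **Thermodynamic integration** — the order-n Gauss–Legendre λ-schedule
  on [0, 1] (the 12-point rule reproduces the published λ-window list),
  Metropolis sampling of ⟨∂U/∂λ⟩ on analytically solvable toy
  alchemical systems, the quadrature estimator
  `ΔG = Σ wᵢ⟨∂U/∂λ⟩ᵢ`, and thermodynamic-cycle assembly
  `ΔΔG = ΔG_bound − ΔG_unbound`.
* **Synthetic assays** — seeded generators reproducing each assay's
  design and noise structure (triplicate gel densitometry, dose series,
  the 30 μM/600 μM 16 × 2.5 μL ITC titration, 300 s BLI phases), so every
  estimator can be validated end to end without external data.

## Worked example

`examples/` holds one short script per capability.  For instance,
`python examples/03_binding_thermodynamics.py` simulates the standard
ITC titration with 0.1 kcal/mol heat noise, refits it, fits a biphasic
BLI sensorgram set, and converts measured K_i pairs into ΔΔG:

```
ITC: K_D = 6.74 uM, N = 1.03, dH = -9.53, dG = -7.06, -TdS = 2.48 kcal/mol
     c-value = 4.6 (fittable range is ~1-1000)
BLI: k_on1 = 10.4, k_on2 = 131.4 M^-1 s^-1; k_off1 = 0.0010, k_off2 = 0.0261 s^-1
     K_D1 = 100 uM, K_D2 = 199 uM (= k_off/k_on)
ddG(compound 12 -> compound 17) = -0.18 +/- 0.08 kcal/mol
ddG(compound 17 -> intronistat A) = -0.37 +/- 0.09 kcal/mol
```

The ITC line is the refit of a noisy titration generated at
K_D = 7.58 μM, ΔH = −10.04 kcal/mol: at this c-value (~4) a single noisy
titration determines K_D to a few tens of percent, which is why ΔH and
−TΔS shift together while ΔG (their sum) is stable.  The ΔΔG lines are
exact transformations of the K_i values with first-order error
propagation.  Similarly, `python examples/01_splicing_kinetics.py`
prints, from noisy triplicates:

```
[  0.0 uM] k1 = 0.0376 +/- 0.0007 min^-1, k2 = 0.0324 +/- 0.0003 min^-1  (s.e.m., n=3)
[ 50.0 uM] k1 = 0.0071 +/- 0.0001 min^-1, k2 = 0.0012 +/- 0.0001 min^-1  (s.e.m., n=3)
control intermediate (I-3e) peaks at 28.6 min
fold_1 = 5.3, fold_2 = 26.4, selectivity (step 2 vs step 1) = 5.0x
```

i.e. the inhibitor slows the second step several-fold more than the
first — the signature of a compound that blocks the conformational
transition between the two catalytic steps.

A thin CLI mirrors the library for shell pipelines
(`intronkit simulate | fit-kinetics | fit-ki | fit-ic50 | fit-itc |
fit-bli | ddg | ti-run | report`); every JSON report embeds the resolved
configuration and seed.

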