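"""Binding thermodynamics: ITC isotherm fit, BLI kinetics, and ΔΔG from K_i.

Simulates the study's ITC geometry (30 μM intron in the cell, 600 μM
ligand in the syringe, 16 x 2.5 μL injections at 25 °C), fits the
single-site model, and decomposes ΔG into ΔH and −TΔS.  Then fits the
biphasic BLI model and converts K_i pairs of ligand analogs into relative
binding free energies.
"""

import intronkit as ik

# --- ITC ---
truth = ik.BindingThermodynamics.from_KD_dH(K_D=7.58e-6, delta_H=-10.04, N=1.0)
titration = ik.generate_itc(truth, noise_sd=0.10, seed=3)
fit = ik.fit_itc_single_site(titration)
t = fit.thermodynamics
print(
    f"ITC: K_D = {t.K_D * 1e6:.2f} uM, N = {t.N:.2f}, "
    f"dH = {t.delta_H:.2f}, dG = {t.delta_G:.2f}, -TdS = {t.minus_T_delta_S:.2f} kcal/mol"
)
print(f"     c-value = {fit.c_value:.1f} (fittable range is ~1-1000)")

# --- BLI ---
kin = ik.BLIKinetics(
    k_on1=10.1, k_on2=132.0, k_off1=0.001, k_off2=0.026, rmax1=0.4, rmax2=0.6
)
sensorgrams = ik.generate_bli(kin, noise_sd=0.002, seed=4)
bli = ik.fit_bli_biphasic(sensorgrams)
print(
    f"BLI: k_on1 = {bli.k_on1:.1f}, k_on2 = {bli.k_on2:.1f} M^-1 s^-1; "
    f"k_off1 = {bli.k_off1:.4f}, k_off2 = {bli.k_off2:.4f} s^-1"
)
print(f"     K_D1 = {bli.K_D1 * 1e6:.0f} uM, K_D2 = {bli.K_D2 * 1e6:.0f} uM (= k_off/k_on)")

# --- relative binding free energies from measured K_i (μM) pairs ---
for (ki_a, se_a, a), (ki_b, se_b, b) in [
    ((5.3, 0.2, "compound 12"), (3.9, 0.5, "compound 17")),
    ((3.9, 0.5, "compound 17"), (2.1, 0.2, "intronistat A")),
]:
    rel = ik.ddG_from_Ki(ki_a, ki_b, se_a, se_b, label_a=a, label_b=b)
    print(f"ddG({a} -> {b}) = {rel.ddG:+.2f} +/- {rel.se:.2f} kcal/mol")
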