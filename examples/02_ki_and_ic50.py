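"""Competitive inhibition: K_i from a k_obs series and IC50 from dose-response.

Generates a noisy k_obs-vs-[inhibitor] series from the hyperbolic model
k_obs = k_max/(1 + [I]/K_i) at K_i = 1.7 μM, refits it, and then fits an
IC50 to a FRET-style %activity dose series.  K_i is the concentration
halving the observed rate; IC50 the concentration halving the normalized
response.
"""

import numpy as np

import intronkit as ik
from intronkit.synthetic import FRET_CONCENTRATIONS

# --- K_i ---
series = ik.generate_kobs_series(
    k_max=0.037, K_i=1.7, concentrations=[0, 0.5, 1, 2, 5, 10, 50],
    noise_sd=0.02, seed=5,
)
fit = ik.fit_ki(series)
lo, hi = fit.confidence_interval(0.95)
print(f"K_i = {fit.K_i:.2f} +/- {fit.se_K_i:.2f} uM  (95% CI {lo:.2f}-{hi:.2f})")
print(f"k_max = {fit.k_max:.4f} min^-1")

# --- IC50 from a %activity dose series ---
rng = np.random.default_rng(5)
points = [
    (c, 100.0 / (1.0 + c / 2.5) + rng.normal(0, 3.0)) for c in FRET_CONCENTRATIONS
]
dr = ik.fit_ic50(points, response_kind="percent_activity")
print(f"IC50 = {dr.IC50:.2f} +/- {dr.se_IC50:.2f} uM ({dr.response_kind})")

# --- percent reacted precursor normalization for the gel readout ---
records = [
    ik.PrecursorFractionRecord(0.0, 0.20, is_dmso_reference=True),
    ik.PrecursorFractionRecord(2.0, 0.55),
    ik.PrecursorFractionRecord(250.0, 0.90, is_imax_reference=True),
]
for conc, pct in ik.percent_reacted_precursor(records):
    print(f"  [{conc:6.1f} uM] reacted precursor = {pct:5.1f}%")
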