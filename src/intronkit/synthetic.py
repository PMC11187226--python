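"""Seeded generators emulating the study's assays.

Every generator is a pure function of (parameters, design, seed), so the
whole analysis pipeline can be exercised without external data.  Defaults
mirror the experimental designs: triplicate gel time courses on a
0-120 min grid at inhibitor doses {0, 10, 50, 250} μM; 11 log-spaced FRET
concentrations from 0.25 μM to 1 mM; the 30 μM / 600 μM, 16 × 2.5 μL ITC
titration; and 300 s BLI association/dissociation phases at 12.5-100 μM
analyte.

Gel noise is applied to the per-species band intensities *before*
normalization (mimicking densitometry): zero-mean Gaussian perturbations
are added to the noiseless fractions, truncated at zero, and the row is
renormalized to sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from . import thermo
from .inhibition import KobsSeries
from .kinetics import SpeciesTimeCourse, SplicingRateConstants, bateman_fractions

__all__ = [
    "AssayDesign",
    "DEFAULT_TIMEPOINTS",
    "DEFAULT_GEL_CONCENTRATIONS",
    "FRET_CONCENTRATIONS",
    "generate_gel_timecourses",
    "generate_kobs_series",
    "generate_itc",
    "generate_bli",
]

#: default gel sampling grid (min); the study's exact grid is not printed,
#: this is a realistic densitometry schedule spanning both splicing steps
DEFAULT_TIMEPOINTS = (0.0, 1.0, 2.0, 5.0, 10.0, 15.0, 30.0, 60.0, 120.0)

#: default inhibitor doses for gel assays (μM)
DEFAULT_GEL_CONCENTRATIONS = (0.0, 10.0, 50.0, 250.0)

#: 11 log-spaced FRET doses, 250 nM to 1 mM (μM)
FRET_CONCENTRATIONS = tuple(np.geomspace(0.25, 1000.0, 11))


@dataclass(frozen=True)
class AssayDesign:
    """Sampling design shared by the gel-assay generators."""

    timepoints: tuple = DEFAULT_TIMEPOINTS
    concentrations: tuple = DEFAULT_GEL_CONCENTRATIONS
    replicates: int = 3
    noise_sd: float = 0.02  # band-intensity s.d. (fraction units)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _child_rngs(seed, n: int) -> list[np.random.Generator]:
    """Deterministic per-stream generators from one root seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(s) for s in ss.spawn(n)]


def generate_gel_timecourses(
    true_rates: Mapping[float, SplicingRateConstants],
    design: AssayDesign = AssayDesign(),
) -> list[SpeciesTimeCourse]:
    """Noisy triplicate gel time courses at each inhibitor concentration.

    ``true_rates`` maps inhibitor concentration (μM) to the generating
    (k1, k2).  Noise is added to band intensities pre-normalization.
    """
    times = np.asarray(design.timepoints, dtype=float)
    concs = sorted(true_rates)
    rngs = _child_rngs(design.seed, len(concs) * design.replicates)
    out = []
    idx = 0
    for conc in concs:
        rates = true_rates[conc]
        p, i, pr = bateman_fractions(times, rates.k1, rates.k2)
        clean = np.column_stack([p, i, pr])
        for rep in range(design.replicates):
            rng = rngs[idx]
            idx += 1
            if design.noise_sd > 0:
                intensities = clean + rng.normal(0.0, design.noise_sd, clean.shape)
                intensities = np.clip(intensities, 0.0, None)
                sums = intensities.sum(axis=1, keepdims=True)
                sums[sums == 0] = 1.0
                fractions = intensities / sums
            else:
                fractions = clean / clean.sum(axis=1, keepdims=True)
            out.append(
                SpeciesTimeCourse(
                    times=times,
                    fractions=fractions,
                    replicate_id=f"rep{rep + 1}",
                    inhibitor_concentration=conc,
                )
            )
    return out


def generate_kobs_series(
    k_max: float,
    K_i: float,
    concentrations: Sequence[float] = (0.0, 1.0, 2.0, 5.0, 10.0, 50.0),
    noise_sd: float = 0.0,
    seed: int | None = None,
    step_label: str = "first",
) -> KobsSeries:
    """k_obs-vs-concentration series from the competitive-inhibition model.

    Noise is multiplicative log-normal: k_obs · exp(N(0, σ)), the natural
    noise model for rate constants estimated from exponential fits.
    """
    conc = np.asarray(concentrations, dtype=float)
    kobs = k_max / (1.0 + conc / K_i)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        kobs = kobs * np.exp(rng.normal(0.0, noise_sd, kobs.shape))
    return KobsSeries(concentrations=conc, kobs=kobs, step_label=step_label)


def generate_itc(
    params: thermo.BindingThermodynamics,
    design: thermo.ITCTitration | None = None,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> thermo.ITCTitration:
    """ITC titration from the single-site forward model with Gaussian heat noise."""
    if design is None:
        design = thermo.ITCTitration.standard_design(conditions=params.conditions)
    return thermo.simulate_itc(params, design, noise_sd=noise_sd, seed=seed)


def generate_bli(
    kinetics: thermo.BLIKinetics,
    concentrations: Sequence[float] = (12.5e-6, 25e-6, 50e-6, 100e-6),
    t_assoc: float = 300.0,
    t_dissoc: float = 300.0,
    n_points: int = 151,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> list[thermo.Sensorgram]:
    """Biphasic BLI sensorgram set with additive Gaussian response noise."""
    return thermo.simulate_bli(
        kinetics,
        concentrations,
        t_assoc=t_assoc,
        t_dissoc=t_dissoc,
        n_points=n_points,
        noise_sd=noise_sd,
        seed=seed,
    )
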