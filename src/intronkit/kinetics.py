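"""Closed-form model of irreversible two-step group II intron self-splicing.

The splicing reaction proceeds through two sequential first-order steps:
the precursor (5e-I-3e) is cleaved at the 5' splice junction with rate
constant ``k1`` to give the intron-3'-exon intermediate (I-3e), which is
then resolved with rate constant ``k2`` into ligated exons and the free
linear intron (I).  With unit initial precursor and both steps
irreversible, the species fractions follow the classical sequential
first-order (Bateman) solution:

    precursor(t)    = exp(-k1 t)
    intermediate(t) = k1/(k2-k1) * (exp(-k1 t) - exp(-k2 t))      (k1 != k2)
                    = k1 t exp(-k1 t)                             (k1 == k2)
    product(t)      = 1 - precursor(t) - intermediate(t)

Times are minutes and rate constants min^-1 throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SplicingRateConstants",
    "SpeciesFractions",
    "SpeciesTimeCourse",
    "species_fractions",
    "bateman_fractions",
    "intermediate_peak_time",
    "simulate_time_course",
]

#: relative |k1-k2| threshold below which the degenerate-limit formula is used
#: (avoids catastrophic cancellation in the two-exponential difference)
DEGENERACY_RTOL = 1e-6


@dataclass(frozen=True)
class SplicingRateConstants:
    """Step-specific first-order rate constants of the splicing scheme.

    Parameters
    ----------
    k1 : float
        Rate constant of the first step (5' junction hydrolysis), min^-1.
    k2 : float
        Rate constant of the second step (intron release), min^-1.
    """

    k1: float
    k2: float

    def __post_init__(self) -> None:
        for name, k in (("k1", self.k1), ("k2", self.k2)):
            if not (math.isfinite(k) and k > 0):
                raise ValueError(f"{name} must be finite and positive, got {k!r}")


@dataclass(frozen=True)
class SpeciesFractions:
    """Fractions of precursor, intermediate, and free intron at one time point."""

    precursor: float
    intermediate: float
    product: float

    def __post_init__(self) -> None:
        tol = 1e-9
        for name, f in self.as_tuple_named():
            if not (-tol <= f <= 1 + tol):
                raise ValueError(f"{name} fraction {f!r} outside [0, 1]")
        total = self.precursor + self.intermediate + self.product
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {total!r}")

    def as_tuple_named(self):
        return (
            ("precursor", self.precursor),
            ("intermediate", self.intermediate),
            ("product", self.product),
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.precursor, self.intermediate, self.product])


@dataclass
class SpeciesTimeCourse:
    """Time-resolved species fractions for one replicate at one inhibitor dose.

    ``fractions`` is an (n, 3) array with columns precursor, intermediate,
    product; rows are expected to sum to 1 (gel fractions are normalized
    band intensities).
    """

    times: np.ndarray  # min
    fractions: np.ndarray  # (n, 3)
    replicate_id: str = "rep1"
    inhibitor_concentration: float = 0.0  # μM

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be one-dimensional")
        if np.any(self.times < 0):
            raise ValueError("times must be non-negative")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.fractions.shape != (self.times.size, 3):
            raise ValueError(
                f"fractions must have shape ({self.times.size}, 3), "
                f"got {self.fractions.shape}"
            )
        if np.any(self.fractions < -1e-9) or np.any(self.fractions > 1 + 1e-9):
            raise ValueError("fractions must lie in [0, 1]")
        sums = self.fractions.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("species fractions must sum to 1 at every time point")
        if self.inhibitor_concentration < 0:
            raise ValueError("inhibitor concentration must be >= 0")

    def __len__(self) -> int:
        return self.times.size


def bateman_fractions(
    times: np.ndarray, k1: float, k2: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Bateman solution; returns (precursor, intermediate, product).

    Switches to the degenerate-limit formula ``k1 t exp(-k1 t)`` when
    |k1 - k2| < DEGENERACY_RTOL * max(k1, k2).
    """
    t = np.asarray(times, dtype=float)
    p = np.exp(-k1 * t)
    if abs(k1 - k2) < DEGENERACY_RTOL * max(k1, k2):
        inter = k1 * t * np.exp(-k1 * t)
    else:
        inter = k1 / (k2 - k1) * (np.exp(-k1 * t) - np.exp(-k2 * t))
    inter = np.clip(inter, 0.0, 1.0)
    prod = np.clip(1.0 - p - inter, 0.0, 1.0)
    return p, inter, prod


def species_fractions(t: float, rates: SplicingRateConstants) -> SpeciesFractions:
    """Species fractions of the two-step scheme at time ``t`` (min).

    Raises ``ValueError`` for negative ``t``.
    """
    if not (math.isfinite(t) and t >= 0):
        raise ValueError(f"time must be finite and >= 0, got {t!r}")
    p, inter, prod = bateman_fractions(np.array([t]), rates.k1, rates.k2)
    return SpeciesFractions(float(p[0]), float(inter[0]), float(prod[0]))


def intermediate_peak_time(rates: SplicingRateConstants) -> float:
    """Time (min) at which the intermediate I-3e fraction is maximal.

    t* = ln(k1/k2) / (k1 - k2), with the continuous limit 1/k at k1 = k2.
    A diagnostic for inhibitor-induced intermediate accumulation.
    """
    k1, k2 = rates.k1, rates.k2
    if abs(k1 - k2) < DEGENERACY_RTOL * max(k1, k2):
        return 1.0 / k1
    return math.log(k1 / k2) / (k1 - k2)


def simulate_time_course(
    grid,
    rates: SplicingRateConstants,
    concentration: float = 0.0,
    replicate_id: str = "rep1",
) -> SpeciesTimeCourse:
    """Noiseless trajectory on a time grid (min) at one inhibitor dose (μM)."""
    t = np.asarray(grid, dtype=float)
    if t.size == 0:
        raise ValueError("time grid must be non-empty")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    p, inter, prod = bateman_fractions(t, rates.k1, rates.k2)
    fractions = np.column_stack([p, inter, prod])
    # renormalize away the clipping epsilon so rows sum to 1 exactly
    fractions /= fractions.sum(axis=1, keepdims=True)
    return SpeciesTimeCourse(
        times=t,
        fractions=fractions,
        replicate_id=replicate_id,
        inhibitor_concentration=concentration,
    )
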