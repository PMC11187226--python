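"""Desk-scale thermodynamic integration over a Gauss-Legendre λ-schedule.

Relative binding free energies are assembled from a thermodynamic cycle:
an alchemical transformation A→B is carried out both in the bound state
(ligand in complex) and in the unbound state (ligand in a bath), giving
ΔΔG_AB = ΔG_bound − ΔG_unbound.  Each leg integrates the ensemble average
of ∂U/∂λ over the coupling parameter λ ∈ [0, 1],

    ΔG = ∫₀¹ ⟨∂U/∂λ⟩_λ dλ ≈ Σᵢ wᵢ ⟨∂U/∂λ⟩_{λᵢ},

with nodes and weights of the order-n Gauss-Legendre quadrature mapped to
the unit interval (weights rescaled to sum to 1).  The per-window averages
are estimated by Metropolis Monte Carlo sampling of analytically tractable
toy potentials, whose closed-form partition functions provide exact ΔG
oracles; U(x; λ) = (1−λ)·U_A(x) + λ·U_B(x), so ∂U/∂λ = U_B(x) − U_A(x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LambdaSchedule",
    "ToyAlchemicalSystem",
    "TIWindowSample",
    "ThermodynamicCycle",
    "gauss_legendre_schedule",
    "sample_dudl",
    "estimate_deltaG",
    "assemble_cycle",
    "run_ti",
]


@dataclass(frozen=True)
class LambdaSchedule:
    """Quadrature nodes/weights for the λ-integral on (0, 1)."""

    order: int
    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)
        if self.order < 1 or nodes.size != self.order or weights.size != self.order:
            raise ValueError("schedule size must match its order")
        if np.any(nodes <= 0) or np.any(nodes >= 1) or np.any(np.diff(nodes) <= 0):
            raise ValueError("nodes must be strictly increasing within (0, 1)")
        if np.any(weights <= 0) or abs(weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be positive and sum to 1")
        if not np.allclose(nodes + nodes[::-1], 1.0, atol=1e-10):
            raise ValueError("nodes must be symmetric about 0.5")
        if not np.allclose(weights, weights[::-1], atol=1e-12):
            raise ValueError("weights must be symmetric")


def gauss_legendre_schedule(order: int) -> LambdaSchedule:
    """Order-n Gauss-Legendre rule affinely mapped from [−1, 1] to [0, 1].

    The mapped weights (halved) sum to 1, so the quadrature approximates
    the plain λ-average ∫₀¹ f(λ) dλ as Σ wᵢ f(λᵢ).  Exact for polynomial
    integrands of degree ≤ 2n−1.
    """
    if not (1 <= order <= 64):
        raise ValueError(f"order must be in [1, 64], got {order!r}")
    x, w = np.polynomial.legendre.leggauss(order)
    return LambdaSchedule(order=order, nodes=(x + 1.0) / 2.0, weights=w / w.sum())


_FAMILIES = ("harmonic_stiffness", "shifted_well", "linear_field")


@dataclass(frozen=True)
class ToyAlchemicalSystem:
    """Analytic toy potential pair with λ-linear interpolation.

    Families (d-dimensional, isotropic):

    ``harmonic_stiffness``
        U = ½ k |x|², morphing stiffness ``k``; ΔG = (d·kT/2)·ln(k_B/k_A).
    ``shifted_well``
        U = ½ k |x − x0 e₁|², same ``k``, morphing the center ``x0``;
        ΔG = 0 (translation leaves the partition function unchanged)
        although ⟨∂U/∂λ⟩ is nonzero at every interior λ.
    ``linear_field``
        U = ½ k |x|² + b x₁, morphing the field ``b``;
        ΔG = −(b_B² − b_A²)/(2k).
    """

    family: str
    params_a: dict
    params_b: dict
    kT: float = 1.0
    dim: int = 1

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown potential family {self.family!r}")
        if self.kT <= 0:
            raise ValueError("kT must be positive")
        if not 1 <= self.dim <= 3:
            raise ValueError("dimension must be 1, 2, or 3")
        for p in (self.params_a, self.params_b):
            if self.family == "harmonic_stiffness" and p.get("k", 0) <= 0:
                raise ValueError("harmonic stiffness k must be positive")
            if self.family in ("shifted_well", "linear_field") and p.get("k", 0) <= 0:
                raise ValueError("confining stiffness k must be positive")
        if self.family == "shifted_well" and self.params_a["k"] != self.params_b["k"]:
            raise ValueError("shifted_well morphs the center at fixed stiffness")
        if self.family == "linear_field" and self.params_a["k"] != self.params_b["k"]:
            raise ValueError("linear_field morphs the field at fixed stiffness")

    def _potential(self, x: np.ndarray, p: dict) -> float:
        if self.family == "harmonic_stiffness":
            return 0.5 * p["k"] * float(x @ x)
        if self.family == "shifted_well":
            d = x.copy()
            d[0] -= p.get("x0", 0.0)
            return 0.5 * p["k"] * float(d @ d)
        return 0.5 * p["k"] * float(x @ x) + p.get("b", 0.0) * float(x[0])

    def U_A(self, x: np.ndarray) -> float:
        return self._potential(x, self.params_a)

    def U_B(self, x: np.ndarray) -> float:
        return self._potential(x, self.params_b)

    def potential(self, x: np.ndarray, lam: float) -> float:
        return (1.0 - lam) * self.U_A(x) + lam * self.U_B(x)

    def dudl(self, x: np.ndarray) -> float:
        return self.U_B(x) - self.U_A(x)

    def exact_deltaG(self) -> float:
        """Closed-form ΔG from the ratio of partition functions."""
        a, b = self.params_a, self.params_b
        if self.family == "harmonic_stiffness":
            return 0.5 * self.dim * self.kT * math.log(b["k"] / a["k"])
        if self.family == "shifted_well":
            return 0.0
        bb, ba = b.get("b", 0.0), a.get("b", 0.0)
        return -(bb * bb - ba * ba) / (2.0 * a["k"])

    def exact_mean_dudl(self, lam: float) -> float:
        """Closed-form ⟨∂U/∂λ⟩ at λ (Gaussian moments of the interpolated state)."""
        a, b = self.params_a, self.params_b
        if self.family == "harmonic_stiffness":
            klam = (1.0 - lam) * a["k"] + lam * b["k"]
            return 0.5 * (b["k"] - a["k"]) * self.dim * self.kT / klam
        if self.family == "shifted_well":
            k = a["k"]
            xa, xb = a.get("x0", 0.0), b.get("x0", 0.0)
            mean = (1.0 - lam) * xa + lam * xb
            # dU/dλ = k x (xa − xb) + ½k(xb² − xa²); ⟨x⟩ = mean
            return k * (xa - xb) * mean + 0.5 * k * (xb * xb - xa * xa)
        k = a["k"]
        ba, bb = a.get("b", 0.0), b.get("b", 0.0)
        blam = (1.0 - lam) * ba + lam * bb
        return (bb - ba) * (-blam / k)

    def reversed(self) -> "ToyAlchemicalSystem":
        return ToyAlchemicalSystem(
            self.family, dict(self.params_b), dict(self.params_a), self.kT, self.dim
        )


@dataclass(frozen=True)
class TIWindowSample:
    """Sample statistics of ∂U/∂λ at one λ-window."""

    lam: float
    mean_dudl: float
    var_dudl: float
    ess: float  # effective sample size
    n_samples: int
    seed: int | None = None
    acceptance_rate: float = float("nan")
    acceptance_warning: bool = False

    def __post_init__(self) -> None:
        if self.ess < 1:
            raise ValueError("effective sample size must be >= 1")


def _effective_sample_size(series: np.ndarray) -> float:
    """Initial-positive-sequence autocorrelation ESS (capped at n)."""
    n = series.size
    if n < 4:
        return float(n)
    x = series - series.mean()
    var = float(x @ x) / n
    if var <= 0:
        return float(n)
    max_lag = min(n // 2, 200)
    acf_sum = 0.0
    for lag in range(1, max_lag):
        rho = float(x[:-lag] @ x[lag:]) / ((n - lag) * var)
        if rho <= 0:
            break
        acf_sum += rho
    return float(np.clip(n / (1.0 + 2.0 * acf_sum), 1.0, n))


def sample_dudl(
    system: ToyAlchemicalSystem,
    lam: float,
    n_steps: int = 5000,
    burn_in: int | None = None,
    seed: int | None = None,
    step_size: float | None = None,
) -> TIWindowSample:
    """Metropolis random-walk estimate of ⟨∂U/∂λ⟩ at one window.

    The proposal step size is auto-tuned during burn-in (default: 20% of
    ``n_steps``) toward a 40% acceptance rate; a final acceptance rate
    outside [0.1, 0.9] sets a warning flag.  Deterministic given ``seed``.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("λ must lie in [0, 1]")
    if n_steps < 10:
        raise ValueError("n_steps must be at least 10")
    if burn_in is None:
        burn_in = n_steps // 5
    rng = np.random.default_rng(seed)
    d = system.dim
    # start near the bottom of the interpolated well
    x = np.zeros(d)
    if system.family == "shifted_well":
        x[0] = (1.0 - lam) * system.params_a.get("x0", 0.0) + lam * system.params_b.get("x0", 0.0)
    u = system.potential(x, lam)
    if step_size is None:
        kref = max(system.params_a.get("k", 1.0), system.params_b.get("k", 1.0))
        step_size = 2.4 * math.sqrt(system.kT / kref)

    accepted = 0
    proposed = 0
    # burn-in with step-size adaptation every 50 proposals
    block_acc = 0
    for i in range(burn_in):
        prop = x + step_size * rng.standard_normal(d)
        u_prop = system.potential(prop, lam)
        if u_prop <= u or rng.random() < math.exp(-(u_prop - u) / system.kT):
            x, u = prop, u_prop
            block_acc += 1
        if (i + 1) % 50 == 0:
            rate = block_acc / 50.0
            step_size *= math.exp(rate - 0.4)
            block_acc = 0

    samples = np.empty(n_steps)
    for i in range(n_steps):
        prop = x + step_size * rng.standard_normal(d)
        u_prop = system.potential(prop, lam)
        proposed += 1
        if u_prop <= u or rng.random() < math.exp(-(u_prop - u) / system.kT):
            x, u = prop, u_prop
            accepted += 1
        samples[i] = system.dudl(x)

    rate = accepted / proposed if proposed else float("nan")
    mean = float(samples.mean())
    var = float(samples.var(ddof=1)) if n_steps > 1 else 0.0
    ess = _effective_sample_size(samples) if var > 0 else float(n_steps)
    return TIWindowSample(
        lam=float(lam),
        mean_dudl=mean,
        var_dudl=var,
        ess=ess,
        n_samples=n_steps,
        seed=seed,
        acceptance_rate=rate,
        acceptance_warning=not (0.1 <= rate <= 0.9),
    )


def estimate_deltaG(
    schedule: LambdaSchedule, samples: Sequence[TIWindowSample]
) -> tuple[float, float]:
    """Quadrature ΔG = Σ wᵢ·⟨∂U/∂λ⟩ᵢ with propagated window standard errors.

    Windows are treated as independent; each window's standard error is
    sqrt(var/ess).
    """
    samples = list(samples)
    if len(samples) != schedule.order:
        raise ValueError("one window sample per schedule node is required")
    lams = np.array([s.lam for s in samples])
    if not np.allclose(lams, schedule.nodes, atol=1e-9):
        raise ValueError("window λ values do not match the schedule nodes")
    means = np.array([s.mean_dudl for s in samples])
    var_of_mean = np.array([s.var_dudl / s.ess for s in samples])
    dG = float(schedule.weights @ means)
    se = float(math.sqrt(float(schedule.weights**2 @ var_of_mean)))
    return dG, se


@dataclass(frozen=True)
class ThermodynamicCycle:
    """Assembled relative binding free energy ΔΔG = ΔG_bound − ΔG_unbound."""

    dG_bound: float
    se_bound: float
    dG_unbound: float
    se_unbound: float
    ddG: float
    se: float
    source: str = "TI"

    def __post_init__(self) -> None:
        if abs(self.ddG - (self.dG_bound - self.dG_unbound)) > 1e-9:
            raise ValueError("ΔΔG must equal bound-leg minus unbound-leg")


def assemble_cycle(
    bound: tuple[float, float], unbound: tuple[float, float], source: str = "TI"
) -> ThermodynamicCycle:
    """Combine the two legs; errors add in quadrature."""
    dgb, seb = bound
    dgu, seu = unbound
    return ThermodynamicCycle(
        dG_bound=dgb,
        se_bound=seb,
        dG_unbound=dgu,
        se_unbound=seu,
        ddG=dgb - dgu,
        se=math.sqrt(seb * seb + seu * seu),
        source=source,
    )


def run_ti(
    bound_system: ToyAlchemicalSystem,
    unbound_system: ToyAlchemicalSystem,
    schedule: LambdaSchedule | None = None,
    n_steps: int = 5000,
    burn_in_fraction: float = 0.2,
    seed: int | None = None,
) -> tuple[ThermodynamicCycle, dict]:
    """End-to-end TI: sample both legs over all windows and assemble the cycle.

    Returns the cycle and a detail dict with per-leg window samples.
    Child window seeds are derived deterministically from ``seed``.
    """
    if schedule is None:
        schedule = gauss_legendre_schedule(12)
    burn_in = int(burn_in_fraction * n_steps)
    ss = np.random.SeedSequence(seed)
    legs = {}
    results = {}
    for leg_name, system, child in zip(
        ("bound", "unbound"), (bound_system, unbound_system), ss.spawn(2)
    ):
        window_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(schedule.order)]
        windows = [
            sample_dudl(system, lam, n_steps=n_steps, burn_in=burn_in, seed=wseed)
            for lam, wseed in zip(schedule.nodes, window_seeds)
        ]
        legs[leg_name] = windows
        results[leg_name] = estimate_deltaG(schedule, windows)
    cycle = assemble_cycle(results["bound"], results["unbound"])
    return cycle, {"schedule": schedule, "windows": legs, "legs": results}
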