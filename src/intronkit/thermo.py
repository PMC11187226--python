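"""Binding thermodynamics and kinetics for RNA-ligand interactions.

Interconversion between dissociation constants and free energies
(ΔG = RT ln(K_D/c°)), the enthalpy-entropy decomposition
(−TΔS = ΔG − ΔH), relative binding free energies from inhibition-constant
pairs with delta-method error propagation, a single-site ITC isotherm
forward model and fit, and the biphasic ("2:1 heterogeneous") BLI kinetic
model fitted globally across analyte concentrations.

Concentrations are molar inside this module (the file readers in
:mod:`intronkit.io` convert from μM); energies are kcal/mol; the standard
state is c° = 1 M and logs are natural.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "GAS_CONSTANT_KCAL",
    "ThermoConditions",
    "BindingThermodynamics",
    "RelativeBindingFreeEnergy",
    "ITCTitration",
    "ITCFitResult",
    "BLIKinetics",
    "Sensorgram",
    "deltaG_from_KD",
    "KD_from_deltaG",
    "minus_T_deltaS",
    "ddG_from_Ki",
    "simulate_itc",
    "fit_itc_single_site",
    "simulate_bli",
    "fit_bli_biphasic",
]

#: gas constant in kcal·mol⁻¹·K⁻¹
GAS_CONSTANT_KCAL = 1.9872042586e-3


@dataclass(frozen=True)
class ThermoConditions:
    """Temperature and standard-state conventions."""

    temperature: float = 298.15  # K
    R: float = GAS_CONSTANT_KCAL  # kcal/mol/K
    standard_concentration: float = 1.0  # M

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (kelvin)")

    @classmethod
    def from_celsius(cls, celsius: float) -> "ThermoConditions":
        return cls(temperature=celsius + 273.15)

    @property
    def RT(self) -> float:
        return self.R * self.temperature


def deltaG_from_KD(K_D: float, conditions: ThermoConditions = ThermoConditions()) -> float:
    """Standard binding free energy ΔG = RT ln(K_D / c°) in kcal/mol."""
    if not (K_D > 0 and math.isfinite(K_D)):
        raise ValueError(f"K_D must be positive and finite, got {K_D!r}")
    return conditions.RT * math.log(K_D / conditions.standard_concentration)


def KD_from_deltaG(delta_G: float, conditions: ThermoConditions = ThermoConditions()) -> float:
    """Inverse of :func:`deltaG_from_KD`."""
    return conditions.standard_concentration * math.exp(delta_G / conditions.RT)


def minus_T_deltaS(delta_G: float, delta_H: float) -> float:
    """Entropic term −TΔS = ΔG − ΔH (kcal/mol)."""
    return delta_G - delta_H


@dataclass(frozen=True)
class BindingThermodynamics:
    """K_D with the full thermodynamic decomposition ΔG = ΔH − TΔS."""

    K_D: float  # M
    delta_H: float  # kcal/mol
    delta_G: float  # kcal/mol
    minus_T_delta_S: float  # kcal/mol
    N: float = 1.0  # stoichiometry
    conditions: ThermoConditions = ThermoConditions()

    def __post_init__(self) -> None:
        if not self.K_D > 0:
            raise ValueError("K_D must be positive")
        if abs(self.delta_G - (self.delta_H + self.minus_T_delta_S)) > 1e-9:
            raise ValueError("ΔG must equal ΔH + (−TΔS)")

    @classmethod
    def from_KD_dH(
        cls,
        K_D: float,
        delta_H: float,
        N: float = 1.0,
        conditions: ThermoConditions = ThermoConditions(),
    ) -> "BindingThermodynamics":
        dG = deltaG_from_KD(K_D, conditions)
        return cls(
            K_D=K_D,
            delta_H=delta_H,
            delta_G=dG,
            minus_T_delta_S=minus_T_deltaS(dG, delta_H),
            N=N,
            conditions=conditions,
        )


@dataclass(frozen=True)
class RelativeBindingFreeEnergy:
    """ΔΔG for a pair of ligands, antisymmetric under label swap."""

    ddG: float  # kcal/mol
    se: float  # kcal/mol
    label_a: str = "A"
    label_b: str = "B"
    source: str = "experimental_Ki"  # or "TI"


def ddG_from_Ki(
    Ki_A: float,
    Ki_B: float,
    se_A: float = 0.0,
    se_B: float = 0.0,
    conditions: ThermoConditions = ThermoConditions(),
    label_a: str = "A",
    label_b: str = "B",
) -> RelativeBindingFreeEnergy:
    """Relative binding free energy ΔΔG = RT ln(Ki_B/Ki_A) from a K_i pair.

    The standard error is first-order (delta-method) propagation,
    RT·sqrt((σ_A/Ki_A)² + (σ_B/Ki_B)²).  Units of the K_i pair cancel.
    """
    for name, ki in (("Ki_A", Ki_A), ("Ki_B", Ki_B)):
        if not (ki > 0 and math.isfinite(ki)):
            raise ValueError(f"{name} must be positive and finite, got {ki!r}")
    RT = conditions.RT
    # difference of logs (not log of ratio) so label-swap antisymmetry is
    # exact in floating point
    ddg = RT * (math.log(Ki_B) - math.log(Ki_A))
    se = RT * math.sqrt((se_A / Ki_A) ** 2 + (se_B / Ki_B) ** 2)
    return RelativeBindingFreeEnergy(ddg, se, label_a, label_b, "experimental_Ki")


# ---------------------------------------------------------------------------
# ITC
# ---------------------------------------------------------------------------


@dataclass
class ITCTitration:
    """An ITC experiment design with (optionally) the measured heats.

    ``heats`` are per-injection integrated heats normalized per mole of
    injectant (kcal/mol); ``None`` for a design not yet measured/simulated.
    """

    cell_concentration: float  # M (macromolecule in the cell)
    syringe_concentration: float  # M (ligand in the syringe)
    injection_volumes: np.ndarray  # L, one entry per injection
    cell_volume: float  # L
    heats: np.ndarray | None = None  # kcal per mol of injectant
    conditions: ThermoConditions = field(default_factory=ThermoConditions)

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if np.any(self.injection_volumes <= 0) or self.cell_volume <= 0:
            raise ValueError("volumes must be positive")
        if self.cell_concentration <= 0 or self.syringe_concentration <= 0:
            raise ValueError("concentrations must be positive")
        if self.heats is not None:
            self.heats = np.asarray(self.heats, dtype=float)
            if self.heats.shape != self.injection_volumes.shape:
                raise ValueError("heats must have one entry per injection")

    @classmethod
    def standard_design(
        cls,
        cell_concentration: float = 30e-6,
        syringe_concentration: float = 600e-6,
        n_injections: int = 16,
        injection_volume: float = 2.5e-6,
        cell_volume: float = 200e-6,
        conditions: ThermoConditions = ThermoConditions(),
    ) -> "ITCTitration":
        """The study's titration geometry: 30 μM cell, 600 μM syringe,
        16 × 2.5 μL injections into a 200 μL calorimetric cell."""
        return cls(
            cell_concentration=cell_concentration,
            syringe_concentration=syringe_concentration,
            injection_volumes=np.full(n_injections, injection_volume),
            cell_volume=cell_volume,
            conditions=conditions,
        )


def _bound_concentration(N: float, Mt: np.ndarray, Xt: np.ndarray, Kd: float) -> np.ndarray:
    """Bound-ligand concentration from single-site mass action (quadratic root)."""
    b = N * Mt + Xt + Kd
    disc = np.clip(b * b - 4.0 * N * Mt * Xt, 0.0, np.inf)
    return 0.5 * (b - np.sqrt(disc))


def _itc_total_concentrations(titration: ITCTitration) -> tuple[np.ndarray, np.ndarray]:
    """Total macromolecule/ligand concentrations in the cell after each
    injection, under the constant-volume perfusion (continuous displacement)
    model: well-mixed injectate enters while an equal volume of mixed cell
    content overflows."""
    frac = np.exp(-np.cumsum(titration.injection_volumes) / titration.cell_volume)
    Mt = titration.cell_concentration * frac
    Xt = titration.syringe_concentration * (1.0 - frac)
    return Mt, Xt


def itc_injection_heats(
    titration: ITCTitration, N: float, Kd: float, delta_H: float, offset: float = 0.0
) -> np.ndarray:
    """Per-injection heats (kcal per mole of injectant) of the single-site model.

    The heat of injection i is ΔH times the moles of complex formed by
    reaction during the injection; complex carried out with the displaced
    volume releases no heat and is accounted for by a trapezoidal term:

        q_i = ΔH·[V0·(B_i − B_{i−1}) + v_i·(B_i + B_{i−1})/2] / (Xs·v_i) + offset
    """
    Mt, Xt = _itc_total_concentrations(titration)
    B = _bound_concentration(N, Mt, Xt, Kd)
    Bprev = np.concatenate([[0.0], B[:-1]])
    v = titration.injection_volumes
    V0 = titration.cell_volume
    reacted_moles = V0 * (B - Bprev) + v * 0.5 * (B + Bprev)
    injected_moles = titration.syringe_concentration * v
    return delta_H * reacted_moles / injected_moles + offset


def simulate_itc(
    params: BindingThermodynamics,
    design: ITCTitration,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> ITCTitration:
    """Forward-simulate an ITC titration; additive Gaussian heat noise (kcal/mol)."""
    heats = itc_injection_heats(design, params.N, params.K_D, params.delta_H)
    if noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        heats = heats + rng.normal(0.0, noise_sd, size=heats.shape)
    return replace(design, heats=heats)


@dataclass
class ITCFitResult:
    """Single-site ITC fit: thermodynamics plus fit diagnostics."""

    thermodynamics: BindingThermodynamics
    offset: float
    se_N: float
    se_K_D: float
    se_delta_H: float
    covariance: np.ndarray
    c_value: float
    residual_ss: float
    c_value_warning: bool = False
    non_identifiable: bool = False


def fit_itc_single_site(titration: ITCTitration) -> ITCFitResult:
    """Fit (N, K_D, ΔH, constant offset) to integrated injection heats.

    The offset absorbs the blank (heat-of-dilution) control; ΔG and −TΔS
    are derived from the fitted K_D at the titration's temperature.
    A c-value (N·[cell]/K_D) outside [1, 1000] sets a warning flag; a flat
    heat profile is flagged non-identifiable.
    """
    if titration.heats is None:
        raise ValueError("titration carries no measured heats")
    y = titration.heats
    n_inform = y.size
    if n_inform < 6:
        raise ValueError("at least 6 injections are required")
    if np.ptp(y) < 1e-12 * max(1.0, np.max(np.abs(y))):
        thermo = BindingThermodynamics.from_KD_dH(
            K_D=1.0, delta_H=0.0, N=1.0, conditions=titration.conditions
        )
        return ITCFitResult(
            thermodynamics=thermo,
            offset=float(np.mean(y)),
            se_N=math.nan,
            se_K_D=math.nan,
            se_delta_H=math.nan,
            covariance=np.full((4, 4), np.nan),
            c_value=math.nan,
            residual_ss=0.0,
            non_identifiable=True,
        )

    def residuals(p):
        N, logKd, dH, off = p
        return itc_injection_heats(titration, N, math.exp(logKd), dH, off) - y

    dH0 = float(y[0] - y[-1])
    if dH0 == 0.0:
        dH0 = float(y[0])
    best = None
    for kd0 in titration.cell_concentration * np.array([0.03, 0.1, 0.3, 1.0, 3.0]):
        res = optimize.least_squares(
            residuals,
            x0=[1.0, math.log(kd0), dH0, float(y[-1])],
            bounds=([1e-3, math.log(1e-12), -1e4, -1e4], [1e3, math.log(1.0), 1e4, 1e4]),
            xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or res.cost < best.cost:
            best = res
    if not best.success and best.cost > 1e-6:
        raise RuntimeError(f"ITC fit did not converge: {best.message}")

    N, logKd, dH, off = best.x
    Kd = math.exp(logKd)
    m, npar = best.jac.shape
    s2 = 2.0 * best.cost / max(m - npar, 1)
    try:
        cov = s2 * np.linalg.inv(best.jac.T @ best.jac)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(best.jac.T @ best.jac)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    c_value = N * titration.cell_concentration / Kd
    thermo = BindingThermodynamics.from_KD_dH(
        K_D=Kd, delta_H=float(dH), N=float(N), conditions=titration.conditions
    )
    return ITCFitResult(
        thermodynamics=thermo,
        offset=float(off),
        se_N=float(se[0]),
        se_K_D=float(Kd * se[1]),  # delta method from log-space
        se_delta_H=float(se[2]),
        covariance=cov,
        c_value=float(c_value),
        residual_ss=float(2.0 * best.cost),
        c_value_warning=not (1.0 <= c_value <= 1000.0),
    )


# ---------------------------------------------------------------------------
# BLI
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BLIKinetics:
    """Rates and amplitudes of the biphasic (two independent site classes)
    Langmuir model; K_Di = k_offi/k_oni by construction."""

    k_on1: float  # M^-1 s^-1
    k_on2: float
    k_off1: float  # s^-1
    k_off2: float
    rmax1: float  # nm, saturating response of each phase
    rmax2: float
    single_phase_warning: bool = False

    @property
    def K_D1(self) -> float:
        return self.k_off1 / self.k_on1

    @property
    def K_D2(self) -> float:
        return self.k_off2 / self.k_on2


@dataclass
class Sensorgram:
    """One association/dissociation trace at a single analyte concentration.

    Dissociation times are measured from the start of the dissociation phase.
    """

    concentration: float  # M
    t_assoc: np.ndarray  # s
    y_assoc: np.ndarray  # nm
    t_dissoc: np.ndarray  # s since dissociation start
    y_dissoc: np.ndarray  # nm

    def __post_init__(self) -> None:
        self.t_assoc = np.asarray(self.t_assoc, dtype=float)
        self.y_assoc = np.asarray(self.y_assoc, dtype=float)
        self.t_dissoc = np.asarray(self.t_dissoc, dtype=float)
        self.y_dissoc = np.asarray(self.y_dissoc, dtype=float)
        if self.concentration <= 0:
            raise ValueError("analyte concentration must be positive")


def _bli_phase_response(kin: BLIKinetics, conc: float, t_assoc, t_dissoc, t_assoc_end):
    """Responses of the sum-of-two-Langmuir-phases model."""
    resp_a = np.zeros_like(np.asarray(t_assoc, dtype=float))
    levels = []
    for kon, koff, rmax in (
        (kin.k_on1, kin.k_off1, kin.rmax1),
        (kin.k_on2, kin.k_off2, kin.rmax2),
    ):
        kobs = kon * conc + koff
        req = rmax * kon * conc / kobs
        resp_a = resp_a + req * (1.0 - np.exp(-kobs * np.asarray(t_assoc, dtype=float)))
        levels.append(req * (1.0 - math.exp(-kobs * t_assoc_end)))
    resp_d = levels[0] * np.exp(-kin.k_off1 * np.asarray(t_dissoc, dtype=float)) + levels[
        1
    ] * np.exp(-kin.k_off2 * np.asarray(t_dissoc, dtype=float))
    return resp_a, resp_d


def simulate_bli(
    kin: BLIKinetics,
    concentrations: Sequence[float],
    t_assoc: float = 300.0,
    t_dissoc: float = 300.0,
    n_points: int = 151,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
) -> list[Sensorgram]:
    """Forward-simulate sensorgrams at each analyte concentration (M)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ta = np.linspace(0.0, t_assoc, n_points)
    td = np.linspace(0.0, t_dissoc, n_points)
    out = []
    for conc in concentrations:
        ya, yd = _bli_phase_response(kin, conc, ta, td, t_assoc)
        if noise_sd > 0:
            ya = ya + rng.normal(0.0, noise_sd, ya.shape)
            yd = yd + rng.normal(0.0, noise_sd, yd.shape)
        out.append(Sensorgram(conc, ta, ya, td, yd))
    return out


def _bli_residuals(p, sensorgrams, t_assoc_end):
    kin = BLIKinetics(
        k_on1=math.exp(p[0]), k_on2=math.exp(p[1]),
        k_off1=math.exp(p[2]), k_off2=math.exp(p[3]),
        rmax1=p[4], rmax2=p[5],
    )
    res = []
    for s in sensorgrams:
        ya, yd = _bli_phase_response(kin, s.concentration, s.t_assoc, s.t_dissoc, t_assoc_end)
        res.append(ya - s.y_assoc)
        res.append(yd - s.y_dissoc)
    return np.concatenate(res)


def _bli_initial_rates(sensorgrams) -> tuple[float, float]:
    """Rough (kon, koff) scales from the highest-concentration trace."""
    s = max(sensorgrams, key=lambda g: g.concentration)
    # koff scale: log-slope of the dissociation tail
    y = np.clip(s.y_dissoc, 1e-12, None)
    mask = y > 0.05 * y[0] if y[0] > 0 else np.ones_like(y, bool)
    if mask.sum() >= 2:
        koff = max(-np.polyfit(s.t_dissoc[mask], np.log(y[mask]), 1)[0], 1e-6)
    else:
        koff = 1e-3
    # kobs scale: time to reach half the final association level
    ya = s.y_assoc
    if ya[-1] > 0:
        half_idx = int(np.searchsorted(ya, 0.5 * ya[-1]))
        t_half = s.t_assoc[min(half_idx, ya.size - 1)]
        kobs = math.log(2.0) / max(t_half, 1e-6)
    else:
        kobs = 1e-2
    kon = max((kobs - koff) / s.concentration, 1e-3)
    return kon, koff


def fit_bli_biphasic(
    sensorgrams: Sequence[Sensorgram],
    t_assoc_end: float | None = None,
) -> BLIKinetics:
    """Global fit of the biphasic Langmuir model across analyte concentrations.

    Rates are shared across all traces; each phase has one shared saturating
    amplitude.  Phases are reported sorted by increasing k_off (phase 1 =
    slow dissociation).  When one phase's amplitude collapses to ~0, the
    result carries a ``single_phase_warning`` and phase-2 rates are not
    meaningful.
    """
    sensorgrams = list(sensorgrams)
    if len(sensorgrams) < 3:
        raise ValueError("at least 3 analyte concentrations are required")
    if t_assoc_end is None:
        t_assoc_end = float(max(s.t_assoc[-1] for s in sensorgrams))

    kon0, koff0 = _bli_initial_rates(sensorgrams)
    rmax0 = float(max(np.max(s.y_assoc) for s in sensorgrams))
    lo = [math.log(1e-6)] * 4 + [0.0, 0.0]
    hi = [math.log(1e9)] * 4 + [np.inf, np.inf]

    best = None
    for split in (3.0, 10.0, 30.0):
        x0 = [
            math.log(kon0 / split), math.log(kon0 * split),
            math.log(max(koff0 / split, 1e-6)), math.log(koff0 * split),
            rmax0, rmax0,
        ]
        res = optimize.least_squares(
            _bli_residuals, x0, args=(sensorgrams, t_assoc_end),
            bounds=(lo, hi), xtol=1e-15, ftol=1e-15, gtol=1e-15,
        )
        if best is None or res.cost < best.cost:
            best = res

    p = best.x
    phases = [
        (math.exp(p[2]), math.exp(p[0]), p[4]),
        (math.exp(p[3]), math.exp(p[1]), p[5]),
    ]
    total_amp = phases[0][2] + phases[1][2]
    warn = any(amp < 1e-2 * max(total_amp, 1e-12) for _, _, amp in phases)
    # order by koff, but keep a vanishing-amplitude phase second
    phases.sort(key=lambda ph: (ph[2] < 1e-2 * max(total_amp, 1e-12), ph[0]))
    (koff1, kon1, r1), (koff2, kon2, r2) = phases
    return BLIKinetics(
        k_on1=kon1, k_on2=kon2, k_off1=koff1, k_off2=koff2,
        rmax1=r1, rmax2=r2, single_phase_warning=warn,
    )
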