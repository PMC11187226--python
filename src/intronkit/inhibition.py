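"""Inference of splicing-inhibition parameters from kinetic assay data.

Covers the quantitative readouts of the splicing assays:

* step-specific rate constants (k1, k2) fitted to species time courses
  with the two-step model in :mod:`intronkit.kinetics`;
* the competitive-inhibition constant K_i from an observed-rate series,
  k_obs = k_max / (1 + [I]/K_i);
* IC50 from dose-response hyperbolas, % = 100 / (1 + [I]/IC50), applied
  both to the percent-reacted-precursor readout of the gel assay and to
  the %activity readout of the FRET-based spliced-exon-reopening assay;
* fold-changes of the two steps between control and inhibited reactions.

All concentrations are μM and rate constants min^-1.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

from .kinetics import SpeciesTimeCourse, SplicingRateConstants, bateman_fractions

__all__ = [
    "KobsSeries",
    "InhibitionFit",
    "RateConstantFit",
    "PrecursorFractionRecord",
    "DoseResponseFit",
    "StepSelectivity",
    "fit_rate_constants",
    "fit_ki",
    "percent_reacted_precursor",
    "fit_ic50",
    "fret_initial_slopes",
    "step_selectivity",
]


class FitError(RuntimeError):
    """A nonlinear fit failed to converge; carries solver diagnostics."""


@dataclass
class KobsSeries:
    """Observed rate constants as a function of inhibitor concentration."""

    concentrations: np.ndarray  # μM
    kobs: np.ndarray  # min^-1
    se: np.ndarray | None = None  # min^-1, optional per-point standard errors
    step_label: Literal["first", "second"] = "first"

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.kobs = np.asarray(self.kobs, dtype=float)
        if self.concentrations.shape != self.kobs.shape:
            raise ValueError("concentrations and kobs must have the same shape")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")
        if len(set(self.concentrations.tolist())) != self.concentrations.size:
            raise ValueError("concentrations must be distinct")
        if np.any(self.kobs <= 0):
            raise ValueError("k_obs values must be positive")
        if self.se is not None:
            self.se = np.asarray(self.se, dtype=float)
            if self.se.shape != self.kobs.shape:
                raise ValueError("se must match kobs shape")

    def __len__(self) -> int:
        return self.kobs.size


@dataclass
class InhibitionFit:
    """Result of the hyperbolic inhibition fit k_obs = k_max/(1 + [I]/K_i)."""

    k_max: float
    K_i: float
    se_k_max: float
    se_K_i: float
    covariance: np.ndarray
    n_points: int
    step_label: str = "first"
    non_identifiable: bool = False

    def confidence_interval(self, level: float = 0.95) -> tuple[float, float]:
        """t-based confidence interval for K_i (df = n - 2)."""
        df = max(self.n_points - 2, 1)
        tcrit = stats.t.ppf(0.5 + level / 2, df)
        return (self.K_i - tcrit * self.se_K_i, self.K_i + tcrit * self.se_K_i)


@dataclass
class RateConstantFit:
    """Fitted step rate constants with fit- and replicate-level uncertainties."""

    rates: SplicingRateConstants
    se_k1: float
    se_k2: float
    covariance: np.ndarray
    mode: str
    n_replicates: int
    residual_ss: float
    sem_k1: float | None = None  # across-replicate s.e.m. when >= 2 replicates
    sem_k2: float | None = None
    per_replicate: list[tuple[float, float]] | None = None
    non_identifiable: bool = False


@dataclass(frozen=True)
class PrecursorFractionRecord:
    """Precursor fraction measured at 15 min for one inhibitor concentration."""

    concentration: float  # μM
    fraction: float  # F_5e-I-3e at 15 min
    is_dmso_reference: bool = False
    is_imax_reference: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError(f"fraction {self.fraction!r} outside [0, 1]")
        if self.concentration < 0:
            raise ValueError("concentration must be >= 0")


@dataclass
class DoseResponseFit:
    """One-parameter dose-response fit % = 100/(1 + [I]/IC50)."""

    IC50: float  # μM
    se_IC50: float
    response_kind: Literal["percent_reacted_precursor", "percent_activity"]
    n_points: int
    monotonicity_warning: bool = False


@dataclass(frozen=True)
class StepSelectivity:
    """Fold slow-down of each step and their ratio (second vs first)."""

    fold_1: float
    fold_2: float
    selectivity_ratio: float


# ---------------------------------------------------------------------------
# rate-constant fitting
# ---------------------------------------------------------------------------


def _initial_rate_guesses(times: np.ndarray, fractions: np.ndarray) -> tuple[float, float]:
    """Heuristic starting values: k1 from the early log-linear precursor decay,
    k2 from the post-peak decay of the intermediate."""
    k1 = 0.05
    half = max(times.size // 2, 2)
    mask = fractions[:half, 0] > 1e-6
    if mask.sum() >= 2:
        slope = np.polyfit(times[:half][mask], np.log(fractions[:half, 0][mask]), 1)[0]
        if slope < 0:
            k1 = -slope
    k2 = 0.02
    peak = int(np.argmax(fractions[:, 1]))
    tail_t, tail_i = times[peak:], fractions[peak:, 1]
    mask = tail_i > 1e-6
    if mask.sum() >= 2:
        slope = np.polyfit(tail_t[mask], np.log(tail_i[mask]), 1)[0]
        if slope < 0:
            k2 = -slope
    return float(np.clip(k1, 1e-4, 10.0)), float(np.clip(k2, 1e-4, 10.0))


def _stack_courses(
    courses: SpeciesTimeCourse | Sequence[SpeciesTimeCourse],
) -> list[SpeciesTimeCourse]:
    if isinstance(courses, SpeciesTimeCourse):
        return [courses]
    out = list(courses)
    if not out:
        raise ValueError("at least one time course is required")
    return out


def _joint_residuals(params, courses):
    k1, k2 = params
    res = []
    for c in courses:
        p, i, pr = bateman_fractions(c.times, k1, k2)
        res.append((np.column_stack([p, i, pr]) - c.fractions).ravel())
    return np.concatenate(res)


def _lsq(fun, x0, bounds, args=()):
    return optimize.least_squares(
        fun, x0, bounds=bounds, args=args, xtol=1e-14, ftol=1e-14, gtol=1e-14
    )


def _cov_from_lsq(res) -> np.ndarray:
    m, n = res.jac.shape
    dof = max(m - n, 1)
    s2 = 2.0 * res.cost / dof
    jtj = res.jac.T @ res.jac
    try:
        cov = s2 * np.linalg.inv(jtj)
    except np.linalg.LinAlgError:
        cov = s2 * np.linalg.pinv(jtj)
    return cov


_RATE_BOUNDS = (1e-9, 50.0)
_FALLBACK_GRID = np.logspace(-4, 0, 5)


def _fit_joint(courses) -> tuple[np.ndarray, "optimize.OptimizeResult"]:
    times = courses[0].times
    x0 = np.array(_initial_rate_guesses(times, courses[0].fractions))
    best = _lsq(_joint_residuals, x0, ([_RATE_BOUNDS[0]] * 2, [_RATE_BOUNDS[1]] * 2), args=(courses,))
    # coarse multistart only when the solver failed or ran into a bound
    if not best.success or np.any(best.x <= 2 * _RATE_BOUNDS[0]) or np.any(
        best.x >= 0.98 * _RATE_BOUNDS[1]
    ):
        for g1 in _FALLBACK_GRID:
            for g2 in _FALLBACK_GRID:
                trial = _lsq(
                    _joint_residuals,
                    np.array([g1, g2]),
                    ([_RATE_BOUNDS[0]] * 2, [_RATE_BOUNDS[1]] * 2),
                    args=(courses,),
                )
                if trial.cost < best.cost:
                    best = trial
    return best.x, best


def _fit_sequential(courses):
    """Fit k1 on the precursor decay alone, then k2 on the intermediate."""

    def res_k1(p):
        return np.concatenate(
            [np.exp(-p[0] * c.times) - c.fractions[:, 0] for c in courses]
        )

    x0 = np.array([_initial_rate_guesses(courses[0].times, courses[0].fractions)[0]])
    r1 = _lsq(res_k1, x0, ([_RATE_BOUNDS[0]], [_RATE_BOUNDS[1]]))
    k1 = float(r1.x[0])

    def res_k2(p):
        out = []
        for c in courses:
            _, inter, _ = bateman_fractions(c.times, k1, p[0])
            out.append(inter - c.fractions[:, 1])
        return np.concatenate(out)

    x0 = np.array([_initial_rate_guesses(courses[0].times, courses[0].fractions)[1]])
    r2 = _lsq(res_k2, x0, ([_RATE_BOUNDS[0]], [_RATE_BOUNDS[1]]))
    k2 = float(r2.x[0])
    cov = np.diag([_cov_from_lsq(r1)[0, 0], _cov_from_lsq(r2)[0, 0]])
    cost = 2.0 * (r1.cost + r2.cost)
    return np.array([k1, k2]), cov, cost


def fit_rate_constants(
    courses: SpeciesTimeCourse | Sequence[SpeciesTimeCourse],
    mode: Literal["joint", "sequential"] = "joint",
) -> RateConstantFit:
    """Fit (k1, k2) to one or more replicate time courses.

    ``joint`` fits all three species simultaneously by unweighted nonlinear
    least squares; ``sequential`` fits k1 to the precursor decay and then
    k2 to the intermediate with k1 held fixed.  When two or more replicates
    are supplied, per-replicate fits additionally yield across-replicate
    standard errors of the mean.
    """
    course_list = _stack_courses(courses)
    for c in course_list:
        if len(c) < 4:
            raise ValueError("at least 4 time points are required for fitting")

    if mode == "joint":
        x, res = _fit_joint(course_list)
        cov = _cov_from_lsq(res)
        cost = 2.0 * res.cost
    elif mode == "sequential":
        x, cov, cost = _fit_sequential(course_list)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    k1, k2 = float(x[0]), float(x[1])
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    non_ident = bool(k1 <= 1e-6 or k2 <= 1e-6 or not np.all(np.isfinite(se)))

    sem_k1 = sem_k2 = None
    per_rep = None
    if len(course_list) >= 2:
        per_rep = []
        for c in course_list:
            if mode == "joint":
                xr, _ = _fit_joint([c])
            else:
                xr, _, _ = _fit_sequential([c])
            per_rep.append((float(xr[0]), float(xr[1])))
        arr = np.asarray(per_rep)
        n = arr.shape[0]
        sem_k1 = float(arr[:, 0].std(ddof=1) / math.sqrt(n))
        sem_k2 = float(arr[:, 1].std(ddof=1) / math.sqrt(n))

    return RateConstantFit(
        rates=SplicingRateConstants(max(k1, 1e-12), max(k2, 1e-12)),
        se_k1=float(se[0]),
        se_k2=float(se[1]),
        covariance=cov,
        mode=mode,
        n_replicates=len(course_list),
        residual_ss=float(cost),
        sem_k1=sem_k1,
        sem_k2=sem_k2,
        per_replicate=per_rep,
        non_identifiable=non_ident,
    )


# ---------------------------------------------------------------------------
# K_i and IC50
# ---------------------------------------------------------------------------


def _hyperbola(c, k_max, ki):
    return k_max / (1.0 + c / ki)


def fit_ki(series: KobsSeries) -> InhibitionFit:
    """Fit k_obs = k_max/(1 + [I]/K_i) to an observed-rate series."""
    if len(series) < 3:
        raise ValueError("at least 3 distinct concentrations are required")
    c, k = series.concentrations, series.kobs
    if np.ptp(k) < 1e-12 * np.max(k):
        # flat series: K_i unidentifiable (inhibitor has no measurable effect)
        return InhibitionFit(
            k_max=float(np.mean(k)),
            K_i=math.inf,
            se_k_max=float("nan"),
            se_K_i=float("nan"),
            covariance=np.full((2, 2), np.nan),
            n_points=len(series),
            step_label=series.step_label,
            non_identifiable=True,
        )
    p0 = [float(np.max(k)), float(np.median(c[c > 0])) if np.any(c > 0) else 1.0]
    sigma = series.se if series.se is not None else None
    popt, pcov = optimize.curve_fit(
        _hyperbola,
        c,
        k,
        p0=p0,
        sigma=sigma,
        absolute_sigma=sigma is not None,
        bounds=([1e-12, 1e-12], [np.inf, np.inf]),
        maxfev=20000,
        xtol=1e-14,
        ftol=1e-14,
    )
    se = np.sqrt(np.diag(pcov))
    return InhibitionFit(
        k_max=float(popt[0]),
        K_i=float(popt[1]),
        se_k_max=float(se[0]),
        se_K_i=float(se[1]),
        covariance=pcov,
        n_points=len(series),
        step_label=series.step_label,
    )


def percent_reacted_precursor(
    records: Sequence[PrecursorFractionRecord],
) -> list[tuple[float, float]]:
    """Normalize 15-min precursor fractions to percent reacted precursor.

    %(c) = 100 * (F_[I]max - F(c)) / (F_[I]max - F_DMSO): the DMSO control
    maps to 100% and the saturating concentration to 0%.
    """
    dmso = [r for r in records if r.is_dmso_reference]
    imax = [r for r in records if r.is_imax_reference]
    if len(dmso) != 1 or len(imax) != 1:
        raise ValueError("exactly one DMSO and one [I]max reference record required")
    f_dmso, f_imax = dmso[0].fraction, imax[0].fraction
    if f_imax == f_dmso:
        raise ValueError("F_[I]max equals F_DMSO: normalization is undefined")
    return [
        (r.concentration, 100.0 * (f_imax - r.fraction) / (f_imax - f_dmso))
        for r in records
    ]


def _ic50_model_log(c, log_ic50):
    # IC50 fitted on the log scale (the standard dose-response
    # parametrization): better-calibrated uncertainties for a positive,
    # order-of-magnitude-uncertain concentration parameter
    return 100.0 / (1.0 + c * np.exp(-log_ic50))


def fit_ic50(
    dose_response: Sequence[tuple[float, float]],
    response_kind: Literal[
        "percent_reacted_precursor", "percent_activity"
    ] = "percent_reacted_precursor",
) -> DoseResponseFit:
    """One-parameter fit of the dose-response hyperbola % = 100/(1 + [I]/IC50)."""
    pts = np.asarray(dose_response, dtype=float)
    if pts.shape[0] < 3:
        raise ValueError("at least 3 concentrations are required")
    c, y = pts[:, 0], pts[:, 1]
    order = np.argsort(c)
    # flag gross non-monotonicity (response rising with dose beyond noise)
    ys = y[order]
    mono_warn = bool(np.any(np.diff(ys) > 10.0))
    pos = c[c > 0]
    p0 = [math.log(float(np.median(pos)))] if pos.size else [0.0]
    popt, pcov = optimize.curve_fit(
        _ic50_model_log, c, y, p0=p0,
        maxfev=20000, xtol=1e-14, ftol=1e-14,
    )
    ic50 = float(np.exp(popt[0]))
    se_log = float(np.sqrt(pcov[0, 0]))
    return DoseResponseFit(
        IC50=ic50,
        se_IC50=ic50 * se_log,  # delta method from the log scale
        response_kind=response_kind,
        n_points=pts.shape[0],
        monotonicity_warning=mono_warn,
    )


def fret_initial_slopes(
    traces: dict[float, tuple[np.ndarray, np.ndarray]],
    window_fraction: float = 0.2,
) -> list[tuple[float, float]]:
    """Percent intron activity from initial slopes of FRET progress curves.

    ``traces`` maps inhibitor concentration (μM) to (time, signal) arrays;
    the entry at concentration 0 is the DMSO control.  The slope is a linear
    fit over the first ``window_fraction`` of time points (at least 3), and
    %activity(c) = 100 * slope(c) / slope(DMSO).
    """
    if 0.0 not in traces:
        raise ValueError("a DMSO control trace at concentration 0 is required")

    def slope(t, y):
        t = np.asarray(t, dtype=float)
        y = np.asarray(y, dtype=float)
        n = max(3, int(math.ceil(window_fraction * t.size)))
        if t.size < 3:
            raise ValueError("at least 3 early time points are required per trace")
        n = min(n, t.size)
        return float(np.polyfit(t[:n], y[:n], 1)[0])

    s0 = slope(*traces[0.0])
    if s0 <= 0:
        raise ValueError("DMSO control slope must be positive")
    return [(c, 100.0 * slope(t, y) / s0) for c, (t, y) in sorted(traces.items())]


def step_selectivity(
    control: SplicingRateConstants, inhibited: SplicingRateConstants
) -> StepSelectivity:
    """Fold slow-down of each splicing step and the second/first ratio."""
    fold_1 = control.k1 / inhibited.k1
    fold_2 = control.k2 / inhibited.k2
    return StepSelectivity(fold_1, fold_2, fold_2 / fold_1)
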