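"""File formats: CSV dialects, YAML sidecars/configs, and JSON reports.

All CSV files are comma-separated, UTF-8, '.' decimal, with a header row.
Concentrations are μM on disk and converted to molar only inside
:mod:`intronkit.thermo`.  Numeric fields are written with 17 significant
digits so write→read round-trips are lossless.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import thermo
from .inhibition import KobsSeries
from .kinetics import SpeciesTimeCourse

__all__ = [
    "ValidationError",
    "read_time_courses",
    "write_time_courses",
    "read_kobs_series",
    "write_kobs_series",
    "read_dose_response",
    "write_dose_response",
    "read_itc",
    "write_itc",
    "read_bli",
    "write_bli",
    "write_report",
    "read_report",
]

_FLOAT_FMT = "%.17g"

TIMECOURSE_COLUMNS = [
    "time_min",
    "frac_precursor",
    "frac_intermediate",
    "frac_product",
    "replicate",
    "conc_uM",
]
KOBS_COLUMNS = ["conc_uM", "kobs_per_min"]
KOBS_OPTIONAL = ["se_per_min"]
DOSE_COLUMNS = ["conc_uM", "response_pct"]
ITC_COLUMNS = ["injection_index", "volume_uL", "heat_kcal_per_mol"]
BLI_COLUMNS = ["time_s", "response_nm", "conc_uM", "phase"]


class ValidationError(ValueError):
    """A file failed schema or content validation."""


def _read_csv(path, required: list[str], optional: list[str] = ()) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, encoding="utf-8", float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: file is empty") from None
    except FileNotFoundError:
        raise ValidationError(f"{path}: file not found") from None
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required column(s) {missing}")
    unknown = [c for c in df.columns if c not in (*required, *optional)]
    if unknown:
        raise ValidationError(f"{path}: unknown column(s) {unknown}")
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    numeric = [c for c in df.columns if c != "replicate" and c != "phase"]
    for col in numeric:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col].astype(str)
            comma = bad[bad.str.contains(",", na=False)]
            if not comma.empty:
                line = int(comma.index[0]) + 2  # 1-based incl. header
                raise ValidationError(
                    f"{path}: column {col!r}, line {line}: decimal commas are not "
                    "accepted; use '.' as the decimal separator"
                )
            raise ValidationError(f"{path}: column {col!r} is not numeric")
    return df


# -- species time courses ---------------------------------------------------


def read_time_courses(path) -> list[SpeciesTimeCourse]:
    """Read gel time courses, one :class:`SpeciesTimeCourse` per
    (replicate, concentration) group."""
    df = _read_csv(path, TIMECOURSE_COLUMNS)
    out = []
    for (conc, rep), g in df.groupby(["conc_uM", "replicate"], sort=True):
        g = g.sort_values("time_min")
        try:
            out.append(
                SpeciesTimeCourse(
                    times=g["time_min"].to_numpy(),
                    fractions=g[
                        ["frac_precursor", "frac_intermediate", "frac_product"]
                    ].to_numpy(),
                    replicate_id=str(rep),
                    inhibitor_concentration=float(conc),
                )
            )
        except ValueError as exc:
            raise ValidationError(
                f"{path}: replicate {rep!r} at {conc} uM: {exc}"
            ) from exc
    return out


def write_time_courses(courses: Sequence[SpeciesTimeCourse], path) -> None:
    frames = []
    for c in courses:
        frames.append(
            pd.DataFrame(
                {
                    "time_min": c.times,
                    "frac_precursor": c.fractions[:, 0],
                    "frac_intermediate": c.fractions[:, 1],
                    "frac_product": c.fractions[:, 2],
                    "replicate": c.replicate_id,
                    "conc_uM": c.inhibitor_concentration,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


# -- k_obs series -----------------------------------------------------------


def read_kobs_series(path, step_label: str = "first") -> KobsSeries:
    df = _read_csv(path, KOBS_COLUMNS, KOBS_OPTIONAL)
    se = df["se_per_min"].to_numpy() if "se_per_min" in df.columns else None
    try:
        return KobsSeries(
            concentrations=df["conc_uM"].to_numpy(),
            kobs=df["kobs_per_min"].to_numpy(),
            se=se,
            step_label=step_label,
        )
    except ValueError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_kobs_series(series: KobsSeries, path) -> None:
    data = {"conc_uM": series.concentrations, "kobs_per_min": series.kobs}
    if series.se is not None:
        data["se_per_min"] = series.se
    pd.DataFrame(data).to_csv(path, index=False, float_format=_FLOAT_FMT)


# -- dose-response ----------------------------------------------------------


def read_dose_response(path) -> list[tuple[float, float]]:
    df = _read_csv(path, DOSE_COLUMNS)
    return list(zip(df["conc_uM"].astype(float), df["response_pct"].astype(float)))


def write_dose_response(points: Sequence[tuple[float, float]], path) -> None:
    pd.DataFrame(points, columns=DOSE_COLUMNS).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


# -- ITC --------------------------------------------------------------------


def read_itc(csv_path, meta_path) -> thermo.ITCTitration:
    """Read injection heats (CSV) plus the YAML metadata sidecar
    (cell_conc_uM, syringe_conc_uM, cell_volume_mL, temperature_C)."""
    df = _read_csv(csv_path, ITC_COLUMNS)
    df = df.sort_values("injection_index")
    meta_path = Path(meta_path)
    try:
        meta = yaml.safe_load(meta_path.read_text(encoding="utf-8"))
    except yaml.YAMLError as exc:
        raise ValidationError(f"{meta_path}: invalid YAML: {exc}") from exc
    required = ["cell_conc_uM", "syringe_conc_uM", "cell_volume_mL", "temperature_C"]
    if not isinstance(meta, dict) or any(k not in meta for k in required):
        raise ValidationError(f"{meta_path}: required keys {required}")
    try:
        return thermo.ITCTitration(
            cell_concentration=float(meta["cell_conc_uM"]) * 1e-6,
            syringe_concentration=float(meta["syringe_conc_uM"]) * 1e-6,
            injection_volumes=df["volume_uL"].to_numpy() * 1e-6,
            cell_volume=float(meta["cell_volume_mL"]) * 1e-3,
            heats=df["heat_kcal_per_mol"].to_numpy(),
            conditions=thermo.ThermoConditions.from_celsius(float(meta["temperature_C"])),
        )
    except ValueError as exc:
        raise ValidationError(f"{csv_path}: {exc}") from exc


def write_itc(titration: thermo.ITCTitration, csv_path, meta_path) -> None:
    heats = titration.heats
    if heats is None:
        raise ValueError("titration has no heats to write")
    pd.DataFrame(
        {
            "injection_index": np.arange(1, heats.size + 1),
            "volume_uL": titration.injection_volumes * 1e6,
            "heat_kcal_per_mol": heats,
        }
    ).to_csv(csv_path, index=False, float_format=_FLOAT_FMT)
    meta = {
        "cell_conc_uM": titration.cell_concentration * 1e6,
        "syringe_conc_uM": titration.syringe_concentration * 1e6,
        "cell_volume_mL": titration.cell_volume * 1e3,
        "temperature_C": titration.conditions.temperature - 273.15,
    }
    Path(meta_path).write_text(yaml.safe_dump(meta), encoding="utf-8")


# -- BLI --------------------------------------------------------------------


def read_bli(path) -> list[thermo.Sensorgram]:
    df = _read_csv(path, BLI_COLUMNS)
    bad_phase = set(df["phase"].unique()) - {"association", "dissociation"}
    if bad_phase:
        raise ValidationError(
            f"{path}: phase must be 'association' or 'dissociation', got {sorted(bad_phase)}"
        )
    out = []
    for conc, g in df.groupby("conc_uM", sort=True):
        a = g[g["phase"] == "association"].sort_values("time_s")
        d = g[g["phase"] == "dissociation"].sort_values("time_s")
        if a.empty or d.empty:
            raise ValidationError(
                f"{path}: both phases are required at every concentration ({conc} uM)"
            )
        out.append(
            thermo.Sensorgram(
                concentration=float(conc) * 1e-6,
                t_assoc=a["time_s"].to_numpy(),
                y_assoc=a["response_nm"].to_numpy(),
                t_dissoc=d["time_s"].to_numpy(),
                y_dissoc=d["response_nm"].to_numpy(),
            )
        )
    return out


def write_bli(sensorgrams: Sequence[thermo.Sensorgram], path) -> None:
    frames = []
    for s in sensorgrams:
        frames.append(
            pd.DataFrame(
                {
                    "time_s": s.t_assoc,
                    "response_nm": s.y_assoc,
                    "conc_uM": s.concentration * 1e6,
                    "phase": "association",
                }
            )
        )
        frames.append(
            pd.DataFrame(
                {
                    "time_s": s.t_dissoc,
                    "response_nm": s.y_dissoc,
                    "conc_uM": s.concentration * 1e6,
                    "phase": "dissociation",
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=_FLOAT_FMT
    )


# -- JSON reports -----------------------------------------------------------


def _jsonify(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return _jsonify(obj.item())
    if isinstance(obj, float) and (obj != obj or obj in (float("inf"), float("-inf"))):
        return str(obj)
    return obj


def write_report(results: dict, path, *, config: dict | None = None, seed=None) -> None:
    """Write a JSON report embedding the resolved configuration and seed."""
    from . import __version__

    payload = {
        "intronkit_version": __version__,
        "seed": seed,
        "config": _jsonify(config or {}),
        "results": _jsonify(results),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
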