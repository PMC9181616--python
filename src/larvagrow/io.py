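"""CSV readers/writers and the analysis configuration.

File conventions (UTF-8, decimal point, fixed units):

* observations: ``time_dpf, length_um, temperature_c, food``
  (+ optional ``stage_setigers, id``)
* summaries: ``time_dpf, mean_um, sd_um, n, temperature_c, food``
* rates: ``temperature_c`` or ``temperature_k``, ``value``, ``dataset``
  (+ optional ``standardized``)

Validation failures name the offending row and column.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from .constants import DEFAULT_L0_UM, T_AH_K, T_B_BY_TEMPERATURE, T_REF_K
from .exceptions import ValidationError
from .observations import (
    LengthObservation,
    RateObservation,
    SummaryObservation,
    observations_to_frame,
    rates_to_frame,
    summaries_to_frame,
)
from .thermal import celsius_to_kelvin

__all__ = [
    "read_observations",
    "read_summaries",
    "read_rates",
    "write_observations",
    "write_summaries",
    "write_rates",
    "AnalysisConfig",
]


def _load_csv(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValidationError(f"{path}: file is empty") from None
    if df.empty:
        raise ValidationError(f"{path}: no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _cell(df, i, col, kind=float, required=True, path=""):
    value = df[col].iloc[i]
    if pd.isna(value):
        if required:
            raise ValidationError(f"{path}: row {i + 2}, column {col!r}: missing value")
        return None
    try:
        return kind(value)
    except (TypeError, ValueError):
        raise ValidationError(
            f"{path}: row {i + 2}, column {col!r}: not a number ({value!r})"
        ) from None


def read_observations(path) -> list[LengthObservation]:
    """Individual larval lengths from CSV; row numbers attached to errors."""
    df = _load_csv(path, ["time_dpf", "length_um", "temperature_c", "food"])
    out = []
    for i in range(len(df)):
        try:
            out.append(
                LengthObservation(
                    time=_cell(df, i, "time_dpf", path=str(path)),
                    length=_cell(df, i, "length_um", path=str(path)),
                    temperature=_cell(df, i, "temperature_c", path=str(path)),
                    food=str(df["food"].iloc[i]),
                    stage=(
                        _cell(df, i, "stage_setigers", int, required=False, path=str(path))
                        if "stage_setigers" in df.columns
                        else None
                    ),
                    id=(
                        str(df["id"].iloc[i])
                        if "id" in df.columns and not pd.isna(df["id"].iloc[i])
                        else None
                    ),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i + 2}: {exc}") from None
    return out


def read_summaries(path) -> list[SummaryObservation]:
    """Per-time summary rows (mean/SD/n) from CSV."""
    df = _load_csv(path, ["time_dpf", "mean_um", "sd_um", "n", "temperature_c", "food"])
    out = []
    for i in range(len(df)):
        try:
            out.append(
                SummaryObservation(
                    time=_cell(df, i, "time_dpf", path=str(path)),
                    mean=_cell(df, i, "mean_um", path=str(path)),
                    sd=_cell(df, i, "sd_um", required=False, path=str(path)),
                    n=_cell(df, i, "n", int, path=str(path)),
                    temperature=_cell(df, i, "temperature_c", path=str(path)),
                    food=str(df["food"].iloc[i]),
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i + 2}: {exc}") from None
    return out


def read_rates(path) -> list[RateObservation]:
    """Rate-versus-temperature rows from CSV (°C or K, explicit column)."""
    df = _load_csv(path, ["value", "dataset"])
    if "temperature_k" in df.columns:
        col, convert = "temperature_k", False
    elif "temperature_c" in df.columns:
        col, convert = "temperature_c", True
    else:
        raise ValidationError(f"{path}: need a temperature_k or temperature_c column")
    out = []
    for i in range(len(df)):
        try:
            temp = _cell(df, i, col, path=str(path))
            if convert:
                temp = celsius_to_kelvin(temp)
            std = bool(df["standardized"].iloc[i]) if "standardized" in df.columns else False
            out.append(
                RateObservation(
                    temperature=temp,
                    value=_cell(df, i, "value", path=str(path)),
                    dataset=str(df["dataset"].iloc[i]),
                    standardized=std,
                )
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {i + 2}: {exc}") from None
    return out


# 17 significant digits: doubles survive the round trip bit-exactly
_FLOAT_FMT = "%.17g"


def write_observations(obs: Sequence[LengthObservation], path) -> None:
    observations_to_frame(obs).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_summaries(summaries: Sequence[SummaryObservation], path) -> None:
    summaries_to_frame(summaries).to_csv(path, index=False, float_format=_FLOAT_FMT)


def write_rates(rates: Sequence[RateObservation], path) -> None:
    rates_to_frame(rates).to_csv(path, index=False, float_format=_FLOAT_FMT)


@dataclass
class AnalysisConfig:
    """End-to-end pipeline configuration with study defaults.

    Every field is overridable; the config round-trips unchanged through
    YAML/JSON serialization.
    """

    observations_path: Optional[str] = None
    summaries_path: Optional[str] = None
    rates_path: Optional[str] = None
    t_b: dict = field(default_factory=lambda: dict(T_B_BY_TEMPERATURE))
    L0: float = DEFAULT_L0_UM
    t_ref: float = T_REF_K
    t_ah: float = T_AH_K
    start_grid: Optional[list] = None
    thermal_start_grid: Optional[list] = None
    seed: Optional[int] = None
    verbosity: int = 1

    def __post_init__(self):
        self.t_b = {float(k): float(v) for k, v in self.t_b.items()}

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["t_b"] = {str(k): v for k, v in self.t_b.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AnalysisConfig":
        d = dict(d)
        if "t_b" in d:
            d["t_b"] = {float(k): float(v) for k, v in d["t_b"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
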