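"""Packaged reference tables and helpers to turn them into fit-ready data.

The package ships the printed development and growth tables for lugworm
larvae reared at 13, 15 and 17°C (see ``data/fixtures_meta.json`` for the
transcription notes and checksums).
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd

from .constants import (
    DEFAULT_L0_UM,
    FED,
    NON_FED,
    PRE_BIRTH,
    T_B_BY_TEMPERATURE,
)
from .exceptions import ValidationError
from .growth import BiphasicParams
from .observations import SummaryObservation

__all__ = [
    "load_table1",
    "load_table2",
    "load_table3",
    "load_fixture_metadata",
    "fixture_summaries",
    "table3_params",
]

_DATA = resources.files("larvagrow") / "data"


def _read_checked(name: str) -> pd.DataFrame:
    meta = load_fixture_metadata()
    raw = (_DATA / name).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    expected = meta["sha256"][name]
    if digest != expected:
        raise ValidationError(f"fixture {name} checksum mismatch ({digest})")
    from io import BytesIO

    return pd.read_csv(BytesIO(raw))


def load_fixture_metadata() -> dict:
    """Transcription notes and checksums for the packaged tables."""
    return json.loads((_DATA / "fixtures_meta.json").read_text())


def load_table1() -> pd.DataFrame:
    """Development table: stage, mean length, SD and n over time per temperature."""
    return _read_checked("table1_development.csv")


def load_table2() -> pd.DataFrame:
    """Post-birth growth under fed / non-fed conditions per temperature."""
    return _read_checked("table2_food.csv")


def load_table3() -> pd.DataFrame:
    """Fitted biphasic growth parameters (long format) per temperature."""
    return _read_checked("table3_growth_params.csv")


def table3_params(temperature: float) -> BiphasicParams:
    """Published biphasic parameter set for one rearing temperature."""
    df = load_table3()
    sub = df[df["temperature_c"] == temperature]
    if sub.empty:
        raise ValidationError(f"no parameters for temperature {temperature}")

    def _val(param, food=None):
        rows = sub[sub["parameter"] == param]
        if food is not None:
            rows = rows[rows["food"] == food]
        return float(rows["value"].iloc[0])

    return BiphasicParams(
        L_inf=_val("L_inf"),
        b=_val("b"),
        L0=DEFAULT_L0_UM,
        t_b=T_B_BY_TEMPERATURE[float(temperature)],
        c_fed=_val("c", FED),
        c_nonfed=_val("c", NON_FED),
    )


def fixture_summaries(
    temperature: float, include_common: bool = True
) -> list[SummaryObservation]:
    """Fit-ready summary rows for one temperature.

    Pre-birth rows come from the development table (labelled
    ``pre_birth``); post-birth rows from the food-condition table with
    their fed / non-fed labels.  ``include_common`` additionally shares
    the 1–6 dpf rows (recorded before the temperature split) with the 13
    and 17°C cohorts.
    """
    temperature = float(temperature)
    t_b = T_B_BY_TEMPERATURE[temperature]
    t1 = load_table1()
    t2 = load_table2()
    out: list[SummaryObservation] = []

    def _add(row, food, temp):
        sd = None if pd.isna(row["sd_um"]) else float(row["sd_um"])
        out.append(
            SummaryObservation(
                time=float(row["time_dpf"]), mean=float(row["mean_um"]),
                sd=sd, n=int(row["n"]), temperature=temp, food=food,
            )
        )

    if include_common and temperature != 15.0:
        for _, row in t1[(t1["temperature_c"] == 15) & (t1["time_dpf"] <= 6)].iterrows():
            _add(row, PRE_BIRTH, temperature)
    own = t1[(t1["temperature_c"] == temperature) & (t1["time_dpf"] < t_b)]
    for _, row in own.iterrows():
        _add(row, PRE_BIRTH, temperature)
    for _, row in t2[t2["temperature_c"] == temperature].iterrows():
        _add(row, str(row["food"]), temperature)
    return out
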