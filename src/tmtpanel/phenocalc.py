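"""Pigment-concentration calculations from DMF-extract absorbances.

Chlorophyll a and total carotenoid concentrations (ug/mL) from optical
densities of an N,N-dimethylformamide extract:

    Chl a            = 12.1 * OD664 - 0.17 * OD625
    total carotenoid = (OD461 - 0.046 * OD664) * 4

Both are linear in the absorbances.  Negative results are physically a
below-detection reading; they are flagged, never clamped.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd


@dataclass(frozen=True)
class PigmentReading:
    """Absorbances of the DMF extract at 664, 625 and 461 nm."""

    od664: float = 0.0
    od625: float = 0.0
    od461: float = 0.0

    def __post_init__(self) -> None:
        for name in ("od664", "od625", "od461"):
            v = getattr(self, name)
            if not (v >= 0.0) or v != v or v == float("inf"):
                raise ValueError(f"{name} must be a finite non-negative absorbance")


@dataclass(frozen=True)
class Concentration:
    value: float  # ug/mL
    below_detection: bool


def chlorophyll_a(reading: PigmentReading) -> Concentration:
    """Chlorophyll a concentration (ug/mL) of the DMF extract."""
    value = 12.1 * reading.od664 - 0.17 * reading.od625
    return Concentration(value=value, below_detection=value < 0.0)


def total_carotenoids(reading: PigmentReading) -> Concentration:
    """Total carotenoid concentration (ug/mL) of the DMF extract."""
    value = (reading.od461 - 0.046 * reading.od664) * 4.0
    return Concentration(value=value, below_detection=value < 0.0)


def pigment_table(readings: pd.DataFrame) -> pd.DataFrame:
    """Batch evaluation: CSV/TSV-style table with od664, od625, od461 columns."""
    rows = []
    for row in readings.itertuples(index=False):
        r = PigmentReading(
            od664=float(row.od664), od625=float(row.od625), od461=float(row.od461)
        )
        chl = chlorophyll_a(r)
        car = total_carotenoids(r)
        rec = row._asdict()
        rec.update(
            chlorophyll_a=chl.value,
            total_carotenoids=car.value,
            below_detection=chl.below_detection or car.below_detection,
        )
        rows.append(rec)
    return pd.DataFrame(rows)


def read_pigments(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = {"od664", "od625", "od461"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing absorbance columns {sorted(missing)}")
    return df
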