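"""Tabular containers shared by the estimator / composite / crossover stages.

A :class:`FractionSchedule` holds the volume fractions of polymer, first
water layer and second water layer on a moisture-content grid; a
:class:`PropertyCurve` holds one material property sampled on such a grid.
Both read/write plain CSV with a ``#``-comment metadata header so every
output file records the parameters that produced it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = ["FractionSchedule", "PropertyCurve", "WATER_MOLECULAR_VOLUME_NM3"]

#: Volume of one water molecule at 1.0 g/cm^3, nm^3 (18.015 g/mol / N_A / rho).
WATER_MOLECULAR_VOLUME_NM3 = 0.0299

_FRACTION_SUM_TOL = 1e-9


@dataclass
class FractionSchedule:
    """Volume fractions (f_p, f_w1, f_w2) on a moisture-content grid.

    The three fractions must close to 1 at every grid point: the system is
    modelled as polymer + first-layer water + second-layer water and
    nothing else.
    """

    m_grid: np.ndarray
    f_p: np.ndarray
    f_w1: np.ndarray
    f_w2: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.m_grid = np.asarray(self.m_grid, dtype=float)
        self.f_p = np.asarray(self.f_p, dtype=float)
        self.f_w1 = np.asarray(self.f_w1, dtype=float)
        self.f_w2 = np.asarray(self.f_w2, dtype=float)
        n = len(self.m_grid)
        if not (len(self.f_p) == len(self.f_w1) == len(self.f_w2) == n):
            raise ValueError("fraction schedule columns have unequal lengths")
        total = self.f_p + self.f_w1 + self.f_w2
        if np.any(np.abs(total - 1.0) > 1e-6):
            raise ValueError("volume fractions must sum to 1 at every grid point")
        for name, f in (("f_p", self.f_p), ("f_w1", self.f_w1), ("f_w2", self.f_w2)):
            if np.any((f < -_FRACTION_SUM_TOL) | (f > 1 + _FRACTION_SUM_TOL)):
                raise ValueError(f"{name} outside [0, 1]")

    def __len__(self) -> int:
        return len(self.m_grid)

    @property
    def fractions(self) -> np.ndarray:
        """(n, 3) array of (f_p, f_w1, f_w2)."""
        return np.column_stack([self.f_p, self.f_w1, self.f_w2])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"m": self.m_grid, "f_p": self.f_p, "f_w1": self.f_w1, "f_w2": self.f_w2}
        )

    def to_csv(self, path: str) -> None:
        _write_csv(self.to_frame(), path, self.metadata)

    @classmethod
    def from_csv(cls, path: str) -> "FractionSchedule":
        df, meta = _read_csv(path)
        return cls(df["m"].values, df["f_p"].values, df["f_w1"].values,
                   df["f_w2"].values, metadata=meta)


@dataclass
class PropertyCurve:
    """One material property sampled on a moisture-content grid.

    ``property`` names the quantity ("K", "E", "G", "NU", "Q", "ALPHA",
    "CP" or free-form); ``fractions`` optionally attaches the aligned
    volume-fraction schedule needed for composite decomposition; ``sd``
    optionally carries per-point uncertainties used as inverse-variance
    weights.
    """

    m_grid: np.ndarray
    values: np.ndarray
    property: str = ""
    units: str = ""
    fractions: FractionSchedule | None = None
    sd: np.ndarray | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.m_grid = np.asarray(self.m_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.m_grid) != len(self.values):
            raise ValueError("m_grid and values have unequal lengths")
        if self.sd is not None:
            self.sd = np.asarray(self.sd, dtype=float)
            if len(self.sd) != len(self.values):
                raise ValueError("sd column length mismatch")
        if self.fractions is not None and len(self.fractions) != len(self.m_grid):
            raise ValueError("fraction schedule not aligned with m_grid")
        self.property = str(self.property).upper()

    def __len__(self) -> int:
        return len(self.m_grid)

    def to_frame(self) -> pd.DataFrame:
        d = {"m": self.m_grid, "value": self.values}
        if self.sd is not None:
            d["sd"] = self.sd
        return pd.DataFrame(d)

    def to_csv(self, path: str) -> None:
        meta = dict(self.metadata)
        meta.setdefault("property", self.property)
        meta.setdefault("units", self.units)
        _write_csv(self.to_frame(), path, meta)

    @classmethod
    def from_csv(
        cls, path: str, fractions: FractionSchedule | None = None
    ) -> "PropertyCurve":
        df, meta = _read_csv(path)
        return cls(
            df["m"].values,
            df["value"].values,
            property=str(meta.get("property", "")),
            units=str(meta.get("units", "")),
            fractions=fractions,
            sd=df["sd"].values if "sd" in df.columns else None,
            metadata=meta,
        )

    def with_fractions(self, schedule: FractionSchedule) -> "PropertyCurve":
        if len(schedule) != len(self.m_grid) or not np.allclose(
            schedule.m_grid, self.m_grid, atol=1e-9
        ):
            raise ValueError("schedule m grid does not match curve m grid")
        return PropertyCurve(
            self.m_grid, self.values, property=self.property, units=self.units,
            fractions=schedule, sd=self.sd, metadata=dict(self.metadata),
        )


# ---------------------------------------------------------------------------
# CSV with '# key = value' metadata header


def _write_csv(df: pd.DataFrame, path: str, metadata: Mapping) -> None:
    with open(path, "w", newline="") as fh:
        for k in sorted(metadata):
            fh.write(f"# {k} = {metadata[k]}\n")
        df.to_csv(fh, index=False, lineterminator="\n")


def _read_csv(path: str) -> tuple[pd.DataFrame, dict]:
    meta: dict = {}
    with open(path) as fh:
        lines = fh.readlines()
    body_start = 0
    for i, line in enumerate(lines):
        if line.startswith("#"):
            if "=" in line:
                k, _, v = line.lstrip("#").partition("=")
                meta[k.strip()] = _coerce(v.strip())
            body_start = i + 1
        else:
            break
    from io import StringIO

    df = pd.read_csv(StringIO("".join(lines[body_start:])))
    return df, meta


def _coerce(v: str):
    for cast in (int, float):
        try:
            return cast(v)
        except ValueError:
            pass
    return v
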