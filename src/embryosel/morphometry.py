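"""Morphometric feature derivation from blastomere diameter measurements.

Embryos are measured as sets of object diameters (µm) on Days 1-3. Objects
are split into blastomeres and fragments by day-specific size thresholds,
and the computer-assisted feature set (total cytoplasmic volume, size
diversity, fragmentation, counts, parity, transformed Day-3 count) is
derived from sphere-model volumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

__all__ = [
    "EmbryoMeasurements",
    "CassFeatures",
    "InvalidMeasurementError",
    "DegenerateEmbryoError",
    "MeasurementNoiseWarning",
    "BLASTOMERE_MIN_DIAMETER",
    "DAY3_OPTIMUM_COUNT",
    "blastomere_volume",
    "classify_objects",
    "total_cytoplasmic_volume",
    "coefficient_of_diversity",
    "fragmentation_fraction",
    "derive_cass_features",
    "read_measurements_csv",
    "write_measurements_csv",
]

#: Minimum diameter (µm) for an object to count as a blastomere, per day.
BLASTOMERE_MIN_DIAMETER = {2: 45.0, 3: 40.0}

#: Optimum Day-3 blastomere count used by the |n - optimum| recoding.
DAY3_OPTIMUM_COUNT = 8.4


class InvalidMeasurementError(ValueError):
    """Raised for physically impossible measurement input."""


class DegenerateEmbryoError(ValueError):
    """Raised when a day has no blastomere-sized object after classification."""


class MeasurementNoiseWarning(UserWarning):
    """Emitted when an apparent volume gain is clamped to zero fragmentation."""


@dataclass(frozen=True)
class EmbryoMeasurements:
    """Raw per-day diameter measurements for one embryo.

    Parameters
    ----------
    embryo_id : str
        Opaque identifier.
    day1_diameter : float
        Zygote diameter on Day 1, µm.
    day2_diameters, day3_diameters : sequence of float
        Diameters of every measured object (blastomeres and fragments), µm.
    """

    embryo_id: str
    day1_diameter: float
    day2_diameters: tuple[float, ...]
    day3_diameters: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "day2_diameters", tuple(self.day2_diameters))
        object.__setattr__(self, "day3_diameters", tuple(self.day3_diameters))
        if self.day1_diameter <= 0:
            raise InvalidMeasurementError(
                f"{self.embryo_id}: Day-1 diameter must be positive, "
                f"got {self.day1_diameter}"
            )
        for day, ds in ((2, self.day2_diameters), (3, self.day3_diameters)):
            if not ds:
                raise InvalidMeasurementError(
                    f"{self.embryo_id}: Day-{day} diameter list is empty"
                )
            if any(d <= 0 for d in ds):
                raise InvalidMeasurementError(
                    f"{self.embryo_id}: Day-{day} diameters must be positive"
                )


@dataclass(frozen=True)
class CassFeatures:
    """Derived morphometric feature set for one embryo.

    ``n_d3_dev`` is the absolute deviation of the Day-3 blastomere count from
    the configured optimum (default 8.4); ``raw_frag_d2``/``raw_frag_d3``
    keep the unclamped fragmentation values for diagnostics.
    """

    embryo_id: str
    tcv_d1: float
    tcv_d2: float
    tcv_d3: float
    n_d2: int
    n_d3: int
    cod_d2: float
    cod_d3: float
    frag_d2: float
    frag_d3: float
    parity_d2: int
    n_d3_dev: float
    raw_frag_d2: float = field(repr=False, default=0.0)
    raw_frag_d3: float = field(repr=False, default=0.0)

    def as_dict(self) -> dict[str, float]:
        return {
            "tcv_d1": self.tcv_d1,
            "tcv_d2": self.tcv_d2,
            "tcv_d3": self.tcv_d3,
            "n_d2": self.n_d2,
            "n_d3": self.n_d3,
            "cod_d2": self.cod_d2,
            "cod_d3": self.cod_d3,
            "frag_d2": self.frag_d2,
            "frag_d3": self.frag_d3,
            "parity_d2": self.parity_d2,
            "n_d3_dev": self.n_d3_dev,
        }


def blastomere_volume(diameter: float) -> float:
    """Volume (µm³) of a blastomere modelled as a sphere of given diameter."""
    if diameter <= 0:
        raise InvalidMeasurementError(f"diameter must be positive, got {diameter}")
    return math.pi / 6.0 * diameter**3


def classify_objects(
    diameters: Sequence[float], day: int
) -> tuple[list[float], list[float]]:
    """Partition measured objects into (blastomeres, fragments).

    Objects with diameter >= 45 µm on Day 2 or >= 40 µm on Day 3 are
    blastomeres; smaller objects are fragments. Order and multiplicity are
    preserved within each partition.
    """
    if day not in BLASTOMERE_MIN_DIAMETER:
        raise ValueError(f"day must be 2 or 3, got {day}")
    diameters = list(diameters)
    if not diameters:
        raise InvalidMeasurementError("empty diameter list")
    thr = BLASTOMERE_MIN_DIAMETER[day]
    blastomeres = [d for d in diameters if d >= thr]
    fragments = [d for d in diameters if d < thr]
    return blastomeres, fragments


def total_cytoplasmic_volume(blastomere_diameters: Sequence[float]) -> float:
    """Sum of sphere volumes (µm³) over a list of blastomere diameters."""
    diameters = list(blastomere_diameters)
    if not diameters:
        raise InvalidMeasurementError("empty blastomere list")
    return sum(blastomere_volume(d) for d in diameters)


def coefficient_of_diversity(blastomere_diameters: Sequence[float]) -> float:
    """Size ratio largest/smallest blastomere diameter; 1.0 when even."""
    diameters = list(blastomere_diameters)
    if not diameters:
        raise InvalidMeasurementError("empty blastomere list")
    if any(d <= 0 for d in diameters):
        raise InvalidMeasurementError("diameters must be positive")
    return max(diameters) / min(diameters)


def fragmentation_fraction(tcv_day1: float, tcv_dayx: float) -> float:
    """Fractional reduction of total volume relative to Day 1, clamped at 0.

    A later-day volume exceeding the Day-1 volume is treated as measurement
    noise: the fraction is clamped to 0 and a :class:`MeasurementNoiseWarning`
    is emitted.
    """
    if tcv_day1 <= 0 or tcv_dayx <= 0:
        raise InvalidMeasurementError("volumes must be positive")
    raw = (tcv_day1 - tcv_dayx) / tcv_day1
    if raw < 0:
        warnings.warn(
            f"volume gain ({tcv_dayx:.1f} > {tcv_day1:.1f} µm³) clamped to "
            "zero fragmentation",
            MeasurementNoiseWarning,
            stacklevel=2,
        )
        return 0.0
    return raw


def derive_cass_features(
    m: EmbryoMeasurements, day3_optimum: float = DAY3_OPTIMUM_COUNT
) -> CassFeatures:
    """Derive the full computer-assisted feature set for one embryo."""
    tcv_d1 = blastomere_volume(m.day1_diameter)

    per_day: dict[int, tuple[list[float], float, float]] = {}
    for day, diameters in ((2, m.day2_diameters), (3, m.day3_diameters)):
        blasts, _ = classify_objects(diameters, day)
        if not blasts:
            raise DegenerateEmbryoError(
                f"{m.embryo_id}: no blastomere-sized object on Day {day}"
            )
        per_day[day] = (
            blasts,
            total_cytoplasmic_volume(blasts),
            coefficient_of_diversity(blasts),
        )

    blasts2, tcv_d2, cod_d2 = per_day[2]
    blasts3, tcv_d3, cod_d3 = per_day[3]

    raw_frag_d2 = (tcv_d1 - tcv_d2) / tcv_d1
    raw_frag_d3 = (tcv_d1 - tcv_d3) / tcv_d1
    frag_d2 = fragmentation_fraction(tcv_d1, tcv_d2)
    frag_d3 = fragmentation_fraction(tcv_d1, tcv_d3)

    n_d2 = len(blasts2)
    n_d3 = len(blasts3)
    return CassFeatures(
        embryo_id=m.embryo_id,
        tcv_d1=tcv_d1,
        tcv_d2=tcv_d2,
        tcv_d3=tcv_d3,
        n_d2=n_d2,
        n_d3=n_d3,
        cod_d2=cod_d2,
        cod_d3=cod_d3,
        frag_d2=frag_d2,
        frag_d3=frag_d3,
        parity_d2=1 if n_d2 % 2 == 0 else 0,
        # rounded at 1e-10 so integer counts recode to exact one-decimal values
        n_d3_dev=round(abs(n_d3 - day3_optimum), 10),
        raw_frag_d2=raw_frag_d2,
        raw_frag_d3=raw_frag_d3,
    )


# ---------------------------------------------------------------------------
# CSV interface: one row per embryo; per-day diameter lists are
# semicolon-separated µm values inside a single cell.

_CSV_COLUMNS = ["embryo_id", "day1_diameter", "day2_diameters", "day3_diameters"]


def _parse_diameter_cell(cell: str) -> tuple[float, ...]:
    return tuple(float(tok) for tok in str(cell).split(";") if tok.strip())


def read_measurements_csv(path) -> list[EmbryoMeasurements]:
    """Read embryo measurements from CSV (header required, UTF-8)."""
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"measurement CSV missing columns: {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            EmbryoMeasurements(
                embryo_id=str(row.embryo_id),
                day1_diameter=float(row.day1_diameter),
                day2_diameters=_parse_diameter_cell(row.day2_diameters),
                day3_diameters=_parse_diameter_cell(row.day3_diameters),
            )
        )
    return out


def write_measurements_csv(measurements: Sequence[EmbryoMeasurements], path) -> None:
    rows = [
        {
            "embryo_id": m.embryo_id,
            "day1_diameter": repr(float(m.day1_diameter)),
            "day2_diameters": ";".join(repr(float(d)) for d in m.day2_diameters),
            "day3_diameters": ";".join(repr(float(d)) for d in m.day3_diameters),
        }
        for m in measurements
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
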