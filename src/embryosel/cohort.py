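"""Cohort assembly: clinical covariate encodings, model-ready feature tables
for the visual (SSS) and computer-assisted (CASS) scoring systems, and the
lenient univariate screen used before multivariable modelling."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .morphometry import CassFeatures

__all__ = [
    "ClinicalProfile",
    "SssGrades",
    "FeatureTable",
    "ScreenRecord",
    "CASS_PREDICTORS",
    "SSS_PREDICTORS",
    "build_feature_table",
    "univariate_screen",
    "ks_two_sample",
    "pregnancy_rate",
    "read_profiles_csv",
    "read_grades_csv",
]

#: Predictor columns offered to the models, per scoring system.
CASS_PREDICTORS = [
    "tcv_d1",
    "tcv_d2",
    "tcv_d3",
    "n_d2",
    "parity_d2",
    "frag_d2",
    "frag_d3",
    "cod_d2",
    "cod_d3",
    "n_d3_dev",
    "male_age",
    "female_age",
]

SSS_PREDICTORS = [
    "n_d2",
    "n_d3_dev",
    "frag_cat_d2",
    "frag_cat_d3",
    "symmetry_d2",
    "symmetry_d3",
    "parity_d2",
    "male_age",
    "female_age",
]


@dataclass(frozen=True)
class ClinicalProfile:
    """Couple-level covariates.

    Indicators use 0 = absence / 1 = presence (``None`` = missing);
    endometriosis stage is ordinal 0 (absent) through 4 (stage IV);
    infertility type is coded 0 = primary, 1 = secondary.
    """

    female_age: float
    male_age: float
    female_pathology: Optional[int] = None
    male_pathology: Optional[int] = None
    ovulation_disorder: Optional[int] = None
    transport_problem: Optional[int] = None
    implantation_problem: Optional[int] = None
    endometriosis_stage: int = 0
    infertility_type: Optional[int] = None
    infertility_duration: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("female_age", "male_age"):
            age = getattr(self, name)
            if not 15 < age < 60:
                raise ValueError(f"{name} {age} outside plausible range (15, 60)")
        if self.endometriosis_stage not in range(5):
            raise ValueError(
                f"endometriosis_stage must be in 0..4, got {self.endometriosis_stage}"
            )
        for name in (
            "female_pathology",
            "male_pathology",
            "ovulation_disorder",
            "transport_problem",
            "implantation_problem",
            "infertility_type",
        ):
            v = getattr(self, name)
            if v is not None and v not in (0, 1):
                raise ValueError(f"{name} must be 0, 1, or missing, got {v}")


@dataclass(frozen=True)
class SssGrades:
    """Visual grades for one embryo.

    Fragmentation category: 0 none, 1 = 0-10 %, 2 = 10-20 %, 3 = 20-50 %,
    4 = >50 %. Symmetry: 0 even, 1 slightly unequal (25-50 % size
    difference), 2 uneven (>50 %).
    """

    embryo_id: str
    n_d2: int
    n_d3: int
    frag_cat_d2: int
    frag_cat_d3: int
    symmetry_d2: int
    symmetry_d3: int

    def __post_init__(self) -> None:
        if self.n_d2 < 1 or self.n_d3 < 1:
            raise ValueError("blastomere counts must be >= 1")
        for name in ("frag_cat_d2", "frag_cat_d3"):
            if getattr(self, name) not in range(5):
                raise ValueError(f"{name} must be in 0..4")
        for name in ("symmetry_d2", "symmetry_d3"):
            if getattr(self, name) not in range(3):
                raise ValueError(f"{name} must be in 0..2")


@dataclass
class FeatureTable:
    """Model-ready table: predictor columns + binary outcome.

    ``data`` holds one row per retained embryo; ``outcome`` is the clinical
    pregnancy label (1 = pregnancy). ``n_dropped`` counts complete-case
    exclusions.
    """

    data: pd.DataFrame
    outcome: pd.Series
    system: str
    n_dropped: int = 0

    @property
    def predictors(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)


def _sss_row(g: SssGrades, day3_optimum: float) -> dict[str, float]:
    return {
        "n_d2": g.n_d2,
        "n_d3_dev": round(abs(g.n_d3 - day3_optimum), 10),
        "frag_cat_d2": g.frag_cat_d2,
        "frag_cat_d3": g.frag_cat_d3,
        "symmetry_d2": g.symmetry_d2,
        "symmetry_d3": g.symmetry_d3,
        "parity_d2": 1 if g.n_d2 % 2 == 0 else 0,
    }


def build_feature_table(
    embryos: Sequence,
    profiles: Sequence[ClinicalProfile],
    outcomes: Sequence[int],
    system: str,
    day3_optimum: float = 8.4,
) -> FeatureTable:
    """Assemble the predictor table for one scoring system.

    ``embryos`` holds :class:`~embryosel.morphometry.CassFeatures` for
    system="CASS" or :class:`SssGrades` for system="SSS", aligned with
    ``profiles`` and binary ``outcomes``. Rows with any missing retained
    covariate are dropped (complete-case); the transport-problem indicator is
    never offered to the models.
    """
    system = system.upper()
    if system not in ("SSS", "CASS"):
        raise ValueError(f"unknown scoring system {system!r}")
    if not (len(embryos) == len(profiles) == len(outcomes)):
        raise ValueError(
            f"length mismatch: {len(embryos)} embryos, {len(profiles)} profiles, "
            f"{len(outcomes)} outcomes"
        )
    rows = []
    for e, p, y in zip(embryos, profiles, outcomes):
        if y not in (0, 1):
            raise ValueError(f"outcome must be 0/1, got {y}")
        if system == "CASS":
            if not isinstance(e, CassFeatures):
                raise TypeError("CASS rows require CassFeatures")
            row = {k: e.as_dict()[k] for k in CASS_PREDICTORS if k in e.as_dict()}
        else:
            if not isinstance(e, SssGrades):
                raise TypeError("SSS rows require SssGrades")
            row = _sss_row(e, day3_optimum)
        row["male_age"] = p.male_age
        row["female_age"] = p.female_age
        row["_outcome"] = y
        rows.append(row)

    cols = CASS_PREDICTORS if system == "CASS" else SSS_PREDICTORS
    df = pd.DataFrame(rows, columns=cols + ["_outcome"])
    complete = df[cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    df = df[complete].reset_index(drop=True)
    return FeatureTable(
        data=df[cols].astype(float),
        outcome=df["_outcome"].astype(int),
        system=system,
        n_dropped=n_dropped,
    )


@dataclass(frozen=True)
class ScreenRecord:
    """Per-feature univariate logistic summary (beta, OR, 95 % CI, Wald p)."""

    feature: str
    beta: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    retained: bool


def univariate_screen(
    table: FeatureTable, alpha: float = 0.3
) -> tuple[list[str], list[ScreenRecord]]:
    """Screen predictors with single-covariate logistic fits.

    Each column is fit alone (plus intercept) against the outcome; columns
    with Wald p < ``alpha`` are retained. Constant columns are excluded with
    a warning. Returns (retained names, per-feature records).
    """
    from .lr_model import fit_logistic  # deferred: avoids import cycle

    y = table.outcome.to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("outcome has a single class; screening impossible")

    selected: list[str] = []
    records: list[ScreenRecord] = []
    for name in table.predictors:
        x = table.data[name].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            warnings.warn(f"constant feature {name!r} excluded from screen")
            continue
        fit = fit_logistic(x[:, None], y, term_names=[name])
        beta = fit.coefficients[1]
        se = fit.standard_errors[1]
        p = fit.p_values[1]
        half = 1.959963984540054 * se
        rec = ScreenRecord(
            feature=name,
            beta=beta,
            odds_ratio=math.exp(beta),
            ci_low=math.exp(beta - half),
            ci_high=math.exp(beta + half),
            p_value=p,
            retained=bool(p < alpha),
        )
        records.append(rec)
        if rec.retained:
            selected.append(name)
    return selected, records


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, int]:
    """Two-sample Kolmogorov-Smirnov test.

    Returns (D, p, reject) where reject=1 means the same-distribution null is
    rejected at the 0.05 level.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue), int(res.pvalue < 0.05)


def pregnancy_rate(n_events: int, n_total: int, ndigits: int = 1) -> float:
    """Clinical pregnancy rate in percent, rounded to ``ndigits`` decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_events <= n_total:
        raise ValueError("n_events must be in [0, n_total]")
    return round(100.0 * n_events / n_total, ndigits)


# ---------------------------------------------------------------------------
# CSV readers (UTF-8, header required, '.' decimal)

_PROFILE_COLS = [
    "female_age",
    "male_age",
    "female_pathology",
    "male_pathology",
    "ovulation_disorder",
    "transport_problem",
    "implantation_problem",
    "endometriosis_stage",
    "infertility_type",
    "infertility_duration",
]


def read_profiles_csv(path) -> list[ClinicalProfile]:
    df = pd.read_csv(path)
    missing = [c for c in ("female_age", "male_age") if c not in df.columns]
    if missing:
        raise ValueError(f"profile CSV missing columns: {missing}")
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in _PROFILE_COLS:
            if col not in df.columns:
                continue
            v = row[col]
            if pd.isna(v):
                kwargs[col] = None
            elif col in ("female_age", "male_age", "infertility_duration"):
                kwargs[col] = float(v)
            else:
                kwargs[col] = int(v)
        if kwargs.get("endometriosis_stage") is None:
            kwargs["endometriosis_stage"] = 0
        out.append(ClinicalProfile(**kwargs))
    return out


def read_grades_csv(path) -> list[SssGrades]:
    df = pd.read_csv(path)
    needed = [
        "embryo_id",
        "n_d2",
        "n_d3",
        "frag_cat_d2",
        "frag_cat_d3",
        "symmetry_d2",
        "symmetry_d3",
    ]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise ValueError(f"grades CSV missing columns: {missing}")
    return [
        SssGrades(
            embryo_id=str(row.embryo_id),
            n_d2=int(row.n_d2),
            n_d3=int(row.n_d3),
            frag_cat_d2=int(row.frag_cat_d2),
            frag_cat_d3=int(row.frag_cat_d3),
            symmetry_d2=int(row.symmetry_d2),
            symmetry_d3=int(row.symmetry_d3),
        )
        for row in df.itertuples(index=False)
    ]
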