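"""Synthetic embryo cohorts with known ground truth.

Embryo geometry is generated under volume conservation: the Day-1 zygote
volume is partitioned between blastomeres and explicit fragment objects on
Days 2 and 3, then converted back to diameters (with optional measurement
noise), so the full measurement-to-feature pipeline is exercised. Visual
grades are deterministic functions of the realized geometry plus an
optional mis-grading noise rate. Outcomes are drawn from a known logistic
model (the published equation or custom coefficients).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np
import pandas as pd

from . import morphometry as mm
from .cohort import ClinicalProfile, SssGrades, FeatureTable, build_feature_table
from .lr_model import PublishedScore, load_published_score, published_score

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_embryo",
    "simulate_cohort",
    "recovery_experiment",
    "frag_category",
    "symmetry_grade",
]


def frag_category(frac: float) -> int:
    """Visual fragmentation category from a realized volume-loss fraction."""
    if frac <= 0:
        return 0
    if frac < 0.10:
        return 1
    if frac < 0.20:
        return 2
    if frac < 0.50:
        return 3
    return 4


def symmetry_grade(cod: float) -> int:
    """Visual symmetry grade from the realized size-diversity ratio."""
    diff = 1.0 - 1.0 / cod  # relative size difference largest vs smallest
    if diff < 0.25:
        return 0
    if diff < 0.50:
        return 1
    return 2


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 100
    embryos_per_patient: tuple[int, int] = (1, 1)  # inclusive range
    # geometry
    day1_mean: float = 110.0
    day1_sd: float = 4.0
    day2_count_target: float = 4.0
    day3_count_target: float = 8.0
    count_dispersion: float = 0.7
    frag_mean_d2: float = 0.05
    frag_mean_d3: float = 0.10
    frag_concentration: float = 40.0
    asymmetry: float = 0.05  # 0 = perfectly even volume split
    diameter_noise: float = 0.01  # relative sd of multiplicative noise
    # clinical covariates
    female_age_mean: float = 31.0
    female_age_sd: float = 2.5
    male_age_mean: float = 33.0
    male_age_sd: float = 4.0
    pathology_prevalence: float = 0.3
    endometriosis_probs: tuple[float, ...] = (0.85, 0.05, 0.04, 0.03, 0.03)
    transport_missing_rate: float = 0.3
    infertility_secondary_p: float = 0.4
    infertility_duration_mean: float = 2.5
    # outcome model: "published_table7" or custom {feature: coefficient}
    outcome_model: str = "published_table7"
    custom_coefficients: Optional[dict] = None
    # visual grading
    misgrade_rate: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 <= self.frag_mean_d2 < 1 or not 0 <= self.frag_mean_d3 < 1:
            raise ValueError("fragmentation means must lie in [0, 1)")
        if abs(sum(self.endometriosis_probs) - 1.0) > 1e-9:
            raise ValueError("endometriosis_probs must sum to 1")
        if self.asymmetry < 0 or self.diameter_noise < 0:
            raise ValueError("scale parameters must be >= 0")

    def config_hash(self) -> str:
        text = repr(sorted(asdict(self).items()))
        return hashlib.sha256(text.encode()).hexdigest()[:12]


@dataclass
class SyntheticCohort:
    measurements: list[mm.EmbryoMeasurements]
    grades: list[SssGrades]
    profiles: list[ClinicalProfile]
    patient_ids: list[str]
    cass_features: list[mm.CassFeatures]
    latent_scores: np.ndarray
    outcomes: np.ndarray
    config_hash: str
    seed: int

    def __len__(self) -> int:
        return len(self.measurements)

    def feature_table(self, system: str) -> FeatureTable:
        embryos = self.cass_features if system.upper() == "CASS" else self.grades
        return build_feature_table(
            embryos, self.profiles, list(self.outcomes), system
        )


def _draw_count(target: float, dispersion: float, rng: np.random.Generator) -> int:
    return int(np.clip(round(rng.normal(target, dispersion)), 2, 12))


def _split_volume(
    volume: float,
    n_parts: int,
    asymmetry: float,
    min_diameter: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Partition a volume into n parts; each part's sphere diameter stays
    at or above ``min_diameter`` (retries, then falls back to even split)."""
    if asymmetry == 0:
        return np.full(n_parts, volume / n_parts)
    conc = 1.0 / asymmetry
    min_vol = math.pi / 6.0 * min_diameter**3
    for _ in range(50):
        w = rng.dirichlet(np.full(n_parts, conc))
        parts = w * volume
        if parts.min() >= min_vol:
            return parts
    return np.full(n_parts, volume / n_parts)


def _fragment_objects(
    lost_volume: float, threshold: float, rng: np.random.Generator
) -> list[float]:
    """Split a lost volume into fragment objects strictly below the day's
    blastomere threshold, conserving volume exactly."""
    if lost_volume <= 0:
        return []
    cap_d = 0.85 * threshold
    cap_vol = math.pi / 6.0 * cap_d**3
    m = max(1, math.ceil(lost_volume / cap_vol))
    for _ in range(50):
        w = rng.dirichlet(np.full(m, 5.0))
        parts = w * lost_volume
        ds = (6.0 * parts / math.pi) ** (1.0 / 3.0)
        if ds.max() < threshold:
            return list(ds)
        m += 1
    parts = np.full(m, lost_volume / m)
    return list((6.0 * parts / math.pi) ** (1.0 / 3.0))


def _diameters_from_volumes(volumes: np.ndarray) -> np.ndarray:
    return (6.0 * np.asarray(volumes) / math.pi) ** (1.0 / 3.0)


def _maybe_misgrade(cat: int, lo: int, hi: int, rate: float,
                    rng: np.random.Generator) -> int:
    if rate > 0 and rng.random() < rate:
        cat = cat + rng.choice([-1, 1])
    return int(np.clip(cat, lo, hi))


def simulate_embryo(
    config: SimulationConfig, rng: np.random.Generator, embryo_id: str = "E1"
) -> tuple[mm.EmbryoMeasurements, SssGrades]:
    """Generate one embryo's measurements and its derived visual grades."""
    d1 = float(max(rng.normal(config.day1_mean, config.day1_sd), 80.0))
    v1 = math.pi / 6.0 * d1**3

    day_diams: dict[int, list[float]] = {}
    realized: dict[int, tuple[int, float, float]] = {}  # day -> (n, frag, cod)
    for day, target, frag_mean in (
        (2, config.day2_count_target, config.frag_mean_d2),
        (3, config.day3_count_target, config.frag_mean_d3),
    ):
        n_blast = _draw_count(target, config.count_dispersion, rng)
        if frag_mean > 0:
            k = config.frag_concentration
            frac = float(rng.beta(frag_mean * k, (1.0 - frag_mean) * k))
        else:
            frac = 0.0
        if frac >= 1.0:
            raise ValueError("configured fragmentation reached 1; no volume left")
        threshold = mm.BLASTOMERE_MIN_DIAMETER[day]
        blast_vols = _split_volume(
            (1.0 - frac) * v1, n_blast, config.asymmetry, threshold * 1.02, rng
        )
        blast_d = _diameters_from_volumes(blast_vols)
        frag_d = _fragment_objects(frac * v1, threshold, rng)
        day_diams[day] = list(blast_d) + frag_d
        realized[day] = (n_blast, frac, float(blast_d.max() / blast_d.min()))

    noise = config.diameter_noise
    if noise > 0:
        d1 = d1 * (1.0 + noise * rng.standard_normal())
        for day in (2, 3):
            jitter = 1.0 + noise * rng.standard_normal(len(day_diams[day]))
            day_diams[day] = list(np.asarray(day_diams[day]) * jitter)

    measurements = mm.EmbryoMeasurements(
        embryo_id=embryo_id,
        day1_diameter=d1,
        day2_diameters=tuple(day_diams[2]),
        day3_diameters=tuple(day_diams[3]),
    )

    rate = config.misgrade_rate
    n2, f2, cod2 = realized[2]
    n3, f3, cod3 = realized[3]
    grades = SssGrades(
        embryo_id=embryo_id,
        n_d2=_maybe_misgrade(n2, 2, 12, rate, rng),
        n_d3=_maybe_misgrade(n3, 2, 12, rate, rng),
        frag_cat_d2=_maybe_misgrade(frag_category(f2), 0, 4, rate, rng),
        frag_cat_d3=_maybe_misgrade(frag_category(f3), 0, 4, rate, rng),
        symmetry_d2=_maybe_misgrade(symmetry_grade(cod2), 0, 2, rate, rng),
        symmetry_d3=_maybe_misgrade(symmetry_grade(cod3), 0, 2, rate, rng),
    )
    return measurements, grades


def _simulate_profile(
    config: SimulationConfig, rng: np.random.Generator
) -> ClinicalProfile:
    prev = config.pathology_prevalence
    transport: Optional[int]
    if rng.random() < config.transport_missing_rate:
        transport = None
    else:
        transport = int(rng.random() < prev)
    return ClinicalProfile(
        female_age=float(
            np.clip(rng.normal(config.female_age_mean, config.female_age_sd),
                    18.0, 35.9)
        ),
        male_age=float(
            np.clip(rng.normal(config.male_age_mean, config.male_age_sd),
                    18.0, 59.0)
        ),
        female_pathology=int(rng.random() < prev),
        male_pathology=int(rng.random() < prev),
        ovulation_disorder=int(rng.random() < prev / 2),
        transport_problem=transport,
        implantation_problem=int(rng.random() < prev / 3),
        endometriosis_stage=int(
            rng.choice(len(config.endometriosis_probs), p=config.endometriosis_probs)
        ),
        infertility_type=int(rng.random() < config.infertility_secondary_p),
        infertility_duration=float(
            rng.exponential(config.infertility_duration_mean)
        ),
    )


def _latent_score(
    config: SimulationConfig,
    features: mm.CassFeatures,
    profile: ClinicalProfile,
    pub: Optional[PublishedScore],
) -> float:
    if config.outcome_model == "published_table7":
        return published_score(features, profile.male_age, pub)
    if config.outcome_model == "custom":
        coefs = config.custom_coefficients or {}
        vals = dict(features.as_dict())
        vals["male_age"] = profile.male_age
        vals["female_age"] = profile.female_age
        score = float(coefs.get("intercept", 0.0))
        for name, c in coefs.items():
            if name == "intercept":
                continue
            if name.startswith("hinge:"):
                # "hinge:<feature>:<knot>" contributes c * max(0, x - knot)
                _, feat, knot = name.split(":")
                if feat not in vals:
                    raise KeyError(f"unknown feature {feat!r} in hinge term")
                score += c * max(0.0, vals[feat] - float(knot))
                continue
            if name not in vals:
                raise KeyError(f"unknown feature {name!r} in custom coefficients")
            score += c * vals[name]
        return score
    raise ValueError(f"unknown outcome model {config.outcome_model!r}")


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full cohort; byte-identical for identical config + seed.

    Each embryo uses a counter-derived substream of the seeded generator, so
    per-embryo draws are independent of cohort ordering.
    """
    pub = load_published_score() if config.outcome_model == "published_table7" else None

    measurements, grades, profiles, patient_ids, feats = [], [], [], [], []
    scores = []
    lo, hi = config.embryos_per_patient
    for i in range(config.n_patients):
        p_rng = np.random.default_rng([config.seed, 1, i])
        profile = _simulate_profile(config, p_rng)
        n_embryos = int(p_rng.integers(lo, hi + 1))
        for j in range(n_embryos):
            e_rng = np.random.default_rng([config.seed, 2, i, j])
            eid = f"P{i:04d}-E{j}"
            m, g = simulate_embryo(config, e_rng, embryo_id=eid)
            f = mm.derive_cass_features(m)
            measurements.append(m)
            grades.append(g)
            profiles.append(profile)
            patient_ids.append(f"P{i:04d}")
            feats.append(f)
            scores.append(_latent_score(config, f, profile, pub))

    scores = np.asarray(scores)
    out_rng = np.random.default_rng([config.seed, 3])
    probs = 1.0 / (1.0 + np.exp(-scores))
    outcomes = (out_rng.random(len(scores)) < probs).astype(int)
    return SyntheticCohort(
        measurements=measurements,
        grades=grades,
        profiles=profiles,
        patient_ids=patient_ids,
        cass_features=feats,
        latent_scores=scores,
        outcomes=outcomes,
        config_hash=config.config_hash(),
        seed=config.seed,
    )


def recovery_experiment(
    config: SimulationConfig,
    model: str = "LR",
    n_validation: Optional[int] = None,
    mars_kwargs: Optional[dict] = None,
) -> dict:
    """Simulate train + validation cohorts and measure recovery of the
    generative truth by the chosen model family.

    For "LR" with a custom truth, the truth's named features are refit by
    main-effects logistic regression and per-coefficient bias / 2-SE
    coverage is reported. For "MARS", selected knots per variable are
    reported. Both report the train-vs-validation AUC gap.
    """
    from .lr_model import fit_logistic
    from .mars import mars_forward, mars_backward, mars_predict
    from .evaluation import roc_auc

    model = model.upper()
    if model not in ("LR", "MARS"):
        raise ValueError("model must be 'LR' or 'MARS'")

    train = simulate_cohort(config)
    val_cfg = SimulationConfig(
        **{**asdict(config), "seed": config.seed + 1_000_003,
           "n_patients": n_validation or config.n_patients}
    )
    validation = simulate_cohort(val_cfg)

    t_table = train.feature_table("CASS")
    v_table = validation.feature_table("CASS")

    report: dict = {"model": model, "n_train": len(t_table), "n_val": len(v_table)}
    if model == "LR":
        if config.outcome_model == "custom":
            names = [k for k in (config.custom_coefficients or {}) if k != "intercept"]
        else:
            names = t_table.predictors
        X = t_table.data[names].to_numpy()
        fit = fit_logistic(X, t_table.outcome.to_numpy(), term_names=names)
        coefs = dict(zip(fit.term_names, fit.coefficients))
        ses = dict(zip(fit.term_names, fit.standard_errors))
        truth = config.custom_coefficients or {}
        recovery = {}
        for name in names:
            true_b = truth.get(name)
            est, se = coefs[name], ses[name]
            recovery[name] = {
                "true": true_b,
                "estimate": est,
                "se": se,
                "covered": (abs(est - true_b) <= 2 * se) if true_b is not None else None,
            }
        report["coefficients"] = recovery
        t_scores = fit.linear_predictor(t_table.data)
        v_scores = fit.linear_predictor(v_table.data)
    else:
        kw = mars_kwargs or {}
        fwd = mars_forward(t_table.data, t_table.outcome.to_numpy(), **kw)
        fit_m = mars_backward(fwd, fwd.penalty)
        report["knots"] = {
            var: sorted(
                {f.knot for b in fit_m.basis for f in b.factors if f.var == var}
            )
            for var in fit_m.variables
        }
        report["n_basis"] = fit_m.n_basis
        t_scores = mars_predict(fit_m, t_table.data)
        v_scores = mars_predict(fit_m, v_table.data)

    auc_t = roc_auc(t_scores, t_table.outcome.to_numpy()).auc
    auc_v = roc_auc(v_scores, v_table.outcome.to_numpy()).auc
    report["train_auc"] = auc_t
    report["validation_auc"] = auc_v
    report["auc_gap"] = auc_t - auc_v
    return report


# ---------------------------------------------------------------------------
# CSV export matching the dialects the pipeline reads

def cohort_to_csvs(cohort: SyntheticCohort, prefix: str) -> dict[str, str]:
    """Write measurements/grades/profiles/outcomes CSVs; returns the paths."""
    paths = {}
    m_path = f"{prefix}_measurements.csv"
    mm.write_measurements_csv(cohort.measurements, m_path)
    paths["measurements"] = m_path

    g_rows = [
        {
            "embryo_id": g.embryo_id,
            "n_d2": g.n_d2,
            "n_d3": g.n_d3,
            "frag_cat_d2": g.frag_cat_d2,
            "frag_cat_d3": g.frag_cat_d3,
            "symmetry_d2": g.symmetry_d2,
            "symmetry_d3": g.symmetry_d3,
        }
        for g in cohort.grades
    ]
    g_path = f"{prefix}_grades.csv"
    pd.DataFrame(g_rows).to_csv(g_path, index=False)
    paths["grades"] = g_path

    p_rows = []
    for pid, prof, y in zip(cohort.patient_ids, cohort.profiles, cohort.outcomes):
        row = {"patient_id": pid, **asdict(prof), "outcome": int(y)}
        p_rows.append(row)
    p_path = f"{prefix}_profiles.csv"
    pd.DataFrame(p_rows).to_csv(p_path, index=False)
    paths["profiles"] = p_path
    return paths
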