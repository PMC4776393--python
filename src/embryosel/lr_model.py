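"""Maximum-likelihood logistic regression with two-way interaction terms and
likelihood-ratio backward elimination, plus the fixed published scoring
equation.

Terms are tuples of feature names: a 1-tuple is a main effect, a 2-tuple a
plain product of two features. The intercept is always present and is never
eligible for removal.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .morphometry import CassFeatures

__all__ = [
    "LogisticFit",
    "PublishedScore",
    "SeparationError",
    "RankDeficiencyError",
    "fit_logistic",
    "fit_logistic_terms",
    "full_interaction_terms",
    "backward_eliminate",
    "load_published_score",
    "published_score",
]

_MAX_ITER = 100
_LL_RTOL = 1e-8
_SEPARATION_BETA = 15.0


class SeparationError(RuntimeError):
    """Perfect separation: coefficients diverge during fitting."""


class RankDeficiencyError(ValueError):
    """Design matrix is rank-deficient; names the collinear columns."""


Term = tuple[str, ...]


def term_name(term: Term) -> str:
    return ":".join(term) if term else "(intercept)"


@dataclass
class LogisticFit:
    """A fitted logistic model over named terms (intercept first)."""

    terms: tuple[Term, ...]
    coefficients: np.ndarray
    standard_errors: np.ndarray
    t_statistics: np.ndarray
    p_values: np.ndarray
    log_likelihood: float
    n_observations: int
    n_iterations: int
    _frame: pd.DataFrame = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)

    @property
    def term_names(self) -> list[str]:
        return [term_name(t) for t in self.terms]

    def linear_predictor(self, frame: pd.DataFrame) -> np.ndarray:
        X = _design_matrix(frame, self.terms)
        return X @ self.coefficients

    def predict_proba(self, frame: pd.DataFrame) -> np.ndarray:
        return _sigmoid(self.linear_predictor(frame))

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.term_names,
                "estimate": self.coefficients,
                "se": self.standard_errors,
                "t_statistic": self.t_statistics,
                "p_value": self.p_values,
            }
        )


def _sigmoid(eta: np.ndarray) -> np.ndarray:
    out = np.empty_like(eta, dtype=float)
    pos = eta >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-eta[pos]))
    e = np.exp(eta[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _log_likelihood(y: np.ndarray, eta: np.ndarray) -> float:
    # log L = sum y*eta - log(1 + exp(eta)), computed stably
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


def _design_matrix(frame: pd.DataFrame, terms: Sequence[Term]) -> np.ndarray:
    cols = [np.ones(len(frame))]
    for t in terms:
        if not t:  # explicit intercept entry
            continue
        col = np.ones(len(frame))
        for name in t:
            if name not in frame.columns:
                raise KeyError(f"missing feature column {name!r}")
            col = col * frame[name].to_numpy(dtype=float)
        cols.append(col)
    return np.column_stack(cols)


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # identify the offending columns incrementally
    bad = []
    kept = X[:, :1]
    for j in range(1, X.shape[1]):
        cand = np.column_stack([kept, X[:, j]])
        if np.linalg.matrix_rank(cand) > kept.shape[1]:
            kept = cand
        else:
            bad.append(names[j - 1] if j - 1 < len(names) else f"col{j}")
    raise RankDeficiencyError(f"collinear design columns: {bad}")


def _irls(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float, int]:
    """IRLS with step-halving; the log-likelihood never decreases."""
    n, p = X.shape
    beta = np.zeros(p)
    ll = _log_likelihood(y, X @ beta)
    for it in range(1, _MAX_ITER + 1):
        eta = X @ beta
        mu = _sigmoid(eta)
        w = np.clip(mu * (1.0 - mu), 1e-10, None)
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        new_beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        step = new_beta - beta
        new_ll = _log_likelihood(y, X @ new_beta)
        halvings = 0
        while new_ll < ll and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll = _log_likelihood(y, X @ new_beta)
            halvings += 1
        converged = abs(new_ll - ll) < _LL_RTOL * (abs(ll) + _LL_RTOL)
        beta, ll = new_beta, new_ll
        if converged:
            return beta, ll, it
    return beta, ll, _MAX_ITER


def fit_logistic(
    X: np.ndarray,
    y: Sequence[int],
    term_names: Optional[Sequence[str]] = None,
) -> LogisticFit:
    """Fit a logistic regression of binary ``y`` on the columns of ``X``.

    An intercept is prepended automatically. Wald standard errors, z
    statistics and two-sided normal p-values are reported per term.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    y = np.asarray(y, dtype=float)
    names = list(term_names) if term_names is not None else [
        f"x{j}" for j in range(X.shape[1])
    ]
    frame = pd.DataFrame(X, columns=names)
    terms = tuple((n,) for n in names)
    return fit_logistic_terms(frame, y, terms)


def fit_logistic_terms(
    frame: pd.DataFrame, y: Sequence[int], terms: Sequence[Term]
) -> LogisticFit:
    """Fit a logistic model over explicit (possibly product) terms."""
    y = np.asarray(y, dtype=float)
    terms = tuple(tuple(t) for t in terms)
    X = _design_matrix(frame, terms)
    n, p = X.shape
    if n <= p:
        raise ValueError(f"need more observations ({n}) than terms ({p})")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("outcome contains a single class")
    if not set(classes) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    _check_rank(X, [term_name(t) for t in terms])

    beta, ll, n_iter = _irls(X, y)
    if np.any(np.abs(beta) > _SEPARATION_BETA):
        raise SeparationError(
            "coefficients diverged (|beta| > "
            f"{_SEPARATION_BETA}); data are likely perfectly separated"
        )

    mu = _sigmoid(X @ beta)
    w = np.clip(mu * (1.0 - mu), 1e-10, None)
    info = X.T @ (X * w[:, None])
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    tstat = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(tstat))

    all_terms = ((),) + terms  # leading () denotes the intercept
    return LogisticFit(
        terms=all_terms,
        coefficients=beta,
        standard_errors=se,
        t_statistics=tstat,
        p_values=pvals,
        log_likelihood=ll,
        n_observations=n,
        n_iterations=n_iter,
        _frame=frame,
        _y=y,
    )


def full_interaction_terms(features: Sequence[str]) -> list[Term]:
    """All main effects plus all pairwise products, deterministically ordered."""
    mains: list[Term] = [(f,) for f in features]
    pairs: list[Term] = [
        tuple(sorted(c)) for c in itertools.combinations(features, 2)
    ]
    return mains + sorted(pairs)


def _eligible_terms(terms: Sequence[Term]) -> list[Term]:
    """Removable terms under hierarchy: a main effect only when no retained
    product contains it; products always removable."""
    products = [t for t in terms if len(t) == 2]
    in_products = {f for t in products for f in t}
    out = list(products)
    out.extend(t for t in terms if len(t) == 1 and t[0] not in in_products)
    return out


def backward_eliminate(fit: LogisticFit, removal_p: float = 0.1) -> LogisticFit:
    """Backward stepwise elimination by likelihood-ratio tests.

    At each step the eligible term whose removal LRT has the largest
    p >= ``removal_p`` is dropped (ties by term name); stops when every
    eligible term is significant at ``removal_p``.
    """
    if fit._frame is None:
        raise ValueError("fit carries no training data; refit before eliminating")
    frame, y = fit._frame, fit._y
    if removal_p >= 1.0:  # everything is removable
        return fit_logistic_terms(frame, y, [])
    current = fit
    while True:
        model_terms = [t for t in current.terms if t]
        eligible = _eligible_terms(model_terms)
        if not eligible:
            return current
        best: Optional[tuple[float, str, Term, LogisticFit]] = None
        for t in eligible:
            reduced_terms = [u for u in model_terms if u != t]
            reduced = fit_logistic_terms(frame, y, reduced_terms)
            lr = 2.0 * (current.log_likelihood - reduced.log_likelihood)
            p = float(stats.chi2.sf(max(lr, 0.0), df=1))
            key = (p, term_name(t))
            # largest p wins; ties broken lexicographically by term name
            if best is None or key > (best[0], best[1]):
                best = (p, term_name(t), t, reduced)
        if best is None or best[0] < removal_p:
            return current
        current = best[3]


# ---------------------------------------------------------------------------
# Published fixed scoring equation

_REQUIRED_SCORE_TERMS = (
    "intercept",
    "number_day2",
    "tcv_day2",
    "fragmentation_day2",
    "age_male",
    "number_day3",
    "number_day2:cod_day3",
    "tcv_day2:age_male",
    "cod_day2:age_male",
    "fragmentation_day2:age_male",
    "cod_day2:number_day3",
    "parity_day2:number_day3",
)


@dataclass(frozen=True)
class PublishedScore:
    """The fixed published log-odds equation (12 coefficients).

    ``number_day3`` is the transformed Day-3 count |n - 8.4|;
    ``tcv_day2`` enters after multiplication by ``tcv_scale``.
    """

    coefficients: dict[str, float]
    tcv_scale: float

    def __post_init__(self) -> None:
        missing = [t for t in _REQUIRED_SCORE_TERMS if t not in self.coefficients]
        if missing:
            raise ValueError(f"published score missing terms: {missing}")

    def linear_predictor(self, values: dict[str, float]) -> float:
        c = self.coefficients
        v = dict(values)
        v["tcv_day2"] = v["tcv_day2"] * self.tcv_scale
        return (
            c["intercept"]
            + c["number_day2"] * v["number_day2"]
            + c["tcv_day2"] * v["tcv_day2"]
            + c["fragmentation_day2"] * v["fragmentation_day2"]
            + c["age_male"] * v["age_male"]
            + c["number_day3"] * v["number_day3"]
            + c["number_day2:cod_day3"] * v["number_day2"] * v["cod_day3"]
            + c["tcv_day2:age_male"] * v["tcv_day2"] * v["age_male"]
            + c["cod_day2:age_male"] * v["cod_day2"] * v["age_male"]
            + c["fragmentation_day2:age_male"]
            * v["fragmentation_day2"]
            * v["age_male"]
            + c["cod_day2:number_day3"] * v["cod_day2"] * v["number_day3"]
            + c["parity_day2:number_day3"] * v["parity_day2"] * v["number_day3"]
        )


def load_published_score(path=None) -> PublishedScore:
    """Load the published coefficients from YAML (packaged default)."""
    if path is None:
        text = (
            resources.files("embryosel").joinpath("data/published_lr.yaml").read_text()
        )
    else:
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    doc = yaml.safe_load(text)
    return PublishedScore(
        coefficients={k: float(v) for k, v in doc["coefficients"].items()},
        tcv_scale=float(doc["tcv_scale"]),
    )


def published_score(
    f: CassFeatures, male_age: float, score: Optional[PublishedScore] = None
) -> float:
    """Log-odds of implantation from the published equation.

    The probability is ``expit`` of the returned value.
    """
    if score is None:
        score = load_published_score()
    values = {
        "number_day2": f.n_d2,
        "tcv_day2": f.tcv_d2,
        "fragmentation_day2": f.frag_d2,
        "age_male": male_age,
        "number_day3": f.n_d3_dev,
        "cod_day2": f.cod_d2,
        "cod_day3": f.cod_d3,
        "parity_day2": f.parity_d2,
    }
    for k, v in values.items():
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise ValueError(f"missing feature {k!r} for published score")
    return score.linear_predictor(values)
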