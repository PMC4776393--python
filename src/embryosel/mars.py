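"""Multivariate adaptive regression splines, built from scratch.

A model is a linear combination of hinge basis functions. Each basis
function is a product of factors max(0, sign*(x_v - knot)); the empty
product is the intercept. Fitting is the classic two-stage procedure: a
greedy forward pass that adds reflected hinge pairs to minimise training
RSS, then a backward pass that prunes basis functions under the
generalized cross-validation (GCV) criterion with a configurable penalty
per knot (default 3).

Binary outcomes are fitted by least squares on the 0/1 label; the raw
model score is used for ranking and ROC analysis.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HingeFactor",
    "HingeBasis",
    "MarsModel",
    "max_basis_count",
    "gcv_score",
    "mars_forward",
    "mars_backward",
    "mars_cv",
    "mars_predict",
    "model_to_json",
    "model_from_json",
]

DEFAULT_PENALTY = 3.0
_RSS_IMPROVE_RTOL = 1e-8


@dataclass(frozen=True)
class HingeFactor:
    """One hinge factor max(0, sign*(x_var - knot)); sign is +1 or -1."""

    var: str
    sign: int
    knot: float

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        return np.maximum(0.0, self.sign * (x - self.knot))


@dataclass(frozen=True)
class HingeBasis:
    """Product of hinge factors; the empty product is the intercept."""

    factors: tuple[HingeFactor, ...] = ()

    def __post_init__(self) -> None:
        vars_ = [f.var for f in self.factors]
        if len(vars_) != len(set(vars_)):
            raise ValueError("a variable may appear only once per basis function")

    @property
    def degree(self) -> int:
        return len(self.factors)

    @property
    def variables(self) -> frozenset[str]:
        return frozenset(f.var for f in self.factors)

    def evaluate(self, frame: pd.DataFrame) -> np.ndarray:
        out = np.ones(len(frame))
        for f in self.factors:
            if f.var not in frame.columns:
                raise KeyError(f"missing variable {f.var!r}")
            out = out * f.evaluate(frame[f.var].to_numpy(dtype=float))
        return out

    def describe(self) -> str:
        if not self.factors:
            return "1"
        parts = [
            f"max(0, {'' if f.sign > 0 else '-'}({f.var} - {f.knot:g}))"
            if f.sign > 0
            else f"max(0, {f.knot:g} - {f.var})"
            for f in self.factors
        ]
        return " * ".join(parts)


@dataclass
class MarsModel:
    """Fitted spline model: basis functions (intercept first) + coefficients."""

    basis: tuple[HingeBasis, ...]
    coefficients: np.ndarray
    gcv: float
    penalty: float
    variables: tuple[str, ...]
    rss: float = float("nan")
    _frame: pd.DataFrame = field(repr=False, default=None)
    _y: np.ndarray = field(repr=False, default=None)

    @property
    def n_basis(self) -> int:
        return len(self.basis)

    @property
    def n_knots(self) -> int:
        return count_knots(self.basis)

    def predict(self, X) -> np.ndarray:
        return mars_predict(self, X)


def count_knots(basis: Sequence[HingeBasis]) -> int:
    """Distinct (variable, knot) placements across all basis factors."""
    return len({(f.var, f.knot) for b in basis for f in b.factors})


def max_basis_count(d: int) -> int:
    """Forward-pass cap on basis functions: min(200, max(20, 2d)) + 1."""
    if d < 1:
        raise ValueError(f"number of variables must be >= 1, got {d}")
    return min(200, max(20, 2 * d)) + 1


def gcv_score(
    rss: float, n: int, n_basis: int, n_knots: int, penalty: float = DEFAULT_PENALTY
) -> float:
    """(rss/n) / (1 - C/n)^2 with effective parameters C = n_basis + penalty*n_knots."""
    c = n_basis + penalty * n_knots
    if c >= n:
        raise ValueError(
            f"effective parameters C={c} must be below sample size n={n}"
        )
    return (rss / n) / (1.0 - c / n) ** 2


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])


def _basis_matrix(basis: Sequence[HingeBasis], frame: pd.DataFrame) -> np.ndarray:
    return np.column_stack([b.evaluate(frame) for b in basis])


def _lstsq_rss(B: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, float]:
    coef, *_ = np.linalg.lstsq(B, y, rcond=None)
    resid = y - B @ coef
    return coef, float(resid @ resid)


def _candidate_knots(x: np.ndarray, max_knots: Optional[int]) -> np.ndarray:
    knots = np.unique(x)
    if max_knots is not None and knots.size > max_knots:
        idx = np.unique(
            np.round(np.linspace(0, knots.size - 1, max_knots)).astype(int)
        )
        knots = knots[idx]
    return knots


def mars_forward(
    X,
    y: Sequence[float],
    max_basis: Optional[int] = None,
    max_degree: int = 2,
    penalty: float = DEFAULT_PENALTY,
    max_knots: Optional[int] = None,
    _min_obs: int = 10,
) -> MarsModel:
    """Greedy forward pass: repeatedly add the reflected hinge pair that most
    reduces training RSS.

    Candidate knots are observed values of each variable on the support of
    the parent basis function (optionally thinned to ``max_knots``
    quantile-spaced observed values). Ties are broken by parent order, then
    lowest variable name, then smallest knot. Stops at ``max_basis`` total
    basis functions or when the best RSS improvement falls below
    1e-8 * var(y) * n.
    """
    frame = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n = len(frame)
    if n < _min_obs:
        raise ValueError(f"need at least {_min_obs} observations, got {n}")
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    variables = tuple(frame.columns)
    if max_basis is None:
        max_basis = max_basis_count(len(variables))

    basis: list[HingeBasis] = [HingeBasis()]
    B = np.ones((n, 1))
    coef, rss = _lstsq_rss(B, y)

    y_var = float(np.var(y))
    if y_var == 0.0:
        return _finalize(basis, frame, y, penalty, variables)
    improve_floor = _RSS_IMPROVE_RTOL * y_var * n

    col_cache = {v: frame[v].to_numpy(dtype=float) for v in variables}

    while len(basis) + 2 <= max_basis:
        # adding a pair must keep GCV's effective parameters below n
        if (len(basis) + 2) + penalty * (count_knots(basis) + 1) >= n:
            break
        # orthonormal basis of the current column space
        Q, _ = np.linalg.qr(B)
        r = y - Q @ (Q.T @ y)
        rss_now = float(r @ r)

        best = None  # (reduction, parent_idx, var, knot)
        for p_idx, parent in enumerate(basis):
            if parent.degree >= max_degree:
                continue
            p_col = B[:, p_idx]
            support = p_col > 0
            if not support.any():
                continue
            for var in variables:
                if var in parent.variables:
                    continue
                x = col_cache[var]
                knots = _candidate_knots(x[support], max_knots)
                if knots.size == 0:
                    continue
                red, k_idx = _best_knot_reduction(p_col, x, knots, Q, r)
                if red is None:
                    continue
                cand = (red, p_idx, var, float(knots[k_idx]))
                if best is None or _better_candidate(cand, best):
                    best = cand

        if best is None or best[0] <= improve_floor:
            break
        _, p_idx, var, knot = best
        parent = basis[p_idx]
        new_cols = []
        for sign in (+1, -1):
            b = HingeBasis(parent.factors + (HingeFactor(var, sign, knot),))
            col = b.evaluate(frame)
            if np.any(col != 0.0):
                basis.append(b)
                new_cols.append(col)
        if not new_cols:
            break
        B = np.column_stack([B] + new_cols)
        coef, new_rss = _lstsq_rss(B, y)
        if rss_now - new_rss <= improve_floor and len(basis) > 1:
            # numerically sterile addition; undo and stop
            basis = basis[: B.shape[1] - len(new_cols)]
            break
        rss = new_rss

    return _finalize(basis, frame, y, penalty, variables)


def _better_candidate(cand, best) -> bool:
    """Strictly larger reduction wins; ties by parent index, variable, knot."""
    red, p_idx, var, knot = cand
    b_red, b_p, b_var, b_knot = best
    if red > b_red + 1e-12 * max(abs(b_red), 1.0):
        return True
    if red < b_red - 1e-12 * max(abs(b_red), 1.0):
        return False
    return (p_idx, var, knot) < (b_p, b_var, b_knot)


def _best_knot_reduction(
    p_col: np.ndarray,
    x: np.ndarray,
    knots: np.ndarray,
    Q: np.ndarray,
    r: np.ndarray,
) -> tuple[Optional[float], int]:
    """Vectorised RSS reduction of adding the reflected pair
    parent*max(0, x-k) and parent*max(0, k-x), for every candidate knot.

    Projects both candidate columns off the current column space (Q) and
    solves the residual 2x2 normal equations per knot.
    """
    diff = x[:, None] - knots[None, :]
    C1 = p_col[:, None] * np.maximum(0.0, diff)
    C2 = p_col[:, None] * np.maximum(0.0, -diff)

    C1p = C1 - Q @ (Q.T @ C1)
    C2p = C2 - Q @ (Q.T @ C2)

    a11 = np.einsum("ij,ij->j", C1p, C1p)
    a22 = np.einsum("ij,ij->j", C2p, C2p)
    a12 = np.einsum("ij,ij->j", C1p, C2p)
    b1 = C1p.T @ r
    b2 = C2p.T @ r

    scale = np.maximum(a11 * a22, 1e-300)
    det = a11 * a22 - a12**2
    ok2 = det > 1e-10 * scale

    red = np.zeros(knots.size)
    with np.errstate(divide="ignore", invalid="ignore"):
        red2 = (a22 * b1**2 - 2.0 * a12 * b1 * b2 + a11 * b2**2) / det
        red1a = np.where(a11 > 1e-12 * np.maximum(a11.max(initial=1.0), 1.0),
                         b1**2 / a11, 0.0)
        red1b = np.where(a22 > 1e-12 * np.maximum(a22.max(initial=1.0), 1.0),
                         b2**2 / a22, 0.0)
    red = np.where(ok2, red2, np.maximum(red1a, red1b))
    red = np.where(np.isfinite(red), red, 0.0)
    if red.size == 0:
        return None, 0
    k_idx = int(np.argmax(red))
    # prefer the smallest knot among near-ties
    tol = 1e-12 * max(abs(red[k_idx]), 1.0)
    ties = np.nonzero(red >= red[k_idx] - tol)[0]
    k_idx = int(ties[0])
    return float(red[k_idx]), k_idx


def _finalize(
    basis: Sequence[HingeBasis],
    frame: pd.DataFrame,
    y: np.ndarray,
    penalty: float,
    variables: tuple[str, ...],
) -> MarsModel:
    basis = tuple(basis)
    B = _basis_matrix(basis, frame)
    coef, rss = _lstsq_rss(B, y)
    gcv = gcv_score(rss, len(y), len(basis), count_knots(basis), penalty)
    return MarsModel(
        basis=basis,
        coefficients=coef,
        gcv=gcv,
        penalty=penalty,
        variables=variables,
        rss=rss,
        _frame=frame,
        _y=y,
    )


def mars_backward(model: MarsModel, penalty: float = DEFAULT_PENALTY) -> MarsModel:
    """Backward pruning under the GCV criterion.

    Small models (at most 7 non-intercept basis functions) are pruned by
    exhaustive subset search, which stepwise deletion is meant to
    approximate; larger models use the classic greedy deletion path,
    returning the subset along the path with the global minimum GCV (the
    full model included).
    """
    if model._frame is None:
        raise ValueError("model carries no training data")
    frame, y = model._frame, model._y
    n = len(y)

    non_intercept = [b for b in model.basis if b.degree > 0]
    if len(non_intercept) <= 7:
        return _backward_exhaustive(model, penalty)

    current = list(model.basis)
    best_subset = tuple(current)
    _, rss = _lstsq_rss(_basis_matrix(current, frame), y)
    best_gcv = gcv_score(rss, n, len(current), count_knots(current), penalty)

    while len(current) > 1:
        step_best = None  # (gcv, removal_idx)
        for i, b in enumerate(current):
            if b.degree == 0:
                continue
            trial = current[:i] + current[i + 1 :]
            _, rss = _lstsq_rss(_basis_matrix(trial, frame), y)
            g = gcv_score(rss, n, len(trial), count_knots(trial), penalty)
            if step_best is None or g < step_best[0]:
                step_best = (g, i)
        if step_best is None:
            break
        g, i = step_best
        current = current[:i] + current[i + 1 :]
        if g < best_gcv:
            best_gcv = g
            best_subset = tuple(current)

    B = _basis_matrix(best_subset, frame)
    coef, rss = _lstsq_rss(B, y)
    return MarsModel(
        basis=best_subset,
        coefficients=coef,
        gcv=gcv_score(rss, n, len(best_subset), count_knots(best_subset), penalty),
        penalty=penalty,
        variables=model.variables,
        rss=rss,
        _frame=frame,
        _y=y,
    )


def _backward_exhaustive(model: MarsModel, penalty: float) -> MarsModel:
    import itertools

    frame, y = model._frame, model._y
    n = len(y)
    intercept = model.basis[0]
    non_intercept = [b for b in model.basis if b.degree > 0]
    best = None
    for r in range(len(non_intercept) + 1):
        for combo in itertools.combinations(non_intercept, r):
            basis = (intercept,) + combo
            _, rss = _lstsq_rss(_basis_matrix(basis, frame), y)
            g = gcv_score(rss, n, len(basis), count_knots(basis), penalty)
            if best is None or g < best[0]:
                best = (g, basis)
    g, basis = best
    B = _basis_matrix(basis, frame)
    coef, rss = _lstsq_rss(B, y)
    return MarsModel(
        basis=basis,
        coefficients=coef,
        gcv=g,
        penalty=penalty,
        variables=model.variables,
        rss=rss,
        _frame=frame,
        _y=y,
    )


def mars_predict(model: MarsModel, X) -> np.ndarray:
    """Evaluate the model score on new data."""
    frame = _as_frame(X)
    needed = {f.var for b in model.basis for f in b.factors}
    missing = sorted(needed - set(frame.columns))
    if missing:
        raise KeyError(f"missing variables for prediction: {missing}")
    return _basis_matrix(model.basis, frame) @ model.coefficients


def _stratified_folds(
    y: np.ndarray, folds: int, rng: np.random.Generator
) -> np.ndarray:
    """Fold labels, stratified by outcome when every class has >= folds
    members, otherwise plain shuffled assignment."""
    n = len(y)
    assignment = np.empty(n, dtype=int)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size >= 2 and counts.min() >= folds:
        for c in classes:
            idx = np.nonzero(y == c)[0]
            idx = rng.permutation(idx)
            assignment[idx] = np.arange(idx.size) % folds
    else:
        assignment[:] = rng.permutation(np.arange(n) % folds)
    return assignment


def mars_cv(
    X,
    y: Sequence[float],
    folds: int = 10,
    seed: int = 0,
    max_basis: Optional[int] = None,
    max_degree: int = 2,
    penalty: float = DEFAULT_PENALTY,
    max_knots: Optional[int] = None,
) -> tuple[float, np.ndarray, MarsModel]:
    """K-fold cross-validation of the forward+backward pipeline.

    Folds are stratified by outcome (seeded); each fold's squared-error mean
    on the held-out part is recorded. Returns (mean CV error, per-fold
    errors, final model refit on all data).
    """
    frame = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n = len(y)
    if folds > n:
        raise ValueError(f"folds ({folds}) cannot exceed sample size ({n})")
    rng = np.random.default_rng(seed)
    assignment = _stratified_folds(y, folds, rng)

    fold_errors = np.empty(folds)
    for k in range(folds):
        test = assignment == k
        train_frame = frame[~test].reset_index(drop=True)
        fwd = mars_forward(
            train_frame, y[~test], max_basis=max_basis, max_degree=max_degree,
            penalty=penalty, max_knots=max_knots, _min_obs=3,
        )
        fit = mars_backward(fwd, penalty)
        pred = mars_predict(fit, frame[test].reset_index(drop=True))
        fold_errors[k] = float(np.mean((y[test] - pred) ** 2))

    fwd = mars_forward(
        frame, y, max_basis=max_basis, max_degree=max_degree,
        penalty=penalty, max_knots=max_knots,
    )
    final = mars_backward(fwd, penalty)
    return float(np.mean(fold_errors)), fold_errors, final


# ---------------------------------------------------------------------------
# JSON serialization of fitted models

def model_to_json(model: MarsModel) -> str:
    doc = {
        "penalty": model.penalty,
        "gcv": model.gcv,
        "variables": list(model.variables),
        "basis": [
            {
                "coefficient": float(c),
                "factors": [
                    {"var": f.var, "sign": f.sign, "knot": f.knot}
                    for f in b.factors
                ],
                "description": b.describe(),
            }
            for b, c in zip(model.basis, model.coefficients)
        ],
    }
    return json.dumps(doc, indent=2)


def model_from_json(text: str) -> MarsModel:
    doc = json.loads(text)
    basis = tuple(
        HingeBasis(
            tuple(
                HingeFactor(f["var"], int(f["sign"]), float(f["knot"]))
                for f in entry["factors"]
            )
        )
        for entry in doc["basis"]
    )
    coef = np.array([entry["coefficient"] for entry in doc["basis"]])
    return MarsModel(
        basis=basis,
        coefficients=coef,
        gcv=float(doc["gcv"]),
        penalty=float(doc["penalty"]),
        variables=tuple(doc["variables"]),
    )
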