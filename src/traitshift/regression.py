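"""OLS fits of CWMs on environmental predictors, AICc stepwise selection,
and per-species trait-environment regressions."""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import EnvironmentTable, SiteSpeciesMeans, ValidationError

logger = logging.getLogger("traitshift")

__all__ = [
    "LinearModelFit",
    "SpeciesResponseFit",
    "fit_ols",
    "stepwise_aicc",
    "species_trait_response",
    "correlation_screen",
    "aicc",
]

#: condition-number threshold above which a design is treated as collinear
COLLINEARITY_LIMIT = 1e10


def aicc(rss: float, n: int, n_coefficients: int) -> float:
    """Small-sample corrected AIC for a Gaussian linear model.

    ``aicc = n ln(RSS/n) + 2k + 2k(k+1)/(n-k-1)`` with
    ``k = n_coefficients + 1`` counting the error variance.  The constant
    additive term of the Gaussian log-likelihood is dropped; it cancels in
    every comparison.
    """
    k = n_coefficients + 1
    if n - k - 1 <= 0:
        return float("inf")
    if rss <= 0:
        return float("-inf")
    return n * np.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class LinearModelFit:
    response: str
    predictors: tuple
    coefficients: dict  # includes "intercept"
    r_squared: float
    ss_explained: float
    ss_residual: float
    ss_total: float
    aicc: float
    n: int
    k: int  # parameter count incl. intercept and error variance

    @property
    def signs(self) -> dict:
        return {p: int(np.sign(self.coefficients[p])) for p in self.predictors}


@dataclass
class SpeciesResponseFit:
    species: str
    trait: str
    predictor: str
    slope: float
    intercept: float
    r_squared: float
    n_sites: int


def _design(env: EnvironmentTable, predictors, sites) -> np.ndarray:
    Xdf = env.transformed(predictors)
    Xdf = Xdf.reindex(sites)
    if Xdf.isna().any().any():
        raise ValidationError("environment table missing values for response sites")
    return np.column_stack([np.ones(len(Xdf)), Xdf.to_numpy()])


def _check_collinearity(X: np.ndarray, predictors) -> None:
    if X.shape[1] < 3:
        return
    # scale columns to unit norm so the condition number reflects correlation
    norms = np.linalg.norm(X, axis=0)
    cond = np.linalg.cond(X / norms)
    if cond > COLLINEARITY_LIMIT:
        body = X[:, 1:]
        corr = np.corrcoef(body, rowvar=False)
        worst, pair = 0.0, None
        for i, j in itertools.combinations(range(len(predictors)), 2):
            if abs(corr[i, j]) > worst:
                worst, pair = abs(corr[i, j]), (predictors[i], predictors[j])
        raise ValidationError(
            f"collinear design (condition number {cond:.3g}); "
            f"most correlated pair: {pair} (|r| = {worst:.4f})"
        )


def fit_ols(y, env: EnvironmentTable, predictors, response: str = "y") -> LinearModelFit:
    """Ordinary least squares of a per-site response on environmental predictors.

    ``y`` may be a pandas Series (aligned to env by index) or an array in
    env's site order.  Flagged variables enter log-transformed.
    """
    predictors = tuple(predictors)
    if isinstance(y, pd.Series):
        sites = list(y.index)
        yv = y.to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
        sites = env.sites
        if len(yv) != len(sites):
            raise ValidationError("response length does not match environment table")
    n = len(yv)
    if n <= len(predictors) + 1:
        raise ValidationError(
            f"n = {n} sites cannot support {len(predictors)} predictors"
        )
    X = _design(env, predictors, sites)
    _check_collinearity(X, predictors)
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    fitted = X @ beta
    resid = yv - fitted
    ss_res = float((resid**2).sum())
    ss_tot = float(((yv - yv.mean()) ** 2).sum())
    ss_exp = float(((fitted - fitted.mean()) ** 2).sum())
    names = ["intercept", *predictors]
    return LinearModelFit(
        response=response,
        predictors=predictors,
        coefficients=dict(zip(names, beta.tolist())),
        r_squared=ss_exp / ss_tot if ss_tot > 0 else float("nan"),
        ss_explained=ss_exp,
        ss_residual=ss_res,
        ss_total=ss_tot,
        aicc=aicc(ss_res, n, len(predictors) + 1),
        n=n,
        k=len(predictors) + 2,
    )


def _intercept_only(y, env, response) -> LinearModelFit:
    if isinstance(y, pd.Series):
        yv = y.to_numpy(dtype=float)
    else:
        yv = np.asarray(y, dtype=float)
    n = len(yv)
    ss_tot = float(((yv - yv.mean()) ** 2).sum())
    return LinearModelFit(
        response=response,
        predictors=(),
        coefficients={"intercept": float(yv.mean())},
        r_squared=0.0 if ss_tot > 0 else float("nan"),
        ss_explained=0.0,
        ss_residual=ss_tot,
        ss_total=ss_tot,
        aicc=aicc(ss_tot, n, 1),
        n=n,
        k=2,
    )


def stepwise_aicc(
    y,
    env: EnvironmentTable,
    candidate_predictors,
    direction: str = "both",
    start: str = "full",
    response: str = "y",
) -> LinearModelFit:
    """Greedy single-term stepwise selection minimizing AICc.

    Starting from the full candidate model (default) or the intercept-only
    model (``start="empty"``), each step evaluates every allowed single-term
    addition or deletion and takes the move with the lowest AICc; ties are
    broken toward the smaller model; the search stops when no move improves
    AICc by more than 0.
    """
    if direction not in {"both", "forward", "backward"}:
        raise ValueError(f"unknown direction {direction!r}")
    candidates = tuple(candidate_predictors)
    if not candidates:
        raise ValidationError("candidate predictor set is empty")

    def fit(subset) -> LinearModelFit:
        if not subset:
            return _intercept_only(y, env, response)
        return fit_ols(y, env, subset, response=response)

    if start == "full" and direction != "forward":
        current_set: tuple = candidates
    elif start in {"empty", "null"} or direction == "forward":
        current_set = ()
    else:
        raise ValueError(f"unknown start {start!r}")
    current = fit(current_set)

    while True:
        moves: list[LinearModelFit] = []
        if direction in {"both", "backward"}:
            for term in current_set:
                subset = tuple(t for t in current_set if t != term)
                moves.append(fit(subset))
        if direction in {"both", "forward"}:
            for term in candidates:
                if term not in current_set:
                    moves.append(fit((*current_set, term)))
        if not moves:
            break
        # lowest AICc wins; ties favor fewer parameters
        best = min(moves, key=lambda f: (f.aicc, f.k))
        if best.aicc < current.aicc or (best.aicc == current.aicc and best.k < current.k):
            current, current_set = best, best.predictors
        else:
            break
    return current


def species_trait_response(
    ssm: SiteSpeciesMeans,
    env: EnvironmentTable,
    species: str,
    trait: str,
    predictor: str,
) -> SpeciesResponseFit | None:
    """Simple OLS of a species' site-specific trait means on one predictor.

    Returns None (with a warning) when the species has trait means in fewer
    than 3 sites.
    """
    sub = ssm.data[(ssm.data["species"] == species) & (ssm.data["trait"] == trait)]
    sub = sub.set_index("site")["mean"]
    sub = sub[sub.index.isin(env.sites)]
    if len(sub) < 3:
        logger.warning(
            "species %s / trait %s: only %d site(s); regression skipped",
            species,
            trait,
            len(sub),
        )
        return None
    x = env.transformed([predictor]).reindex(sub.index)[predictor].to_numpy()
    yv = sub.to_numpy(dtype=float)
    X = np.column_stack([np.ones(len(x)), x])
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    fitted = X @ beta
    ss_tot = float(((yv - yv.mean()) ** 2).sum())
    ss_exp = float(((fitted - fitted.mean()) ** 2).sum())
    return SpeciesResponseFit(
        species=species,
        trait=trait,
        predictor=predictor,
        slope=float(beta[1]),
        intercept=float(beta[0]),
        r_squared=ss_exp / ss_tot if ss_tot > 0 else float("nan"),
        n_sites=len(sub),
    )


def correlation_screen(
    env: EnvironmentTable, variables=None, threshold: float = 0.5
) -> list[tuple[str, str, float]]:
    """Report variable pairs whose |Pearson r| meets or exceeds ``threshold``.

    Nothing is dropped automatically; the caller decides which member of a
    violating pair to keep.
    """
    df = env.transformed(variables)
    corr = df.corr().to_numpy()
    cols = list(df.columns)
    out = []
    for i, j in itertools.combinations(range(len(cols)), 2):
        if abs(corr[i, j]) >= threshold:
            out.append((cols[i], cols[j], float(corr[i, j])))
    return out
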