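"""Pairwise between-site analyses: distance matrices, the per-pair
turnover/intraspecific decomposition, Mantel and partial Mantel permutation
tests, and equal-count distance-bin bootstrap summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .data_model import EnvironmentTable, SiteCoordinates, ValidationError

if TYPE_CHECKING:  # pragma: no cover
    from .cwm_decomposition import CWMTriple

logger = logging.getLogger("traitshift")

__all__ = [
    "EARTH_RADIUS_KM",
    "DistanceMatrix",
    "PairwiseDecomposition",
    "MantelResult",
    "great_circle_distance",
    "environmental_distance",
    "pairwise_decomposition",
    "mantel_test",
    "mantel_r",
    "partial_mantel_test",
    "partial_mantel_r",
    "distance_bin_summary",
    "equal_count_bins",
]

#: IUGG mean Earth radius, km
EARTH_RADIUS_KM = 6371.0088


@dataclass
class DistanceMatrix:
    """Symmetric site x site matrix with zero diagonal.

    ``signed=True`` matrices (trait log-ratios, covariation components) are
    exempt from the non-negativity check and may hold +/-inf sentinels.
    """

    sites: list
    values: np.ndarray
    kind: str = "generic"
    signed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sites)
        if v.shape != (n, n):
            raise ValidationError(f"distance matrix shape {v.shape} != ({n}, {n})")
        finite = np.isfinite(v)
        if not np.array_equal(v[finite], v.T[finite.T]):
            if not np.allclose(v, v.T, atol=1e-10, rtol=0, equal_nan=True):
                raise ValidationError("distance matrix is not symmetric")
        if not np.all((np.diag(v) == 0) | ~np.isfinite(np.diag(v))):
            if self.signed:
                pass  # log-ratio diagonals are undefined; forced to 0 below
            else:
                raise ValidationError("distance matrix diagonal must be zero")
        if not self.signed and (v[np.isfinite(v)] < 0).any():
            raise ValidationError("negative entries in unsigned distance matrix")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sites)

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in row-major (j > k) order."""
        il = np.tril_indices(self.n, k=-1)
        return self.values[il]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sites, columns=self.sites)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kind: str = "generic", signed=False):
        return cls(list(df.index), df.to_numpy(dtype=float), kind=kind, signed=signed)


def _check_alignment(*matrices: DistanceMatrix) -> None:
    first = matrices[0]
    for m in matrices[1:]:
        if m.n != first.n:
            raise ValidationError("distance matrices have different dimensions")
        if list(m.sites) != list(first.sites):
            raise ValidationError("distance matrices have mismatched site ordering")


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------


def great_circle_distance(coords: SiteCoordinates) -> DistanceMatrix:
    """Haversine great-circle distances in km (Earth radius 6371.0088 km)."""
    lat = np.radians(coords.data["lat"].to_numpy())
    lon = np.radians(coords.data["lon"].to_numpy())
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    a = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(coords.sites, d, kind="geographic_km")


def environmental_distance(env: EnvironmentTable, variables=None) -> DistanceMatrix:
    """Euclidean distance on z-scored (after any log transform) variables."""
    z = env.scaled(variables).to_numpy()
    diff = z[:, None, :] - z[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2))
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(env.sites, d, kind="environmental")


# ---------------------------------------------------------------------------
# Pairwise decomposition
# ---------------------------------------------------------------------------


@dataclass
class PairwiseDecomposition:
    """Per-pair CWM dissimilarity split into turnover, intraspecific, and
    covariation components, plus the log turnover/intraspecific ratio.

    ``d_total = d_turnover + d_intra + d_cov`` holds pair by pair;
    ``log_ratio`` is ``ln(d_turnover / d_intra)`` with +/-inf sentinels where
    a component is exactly zero.
    """

    trait: str
    sites: list
    d_total: DistanceMatrix
    d_turnover: DistanceMatrix
    d_intra: DistanceMatrix
    d_cov: DistanceMatrix
    log_ratio: DistanceMatrix
    n_nonfinite_log_ratio: int = 0

    def to_dataframe(self) -> pd.DataFrame:
        il = np.tril_indices(len(self.sites), k=-1)
        return pd.DataFrame(
            {
                "site_a": np.asarray(self.sites)[il[0]],
                "site_b": np.asarray(self.sites)[il[1]],
                "d_total": self.d_total.values[il],
                "d_turnover": self.d_turnover.values[il],
                "d_intra": self.d_intra.values[il],
                "d_cov": self.d_cov.values[il],
                "log_ratio": self.log_ratio.values[il],
            }
        )


def pairwise_decomposition(triple: "CWMTriple") -> PairwiseDecomposition:
    """Apply the sum-of-squares split to every site pair.

    For a pair (j, k): turnover = (inter_j - inter_k)^2, intraspecific =
    (intra_j - intra_k)^2, total = (total_j - total_k)^2, covariation =
    total - turnover - intraspecific = 2 * dinter * dintra.
    """
    df = triple.data
    if len(df) < 2:
        raise ValidationError("pairwise decomposition requires at least 2 sites")
    sites = list(df.index)

    def sq_diff(col):
        x = df[col].to_numpy()
        return (x[:, None] - x[None, :]) ** 2

    d_total = sq_diff("total")
    d_turn = sq_diff("inter")
    d_intra = sq_diff("intra")
    d_cov = d_total - d_turn - d_intra
    with np.errstate(divide="ignore", invalid="ignore"):
        log_ratio = np.log(d_turn) - np.log(d_intra)
    np.fill_diagonal(log_ratio, 0.0)
    il = np.tril_indices(len(sites), k=-1)
    n_bad = int((~np.isfinite(log_ratio[il])).sum())
    if n_bad:
        logger.warning(
            "pairwise_decomposition(%s): %d pair(s) with non-finite log-ratio "
            "(zero component); excluded from correlations",
            triple.trait,
            n_bad,
        )
    return PairwiseDecomposition(
        trait=triple.trait,
        sites=sites,
        d_total=DistanceMatrix(sites, d_total, kind="trait_component"),
        d_turnover=DistanceMatrix(sites, d_turn, kind="trait_component"),
        d_intra=DistanceMatrix(sites, d_intra, kind="trait_component"),
        d_cov=DistanceMatrix(sites, d_cov, kind="trait_component", signed=True),
        log_ratio=DistanceMatrix(sites, log_ratio, kind="trait_component", signed=True),
        n_nonfinite_log_ratio=n_bad,
    )


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------


@dataclass
class MantelResult:
    r: float
    p: float
    n_permutations: int
    tail: str
    partial: bool = False
    controlled_matrix: str | None = None
    seed: int | None = None
    n_pairs_used: int = 0

    def __str__(self) -> str:  # pragma: no cover
        label = "partial Mantel" if self.partial else "Mantel"
        return f"{label} r = {self.r:.3f}, p = {self.p:.4g} ({self.n_permutations} perms)"


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc**2).sum() * (yc**2).sum())
    if denom == 0:
        raise ValidationError("zero variance in distance-matrix entries")
    return float((xc * yc).sum() / denom)


def _tail_p(obs: float, perms: np.ndarray, tail: str) -> float:
    n = len(perms)
    if tail == "two-sided":
        count = int((np.abs(perms) >= abs(obs) - 1e-15).sum())
    elif tail == "greater":
        count = int((perms >= obs - 1e-15).sum())
    elif tail == "less":
        count = int((perms <= obs + 1e-15).sum())
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return (count + 1) / (n + 1)


def mantel_test(
    a: DistanceMatrix,
    b: DistanceMatrix,
    n_permutations: int = 9999,
    seed: int | None = None,
    tail: str = "two-sided",
) -> MantelResult:
    """Permutation test of the correlation between two distance matrices.

    The observed statistic is the Pearson correlation of lower-triangle
    entries; the null is built by simultaneously permuting rows and columns
    of ``b``.  Pairs with non-finite entries in either matrix (log-ratio
    sentinels) are excluded, with the finite mask re-derived per permutation.
    """
    _check_alignment(a, b)
    if n_permutations < 99:
        raise ValueError("n_permutations must be at least 99")
    n = a.n
    il = np.tril_indices(n, k=-1)
    av = a.values[il]
    bv = b.values[il]
    mask = np.isfinite(av) & np.isfinite(bv)
    if mask.sum() < 3:
        raise ValidationError("fewer than 3 finite pairs for Mantel correlation")
    if not mask.all():
        logger.warning("mantel_test: excluded %d non-finite pair(s)", int((~mask).sum()))
    r_obs = _pearson(av[mask], bv[mask])

    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    for i in range(n_permutations):
        p = rng.permutation(n)
        bp = b.values[np.ix_(p, p)][il]
        m = np.isfinite(av) & np.isfinite(bp)
        perms[i] = _pearson(av[m], bp[m])
    return MantelResult(
        r=r_obs,
        p=_tail_p(r_obs, perms, tail),
        n_permutations=n_permutations,
        tail=tail,
        seed=seed,
        n_pairs_used=int(mask.sum()),
    )


def mantel_r(a: DistanceMatrix, b: DistanceMatrix) -> float:
    """Observed Mantel correlation only (no permutation test)."""
    _check_alignment(a, b)
    il = np.tril_indices(a.n, k=-1)
    av, bv = a.values[il], b.values[il]
    mask = np.isfinite(av) & np.isfinite(bv)
    return _pearson(av[mask], bv[mask])


def partial_mantel_r(a: DistanceMatrix, b: DistanceMatrix, c: DistanceMatrix) -> float:
    """Observed partial Mantel correlation only (no permutation test).

    If the controlled matrix explains exactly one of ``a``/``b`` completely,
    the partial correlation is 0 by convention; if it explains both, the
    statistic is undefined and a :class:`ValidationError` is raised.
    """
    _check_alignment(a, b, c)
    il = np.tril_indices(a.n, k=-1)
    av, bv, cv = a.values[il], b.values[il], c.values[il]
    mask = np.isfinite(av) & np.isfinite(bv) & np.isfinite(cv)
    res_a = _residuals(av[mask], cv[mask])
    res_b = _residuals(bv[mask], cv[mask])
    if _check_partial_degeneracy(res_a, res_b, av[mask], bv[mask]):
        return 0.0
    return _pearson(res_a, res_b)


def _residuals(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return y - X @ beta


def _residual_is_null(res: np.ndarray, orig: np.ndarray) -> bool:
    """True when residual variance is zero up to numerical noise (the
    controlled matrix explains the input completely)."""
    return float(np.var(res)) <= 1e-20 * max(float(np.var(orig)), 1e-300)


def _check_partial_degeneracy(res_a, res_b, av, bv) -> bool:
    """Reject the fully-degenerate case; return True when exactly one
    residual series is null (partial r is then 0 by convention)."""
    null_a = _residual_is_null(res_a, av)
    null_b = _residual_is_null(res_b, bv)
    if null_a and null_b:
        raise ValidationError(
            "partial Mantel undefined: controlled matrix explains both inputs"
        )
    return null_a or null_b


def _null_partial_result(c, n_permutations, tail, seed, n_pairs) -> "MantelResult":
    return MantelResult(
        r=0.0,
        p=1.0,
        n_permutations=n_permutations,
        tail=tail,
        partial=True,
        controlled_matrix=c.kind,
        seed=seed,
        n_pairs_used=n_pairs,
    )


def partial_mantel_test(
    a: DistanceMatrix,
    b: DistanceMatrix,
    c: DistanceMatrix,
    n_permutations: int = 9999,
    seed: int | None = None,
    tail: str = "two-sided",
) -> MantelResult:
    """Correlation between ``a`` and ``b`` controlling for ``c``.

    Residuals of a ~ c and b ~ c (lower triangles) are correlated; the null
    permutes the residual matrix of b ~ c by rows and columns simultaneously
    (residual-permutation method).
    """
    _check_alignment(a, b, c)
    if n_permutations < 99:
        raise ValueError("n_permutations must be at least 99")
    n = a.n
    il = np.tril_indices(n, k=-1)
    av, bv, cv = a.values[il], b.values[il], c.values[il]
    mask = np.isfinite(av) & np.isfinite(bv) & np.isfinite(cv)
    if mask.sum() < 4:
        raise ValidationError("fewer than 4 finite pairs for partial Mantel")
    if not mask.all():
        logger.warning(
            "partial_mantel_test: excluded %d non-finite pair(s)", int((~mask).sum())
        )
        av, bv, cv = av[mask], bv[mask], cv[mask]
        res_a = _residuals(av, cv)
        res_b = _residuals(bv, cv)
        if _check_partial_degeneracy(res_a, res_b, av, bv):
            return _null_partial_result(c, n_permutations, tail, seed, int(mask.sum()))
        r_obs = _pearson(res_a, res_b)
        # with an irregular mask the residual matrix cannot be permuted as a
        # site-labelled matrix; fall back to permuting residual entries
        rng = np.random.default_rng(seed)
        perms = np.empty(n_permutations)
        for i in range(n_permutations):
            perms[i] = _pearson(res_a, rng.permutation(res_b))
        return MantelResult(
            r=r_obs,
            p=_tail_p(r_obs, perms, tail),
            n_permutations=n_permutations,
            tail=tail,
            partial=True,
            controlled_matrix=c.kind,
            seed=seed,
            n_pairs_used=int(mask.sum()),
        )

    res_a = _residuals(av, cv)
    res_b = _residuals(bv, cv)
    if _check_partial_degeneracy(res_a, res_b, av, bv):
        return _null_partial_result(c, n_permutations, tail, seed, len(av))
    r_obs = _pearson(res_a, res_b)

    # place b-residuals back into a symmetric matrix and permute site labels
    res_b_mat = np.zeros((n, n))
    res_b_mat[il] = res_b
    res_b_mat += res_b_mat.T
    rng = np.random.default_rng(seed)
    perms = np.empty(n_permutations)
    for i in range(n_permutations):
        p = rng.permutation(n)
        perms[i] = _pearson(res_a, res_b_mat[np.ix_(p, p)][il])
    return MantelResult(
        r=r_obs,
        p=_tail_p(r_obs, perms, tail),
        n_permutations=n_permutations,
        tail=tail,
        partial=True,
        controlled_matrix=c.kind,
        seed=seed,
        n_pairs_used=len(av),
    )


# ---------------------------------------------------------------------------
# Distance-binned bootstrap summaries
# ---------------------------------------------------------------------------


def equal_count_bins(distances: np.ndarray, n_bins: int) -> list[np.ndarray]:
    """Split pair indices into ``n_bins`` equal-count bins by distance.

    Pairs are sorted by distance (stable, index tie-break); remainder pairs
    go one each to the smallest-distance bins, so 231 pairs in 4 bins give
    sizes 58/58/58/57.
    """
    m = len(distances)
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if m < n_bins:
        raise ValidationError(f"{m} pairs cannot fill {n_bins} bins")
    order = np.argsort(distances, kind="stable")
    return [np.asarray(chunk) for chunk in np.array_split(order, n_bins)]


def distance_bin_summary(
    values: np.ndarray,
    dist: DistanceMatrix,
    n_bins: int = 4,
    n_bootstrap: int = 999,
    seed: int | None = None,
) -> pd.DataFrame:
    """Mean and percentile-bootstrap 95% CI of ``values`` per distance bin.

    ``values`` is a condensed (lower-triangle) vector aligned with ``dist``;
    non-finite values are dropped within bins (count reported).
    """
    d = dist.condensed()
    values = np.asarray(values, dtype=float)
    if values.shape != d.shape:
        raise ValidationError("values vector does not match number of pairs")
    bins = equal_count_bins(d, n_bins)
    rng = np.random.default_rng(seed)
    rows = []
    for i, idx in enumerate(bins):
        v = values[idx]
        finite = np.isfinite(v)
        n_dropped = int((~finite).sum())
        v = v[finite]
        if len(v) == 0:
            raise ValidationError(f"bin {i} has no finite values")
        boots = rng.choice(v, size=(n_bootstrap, len(v)), replace=True).mean(axis=1)
        lo, hi = np.percentile(boots, [2.5, 97.5])
        rows.append(
            {
                "bin": i,
                "n_pairs": len(idx),
                "n_dropped": n_dropped,
                "dist_min": float(d[idx].min()),
                "dist_max": float(d[idx].max()),
                "dist_mean": float(d[idx].mean()),
                "mean": float(v.mean()),
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return pd.DataFrame(rows)
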