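"""Community-weighted means and the turnover / intraspecific / covariation
sum-of-squares decomposition.

Three CWM variants are computed per site and trait:

* total ("specific") CWM — cover-weighted average of *site-specific*
  species mean trait values; varies with both species turnover and
  intraspecific shifts;
* interspecific ("fixed") CWM — cover-weighted average of one *global*
  mean per species; varies with turnover only;
* intraspecific CWM — total minus interspecific; varies with
  intraspecific shifts only.

Among-site (or model-explained) variation in the total CWM is then split
into a turnover component (SS of the interspecific CWM), an intraspecific
component (SS of the intraspecific CWM), and a covariation remainder.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import (
    CoverMatrix,
    EnvironmentTable,
    GlobalSpeciesMeans,
    SiteSpeciesMeans,
    ValidationError,
)
from .spatial_analysis import DistanceMatrix

logger = logging.getLogger("traitshift")

__all__ = [
    "CWMTriple",
    "DecompositionResult",
    "compute_cwms",
    "cwm_triples",
    "decompose_total_variation",
    "decompose_explained_variation",
    "single_predictor_partition_table",
    "bray_curtis_dissimilarity",
]


@dataclass
class CWMTriple:
    """Per-site total, interspecific, and intraspecific CWMs for one trait.

    Invariant: ``intra = total - inter`` exactly (intra is stored as that
    floating-point difference, never recomputed another way).
    """

    trait: str
    data: pd.DataFrame  # index site, columns total, inter, intra

    def __post_init__(self) -> None:
        need = {"total", "inter", "intra"}
        if not need.issubset(self.data.columns):
            raise ValidationError(f"CWMTriple needs columns {sorted(need)}")
        diff = self.data["total"] - self.data["inter"] - self.data["intra"]
        if (diff != 0).any():
            raise ValidationError("intra must equal total - inter exactly")

    @property
    def sites(self) -> list:
        return list(self.data.index)

    @property
    def n_sites(self) -> int:
        return len(self.data.index)

    @classmethod
    def from_components(cls, trait: str, inter, intra, sites=None) -> "CWMTriple":
        """Build a triple from interspecific and intraspecific series.

        The stored intra column is re-derived as ``total - inter`` so the
        exact-subtraction invariant holds bit-for-bit.
        """
        inter = np.asarray(inter, dtype=float)
        intra = np.asarray(intra, dtype=float)
        if sites is None:
            sites = [f"s{i}" for i in range(len(inter))]
        total = inter + intra
        df = pd.DataFrame({"total": total, "inter": inter}, index=list(sites))
        df["intra"] = df["total"] - df["inter"]
        return cls(trait=trait, data=df)


@dataclass
class DecompositionResult:
    """SS components of CWM variation and their percentages of the total.

    ``kind`` is ``total_variation`` for among-site variation or
    ``explained_variation`` for the part explained by an OLS model.  The
    covariation component is always the remainder, so the additivity
    identity ``ss_total = ss_turnover + ss_intra + ss_cov`` holds by
    construction.  ``degenerate`` flags ss_total == 0 (percentages NaN);
    ``negative_components`` flags negative explained-SS remainders.
    """

    trait: str
    kind: str
    n_sites: int
    ss_turnover: float
    ss_intra: float
    ss_cov: float
    ss_total: float
    pct_turnover: float
    pct_intra: float
    pct_cov: float
    predictors: tuple = ()
    r_squared: dict = field(default_factory=dict)
    degenerate: bool = False
    negative_components: bool = False

    def as_row(self) -> dict:
        row = {
            "trait": self.trait,
            "kind": self.kind,
            "predictors": "+".join(self.predictors),
            "n_sites": self.n_sites,
            "ss_turnover": self.ss_turnover,
            "ss_intra": self.ss_intra,
            "ss_cov": self.ss_cov,
            "ss_total": self.ss_total,
            "pct_turnover": self.pct_turnover,
            "pct_intra": self.pct_intra,
            "pct_cov": self.pct_cov,
        }
        for name, r2 in self.r_squared.items():
            row[f"r2_{name}"] = r2
        return row


def _make_result(trait, kind, n_sites, ss_turn, ss_intra, ss_total, **kw):
    ss_cov = ss_total - ss_turn - ss_intra
    degenerate = ss_total == 0
    if degenerate:
        logger.warning("decomposition for %s: zero total SS; percentages undefined", trait)
        pcts = (float("nan"),) * 3
    else:
        pcts = tuple(100.0 * s / ss_total for s in (ss_turn, ss_intra, ss_cov))
    return DecompositionResult(
        trait=trait,
        kind=kind,
        n_sites=n_sites,
        ss_turnover=ss_turn,
        ss_intra=ss_intra,
        ss_cov=ss_cov,
        ss_total=ss_total,
        pct_turnover=pcts[0],
        pct_intra=pcts[1],
        pct_cov=pcts[2],
        degenerate=degenerate,
        negative_components=bool(min(ss_turn, ss_intra, ss_total) < 0),
        **kw,
    )


# ---------------------------------------------------------------------------
# CWM computation
# ---------------------------------------------------------------------------


def compute_cwms(
    cover: CoverMatrix,
    ssm: SiteSpeciesMeans,
    gsm: GlobalSpeciesMeans,
    trait: str,
    gap_fill: bool = False,
) -> CWMTriple:
    """Compute the three CWM variants for one trait.

    Cover is renormalized per site over the species that have a trait mean
    there, so the CWMs are weighted averages over the trait-sampled subset.
    With ``gap_fill=True``, species present but unmeasured in a site use the
    global species mean for both the total and interspecific CWM instead of
    being dropped (this deflates the intraspecific component; off by
    default).  Sites with no usable species are excluded with a warning.
    """
    means = ssm.pivot(trait)
    global_means = gsm.series(trait)

    species = [s for s in cover.species if s in global_means.index]
    P = cover.data.reindex(columns=species, fill_value=0.0)
    X = means.reindex(index=P.index, columns=species)
    xi = global_means.reindex(species)

    if gap_fill:
        X = X.where(X.notna(), xi, axis=1)

    # numpy throughout so the total and interspecific sums share one
    # reduction path (keeps intra exactly zero when x_ij == x_i bitwise)
    Pv = P.to_numpy(dtype=float)
    Xv = X.to_numpy(dtype=float)
    xiv = xi.to_numpy(dtype=float)
    usable = np.isfinite(Xv) & (Pv > 0)
    Pu = np.where(usable, Pv, 0.0)
    weight = Pu.sum(axis=1)
    empty = weight == 0
    sites = P.index
    if empty.any():
        logger.warning(
            "sites with no trait-sampled species excluded: %s", list(sites[empty])
        )
        Pu, Xv, weight = Pu[~empty], Xv[~empty], weight[~empty]
        usable, sites = usable[~empty], sites[~empty]
    if not len(Pu):
        raise ValidationError("no site has any trait-sampled species with cover")

    Pn = Pu / weight[:, None]
    Xt = np.where(usable, Xv, 0.0)
    Xg = np.where(usable, np.broadcast_to(xiv, Xv.shape), 0.0)
    total = (Pn * Xt).sum(axis=1)
    inter = (Pn * Xg).sum(axis=1)
    df = pd.DataFrame({"total": total, "inter": inter}, index=sites)
    df["intra"] = df["total"] - df["inter"]
    return CWMTriple(trait=trait, data=df)


def cwm_triples(cover, trait_table, traits=None, gap_fill: bool = False) -> dict:
    """Convenience wrapper: trait records -> CWM triples for each trait."""
    from .data_model import global_species_means, site_species_means

    ssm = site_species_means(trait_table)
    gsm = global_species_means(ssm)
    names = list(traits) if traits is not None else ssm.traits
    return {t: compute_cwms(cover, ssm, gsm, t, gap_fill=gap_fill) for t in names}


# ---------------------------------------------------------------------------
# Decomposition of among-site variation
# ---------------------------------------------------------------------------


def _centered_ss(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    return float(((x - x.mean()) ** 2).sum())


def decompose_total_variation(triple: CWMTriple) -> DecompositionResult:
    """Split among-site SS of the total CWM into turnover, intraspecific,
    and covariation components (covariation as the remainder)."""
    if triple.n_sites < 2:
        raise ValidationError("decomposition requires at least 2 sites")
    df = triple.data
    return _make_result(
        triple.trait,
        "total_variation",
        triple.n_sites,
        _centered_ss(df["inter"]),
        _centered_ss(df["intra"]),
        _centered_ss(df["total"]),
    )


def _explained_ss(y: np.ndarray, X: np.ndarray) -> float:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    return _centered_ss(fitted)


def decompose_explained_variation(
    triple: CWMTriple,
    env: EnvironmentTable,
    predictors,
    allow_saturated: bool = False,
) -> DecompositionResult:
    """Split the model-explained SS of the total CWM into components.

    The same OLS predictor set is fitted to the total, interspecific, and
    intraspecific CWM series; each component is the regression (explained)
    SS of its fit, and covariation is the remainder
    ``explained_total - explained_inter - explained_intra`` (may be
    negative; flagged).  R-squared for the three fits is attached.
    """
    predictors = tuple(predictors)
    if not predictors:
        raise ValidationError("at least one predictor required")
    n = triple.n_sites
    if len(predictors) >= n - 1 and not allow_saturated:
        raise ValidationError(
            f"{len(predictors)} predictors with {n} sites: saturated model"
        )
    if len(predictors) > n - 1:
        raise ValidationError("more predictors than residual degrees of freedom")
    Xdf = env.transformed(predictors).reindex(triple.sites)
    if Xdf.isna().any().any():
        raise ValidationError("environment table missing values for CWM sites")
    X = np.column_stack([np.ones(n), Xdf.to_numpy()])

    df = triple.data
    ss, r2 = {}, {}
    for name in ("total", "inter", "intra"):
        y = df[name].to_numpy(dtype=float)
        ss[name] = _explained_ss(y, X)
        tot = _centered_ss(y)
        r2[name] = ss[name] / tot if tot > 0 else float("nan")

    result = _make_result(
        triple.trait,
        "explained_variation",
        n,
        ss["inter"],
        ss["intra"],
        ss["total"],
        predictors=predictors,
        r_squared=r2,
    )
    if result.ss_cov < 0:
        result.negative_components = True
    return result


def single_predictor_partition_table(
    triple: CWMTriple, env: EnvironmentTable, variables=None
) -> list[DecompositionResult]:
    """Run the explained-variation decomposition once per single variable."""
    variables = list(variables) if variables is not None else env.variables
    return [
        decompose_explained_variation(triple, env, [var]) for var in variables
    ]


# ---------------------------------------------------------------------------
# Compositional dissimilarity
# ---------------------------------------------------------------------------


def bray_curtis_dissimilarity(cover: CoverMatrix, binary: bool = False) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity between sites.

    BC(j, k) = sum|p_ij - p_ik| / sum(p_ij + p_ik).  With ``binary=True``
    covers are reduced to presence/absence first (Sorensen complement).
    """
    P = cover.values()
    if binary:
        P = (P > 0).astype(float)
    num = np.abs(P[:, None, :] - P[None, :, :]).sum(axis=2)
    den = (P[:, None, :] + P[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        bc = np.where(den > 0, num / den, 0.0)
    bc = (bc + bc.T) / 2.0
    np.fill_diagonal(bc, 0.0)
    return DistanceMatrix(cover.sites, bc, kind="bray_curtis")
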