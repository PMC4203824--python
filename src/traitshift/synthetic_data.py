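"""Synthetic metacommunities with known turnover and intraspecific structure.

Sites sit on a latitudinal transect.  A latent climatic axis ``g`` follows
latitude; a latent edaphic axis ``e`` is coupled to it with correlation
``rho_ge``.  Observed climatic variables (MAT, MAP) load on ``g`` and
observed edaphic variables (sand, pH, CEC, OM, N, P) load on ``e``, each
with variable-level noise.  Species have Gaussian abundance responses along
``g``; realized covers are Dirichlet draws around the expected composition.
Individual trait values follow per-species linear responses to the two
latent axes plus Gaussian individual noise, and trait sampling mimics the
field protocol: species are measured in decreasing-cover order until a
cumulative cover threshold is reached, a fixed number of individuals each.

Every generated dataset carries a :class:`SyntheticTruth` with the
generating parameters and the noiseless, all-species decomposition of CWM
variation, so pipeline estimates can be checked against ground truth.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cwm_decomposition import CWMTriple, decompose_total_variation
from .data_model import (
    CoverMatrix,
    EnvironmentTable,
    SiteCoordinates,
    TraitRecordTable,
)

logger = logging.getLogger("traitshift")

__all__ = [
    "TraitGenConfig",
    "GeneratorConfig",
    "SyntheticTruth",
    "SyntheticDataset",
    "generate_environment",
    "generate_communities",
    "generate_traits",
    "generate_dataset",
    "default_config",
    "pure_turnover_config",
    "pure_itv_config",
    "mixed_config",
    "edaphic_itv_config",
    "turnover_gradient_config",
]

CLIMATIC_VARIABLES = ("MAT", "MAP")
EDAPHIC_VARIABLES = ("sand", "pH", "CEC", "OM", "N", "P")

# variable = offset + loading * latent + N(0, noise_sd * |loading|)
_VARIABLE_SPECS = {
    "MAT": ("g", 12.0, -3.2),
    "MAP": ("g", 1050.0, 160.0),
    "sand": ("e", 55.0, -12.0),
    "pH": ("e", 6.1, 0.55),
    "CEC": ("e", 13.0, 3.5),
    "OM": ("e", 4.5, 1.3),
    "N": ("e", 22.0, 6.0),
    "P": ("e", 35.0, 9.0),
}


@dataclass
class TraitGenConfig:
    """Generating parameters for one trait.

    Individual value = beta0_i + b_climate_i * g_j + b_edaphic_i * e_j
    + N(0, sigma_ind^2), where beta0_i = beta0_mean
    + beta0_gradient_slope * mu_i + N(0, beta0_sd^2) ties the species
    baseline to its niche optimum (the turnover signal), and the slopes are
    drawn per species with a sign flip for ``sign_mix_fraction`` of species
    (idiosyncratic responses).
    """

    beta0_mean: float = 25.0
    beta0_sd: float = 3.0
    beta0_gradient_slope: float = 0.0
    slope_climate_mean: float = 0.0
    slope_climate_sd: float = 0.0
    slope_edaphic_mean: float = 0.0
    slope_edaphic_sd: float = 0.0
    sign_mix_fraction: float = 0.0
    sigma_ind: float = 1.0


@dataclass
class GeneratorConfig:
    n_sites: int = 22
    n_species_pool: int = 30
    lat_range: tuple = (33.5, 43.5)
    lon_center: float = -78.0
    lon_jitter_sd: float = 0.8
    rho_ge: float = 0.7
    env_noise_sd: float = 0.25
    niche_breadth_mean: float = 0.55
    niche_breadth_log_sd: float = 0.25
    abundance_log_sd: float = 0.4
    dirichlet_concentration: float = 120.0
    detection_limit: float = 1e-3
    cover_threshold: float = 0.8
    individuals_per_species: int = 5
    traits: dict = field(default_factory=lambda: {"sla": TraitGenConfig()})

    def __post_init__(self) -> None:
        if not 0 < self.cover_threshold <= 1:
            raise ValueError("cover_threshold must lie in (0, 1]")
        if not -1 <= self.rho_ge <= 1:
            raise ValueError("rho_ge must lie in [-1, 1]")
        for name, tc in self.traits.items():
            for f in ("beta0_sd", "slope_climate_sd", "slope_edaphic_sd", "sigma_ind"):
                if getattr(tc, f) < 0:
                    raise ValueError(f"trait {name!r}: {f} must be >= 0")


@dataclass
class SyntheticTruth:
    """Generating parameters plus the noiseless decomposition of CWM variation."""

    seed: int
    latent_climate: np.ndarray  # g_j per site
    latent_edaphic: np.ndarray  # e_j per site
    niche_optima: np.ndarray
    niche_breadths: np.ndarray
    baseline: dict  # trait -> beta0_i
    slope_climate: dict  # trait -> b_i
    slope_edaphic: dict  # trait -> b_i
    expected_cover: np.ndarray  # site x species expectation before Dirichlet noise
    expected_cwm: dict = field(default_factory=dict)  # trait -> CWMTriple
    truth_pct: dict = field(default_factory=dict)  # trait -> dict of pct_*

    def to_json(self, path) -> None:
        def convert(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, CWMTriple):
                return x.data.to_dict(orient="index")
            return x

        payload = {
            k: convert(v) if not isinstance(v, dict) else {kk: convert(vv) for kk, vv in v.items()}
            for k, v in dataclasses.asdict(self).items()
        }
        # asdict already converted nested dataclasses; re-serialize CWMTriples
        payload["expected_cwm"] = {
            t: trip.data.to_dict(orient="index") for t, trip in self.expected_cwm.items()
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2, default=lambda o: list(o) if hasattr(o, "__iter__") else float(o))


@dataclass
class SyntheticDataset:
    config: GeneratorConfig
    env: EnvironmentTable
    coords: SiteCoordinates
    cover: CoverMatrix
    traits: TraitRecordTable
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Generation stages
# ---------------------------------------------------------------------------


def _site_ids(n: int) -> list:
    return [f"site{str(i + 1).zfill(2)}" for i in range(n)]


def _species_ids(n: int) -> list:
    return [f"sp{str(i + 1).zfill(2)}" for i in range(n)]


def generate_environment(config: GeneratorConfig, rng: np.random.Generator):
    """Latent axes, observed environmental table, and site coordinates.

    Returns (env, coords, g, e).  ``g`` is a standardized climatic axis
    linear in latitude; ``e = rho_ge * g + sqrt(1 - rho_ge^2) * noise``.
    """
    n = config.n_sites
    sites = _site_ids(n)
    lat = np.linspace(*config.lat_range, n)
    lon = config.lon_center + rng.normal(0.0, config.lon_jitter_sd, n)
    g = (lat - lat.mean()) / lat.std(ddof=0)
    noise = rng.normal(0.0, 1.0, n)
    noise = (noise - noise.mean()) / noise.std(ddof=0)
    rho = config.rho_ge
    e = rho * g + np.sqrt(max(0.0, 1.0 - rho**2)) * noise

    data = {}
    for var, (axis, offset, loading) in _VARIABLE_SPECS.items():
        latent = g if axis == "g" else e
        meas = rng.normal(0.0, config.env_noise_sd * abs(loading), n)
        data[var] = offset + loading * latent + meas
    env = EnvironmentTable(pd.DataFrame(data, index=sites))
    coords = SiteCoordinates(pd.DataFrame({"lat": lat, "lon": lon}, index=sites))
    return env, coords, g, e


def generate_communities(
    config: GeneratorConfig, g: np.ndarray, rng: np.random.Generator
):
    """Gaussian-niche expected composition with Dirichlet abundance noise.

    Returns (cover, expected_cover, optima, breadths).  Expected cover of
    species i at site j is proportional to its Gaussian response
    exp(-(g_j - mu_i)^2 / (2 sigma_i^2)) times a lognormal species
    abundance multiplier; realized covers are Dirichlet draws with
    concentration ``dirichlet_concentration * expectation``, and covers
    below ``detection_limit`` are censored to zero before renormalization.
    """
    n_sites, n_sp = config.n_sites, config.n_species_pool
    lo, hi = g.min() - 0.3, g.max() + 0.3
    for _ in range(20):
        optima = rng.uniform(lo, hi, n_sp)
        breadths = np.exp(
            rng.normal(np.log(config.niche_breadth_mean), config.niche_breadth_log_sd, n_sp)
        )
        amplitude = np.exp(rng.normal(0.0, config.abundance_log_sd, n_sp))
        response = amplitude[None, :] * np.exp(
            -((g[:, None] - optima[None, :]) ** 2) / (2.0 * breadths[None, :] ** 2)
        )
        row_sums = response.sum(axis=1)
        if (row_sums > 1e-12).all():
            break
        logger.warning("site with all-zero expected cover; resampling niche optima")
    else:  # pragma: no cover
        raise RuntimeError("could not place niche optima covering all sites")

    expected = response / row_sums[:, None]
    alpha = np.maximum(config.dirichlet_concentration * expected, 1e-12)
    realized = np.vstack([rng.dirichlet(alpha[j]) for j in range(n_sites)])
    realized[realized < config.detection_limit] = 0.0
    realized /= realized.sum(axis=1, keepdims=True)
    cover = CoverMatrix(
        pd.DataFrame(realized, index=_site_ids(n_sites), columns=_species_ids(n_sp))
    )
    return cover, expected, optima, breadths


def _draw_trait_params(tc: TraitGenConfig, optima: np.ndarray, rng: np.random.Generator):
    n_sp = len(optima)
    beta0 = tc.beta0_mean + tc.beta0_gradient_slope * optima + rng.normal(0.0, tc.beta0_sd, n_sp)
    bc = rng.normal(tc.slope_climate_mean, tc.slope_climate_sd, n_sp)
    be = rng.normal(tc.slope_edaphic_mean, tc.slope_edaphic_sd, n_sp)
    if tc.sign_mix_fraction > 0:
        flip = rng.random(n_sp) < tc.sign_mix_fraction
        bc[flip] *= -1.0
        be[flip] *= -1.0
    return beta0, bc, be


def generate_traits(
    config: GeneratorConfig,
    g: np.ndarray,
    e: np.ndarray,
    cover: CoverMatrix,
    rng: np.random.Generator,
    niche_optima: np.ndarray | None = None,
):
    """Individual trait records for the cover-ranked sampled species.

    In each site, species are sampled in decreasing-cover order until their
    cumulative relative cover reaches ``cover_threshold``;
    ``individuals_per_species`` individuals are drawn per sampled
    species-site.  ``niche_optima`` feeds the baseline-optimum coupling
    (zeros when absent).  Non-positive draws are truncated to a small
    positive floor (the rate is logged and should stay below 1%).
    """
    sites, species = cover.sites, cover.species
    P = cover.values()
    if niche_optima is None:
        niche_optima = np.zeros(len(species))

    records = {"site": [], "species": [], "individual": [], "trait": [], "value": []}
    truth_beta0, truth_bc, truth_be = {}, {}, {}
    trait_params = {}
    for trait_name, tc in config.traits.items():
        beta0, bc, be = _draw_trait_params(tc, niche_optima, rng)
        trait_params[trait_name] = (tc, beta0, bc, be)
        truth_beta0[trait_name] = beta0
        truth_bc[trait_name] = bc
        truth_be[trait_name] = be

    n_ind = config.individuals_per_species
    n_truncated = n_total = 0
    for j, site in enumerate(sites):
        order = np.argsort(-P[j], kind="stable")
        cum = np.cumsum(P[j][order])
        n_keep = int(np.searchsorted(cum, config.cover_threshold - 1e-12) + 1)
        sampled = [i for i in order[:n_keep] if P[j][i] > 0]
        for i in sampled:
            for trait_name, (tc, beta0, bc, be) in trait_params.items():
                mean_ij = beta0[i] + bc[i] * g[j] + be[i] * e[j]
                if tc.sigma_ind > 0:
                    vals = mean_ij + rng.normal(0.0, tc.sigma_ind, n_ind)
                else:
                    vals = np.full(n_ind, mean_ij)
                n_total += n_ind
                bad = vals <= 0
                if bad.any():
                    n_truncated += int(bad.sum())
                    vals = np.where(bad, 1e-6, vals)
                records["site"].extend([site] * n_ind)
                records["species"].extend([species[i]] * n_ind)
                records["individual"].extend(range(1, n_ind + 1))
                records["trait"].extend([trait_name] * n_ind)
                records["value"].extend(vals.tolist())
    if n_total and n_truncated:
        rate = n_truncated / n_total
        logger.warning("truncated %d/%d (%.2f%%) non-positive trait draws", n_truncated, n_total, 100 * rate)
    table = TraitRecordTable(pd.DataFrame(records))
    return table, (truth_beta0, truth_bc, truth_be), n_truncated / max(n_total, 1)


def _expected_truth(
    config: GeneratorConfig,
    g: np.ndarray,
    e: np.ndarray,
    expected_cover: np.ndarray,
    beta0: dict,
    bc: dict,
    be: dict,
) -> tuple[dict, dict]:
    """Noiseless all-species CWM triple and decomposition percentages."""
    sites = _site_ids(config.n_sites)
    expected_cwm, truth_pct = {}, {}
    for trait_name in config.traits:
        X = beta0[trait_name][None, :] + np.outer(g, bc[trait_name]) + np.outer(e, be[trait_name])
        xi = X.mean(axis=0)  # unweighted mean over sites (all species everywhere)
        total = (expected_cover * X).sum(axis=1)
        inter = expected_cover @ xi
        df = pd.DataFrame({"total": total, "inter": inter}, index=sites)
        df["intra"] = df["total"] - df["inter"]
        triple = CWMTriple(trait=trait_name, data=df)
        expected_cwm[trait_name] = triple
        res = decompose_total_variation(triple)
        truth_pct[trait_name] = {
            "pct_turnover": res.pct_turnover,
            "pct_intra": res.pct_intra,
            "pct_cov": res.pct_cov,
        }
    return expected_cwm, truth_pct


def generate_dataset(config: GeneratorConfig, seed: int) -> SyntheticDataset:
    """Run all generation stages with a single seeded RNG stream."""
    rng = np.random.default_rng(seed)
    env, coords, g, e = generate_environment(config, rng)
    cover, expected, optima, breadths = generate_communities(config, g, rng)
    traits, (beta0, bc, be), _ = generate_traits(
        config, g, e, cover, rng, niche_optima=optima
    )
    expected_cwm, truth_pct = _expected_truth(config, g, e, expected, beta0, bc, be)
    truth = SyntheticTruth(
        seed=seed,
        latent_climate=g,
        latent_edaphic=e,
        niche_optima=optima,
        niche_breadths=breadths,
        baseline=beta0,
        slope_climate=bc,
        slope_edaphic=be,
        expected_cover=expected,
        expected_cwm=expected_cwm,
        truth_pct=truth_pct,
    )
    return SyntheticDataset(config=config, env=env, coords=coords, cover=cover, traits=traits, truth=truth)


# ---------------------------------------------------------------------------
# Scenario factories
# ---------------------------------------------------------------------------


def default_config(**overrides) -> GeneratorConfig:
    """Mixed turnover + ITV regime resembling the study system.

    Narrow niches and moderate Dirichlet concentration are calibrated to a
    mean pairwise Bray-Curtis dissimilarity near 0.75 and a geographic-
    environmental Mantel correlation in the 0.5-0.85 band.
    """
    traits = {
        "sla": TraitGenConfig(
            beta0_mean=22.0,
            beta0_sd=1.5,
            beta0_gradient_slope=4.0,
            slope_climate_mean=0.8,
            slope_climate_sd=0.5,
            slope_edaphic_mean=1.0,
            slope_edaphic_sd=0.5,
            sign_mix_fraction=0.25,
            sigma_ind=1.2,
        )
    }
    overrides.setdefault("n_species_pool", 60)
    overrides.setdefault("niche_breadth_mean", 0.35)
    overrides.setdefault("dirichlet_concentration", 60.0)
    overrides.setdefault("rho_ge", 0.8)
    overrides.setdefault("env_noise_sd", 0.2)
    return GeneratorConfig(traits=traits, **overrides)


def pure_turnover_config(**overrides) -> GeneratorConfig:
    """Species differ in baseline only; zero ITV and zero individual noise."""
    traits = {
        "sla": TraitGenConfig(
            beta0_mean=22.0,
            beta0_sd=2.0,
            beta0_gradient_slope=4.0,
            sigma_ind=0.0,
        )
    }
    return GeneratorConfig(traits=traits, **overrides)


def pure_itv_config(**overrides) -> GeneratorConfig:
    """Identical species baselines; all variation from intraspecific shifts.

    Niches are broad so every species occurs nearly everywhere and global
    species means coincide, keeping the turnover component near zero.
    """
    traits = {
        "sla": TraitGenConfig(
            beta0_mean=22.0,
            beta0_sd=0.0,
            beta0_gradient_slope=0.0,
            slope_climate_mean=2.5,
            slope_climate_sd=0.4,
            slope_edaphic_mean=0.0,
            slope_edaphic_sd=0.0,
            sigma_ind=0.3,
        )
    }
    overrides.setdefault("niche_breadth_mean", 6.0)
    overrides.setdefault("niche_breadth_log_sd", 0.05)
    return GeneratorConfig(traits=traits, **overrides)


def mixed_config(**overrides) -> GeneratorConfig:
    """Turnover-dominated regime with a ~25% intraspecific share.

    Turnover runs along the climatic niche axis via the baseline-optimum
    coupling; ITV responds to the *edaphic* axis with ``rho_ge = 0`` so the
    intraspecific signal is orthogonal to turnover (covariation ~ 0) and is
    not attenuated by range-restricted trait sampling.
    """
    traits = {
        "sla": TraitGenConfig(
            beta0_mean=22.0,
            beta0_sd=1.0,
            beta0_gradient_slope=3.0,
            slope_climate_mean=0.0,
            slope_climate_sd=0.0,
            slope_edaphic_mean=1.8,
            slope_edaphic_sd=0.25,
            sign_mix_fraction=0.0,
            sigma_ind=0.5,
        )
    }
    overrides.setdefault("rho_ge", 0.0)
    return GeneratorConfig(traits=traits, **overrides)


def edaphic_itv_config(**overrides) -> GeneratorConfig:
    """ITV responds only to the edaphic axis; turnover follows the climatic
    gradient through the baseline-optimum coupling."""
    traits = {
        "sla": TraitGenConfig(
            beta0_mean=22.0,
            beta0_sd=1.0,
            beta0_gradient_slope=3.5,
            slope_climate_mean=0.0,
            slope_climate_sd=0.0,
            slope_edaphic_mean=2.2,
            slope_edaphic_sd=0.4,
            sigma_ind=0.6,
        )
    }
    overrides.setdefault("rho_ge", 0.45)
    return GeneratorConfig(traits=traits, **overrides)


def turnover_gradient_config(**overrides) -> GeneratorConfig:
    """Strong turnover along the gradient; ITV is pure unstructured noise."""
    traits = {
        "sla": TraitGenConfig(
            beta0_mean=22.0,
            beta0_sd=1.0,
            beta0_gradient_slope=4.5,
            slope_climate_mean=0.0,
            slope_climate_sd=0.0,
            slope_edaphic_mean=0.0,
            slope_edaphic_sd=0.0,
            sigma_ind=0.8,
        )
    }
    return GeneratorConfig(traits=traits, **overrides)


SCENARIOS = {
    "default": default_config,
    "pure_turnover": pure_turnover_config,
    "pure_itv": pure_itv_config,
    "mixed": mixed_config,
    "edaphic_itv": edaphic_itv_config,
    "turnover_gradient": turnover_gradient_config,
}
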