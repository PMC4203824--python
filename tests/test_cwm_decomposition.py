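import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from traitshift import (
    CoverMatrix,
    CWMTriple,
    EnvironmentTable,
    TraitRecordTable,
    ValidationError,
    bray_curtis_dissimilarity,
    compute_cwms,
    decompose_explained_variation,
    decompose_total_variation,
    global_species_means,
    single_predictor_partition_table,
    site_species_means,
)


def _triple(inter, intra, trait="t"):
    return CWMTriple.from_components(trait, inter, intra)


def _tables(cover_body, site_means, global_means):
    """Build CoverMatrix / SiteSpeciesMeans / GlobalSpeciesMeans by hand."""
    sites = [f"s{i}" for i in range(len(cover_body))]
    species = [f"sp{i}" for i in range(len(cover_body[0]))]
    cov = CoverMatrix(pd.DataFrame(cover_body, index=sites, columns=species, dtype=float))
    rows = []
    for (site, sp), m in site_means.items():
        rows.append({"site": site, "species": sp, "trait": "t", "mean": m, "n_individuals": 1})
    from traitshift.data_model import GlobalSpeciesMeans, SiteSpeciesMeans

    ssm = SiteSpeciesMeans(pd.DataFrame(rows))
    gsm = GlobalSpeciesMeans(
        pd.DataFrame(
            [{"species": sp, "trait": "t", "mean": m} for sp, m in global_means.items()]
        )
    )
    return cov, ssm, gsm


class TestComputeCwms:
    def test_single_species(self):
        cov, ssm, gsm = _tables([[1.0]], {("s0", "sp0"): 10.0}, {"sp0": 8.0})
        triple = compute_cwms(cov, ssm, gsm, "t")
        row = triple.data.loc["s0"]
        assert row["total"] == 10.0 and row["inter"] == 8.0 and row["intra"] == 2.0

    def test_no_itv_limit(self):
        # x_ij == x_i everywhere -> intra exactly zero
        cov, ssm, gsm = _tables(
            [[0.6, 0.4], [0.3, 0.7]],
            {("s0", "sp0"): 5.0, ("s0", "sp1"): 9.0, ("s1", "sp0"): 5.0, ("s1", "sp1"): 9.0},
            {"sp0": 5.0, "sp1": 9.0},
        )
        triple = compute_cwms(cov, ssm, gsm, "t")
        assert (triple.data["intra"] == 0.0).all()

    def test_against_weighted_average_oracle(self):
        cover = [[0.5, 0.3, 0.2], [0.1, 0.8, 0.1], [0.25, 0.25, 0.5]]
        site_means = {
            (f"s{j}", f"sp{i}"): 10.0 + 3.0 * i + 0.7 * j for j in range(3) for i in range(3)
        }
        gmeans = {f"sp{i}": np.mean([site_means[(f"s{j}", f"sp{i}")] for j in range(3)]) for i in range(3)}
        cov, ssm, gsm = _tables(cover, site_means, gmeans)
        triple = compute_cwms(cov, ssm, gsm, "t")
        for j in range(3):
            total_oracle = sum(cover[j][i] * site_means[(f"s{j}", f"sp{i}")] for i in range(3))
            inter_oracle = sum(cover[j][i] * gmeans[f"sp{i}"] for i in range(3))
            assert triple.data.loc[f"s{j}", "total"] == pytest.approx(total_oracle, abs=1e-12)
            assert triple.data.loc[f"s{j}", "inter"] == pytest.approx(inter_oracle, abs=1e-12)

    def test_renormalizes_over_sampled_species(self):
        # sp1 has cover but no trait measurement in s0 -> dropped, p renormalized
        cov, ssm, gsm = _tables(
            [[0.5, 0.5]], {("s0", "sp0"): 10.0}, {"sp0": 8.0, "sp1": 99.0}
        )
        triple = compute_cwms(cov, ssm, gsm, "t")
        assert triple.data.loc["s0", "total"] == 10.0
        assert triple.data.loc["s0", "inter"] == 8.0

    def test_gap_fill_uses_global_mean(self):
        cov, ssm, gsm = _tables(
            [[0.5, 0.5]], {("s0", "sp0"): 10.0}, {"sp0": 8.0, "sp1": 20.0}
        )
        triple = compute_cwms(cov, ssm, gsm, "t", gap_fill=True)
        assert triple.data.loc["s0", "total"] == pytest.approx(0.5 * 10 + 0.5 * 20)
        assert triple.data.loc["s0", "inter"] == pytest.approx(0.5 * 8 + 0.5 * 20)

    def test_site_without_sampled_species_excluded(self):
        cov, ssm, gsm = _tables(
            [[1.0, 0.0], [0.0, 1.0]], {("s0", "sp0"): 10.0}, {"sp0": 10.0}
        )
        triple = compute_cwms(cov, ssm, gsm, "t")
        assert triple.sites == ["s0"]


class TestDecomposeTotalVariation:
    def test_constant_intra_pure_turnover(self):
        res = decompose_total_variation(_triple([1.0, 2.0, 5.0], [3.0, 3.0, 3.0]))
        assert res.pct_turnover == pytest.approx(100.0, abs=1e-9)
        assert res.pct_intra == 0.0
        assert res.pct_cov == pytest.approx(0.0, abs=1e-9)

    def test_zero_intra_exact_limit(self):
        res = decompose_total_variation(_triple([1.0, 2.0, 5.0], [0.0, 0.0, 0.0]))
        assert res.pct_turnover == 100.0
        assert res.pct_intra == 0.0 and res.pct_cov == 0.0

    def test_constant_inter_pure_itv(self):
        res = decompose_total_variation(_triple([4.0, 4.0, 4.0], [1.0, 2.0, 7.0]))
        assert res.pct_turnover == 0.0 and res.pct_intra == 100.0 and res.pct_cov == 0.0

    def test_identical_composition_zero_turnover(self):
        # all cover columns equal across sites, varying x_ij
        cov, ssm, gsm = _tables(
            [[0.5, 0.5], [0.5, 0.5], [0.5, 0.5]],
            {(f"s{j}", f"sp{i}"): 10.0 + i + 2.0 * j for j in range(3) for i in range(2)},
            {"sp0": 12.0, "sp1": 13.0},
        )
        triple = compute_cwms(cov, ssm, gsm, "t")
        res = decompose_total_variation(triple)
        assert res.pct_turnover == pytest.approx(0.0, abs=1e-10)

    def test_direct_arithmetic_oracle(self):
        # inter = intra = (1,2,3): SS_turn = SS_intra = 2, SS_total = 8, cov = 4
        res = decompose_total_variation(_triple([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert res.ss_turnover == pytest.approx(2.0)
        assert res.ss_intra == pytest.approx(2.0)
        assert res.ss_cov == pytest.approx(4.0)
        assert res.ss_total == pytest.approx(8.0)
        assert (res.pct_turnover, res.pct_intra, res.pct_cov) == pytest.approx((25, 25, 50))

    def test_cov_equals_cross_product_oracle(self):
        rng = np.random.default_rng(3)
        inter, intra = rng.normal(size=12), rng.normal(size=12)
        res = decompose_total_variation(_triple(inter, intra))
        cross = 2.0 * np.sum((inter - inter.mean()) * (intra - intra.mean()))
        assert res.ss_cov == pytest.approx(cross, rel=1e-9, abs=1e-12)

    def test_single_site_error(self):
        with pytest.raises(ValidationError, match="2 sites"):
            decompose_total_variation(_triple([1.0], [1.0]))

    def test_zero_total_flagged(self):
        res = decompose_total_variation(_triple([1.0, 1.0], [2.0, 2.0]))
        assert res.degenerate
        assert np.isnan(res.pct_turnover)

    # ---- invariants (property-based) ----

    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=30),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=60, deadline=None)
    def test_additivity_property(self, inter, seed):
        intra = np.random.default_rng(seed).normal(size=len(inter)) * 10
        res = decompose_total_variation(_triple(np.array(inter), intra))
        lhs = res.ss_total
        rhs = res.ss_turnover + res.ss_intra + res.ss_cov
        assert lhs == pytest.approx(rhs, rel=1e-8, abs=1e-8)
        if not res.degenerate:
            assert res.pct_turnover + res.pct_intra + res.pct_cov == pytest.approx(
                100.0, abs=1e-6
            )

    @given(st.floats(0.1, 50.0), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_scale_equivariance(self, c, seed):
        rng = np.random.default_rng(seed)
        inter, intra = rng.normal(size=8), rng.normal(size=8)
        base = decompose_total_variation(_triple(inter, intra))
        scaled = decompose_total_variation(_triple(c * inter, c * intra))
        assert scaled.ss_total == pytest.approx(c**2 * base.ss_total, rel=1e-9)
        assert scaled.pct_turnover == pytest.approx(base.pct_turnover, rel=1e-6, abs=1e-9)
        assert scaled.pct_intra == pytest.approx(base.pct_intra, rel=1e-6, abs=1e-9)

    @given(st.floats(-100.0, 100.0), st.integers(0, 2**31 - 1))
    @settings(max_examples=40, deadline=None)
    def test_translation_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        inter, intra = rng.normal(size=8), rng.normal(size=8)
        base = decompose_total_variation(_triple(inter, intra))
        shifted = decompose_total_variation(_triple(inter + shift, intra))
        assert shifted.ss_turnover == pytest.approx(base.ss_turnover, rel=1e-7, abs=1e-9)
        assert shifted.ss_total == pytest.approx(base.ss_total, rel=1e-7, abs=1e-9)


def _env_from(df: pd.DataFrame) -> EnvironmentTable:
    return EnvironmentTable(df)


class TestDecomposeExplainedVariation:
    def _fixture(self, seed=0, n=12):
        rng = np.random.default_rng(seed)
        sites = [f"s{i}" for i in range(n)]
        env = _env_from(
            pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)}, index=sites)
        )
        inter = rng.normal(size=n)
        intra = rng.normal(size=n)
        return CWMTriple.from_components("t", inter, intra, sites=sites), env

    def test_orthogonal_env_explains_nothing(self):
        n = 8
        sites = [f"s{i}" for i in range(n)]
        x = np.array([1.0, -1.0] * 4)  # orthogonal to the site-index trend below
        env = _env_from(pd.DataFrame({"a": x}, index=sites))
        inter = np.arange(n, dtype=float)
        inter -= inter.mean()
        # make response exactly orthogonal to x
        inter -= (inter @ x) / (x @ x) * x
        triple = CWMTriple.from_components("t", inter, np.zeros(n), sites=sites)
        res = decompose_explained_variation(triple, env, ["a"])
        assert res.ss_total == pytest.approx(0.0, abs=1e-18)

    def test_zero_intra_identity(self):
        triple, env = self._fixture()
        zero = CWMTriple.from_components(
            "t", triple.data["inter"].to_numpy(), np.zeros(triple.n_sites), sites=triple.sites
        )
        res = decompose_explained_variation(zero, env, ["a", "b"])
        assert res.ss_turnover == pytest.approx(res.ss_total, rel=1e-12)
        assert res.ss_intra == 0.0
        assert res.ss_cov == pytest.approx(0.0, abs=1e-12)

    def test_single_predictor_closed_form(self):
        # explained SS of simple regression = r^2 * SS_y (closed-form oracle)
        triple, env = self._fixture(seed=4)
        y = triple.data["total"].to_numpy()
        x = env.data["a"].to_numpy()
        r = np.corrcoef(x, y)[0, 1]
        ss_y = ((y - y.mean()) ** 2).sum()
        res = decompose_explained_variation(triple, env, ["a"])
        ss_exp_oracle = r**2 * ss_y
        assert res.ss_total == pytest.approx(ss_exp_oracle, rel=1e-10)
        assert res.r_squared["total"] == pytest.approx(r**2, rel=1e-10)

    def test_saturated_model_rejected(self):
        n = 4
        sites = [f"s{i}" for i in range(n)]
        rng = np.random.default_rng(0)
        env = _env_from(
            pd.DataFrame(rng.normal(size=(n, 3)), index=sites, columns=["a", "b", "c"])
        )
        triple = CWMTriple.from_components(
            "t", rng.normal(size=n), rng.normal(size=n), sites=sites
        )
        with pytest.raises(ValidationError, match="saturated"):
            decompose_explained_variation(triple, env, ["a", "b", "c"])

    def test_full_indicator_basis_reproduces_total(self):
        # saturated site-indicator design -> explained == total variation
        triple, _ = self._fixture(seed=7, n=6)
        n = triple.n_sites
        dummies = pd.DataFrame(
            np.eye(n)[:, :-1], index=triple.sites, columns=[f"d{i}" for i in range(n - 1)]
        )
        env = _env_from(dummies)
        res = decompose_explained_variation(
            triple, env, list(dummies.columns), allow_saturated=True
        )
        ref = decompose_total_variation(triple)
        assert res.ss_total == pytest.approx(ref.ss_total, rel=1e-9)
        assert res.ss_turnover == pytest.approx(ref.ss_turnover, rel=1e-9)
        assert res.ss_intra == pytest.approx(ref.ss_intra, rel=1e-9)


class TestSinglePredictorPartition:
    def test_eight_variable_structure(self, env8):
        rng = np.random.default_rng(1)
        triple = CWMTriple.from_components(
            "t", rng.normal(size=6), rng.normal(size=6), sites=env8.sites
        )
        results = single_predictor_partition_table(triple, env8)
        assert len(results) == 8
        for res in results:
            assert len(res.predictors) == 1
            assert res.ss_total == pytest.approx(
                res.ss_turnover + res.ss_intra + res.ss_cov, rel=1e-8
            )

    def test_self_predictor_perfect_fit(self):
        rng = np.random.default_rng(2)
        n = 9
        sites = [f"s{i}" for i in range(n)]
        total = rng.normal(size=n)
        triple = CWMTriple.from_components("t", total, np.zeros(n), sites=sites)
        env = _env_from(pd.DataFrame({"self": triple.data["total"]}, index=sites))
        res = decompose_explained_variation(triple, env, ["self"])
        ref = decompose_total_variation(triple)
        assert res.ss_total == pytest.approx(ref.ss_total, rel=1e-10)
        assert res.r_squared["total"] == pytest.approx(1.0, rel=1e-12)


class TestBrayCurtis:
    def test_identical_sites_zero(self):
        cov = CoverMatrix(
            pd.DataFrame([[0.5, 0.5], [0.5, 0.5]], index=["a", "b"], columns=["x", "y"])
        )
        assert bray_curtis_dissimilarity(cov).values[0, 1] == 0.0

    def test_disjoint_sites_one(self):
        cov = CoverMatrix(
            pd.DataFrame([[1.0, 0.0], [0.0, 1.0]], index=["a", "b"], columns=["x", "y"])
        )
        assert bray_curtis_dissimilarity(cov).values[0, 1] == 1.0

    def test_hand_arithmetic(self):
        cov = CoverMatrix(
            pd.DataFrame(
                [[0.5, 0.5, 0.0], [0.0, 0.5, 0.5]], index=["a", "b"], columns=list("xyz")
            )
        )
        assert bray_curtis_dissimilarity(cov).values[0, 1] == pytest.approx(0.5)

    @pytest.mark.parametrize("binary", [False, True])
    def test_matches_scipy_oracle(self, small_cover, binary):
        ours = bray_curtis_dissimilarity(small_cover, binary=binary).values
        P = small_cover.values()
        if binary:
            P = (P > 0).astype(float)
        ref = squareform(pdist(P, metric="braycurtis"))
        np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_binary_equals_sorensen_complement(self, small_cover):
        # Sorensen similarity = 2a / (2a + b + c) on presence/absence
        P = (small_cover.values() > 0).astype(int)
        ours = bray_curtis_dissimilarity(small_cover, binary=True).values
        for j in range(len(P)):
            for k in range(j):
                a = int(((P[j] == 1) & (P[k] == 1)).sum())
                b = int(((P[j] == 1) & (P[k] == 0)).sum())
                c = int(((P[j] == 0) & (P[k] == 1)).sum())
                sorensen = 2 * a / (2 * a + b + c)
                assert ours[j, k] == pytest.approx(1.0 - sorensen)


class TestPipelineIntegration:
    def test_cwms_from_raw_tables(self, small_cover, small_traits):
        ssm = site_species_means(small_traits)
        gsm = global_species_means(ssm)
        triple = compute_cwms(small_cover, ssm, gsm, "height")
        # s3 has cover only for spB/spC/spD but traits only exist for spA/spB
        assert set(triple.sites) <= set(small_cover.sites)
        assert (triple.data["total"] > 0).all()
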