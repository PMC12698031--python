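import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import _oracles as oracles
from fdassembly.core_data import CommunityMatrix, TraitTable, ValidationError, default_codebook
from fdassembly.diversity_metrics import (
    FD_METRICS,
    MetricEngine,
    R_FEW_POINTS,
    community_weighted_means,
    fd_profile,
    functional_dispersion,
    functional_divergence,
    functional_evenness,
    functional_redundancy,
    functional_richness,
    rao_quadratic_entropy,
    simpson_diversity,
    species_richness,
)
from fdassembly.trait_space import gower_dissimilarity, pcoa_embed

from conftest import random_trait_frame

CB = default_codebook()


def random_weights(rng, s):
    return rng.dirichlet(np.ones(s))


class TestRichnessAndSimpson:
    def test_richness_examples(self):
        assert species_richness(np.array([1, 0, 1, 1])) == 3
        assert species_richness(np.zeros(4)) == 0
        assert species_richness(np.array([0.2, 0, 5])) == 2

    def test_simpson_examples(self):
        assert simpson_diversity([1.0]) == pytest.approx(0.0)
        assert simpson_diversity([0.5, 0.5]) == pytest.approx(0.5)
        assert simpson_diversity([0.5, 0.3, 0.2]) == pytest.approx(0.62)

    def test_simpson_empty_errors(self):
        with pytest.raises(ValidationError):
            simpson_diversity([])


class TestRaoQ:
    def test_monoculture_is_zero(self):
        assert rao_quadratic_entropy(np.zeros((1, 1)), [1.0]) == 0.0

    def test_two_species_max_dissimilarity(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert rao_quadratic_entropy(d, [0.5, 0.5]) == pytest.approx(0.5)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            s = 6
            d = rng.random((s, s))
            d = (d + d.T) / 2
            np.fill_diagonal(d, 0.0)
            p = random_weights(rng, s)
            assert rao_quadratic_entropy(d, p) == pytest.approx(
                oracles.rao_brute(d, p), abs=1e-12)

    def test_d2half_convention(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert rao_quadratic_entropy(d, [0.5, 0.5], "d2half") == pytest.approx(0.25)

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            rao_quadratic_entropy(np.zeros((2, 2)), [1.0])


class TestFRed:
    def test_examples(self):
        assert functional_redundancy(0.0, 0.5) == pytest.approx(1.0)
        assert functional_redundancy(0.5, 0.5) == pytest.approx(0.0)
        assert functional_redundancy(0.25, 0.5) == pytest.approx(0.5)

    def test_monoculture_is_nan(self):
        assert np.isnan(functional_redundancy(0.0, 0.0))

    def test_corrupt_inputs_error(self):
        with pytest.raises(ValidationError, match="exceeds"):
            functional_redundancy(0.7, 0.5)

    def test_saturated_dissimilarity_gives_zero_redundancy(self):
        # d_ij = 1 for all i != j  =>  Q = 1 - sum p^2 = D exactly
        rng = np.random.default_rng(1)
        for s in (2, 4, 6):
            d = 1.0 - np.eye(s)
            p = random_weights(rng, s)
            q = rao_quadratic_entropy(d, p)
            ds = simpson_diversity(p)
            assert q == pytest.approx(ds, abs=1e-12)
            assert functional_redundancy(q, ds) == pytest.approx(0.0, abs=1e-9)


class TestFRic:
    def test_triangle_area(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        assert functional_richness(pts) == pytest.approx(0.5)

    def test_interior_point_does_not_change_volume(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.25, 0.25]])
        assert functional_richness(pts) == pytest.approx(0.5)

    def test_collinear_points_are_nan(self):
        pts = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        assert np.isnan(functional_richness(pts))

    def test_too_few_unique_points_nan(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 0.0]])
        assert np.isnan(functional_richness(pts))

    def test_one_dimensional_range(self):
        pts = np.array([[0.2], [1.4], [0.9]])
        assert functional_richness(pts) == pytest.approx(1.2)

    def test_monotone_under_species_addition(self):
        rng = np.random.default_rng(4)
        pts = rng.random((6, 2))
        base = functional_richness(pts)
        for _ in range(20):
            extra = np.vstack([pts, rng.random((1, 2))])
            assert functional_richness(extra) >= base - 1e-12


class TestFEve:
    def test_equilateral_triangle_equal_weights(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, np.sqrt(3) / 2]])
        assert functional_evenness(pts, np.full(3, 1 / 3)) == pytest.approx(1.0)

    def test_two_species_is_nan(self):
        assert np.isnan(functional_evenness(np.array([[0.0], [1.0]]), [0.5, 0.5]))

    def test_skewed_weights_on_line_matches_brute_force(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [2.5, 0.0], [7.0, 0.0]])
        p = np.array([0.6, 0.2, 0.15, 0.05])
        assert functional_evenness(pts, p) == pytest.approx(
            oracles.feve_brute(pts, p), abs=1e-12)


class TestFDiv:
    def test_square_corners_equal_weights(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        assert functional_divergence(pts, np.full(4, 0.25)) == pytest.approx(1.0)

    def test_equidistant_from_centroid(self):
        ang = np.linspace(0, 2 * np.pi, 5, endpoint=False)
        pts = np.c_[np.cos(ang), np.sin(ang)]
        p = random_weights(np.random.default_rng(0), 5)
        assert functional_divergence(pts, p) == pytest.approx(1.0)

    def test_asymmetric_cloud_matches_brute_force(self):
        rng = np.random.default_rng(9)
        pts = rng.random((5, 2))
        p = random_weights(rng, 5)
        assert functional_divergence(pts, p) == pytest.approx(
            oracles.fdiv_brute(pts, p), abs=1e-10)


class TestFDis:
    def test_monoculture_is_zero(self):
        assert functional_dispersion(np.array([[0.3, 0.4]]), [1.0]) == 0.0

    def test_two_point_example(self):
        pts = np.array([[0.0, 0.0], [1.0, 0.0]])
        assert functional_dispersion(pts, [0.5, 0.5]) == pytest.approx(0.5)

    def test_weighted_case_matches_brute_force(self):
        rng = np.random.default_rng(2)
        pts = rng.random((4, 3))
        p = random_weights(rng, 4)
        assert functional_dispersion(pts, p) == pytest.approx(
            oracles.fdis_brute(pts, p), abs=1e-12)


class TestCWM:
    def test_all_pelagic(self, codebook):
        traits = TraitTable(pd.DataFrame({
            "size_class": ["<200", ">600"],
            "feeding_type": ["microphagous", "D_filtration"],
            "trophic_group": ["herbivorous", "herbivorous"],
            "habitat": ["pelagic", "pelagic"],
        }, index=["a", "b"]), codebook)
        m = CommunityMatrix(pd.DataFrame([[2.0, 3.0]], index=["s"],
                                         columns=["a", "b"]), mode="biomass")
        cwm = community_weighted_means(m, traits).set_index("category")
        assert cwm.loc["pelagic", "cwm"] == pytest.approx(1.0)
        assert cwm.loc["littoral", "cwm"] == pytest.approx(0.0)

    def test_biomass_weighting(self, codebook):
        traits = TraitTable(pd.DataFrame({
            "size_class": ["<200", ">600", ">600"],
            "feeding_type": ["microphagous", "D_filtration", "D_filtration"],
            "trophic_group": ["herbivorous"] * 3,
            "habitat": ["littoral", "pelagic", "pelagic"],
        }, index=["a", "b", "c"]), codebook)
        m = CommunityMatrix(pd.DataFrame([[10.0, 30.0, 60.0]], index=["s"],
                                         columns=["a", "b", "c"]), mode="biomass")
        cwm = community_weighted_means(m, traits).set_index("category")
        assert cwm.loc["pelagic", "cwm"] == pytest.approx(0.9)

    def test_categories_partition_each_trait(self, codebook):
        rng = np.random.default_rng(8)
        traits = TraitTable(random_trait_frame(rng, 10, codebook), codebook)
        vals = rng.gamma(1.0, 3.0, size=(6, 10)) * (rng.random((6, 10)) < 0.7)
        vals[vals.sum(axis=1) == 0, 0] = 1.0
        m = CommunityMatrix(pd.DataFrame(vals, columns=traits.species_ids),
                            mode="biomass")
        cwm = community_weighted_means(m, traits)
        sums = cwm.groupby(["sample_id", "trait"])["cwm"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_missing_trait_species_errors(self, codebook):
        traits = TraitTable(pd.DataFrame({
            "size_class": ["<200"], "feeding_type": ["microphagous"],
            "trophic_group": ["herbivorous"], "habitat": ["pelagic"],
        }, index=["a"]), codebook)
        m = CommunityMatrix(pd.DataFrame([[1.0, 1.0]], columns=["a", "b"]),
                            mode="biomass")
        with pytest.raises(ValidationError, match="b"):
            community_weighted_means(m, traits)


@pytest.fixture
def small_engine():
    rng = np.random.default_rng(42)
    traits = TraitTable(random_trait_frame(rng, 12, CB), CB)
    d = gower_dissimilarity(traits)
    space = pcoa_embed(d)
    return MetricEngine(d, space, 2, traits=traits), traits


class TestFdProfile:
    def test_three_sample_toy(self, small_engine):
        engine, traits = small_engine
        rng = np.random.default_rng(1)
        vals = (rng.random((3, 12)) < 0.6).astype(float)
        vals[vals.sum(axis=1) == 0, 0] = 1
        m = CommunityMatrix(pd.DataFrame(vals, index=["s1", "s2", "s3"],
                                         columns=traits.species_ids),
                            mode="incidence")
        profile = fd_profile(m, engine)
        assert len(profile) == 3
        assert set(profile["basis"]) == {"incidence"}

    def test_monoculture_cascade(self, small_engine):
        engine, traits = small_engine
        vals = np.zeros((1, 12))
        vals[0, 3] = 1.0
        m = CommunityMatrix(pd.DataFrame(vals, index=["s"],
                                         columns=traits.species_ids),
                            mode="incidence")
        row = fd_profile(m, engine).iloc[0]
        assert row["S"] == 1
        assert np.isnan(row["FRic"]) and np.isnan(row["FEve"]) and np.isnan(row["FDiv"])
        assert row["FDis"] == 0.0 and row["RaoQ"] == 0.0
        assert np.isnan(row["FRed"])
        assert row["reason_FRic"] == R_FEW_POINTS

    def test_fd_composite_identity(self, small_engine):
        engine, traits = small_engine
        rng = np.random.default_rng(3)
        vals = rng.gamma(1.0, 4.0, size=(5, 12)) * (rng.random((5, 12)) < 0.6)
        vals[vals.sum(axis=1) == 0, 0] = 1.0
        m = CommunityMatrix(pd.DataFrame(vals, columns=traits.species_ids),
                            mode="biomass")
        profile = fd_profile(m, engine)
        np.testing.assert_allclose(profile["FD"], (profile["FDis"] + profile["RaoQ"]) / 2)

    def test_fred_identity_and_rao_bounded_by_simpson(self, small_engine):
        engine, traits = small_engine
        rng = np.random.default_rng(5)
        vals = rng.gamma(1.0, 4.0, size=(10, 12)) * (rng.random((10, 12)) < 0.7)
        vals[vals.sum(axis=1) == 0, 0] = 1.0
        m = CommunityMatrix(pd.DataFrame(vals, columns=traits.species_ids),
                            mode="biomass")
        profile = fd_profile(m, engine)
        ok = profile["D"] > 0
        assert (profile.loc[ok, "RaoQ"] <= profile.loc[ok, "D"] + 1e-12).all()
        np.testing.assert_allclose(
            profile.loc[ok, "FRed"], 1 - profile.loc[ok, "RaoQ"] / profile.loc[ok, "D"])


class TestEngineInvariances:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=5000))
    def test_feve_fdiv_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        s = int(rng.integers(3, 9))
        pts = rng.random((s, 2))
        p = random_weights(rng, s)
        fe = functional_evenness(pts, p)
        fv = functional_divergence(pts, p)
        if not np.isnan(fe):
            assert -1e-10 <= fe <= 1 + 1e-10
        if not np.isnan(fv):
            assert -1e-10 <= fv <= 1 + 1e-10

    def test_column_order_invariance(self, small_engine):
        engine, traits = small_engine
        rng = np.random.default_rng(7)
        vals = rng.gamma(1.0, 4.0, size=(4, 12)) * (rng.random((4, 12)) < 0.7)
        vals[vals.sum(axis=1) == 0, 0] = 1.0
        df = pd.DataFrame(vals, columns=traits.species_ids)
        m1 = CommunityMatrix(df, mode="biomass")
        perm = list(rng.permutation(traits.species_ids))
        m2 = CommunityMatrix(df[perm], mode="biomass")
        p1 = fd_profile(m1, engine).drop(columns=["sample_id"])
        p2 = fd_profile(m2, engine).drop(columns=["sample_id"])
        pd.testing.assert_frame_equal(p1, p2)

    def test_uniform_row_scaling_invariance(self, small_engine):
        engine, traits = small_engine
        rng = np.random.default_rng(8)
        vals = rng.gamma(1.0, 4.0, size=(4, 12)) * (rng.random((4, 12)) < 0.7)
        vals[vals.sum(axis=1) == 0, 0] = 1.0
        m1 = CommunityMatrix(pd.DataFrame(vals, columns=traits.species_ids),
                             mode="biomass")
        m2 = CommunityMatrix(pd.DataFrame(vals * 37.5, columns=traits.species_ids),
                             mode="biomass")
        p1 = fd_profile(m1, engine)
        p2 = fd_profile(m2, engine)
        pd.testing.assert_frame_equal(p1, p2)
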