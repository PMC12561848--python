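import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gxekit import GGEBiplot, fit_gge, rank_k_interaction


def rank2_matrix(g, e, seed, row_effects=True):
    """Random g x e matrix whose environment-centered part has rank <= 2."""
    rng = np.random.default_rng(seed)
    rows = rng.normal(0, 3, g) if row_effects else np.zeros(g)
    m = rows[:, None] + rank_k_interaction(g, e, rng.uniform(1, 4, 1))
    return pd.DataFrame(m + rng.normal(0, 2, e)[None, :])


class TestFitGGE:
    def test_constant_matrix_gives_zero_model(self):
        model = fit_gge(pd.DataFrame(np.full((3, 4), 2.0)))
        np.testing.assert_allclose(model.centered_.to_numpy(), 0.0)
        np.testing.assert_allclose(model.genotype_coords_.to_numpy(), 0.0)
        np.testing.assert_allclose(model.environment_coords_.to_numpy(), 0.0)

    def test_hand_svd_of_identity(self):
        model = fit_gge(pd.DataFrame(np.eye(2)))
        np.testing.assert_allclose(model.centered_.to_numpy(),
                                   [[0.5, -0.5], [-0.5, 0.5]])
        assert model.singular_values_[0] == pytest.approx(1.0)
        assert model.singular_values_[1] == pytest.approx(0.0, abs=1e-12)
        np.testing.assert_allclose(model.var_explained_, [1.0, 0.0],
                                   atol=1e-12)

    def test_var_explained_against_full_svd_oracle(self):
        rng = np.random.default_rng(0)
        means = pd.DataFrame(rng.normal(0, 2, (4, 5)))
        model = fit_gge(means)
        centered = means.to_numpy() - means.to_numpy().mean(0)
        s = np.linalg.svd(centered, compute_uv=False)
        np.testing.assert_allclose(model.var_explained_, s**2 / (s**2).sum(),
                                   rtol=1e-10, atol=1e-12)
        # with 4 genotypes the centered matrix has rank 3 > 2 axes
        assert model.var_explained_[:2].sum() < 1.0

    @pytest.mark.parametrize("scaling", [0.0, 0.5, 1.0])
    def test_rank2_reconstruction_exact(self, scaling):
        means = rank2_matrix(5, 4, seed=1)
        model = GGEBiplot(scaling=scaling).fit(means)
        recon = (model.genotype_coords_.to_numpy()
                 @ model.environment_coords_.to_numpy().T)
        np.testing.assert_allclose(recon, model.centered_.to_numpy(),
                                   atol=1e-8)

    def test_long_table_input_equals_cell_mean_input(self, tiny_table):
        from gxekit import aggregate_cell_means

        a = fit_gge(tiny_table)
        b = fit_gge(aggregate_cell_means(tiny_table))
        np.testing.assert_allclose(a.genotype_coords_, b.genotype_coords_)

    def test_bad_scaling_rejected(self):
        with pytest.raises(ValueError, match="scaling"):
            GGEBiplot(scaling=1.5).fit(np.eye(3))


class TestEnvRelationship:
    def test_identical_environment_columns_have_zero_angle(self):
        base = np.array([1.0, -1.0, 0.0])
        means = pd.DataFrame(np.column_stack([base, base, -base]))
        angles, lengths = fit_gge(means).env_relationship()
        assert angles.iloc[0, 1] == pytest.approx(0.0, abs=1e-8)
        assert angles.iloc[0, 2] == pytest.approx(np.pi, abs=1e-8)
        assert lengths.iloc[0] > 0

    def test_angles_symmetric_zero_diagonal(self):
        model = fit_gge(rank2_matrix(4, 4, seed=2))
        angles, _ = model.env_relationship()
        arr = angles.to_numpy()
        np.testing.assert_allclose(arr, arr.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(arr), 0.0, atol=1e-12)

    def test_cosine_matches_column_correlation_for_rank2(self):
        """With f=0 the environment markers carry the full singular values,
        so for a rank-2 centered table cos(angle) equals the Pearson
        correlation between the two environments' centered columns."""
        means = rank2_matrix(6, 5, seed=3)
        model = GGEBiplot(scaling=0.0).fit(means)
        angles, _ = model.env_relationship()
        centered = model.centered_.to_numpy()
        corr = np.corrcoef(centered.T)
        np.testing.assert_allclose(np.cos(angles.to_numpy()), corr, atol=1e-8)

    def test_zero_length_vector_angle_undefined(self):
        # one environment identical to the column mean profile
        means = pd.DataFrame(np.zeros((3, 3)))
        means.iloc[:, 1] = [1.0, 0.0, -1.0]
        angles, lengths = fit_gge(means).env_relationship()
        assert lengths.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert np.isnan(angles.iloc[0, 1])


class TestWhichWonWhere:
    def test_rank2_sector_winner_equals_argmax(self):
        means = rank2_matrix(3, 3, seed=4)
        model = fit_gge(means)
        _, sectors = model.which_won_where()
        centered = model.centered_
        for env in centered.columns:
            assert sectors[env] == centered[env].idxmax()

    @pytest.mark.parametrize("scaling", [0.0, 0.5, 1.0])
    def test_winners_invariant_to_scaling(self, scaling):
        means = rank2_matrix(5, 5, seed=5)
        _, sectors = GGEBiplot(scaling=scaling).fit(means).which_won_where()
        _, ref = GGEBiplot(scaling=0.5).fit(means).which_won_where()
        assert sectors == ref

    def test_dominant_genotype_wins_every_sector(self):
        # one enzyme strictly most active at every temperature, rank-2 table
        means = rank2_matrix(4, 5, seed=6)
        means.iloc[0] = means.to_numpy().max() + np.linspace(5, 6, 5)
        model = fit_gge(means)
        hull, sectors = model.which_won_where()
        assert model.var_explained_[:2].sum() >= 0.999
        assert set(sectors.values()) == {0}
        assert 0 in hull

    def test_collinear_genotypes_fall_back_with_warning(self):
        means = pd.DataFrame(np.outer([1.0, 2.0, 3.0], [1.0, -1.0]))
        model = fit_gge(means)
        with pytest.warns(UserWarning, match="collinear"):
            hull, sectors = model.which_won_where()
        assert hull == []
        assert sectors[0] == 2   # largest centered value in column 0

    def test_hull_vertices_cover_all_winners(self):
        rng = np.random.default_rng(7)
        means = pd.DataFrame(rng.normal(0, 2, (6, 5)))
        hull, sectors = fit_gge(means).which_won_where()
        assert set(sectors.values()) <= set(hull)


class TestMeanVsStability:
    def test_rank1_model_has_zero_instability(self):
        means = pd.DataFrame(np.outer([1.0, -0.5, 2.0], [1.0, 0.8, 1.2]))
        model = fit_gge(means)
        assert model.singular_values_[1] == pytest.approx(0.0, abs=1e-10)
        _, dist = model.mean_vs_stability()
        np.testing.assert_allclose(dist, 0.0, atol=1e-8)

    def test_projection_ranking_equals_row_mean_ranking(self):
        means = rank2_matrix(5, 5, seed=8)
        model = fit_gge(means)
        assert model.var_explained_[:2].sum() >= 0.999
        proj, _ = model.mean_vs_stability()
        row_means = model.centered_.mean(axis=1)
        assert list(proj.sort_values().index) == list(
            row_means.sort_values().index)

    def test_flat_profile_genotype_is_most_stable(self):
        """A genotype with a flat environment-centered profile (identical
        centered values everywhere) out-stabilizes every alternative, and
        perturbing its profile increases its instability."""
        from gxekit import contrast_basis

        v = contrast_basis(5, 1)[:, 0]
        r_eff = np.array([6.0, 1.0, -1.0, 2.0])
        m = np.array([0.0, -2.0, 1.0, 3.0])
        m[0] = m[1:].mean()   # makes genotype 0's centered row constant
        means = pd.DataFrame(r_eff[:, None] + np.outer(m, v) + 10.0)
        model = fit_gge(means)
        _, dist = model.mean_vs_stability()
        assert dist.idxmin() == 0
        perturbed = means.copy()
        perturbed.iloc[0] += 1.5 * v
        _, dist_p = fit_gge(perturbed).mean_vs_stability()
        assert dist_p[0] > dist[0]

    def test_zero_average_environment_is_an_error(self):
        # antisymmetric columns: environment markers cancel
        means = pd.DataFrame(np.outer([1.0, -1.0, 0.0], [1.0, -1.0]))
        model = fit_gge(means)
        with pytest.raises(ValueError, match="zero length"):
            model.mean_vs_stability()


class TestIdealEntry:
    def test_genotype_at_ideal_point_has_zero_distance(self):
        means = pd.DataFrame(np.outer([3.0, 1.0, -4.0], [1.0, 1.1, 0.9]))
        model = fit_gge(means)
        dist, ranking = model.ideal_entry()
        proj, aec = model.mean_vs_stability()
        top = proj.idxmax()
        assert aec[top] == pytest.approx(0.0, abs=1e-10)
        assert dist[top] == pytest.approx(0.0, abs=1e-10)
        assert ranking[0] == top

    def test_rank1_distance_is_projection_gap(self):
        means = pd.DataFrame(np.outer([2.0, 0.0, -1.0], [1.0, 0.7, 1.3]))
        model = fit_gge(means)
        proj, _ = model.mean_vs_stability()
        dist, _ = model.ideal_entry()
        np.testing.assert_allclose(dist, proj.max() - proj, atol=1e-8)

    def test_best_mean_and_lowest_variance_ranks_first(self):
        """The enzyme with both the top mean and the flattest profile
        across environments wins the concentric-circles ranking."""
        from gxekit import contrast_basis

        v = contrast_basis(5, 1)[:, 0]
        r_eff = np.array([6.0, 1.0, -1.0, 2.0])
        m = np.array([0.0, -2.0, 1.0, 3.0])
        m[0] = m[1:].mean()
        means = pd.DataFrame(r_eff[:, None] + np.outer(m, v) + 10.0)
        dist, ranking = fit_gge(means).ideal_entry()
        assert ranking[0] == 0
        assert dist[0] == dist.min()


@settings(max_examples=20, derandomize=True, deadline=None)
@given(st.integers(0, 10**6))
def test_label_equivariance_under_genotype_permutation(seed):
    rng = np.random.default_rng(seed)
    means = pd.DataFrame(rng.normal(0, 2, (5, 4)),
                         index=list("abcde"))
    perm = rng.permutation(5)
    permuted = means.iloc[perm]
    a = fit_gge(means)
    b = fit_gge(permuted)
    np.testing.assert_allclose(
        a.genotype_coords_.loc[permuted.index], b.genotype_coords_,
        atol=1e-8)
    _, sa = a.which_won_where()
    _, sb = b.which_won_where()
    assert sa == sb
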