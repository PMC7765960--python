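"""Interaction scores, the differential statistic and the permutation test."""

import math

import numpy as np
import pytest

from gdcoxs.density import fit_shrinkage_gaussian, log_density_samples
from gdcoxs.divergence import renyi_distance_matrix, upper_triangle
from gdcoxs.interaction import (
    bonferroni_threshold,
    diff_ias_statistic,
    group_ias,
    ias_from_log_densities,
    interaction_score,
    permutation_test,
)
from gdcoxs.io import ConditionLabels

from conftest import make_matrix


class TestInteractionScore:
    def test_self_correlation_is_one(self, rng):
        v = rng.standard_normal(10)
        assert interaction_score(v, v) == pytest.approx(1.0)
        assert interaction_score(v, -v) == pytest.approx(-1.0)

    def test_hand_computed_pearson(self):
        re_c = np.array([1.0, 2.0, 3.0, 4.0])
        re_g = np.array([1.0, 2.0, 3.0, 5.0])
        # direct formula: r = cov / (sd_c * sd_g), computed by hand
        c = re_c - 2.5
        g = re_g - 2.75
        expected = (c @ g) / math.sqrt((c @ c) * (g @ g))
        assert interaction_score(re_c, re_g) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.9827076298239908, rel=1e-12)

    def test_zero_variance_flagged_as_nan(self, rng):
        flat = np.ones(6)
        assert math.isnan(interaction_score(flat, rng.standard_normal(6)))

    def test_invariant_to_common_pair_reordering(self, rng):
        u, v = rng.standard_normal((2, 15))
        perm = rng.permutation(15)
        assert interaction_score(u, v) == pytest.approx(
            interaction_score(u[perm], v[perm]), rel=1e-12
        )

    def test_invariant_to_affine_rescaling(self, rng):
        u, v = rng.standard_normal((2, 15))
        assert interaction_score(3.5 * u - 2.0, v) == pytest.approx(
            interaction_score(u, v), rel=1e-10
        )


class TestIasFromLogDensities:
    def test_matches_explicit_upper_triangle_correlation(self, rng):
        # closed form vs the literal construction via distance matrices
        for n in (4, 9, 25):
            a = rng.standard_normal(n) * 3 - 40.0
            b = rng.standard_normal(n) + 0.5 * a
            u = upper_triangle(a[:, None] - a[None, :])
            v = upper_triangle(b[:, None] - b[None, :])
            assert ias_from_log_densities(a, b) == pytest.approx(
                interaction_score(u, v), rel=1e-9, abs=1e-12
            )

    def test_full_divergence_path_equivalence(self, rng):
        x = rng.standard_normal((5, 12))
        y = 0.7 * x + rng.standard_normal((5, 12))
        mx = fit_shrinkage_gaussian(x)
        my = fit_shrinkage_gaussian(y)
        via_matrices = interaction_score(
            upper_triangle(renyi_distance_matrix(x, mx)),
            upper_triangle(renyi_distance_matrix(y, my)),
        )
        via_closed_form = ias_from_log_densities(
            log_density_samples(mx, x), log_density_samples(my, y)
        )
        assert via_closed_form == pytest.approx(via_matrices, rel=1e-9)

    def test_constant_log_densities_flagged(self):
        assert math.isnan(ias_from_log_densities(np.ones(5), np.arange(5.0)))


class TestDiffIasStatistic:
    def test_equal_scores_give_zero(self):
        assert diff_ias_statistic(0.3, 10, 0.3, 15) == 0.0

    def test_swapping_groups_flips_the_sign(self):
        z = diff_ias_statistic(0.5, 12, 0.1, 20)
        assert diff_ias_statistic(0.1, 20, 0.5, 12) == pytest.approx(-z, rel=1e-12)

    def test_hand_evaluated_fisher_z(self):
        # n = 10 samples per group -> m = 45 pairs each
        z = diff_ias_statistic(0.5, 10, 0.0, 10)
        expected = math.atanh(0.5) / math.sqrt(2.0 / 42.0)
        assert z == pytest.approx(expected, rel=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 4 samples"):
            diff_ias_statistic(0.2, 3, 0.1, 10)

    def test_extreme_scores_are_clipped_not_infinite(self):
        z = diff_ias_statistic(1.0, 10, -1.0, 10)
        assert math.isfinite(z)

    def test_nan_score_propagates(self):
        assert math.isnan(diff_ias_statistic(float("nan"), 10, 0.2, 10))


def _differential_fixture(rng, n_per_group=12, d=5):
    """Group A: expression tracks copy number; group B: independent."""
    cna_a = rng.choice([-1.0, 0.0, 1.0], size=(d, n_per_group), p=[0.2, 0.6, 0.2])
    cna_b = rng.choice([-1.0, 0.0, 1.0], size=(d, n_per_group), p=[0.2, 0.6, 0.2])
    ge_a = cna_a + 0.3 * rng.standard_normal((d, n_per_group))
    ge_b = rng.standard_normal((d, n_per_group))
    cna = make_matrix(np.hstack([cna_a, cna_b]), "CNA")
    ge = make_matrix(np.hstack([ge_a, ge_b]), "GE")
    labels = ConditionLabels(
        {f"s{j}": ("A" if j < n_per_group else "B") for j in range(2 * n_per_group)}
    )
    return cna, ge, labels


class TestPermutationTest:
    def test_p_value_bounds(self, rng):
        cna, ge, labels = _differential_fixture(rng)
        res = permutation_test(
            cna, ge, labels, cna.gene_ids, n_permutations=99, seed=3, set_name="S"
        )
        assert 1.0 / 100.0 <= res.p_value <= 1.0

    def test_deterministic_for_fixed_seed(self, rng):
        cna, ge, labels = _differential_fixture(rng)
        r1 = permutation_test(cna, ge, labels, cna.gene_ids, n_permutations=50, seed=11)
        r2 = permutation_test(cna, ge, labels, cna.gene_ids, n_permutations=50, seed=11)
        assert r1 == r2

    def test_detects_planted_differential_interaction(self, rng):
        cna, ge, labels = _differential_fixture(rng, n_per_group=30, d=6)
        res = permutation_test(
            cna, ge, labels, cna.gene_ids, n_permutations=199, seed=5
        )
        assert res.p_value < 0.05
        # interaction is stronger in the reference group A
        assert res.ias_group_a > res.ias_group_b
        assert res.diff_ias > 0

    def test_reference_group_controls_the_sign(self, rng):
        cna, ge, labels = _differential_fixture(rng, n_per_group=20)
        res_a = permutation_test(
            cna, ge, labels, cna.gene_ids, n_permutations=50, seed=2,
            reference_group="A",
        )
        res_b = permutation_test(
            cna, ge, labels, cna.gene_ids, n_permutations=50, seed=2,
            reference_group="B",
        )
        assert res_a.diff_ias == pytest.approx(-res_b.diff_ias, rel=1e-12)

    def test_small_gene_set_skipped(self, rng):
        cna, ge, labels = _differential_fixture(rng)
        assert (
            permutation_test(cna, ge, labels, ["g0"], n_permutations=10, seed=0)
            is None
        )

    def test_result_records_member_counts_and_groups(self, rng):
        cna, ge, labels = _differential_fixture(rng)
        res = permutation_test(
            cna, ge, labels, ["g0", "g1", "g2"], n_permutations=20, seed=0
        )
        assert res.n_cna == res.n_exp == 3
        assert (res.group_a, res.group_b) == ("A", "B")


class TestGroupIas:
    def test_gdcoxs_and_kernel_agree_on_sign_for_coupled_data(self, rng):
        x = rng.choice([-1.0, 0.0, 1.0], size=(4, 40), p=[0.2, 0.6, 0.2])
        y = x + 0.1 * rng.standard_normal(x.shape)
        assert group_ias(x, y, "gdcoxs") > 0.5
        assert group_ias(x, y, "dcoxs_kernel") > 0.0

    def test_unknown_method_rejected(self, rng):
        with pytest.raises(ValueError):
            group_ias(rng.standard_normal((2, 5)), rng.standard_normal((2, 5)), "nope")


class TestBonferroni:
    def test_pathway_family_threshold(self):
        # 1282 pathway tests at alpha = 0.05
        assert bonferroni_threshold(0.05, 1282) == pytest.approx(3.9e-5, rel=0.005)

    def test_pairwise_family_threshold(self):
        # 6202 x 6233 single-pair tests at alpha = 0.05
        assert bonferroni_threshold(0.05, 6202 * 6233) == pytest.approx(
            1.29e-9, rel=0.005
        )

    def test_single_test_returns_alpha(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(0.0, 10)
        with pytest.raises(ValueError):
            bonferroni_threshold(0.05, 0)
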