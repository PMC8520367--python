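"""Effective distances, the four regional/boundary penalties and E(x)."""

import numpy as np
import pytest

from tensorcut import (
    ConfigurationError,
    ContractViolationError,
    DiffusionTensor,
    EnergyParams,
    ScalarImage,
    SeedSets,
    TensorField,
    boundary_penalty,
    compute_effective_distances,
    effective_distance,
    regional_penalty,
    total_energy,
)
from tensorcut.energy import TARGET, BACKGROUND, neighbor_pairs, resolve_params
from tensorcut.errors import InvalidInputError


def tiny_tensor_field():
    """1x3 field: identity, identity, e*identity."""
    lower = np.zeros((1, 3, 6))
    lower[0, 0] = [1, 0, 1, 0, 0, 1]
    lower[0, 1] = [1, 0, 1, 0, 0, 1]
    lower[0, 2] = [np.e, 0, np.e, 0, 0, np.e]
    return TensorField(lower)


class TestSeedSets:
    def test_overlap_rejected(self):
        with pytest.raises(ConfigurationError):
            SeedSets(frozenset({(0, 0)}), frozenset({(0, 0)}))

    def test_empty_or_out_of_range_rejected(self):
        s = SeedSets(frozenset({(0, 0)}), frozenset())
        with pytest.raises(ConfigurationError):
            s.validate_for((2, 2))
        s = SeedSets(frozenset({(5, 0)}), frozenset({(0, 0)}))
        with pytest.raises(ConfigurationError):
            s.validate_for((2, 2))


class TestEnergyParams:
    @pytest.mark.parametrize("alpha", [0.0, 1.0, -0.2, 1.5])
    def test_alpha_open_interval(self, alpha):
        with pytest.raises(ConfigurationError):
            EnergyParams(alpha=alpha)

    def test_json_round_trip(self):
        p = EnergyParams(alpha=0.3, sigma=2.0, hard_constraint_weight=50.0, metric="frobenius")
        assert EnergyParams.from_json(p.to_json()) == p


class TestEffectiveDistance:
    def test_singleton_seed_set_is_plain_distance(self):
        img = ScalarImage(np.array([[5.0, 3.0, 9.0]]))
        assert effective_distance((0, 0), {(0, 1)}, img) == 2.0

    def test_scalar_set_average(self):
        """P_i = 5 against seed intensities {3, 9}: (2 + 4) / 2 = 3."""
        img = ScalarImage(np.array([[5.0, 3.0, 9.0]]))
        assert effective_distance((0, 0), {(0, 1), (0, 2)}, img) == 3.0

    def test_tensor_set_average(self):
        """Identity vs {identity, e*identity}: mean of 0 and sqrt(3)."""
        field = tiny_tensor_field()
        d = effective_distance((0, 0), {(0, 1), (0, 2)}, field)
        assert d == pytest.approx(np.sqrt(3) / 2, abs=1e-12)

    def test_empty_seed_set_rejected(self):
        img = ScalarImage(np.zeros((2, 2)))
        with pytest.raises(ConfigurationError):
            effective_distance((0, 0), set(), img)

    def test_vectorized_matches_scalar_op(self, rng):
        img = ScalarImage(rng.uniform(0, 10, (4, 4)))
        seeds = SeedSets(frozenset({(0, 0), (3, 3)}), frozenset({(0, 3), (2, 1)}))
        dists = compute_effective_distances(img, seeds)
        for v in [(1, 1), (2, 2), (0, 2)]:
            assert dists.to_target[v] == pytest.approx(
                effective_distance(v, seeds.target, img), abs=1e-12
            )
            assert dists.to_background[v] == pytest.approx(
                effective_distance(v, seeds.background, img), abs=1e-12
            )


class TestRegionalPenalty:
    @pytest.fixture
    def setup(self):
        img = ScalarImage(np.array([[0.0, 2.0, 10.0]]))
        seeds = SeedSets(frozenset({(0, 0)}), frozenset({(0, 2)}))
        params, _, _, dists = resolve_params(img, seeds, EnergyParams())
        return img, seeds, params, dists

    def test_hard_constraints_on_seeds(self, setup):
        _, seeds, params, dists = setup
        assert regional_penalty((0, 0), TARGET, seeds, dists, params) == 0.0
        assert regional_penalty((0, 0), BACKGROUND, seeds, dists, params) == params.hard_constraint_weight
        assert regional_penalty((0, 2), BACKGROUND, seeds, dists, params) == 0.0
        assert regional_penalty((0, 2), TARGET, seeds, dists, params) == params.hard_constraint_weight

    def test_unknown_normalized_distances(self, setup):
        """D^O = 2, D^B = 8: penalty(target) = 0.2, penalty(background) = 0.8."""
        _, seeds, params, dists = setup
        pt = regional_penalty((0, 1), TARGET, seeds, dists, params)
        pb = regional_penalty((0, 1), BACKGROUND, seeds, dists, params)
        assert pt == pytest.approx(0.2)
        assert pb == pytest.approx(0.8)

    def test_quarter_three_quarter_split(self):
        """D^O = 1, D^B = 3 gives penalties 0.25 / 0.75."""
        img = ScalarImage(np.array([[0.0, 1.0, 4.0]]))
        seeds = SeedSets(frozenset({(0, 0)}), frozenset({(0, 2)}))
        params, _, _, dists = resolve_params(img, seeds, EnergyParams())
        assert regional_penalty((0, 1), TARGET, seeds, dists, params) == pytest.approx(0.25)
        assert regional_penalty((0, 1), BACKGROUND, seeds, dists, params) == pytest.approx(0.75)

    def test_zero_distance_tie_is_half(self):
        img = ScalarImage(np.zeros((1, 3)))
        seeds = SeedSets(frozenset({(0, 0)}), frozenset({(0, 2)}))
        params, _, _, dists = resolve_params(img, seeds, EnergyParams())
        assert regional_penalty((0, 1), TARGET, seeds, dists, params) == 0.5
        assert regional_penalty((0, 1), BACKGROUND, seeds, dists, params) == 0.5

    def test_unknown_penalties_sum_to_one(self, rng):
        img = ScalarImage(rng.uniform(0, 5, (3, 3)))
        seeds = SeedSets(frozenset({(0, 0)}), frozenset({(2, 2)}))
        params, _, _, dists = resolve_params(img, seeds, EnergyParams())
        for v in [(0, 1), (1, 1), (2, 0)]:
            total = regional_penalty(v, TARGET, seeds, dists, params) + regional_penalty(
                v, BACKGROUND, seeds, dists, params
            )
            assert total == pytest.approx(1.0, abs=1e-12)


class TestBoundaryPenalty:
    def test_identical_features_cost_one(self):
        img = ScalarImage(np.zeros((1, 2)))
        p = EnergyParams(sigma=1.0)
        assert boundary_penalty((0, 0), (0, 1), img, p) == 1.0

    def test_gaussian_kernel_value(self):
        """sigma = 1, d = 1 -> exp(-1/2)."""
        img = ScalarImage(np.array([[0.0, 1.0]]))
        p = EnergyParams(sigma=1.0)
        assert boundary_penalty((0, 0), (0, 1), img, p) == pytest.approx(np.exp(-0.5))

    def test_large_contrast_tends_to_zero(self):
        img = ScalarImage(np.array([[0.0, 1e6]]))
        p = EnergyParams(sigma=1.0)
        assert boundary_penalty((0, 0), (0, 1), img, p) == pytest.approx(0.0, abs=1e-300)

    def test_non_neighbors_rejected(self):
        img = ScalarImage(np.zeros((1, 4)))
        with pytest.raises(ContractViolationError):
            boundary_penalty((0, 0), (0, 3), img, EnergyParams(sigma=1.0))


class TestNeighborhood:
    def test_2x2_has_six_pairs_with_diagonals(self):
        pairs = neighbor_pairs((2, 2), np.ones((2, 2), bool))
        assert len(pairs) == 6

    def test_1x3_chain(self):
        pairs = neighbor_pairs((1, 3), np.ones((1, 3), bool))
        assert len(pairs) == 2

    def test_3d_slice_wise_has_no_cross_slice_pairs(self):
        pairs = neighbor_pairs((2, 2, 2), np.ones((2, 2, 2), bool))
        assert all(i[0] == j[0] for i, j in pairs)

    def test_3d_full_mode_is_6_neighborhood(self):
        pairs = neighbor_pairs((2, 2, 2), np.ones((2, 2, 2), bool), full_3d=True)
        assert len(pairs) == 12  # edges of a 2x2x2 lattice


class TestTotalEnergy:
    def test_uniform_image_energy_decomposition(self):
        """Uniform 2x3 image: unknowns tie at 0.5 each; cut isolates one corner."""
        img = ScalarImage(np.zeros((2, 3)))
        seeds = SeedSets(frozenset({(0, 0)}), frozenset({(1, 2)}))
        lab = np.ones((2, 3), bool)
        lab[1, 2] = False
        # regional: 4 unknowns x 0.5 tie; boundary: 3 unit edges around (1,2)
        e = total_energy(lab, img, seeds, EnergyParams(alpha=0.5, sigma=1.0))
        assert e == pytest.approx(0.5 * (4 * 0.5) + 0.5 * 3)

    def test_two_pixel_seeded_cut(self):
        """1x2 image, opposite seeds, equal intensity: E = 0.5 * 1."""
        img = ScalarImage(np.zeros((1, 2)))
        seeds = SeedSets(frozenset({(0, 0)}), frozenset({(0, 1)}))
        lab = np.array([[True, False]])
        e = total_energy(lab, img, seeds, EnergyParams(alpha=0.5, sigma=1.0))
        assert e == pytest.approx(0.5)

    def test_seed_violation_scores_hard_weight(self):
        img = ScalarImage(np.zeros((1, 2)))
        seeds = SeedSets(frozenset({(0, 0)}), frozenset({(0, 1)}))
        params = EnergyParams(alpha=0.5, sigma=1.0, hard_constraint_weight=100.0)
        violating = np.array([[False, True]])  # both seeds flipped
        e = total_energy(violating, img, seeds, params)
        assert e == pytest.approx(0.5 * 200 + 0.5)

    def test_monotone_in_cut_edge_weight(self):
        """Raising sigma raises every boundary weight, never lowering E of a cut."""
        img = ScalarImage(np.array([[0.0, 1.0]]))
        seeds = SeedSets(frozenset({(0, 0)}), frozenset({(0, 1)}))
        lab = np.array([[True, False]])
        e_small = total_energy(lab, img, seeds, EnergyParams(sigma=0.5))
        e_big = total_energy(lab, img, seeds, EnergyParams(sigma=5.0))
        assert e_big >= e_small

    def test_shape_mismatch_rejected(self):
        img = ScalarImage(np.zeros((2, 2)))
        seeds = SeedSets(frozenset({(0, 0)}), frozenset({(1, 1)}))
        with pytest.raises(InvalidInputError):
            total_energy(np.ones((3, 3), bool), img, seeds, EnergyParams())


class TestResolveParams:
    def test_adaptive_sigma_is_mean_neighbor_distance(self):
        img = ScalarImage(np.array([[0.0, 2.0, 4.0]]))
        seeds = SeedSets(frozenset({(0, 0)}), frozenset({(0, 2)}))
        resolved, pairs, _, _ = resolve_params(img, seeds, EnergyParams())
        assert resolved.sigma == pytest.approx(2.0)  # both neighbor gaps are 2

    def test_uniform_image_sigma_fallback(self):
        img = ScalarImage(np.zeros((1, 3)))
        seeds = SeedSets(frozenset({(0, 0)}), frozenset({(0, 2)}))
        resolved, _, _, _ = resolve_params(img, seeds, EnergyParams())
        assert resolved.sigma == 1.0

    def test_hard_weight_dominates_incident_boundary_sum(self, rng):
        img = ScalarImage(rng.uniform(0, 3, (4, 4)))
        seeds = SeedSets(frozenset({(0, 0)}), frozenset({(3, 3)}))
        params, pairs, weights, _ = resolve_params(img, seeds, EnergyParams())
        incident = {}
        for (i, j), w in zip(pairs, weights):
            incident[i] = incident.get(i, 0.0) + w
            incident[j] = incident.get(j, 0.0) + w
        alpha = params.alpha
        assert alpha * params.hard_constraint_weight > (1 - alpha) * max(incident.values())
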