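"""Block meta-communities, sigma sweeps and the pseudo-spatial model."""

import numpy as np
import pytest

from chainstab import (
    MetaCommunityState,
    MigrationParams,
    build_block_metacommunity,
    build_pseudo_system,
    compute_features,
    generate_base_communities,
    integrate_cycle,
    run_pseudo_experiment,
    sample_half_normal_block,
    sweep_sigma,
)


@pytest.fixture(scope="module")
def base_pair():
    rng = np.random.default_rng(21)
    return generate_base_communities(2, size=8, rng=rng)


class TestHalfNormal:
    def test_sigma_zero_is_all_zero(self, rng):
        assert np.all(sample_half_normal_block(0.0, rng) == 0.0)

    def test_entries_nonnegative(self, rng):
        assert np.all(sample_half_normal_block(0.3, rng, (20, 20)) >= 0)

    def test_empirical_mean(self):
        rng = np.random.default_rng(1)
        sigma = 0.4
        draws = sample_half_normal_block(sigma, rng, (400, 250)).ravel()
        expected = sigma * np.sqrt(2 / np.pi)
        se = sigma * np.sqrt(1 - 2 / np.pi) / np.sqrt(draws.size)
        assert abs(draws.mean() - expected) < 3 * se

    def test_negative_sigma_raises(self, rng):
        with pytest.raises(ValueError):
            sample_half_normal_block(-0.1, rng)


class TestBlockAssembly:
    def test_block_structure_and_signs(self, base_pair, rng):
        pool, state = build_block_metacommunity(base_pair[0], base_pair[1], 0.3, rng)
        assert pool.N == 16
        A = pool.A
        np.testing.assert_array_equal(np.diag(A), -1.0)
        assert np.all(A[8:, :8] >= 0)  # up -> down positive
        assert np.all(A[:8, 8:] <= 0)  # down -> up negative
        np.testing.assert_array_equal(A[:8, :8], base_pair[0][0].A)
        np.testing.assert_array_equal(A[8:, 8:], base_pair[1][0].A)
        assert np.all(state.x1[:8] > 0) and np.all(state.x1[8:] == 0)
        assert np.all(state.x2[8:] > 0) and np.all(state.x2[:8] == 0)

    def test_sigma_zero_decouples_patches(self, base_pair, rng):
        """With zero cross blocks each community evolves exactly as it
        would alone, so the joint equilibrium is the pair of isolated ones."""
        pool, state = build_block_metacommunity(base_pair[0], base_pair[1], 0.0, rng)
        final = integrate_cycle(state, pool).final
        np.testing.assert_allclose(final.x1[:8], base_pair[0][1], atol=1e-5)
        np.testing.assert_allclose(final.x2[8:], base_pair[1][2], atol=1e-5)

    def test_within_block_features_invariant_in_sigma(self, base_pair, rng):
        feats = []
        for sigma in (0.0, 0.5):
            pool, state = build_block_metacommunity(
                base_pair[0], base_pair[1], sigma, rng
            )
            feats.append(compute_features(state, pool, MigrationParams(0.5, 0.5)))
        assert feats[0].total_pos_up == pytest.approx(feats[1].total_pos_up)
        assert feats[0].total_neg_down == pytest.approx(feats[1].total_neg_down)

    def test_ordered_pair_count(self):
        import itertools

        pairs = list(itertools.permutations(range(11), 2))
        assert len(pairs) == 110


class TestSweepSigma:
    def test_single_sigma_correlation_is_missing(self, base_pair, rng):
        _, corr = sweep_sigma(base_pair[0], base_pair[1], [0.0], rng)
        assert np.isnan(corr)

    def test_records_report_trans_strength(self, base_pair, rng):
        recs, _ = sweep_sigma(base_pair[0], base_pair[1], [0.0, 0.1, 0.3], rng)
        sig0 = [r for r in recs if r["sigma"] == 0.0]
        assert sig0 and sig0[0]["total_pos_trans"] == 0.0
        assert all(0.0 <= r["q0"] <= 1.0 for r in recs)


class TestPseudoSystem:
    def test_resident_interactions_have_sign_and_mean_of_m(self):
        rng = np.random.default_rng(2)
        draws = []
        for _ in range(300):
            sys_ = build_pseudo_system(0.9, rng)
            draws.extend(sys_.pool.A[sys_.residents, 0])
        draws = np.asarray(draws)
        assert np.all(draws > 0)
        # Beta(9, 1) has mean 0.9 and SD ~0.09
        assert abs(draws.mean() - 0.9) < 3 * 0.0905 / np.sqrt(draws.size)

    def test_negative_m_flips_sign(self, rng):
        sys_ = build_pseudo_system(-0.3, rng)
        assert np.all(sys_.pool.A[sys_.residents, 0] < 0)
        assert np.all(np.abs(sys_.pool.A[sys_.residents, 0]) < 1.0)

    def test_invalid_m_raises(self, rng):
        for m in (0.0, 1.0, -1.0, 1.5):
            with pytest.raises(ValueError):
                build_pseudo_system(m, rng)

    def test_species0_is_autonomous(self, rng):
        """Species 0's trajectory is the unperturbed mono-culture logistic
        regardless of the residents."""
        sys_ = build_pseudo_system(0.6, rng)
        pool = sys_.pool
        state = MetaCommunityState.empty(25)
        state.x2[0] = 0.01
        state.x2[sys_.residents] = 0.5
        traj = integrate_cycle(state, pool, duration=30.0, n_out=4)
        r0 = pool.r2[0]
        for t, s in zip(traj.times, traj.states):
            expected = r0 * 0.01 * np.exp(r0 * t) / (r0 + 0.01 * (np.exp(r0 * t) - 1))
            assert s.x2[0] == pytest.approx(expected, rel=1e-5)

    def test_nonautonomous_variant_keeps_row0(self, rng):
        sys_ = build_pseudo_system(0.6, rng, autonomous_species0=False)
        assert np.any(sys_.pool.A[0, 1:] != 0.0)


class TestPseudoExperiment:
    def test_neutral_species0_gives_near_zero_difference(self):
        """A species 0 with no effect on anyone leaves the residents'
        stability unchanged up to the pool-size correction."""
        rng = np.random.default_rng(3)
        while True:
            sys_ = build_pseudo_system(0.1, rng)
            A = sys_.pool.A.copy()
            A[1:, 0] = 0.0  # remove all effects of species 0
            from chainstab.pool import SpeciesPool
            from chainstab.interventions import PseudoSystem, _coexists

            pool = SpeciesPool(sys_.pool.r1, sys_.pool.r2, A)
            neutered = PseudoSystem(pool, sys_.residents, 0.1, True)
            members = np.sort(np.concatenate([[0], neutered.residents]))
            if _coexists(pool, members) is not None:
                break
        out = run_pseudo_experiment([neutered])
        assert len(out["records"]) == 1
        rec = out["records"][0]
        assert rec["strength_from_0"] == 0.0
        # identical resident dynamics; only the species-0 trial itself and
        # the 25/24 rescaling can differ, both bounded by one trial weight
        assert abs(rec["difference"]) <= 1 / 24 + 1e-9

    def test_discards_systems_where_coexistence_depends_on_species0(self, rng):
        """Retained systems are exactly those whose residents coexist both
        with and without species 0."""
        systems = [build_pseudo_system(0.6, rng) for _ in range(12)]
        out = run_pseudo_experiment(systems)
        assert len(out["records"]) <= len(systems)
        for rec in out["records"]:
            assert 0.0 <= rec["q_with"] <= 1.0
            assert rec["q_without"] >= 0.0
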