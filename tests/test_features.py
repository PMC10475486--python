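"""Community feature extraction, including the worked two/three-species
meta-community example."""

import numpy as np
import pytest

from chainstab import (
    EnsembleConfig,
    MetaCommunityState,
    MigrationParams,
    SpeciesPool,
    compute_features,
    sample_pool,
)

PARAMS = MigrationParams(0.5, 0.5)


@pytest.fixture
def worked_example():
    """Upstream community {0, 1}, downstream {2, 3, 4}.

    Within upstream: two positive links of 0.5 each.  Within downstream:
    one positive link (0.7) and two negative (0.2 each).  Trans: one
    positive (0.5) and one negative (0.2).
    """
    A = -np.eye(5)
    A[0, 1] = 0.5   # 1 -> 0 (upstream, positive)
    A[1, 0] = 0.5   # 0 -> 1 (upstream, positive)
    A[2, 3] = 0.7   # 3 -> 2 (downstream, positive)
    A[3, 2] = -0.2  # 2 -> 3 (downstream, negative)
    A[3, 4] = -0.2  # 4 -> 3 (downstream, negative)
    A[2, 0] = 0.5   # upstream 0 -> downstream 2 (trans, positive)
    A[3, 1] = -0.2  # upstream 1 -> downstream 3 (trans, negative)
    pool = SpeciesPool(r1=np.full(5, 0.5), r2=np.full(5, 0.5), A=A)
    state = MetaCommunityState(
        x1=np.array([1.0, 1.0, 0.0, 0.0, 0.0]),
        x2=np.array([0.0, 0.0, 1.0, 1.0, 1.0]),
    )
    return pool, state


def brute_force_features(state, pool):
    """Independent oracle: explicit loops over ordered present pairs."""
    up = [i for i in range(pool.N) if state.x1[i] > 0]
    down = [i for i in range(pool.N) if state.x2[i] > 0]

    def collect(receivers, senders, exclude_self):
        pos, neg, links = [], [], 0
        for i in receivers:
            for k in senders:
                if exclude_self and i == k:
                    continue
                a = pool.A[i, k]
                if a > 0:
                    pos.append(a)
                    links += 1
                elif a < 0:
                    neg.append(-a)
                    links += 1
        return pos, neg, links

    out = {}
    for name, (recv, send) in {"up": (up, up), "down": (down, down)}.items():
        pos, neg, links = collect(recv, send, True)
        out[f"total_pos_{name}"] = sum(pos)
        out[f"mean_pos_{name}"] = np.mean(pos) if pos else 0.0
        out[f"total_neg_{name}"] = sum(neg)
        out[f"mean_neg_{name}"] = np.mean(neg) if neg else 0.0
        out[f"mean_degree_{name}"] = links / len(recv) if recv else 0.0
    pos, neg, links = collect(down, up, True)
    out["total_pos_trans"] = sum(pos)
    out["mean_pos_trans"] = np.mean(pos) if pos else 0.0
    out["total_neg_trans"] = sum(neg)
    out["mean_neg_trans"] = np.mean(neg) if neg else 0.0
    out["mean_degree_trans"] = links / len(down) if down else 0.0
    out["richness_up"] = len(up)
    out["richness_down"] = len(down)
    return out


class TestWorkedExample:
    def test_all_quantities(self, worked_example):
        pool, state = worked_example
        f = compute_features(state, pool, PARAMS)
        assert f.richness_up == 2 and f.richness_down == 3
        assert f.total_pos_up == pytest.approx(1.0)
        assert f.mean_pos_up == pytest.approx(0.5)
        assert f.total_pos_down == pytest.approx(0.7)
        assert f.mean_pos_down == pytest.approx(0.7)
        assert f.total_neg_down == pytest.approx(0.4)
        assert f.mean_neg_down == pytest.approx(0.2)
        assert f.total_pos_trans == pytest.approx(0.5)
        assert f.total_neg_trans == pytest.approx(0.2)
        assert f.mean_degree_up == pytest.approx(1.0)
        assert f.mean_degree_down == pytest.approx(1.0)
        assert f.mean_degree_trans == pytest.approx(2 / 3, abs=5e-4)

    def test_migration_params_passed_through(self, worked_example):
        pool, state = worked_example
        f = compute_features(state, pool, MigrationParams(0.25, 0.75))
        assert f.rho == 0.25 and f.mu == 0.75


class TestGeneralProperties:
    def test_empty_patches_give_all_zero(self, random_pool):
        f = compute_features(MetaCommunityState.empty(random_pool.N), random_pool, PARAMS)
        for name, value in f.as_dict().items():
            if name not in ("rho", "mu"):
                assert value == 0

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        pool = sample_pool(EnsembleConfig(N=10, richness_range=(1, 10)), rng)
        x1 = rng.uniform(0.1, 1, 10) * (rng.uniform(size=10) < 0.5)
        x2 = rng.uniform(0.1, 1, 10) * (rng.uniform(size=10) < 0.5)
        state = MetaCommunityState(x1, x2)
        f = compute_features(state, pool, PARAMS).as_dict()
        oracle = brute_force_features(state, pool)
        for name, expected in oracle.items():
            assert f[name] == pytest.approx(expected, abs=1e-12), name

    def test_absent_species_entries_are_ignored(self, rng):
        pool = sample_pool(EnsembleConfig(N=6, richness_range=(1, 6)), rng)
        state = MetaCommunityState(
            np.array([1.0, 0, 0, 0, 0.5, 0]), np.array([0, 1.0, 0.3, 0, 0, 0])
        )
        f1 = compute_features(state, pool, PARAMS)
        # rewrite every matrix entry touching the absent species 3 and 5
        A = pool.A.copy()
        A[3, :] = 99.0
        A[:, 3] = -99.0
        A[5, :] = 42.0
        A[:, 5] = -42.0
        np.fill_diagonal(A, -1.0)
        pool2 = SpeciesPool(pool.r1, pool.r2, A)
        f2 = compute_features(state, pool2, PARAMS)
        assert f1.as_dict() == f2.as_dict()

    def test_mean_times_count_equals_total(self, rng):
        pool = sample_pool(EnsembleConfig(N=8, richness_range=(1, 8)), rng)
        state = MetaCommunityState(
            rng.uniform(0.1, 1, 8) * (rng.uniform(size=8) < 0.7),
            rng.uniform(0.1, 1, 8) * (rng.uniform(size=8) < 0.7),
        )
        f = compute_features(state, pool, PARAMS)
        down = np.flatnonzero(state.x2 > 0)
        up = np.flatnonzero(state.x1 > 0)
        block = pool.A[np.ix_(down, down)].copy()
        np.fill_diagonal(block, 0.0)
        n_pos = int((block > 0).sum())
        if n_pos:
            assert f.mean_pos_down * n_pos == pytest.approx(f.total_pos_down)

    def test_zero_interactions_do_not_count(self):
        A = -np.eye(3)
        A[0, 1] = 0.0  # explicit zero link
        A[1, 0] = 0.4
        pool = SpeciesPool(np.full(3, 0.5), np.full(3, 0.5), A)
        state = MetaCommunityState(np.array([1.0, 1, 0]), np.zeros(3))
        f = compute_features(state, pool, PARAMS)
        assert f.mean_degree_up == pytest.approx(0.5)  # only the 0 -> 1 link
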