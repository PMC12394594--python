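import numpy as np
import pandas as pd
import pytest
from scipy import stats

from emotrans.data import EmotionState, ValidationError
from emotrans.meta import pool
from emotrans.simulate import SyntheticConfig, generate_study
from emotrans.typicality import (
    SimilarityMatrix,
    ak_isrsa,
    similarity_matrix,
    typicality_effect,
    typicality_index,
)
from conftest import make_dataset


@pytest.fixture
def three_states():
    return [
        EmotionState("anxious", "negative"),
        EmotionState("sad", "negative"),
        EmotionState("happy", "positive"),
    ]


# 3 transitions each: six-pair enumeration on 3 states has 6 entries, so use
# vectors over all 6 ordered pairs
VEC_A = [10, 20, 30, 40, 50, 60]


class TestTypicalityIndex:
    def test_participant_equal_to_group_mean(self, three_states):
        ds = make_dataset(
            {"p1": VEC_A, "p2": VEC_A, "p3": VEC_A}, three_states
        )
        res = typicality_index(ds, "self", "include_self")
        np.testing.assert_allclose(res.indices.to_numpy(), 1.0)

    def test_anti_linear_participant(self, three_states):
        mean_vec = np.array([40, 45, 50, 55, 60, 65], float)
        anti = 100.0 - mean_vec
        ds = make_dataset(
            {"p1": anti, "p2": mean_vec + (mean_vec - anti) / 2.0,
             "p3": mean_vec + (mean_vec - anti) / 2.0},
            three_states,
        )
        # group mean = mean_vec by construction
        res = typicality_index(ds, "self", "include_self")
        assert res.indices["p1"] == pytest.approx(-1.0)

    def test_leave_one_out_worked_example(self, three_states):
        # 3 participants, 3 transitions rated; pad to 6 with a shared tail
        v1 = [10, 20, 30]
        v2 = [20, 20, 20]
        v3 = [30, 20, 10]
        tail = [50, 60, 70]
        ds = make_dataset(
            {"p1": v1 + tail, "p2": v2 + tail, "p3": v3 + tail}, three_states
        )
        res = typicality_index(ds, "self", "leave_one_out")
        # brute-force oracle
        mat = np.array([v1 + tail, v2 + tail, v3 + tail], float)
        for i, pid in enumerate(["p1", "p2", "p3"]):
            loo_mean = np.delete(mat, i, axis=0).mean(axis=0)
            expect = stats.pearsonr(mat[i], loo_mean)[0]
            assert res.indices[pid] == pytest.approx(expect)

    def test_leave_one_out_pure_three_transition_example(self, three_states):
        # restricted to the three varying transitions, the LOO index for the
        # first participant is exactly -1: mean of others = {25,20,15}
        v = np.array([[10, 20, 30], [20, 20, 20], [30, 20, 10]], float)
        loo = v[[1, 2]].mean(axis=0)
        np.testing.assert_allclose(loo, [25, 20, 15])
        assert stats.pearsonr(v[0], loo)[0] == pytest.approx(-1.0)

    def test_zero_variance_participant_excluded_but_shapes_mean(self, three_states):
        const = [40.0] * 6
        ds = make_dataset(
            {"p1": VEC_A, "p2": const, "p3": list(reversed(VEC_A)),
             "p4": [v + 1 for v in VEC_A]},
            three_states,
        )
        res = typicality_index(ds, "self", "include_self")
        assert "p2" not in res.indices.index
        assert res.n_used == 3
        assert "p2" in res.excluded
        # the constant participant still contributes to the group mean
        grand = np.array(
            [VEC_A, const, list(reversed(VEC_A)), [v + 1 for v in VEC_A]], float
        ).mean(axis=0)
        expect = stats.pearsonr(np.array(VEC_A, float), grand)[0]
        assert res.indices["p1"] == pytest.approx(expect)

    def test_too_few_participants(self, three_states):
        ds = make_dataset({"p1": VEC_A, "p2": VEC_A}, three_states)
        with pytest.raises(ValidationError):
            typicality_index(ds, "self")

    def test_include_self_bias_vs_loo(self, six_states):
        cfg = SyntheticConfig("s", six_states, n_participants=30,
                              include_same_state=False, noise_sd=10.0, seed=2)
        ds = generate_study(cfg)
        inc = typicality_index(ds, "self", "include_self").indices
        loo = typicality_index(ds, "self", "leave_one_out").indices
        assert (inc <= 1.0 + 1e-12).all() and (loo <= 1.0 + 1e-12).all()
        assert inc.mean() > loo.mean()


class TestTypicalityEffect:
    def test_null_association_near_zero(self, three_states):
        rng = np.random.default_rng(0)
        n = 200
        vecs = {f"p{i:03d}": 50 + rng.normal(0, 10, 6) for i in range(n)}
        ds = make_dataset(vecs, three_states, loneliness=rng.integers(5, 55, n))
        res = typicality_index(ds, "self")
        eff = typicality_effect(res, ds.participants, "toy")
        assert abs(np.tanh(eff.estimate)) < 2.0 / np.sqrt(n)

    def test_perfect_correlation_guarded(self, three_states):
        # indices exactly equal to loneliness_z -> degenerate r = 1
        from emotrans.typicality import TypicalityResult
        from emotrans.data import standardize

        lz = standardize([10.0, 20.0, 30.0, 40.0])
        parts = pd.DataFrame(
            dict(participant_id=[f"p{i}" for i in range(4)],
                 loneliness_raw=[10.0, 20.0, 30.0, 40.0],
                 loneliness_z=lz, completion_fraction=1.0)
        )
        res = TypicalityResult(
            indices=pd.Series(lz, index=[f"p{i}" for i in range(4)]),
            n_used=4, mode="include_self", target="self", excluded=[],
        )
        with pytest.raises(ValidationError):
            typicality_effect(res, parts, "toy")

    def test_constant_loneliness_error(self, three_states):
        ds = make_dataset(
            {"p1": VEC_A, "p2": list(reversed(VEC_A)), "p3": [v + 5 for v in VEC_A],
             "p4": [v * 0.5 for v in VEC_A]},
            three_states, loneliness=[10, 20, 30, 40],
        )
        ds.participants["loneliness_z"] = 0.0  # force a degenerate trait
        res = typicality_index(ds, "self")
        with pytest.raises(ValidationError):
            typicality_effect(res, ds.participants, "toy")


class TestSimilarityMatrix:
    def test_identical_participants_offdiag_one(self, three_states):
        ds = make_dataset({"p1": VEC_A, "p2": VEC_A, "p3": list(reversed(VEC_A))},
                          three_states)
        sim = similarity_matrix(ds, "self")
        i, j = sim.participant_ids.index("p1"), sim.participant_ids.index("p2")
        assert sim.values[i, j] == pytest.approx(1.0)

    def test_brute_force_oracle(self, three_states):
        rng = np.random.default_rng(5)
        vecs = {f"p{i}": rng.uniform(0, 100, 6) for i in range(5)}
        ds = make_dataset(vecs, three_states)
        sim = similarity_matrix(ds, "self")
        for a in range(5):
            for b in range(5):
                expect = stats.pearsonr(
                    vecs[sim.participant_ids[a]], vecs[sim.participant_ids[b]]
                )[0]
                assert sim.values[a, b] == pytest.approx(expect, abs=1e-12)

    def test_symmetry_and_diagonal(self, null_study):
        sim = similarity_matrix(null_study, "self")
        np.testing.assert_allclose(sim.values, sim.values.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(sim.values), 1.0)


def _null_sim_and_trait(n, rng):
    ratings = rng.normal(50, 10, size=(n, 20))
    vals = np.corrcoef(ratings)
    sim = SimilarityMatrix([f"p{i}" for i in range(n)], 0.5 * (vals + vals.T))
    return sim, rng.normal(size=n)


class TestAkIsrsa:
    def test_p_floor(self):
        # planted structure so extreme that no permutation beats it
        rng = np.random.default_rng(0)
        n = 40
        L = np.sort(rng.normal(size=n))
        base = rng.normal(50, 10, 20)
        ratings = base + np.maximum(L, 0)[:, None] * rng.normal(0, 30, size=(n, 20))
        sim_v = np.corrcoef(ratings)
        sim = SimilarityMatrix([f"p{i}" for i in range(n)], 0.5 * (sim_v + sim_v.T))
        res = ak_isrsa(sim, L, n_perm=999, seed=1)
        assert res.p_perm == pytest.approx(1.0 / 1000.0)
        assert res.rho < 0

    def test_requires_seed_and_min_perm(self):
        rng = np.random.default_rng(2)
        sim, L = _null_sim_and_trait(10, rng)
        with pytest.raises(ValidationError):
            ak_isrsa(sim, L, n_perm=1000, seed=None)
        with pytest.raises(ValidationError):
            ak_isrsa(sim, L, n_perm=50, seed=1)

    def test_constant_trait_error(self):
        rng = np.random.default_rng(3)
        sim, _ = _null_sim_and_trait(10, rng)
        with pytest.raises(ValidationError):
            ak_isrsa(sim, np.zeros(10), n_perm=100, seed=1)

    def test_matches_scipy_spearman(self):
        rng = np.random.default_rng(4)
        sim, L = _null_sim_and_trait(15, rng)
        res = ak_isrsa(sim, L, model="ak_mean", n_perm=100, seed=9)
        rows, cols = np.tril_indices(15, k=-1)
        m = 0.5 * (L[:, None] + L[None, :])
        expect = stats.spearmanr(sim.values[rows, cols], m[rows, cols])[0]
        assert res.rho == pytest.approx(expect, abs=1e-12)

    @pytest.mark.parametrize("model", ["ak_mean", "ak_min", "nn"])
    def test_models_run_and_reproduce(self, model):
        rng = np.random.default_rng(6)
        sim, L = _null_sim_and_trait(12, rng)
        a = ak_isrsa(sim, L, model=model, n_perm=200, seed=5)
        b = ak_isrsa(sim, L, model=model, n_perm=200, seed=5)
        assert a.rho == b.rho and a.p_perm == b.p_perm

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(8)
        sim, L = _null_sim_and_trait(12, rng)
        perm = rng.permutation(12)
        sim2 = SimilarityMatrix(
            [sim.participant_ids[i] for i in perm],
            sim.values[np.ix_(perm, perm)],
        )
        a = ak_isrsa(sim, L, n_perm=500, seed=3)
        b = ak_isrsa(sim2, L[perm], n_perm=500, seed=3)
        assert a.rho == pytest.approx(b.rho, abs=1e-12)
        # same permutation lattice; p-values agree to lattice resolution
        assert abs(a.p_perm - b.p_perm) < 0.05

    def test_null_rejection_rate_light(self):
        # light type-I check (the full 1000-dataset version is in acceptance)
        rng = np.random.default_rng(10)
        rejections = 0
        reps = 200
        for _ in range(reps):
            sim, L = _null_sim_and_trait(16, rng)
            res = ak_isrsa(sim, L, n_perm=199, seed=int(rng.integers(2**31)))
            rejections += res.p_perm <= 0.05
        assert 0.01 <= rejections / reps <= 0.10

    def test_planted_ank_power(self, six_states):
        hits = 0
        for seed in range(10):
            cfg = SyntheticConfig(
                "s", six_states, n_participants=100, include_same_state=False,
                atypicality_gain=0.5, noise_sd=5.0, seed=seed,
            )
            ds = generate_study(cfg)
            sim = similarity_matrix(ds, "self")
            lz = ds.loneliness_z_by_id().loc[sim.participant_ids]
            res = ak_isrsa(sim, lz, n_perm=199, seed=seed)
            hits += (res.rho < 0) and (res.p_perm < 0.05)
        assert hits >= 8

    def test_fisher_pooling_recovers_common_rho(self, six_states):
        # seven same-config studies; pooled back-transformed rho close to
        # the mean of per-study rhos
        effects, rhos = [], []
        for seed in range(7):
            cfg = SyntheticConfig(
                f"s{seed}", six_states, n_participants=80, include_same_state=False,
                atypicality_gain=0.4, noise_sd=5.0, seed=100 + seed,
            )
            ds = generate_study(cfg)
            sim = similarity_matrix(ds, "self")
            lz = ds.loneliness_z_by_id().loc[sim.participant_ids]
            res = ak_isrsa(sim, lz, n_perm=100, seed=seed)
            rhos.append(res.rho)
            effects.append(res.effect(ds.study_id, "isrsa_self"))
        pooled = pool(effects)
        assert pooled.back_transformed == pytest.approx(np.mean(rhos), abs=0.02)
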