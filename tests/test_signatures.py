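import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.stats import rankdata, spearmanr

from cinsig.signatures import (
    assign_activities,
    correlate_with_reference,
    exposure_fractions,
    extract_signatures,
    generalized_kl,
    nmf_kl,
    signature_names,
)
from cinsig.simulate import synthetic_count_matrix


def matched_cosines(W_est: np.ndarray, W_true: np.ndarray) -> np.ndarray:
    """Cosine of optimally matched columns (Hungarian on cosine similarity)."""
    A = W_est / np.maximum(np.linalg.norm(W_est, axis=0), 1e-300)
    B = W_true / np.maximum(np.linalg.norm(W_true, axis=0), 1e-300)
    sim = A.T @ B
    r, c = linear_sum_assignment(-sim)
    return sim[r, c], r, c


class TestNMF:
    def test_noiseless_recovery(self):
        rng = np.random.default_rng(0)
        W0 = rng.gamma(0.5, 1.0, size=(30, 3))
        W0 /= W0.sum(axis=0)
        H0 = rng.gamma(1.0, 50.0, size=(3, 40))
        V = W0 @ H0
        W, H = nmf_kl(V, 3, seed=1, max_iter=5000)
        assert generalized_kl(V, W @ H) < 1e-3 * V.sum()
        cos, _, _ = matched_cosines(W, W0)
        assert cos.min() >= 0.99

    def test_rank_one_is_column_marginal(self):
        rng = np.random.default_rng(2)
        V = rng.poisson(5.0, size=(20, 15)).astype(float)
        W, H = nmf_kl(V, 1, seed=0)
        expected = V.sum(axis=1) / V.sum()
        assert np.allclose(W[:, 0], expected, atol=1e-6)

    def test_same_seed_bit_identical(self):
        rng = np.random.default_rng(3)
        V = rng.poisson(4.0, size=(25, 20)).astype(float)
        W1, H1 = nmf_kl(V, 4, seed=11, max_iter=500)
        W2, H2 = nmf_kl(V, 4, seed=11, max_iter=500)
        assert np.array_equal(W1, W2) and np.array_equal(H1, H2)

    def test_zero_rows_reinserted(self):
        rng = np.random.default_rng(4)
        V = rng.poisson(4.0, size=(20, 15)).astype(float)
        V[5] = 0.0
        with pytest.warns(UserWarning, match="all-zero"):
            W, H = nmf_kl(V, 2, seed=0, max_iter=300)
        assert (W[5] == 0).all()
        assert W.shape == (20, 2)

    def test_columns_l1_normalized(self):
        rng = np.random.default_rng(5)
        V = rng.poisson(6.0, size=(15, 12)).astype(float)
        W, _ = nmf_kl(V, 3, seed=0, max_iter=300)
        assert np.allclose(W.sum(axis=0), 1.0)

    def test_divergence_decreases(self):
        rng = np.random.default_rng(6)
        V = rng.poisson(5.0, size=(20, 20)).astype(float)
        W1, H1 = nmf_kl(V, 3, seed=0, max_iter=50)
        W2, H2 = nmf_kl(V, 3, seed=0, max_iter=2000)
        assert generalized_kl(V, W2 @ H2) <= generalized_kl(V, W1 @ H1) + 1e-9

    def test_bad_rank_rejected(self):
        with pytest.raises(ValueError, match="rank"):
            nmf_kl(np.ones((4, 4)), 5)


class TestExtraction:
    def test_recovers_planted_rank_and_profiles(self):
        V, W_true, H_true = synthetic_count_matrix(3, 60, seed=10)
        sigs, report = extract_signatures(
            V, rank_range=(2, 5), n_bootstraps=10, n_inits=1, seed=1,
            max_iter=2000,
        )
        assert report.selected_rank == 3
        cos, _, _ = matched_cosines(sigs.to_numpy(), W_true.to_numpy())
        assert cos.mean() >= 0.9

    def test_degenerate_single_bootstrap(self):
        V, _, _ = synthetic_count_matrix(2, 20, seed=3)
        sigs, report = extract_signatures(
            V, rank_range=(2, 2), n_bootstraps=1, n_inits=1, seed=1, max_iter=500
        )
        assert sigs.shape[1] == 2
        assert report.selected_rank == 2

    def test_pure_noise_takes_fallback(self):
        rng = np.random.default_rng(8)
        V = pd.DataFrame(rng.poisson(5.0, size=(40, 30)).astype(float))
        _, report = extract_signatures(
            V, rank_range=(2, 4), n_bootstraps=8, n_inits=1, seed=2, max_iter=800
        )
        assert report.fallback_used
        assert all(s < 0.8 for s in report.stability.values() if np.isfinite(s))

    def test_signature_naming(self):
        assert signature_names(3) == ["SCN-A", "SCN-B", "SCN-C"]
        assert signature_names(28)[26] == "SCN-AA"


class TestAssignment:
    def test_single_signature_mixture(self):
        rng = np.random.default_rng(1)
        W = rng.gamma(0.5, 1.0, size=(44, 4))
        W /= W.sum(axis=0)
        sigs = pd.DataFrame(W, index=[f"f{i}" for i in range(44)],
                            columns=list("ABCD"))
        V = pd.DataFrame(100 * W[:, [1]].T, index=["s1"], columns=sigs.index)
        H = assign_activities(V, sigs)
        assert H.loc["s1", "B"] == pytest.approx(100, rel=1e-6)
        assert H.drop(columns="B").loc["s1"].sum() == pytest.approx(0, abs=1e-6)

    def test_noiseless_two_signature_mix(self):
        rng = np.random.default_rng(2)
        W = rng.gamma(0.5, 1.0, size=(44, 3))
        W /= W.sum(axis=0)
        sigs = pd.DataFrame(W, index=[f"f{i}" for i in range(44)],
                            columns=list("ABC"))
        v = 60 * W[:, 0] + 40 * W[:, 2]
        H = assign_activities(pd.DataFrame([v], index=["s"], columns=sigs.index),
                              sigs, prune_threshold=0.0)
        assert H.loc["s", "A"] == pytest.approx(60, rel=1e-6)
        assert H.loc["s", "C"] == pytest.approx(40, rel=1e-6)

    def test_all_zero_sample(self):
        rng = np.random.default_rng(3)
        W = rng.gamma(0.5, 1.0, size=(10, 2))
        W /= W.sum(axis=0)
        sigs = pd.DataFrame(W, index=[f"f{i}" for i in range(10)], columns=["A", "B"])
        V = pd.DataFrame(np.zeros((1, 10)), index=["z"], columns=sigs.index)
        assert (assign_activities(V, sigs).loc["z"] == 0).all()

    def test_layout_mismatch_named(self):
        sigs = pd.DataFrame(np.ones((3, 1)) / 3, index=["a", "b", "c"], columns=["S"])
        V = pd.DataFrame(np.ones((1, 3)), columns=["a", "b", "X"])
        with pytest.raises(ValueError, match="X"):
            assign_activities(V, sigs)

    def test_pruning_drops_spurious_signatures(self):
        rng = np.random.default_rng(4)
        W = rng.gamma(0.5, 1.0, size=(44, 5))
        W /= W.sum(axis=0)
        sigs = pd.DataFrame(W, index=[f"f{i}" for i in range(44)],
                            columns=list("ABCDE"))
        v = 200 * W[:, 0]
        H = assign_activities(pd.DataFrame([v], index=["s"], columns=sigs.index),
                              sigs, prune_threshold=0.01)
        assert (H.loc["s"] > 1e-9).sum() == 1

    def test_extraction_exposures_reproduced_by_assignment(self):
        V, W_true, _ = synthetic_count_matrix(3, 50, seed=21)
        sigs, report = extract_signatures(
            V, rank_range=(3, 3), n_bootstraps=8, n_inits=1, seed=5, max_iter=2000
        )
        H = assign_activities(V, sigs)
        recon = H.to_numpy() @ sigs.to_numpy().T
        rel = np.linalg.norm(V.to_numpy() - recon) / np.linalg.norm(V.to_numpy())
        assert rel < 0.35  # Poisson noise floor dominates the residual


class TestReferenceCorrelation:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(0)
        E = pd.DataFrame(rng.random((10, 2)), columns=["S1", "S2"])
        table = correlate_with_reference(E, E.rename(columns={"S1": "R1", "S2": "R2"}))
        row = table[(table.signature == "S1") & (table.reference == "R1")]
        assert row.rho.iloc[0] == pytest.approx(1.0)

    def test_reversed_ranks_minus_one(self):
        E = pd.DataFrame({"S": [1.0, 2.0, 3.0, 4.0]})
        R = pd.DataFrame({"R": [9.0, 7.0, 5.0, 1.0]})
        table = correlate_with_reference(E, R)
        assert table.rho.iloc[0] == pytest.approx(-1.0)

    def test_constant_vector_gives_nan(self):
        E = pd.DataFrame({"S": [1.0, 1.0, 1.0, 1.0]})
        R = pd.DataFrame({"R": [1.0, 2.0, 3.0, 4.0]})
        assert np.isnan(correlate_with_reference(E, R).rho.iloc[0])

    def test_toy_table_vs_manual_bh(self):
        rng = np.random.default_rng(9)
        E = pd.DataFrame(rng.random((8, 5)), columns=[f"S{i}" for i in range(5)])
        R = pd.DataFrame(rng.random((8, 4)), columns=[f"R{i}" for i in range(4)])
        table = correlate_with_reference(E, R)
        # independent check: rank correlation + hand BH on sorted p-values
        ps = []
        for sig in E.columns:
            for ref in R.columns:
                rho_manual = np.corrcoef(rankdata(E[sig]), rankdata(R[ref]))[0, 1]
                row = table[(table.signature == sig) & (table.reference == ref)]
                assert row.rho.iloc[0] == pytest.approx(rho_manual)
                ps.append(row.p.iloc[0])
        m = len(ps)
        order = np.argsort(ps)
        q_manual = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, ps[i] * m / (rank_idx + 1))
            q_manual[i] = running
        assert np.allclose(table.q.to_numpy(), q_manual)

    def test_too_few_shared_samples(self):
        E = pd.DataFrame({"S": [1.0, 2.0]}, index=["a", "b"])
        R = pd.DataFrame({"R": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(ValueError, match="shared"):
            correlate_with_reference(E, R)


def test_exposure_fractions_rows_sum_to_one():
    E = pd.DataFrame({"A": [2.0, 0.0], "B": [6.0, 0.0]})
    F = exposure_fractions(E)
    assert F.iloc[0].sum() == pytest.approx(1.0)
    assert (F.iloc[1] == 0).all()
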