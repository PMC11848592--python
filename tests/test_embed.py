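import numpy as np
import pytest
from sklearn.metrics import silhouette_score
from sklearn.neighbors import NearestNeighbors

from msiseg import (
    Embedding,
    EncoderParams,
    PhantomSpec,
    TrainConfig,
    compute_fuzzy_memberships,
    encode,
    find_ab_params,
    fit_warmup,
    generate_adjacent_slices,
    generate_phantom,
    project,
    tic_normalize,
    umap_loss,
)
from msiseg.embed import FuzzyMemberships, _BN_EPS
import scipy.sparse as sp

from conftest import random_dataset


class TestAbParams:
    def test_matches_reference_implementation(self):
        import umap

        a, b = find_ab_params(1.0, 0.1)
        a_ref, b_ref = umap.umap_.find_ab_params(1.0, 0.1)
        assert a == pytest.approx(a_ref, rel=1e-3)
        assert b == pytest.approx(b_ref, rel=1e-3)


class TestFuzzyMemberships:
    def test_symmetric_zero_diagonal_unit_range(self, rng):
        X = rng.normal(size=(80, 6))
        fm = compute_fuzzy_memberships(X, n_neighbors=10)
        diff = (fm.matrix - fm.matrix.T).toarray()
        assert np.abs(diff).max() < 1e-12
        assert fm.matrix.diagonal().max() == 0.0
        assert fm.matrix.data.min() >= 0.0 and fm.matrix.data.max() <= 1.0

    def test_rho_is_nearest_neighbor_distance(self, rng):
        X = rng.normal(size=(50, 4))
        fm = compute_fuzzy_memberships(X, n_neighbors=8)
        d, _ = NearestNeighbors(n_neighbors=2).fit(X).kneighbors(X)
        assert np.allclose(fm.rho, d[:, 1])

    def test_calibration_residual_small(self, rng):
        X = rng.normal(size=(200, 10))
        n_neighbors = 15
        fm = compute_fuzzy_memberships(X, n_neighbors=n_neighbors)
        d, _ = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(X).kneighbors(X)
        d = d[:, 1:]
        sums = np.exp(
            -np.maximum(d - fm.rho[:, None], 0.0) / fm.sigma[:, None]
        ).sum(axis=1)
        assert np.abs(sums - np.log2(n_neighbors)).max() <= 1e-4

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError, match="smaller"):
            compute_fuzzy_memberships(rng.normal(size=(5, 3)), n_neighbors=5)

    def test_duplicate_points_handled(self, rng):
        X = np.repeat(rng.normal(size=(4, 3)), 5, axis=0)
        fm = compute_fuzzy_memberships(X, n_neighbors=4)
        assert np.all(np.isfinite(fm.sigma)) and np.all(fm.sigma > 0)


def unit_stats_params(W1, b1, W2, b2):
    h = W1.shape[1]
    return EncoderParams(
        W1=W1, b1=b1, gamma=np.ones(h), beta=np.zeros(h),
        running_mean=np.zeros(h), running_var=np.ones(h), W2=W2, b2=b2,
    )


class TestEncode:
    def test_zero_parameters_give_zero_embedding(self, rng):
        ds = random_dataset(rng, n_ions=6)
        p = unit_stats_params(np.zeros((6, 4)), np.zeros(4),
                              np.zeros((4, 3)), np.zeros(3))
        p.gamma[:] = 0.0
        emb = encode(ds, p)
        assert np.array_equal(emb.values, np.zeros((ds.n_spots, 3)))

    def test_identical_spots_identical_embeddings(self, rng):
        ds = random_dataset(rng, n_ions=6)
        ds.intensities[1] = ds.intensities[0]
        p = unit_stats_params(rng.normal(size=(6, 5)), rng.normal(size=5),
                              rng.normal(size=(5, 3)), rng.normal(size=3))
        emb = encode(ds, p)
        assert np.array_equal(emb.values[0], emb.values[1])

    def test_matches_dense_hand_oracle(self, rng):
        ds = random_dataset(rng, n_rows=1, n_cols=5, n_ions=4)
        W1 = rng.normal(size=(4, 6)); b1 = rng.normal(size=6)
        W2 = rng.normal(size=(6, 2)); b2 = rng.normal(size=2)
        p = unit_stats_params(W1, b1, W2, b2)
        emb = encode(ds, p)
        X = ds.intensities
        hidden = np.maximum((X @ W1 + b1) / np.sqrt(1.0 + _BN_EPS), 0.0)
        expected = hidden @ W2 + b2
        assert np.allclose(emb.values, expected, atol=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        ds = random_dataset(rng, n_ions=6)
        p = unit_stats_params(np.zeros((5, 4)), np.zeros(4),
                              np.zeros((4, 2)), np.zeros(2))
        with pytest.raises(ValueError, match="ions"):
            encode(ds, p)


def memberships_from_dense(P):
    return FuzzyMemberships(sp.csr_matrix(P), 2, np.zeros(len(P)),
                            np.ones(len(P)))


def grid_embedding(values):
    values = np.asarray(values, dtype=float)
    n = len(values)
    pix = np.stack([np.zeros(n, dtype=int), np.arange(n)], axis=1)
    return Embedding(values, (1, n), pix)


class TestUmapLoss:
    def test_zero_when_p_equals_q(self, rng):
        E = rng.normal(size=(6, 2))
        a, b = 1.3, 0.9
        d2 = ((E[:, None] - E[None]) ** 2).sum(-1)
        Q = 1.0 / (1.0 + a * np.maximum(d2, 1e-12) ** b)
        np.fill_diagonal(Q, 0.0)
        loss = umap_loss(memberships_from_dense(Q), grid_embedding(E), a, b)
        assert loss == pytest.approx(0.0, abs=1e-9)

    def test_single_pair_log2(self):
        # two points at distance 1 with a=b=1 -> q = 0.5; p = 1 -> loss log 2
        E = np.array([[0.0, 0.0], [1.0, 0.0]])
        P = np.array([[0.0, 1.0], [1.0, 0.0]])
        loss = umap_loss(memberships_from_dense(P), grid_embedding(E), 1.0, 1.0)
        assert loss == pytest.approx(np.log(2.0), abs=1e-9)

    def test_full_batch_matches_brute_force_double_loop(self, rng):
        n = 20
        E = rng.normal(size=(n, 3))
        P = rng.random((n, n))
        P = np.triu(P, 1)
        P = P + P.T
        a, b = find_ab_params()
        got = umap_loss(memberships_from_dense(P), grid_embedding(E), a, b)
        eps = 1e-7
        expected = 0.0
        for i in range(n):
            for j in range(i + 1, n):
                d2 = np.sum((E[i] - E[j]) ** 2)
                q = np.clip(1.0 / (1.0 + a * d2**b), eps, 1 - eps)
                p = P[i, j]
                if p > 0:
                    expected += p * (np.log(p) - np.log(q))
                if p < 1:
                    expected += (1 - p) * (np.log(1 - p) - np.log(1 - q))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_nonnegative_on_random_instances(self, rng):
        for _ in range(5):
            E = rng.normal(size=(10, 2))
            P = rng.random((10, 10))
            P = np.triu(P, 1); P = P + P.T
            loss = umap_loss(memberships_from_dense(P), grid_embedding(E), 1.5, 0.9)
            assert loss >= 0.0

    def test_invariant_to_spot_relabeling(self, rng):
        n = 12
        E = rng.normal(size=(n, 3))
        P = rng.random((n, n)); P = np.triu(P, 1); P = P + P.T
        perm = rng.permutation(n)
        l1 = umap_loss(memberships_from_dense(P), grid_embedding(E), 1.0, 1.0)
        l2 = umap_loss(memberships_from_dense(P[np.ix_(perm, perm)]),
                       grid_embedding(E[perm]), 1.0, 1.0)
        assert l1 == pytest.approx(l2, abs=1e-9)


class TestWarmupAndProject:
    def test_embedding_beats_raw_silhouette_under_noise(self):
        # the embedding's denoising advantage shows at realistic spot noise;
        # at near-zero noise the raw-space silhouette is already near-ideal
        spec = PhantomSpec(grid_shape=(18, 18), n_regions=3, n_ions=30,
                           enriched_per_region=4, seed=5, spot_noise_cv=0.4)
        ds, truth = generate_phantom(spec)
        ds = tic_normalize(ds)
        cfg = TrainConfig(seed=5, warmup_epochs=400, hidden_dim=64,
                          n_neighbors=10)
        _, emb = fit_warmup(ds, cfg)
        labs = truth.spot_labels(ds.pixel_index)
        s_raw = silhouette_score(ds.intensities, labs)
        s_emb = silhouette_score(emb.values, labs)
        assert s_emb > s_raw

    def test_same_seed_identical_parameters(self, small_phantom, fast_config):
        ds, _, _ = small_phantom
        p1, e1 = fit_warmup(ds, fast_config)
        p2, e2 = fit_warmup(ds, fast_config)
        assert np.array_equal(e1.values, e2.values)
        assert np.array_equal(p1.W1, p2.W1)
        assert np.array_equal(p1.running_mean, p2.running_mean)

    def test_single_region_phantom_trains_to_finite_embedding(self):
        spec = PhantomSpec(grid_shape=(12, 12), n_regions=1, n_ions=20,
                           enriched_per_region=2, seed=2)
        ds, _ = generate_phantom(spec)
        cfg = TrainConfig(seed=2, warmup_epochs=30, hidden_dim=32,
                          n_neighbors=8)
        _, emb = fit_warmup(ds, cfg)
        assert np.all(np.isfinite(emb.values))

    def test_project_equals_encode_on_training_data(self, small_phantom, fast_config):
        ds, _, _ = small_phantom
        params, emb = fit_warmup(ds, fast_config)
        proj = project(ds, params, mz_train=ds.mz)
        assert np.array_equal(proj.values, emb.values)

    def test_project_rejects_mismatched_axis(self, small_phantom, fast_config):
        ds, _, _ = small_phantom
        params, _ = fit_warmup(ds, fast_config)
        with pytest.raises(ValueError, match="re-align"):
            project(ds, params, mz_train=ds.mz + 1.0)

    def test_batch_shifted_slice_keeps_region_centroids(self):
        spec = PhantomSpec(grid_shape=(24, 24), n_regions=3, n_ions=30,
                           enriched_per_region=4, batch_log_sd=0.2, seed=3)
        series = generate_adjacent_slices(spec, 2, 0.0)
        (dsA, trA), (dsB, trB) = series
        dsA, dsB = tic_normalize(dsA), tic_normalize(dsB)
        cfg = TrainConfig(seed=3, warmup_epochs=150, hidden_dim=64,
                          n_neighbors=10)
        params, embA = fit_warmup(dsA, cfg)
        embB = project(dsB, params, mz_train=dsA.mz)
        labsA = trA.spot_labels(dsA.pixel_index)
        labsB = trB.spot_labels(dsB.pixel_index)
        regions = np.unique(labsA)
        centroids = np.stack([embA.values[labsA == r].mean(axis=0)
                              for r in regions])
        d = np.linalg.norm(embB.values[:, None, :] - centroids[None], axis=2)
        assigned = regions[np.argmin(d, axis=1)]
        assert np.mean(assigned == labsB) >= 0.8


def test_embedding_csv_export(rng, tmp_path):
    import pandas as pd

    emb = grid_embedding(rng.normal(size=(6, 3)))
    emb.save_csv(tmp_path / "emb.csv")
    df = pd.read_csv(tmp_path / "emb.csv")
    assert list(df.columns) == ["row", "col", "e_1", "e_2", "e_3"]
    assert np.allclose(df[["e_1", "e_2", "e_3"]].to_numpy(), emb.values)
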