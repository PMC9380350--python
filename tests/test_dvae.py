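import numpy as np
import pytest
from scipy import special, stats

from bindvae import dvae, kmer_space


def make_model(vocab, M=5, seed=0, dtype=np.float64):
    rng = np.random.default_rng(seed)
    model = dvae.BindVAEModel.initialize(
        vocab.D, M, alpha_init=10.0, vocab_signature=vocab.signature,
        rng=rng, dtype=dtype)
    model.vocabulary = vocab
    return model


# -- encoder -----------------------------------------------------------------


def test_encode_always_positive(vocab4):
    model = make_model(vocab4)
    rng = np.random.default_rng(1)
    x = rng.integers(0, 10, size=(20, vocab4.D))
    alpha = dvae.encode(x, model)
    assert alpha.shape == (20, 5)
    assert (alpha > 0).all()


def test_encode_zero_vector_depends_only_on_biases(vocab4):
    model = make_model(vocab4)
    z0 = dvae.encode(np.zeros(vocab4.D), model)
    model.params["W1"] = model.params["W1"] * 2  # weights irrelevant at x=0
    assert np.allclose(dvae.encode(np.zeros(vocab4.D), model), z0)


def test_encode_deterministic(vocab4):
    model = make_model(vocab4)
    x = np.random.default_rng(2).integers(0, 5, size=vocab4.D)
    assert np.array_equal(dvae.encode(x, model), dvae.encode(x, model))


def test_encode_rejects_negative_counts(vocab4):
    model = make_model(vocab4)
    with pytest.raises(ValueError):
        dvae.encode(-np.ones(vocab4.D), model)


# -- latent sampling ---------------------------------------------------------


def test_sample_latent_on_simplex():
    rng = np.random.default_rng(0)
    z = dvae.sample_latent(np.array([0.5, 2.0, 7.0]), rng)
    assert z.shape == (3,)
    assert abs(z.sum() - 1) < 1e-6
    assert (z >= 0).all()


def test_sample_latent_mean_matches_dirichlet():
    rng = np.random.default_rng(1)
    alpha = np.array([5.0, 1.0, 1.0])
    draws = dvae.sample_latent(np.tile(alpha, (100_000, 1)), rng)
    mean = draws.mean(axis=0)
    expected = alpha / alpha.sum()
    # Dirichlet component variance / 1e5 draws -> ~3 standard errors
    se = np.sqrt(expected * (1 - expected) / (alpha.sum() + 1) / 100_000)
    assert (np.abs(mean - expected) < 3 * se + 1e-4).all()


def test_sample_latent_concentrates():
    rng = np.random.default_rng(2)
    draws = dvae.sample_latent(
        np.tile([1000.0, 1.0, 1.0], (200, 1)), rng)
    assert (draws[:, 0] > 0.9).mean() > 0.99


def test_sample_latent_rejects_nonpositive():
    with pytest.raises(ValueError):
        dvae.sample_latent(np.array([1.0, 0.0]), np.random.default_rng(0))


# -- decoder -----------------------------------------------------------------


def test_decode_one_hot_returns_theta_row(vocab4):
    model = make_model(vocab4)
    z = np.zeros(5)
    z[2] = 1.0
    assert np.allclose(dvae.decode(z, model), model.theta[2])


def test_decode_uniform_is_column_mean(vocab4):
    model = make_model(vocab4)
    p = dvae.decode(np.full(5, 0.2), model)
    assert np.allclose(p, model.theta.mean(axis=0))
    assert abs(p.sum() - 1) < 1e-6


def test_decoded_rows_normalize(vocab4):
    model = make_model(vocab4)
    rng = np.random.default_rng(3)
    z = rng.dirichlet(np.ones(5), size=50)
    p = dvae.decode(z, model)
    assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)
    assert (p > 0).all()


# -- KL ----------------------------------------------------------------------


def test_dirichlet_kl_self_is_zero():
    a = np.array([2.0, 1.0, 0.5])
    assert abs(dvae.dirichlet_kl(a, a)) < 1e-12


def _mc_kl(a, b, n, seed):
    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(a, size=n)
    return np.mean(stats.dirichlet.logpdf(samples.T, a)
                   - stats.dirichlet.logpdf(samples.T, b))


def test_dirichlet_kl_matches_monte_carlo_example():
    a, b = np.array([2.0, 1.0]), np.array([1.0, 1.0])
    closed = dvae.dirichlet_kl(a, b)
    mc = _mc_kl(a, b, 1_000_000, seed=4)
    assert abs(closed - mc) / abs(mc) < 1e-2


@pytest.mark.parametrize("seed", range(5))
def test_dirichlet_kl_matches_monte_carlo_random(seed):
    rng = np.random.default_rng(100 + seed)
    M = int(rng.integers(2, 6))
    a = rng.uniform(0.1, 50, M)
    b = rng.uniform(0.1, 50, M)
    closed = dvae.dirichlet_kl(a, b)
    mc = _mc_kl(a, b, 200_000, seed=seed)
    assert abs(closed - mc) / max(abs(mc), 0.05) < 2e-2


def test_elbo_uniform_decoder_reconstruction(vocab4):
    model = make_model(vocab4, M=3)
    model.params["decoder_logits"] = np.zeros((3, vocab4.D))
    x = np.random.default_rng(5).integers(0, 4, size=vocab4.D).astype(float)
    z = np.array([0.2, 0.5, 0.3])
    alpha_hat = model.prior_alpha  # KL term vanishes
    loss = dvae.elbo_loss(x, alpha_hat, z, model)
    assert np.isclose(loss, x.sum() * np.log(vocab4.D), rtol=1e-10)


# -- gradients ---------------------------------------------------------------


def test_decoder_gradient_matches_finite_difference(vocab2):
    model = make_model(vocab2, M=4, dtype=np.float64)
    rng = np.random.default_rng(6)
    x = rng.integers(0, 6, size=(1, vocab2.D)).astype(np.float64)
    g = rng.standard_gamma(np.full((1, 4), 3.0))
    _, grads, _ = dvae._loss_and_grads(model, x, g=g)
    h = 1e-6
    for i, j in [(0, 1), (1, 5), (2, 9), (3, 0), (0, 14)]:
        model.params["decoder_logits"][i, j] += h
        lp, _, _ = dvae._loss_and_grads(model, x, g=g)
        model.params["decoder_logits"][i, j] -= 2 * h
        lm, _, _ = dvae._loss_and_grads(model, x, g=g)
        model.params["decoder_logits"][i, j] += h
        fd = (lp - lm) / (2 * h)
        assert abs(fd - grads["decoder_logits"][i, j]) <= 1e-3 * max(abs(fd), 1e-6)


def test_gamma_implicit_gradient_matches_inverse_cdf():
    rng = np.random.default_rng(7)
    a = rng.uniform(0.2, 50, 500)
    u = rng.uniform(0.01, 0.99, 500)
    g = special.gammaincinv(a, u)
    h = 1e-5 * a
    fd = (special.gammaincinv(a + h, u) - special.gammaincinv(a - h, u)) / (2 * h)
    imp = dvae._gamma_implicit_grad(g, a)
    assert (np.abs(fd - imp) / np.maximum(np.abs(fd), 1e-12) < 1e-3).all()


# -- training ----------------------------------------------------------------


def test_training_reduces_loss(tiny_model):
    trace = tiny_model["trace"]
    n = len(trace)
    head = trace.loss.iloc[: max(1, n // 10)].mean()
    tail = trace.loss.iloc[-max(1, n // 10):].mean()
    assert tail < head


def test_burn_in_freezes_prior(tiny_world):
    config = dvae.TrainConfig(alpha_init=10.0, burn_in_steps=100,
                              max_steps=100, batch_size=32,
                              learning_rate=3e-4, seed=8, M=4, log_every=50)
    model, _ = dvae.train(tiny_world["counts"], config)
    assert np.allclose(model.params["prior_log_alpha"], np.log(10.0))


def test_prior_moves_after_burn_in(tiny_world):
    config = dvae.TrainConfig(alpha_init=10.0, burn_in_steps=20,
                              max_steps=120, batch_size=32,
                              learning_rate=1e-2, seed=8, M=4, log_every=50)
    model, _ = dvae.train(tiny_world["counts"], config)
    assert not np.allclose(model.params["prior_log_alpha"], np.log(10.0))


def test_training_is_deterministic(tiny_world):
    config = dvae.TrainConfig(alpha_init=10.0, burn_in_steps=50,
                              max_steps=100, batch_size=32,
                              learning_rate=3e-4, seed=9, M=4, log_every=10)
    _, trace1 = dvae.train(tiny_world["counts"], config)
    _, trace2 = dvae.train(tiny_world["counts"], config)
    assert trace1.loss.tolist() == trace2.loss.tolist()


def test_training_rejects_empty_counts(vocab4):
    from scipy import sparse

    empty = kmer_space.KmerCountMatrix(
        entries=sparse.csr_matrix((0, vocab4.D), dtype=np.int64),
        vocabulary=vocab4, row_ids=[])
    with pytest.raises(ValueError):
        dvae.train(empty, dvae.TrainConfig(max_steps=10, M=2))


# -- inference ---------------------------------------------------------------


def test_infer_posterior_mean_rows_normalized(tiny_world, tiny_model):
    latent = dvae.infer(tiny_world["counts"], tiny_model["model"])
    assert latent.mode == "posterior_mean"
    assert np.allclose(latent.rows.sum(axis=1), 1.0, atol=1e-6)


def test_infer_posterior_mean_deterministic(tiny_world, tiny_model):
    l1 = dvae.infer(tiny_world["counts"], tiny_model["model"])
    l2 = dvae.infer(tiny_world["counts"], tiny_model["model"])
    assert np.array_equal(l1.rows, l2.rows)


def test_infer_sampled_mean_converges_to_posterior_mean(tiny_world, tiny_model):
    model = tiny_model["model"]
    counts = tiny_world["counts"]
    mean = dvae.infer(counts, model).rows[0]
    alpha = np.atleast_2d(dvae.encode(counts.row(0).astype(model.dtype), model))
    rng = np.random.default_rng(10)
    draws = dvae.sample_latent(np.tile(alpha, (10_000, 1)), rng)
    a0 = alpha.sum()
    se = np.sqrt(mean * (1 - mean) / (a0 + 1) / 10_000)
    assert (np.abs(draws.mean(axis=0) - mean) < 3 * se + 1e-4).all()


def test_infer_rejects_vocabulary_mismatch(tiny_world, tiny_model, vocab6):
    rng = np.random.default_rng(11)
    seqs = ["".join(rng.choice(list("ACGT"), 40)) for _ in range(3)]
    other = kmer_space.featurize_many(seqs, vocab6)
    with pytest.raises(dvae.VocabularyMismatchError):
        dvae.infer(other, tiny_model["model"])


def test_infer_sampled_requires_rng(tiny_world, tiny_model):
    with pytest.raises(ValueError):
        dvae.infer(tiny_world["counts"], tiny_model["model"], mode="sampled")


# -- checkpoints -------------------------------------------------------------


def test_checkpoint_round_trip(tmp_path, tiny_model, tiny_world):
    model = tiny_model["model"]
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = dvae.BindVAEModel.load(path)
    for key, value in model.params.items():
        assert np.array_equal(loaded.params[key], value)
    assert loaded.vocab_signature == model.vocab_signature
    assert loaded.vocabulary.D == tiny_world["vocab"].D
    l1 = dvae.infer(tiny_world["counts"], model)
    l2 = dvae.infer(tiny_world["counts"], loaded)
    assert np.array_equal(l1.rows, l2.rows)


# -- ensemble selection ------------------------------------------------------


def _stub_mapping_stage(monkeypatch, tf_sets_by_model):
    """Make each candidate model map a prescribed TF set, so the selection
    and aggregation logic is exercised in isolation."""
    from bindvae import tf_mapping

    def fake_infer(counts, model, mode="posterior_mean", **kw):
        return dvae.LatentMatrix(
            rows=np.full((counts.n_rows, 2), 0.5), mode=mode)

    def fake_map(latent, probes, p_threshold=0.05, **kw):
        tfs = tf_sets_by_model[fake_map.calls]
        fake_map.calls += 1
        return tf_mapping.TFMapping(
            entries=[(i, t, 0.01) for i, t in enumerate(sorted(tfs))])

    fake_map.calls = 0
    monkeypatch.setattr(dvae, "infer", fake_infer)
    monkeypatch.setattr(tf_mapping, "map_dimensions_to_tfs", fake_map)


def _probe_counts(vocab2):
    seqs = ["AAAAAAAA"] * 8 + ["ACACACAC"] * 8
    return kmer_space.featurize_many(seqs, vocab2), ["A"] * 8 + ["B"] * 8


def test_select_ensemble_keeps_top3_and_unions(vocab2, monkeypatch):
    counts, labels = _probe_counts(vocab2)
    models = [make_model(vocab2, M=2, seed=s) for s in range(4)]
    for m in models:
        m.final_loss = 1.0
    _stub_mapping_stage(
        monkeypatch, [{"A", "B"}, {"B", "C"}, {"C"}, set()])
    top, union = dvae.select_ensemble(models, counts, labels)
    assert top == models[:3]
    assert union == {"A", "B", "C"}


def test_select_ensemble_single_model(vocab2, monkeypatch):
    counts, labels = _probe_counts(vocab2)
    model = make_model(vocab2, M=2)
    _stub_mapping_stage(monkeypatch, [{"A"}])
    top, union = dvae.select_ensemble([model], counts, labels)
    assert top == [model]
    assert union == {"A"}


def test_select_ensemble_tie_broken_by_loss(vocab2, monkeypatch):
    counts, labels = _probe_counts(vocab2)
    m_high = make_model(vocab2, M=2, seed=0)
    m_high.final_loss = 9.0
    m_low = make_model(vocab2, M=2, seed=1)
    m_low.final_loss = 1.0
    _stub_mapping_stage(monkeypatch, [{"A"}, {"B"}])
    top, _ = dvae.select_ensemble([m_high, m_low], counts, labels)
    assert top[0] is m_low
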