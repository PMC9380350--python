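import numpy as np
import pytest

from bindvae import dvae, kmer_space, synthetic


@pytest.fixture(scope="session")
def vocab2():
    return kmer_space.build_vocabulary(2, 2)


@pytest.fixture(scope="session")
def vocab4():
    return kmer_space.build_vocabulary(4, 2)


@pytest.fixture(scope="session")
def vocab6():
    return kmer_space.build_vocabulary(6, 2)


@pytest.fixture(scope="session")
def tiny_world():
    """A small seeded synthetic world: 2 motifs, 300 peaks of 120 bp, k=4.

    Small enough that training a few hundred steps takes seconds; used by
    optimization-sanity and pipeline tests.
    """
    rng = np.random.default_rng(123)
    names, pwms = synthetic.make_toy_motifs(
        2, length_range=(6, 7), sharpness=0.95, rng=rng)
    seqs, truth = synthetic.simulate_peaks(
        names, pwms, n_peaks=300, length=120, alpha_true=1.0, seed=124)
    vocab = kmer_space.build_vocabulary(4, 2)
    counts = kmer_space.featurize_many(
        seqs, vocab, row_ids=[r.peak_id for r in truth.records])
    return {"names": names, "pwms": pwms, "sequences": seqs,
            "truth": truth, "vocab": vocab, "counts": counts}


@pytest.fixture(scope="session")
def tiny_model(tiny_world):
    """Model trained briefly on the tiny world (seconds)."""
    config = dvae.TrainConfig(
        alpha_init=10.0, burn_in_steps=200, max_steps=400, batch_size=64,
        learning_rate=3e-4, seed=7, M=5, log_every=10)
    model, trace = dvae.train(tiny_world["counts"], config)
    return {"model": model, "trace": trace, "config": config}
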