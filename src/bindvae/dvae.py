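"""Dirichlet variational autoencoder over bag-of-k-mers counts.

Generative model: each accessible region i has latent topic proportions
z_i ~ Dirichlet(alpha) on the M-simplex; its bag of k-mers x_i is multinomial
with probabilities p_i = z_i^T theta, where row m of theta is a distribution
over the D k-mer features (one "binding pattern" per latent dimension).  The
encoder is a 3-layer fully connected network (300 units per layer) mapping a
count vector to the concentration vector alpha_hat of the variational
posterior Dirichlet(alpha_hat).  Training maximizes the ELBO

    E_q[log p(x|z)] - KL(Dirichlet(alpha_hat) || Dirichlet(alpha))

with one Monte-Carlo sample of z per example per step, drawn through the
Gamma composition z_m = g_m / sum_j g_j, g_m ~ Gamma(alpha_hat_m, 1).
Gradients of the sample with respect to the concentrations use implicit
reparameterization: dg/da = -(dF/da) / f(g; a) with F the regularized
incomplete gamma CDF (the d/da derivative is taken by central difference)
and f the Gamma density.  The Dirichlet KL and its gradients are closed
form (log-gamma, digamma, trigamma terms).  The prior concentration is kept
frozen for a burn-in period, then optimized in log-space alongside the
network.  Everything runs in numpy/scipy with analytic backpropagation and
a hand-rolled Adam update; all randomness flows from a single seeded
generator, so training is deterministic given a seed and thread count.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import sparse, special

from bindvae.kmer_space import KmerCountMatrix

_EPS_CONC = 1e-4  # floor added to softplus output; keeps alpha_hat positive
_HIDDEN = 300
_N_HIDDEN_LAYERS = 3


class TrainingInstabilityError(RuntimeError):
    """Raised when the loss or activations become non-finite."""


class VocabularyMismatchError(ValueError):
    """Counts were built on a different vocabulary than the model."""


@dataclass
class TrainConfig:
    """Training hyperparameters.

    ``alpha_init`` is the shared initial prior concentration (the prior is
    alpha * 1 across the M dimensions); it stays frozen for
    ``burn_in_steps`` optimizer steps and is then optimized in log-space.
    Defaults follow the reference setting: Adam at 3e-4, batches of 128,
    burn-in 150k of at most 300k steps, alpha_init 10.
    """

    alpha_init: float = 10.0
    burn_in_steps: int = 150_000
    max_steps: int = 300_000
    batch_size: int = 128
    learning_rate: float = 3e-4
    seed: int = 0
    M: int = 100
    log_every: int = 50

    def __post_init__(self):
        if self.burn_in_steps > self.max_steps:
            # legal: the prior simply stays frozen for the whole run
            pass
        for name in ("alpha_init", "max_steps", "batch_size",
                     "learning_rate", "M", "log_every"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.burn_in_steps < 0:
            raise ValueError("burn_in_steps must be >= 0")


@dataclass
class LatentMatrix:
    """N x M matrix of latent score vectors, rows on the probability simplex."""

    rows: np.ndarray
    mode: str  # "posterior_mean" | "sampled"
    row_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.mode not in ("posterior_mean", "sampled"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.rows = np.asarray(self.rows, dtype=np.float64)
        if not self.row_ids:
            self.row_ids = [f"row{i}" for i in range(self.rows.shape[0])]

    @property
    def n(self) -> int:
        return self.rows.shape[0]

    @property
    def M(self) -> int:
        return self.rows.shape[1]


class BindVAEModel:
    """Encoder weights, decoder logits and prior concentration.

    ``params`` maps parameter names to numpy arrays: W1/b1 .. W3/b3 for the
    three hidden layers, Wout/bout for the concentration head,
    ``decoder_logits`` (M x D, row-softmaxed into theta) and
    ``prior_log_alpha`` (length M).
    """

    def __init__(self, params: dict[str, np.ndarray], vocab_signature: str,
                 dtype=np.float32, vocabulary=None):
        self.params = {k: np.asarray(v, dtype=dtype) for k, v in params.items()}
        self.vocab_signature = vocab_signature
        self.dtype = np.dtype(dtype)
        self.final_loss: float | None = None
        self.vocabulary = vocabulary  # KmerVocabulary, optional

    @classmethod
    def initialize(cls, D: int, M: int, alpha_init: float,
                   vocab_signature: str, rng: np.random.Generator,
                   dtype=np.float32,
                   decoder_init_logp: np.ndarray | None = None) -> "BindVAEModel":
        """Fresh parameters.  ``decoder_init_logp`` (length D) initializes
        every decoder row near a common log-distribution — typically the
        corpus k-mer log-frequency — so rows start by explaining the shared
        background and differentiate from there; without it rows start near
        uniform."""
        widths = [D] + [_HIDDEN] * _N_HIDDEN_LAYERS
        params: dict[str, np.ndarray] = {}
        for i in range(_N_HIDDEN_LAYERS):
            fan_in, fan_out = widths[i], widths[i + 1]
            params[f"W{i + 1}"] = rng.normal(
                0.0, np.sqrt(2.0 / (fan_in + fan_out)), size=(fan_in, fan_out))
            params[f"b{i + 1}"] = np.zeros(fan_out)
        params["Wout"] = rng.normal(
            0.0, np.sqrt(2.0 / (_HIDDEN + M)), size=(_HIDDEN, M))
        params["bout"] = np.zeros(M)
        noise = 0.01 * rng.normal(size=(M, D))
        if decoder_init_logp is not None:
            base = np.asarray(decoder_init_logp, dtype=np.float64)
            params["decoder_logits"] = base[None, :] + noise
        else:
            params["decoder_logits"] = noise
        params["prior_log_alpha"] = np.full(M, np.log(alpha_init))
        return cls(params, vocab_signature, dtype=dtype)

    @property
    def M(self) -> int:
        return self.params["decoder_logits"].shape[0]

    @property
    def D(self) -> int:
        return self.params["decoder_logits"].shape[1]

    @property
    def prior_alpha(self) -> np.ndarray:
        return np.exp(self.params["prior_log_alpha"].astype(np.float64))

    @property
    def theta(self) -> np.ndarray:
        """Row-softmax of the decoder logits: M distributions over k-mers."""
        logits = self.params["decoder_logits"].astype(np.float64)
        logits = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        meta = {
            "vocab_signature": self.vocab_signature,
            "dtype": self.dtype.name,
            "final_loss": self.final_loss,
        }
        if self.vocabulary is not None:
            meta["vocab_k"] = self.vocabulary.k
            meta["vocab_max_run"] = self.vocabulary.max_run
        np.savez_compressed(path, _meta=np.array(json.dumps(meta)),
                            **self.params)

    @classmethod
    def load(cls, path) -> "BindVAEModel":
        with np.load(path, allow_pickle=False) as archive:
            meta = json.loads(str(archive["_meta"]))
            params = {k: archive[k] for k in archive.files if k != "_meta"}
        vocab = None
        if "vocab_k" in meta:
            from bindvae.kmer_space import build_vocabulary

            vocab = build_vocabulary(meta["vocab_k"], meta["vocab_max_run"])
            if vocab.signature != meta["vocab_signature"]:
                raise VocabularyMismatchError(
                    "rebuilt vocabulary does not match checkpoint signature")
        model = cls(params, meta["vocab_signature"],
                    dtype=np.dtype(meta["dtype"]), vocabulary=vocab)
        model.final_loss = meta.get("final_loss")
        return model


# ---------------------------------------------------------------------------
# Forward pieces


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _encoder_forward(params: dict, x: np.ndarray):
    """Returns alpha_hat and the intermediate activations for backprop."""
    h = x
    acts = [x]
    for i in range(1, _N_HIDDEN_LAYERS + 1):
        h = np.maximum(h @ params[f"W{i}"] + params[f"b{i}"], 0.0)
        acts.append(h)
    pre = h @ params["Wout"] + params["bout"]
    alpha_hat = _softplus(pre) + _EPS_CONC
    if not np.all(np.isfinite(alpha_hat)):
        raise TrainingInstabilityError("non-finite encoder activations")
    return alpha_hat, pre, acts


def encode(x: np.ndarray, model: BindVAEModel) -> np.ndarray:
    """Posterior Dirichlet concentrations alpha_hat = softplus(MLP(x)) + eps.

    Accepts a single count vector or an (N, D) batch; always positive.
    """
    x = np.atleast_2d(np.asarray(x, dtype=model.dtype))
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    alpha_hat, _, _ = _encoder_forward(model.params, x)
    return alpha_hat.astype(np.float64).squeeze()


def sample_latent(alpha_hat: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One Dirichlet(alpha_hat) draw via normalized Gamma variables."""
    alpha_hat = np.asarray(alpha_hat, dtype=np.float64)
    if np.any(alpha_hat <= 0):
        raise ValueError("concentrations must be strictly positive")
    g = rng.standard_gamma(alpha_hat)
    g = np.maximum(g, 1e-300)
    return g / g.sum(axis=-1, keepdims=True)


def decode(z: np.ndarray, model: BindVAEModel) -> np.ndarray:
    """Mixture distribution over k-mers: p = z^T theta."""
    z = np.asarray(z, dtype=np.float64)
    return z @ model.theta


def dirichlet_kl(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Closed-form KL(Dirichlet(a) || Dirichlet(b)), broadcast over rows."""
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.broadcast_to(np.asarray(b, dtype=np.float64), a.shape)
    sa = a.sum(axis=1)
    sb = b.sum(axis=1)
    kl = (special.gammaln(sa) - special.gammaln(a).sum(axis=1)
          + special.gammaln(b).sum(axis=1) - special.gammaln(sb)
          + ((a - b) * (special.digamma(a)
                        - special.digamma(sa)[:, None])).sum(axis=1))
    return kl.squeeze()


def elbo_loss(x: np.ndarray, alpha_hat: np.ndarray, z: np.ndarray,
              model: BindVAEModel) -> float:
    """Negative ELBO for given counts, posterior concentrations and latent
    sample: multinomial reconstruction term plus Dirichlet KL, summed over
    the batch."""
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    p = decode(z, model)
    recon = -(x * np.log(p + 1e-300)).sum()
    kl = np.atleast_1d(dirichlet_kl(alpha_hat, model.prior_alpha)).sum()
    return float(recon + kl)


# ---------------------------------------------------------------------------
# Backward pass


def _gamma_implicit_grad(g: np.ndarray, a: np.ndarray) -> np.ndarray:
    """dg/da for g ~ Gamma(a, 1) by implicit differentiation of the CDF:
    dg/da = -(dF/da) / f(g; a), with dF/da by central finite difference."""
    h = 1e-4 * a + 1e-7
    dFda = (special.gammainc(a + h, g) - special.gammainc(a - h, g)) / (2 * h)
    log_pdf = (a - 1) * np.log(np.maximum(g, 1e-300)) - g - special.gammaln(a)
    pdf = np.exp(np.clip(log_pdf, -700, 700))
    return -dFda / np.maximum(pdf, 1e-300)


def _loss_and_grads(model: BindVAEModel, x: np.ndarray,
                    rng: np.random.Generator | None = None,
                    g: np.ndarray | None = None):
    """Negative-ELBO (mean per example) and gradients for one minibatch.

    If ``g`` (the Gamma draws) is supplied the pass is deterministic, which
    is what finite-difference gradient checks use; otherwise one sample per
    example is drawn from ``rng``.
    """
    params = model.params
    B = x.shape[0]
    alpha_hat, pre, acts = _encoder_forward(params, x)
    alpha_hat = alpha_hat.astype(np.float64)
    if g is None:
        g = rng.standard_gamma(alpha_hat)
    g = np.maximum(np.asarray(g, dtype=np.float64), 1e-300)
    S = g.sum(axis=1, keepdims=True)
    z = g / S

    # decoder forward in float64 for a stable softmax/likelihood
    logits = params["decoder_logits"].astype(np.float64)
    logits = logits - logits.max(axis=1, keepdims=True)
    expl = np.exp(logits)
    theta = expl / expl.sum(axis=1, keepdims=True)
    p = z @ theta
    xf = np.asarray(x, dtype=np.float64)
    recon = -(xf * np.log(p + 1e-300)).sum()

    b = np.exp(params["prior_log_alpha"].astype(np.float64))
    kl = np.atleast_1d(dirichlet_kl(alpha_hat, b)).sum()
    loss = (recon + kl) / B

    # --- backward ---
    grads: dict[str, np.ndarray] = {}
    dp = -xf / np.maximum(p, 1e-300) / B          # (B, D)
    dz = dp @ theta.T                             # (B, M)
    dtheta = z.T @ dp                             # (M, D)
    grads["decoder_logits"] = theta * (
        dtheta - (dtheta * theta).sum(axis=1, keepdims=True))

    # z = g / S  ->  dL/dg
    dg = (dz - (dz * z).sum(axis=1, keepdims=True)) / S

    # implicit reparameterization through the Gamma draws
    dalpha = dg * _gamma_implicit_grad(g, alpha_hat)

    # closed-form KL gradients
    sa = alpha_hat.sum(axis=1, keepdims=True)
    diff = alpha_hat - b[None, :]
    dalpha += (diff * special.polygamma(1, alpha_hat)
               - special.polygamma(1, sa) * diff.sum(axis=1, keepdims=True)) / B
    dkl_db = (special.digamma(b) - special.digamma(b.sum())
              - special.digamma(alpha_hat) + special.digamma(sa)).sum(axis=0) / B
    grads["prior_log_alpha"] = dkl_db * b

    # softplus head
    dpre = dalpha * special.expit(pre.astype(np.float64))
    dpre = dpre.astype(np.float64)
    grads["Wout"] = acts[-1].astype(np.float64).T @ dpre
    grads["bout"] = dpre.sum(axis=0)
    dh = dpre @ params["Wout"].T.astype(np.float64)
    for i in range(_N_HIDDEN_LAYERS, 0, -1):
        dh = dh * (acts[i] > 0)
        grads[f"W{i}"] = acts[i - 1].astype(np.float64).T @ dh
        grads[f"b{i}"] = dh.sum(axis=0)
        if i > 1:
            dh = dh @ params[f"W{i}"].T.astype(np.float64)

    aux = {"recon": recon / B, "kl": kl / B, "alpha_hat": alpha_hat, "z": z}
    return loss, grads, aux


class _Adam:
    """Adam with optional decoupled (AdamW-style) per-parameter weight decay.

    The input-layer decay exists for out-of-distribution robustness: k-mer
    features absent from (or rare in) the training corpus never receive
    gradient, so their random initialization weights would otherwise survive
    training and inject noise when short sequences built on those features
    are scored.  The decay rate is calibrated so a gradient-free weight
    shrinks by roughly an order of magnitude across a training schedule,
    while the decay equilibrium for any consistently-updated weight
    (|w| ~ 1/lambda) sits far above the working weight scale, leaving
    learned weights untouched.
    """

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1=0.9, beta2=0.999, eps=1e-8,
                 weight_decay: dict[str, float] | None = None):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.weight_decay = weight_decay or {}
        self.m = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.v = {k: np.zeros_like(v, dtype=np.float64) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray],
             frozen: set[str]):
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for k, gval in grads.items():
            if k in frozen:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * gval
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * gval**2
            w = params[k].astype(np.float64)
            update = self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t)
                                                    + self.eps)
            decay = self.weight_decay.get(k, 0.0)
            if decay:
                update = update + self.lr * decay * w
            params[k] = (w - update).astype(params[k].dtype)


def train(counts: KmerCountMatrix, config: TrainConfig,
          dtype=np.float32) -> tuple[BindVAEModel, pd.DataFrame]:
    """Fit the model by minibatch stochastic optimization of the negative
    ELBO.

    The prior concentration stays frozen at ``alpha_init`` for
    ``burn_in_steps`` steps and is optimized in log-space afterwards.
    Returns the fitted model and a loss trace (step, loss, recon, kl; the
    per-example means) sampled every ``log_every`` steps.
    """
    if counts.n_rows == 0:
        raise ValueError("empty count matrix")
    rng = np.random.default_rng(config.seed)
    # decoder rows start at the corpus k-mer log-frequency: the shared
    # background is explained immediately and training differentiates rows
    freq = np.asarray(counts.entries.sum(axis=0), dtype=np.float64).ravel()
    logp = np.log(freq + 1.0)
    logp -= logp.max()
    model = BindVAEModel.initialize(
        D=counts.vocabulary.D, M=config.M, alpha_init=config.alpha_init,
        vocab_signature=counts.vocabulary.signature, rng=rng, dtype=dtype,
        decoder_init_logp=logp)
    model.vocabulary = counts.vocabulary
    # input-layer decay calibrated to the schedule: a weight with no
    # gradient decays 10x over max_steps, a learned weight is unaffected
    w1_decay = np.log(10.0) / (config.learning_rate * config.max_steps)
    opt = _Adam(model.params, config.learning_rate,
                weight_decay={"W1": w1_decay})
    X = counts.entries.tocsr()
    trace: list[dict] = []
    for step in range(config.max_steps):
        idx = rng.integers(0, counts.n_rows, size=config.batch_size)
        batch = np.asarray(X[idx].todense(), dtype=dtype)
        loss, grads, aux = _loss_and_grads(model, batch, rng=rng)
        if not np.isfinite(loss):
            raise TrainingInstabilityError(
                f"non-finite loss at step {step}: {loss}")
        frozen = {"prior_log_alpha"} if step < config.burn_in_steps else set()
        opt.step(model.params, grads, frozen)
        if step % config.log_every == 0 or step == config.max_steps - 1:
            trace.append({"step": step, "loss": loss,
                          "recon": aux["recon"], "kl": aux["kl"]})
    model.final_loss = trace[-1]["loss"] if trace else None
    return model, pd.DataFrame(trace)


def infer(counts: KmerCountMatrix, model: BindVAEModel,
          mode: str = "posterior_mean",
          rng: np.random.Generator | None = None,
          batch_size: int = 2048) -> LatentMatrix:
    """Latent score vectors for every row of ``counts``.

    ``posterior_mean`` mode returns the deterministic Dirichlet mean
    alpha_hat / sum(alpha_hat); ``sampled`` mode draws one z per row.
    """
    if counts.vocabulary.signature != model.vocab_signature:
        raise VocabularyMismatchError(
            "count matrix vocabulary does not match the model")
    if mode not in ("posterior_mean", "sampled"):
        raise ValueError(f"unknown inference mode {mode!r}")
    if mode == "sampled" and rng is None:
        raise ValueError("sampled mode requires an rng")
    X = counts.entries.tocsr()
    out = np.empty((counts.n_rows, model.M), dtype=np.float64)
    for lo in range(0, counts.n_rows, batch_size):
        hi = min(lo + batch_size, counts.n_rows)
        batch = np.asarray(X[lo:hi].todense(), dtype=model.dtype)
        alpha_hat = np.atleast_2d(encode(batch, model))
        if mode == "posterior_mean":
            out[lo:hi] = alpha_hat / alpha_hat.sum(axis=1, keepdims=True)
        else:
            out[lo:hi] = sample_latent(alpha_hat, rng)
    return LatentMatrix(rows=out, mode=mode, row_ids=list(counts.row_ids))


def select_ensemble(models: Sequence[BindVAEModel],
                    probe_counts: KmerCountMatrix,
                    probe_labels: Sequence[str],
                    p_threshold: float = 0.05) -> tuple[list[BindVAEModel], set[str]]:
    """Rank candidate models by how many distinct TFs their latent space
    maps (via the enrichment procedure on labeled probes) and keep the top
    three; ties are broken by lower final training loss.  Returns the
    retained models and the union of their mapped TF sets."""
    from bindvae.tf_mapping import ProbeSet, map_dimensions_to_tfs

    if not models:
        raise ValueError("need at least one model")
    probes = ProbeSet(tf_labels=list(probe_labels))
    scored = []
    for j, model in enumerate(models):
        latent = infer(probe_counts, model, mode="posterior_mean")
        mapping = map_dimensions_to_tfs(latent, probes, p_threshold=p_threshold)
        tfs = mapping.tf_set()
        tiebreak = model.final_loss if model.final_loss is not None else np.inf
        scored.append((len(tfs), -tiebreak, -j, model, tfs))
    scored.sort(reverse=True)
    top = scored[:3]
    union: set[str] = set()
    for _, _, _, _, tfs in top:
        union |= tfs
    return [entry[3] for entry in top], union
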