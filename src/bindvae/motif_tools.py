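"""De novo motif reconstruction from a trained model.

Short wildcard k-mers limit how much of a binding motif a single decoder
row can show, so motifs are reconstructed by scoring longer probe sequences
with the model itself: enumerate every canonical n-mer (n=10 by default),
run posterior-mean inference on their bags of k-mers, rank them by the
latent score of the dimension of interest, and build a PWM from the top 200.
PWM construction is a deterministic consensus-anchored ungapped alignment
(every sequence is aligned to the top-ranked one over both strands and all
offsets with enough overlap, then per-column base frequencies are counted
with a pseudocount), so results are bit-reproducible; the ranked top set can
also be exported as FASTA for external motif finders.  Composite
(cooperative-binding) motifs use longer probes (15-mers), sampled at a
fraction of the enormous canonical space instead of enumerated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from bindvae import kmer_space
from bindvae.dvae import BindVAEModel, LatentMatrix, infer
from bindvae.kmer_space import KmerVocabulary, featurize_many, reverse_complement

_BASE_ORDER = "ACGT"


@dataclass
class PWM:
    """Position weight matrix: L x 4 column-stochastic matrix over A,C,G,T."""

    columns: np.ndarray
    source_dimension: int = -1
    n_sequences: int = 0
    name: str = "motif"

    def __post_init__(self):
        self.columns = np.asarray(self.columns, dtype=np.float64)
        if self.columns.ndim != 2 or self.columns.shape[1] != 4:
            raise ValueError("PWM columns must be an L x 4 matrix")

    @property
    def length(self) -> int:
        return self.columns.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(_BASE_ORDER[i] for i in self.columns.argmax(axis=1))

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (0..2)."""
        p = np.clip(self.columns, 1e-12, 1.0)
        return 2.0 + (p * np.log2(p)).sum(axis=1)

    def to_meme(self) -> str:
        """MEME minimal motif format."""
        lines = [
            "MEME version 4", "",
            "ALPHABET= ACGT", "",
            "strands: + -", "",
            "Background letter frequencies",
            "A 0.25 C 0.25 G 0.25 T 0.25", "",
            f"MOTIF {self.name}",
            f"letter-probability matrix: alength= 4 w= {self.length} "
            f"nsites= {max(self.n_sequences, 1)}",
        ]
        for row in self.columns:
            lines.append(" ".join(f"{v:.6f}" for v in row))
        lines.append("")
        return "\n".join(lines)


@dataclass
class KmerRanking:
    """k-mers of one decoder row (or latent scoring), best first."""

    dimension: int
    ranked: list[tuple[str, float]]

    def kmers(self) -> list[str]:
        return [k for k, _ in self.ranked]


def top_kmers(model: BindVAEModel, dimension: int, n: int = 20) -> KmerRanking:
    """The n highest-probability canonical k-mers of decoder row
    ``dimension`` (descending weight; ties in lexicographic order).

    Requires the model's vocabulary patterns, so pass n <= D; n beyond D is
    truncated.
    """
    if not 0 <= dimension < model.M:
        raise ValueError(f"dimension {dimension} out of range [0, {model.M})")
    vocab = _model_vocabulary(model)
    row = model.theta[dimension]
    n = min(n, len(row))
    # argsort on (-weight, index): vocabulary order is lexicographic, so a
    # stable sort on descending weight gives the lexicographic tie-break
    order = np.argsort(-row, kind="stable")[:n]
    patterns = vocab.patterns
    return KmerRanking(dimension=dimension,
                       ranked=[(patterns[j], float(row[j])) for j in order])


def _model_vocabulary(model: BindVAEModel) -> KmerVocabulary:
    vocab = getattr(model, "vocabulary", None)
    if vocab is None:
        raise ValueError("model has no vocabulary attached")
    if vocab.signature != model.vocab_signature:
        raise ValueError("vocabulary signature does not match the model")
    return vocab


def score_sequences(model: BindVAEModel, sequences: list[str],
                    batch_size: int = 4096) -> LatentMatrix:
    """Posterior-mean latent scores of arbitrary DNA sequences.

    Each sequence is featurized with the model's vocabulary and passed
    through deterministic inference; sequences shorter than k give zero
    count vectors (posterior driven by encoder biases alone).
    """
    vocab = _model_vocabulary(model)
    counts = featurize_many(sequences, vocab)
    return infer(counts, model, mode="posterior_mean", batch_size=batch_size)


def build_pwm(sequences: list[str], scores: list[float] | np.ndarray,
              min_overlap: int = 6, pseudocount: float = 0.25,
              source_dimension: int = -1) -> PWM:
    """Deterministic consensus-anchored PWM from scored sequences.

    The highest-scoring sequence anchors the coordinate frame.  Every other
    sequence is aligned to it ungapped over both orientations and all
    offsets with overlap >= ``min_overlap``, at the placement maximizing
    matches (ties: smaller |offset|, then forward strand).  Base counts are
    accumulated over the anchor's positions, pseudocounted and normalized.
    """
    if len(sequences) == 0:
        raise ValueError("need at least one sequence")
    scores = np.asarray(scores, dtype=np.float64)
    anchor = sequences[int(np.argmax(scores))]
    L = len(anchor)
    counts = np.zeros((L, 4), dtype=np.float64)
    base_idx = {c: i for i, c in enumerate(_BASE_ORDER)}

    def add(seq: str, offset: int) -> None:
        # offset: position of seq[0] in anchor coordinates
        for j, c in enumerate(seq):
            pos = offset + j
            if 0 <= pos < L and c in base_idx:
                counts[pos, base_idx[c]] += 1.0

    for seq in sequences:
        best = None  # ((matches, -|offset|, strand_pref), seq, offset)
        overlap = min(min_overlap, L, len(seq))
        for strand_pref, cand in ((1, seq), (0, reverse_complement(seq))):
            lo = -(len(cand) - overlap)
            hi = L - overlap
            for off in range(lo, hi + 1):
                matches = sum(
                    1 for j, c in enumerate(cand)
                    if 0 <= off + j < L and anchor[off + j] == c)
                key = (matches, -abs(off), strand_pref)
                if best is None or key > best[0]:
                    best = (key, cand, off)
        _, cand, off = best
        add(cand, off)
    counts += pseudocount
    columns = counts / counts.sum(axis=1, keepdims=True)
    return PWM(columns=columns, source_dimension=source_dimension,
               n_sequences=len(sequences))


def discover_motif(model: BindVAEModel, dimension: int,
                   probe_len: int = 10, top_n: int = 200,
                   return_top_set: bool = False):
    """Reconstruct the motif of a latent dimension de novo.

    Enumerates all canonical wildcard-free ``probe_len``-mers (524,800 for
    length 10), scores them with the model, ranks by the latent score of
    ``dimension`` (descending; lexicographic tie-break) and builds a PWM
    from the ``top_n`` best.  Deterministic.  To reconstruct several
    dimensions of one model, :func:`discover_motifs` scores the candidate
    space once and reuses it.
    """
    sequences = kmer_space.enumerate_canonical_sequences(probe_len)
    return _motif_from_candidates(model, dimension, sequences, top_n,
                                  return_top_set)


def discover_motifs(model: BindVAEModel, dimensions: list[int],
                    probe_len: int = 10, top_n: int = 200) -> dict[int, PWM]:
    """Batch :func:`discover_motif` over several dimensions, scoring the
    enumerated candidate space once (the scoring pass dominates the cost)."""
    sequences = kmer_space.enumerate_canonical_sequences(probe_len)
    latent = score_sequences(model, sequences)
    return {dim: _rank_and_build(sequences, latent.rows[:, dim], top_n, dim)[0]
            for dim in dimensions}


def _rank_and_build(sequences: list[str], col: np.ndarray, top_n: int,
                    dimension: int):
    # sequences are lexicographically sorted, so a stable descending sort
    # breaks score ties lexicographically
    order = np.argsort(-col, kind="stable")[:top_n]
    top_seqs = [sequences[i] for i in order]
    top_scores = col[order]
    pwm = build_pwm(top_seqs, top_scores, source_dimension=dimension)
    pwm.name = f"dim{dimension}"
    return pwm, list(zip(top_seqs, top_scores.tolist()))


def _motif_from_candidates(model: BindVAEModel, dimension: int,
                           sequences: list[str], top_n: int,
                           return_top_set: bool):
    latent = score_sequences(model, sequences)
    pwm, top_set = _rank_and_build(sequences, latent.rows[:, dimension],
                                   top_n, dimension)
    if return_top_set:
        return pwm, top_set
    return pwm


def sample_canonical_sequences(probe_len: int, fraction: float,
                               rng: np.random.Generator) -> list[str]:
    """Uniform sample without replacement of canonical ``probe_len``-mers at
    the given fraction of the canonical space, drawn without enumerating it
    (the 15-mer space holds >5e8 sequences).  Returned sorted."""
    n_total = kmer_space.count_canonical_sequences(probe_len)
    n_sample = int(round(fraction * n_total))
    chosen: set[int] = set()
    shifts = 2 * np.arange(probe_len - 1, -1, -1, dtype=np.int64)
    powers = 4 ** np.arange(probe_len - 1, -1, -1, dtype=np.int64)
    while len(chosen) < n_sample:
        draw = rng.integers(0, 4**probe_len,
                            size=max(1024, n_sample - len(chosen)))
        digits = ((draw[:, None] >> shifts) & 3).astype(np.int8)
        rc = (3 - digits)[:, ::-1].astype(np.int64) @ powers
        canon = np.minimum(draw, rc)
        for c in canon:
            chosen.add(int(c))
            if len(chosen) >= n_sample:
                break
    codes = np.sort(np.fromiter(chosen, dtype=np.int64, count=n_sample))
    digits = ((codes[:, None] >> shifts) & 3).astype(np.int8)
    lut = np.frombuffer(_BASE_ORDER.encode(), dtype=np.uint8)
    return [row.tobytes().decode() for row in lut[digits]]


def discover_composite_motif(model: BindVAEModel, dimension: int,
                             probe_len: int = 15, sample_fraction: float = 0.1,
                             top_n: int = 200, seed: int = 0,
                             return_top_set: bool = False):
    """Composite-motif variant of :func:`discover_motif` for cooperative
    binding: candidate probes are a seeded uniform sample (without
    replacement) of the canonical ``probe_len``-mer space at
    ``sample_fraction``, long enough to hold two adjacent binding sites."""
    rng = np.random.default_rng(seed)
    sequences = sample_canonical_sequences(probe_len, sample_fraction, rng)
    return _motif_from_candidates(model, dimension, sequences, top_n,
                                  return_top_set)
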