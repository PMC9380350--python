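"""Wildcard k-mer vocabulary and bag-of-k-mers featurization.

The input space of the model is the set of DNA k-mers (default k=8) with up
to ``max_run`` consecutive wildcard positions (default 2), where a k-mer and
its reverse complement are collapsed into a single canonical feature.  For
k=8 / max_run=2 this gives D = 112800 features.  A sequence is represented
as a bag of k-mers: every k-length window made solely of A/C/G/T increments
the canonical feature of the exact window and of each of its wildcard
variants (one N at any position, and a run of N's at any position for every
run length up to ``max_run``), so each valid window contributes exactly
``1 + k + (k-1) == 2k`` counts at the defaults.

Internally patterns are encoded as base-5 integers with digit order
A=0 < C=1 < G=2 < T=3 < N=4, so integer comparison coincides with
lexicographic comparison under that character order and canonicalization is
``min(code, revcomp_code)``.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse

logger = logging.getLogger(__name__)

_ALPHABET = "ACGTN"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# character rank implementing the A < C < G < T < N comparison order
_RANK = {c: i for i, c in enumerate(_ALPHABET)}

# 256-entry byte -> digit table; 0xFF marks non-ACGT characters
_BYTE_TO_DIGIT = np.full(256, 0xFF, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _BYTE_TO_DIGIT[ord(_c)] = _i
    _BYTE_TO_DIGIT[ord(_c.lower())] = _i


class InvalidAlphabetError(ValueError):
    """A pattern contains a character outside {A, C, G, T, N}."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string; N is its own complement."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonicalize(pattern: str) -> str:
    """Collapse a wildcard k-mer with its reverse complement.

    Returns whichever of ``pattern`` and its reverse complement is
    lexicographically smaller under the character order A < C < G < T < N.
    Idempotent.
    """
    pattern = pattern.upper()
    for c in pattern:
        if c not in _RANK:
            raise InvalidAlphabetError(
                f"invalid character {c!r} in pattern {pattern!r}"
            )
    rc = reverse_complement(pattern)
    key = [_RANK[c] for c in pattern]
    rc_key = [_RANK[c] for c in rc]
    return pattern if key <= rc_key else rc


def _digits_to_strings(digits: np.ndarray) -> list[str]:
    lut = np.frombuffer(_ALPHABET.encode(), dtype=np.uint8)
    as_bytes = lut[digits]
    return [row.tobytes().decode() for row in as_bytes]


def _base5(digits: np.ndarray) -> np.ndarray:
    k = digits.shape[1]
    powers = 5 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return digits.astype(np.int64) @ powers


def _revcomp_digits(digits: np.ndarray) -> np.ndarray:
    rc = np.where(digits == 4, 4, 3 - digits)
    return rc[:, ::-1]


def _canonical_codes(digits: np.ndarray) -> np.ndarray:
    return np.minimum(_base5(digits), _base5(_revcomp_digits(digits)))


def _enumerate_pattern_digits(k: int, max_run: int) -> np.ndarray:
    """All raw patterns: exact k-mers plus every single N-run placement of
    length 1..max_run, as a (P, k) digit matrix."""
    blocks = []
    for run in range(0, max_run + 1):
        n_letters = k - run
        codes = np.arange(4**n_letters, dtype=np.int64)
        shifts = 2 * np.arange(n_letters - 1, -1, -1, dtype=np.int64)
        letters = ((codes[:, None] >> shifts) & 3).astype(np.int8)
        positions = [0] if run == 0 else range(k - run + 1)
        for pos in positions:
            block = np.empty((len(codes), k), dtype=np.int8)
            block[:, :pos] = letters[:, :pos]
            block[:, pos : pos + run] = 4
            block[:, pos + run :] = letters[:, pos:]
            blocks.append(block)
    return np.concatenate(blocks, axis=0)


@dataclass
class KmerVocabulary:
    """Canonical wildcard k-mer vocabulary defining the model input space.

    Attributes
    ----------
    k : k-mer length.
    max_run : maximum length of the single contiguous wildcard run.
    codes : sorted base-5 integer codes of the canonical patterns; the
        position of a code in this array is its feature index, so indices
        follow lexicographic order of the canonical pattern.
    """

    k: int
    max_run: int
    codes: np.ndarray
    _patterns: list[str] | None = field(default=None, repr=False)
    _index_of: dict[str, int] | None = field(default=None, repr=False)
    _variant_table: np.ndarray | None = field(default=None, repr=False)

    @property
    def D(self) -> int:
        return len(self.codes)

    @property
    def n_variants_per_window(self) -> int:
        """Number of features each valid window increments (2k at defaults)."""
        return 1 + sum(self.k - r + 1 for r in range(1, self.max_run + 1))

    @property
    def patterns(self) -> list[str]:
        """Canonical pattern strings in index order."""
        if self._patterns is None:
            digits = _code_to_digits(self.codes, self.k)
            self._patterns = _digits_to_strings(digits)
        return self._patterns

    @property
    def index_of(self) -> dict[str, int]:
        if self._index_of is None:
            self._index_of = {p: i for i, p in enumerate(self.patterns)}
        return self._index_of

    @property
    def signature(self) -> str:
        """Stable hash identifying this vocabulary (k, max_run, contents)."""
        h = hashlib.sha256()
        h.update(f"k={self.k};max_run={self.max_run};D={self.D};".encode())
        h.update(self.codes.tobytes())
        return h.hexdigest()[:16]

    def index(self, pattern: str) -> int:
        """Feature index of a pattern (canonicalized first)."""
        canon = canonicalize(pattern)
        try:
            return self.index_of[canon]
        except KeyError:
            raise KeyError(f"pattern {pattern!r} not in vocabulary") from None

    def window_variant_table(self) -> np.ndarray:
        """(4**k, n_variants) table mapping an exact window's 2-bit code to
        the feature indices of all its wildcard variants.  Cached."""
        if self._variant_table is None:
            k = self.k
            codes = np.arange(4**k, dtype=np.int64)
            shifts = 2 * np.arange(k - 1, -1, -1, dtype=np.int64)
            digits = ((codes[:, None] >> shifts) & 3).astype(np.int8)
            columns = [np.searchsorted(self.codes, _canonical_codes(digits))]
            for run in range(1, self.max_run + 1):
                for pos in range(k - run + 1):
                    var = digits.copy()
                    var[:, pos : pos + run] = 4
                    columns.append(
                        np.searchsorted(self.codes, _canonical_codes(var))
                    )
            self._variant_table = np.stack(columns, axis=1).astype(np.int32)
        return self._variant_table


def _code_to_digits(codes: np.ndarray, k: int) -> np.ndarray:
    powers = 5 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return ((codes[:, None] // powers) % 5).astype(np.int8)


def build_vocabulary(k: int = 8, max_run: int = 2) -> KmerVocabulary:
    """Enumerate, canonicalize and index the wildcard k-mer vocabulary.

    Parameters
    ----------
    k : k-mer length (>= 1).
    max_run : maximum consecutive-wildcard run length (0 <= max_run < k).
        Patterns carry zero wildcards or one contiguous run of 1..max_run N's.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if not 0 <= max_run <= k:
        raise ValueError(f"max_run must satisfy 0 <= max_run <= k, got {max_run}")
    digits = _enumerate_pattern_digits(k, max_run)
    codes = np.unique(_canonical_codes(digits))
    return KmerVocabulary(k=k, max_run=max_run, codes=codes)


def enumerate_canonical_sequences(k: int) -> list[str]:
    """All wildcard-free k-mers collapsed under reverse complement,
    lexicographically sorted.  4**k/2 sequences for odd k,
    (4**k + 4**(k/2))/2 for even k (e.g. 524800 for k=10)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    codes = np.arange(4**k, dtype=np.int64)
    shifts = 2 * np.arange(k - 1, -1, -1, dtype=np.int64)
    digits = ((codes[:, None] >> shifts) & 3).astype(np.int8)
    rc = (3 - digits)[:, ::-1]
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    rc_codes = rc.astype(np.int64) @ powers
    canon = np.unique(np.minimum(codes, rc_codes))
    canon_digits = ((canon[:, None] >> shifts) & 3).astype(np.int8)
    return _digits_to_strings(canon_digits)


def count_canonical_sequences(k: int) -> int:
    """Closed-form size of :func:`enumerate_canonical_sequences`."""
    if k % 2 == 0:
        return (4**k + 4 ** (k // 2)) // 2
    return 4**k // 2


# ---------------------------------------------------------------------------
# Featurization


def _window_codes(seq: str, k: int) -> np.ndarray:
    """2-bit codes of all valid (ACGT-only) k-length windows of seq."""
    arr = _BYTE_TO_DIGIT[np.frombuffer(seq.encode(), dtype=np.uint8)]
    if len(arr) < k:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(arr, k)
    valid = (windows != 0xFF).all(axis=1)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return windows[valid].astype(np.int64) @ powers


def featurize(sequence: str, vocab: KmerVocabulary) -> np.ndarray:
    """Bag-of-k-mers count vector (length D) of a DNA sequence.

    Every window of length k consisting solely of A/C/G/T contributes one
    count to the canonical feature of each of its ``n_variants_per_window``
    wildcard variants; windows touching any other character are skipped.
    Sequences shorter than k give the zero vector.
    """
    codes = _window_codes(sequence, vocab.k)
    if len(codes) == 0:
        return np.zeros(vocab.D, dtype=np.int64)
    idx = vocab.window_variant_table()[codes]
    return np.bincount(idx.ravel(), minlength=vocab.D)


def featurize_many(
    sequences: Sequence[str],
    vocab: KmerVocabulary,
    row_ids: Sequence[str] | None = None,
) -> "KmerCountMatrix":
    """Featurize a batch of sequences into a sparse N x D count matrix."""
    table = vocab.window_variant_table()
    rows, cols = [], []
    for i, seq in enumerate(sequences):
        codes = _window_codes(seq, vocab.k)
        if len(codes) == 0:
            continue
        idx = table[codes].ravel()
        cols.append(idx)
        rows.append(np.full(len(idx), i, dtype=np.int64))
    if rows:
        data = np.ones(sum(len(r) for r in rows), dtype=np.int64)
        mat = sparse.coo_matrix(
            (data, (np.concatenate(rows), np.concatenate(cols))),
            shape=(len(sequences), vocab.D),
        ).tocsr()
    else:
        mat = sparse.csr_matrix((len(sequences), vocab.D), dtype=np.int64)
    if row_ids is None:
        row_ids = [f"seq{i}" for i in range(len(sequences))]
    return KmerCountMatrix(entries=mat, vocabulary=vocab, row_ids=list(row_ids))


@dataclass
class KmerCountMatrix:
    """Sparse N x D matrix of bag-of-k-mers counts, one row per sequence."""

    entries: sparse.csr_matrix
    vocabulary: KmerVocabulary
    row_ids: list[str]

    @property
    def n_rows(self) -> int:
        return self.entries.shape[0]

    def row(self, i: int) -> np.ndarray:
        return np.asarray(self.entries[i].todense()).ravel()

    def dense(self) -> np.ndarray:
        return np.asarray(self.entries.todense())


# ---------------------------------------------------------------------------
# Peak windows


@dataclass
class SequenceRegion:
    """A genomic interval (0-based half-open), optionally with a summit
    offset (narrowPeak column 10) and an attached sequence."""

    chrom: str
    start: int
    end: int
    summit_offset: int | None = None
    sequence: str | None = None
    name: str | None = None

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"end must exceed start: {self.chrom}:{self.start}-{self.end}"
            )
        if self.sequence is not None and len(self.sequence) != self.end - self.start:
            raise ValueError("sequence length does not match interval length")

    @property
    def region_id(self) -> str:
        return self.name or f"{self.chrom}:{self.start}-{self.end}"


def extract_peak_windows(
    regions: Iterable[SequenceRegion],
    genome,
    window: int = 200,
) -> list[SequenceRegion]:
    """Fixed-width windows centered on peak summits, with sequence attached.

    ``genome`` is a ``pyfaidx.Fasta`` (or path to an indexed FASTA).  The
    window is [summit - window/2, summit + window/2); the interval midpoint
    stands in when no summit is recorded.  Windows running past a chromosome
    end are dropped with a warning; regions on chromosomes absent from the
    genome are skipped and counted.
    """
    import pyfaidx

    if window % 2 != 0:
        raise ValueError(f"window must be even, got {window}")
    if not isinstance(genome, pyfaidx.Fasta):
        genome = pyfaidx.Fasta(str(genome))
    half = window // 2
    out: list[SequenceRegion] = []
    n_missing = n_dropped = 0
    for region in regions:
        if region.chrom not in genome:
            n_missing += 1
            logger.error("chromosome %s absent from genome; region skipped",
                         region.chrom)
            continue
        summit = (
            region.start + region.summit_offset
            if region.summit_offset is not None
            else (region.start + region.end) // 2
        )
        start, end = summit - half, summit + half
        chrom_len = len(genome[region.chrom])
        if start < 0 or end > chrom_len:
            n_dropped += 1
            logger.warning(
                "window %s:%d-%d extends past chromosome end; dropped",
                region.chrom, start, end,
            )
            continue
        seq = str(genome[region.chrom][start:end]).upper()
        out.append(
            SequenceRegion(
                chrom=region.chrom, start=start, end=end,
                sequence=seq, name=region.name,
            )
        )
    if n_missing or n_dropped:
        logger.info(
            "extract_peak_windows: %d regions skipped (missing chrom), "
            "%d dropped (chromosome boundary)", n_missing, n_dropped,
        )
    return out
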