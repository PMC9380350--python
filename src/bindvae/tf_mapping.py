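"""Interpreting the latent space: mapping dimensions to TFs and scoring peaks.

A latent dimension is labeled with a transcription factor when that TF's
SELEX-like probes receive significantly higher latent scores in the
dimension than all other TFs' probes (one-sided Mann-Whitney U, default
p < 0.05, no multiple-testing correction by default).  The mapping can be
many-to-many: paralogous TFs with near-identical binding preferences land on
the same dimension, and one TF can mark several dimensions.  Peaks are then
annotated with the TFs of their top-scoring dimensions, a per-topic
"accessibility score" is the column sum of the peak latent matrix, and a
centered log-ratio transform is provided for comparing compositional latent
vectors across models.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from bindvae.dvae import LatentMatrix


@dataclass
class ProbeSet:
    """Labeled probe sequences (typically 20 bp SELEX probes), one TF label
    per sequence.  ``sequences`` may be None when only labels are needed."""

    tf_labels: list[str]
    sequences: list[str] | None = None

    def __post_init__(self):
        if not self.tf_labels:
            raise ValueError("tf_labels must be nonempty")
        if self.sequences is not None and len(self.sequences) != len(self.tf_labels):
            raise ValueError("sequences and tf_labels must be parallel")

    @property
    def tfs(self) -> list[str]:
        """Distinct TF names in first-appearance order."""
        return list(dict.fromkeys(self.tf_labels))

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for t in self.tf_labels:
            out[t] = out.get(t, 0) + 1
        return out


@dataclass
class TFMapping:
    """Many-to-many map latent dimension -> {(TF, p-value)}."""

    entries: list[tuple[int, str, float]] = field(default_factory=list)
    p_threshold: float = 0.05

    def dimension_to_tfs(self) -> dict[int, list[tuple[str, float]]]:
        out: dict[int, list[tuple[str, float]]] = {}
        for m, t, p in self.entries:
            out.setdefault(m, []).append((t, p))
        for m in out:
            out[m].sort(key=lambda tp: (tp[1], tp[0]))
        return out

    def tf_to_dimensions(self) -> dict[str, list[tuple[int, float]]]:
        out: dict[str, list[tuple[int, float]]] = {}
        for m, t, p in self.entries:
            out.setdefault(t, []).append((m, p))
        for t in out:
            out[t].sort(key=lambda mp: (mp[1], mp[0]))
        return out

    def tf_set(self) -> set[str]:
        return {t for _, t, _ in self.entries}

    def best_tf(self, dimension: int) -> str | None:
        """Lowest-p TF for a dimension (name tie-break), or None."""
        candidates = self.dimension_to_tfs().get(dimension)
        return candidates[0][0] if candidates else None


def mwu_enrichment(scores_t: Sequence[float],
                   scores_rest: Sequence[float]) -> tuple[float, float]:
    """One-sided Mann-Whitney U test that ``scores_t`` is stochastically
    greater than ``scores_rest``.

    U counts pairs (a, b) with a > b plus half the ties.  The p-value is
    exact (full enumeration) for tie-free samples with combined n <= 25 and
    a tie-corrected normal approximation otherwise; all-tied degenerate
    input returns p = 0.5.
    """
    a = np.asarray(scores_t, dtype=np.float64)
    b = np.asarray(scores_rest, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both score lists must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    if np.ptp(pooled) == 0.0:
        return float(a.size * b.size / 2.0), 0.5
    method = "exact" if (not has_ties and pooled.size <= 25) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


def map_dimensions_to_tfs(Z_probes: LatentMatrix, labels: ProbeSet,
                          p_threshold: float = 0.05,
                          best_only: bool = False,
                          bh_correct: bool = False) -> TFMapping:
    """Assign TF labels to latent dimensions from labeled probe scores.

    For every (dimension m, TF t) pair, the latent scores of t's probes in
    column m are tested against the scores of all other probes in that
    column; (m, t, p) is recorded whenever p < ``p_threshold``.  With
    ``best_only`` each dimension keeps only its lowest-p TF; with
    ``bh_correct`` the p-values are Benjamini-Hochberg adjusted across the
    M x T tests before thresholding (off by default).
    """
    label_arr = np.asarray(labels.tf_labels)
    if Z_probes.n != label_arr.size:
        raise ValueError("latent rows and probe labels must be parallel")
    tfs = labels.tfs
    if len(tfs) < 2:
        raise ValueError("need >= 2 distinct TFs for enrichment testing")
    raw: list[tuple[int, str, float]] = []
    pvals: list[float] = []
    for m in range(Z_probes.M):
        col = Z_probes.rows[:, m]
        for t in tfs:
            mask = label_arr == t
            _, p = mwu_enrichment(col[mask], col[~mask])
            raw.append((m, t, p))
            pvals.append(p)
    if bh_correct:
        pvals = list(_benjamini_hochberg(np.asarray(pvals)))
    entries = [(m, t, p) for (m, t, _), p in zip(raw, pvals) if p < p_threshold]
    mapping = TFMapping(entries=entries, p_threshold=p_threshold)
    if best_only:
        best = []
        for m, cand in mapping.dimension_to_tfs().items():
            t, p = cand[0]
            best.append((m, t, p))
        mapping = TFMapping(entries=sorted(best), p_threshold=p_threshold)
    return mapping


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def assign_peaks_to_tfs(Z_peaks: LatentMatrix, mapping: TFMapping,
                        top_n: int = 3) -> list[list[str]]:
    """Ranked TF annotation for each peak.

    The ``top_n`` dimensions with the highest latent scores (ties broken by
    lower dimension index) each contribute one entry: the dimension's
    lowest-p TF, or the token ``unmapped:<dim>`` when the dimension carries
    no TF label.
    """
    dim_best = {m: cand[0][0] for m, cand in mapping.dimension_to_tfs().items()}
    out: list[list[str]] = []
    for row in Z_peaks.rows:
        top_dims = np.argsort(-row, kind="stable")[:top_n]
        out.append([dim_best.get(int(m), f"unmapped:{int(m)}")
                    for m in top_dims])
    return out


def accessibility_scores(Z_peaks: LatentMatrix) -> np.ndarray:
    """Per-topic accessibility: the latent scores summed over all peaks,
    score_m = sum_i z_im."""
    if Z_peaks.mode != "posterior_mean":
        raise ValueError("accessibility scores require posterior_mean latents")
    return Z_peaks.rows.sum(axis=0)


def clr_transform(Z, pseudocount: float = 1e-6) -> np.ndarray:
    """Centered log-ratio transform, rowwise:
    y_m = log(z_m + pseudocount) - mean_m log(z_m + pseudocount)."""
    rows = Z.rows if isinstance(Z, LatentMatrix) else np.asarray(Z, dtype=np.float64)
    if np.any(rows < 0):
        raise ValueError("CLR input must be nonnegative")
    logs = np.log(rows + pseudocount)
    return logs - logs.mean(axis=1, keepdims=True)
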