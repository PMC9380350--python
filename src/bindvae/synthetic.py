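"""Synthetic accessible-region and SELEX-probe generator with ground truth.

Emulates the generative structure the model assumes: each 200 bp "peak" has
topic proportions drawn from a Dirichlet, topics correspond to TF binding
motifs (plus one explicit background topic that plants nothing, mirroring
the genomic-background factors real models learn), and motif instances
sampled from per-TF PWMs are placed at random non-overlapping positions and
strands over i.i.d. background DNA of a given GC content.  SELEX-like
probes are short (20 bp) sequences each carrying a single instance of one
motif.  Everything is reproducible from a seed, and the per-peak instance
log plus per-peak background seeds allow every generated sequence to be
reconstructed exactly (replay).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from bindvae.kmer_space import reverse_complement

_BASES = np.array(list("ACGT"))

BACKGROUND_TOPIC = "background"


@dataclass
class TruthRecord:
    """One generated peak: its topic mixture, planted instances and the seed
    of its background stream."""

    peak_id: str
    mixture: np.ndarray
    instances: list[tuple[str, int, str, str]]  # (motif name, pos, strand, instance seq)
    background_seed: int
    length: int


@dataclass
class SyntheticTruth:
    """Ground truth for a synthetic world."""

    motif_names: list[str]
    motif_pwms: list[np.ndarray]  # L x 4 each, columns A,C,G,T
    records: list[TruthRecord]
    background_gc: float
    seed: int

    @property
    def peak_mixtures(self) -> np.ndarray:
        return np.stack([r.mixture for r in self.records])

    def consensus(self, i: int) -> str:
        return "".join(_BASES[self.motif_pwms[i].argmax(axis=1)])

    def replay(self, record: TruthRecord) -> str:
        """Reconstruct a peak sequence exactly from its truth record."""
        seq = _random_background(record.length, self.background_gc,
                                 np.random.default_rng(record.background_seed))
        seq = list(seq)
        for _, pos, _, inst in record.instances:
            seq[pos:pos + len(inst)] = list(inst)
        return "".join(seq)

    def to_json(self) -> str:
        return json.dumps({
            "motif_names": self.motif_names,
            "motif_pwms": [p.tolist() for p in self.motif_pwms],
            "background_gc": self.background_gc,
            "seed": self.seed,
            "records": [
                {"peak_id": r.peak_id, "mixture": r.mixture.tolist(),
                 "instances": r.instances, "background_seed": r.background_seed,
                 "length": r.length}
                for r in self.records
            ],
        })

    @classmethod
    def from_json(cls, text: str) -> "SyntheticTruth":
        d = json.loads(text)
        return cls(
            motif_names=d["motif_names"],
            motif_pwms=[np.asarray(p) for p in d["motif_pwms"]],
            records=[TruthRecord(
                peak_id=r["peak_id"], mixture=np.asarray(r["mixture"]),
                instances=[tuple(i) for i in r["instances"]],
                background_seed=r["background_seed"], length=r["length"])
                for r in d["records"]],
            background_gc=d["background_gc"], seed=d["seed"],
        )


def _random_background(length: int, gc: float, rng: np.random.Generator) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=length, p=p)])


def _sample_from_pwm(pwm: np.ndarray, rng: np.random.Generator) -> str:
    return "".join(_BASES[rng.choice(4, p=col / col.sum())] for col in pwm)


def _consensus_distance(c1: str, c2: str) -> int:
    """Minimum Hamming distance over all full overlaps of the shorter
    consensus within the longer, on either strand."""
    if len(c1) > len(c2):
        c1, c2 = c2, c1
    best = len(c1)
    for cand in (c2, reverse_complement(c2)):
        for off in range(len(cand) - len(c1) + 1):
            d = sum(a != b for a, b in zip(c1, cand[off:off + len(c1)]))
            best = min(best, d)
    return best


def make_toy_motifs(n: int, length_range: tuple[int, int] = (6, 10),
                    sharpness: float = 0.9,
                    rng: np.random.Generator | None = None,
                    min_distance: int = 3,
                    max_tries: int = 1000) -> tuple[list[str], list[np.ndarray]]:
    """Random distinguishable motifs: each PWM puts probability ``sharpness``
    on a random consensus base per column and spreads the rest evenly.
    Consensi are rejection-resampled until all pairwise (strand- and
    offset-minimized) Hamming distances are >= ``min_distance``.

    Returns (names, pwms); names are TF0, TF1, ...
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    consensi: list[str] = []
    for _ in range(n):
        for _try in range(max_tries):
            L = int(rng.integers(length_range[0], length_range[1] + 1))
            cand = "".join(_BASES[rng.integers(0, 4, size=L)])
            if all(_consensus_distance(cand, c) >= min_distance for c in consensi):
                consensi.append(cand)
                break
        else:
            raise RuntimeError(
                f"could not place {n} motifs at pairwise distance "
                f">= {min_distance} after {max_tries} tries")
    pwms = []
    for cons in consensi:
        pwm = np.full((len(cons), 4), (1 - sharpness) / 3)
        for i, c in enumerate(cons):
            pwm[i, "ACGT".index(c)] = sharpness
        pwms.append(pwm)
    names = [f"TF{i}" for i in range(n)]
    return names, pwms


def simulate_peaks(motif_names: list[str], motif_pwms: list[np.ndarray],
                   n_peaks: int = 5000, length: int = 200,
                   alpha_true: np.ndarray | float = 1.0,
                   instances_per_peak: int = 3,
                   background_gc: float = 0.45,
                   seed: int = 0,
                   max_placement_tries: int = 50) -> tuple[list[str], SyntheticTruth]:
    """Generate peaks as Dirichlet mixtures of planted motif instances.

    Topics are the given motifs plus one background topic (index T) that
    plants nothing.  Per peak: draw a mixture over the T+1 topics from
    Dirichlet(alpha_true); draw ``instances_per_peak`` topic assignments
    from it; sample each non-background instance from its PWM on a random
    strand and place it uniformly at random without overlap.  Returns the
    sequences and the full ground truth.
    """
    T = len(motif_names)
    if any(p.shape[0] >= length for p in motif_pwms):
        raise ValueError("motif length must be below peak length")
    alpha = np.broadcast_to(np.asarray(alpha_true, dtype=np.float64),
                            (T + 1,)).copy()
    rng = np.random.default_rng(seed)
    sequences: list[str] = []
    records: list[TruthRecord] = []
    for i in range(n_peaks):
        for _attempt in range(max_placement_tries):
            mixture = rng.dirichlet(alpha)
            topic_draws = rng.choice(T + 1, size=instances_per_peak, p=mixture)
            bg_seed = int(rng.integers(0, 2**31 - 1))
            seq = list(_random_background(
                length, background_gc, np.random.default_rng(bg_seed)))
            occupied = np.zeros(length, dtype=bool)
            instances: list[tuple[str, int, str, str]] = []
            ok = True
            for topic in topic_draws:
                if topic == T:
                    continue  # background topic plants nothing
                pwm = motif_pwms[topic]
                inst = _sample_from_pwm(pwm, rng)
                strand = "+-"[rng.integers(0, 2)]
                placed_seq = inst if strand == "+" else reverse_complement(inst)
                L = len(inst)
                free = [p for p in range(length - L + 1)
                        if not occupied[p:p + L].any()]
                if not free:
                    ok = False
                    break
                pos = int(free[rng.integers(0, len(free))])
                occupied[pos:pos + L] = True
                seq[pos:pos + L] = list(placed_seq)
                instances.append((motif_names[topic], pos, strand, placed_seq))
            if ok:
                break
        else:
            raise RuntimeError(f"could not place instances in peak {i}")
        sequences.append("".join(seq))
        records.append(TruthRecord(
            peak_id=f"peak{i}", mixture=mixture, instances=instances,
            background_seed=bg_seed, length=length))
    truth = SyntheticTruth(
        motif_names=list(motif_names), motif_pwms=list(motif_pwms),
        records=records, background_gc=background_gc, seed=seed)
    return sequences, truth


def simulate_selex_probes(motif_name: str, motif_pwm: np.ndarray,
                          n_probes: int = 200, probe_len: int = 20,
                          background_gc: float = 0.45,
                          seed: int = 0) -> tuple[list[str], list[str]]:
    """SELEX-like probes: background flanks around a single PWM-sampled
    motif instance at a random offset and strand.  Returns parallel
    (sequences, labels) with every label equal to ``motif_name``."""
    L = motif_pwm.shape[0]
    if L > probe_len:
        raise ValueError("motif longer than probe")
    rng = np.random.default_rng(seed)
    probes: list[str] = []
    for _ in range(n_probes):
        seq = list(_random_background(probe_len, background_gc, rng))
        inst = _sample_from_pwm(motif_pwm, rng)
        if rng.integers(0, 2):
            inst = reverse_complement(inst)
        pos = int(rng.integers(0, probe_len - L + 1))
        seq[pos:pos + L] = list(inst)
        probes.append("".join(seq))
    return probes, [motif_name] * n_probes
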