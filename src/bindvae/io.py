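"""Readers and writers for the standard formats the pipeline touches.

Peaks come in as BED3+/narrowPeak, sequences as FASTA, count matrices go
out as MatrixMarket triplets with two text sidecars (the canonical pattern
list in index order and the row ids), latent matrices and TF mappings as
TSV.  Everything round-trips exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as scipy_io
from scipy import sparse

from bindvae.dvae import LatentMatrix
from bindvae.kmer_space import (
    KmerCountMatrix,
    KmerVocabulary,
    SequenceRegion,
    build_vocabulary,
)
from bindvae.tf_mapping import TFMapping


class FormatError(ValueError):
    """Malformed input file."""


def read_bed(path) -> list[SequenceRegion]:
    """Parse BED3+ / narrowPeak into regions (0-based half-open).

    The narrowPeak summit offset (column 10) is used when present and
    nonnegative.  Track/browser/comment lines are ignored.
    """
    regions: list[SequenceRegion] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            try:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
            summit = None
            if len(fields) >= 10:
                try:
                    offset = int(fields[9])
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: bad summit column") from None
                if offset >= 0:
                    summit = offset
            name = fields[3] if len(fields) >= 4 and fields[3] not in (".", "") \
                else None
            try:
                regions.append(SequenceRegion(
                    chrom=chrom, start=start, end=end,
                    summit_offset=summit, name=name))
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from None
    return regions


def read_fasta(path) -> list[tuple[str, str]]:
    """(id, uppercased sequence) pairs; duplicate ids are an error."""
    from Bio import SeqIO

    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise FormatError(f"duplicate FASTA id {record.id!r} in {path}")
        seen.add(record.id)
        out.append((record.id, str(record.seq).upper()))
    return out


def write_fasta(path, records: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")


# ---------------------------------------------------------------------------
# Count matrix round trip


def write_count_matrix(matrix: KmerCountMatrix, prefix) -> None:
    """MatrixMarket triplets plus pattern and row-id sidecars at
    ``prefix``.mtx / ``prefix``.patterns.txt / ``prefix``.rows.txt."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    scipy_io.mmwrite(str(prefix) + ".mtx", matrix.entries.tocoo(),
                     field="integer")
    vocab = matrix.vocabulary
    with open(str(prefix) + ".patterns.txt", "w") as fh:
        fh.write(f"# k={vocab.k} max_run={vocab.max_run} "
                 f"signature={vocab.signature}\n")
        fh.write("\n".join(vocab.patterns) + "\n")
    with open(str(prefix) + ".rows.txt", "w") as fh:
        for rid in matrix.row_ids:
            fh.write(rid + "\n")


def load_count_matrix(prefix, vocab: KmerVocabulary | None = None) -> KmerCountMatrix:
    """Inverse of :func:`write_count_matrix`.

    The vocabulary is rebuilt from the sidecar header (or checked against a
    supplied one); a signature mismatch is a hard error.
    """
    prefix = Path(prefix)
    with open(str(prefix) + ".patterns.txt") as fh:
        header = fh.readline().strip()
    meta = dict(item.split("=", 1) for item in header.lstrip("# ").split())
    if vocab is None:
        vocab = build_vocabulary(int(meta["k"]), int(meta["max_run"]))
    if vocab.signature != meta["signature"]:
        raise FormatError(
            f"vocabulary signature mismatch for {prefix}: sidecar has "
            f"{meta['signature']}, expected {vocab.signature}")
    entries = sparse.csr_matrix(scipy_io.mmread(str(prefix) + ".mtx"),
                                dtype=np.int64)
    if entries.shape[1] != vocab.D:
        raise FormatError(f"matrix width {entries.shape[1]} != D {vocab.D}")
    row_ids = Path(str(prefix) + ".rows.txt").read_text().splitlines()
    return KmerCountMatrix(entries=entries, vocabulary=vocab, row_ids=row_ids)


# ---------------------------------------------------------------------------
# Latent matrices, mappings, probes


def write_latent(path, latent: LatentMatrix, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        cols = "\t".join(f"z{m}" for m in range(latent.M))
        fh.write(f"id\t{cols}\n")
        for rid, row in zip(latent.row_ids, latent.rows):
            vals = "\t".join(f"{v:.8g}" for v in row)
            fh.write(f"{rid}\t{vals}\n")


def read_latent(path, mode: str = "posterior_mean") -> LatentMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    return LatentMatrix(rows=df.iloc[:, 1:].to_numpy(dtype=np.float64),
                        mode=mode, row_ids=df.iloc[:, 0].astype(str).tolist())


def write_mapping(path, mapping: TFMapping, header_comment: str = "") -> None:
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("dimension\ttf\tp_value\n")
        for m, t, p in sorted(mapping.entries):
            fh.write(f"{m}\t{t}\t{p:.6g}\n")


def read_mapping(path) -> TFMapping:
    df = pd.read_csv(path, sep="\t", comment="#")
    entries = [(int(r.dimension), str(r.tf), float(r.p_value))
               for r in df.itertuples()]
    return TFMapping(entries=entries)


def read_probes(path) -> tuple[list[str], list[str]]:
    """Labeled probes from a 2-column TSV (sequence, tf) or FASTA whose
    record ids carry the TF name as the prefix before the first '_'."""
    path = Path(path)
    if path.suffix.lower() in (".fa", ".fasta", ".fna"):
        records = read_fasta(path)
        seqs = [s for _, s in records]
        labels = [rid.split("_")[0] for rid, _ in records]
        return seqs, labels
    seqs, labels = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{lineno}: need sequence<TAB>tf")
            if lineno == 1 and parts[0].lower() in ("sequence", "seq"):
                continue
            seqs.append(parts[0].upper())
            labels.append(parts[1])
    return seqs, labels


def write_probes(path, sequences: list[str], labels: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\ttf\n")
        for s, t in zip(sequences, labels):
            fh.write(f"{s}\t{t}\n")


@dataclass
class RunConfig:
    """Pipeline-wide configuration, YAML round-trippable.

    Bundles the vocabulary parameters, training hyperparameters and
    interpretation defaults so a whole run is reproducible from one file.
    """

    k: int = 8
    max_run: int = 2
    window: int = 200
    M: int = 100
    alpha_init: float = 10.0
    burn_in_steps: int = 150_000
    max_steps: int = 300_000
    batch_size: int = 128
    learning_rate: float = 3e-4
    seed: int = 0
    p_threshold: float = 0.05
    top_n: int = 3
    motif_probe_len: int = 10
    motif_top_n: int = 200

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - {f.name for f in fields(cls)}
        if unknown:
            raise FormatError(f"unknown config keys in {path}: {sorted(unknown)}")
        return cls(**data)

    def train_config(self, **overrides):
        from bindvae.dvae import TrainConfig

        kwargs = {
            "alpha_init": self.alpha_init,
            "burn_in_steps": self.burn_in_steps,
            "max_steps": self.max_steps,
            "batch_size": self.batch_size,
            "learning_rate": self.learning_rate,
            "seed": self.seed,
            "M": self.M,
        }
        kwargs.update(overrides)
        return TrainConfig(**kwargs)


def config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def write_manifest(path, stage: str, config: dict, outputs: list[str]) -> None:
    """Machine-readable provenance record for one pipeline stage."""
    import bindvae

    manifest = {
        "stage": stage,
        "config": config,
        "config_hash": config_hash(config),
        "outputs": outputs,
        "versions": {"bindvae": bindvae.__version__, "numpy": np.__version__},
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
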