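# bindvae

A Dirichlet variational autoencoder over bag-of-k-mers representations of
chromatin-accessible regions, for people who want to know *which
transcription factors' binding signals* live in their ATAC-seq peaks
without TF labels, ChIP-seq, or a motif database.

Each peak (a 200 bp window around the summit) is represented as a bag of
wildcard 8-mers: all 8-mers with up to two consecutive wildcard positions,
a k-mer and its reverse complement collapsed into one canonical feature
(D = 112,800 features).  The model is a VAE with a Dirichlet latent space:

    z_i ~ Dirichlet(alpha),    x_i ~ Multinomial(n_i, z_i^T theta)

so each latent dimension m carries a distribution theta_m over k-mers — a
candidate binding pattern — and each peak's latent score vector z_i says
how much of each pattern it contains.  Training maximizes the ELBO with
implicit reparameterization through the Gamma composition of the Dirichlet;
the encoder is a 3x300 MLP and the decoder is linear (z^T theta).

On top of the trained model the package provides the interpretation
machinery:

- **dimension -> TF mapping**: score labeled SELEX-like probes, then label
  dimension m with TF t when t's probes rank significantly higher than all
  other probes (one-sided Mann-Whitney U, p < 0.05; many-to-many).
- **peak -> TF assignment**: each peak's top-3 dimensions, translated
  through the mapping.
- **de novo motifs**: enumerate all 524,800 canonical 10-mers, score them
  with the model, and build a PWM from the 200 best for a dimension
  (deterministic consensus-anchored alignment; MEME-format output).
- **composite motifs** from sampled 15-mers, for cooperative binding.
- **accessibility scores** (per-topic latent mass over all peaks) and a
  CLR transform for cross-model comparison.
- a **synthetic-data generator** that plants PWM-sampled motif instances
  into Dirichlet-mixed peaks and probes, with full ground-truth logs.

Everything runs in numpy/scipy with hand-derived gradients — no deep
learning framework — and is bit-reproducible from a seed.

## Worked example

Simulate a small world (3 planted TF motifs, 2000 peaks), train, and
interpret (shell interface; every command is also a library call):

```
bindvae simulate --n-peaks 2000 --n-tfs 3 --seed 7 --out sim/
bindvae featurize --fasta sim/peaks.fa --k 6 --out peaks
bindvae train --counts peaks --latent-dim 10 --alpha 10 \
              --burn-in 5000 --max-steps 5000 --batch 128 --lr 3e-4 \
              --seed 7 --out model.npz
bindvae featurize --fasta sim/probes.fa --k 6 --out probes   # or probes.tsv
bindvae infer --counts probes --model model.npz --mode mean --out latent_probes.tsv
bindvae map-tfs --latent latent_probes.tsv --probe-labels sim/probes.tsv \
                --p 0.05 --out mapping.tsv
bindvae motifs --model model.npz --dimension 0 --probe-len 10 --out motif.meme
```

`map-tfs` reports `mapped 10 (dimension, TF) pairs covering 3 TFs`;
`mapping.tsv` starts

    dimension  tf    p_value
    0          TF0   2.29872e-85
    1          TF0   5.99493e-47
    2          TF2   3.46128e-84
    3          TF1   0.000248517

meaning e.g. dimension 0 ranks TF0's probes above all other probes with
Mann-Whitney p = 2.3e-85 — that dimension has learned TF0's binding
pattern (the mapping is many-to-many: TF0 also marks dimension 1).
`motifs` then reconstructs dimension 0 de novo and logs
`dimension 0 consensus: GGTGTTAACA`; the planted TF0 consensus in
`sim/truth.json` is GGTGTTAACC — recovered within one mismatch, without
the model ever seeing a TF label during training.  `motif.meme` holds the
full PWM in MEME minimal format.

For real data, start from `bindvae featurize --peaks peaks.narrowPeak
--genome hg38.fa --k 8 --window 200 --out peaks` and use the paper-scale
training defaults (`--latent-dim 100 --burn-in 150000 --max-steps 300000
--lr 3e-4`).

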