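# Methods

## The model

`bindvae` models chromatin-accessible regions as admixtures of sequence
"topics".  Each 200 bp region i is represented as a bag of wildcard k-mers:
every k-length window (k = 8 by default) made solely of A/C/G/T increments
the canonical feature of the exact window, of each single-wildcard variant,
and of each two-consecutive-wildcard variant, so a valid window contributes
2k counts.  A k-mer and its reverse complement are one feature (canonical
form = lexicographic minimum under A < C < G < T < N), which makes the
representation strand-symmetric by construction.  For k = 8 with wildcard
runs up to 2 the feature space has D = 112,800 dimensions; the package also
supports k = 6 (D = 5,800), which is what the desk-scale test worlds use.

The generative model is a Dirichlet variational autoencoder:

    z_i ~ Dirichlet(alpha),          z_i on the M-simplex
    x_i ~ Multinomial(n_i, z_i^T theta)

where row m of theta (M x D, row-stochastic) is the k-mer distribution of
topic m — ideally the binding preference of one transcription factor, or a
genomic-background signature.  The encoder is a 3-layer fully connected
ReLU network with 300 units per layer whose output is mapped through
softplus (+1e-4) to the concentration vector alpha_hat of the variational
posterior Dirichlet(alpha_hat).  Raw integer counts are fed to the encoder
without normalization: the multinomial likelihood consumes counts directly
and no transform is part of the model.

Training minimizes the negative ELBO

    -E_q[log p(x|z)] + KL(Dirichlet(alpha_hat) || Dirichlet(alpha))

with one Monte-Carlo latent sample per example per step.  Sampling goes
through the Gamma composition z_m = g_m / sum_j g_j, g_m ~ Gamma(alpha_hat_m, 1),
and gradients flow through the draws by implicit reparameterization:
dg/da = -(dF/da)/f(g; a), with F the regularized incomplete gamma CDF
(the shape-derivative is computed by central finite difference with a
relative step of 1e-4, accurate to ~1e-6 relative error against the
inverse-CDF path) and f the Gamma density.  The Dirichlet KL and its
gradients are closed form.  The whole forward/backward pass is hand-derived
and runs in numpy/scipy (float32 training arithmetic, float64 for the
likelihood and KL); the optimizer is Adam.  A finite-difference check on
the decoder logits and a Monte-Carlo check on the KL guard the derivation
in the test suite.

The decoder is parameterized as the row-softmax of unconstrained logits,
so the simplex constraint on theta can never be violated regardless of the
prior concentration — large shared priors are known to cause constraint
violations when theta is parameterized directly.

## Hyperparameters

| parameter | default | notes |
|---|---|---|
| k, max_run | 8, 2 | D = 112,800; k = 6 (D = 5,800) for CPU-scale tests |
| M | 100 | latent dimensions (topics) |
| alpha_init | 10 | shared prior concentration; useful range ~[10, 20] |
| burn-in | 150,000 steps | prior frozen, then optimized in log-space |
| max steps | 300,000 | |
| batch | 128 | |
| learning rate | 3e-4 | Adam |

The prior concentration is optimized in log-space after burn-in
(positivity).  All randomness flows from one seeded generator, so training
and inference are bit-reproducible at a fixed thread count.

Two initialization/optimization choices matter in practice:

- **Decoder rows start at the corpus log-frequency.**  Every decoder row is
  initialized to the log of the aggregate k-mer frequency of the training
  counts (plus small noise) rather than near-uniform.  The shared
  background component of the data is then explained at step 0 and the
  reconstruction gradient differentiates rows by their covariance
  structure from the start; with a near-uniform initialization most of a
  short schedule is spent moving every row toward the same background
  distribution.
- **Input-layer weight decay calibrated to the schedule.**  k-mer features
  that are rare in the corpus receive almost no gradient, so their random
  initialization weights would survive training and inject noise exactly
  where it hurts: when scoring short sequences (10-mers) whose few counts
  may land on rare features.  The optimizer applies decoupled weight decay
  to the input layer with rate log(10)/(lr x max_steps), so a weight that
  never receives gradient shrinks tenfold over the run while the decay
  equilibrium for consistently-updated weights (|w| ~ 1/lambda) sits two
  orders of magnitude above the working weight scale and leaves them
  unaffected.

Inference uses the deterministic posterior mean z = alpha_hat/sum(alpha_hat)
for all downstream analyses (mapping, scoring, motif reconstruction);
sampled inference is available but the posterior mean is the stable choice
for deterministic interpretation, and downstream rankings only need the
mean.

## Interpreting the latent space

**Dimension -> TF mapping.**  Labeled SELEX-like probes are featurized and
scored by the trained model.  For each (dimension m, TF t), the latent
scores of t's probes in column m are tested against the scores of all other
probes in that column with a one-sided Mann-Whitney U test ("t's probes
rank higher"); every pair with p < 0.05 is recorded.  The mapping is
deliberately many-to-many — paralogous TFs share binding preferences and
land on the same dimension.  No multiple-testing correction is applied by
default (a Benjamini-Hochberg option exists), and a best-only variant
keeps just the lowest-p TF per dimension.  The test is exact (full
enumeration) for tie-free samples with combined n <= 25 and a
tie-corrected normal approximation otherwise; all-tied degenerate input is
reported as p = 0.5.

**Peak annotation.**  Each peak's top-3 dimensions by latent score (ties
broken toward lower dimension index) are translated through the mapping; a
dimension mapped to several TFs contributes its lowest-p TF, and unmapped
dimensions yield an explicit `unmapped:<dim>` token rather than being
silently dropped.

**Accessibility scores.**  score_m = sum_i z_im over all peaks: the total
membership of topic m, comparable across topics (columns of a
posterior-mean latent matrix).  A centered log-ratio transform
(pseudocount 1e-6) is provided for comparing compositional latent vectors
across models.

**De novo motifs.**  Short wildcard k-mers cap the motif length visible in
a single decoder row, so motifs are reconstructed by scoring longer exact
n-mers with the model itself: enumerate all canonical n-mers (524,800 at
n = 10), run posterior-mean inference on their k-mer bags, rank by the
latent score of the dimension of interest, and build a PWM from the top
200.  PWM construction is a deterministic consensus-anchored ungapped
alignment: the top-ranked sequence anchors the frame, every other sequence
is aligned over both strands and all offsets with overlap >= 6 (the
shortest motif width worth reporting), choosing maximal matches with ties
broken toward smaller offsets and the forward strand; column counts get a
0.25 pseudocount.  This replaces an external motif finder so that the
procedure is dependency-free and bit-reproducible; the ranked top set can
be exported as FASTA for any external tool.  Composite (cooperative
binding) motifs use 15-mers sampled uniformly without replacement at 10%
of the canonical space — the full 15-mer space (>5e8) is never enumerated;
sampling draws random codes and canonicalizes them numerically.

**Ensemble selection.**  Candidate models (e.g. across prior settings) are
ranked by the number of distinct TFs their latent space maps at p < 0.05;
the top three are kept (ties broken by lower final training loss) and
their TF sets are unioned.

## The synthetic data generator

The generator emulates exactly the structure the model assumes, so that
every stage is testable without downloads.  Toy motifs are PWMs with a
random consensus (lengths 6-10) carrying probability `sharpness` (default
0.9) on the consensus base per column; consensi are rejection-resampled to
pairwise, strand- and offset-minimized Hamming distance >= 3 so recovery is
well-defined.  Peaks draw topic proportions from Dirichlet(alpha_true)
(default all-ones: heterogeneous peaks) over the T motif topics plus one
explicit background topic that plants nothing — mirroring the
genomic-background factors real models learn.  Three instance draws per
peak are sampled from the mixture; non-background instances are PWM-sampled,
strand-flipped at random, and placed uniformly without overlap on i.i.d.
background DNA at GC 0.45 (roughly the GC content of human regulatory
regions).  SELEX-like probes are 20 bp with a single planted instance at a
random offset and strand, 200 probes per toy TF.  Ground truth (mixtures,
instance positions, per-peak background seeds) is logged so every sequence
can be reconstructed exactly.

What the generator does *not* emulate: Tn5 insertion bias, soft-masked
repeats and low-complexity sequence, correlated motif co-occurrence
(except when constructed deliberately), non-uniform peak widths, and
composition differences between peaks and flanks.  Passing recovery tests
therefore demonstrates that the inference machinery works when the model's
assumptions hold, not that the model resolves real chromatin.

## Scaled test world

The expensive end-to-end checks run one seeded synthetic world: 5 motifs,
5,000 peaks of 200 bp, k = 6 (D = 5,800), M = 10, 5,000 training steps,
batch 128 at learning rate 3e-4, 200 probes per toy TF.  The prior
concentration stays frozen for the whole scaled run: at short schedules,
unfreezing it lets the KL term drag the shared concentration toward zero
before the encoder stabilizes, collapsing the posterior (at the full
150k/300k schedule the posterior is settled long before the prior
unfreezes, so late alpha optimization is safe).  The log-frequency decoder
initialization is what makes a 5,000-step schedule viable at all: decoder
rows otherwise spend the entire budget converging toward the shared
background distribution (Adam's per-step update is bounded by the learning
rate, so 5,000 steps move a logit by at most ~1.5).

Two models are trained from different parameter seeds and interpreted as
an ensemble, mirroring the full-scale protocol of aggregating several
models' TF sets: individual short-schedule models reliably map all planted
TFs by probe enrichment, but reconstruct complementary subsets of the
motifs de novo, because the encoder's response to 10-mer inputs (an order
of magnitude sparser than anything seen in training) is the least robust
part of a short-schedule model and varies by initialization.  Motif
reconstruction scores the enumerated canonical 10-mers and a planted
consensus counts as recovered when the reconstructed PWM consensus matches
it within one mismatch, where a core position truncated at the
reconstruction boundary counts as a mismatch (ungapped overlap alignment,
both strands, overlap >= 5).

## Numerical choices and edge cases

- Posterior concentrations are floored at softplus(pre) + 1e-4; Gamma draws
  at 1e-300 before normalization.
- Likelihood probabilities are floored at 1e-300 inside the log; decoder
  softmax is computed in float64 with max-subtraction.
- Windows containing any non-ACGT character contribute nothing; lowercase
  (soft-masked) bases are uppercased and kept.
- Sequences shorter than k featurize to the zero vector (not an error);
  their posterior is driven by the encoder biases alone.
- Ties: k-mer rankings break ties lexicographically (the vocabulary is
  stored in lexicographic order, so a stable sort suffices); top-dimension
  ranking breaks ties toward lower dimension index; PWM alignment ties
  prefer smaller |offset|, then the forward strand.
- The non-standard character order A < C < G < T < N is implemented by
  encoding patterns as base-5 integers, so integer comparison is
  lexicographic comparison and reverse-complement canonicalization is a
  vectorized min.

## Known limitations

- Training is CPU-bound numpy; the full-scale configuration (M = 100,
  D = 112,800, 300k steps) is feasible but slow (order of a day on one
  core).  The implementation is intended to be exact rather than fast.
- The implicit-reparameterization shape-derivative uses a finite
  difference of the incomplete gamma CDF; for extremely large
  concentrations (>1e4) the difference can lose precision.  Training keeps
  concentrations well below that in practice.
- The deterministic PWM builder is ungapped; motifs with variable-length
  spacers are reconstructed only as their dominant register.
- Exact Mann-Whitney p-values are used only for combined n <= 25; at the
  200-probes-per-TF scale the tie-corrected normal approximation is
  standard and accurate.
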