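# Methods

## Sequence representation

Sequences are strings over the 20 standard amino acids. The numeric
dictionary fixes pad = 0 and maps the residues to 1..20 in alphabetical
order (A, C, D, …, Y); a sequence is right-padded with 0 to the fixed model
length L (default 25, covering the CDR3 length range 8–25 the synthetic
generator emits). Codes are rescaled affinely to s = 2·c/20 − 1 ∈ [−1, 1]
so that a tanh output head spans the full code range, with pad at −1.
Continuous model outputs are discretized by the inverse map c = round(10·(s
+ 1)), clamped to [0, 20]; this nearest-code rounding is the simplest
deterministic inverse of the affine scaling. During decoding the first pad
code terminates the sequence, so a fixed-length head yields variable-length
sequences; rows that decode to nothing are excluded and counted.

## Adversarial models

Both architectures share the generator trunk concat(latent 100, frequency
20) → Dense 256 → LeakyReLU(0.2) → BatchNorm(momentum 0.8) → Dense 128 →
LeakyReLU(0.2) → BatchNorm(0.8). The dense variant ends in Dense(L, tanh);
the recurrent variant continues Dense(T·U) → reshape(T, U) → LSTM(128,
sequences) → LSTM(128, sequences) → flatten → Dense(L, tanh), with T
timesteps defaulting to L and U = 128 units. The dense discriminator is
Dense 256/128/64 with LeakyReLU(0.8) between layers and a Dense(1, tanh)
score; since binary cross-entropy needs a probability, the tanh score s is
mapped to (s + 1)/2, which preserves the printed layer while making the
loss well-defined. The recurrent discriminator reads the sequence one
position per timestep: reshape(L, 1) → LSTM(128, sequences) →
LeakyReLU(0.2) → LSTM(64) → LeakyReLU(0.2) → Dense 64 → Dense 32 →
Dense(1, sigmoid). All layer shapes are assertion-checked at call time.

The frequency conditioning input is the real training repertoire's
20-dimensional residue frequency vector, broadcast identically to every
sample; it is the only frequency object the training objective defines, and
using it keeps the KL target coherent with the conditioning.

The networks run on a small reverse-mode automatic-differentiation tape
over numpy arrays (`_nn.py`), written for exactly the operations these
architectures need; the LSTM is expressed per-timestep through column
slicing so every tensor stays two-dimensional. The optimizer is Adam at
learning rate 2·10⁻⁴, batch 64 — standard adversarial-training practice.
Labels are real = 1 / generated = 0 with a probability threshold of 0.5.

## Training objective

Per epoch, the discriminator is updated on real rows (label 1) and
generated rows (label 0) under binary cross-entropy; the generator then
minimizes the flipped-label cross-entropy plus λ·KL(p_real ‖ p_generated),
λ = 1 by default ("the sum" of the two terms). Because decoding is not
differentiable, the gradient uses a soft frequency profile: each continuous
output value is assigned to the 21 code centers with a Gaussian kernel of
bandwidth 0.1 (one code spacing in scaled units); summed weights of the 20
residue codes, renormalized, form a differentiable profile. The per-epoch
KL term recorded in the training history is the exact divergence
kl_divergence(p_real, p_decoded) on hard-decoded sequences, so the reported
quantity is the true discrete divergence while the surrogate only shapes
the gradient. A 20 % held-out split provides validation loss, accuracy and
AUC each epoch; NaN losses abort with the offending epoch named.

KL(p ‖ q) = Σ pᵢ ln(pᵢ/qᵢ) in nats, with q epsilon-smoothed (1e-8, then
renormalized) so empirical profiles with empty bins stay finite and pᵢ = 0
terms contributing zero.

## Baselines

The PWM baseline consumes a MEME minimal-motif letter-probability matrix
(motif discovery itself is out of scope — the PWM is an input artifact) and
samples each position independently from its column; columns off unit sum
by ≤ 1e-3 are renormalized, larger deviations rejected. The Markov baseline
counts first-order (bigram) or second-order (trigram) transitions;
probabilities are exactly count/row-total (no pseudocounts by default, a
Laplace α option for sparse corpora). Generation starts from a pair drawn
from the **empirical** first-pair distribution rather than uniformly —
uniform starts could begin at pairs never observed; a uniform-start switch
exists. A walk reaching a state with no outgoing mass restarts from a fresh
start pair (logged); such dead ends are possible with sparse corpora and
are otherwise unspecified by the procedure.

## Evaluation choices

* **Frequency filter**: a candidate is accepted iff the max-absolute
  per-residue deviation between its own profile and the reference is ≤ the
  threshold. Max-absolute deviation is the simplest metric on the same
  scale as the architecture presets (0.04 dense, 0.14 lstm; 0.05 also
  appears in the literature for the dense variant — 0.04 is the coded
  default).
* **Per-residue Pearson** is defined over paired seeded subsampling
  batches (default 50 batches of 100), both sides drawing from streams
  seeded identically so that identical repertoires give correlation 1.
  The overall Pearson over the 20-residue profiles is exposed separately;
  both readings of "average and individual" correlations are available.
* **KS test** delegates to the standard two-sample implementation with the
  asymptotic p-value; the statistic is verified against a brute-force ECDF
  scan in the tests.
* **t-SNE** uses PCA initialization and a fixed random state (perplexity
  default 10, suited to 35-point groups); runs are reproducible on the same
  backend.
* **Embedding distances**: 2-D KL uses occupancy histograms on a shared
  10×10 grid spanning the joint bounding box with epsilon smoothing
  (documented as asymmetric); Earth Mover's distance solves the transport
  linear program with uniform weights and Euclidean ground cost (verified
  in tests against an independent assignment-problem oracle on equal-size
  sets). Cosine similarity is computed on raw embedding coordinates and is
  therefore origin-dependent. No multiple-testing correction is applied
  anywhere.

## Synthetic data

The generator emulates exactly the features downstream statistics consume:
canonical cysteine…phenylalanine framing, interior residues i.i.d. from a
glycine/serine/tyrosine-rich composition, lengths uniform on 8–25, and a
3,000-sequence default for the uniform-composition non-TCR decoy set. It
deliberately does **not** model V(D)J recombination, germline-gene usage,
positional composition gradients, or residue correlations — so passing
tests demonstrate the pipeline's statistical and numerical correctness on
composition-structured repertoires, not biological fidelity of generated
receptors on real data. A Markov-corpus generator samples exactly from a
fitted chain's transition law for parameter-recovery experiments. All
generators take a single integer seed from which all randomness flows.

## Problem sizes and numerical notes

Training experiments use 2,000-sequence corpora for 30 epochs (three seeds,
medians reported): sufficient for the dense discriminator to reach held-out
accuracy ≥ 0.9 against untrained-generator output, and for a heavy KL
weight (λ = 50) to measurably reduce the recorded KL term from first to
final epoch. Statistical convergence checks use 5,000 Markov sequences
(transition recovery within ±0.02) and 10,000 PWM samples (columns within
±0.015), both comfortably above three binomial standard errors. Oracle
comparisons run at 1e-6 tolerance. Degenerate inputs are handled
explicitly: zero-variance profiles make Pearson undefined (reported
missing), a scorer predicting no positives leaves precision undefined,
single-letter corpora cannot be Markov-fitted, and all-pad rows are dropped
on decode.

## Known limitations

Adversarial training at these scales does not produce generators whose
composition passes the strict 0.04 filter; the looser 0.14 preset and the
KL-weighted objective show the intended direction of improvement. The
recurrent variant trains an order of magnitude slower than the dense one
under the numpy tape and is exercised at reduced sizes. Earth Mover's
distance between t-SNE embeddings from *separate* runs is only loosely
comparable, since t-SNE fixes no global scale; comparisons in the tests
keep the embedding run fixed or the contrast large.
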