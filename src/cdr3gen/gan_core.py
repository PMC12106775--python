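"""Adversarial sequence models: two generator/discriminator architectures
trained under a combined objective of binary cross-entropy and the KL
divergence between real and generated amino-acid frequency profiles.

Both variants share a dense trunk in the generator — concat(latent, freq
conditioning) -> Dense 256 -> LeakyReLU(0.2) -> BatchNorm(0.8) -> Dense 128
-> LeakyReLU(0.2) -> BatchNorm(0.8) — and differ in the head:

* ``dense_leakyrelu``: Dense(L, tanh) head; discriminator is a LeakyReLU(0.8)
  MLP with a tanh score mapped to probability via (s + 1) / 2.
* ``lstm``: Dense(timesteps * units) reshaped to a sequence and passed
  through two stacked LSTMs before the tanh head; discriminator reads the
  sequence one position per timestep through stacked LSTMs and ends in a
  sigmoid unit.

The generator emits continuous values in [-1, 1]; decoding to residues is by
nearest-code rounding. Because that decode is not differentiable, the KL
penalty trains against a soft (kernel-weighted) frequency profile of the
continuous outputs, while the recorded per-epoch KL term is the exact
divergence on hard-decoded sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import _nn
from ._nn import Adam, BatchNorm, Dense, LSTMLayer, Tensor, concat
from .io_encoding import DEFAULT_MAX_LEN, EncodedBatch, Repertoire, decode_sequences, encode_sequences
from .evaluation import FrequencyProfile, amino_acid_frequencies

logger = logging.getLogger("cdr3gen")

VARIANT_DENSE = "dense_leakyrelu"
VARIANT_LSTM = "lstm"

_BCE_EPS = 1e-7


@dataclass
class GANConfig:
    """Hyperparameters of both architectures.

    The LeakyReLU slopes (0.2 in the generator, 0.8 in the dense
    discriminator) and batch-norm momentum 0.8 follow the published layer
    table; ``kl_weight`` defaults to 1 so the generator objective is the
    plain sum of adversarial loss and KL penalty.
    """

    variant: str = VARIANT_DENSE
    latent_dim: int = 100
    sequence_length: int = DEFAULT_MAX_LEN
    lstm_units: int = 128
    timesteps: int | None = None  # defaults to sequence_length
    leaky_slope_gen: float = 0.2
    leaky_slope_disc_dense: float = 0.8
    batchnorm_momentum: float = 0.8
    kl_weight: float = 1.0
    epochs: int = 30
    batch_size: int = 64
    learning_rate: float = 2e-4
    validation_split: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if self.variant not in (VARIANT_DENSE, VARIANT_LSTM):
            raise ValueError(f"unknown variant {self.variant!r}; "
                             f"expected {VARIANT_DENSE!r} or {VARIANT_LSTM!r}")
        if not (0 < self.leaky_slope_gen < 1 and 0 < self.leaky_slope_disc_dense < 1):
            raise ValueError("LeakyReLU slopes must lie in (0, 1)")
        if self.kl_weight < 0:
            raise ValueError("kl_weight must be nonnegative")
        if self.sequence_length <= 0:
            raise ValueError("sequence_length must be positive")
        if self.timesteps is None:
            self.timesteps = self.sequence_length


@dataclass
class FrequencyConditioner:
    """The real repertoire's residue-frequency vector, concatenated onto the
    latent input of every generated sample."""

    profile: FrequencyProfile

    @classmethod
    def from_repertoire(cls, rep: Repertoire) -> "FrequencyConditioner":
        return cls(profile=amino_acid_frequencies(rep))

    @property
    def vector(self) -> np.ndarray:
        return self.profile.freq


@dataclass
class TrainingHistory:
    """Per-epoch metrics: losses, discriminator accuracy/AUC and the KL term."""

    records: list[dict] = field(default_factory=list)

    def append(self, **metrics) -> None:
        for k, v in metrics.items():
            if isinstance(v, float) and not np.isfinite(v):
                raise RuntimeError(f"non-finite metric {k} at epoch {metrics.get('epoch')}")
        self.records.append(metrics)

    def __len__(self) -> int:
        return len(self.records)

    def series(self, key: str) -> list[float]:
        return [r[key] for r in self.records]


# ---------------------------------------------------------------------------
# Architectures
# ---------------------------------------------------------------------------


class Generator:
    """Maps (latent noise, frequency conditioning) to n x L values in [-1, 1]."""

    def __init__(self, cfg: GANConfig, rng: np.random.Generator):
        self.cfg = cfg
        L, T, U = cfg.sequence_length, cfg.timesteps, cfg.lstm_units
        in_dim = cfg.latent_dim + 20
        self.d1 = Dense(in_dim, 256, rng)
        self.bn1 = BatchNorm(256, momentum=cfg.batchnorm_momentum)
        self.d2 = Dense(256, 128, rng)
        self.bn2 = BatchNorm(128, momentum=cfg.batchnorm_momentum)
        if cfg.variant == VARIANT_DENSE:
            self.head = Dense(128, L, rng)
            self.layers = [self.d1, self.bn1, self.d2, self.bn2, self.head]
        else:
            self.d3 = Dense(128, T * U, rng)
            self.lstm1 = LSTMLayer(U, 128, T, rng, return_sequences=True)
            self.lstm2 = LSTMLayer(128, 128, T, rng, return_sequences=True)
            self.head = Dense(T * 128, L, rng)
            self.layers = [self.d1, self.bn1, self.d2, self.bn2,
                           self.d3, self.lstm1, self.lstm2, self.head]
        self.layer_shapes = [(type(l).__name__, getattr(l, "n_in", getattr(l, "n_features", None)),
                              getattr(l, "n_out", getattr(l, "units", getattr(l, "n_features", None))))
                             for l in self.layers]

    def forward(self, z: Tensor, freq: Tensor, training: bool = True) -> Tensor:
        slope = self.cfg.leaky_slope_gen
        x = concat([z, freq], axis=1)
        x = self.bn1(self.d1(x).leaky_relu(slope), training)
        x = self.bn2(self.d2(x).leaky_relu(slope), training)
        if self.cfg.variant == VARIANT_DENSE:
            out = self.head(x).tanh()
        else:
            x = self.d3(x)  # (n, T*U), read as T blocks of width U
            x = self.lstm1(x)
            x = self.lstm2(x)  # flattened sequence output (n, T*128)
            out = self.head(x).tanh()
        assert out.shape[1] == self.cfg.sequence_length
        return out

    @property
    def parameters(self) -> list[Tensor]:
        return [p for l in self.layers for p in l.parameters]

    @property
    def n_parameters(self) -> int:
        return sum(l.n_parameters for l in self.layers)


class Discriminator:
    """Maps n x L sequence representations to real-vs-generated probabilities."""

    def __init__(self, cfg: GANConfig, rng: np.random.Generator):
        self.cfg = cfg
        L = cfg.sequence_length
        if cfg.variant == VARIANT_DENSE:
            self.d1 = Dense(L, 256, rng)
            self.d2 = Dense(256, 128, rng)
            self.d3 = Dense(128, 64, rng)
            self.head = Dense(64, 1, rng)
            self.layers = [self.d1, self.d2, self.d3, self.head]
        else:
            # input reshaped to (L, 1): one residue value per timestep
            self.lstm1 = LSTMLayer(1, 128, L, rng, return_sequences=True)
            self.lstm2 = LSTMLayer(128, 64, L, rng, return_sequences=False)
            self.d1 = Dense(64, 64, rng)
            self.d2 = Dense(64, 32, rng)
            self.head = Dense(32, 1, rng)
            self.layers = [self.lstm1, self.lstm2, self.d1, self.d2, self.head]
        self.layer_shapes = [(type(l).__name__, getattr(l, "n_in", None),
                              getattr(l, "n_out", getattr(l, "units", None)))
                             for l in self.layers]

    def forward(self, x: Tensor) -> Tensor:
        """Return probabilities in [0, 1], shape (n, 1)."""
        if self.cfg.variant == VARIANT_DENSE:
            s = self.cfg.leaky_slope_disc_dense
            h = self.d1(x).leaky_relu(s)
            h = self.d2(h).leaky_relu(s)
            h = self.d3(h).leaky_relu(s)
            score = self.head(h).tanh()  # raw score in [-1, 1]
            prob = (score + 1.0) * 0.5
        else:
            s = 0.2
            h = self.lstm1(x).leaky_relu(s)
            h = self.lstm2(h).leaky_relu(s)
            h = self.d1(h).leaky_relu(s)
            h = self.d2(h)
            prob = self.head(h).sigmoid()
        assert prob.shape == (x.shape[0], 1)
        return prob

    def predict_proba(self, scaled: np.ndarray) -> np.ndarray:
        """Probabilities for a plain numpy batch of scaled representations."""
        return self.forward(Tensor(np.atleast_2d(scaled))).data.ravel()

    def score_sequences(self, sequences: list[str]) -> np.ndarray:
        rep = Repertoire(list(sequences), label="generated", source="scoring")
        batch = encode_sequences(rep, length=self.cfg.sequence_length)
        return self.predict_proba(batch.scaled)

    @property
    def parameters(self) -> list[Tensor]:
        return [p for l in self.layers for p in l.parameters]

    @property
    def n_parameters(self) -> int:
        return sum(l.n_parameters for l in self.layers)


def build_generator(cfg: GANConfig, seed: int | None = None) -> Generator:
    return Generator(cfg, np.random.default_rng(cfg.seed if seed is None else seed))


def build_discriminator(cfg: GANConfig, seed: int | None = None) -> Discriminator:
    return Discriminator(cfg, np.random.default_rng((cfg.seed if seed is None else seed) + 1))


# ---------------------------------------------------------------------------
# KL divergence
# ---------------------------------------------------------------------------


def kl_divergence(p, q, epsilon: float = 1e-8) -> float:
    """KL(p || q) in nats over discrete distributions.

    ``epsilon`` is added to q, which is then renormalized, so empirical
    profiles with empty bins stay finite; p_i = 0 terms contribute 0.
    """
    p = p.freq if isinstance(p, FrequencyProfile) else np.asarray(p, dtype=float)
    q = q.freq if isinstance(q, FrequencyProfile) else np.asarray(q, dtype=float)
    if (p < 0).any() or (q < 0).any():
        raise ValueError("distributions must be nonnegative")
    if abs(p.sum() - 1.0) > 1e-6 or abs(q.sum() - 1.0) > 1e-6:
        raise ValueError("both distributions must sum to 1 within 1e-6")
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    q = q + epsilon
    q = q / q.sum()
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def _soft_frequency_kl(gen_out: Tensor, real_profile: np.ndarray,
                       bandwidth: float = 0.1, epsilon: float = 1e-8) -> Tensor:
    """Differentiable surrogate of KL(real || generated profile).

    Each continuous output value is softly assigned to the 21 code centers
    with a Gaussian kernel (bandwidth = one code spacing); summed weights of
    codes 1..20, renormalized, form a soft residue profile the gradient can
    move.
    """
    centers = 2.0 * np.arange(21) / 20.0 - 1.0
    masses = []
    for k in range(21):
        w = (-((gen_out - centers[k]) * (1.0 / bandwidth)).square()).exp()
        masses.append(w.sum())
    residue_mass = masses[1:]  # exclude pad
    total = residue_mass[0]
    for m in residue_mass[1:]:
        total = total + m
    kl = None
    for k in range(20):
        pk = real_profile[k]
        if pk <= 0:
            continue
        qk = residue_mass[k] / total + epsilon
        term = (-qk.log() + float(np.log(pk))) * pk
        kl = term if kl is None else kl + term
    return kl


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------


def _bce(prob: Tensor, target: float) -> Tensor:
    """Binary cross-entropy of probabilities against a constant label."""
    p = prob * (1 - 2 * _BCE_EPS) + _BCE_EPS  # keep log arguments positive
    if target == 1.0:
        return (-(p.log())).mean()
    if target == 0.0:
        return (-((1.0 - p).log())).mean()
    return (-(p.log() * target + (1.0 - p).log() * (1.0 - target))).mean()


def _auc(labels: np.ndarray, scores: np.ndarray) -> float:
    from sklearn.metrics import roc_auc_score

    if len(np.unique(labels)) < 2:
        return float("nan")
    return float(roc_auc_score(labels, scores))


def generate_sequences(generator: Generator, n: int, conditioner: FrequencyConditioner,
                       seed: int = 0, return_batch: bool = False):
    """Sample ``n`` latent vectors, run the generator in inference mode and
    decode the outputs to a repertoire (all-pad rows are excluded)."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    z = Tensor(rng.standard_normal((n, generator.cfg.latent_dim)))
    freq = Tensor(np.tile(conditioner.vector, (n, 1)))
    out = generator.forward(z, freq, training=False).data
    rep = decode_sequences(out, label="generated", scaled=True)
    return (rep, out) if return_batch else rep


def train_gan(real: EncodedBatch, cfg: GANConfig,
              conditioner: FrequencyConditioner,
              freeze_generator: bool = False):
    """Alternating adversarial training.

    Each epoch the discriminator sees real rows (label 1) and freshly
    generated rows (label 0) under binary cross-entropy; the generator (unless
    frozen) minimizes the flipped-label cross-entropy plus
    ``kl_weight`` times the soft-profile KL surrogate. A held-out split
    (``validation_split``) provides validation loss/accuracy/AUC each epoch,
    and the recorded KL term is the exact divergence between the conditioning
    profile and the hard-decoded generated profile.

    Returns (generator, discriminator, history).
    """
    if real.n == 0:
        raise ValueError("real batch is empty")
    n_val = int(round(real.n * cfg.validation_split))
    if cfg.validation_split > 0 and n_val == 0:
        raise ValueError("validation split leaves no held-out rows")
    rng = np.random.default_rng(cfg.seed)
    perm = rng.permutation(real.n)
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    X_train = real.scaled[train_idx]
    X_val = real.scaled[val_idx]

    gen = build_generator(cfg)
    disc = build_discriminator(cfg)
    opt_d = Adam(disc.parameters, lr=cfg.learning_rate)
    opt_g = Adam(gen.parameters, lr=cfg.learning_rate)
    history = TrainingHistory()
    freq_row = conditioner.vector
    real_profile = conditioner.vector

    def latent(nb):
        return Tensor(rng.standard_normal((nb, cfg.latent_dim)))

    def freq(nb):
        return Tensor(np.tile(freq_row, (nb, 1)))

    for epoch in range(cfg.epochs):
        order = rng.permutation(X_train.shape[0])
        d_losses, g_losses = [], []
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            nb = len(idx)
            xb = Tensor(X_train[idx])

            # discriminator step: real=1, generated=0 (generator detached)
            fake = gen.forward(latent(nb), freq(nb), training=True)
            fake_detached = Tensor(fake.data)
            opt_d.zero_grad()
            loss_d = 0.5 * (_bce(disc.forward(xb), 1.0)
                            + _bce(disc.forward(fake_detached), 0.0))
            loss_d.backward()
            opt_d.step()
            d_losses.append(float(loss_d.data))

            if freeze_generator:
                continue
            # generator step: fool the discriminator + KL pressure
            opt_g.zero_grad()
            gen_out = gen.forward(latent(nb), freq(nb), training=True)
            loss_g = _bce(disc.forward(gen_out), 1.0)
            if cfg.kl_weight > 0:
                soft_kl = _soft_frequency_kl(gen_out, real_profile)
                if soft_kl is not None:
                    loss_g = loss_g + cfg.kl_weight * soft_kl
            loss_g.backward()
            opt_g.step()
            g_losses.append(float(loss_g.data))

        if not np.isfinite(np.mean(d_losses)):
            raise RuntimeError(f"NaN discriminator loss at epoch {epoch}")

        # epoch-end evaluation on the held-out split plus fresh fakes
        n_eval = max(len(X_val), 1)
        gen_rep, gen_raw = generate_sequences(
            gen, n_eval, conditioner, seed=int(rng.integers(2**31)), return_batch=True)
        eval_x = np.vstack([X_val, gen_raw]) if len(X_val) else gen_raw
        eval_y = np.concatenate([np.ones(len(X_val)), np.zeros(n_eval)])
        probs = disc.predict_proba(eval_x)
        val_loss = float(-np.mean(eval_y * np.log(probs + _BCE_EPS)
                                  + (1 - eval_y) * np.log(1 - probs + _BCE_EPS)))
        val_acc = float(np.mean((probs >= 0.5) == eval_y))
        val_auc = _auc(eval_y, probs)
        if len(gen_rep):
            gen_profile = amino_acid_frequencies(gen_rep)
            kl_term = kl_divergence(real_profile, gen_profile.freq)
        else:
            kl_term = float("inf")
        history.append(
            epoch=epoch,
            d_loss=float(np.mean(d_losses)),
            g_loss=float(np.mean(g_losses)) if g_losses else 0.0,
            val_loss=val_loss,
            val_accuracy=val_acc,
            val_auc=val_auc,
            kl_term=kl_term,
        )
        logger.debug("epoch %d: d_loss=%.4f g_loss=%.4f val_acc=%.3f kl=%.4f",
                     epoch, history.records[-1]["d_loss"],
                     history.records[-1]["g_loss"], val_acc, kl_term)
    return gen, disc, history


# ---------------------------------------------------------------------------
# Model persistence (weights + config as .npz / JSON for the CLI)
# ---------------------------------------------------------------------------


def save_model(path, gen: Generator, disc: Discriminator, cfg: GANConfig,
               conditioner: FrequencyConditioner) -> None:
    import json
    from dataclasses import asdict
    from pathlib import Path

    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    arrays = {}
    for tag, model in (("gen", gen), ("disc", disc)):
        for i, p in enumerate(model.parameters):
            arrays[f"{tag}_{i}"] = p.data
    arrays["freq_vector"] = conditioner.vector
    np.savez(path / "weights.npz", **arrays)
    (path / "config.json").write_text(json.dumps(asdict(cfg), indent=2))


def load_model(path):
    import json
    from pathlib import Path

    path = Path(path)
    cfg = GANConfig(**json.loads((path / "config.json").read_text()))
    gen, disc = build_generator(cfg), build_discriminator(cfg)
    data = np.load(path / "weights.npz")
    for tag, model in (("gen", gen), ("disc", disc)):
        for i, p in enumerate(model.parameters):
            p.data = data[f"{tag}_{i}"]
    conditioner = FrequencyConditioner(
        profile=FrequencyProfile(freq=data["freq_vector"], n_residues=0))
    return gen, disc, cfg, conditioner
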