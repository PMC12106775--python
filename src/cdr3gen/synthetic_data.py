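"""Seeded synthetic repertoires with the statistical structure the models
and evaluation metrics assume.

Three generators: CDR3-like sequences (canonical C...F framing, length 8-25,
TCR-biased interior composition), compositionally flat non-TCR decoys, and
corpora sampled exactly from a known Markov model for parameter-recovery
experiments. Realism is deliberately limited to framing, composition and
length; no V(D)J recombination or germline-gene usage is modeled.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_encoding import AMINO_ACIDS, Repertoire

# Interior-residue bias loosely following observed human CDR3 composition:
# glycine/serine-rich with frequent tyrosine and the polar residues that
# dominate the hypervariable loop.
DEFAULT_CDR3_COMPOSITION: dict[str, float] = {
    "A": 0.055, "C": 0.010, "D": 0.040, "E": 0.045, "F": 0.035,
    "G": 0.120, "H": 0.015, "I": 0.030, "K": 0.030, "L": 0.055,
    "M": 0.010, "N": 0.045, "P": 0.040, "Q": 0.055, "R": 0.055,
    "S": 0.125, "T": 0.070, "V": 0.045, "W": 0.015, "Y": 0.105,
}


@dataclass
class SyntheticConfig:
    """Parameters of the CDR3-like generator.

    ``composition`` biases interior residues only; the frame letters (default
    cysteine prefix, phenylalanine suffix) are fixed per sequence.
    """

    n: int = 2000
    length_range: tuple[int, int] = (8, 25)
    seed: int = 0
    composition: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CDR3_COMPOSITION))
    frame: tuple[str, str] = ("C", "F")

    def __post_init__(self):
        lo, hi = self.length_range
        if lo < 3:
            raise ValueError("minimum length must be >= 3 (two frame letters + interior)")
        if hi < lo:
            raise ValueError("length_range must be (min, max) with max >= min")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"composition sums to {total}, expected 1")
        if set(self.composition) - set(AMINO_ACIDS):
            raise ValueError("composition keys must be standard amino acids")


def _composition_arrays(composition: dict[str, float]) -> tuple[np.ndarray, np.ndarray]:
    letters = np.array(list(AMINO_ACIDS))
    probs = np.array([composition.get(c, 0.0) for c in AMINO_ACIDS])
    return letters, probs / probs.sum()


def generate_cdr3_like(cfg: SyntheticConfig) -> Repertoire:
    """Sample ``cfg.n`` framed CDR3-like sequences.

    Lengths are uniform on ``cfg.length_range``; interior residues i.i.d.
    from ``cfg.composition``. The same seed reproduces the repertoire
    byte-for-byte.
    """
    rng = np.random.default_rng(cfg.seed)
    letters, probs = _composition_arrays(cfg.composition)
    lo, hi = cfg.length_range
    lengths = rng.integers(lo, hi + 1, size=cfg.n)
    prefix, suffix = cfg.frame
    sequences = []
    for L in lengths:
        interior = rng.choice(letters, size=L - 2, p=probs)
        sequences.append(prefix + "".join(interior) + suffix)
    return Repertoire(sequences, label="real_tcr", source=f"synthetic_cdr3(seed={cfg.seed})")


def generate_non_tcr(n: int = 3000, seed: int = 0,
                     length_range: tuple[int, int] = (8, 25)) -> Repertoire:
    """Sample decoy sequences with uniform residue usage and no C...F frame,
    emulating generic (non-receptor) protein fragments."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    lo, hi = length_range
    lengths = rng.integers(lo, hi + 1, size=n)
    sequences = ["".join(rng.choice(letters, size=L)) for L in lengths]
    return Repertoire(sequences, label="non_tcr", source=f"synthetic_non_tcr(seed={seed})")


def generate_markov_corpus(model, n: int, length: int, seed: int) -> Repertoire:
    """Sample ``n`` sequences of ``length`` exactly per a fitted Markov
    model's transition law (order 1 or 2).

    Serves as the ground-truth corpus for fit/refit recovery experiments:
    refitting on this output must converge to ``model`` as n grows.
    """
    from .baselines import sample_markov_sequences  # local import avoids cycle

    return sample_markov_sequences(model, length=length, n=n, seed=seed,
                                   label="real_tcr",
                                   source=f"markov_corpus(seed={seed})")
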