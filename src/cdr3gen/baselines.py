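"""Comparison generators: PWM-conditioned sampling and Markov chains.

The PWM baseline consumes a position-specific probability matrix in MEME
minimal motif text format (motif discovery itself is out of scope) and
samples residues independently per column. The Markov baseline fits first-
and second-order transition tables by counting and generates sequences by
starting from an observed pair and walking the conditional next-residue
distributions to a predefined length.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io_encoding import AMINO_ACIDS, Repertoire

logger = logging.getLogger("cdr3gen")

_AA_INDEX = {c: i for i, c in enumerate(AMINO_ACIDS)}


class MemeFormatError(ValueError):
    """A MEME minimal-motif file is malformed."""


@dataclass
class PositionWeightMatrix:
    """Per-position residue probabilities over the 20 standard amino acids.

    ``columns`` has shape (width, 20); rows index motif positions, columns
    follow alphabetical residue order.
    """

    columns: np.ndarray
    source_motif: str = ""

    def __post_init__(self):
        self.columns = np.asarray(self.columns, dtype=float)
        if self.columns.ndim != 2 or self.columns.shape[1] != 20:
            raise ValueError("PWM columns must have shape (width, 20)")
        if (self.columns < 0).any():
            raise ValueError("PWM entries must be nonnegative")
        sums = self.columns.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("every PWM column must sum to 1 within 1e-6")

    @property
    def width(self) -> int:
        return self.columns.shape[0]


@dataclass
class MarkovModel:
    """Transition-probability tables fitted by counting.

    ``transition`` maps a state (a letter for order 1, a letter pair for
    order 2) to a probability vector over the 20 residues; probabilities are
    exactly count/row-total. States whose row never occurred keep an all-zero
    row and are flagged absorbing.
    """

    order: int
    transition: dict[str, np.ndarray]
    start_distribution: dict[str, float]
    absorbing_states: set[str] = field(default_factory=set)

    def __post_init__(self):
        if self.order not in (1, 2):
            raise ValueError("only orders 1 and 2 are supported")
        for state, row in self.transition.items():
            total = row.sum()
            if state in self.absorbing_states:
                if total != 0:
                    raise ValueError(f"absorbing state {state} has outgoing mass")
            elif abs(total - 1.0) > 1e-9:
                raise ValueError(f"transition row {state} sums to {total}")

    def next_distribution(self, state: str) -> np.ndarray:
        return self.transition[state]


# ---------------------------------------------------------------------------
# MEME minimal-format PWM input
# ---------------------------------------------------------------------------


def read_meme_pwm(path: str | Path, motif_index: int = 0) -> PositionWeightMatrix:
    """Parse the ``motif_index``-th letter-probability matrix from a MEME
    minimal motif text file.

    Columns off unit sum by at most 1e-3 are renormalized (MEME prints
    rounded probabilities); larger deviations are format errors.
    """
    path = Path(path)
    text = path.read_text()
    if "MEME version" not in text:
        raise MemeFormatError(f"{path.name}: missing 'MEME version' header")
    alpha_match = re.search(r"ALPHABET\s*=\s*(\S+)", text)
    if alpha_match is None:
        raise MemeFormatError(f"{path.name}: missing ALPHABET line")
    alphabet = alpha_match.group(1)
    if sorted(alphabet) != sorted(AMINO_ACIDS):
        raise MemeFormatError(f"{path.name}: alphabet {alphabet!r} is not the 20 amino acids")

    motifs: list[tuple[str, np.ndarray]] = []
    lines = text.splitlines()
    i = 0
    while i < len(lines):
        line = lines[i]
        if line.startswith("MOTIF"):
            name = line.split(maxsplit=1)[1].strip() if len(line.split()) > 1 else f"motif_{len(motifs)}"
            while i < len(lines) and "letter-probability matrix" not in lines[i]:
                i += 1
            if i == len(lines):
                raise MemeFormatError(f"{path.name}: MOTIF {name} lacks a letter-probability matrix")
            header = lines[i]
            w_match = re.search(r"w\s*=\s*(\d+)", header)
            rows = []
            i += 1
            while i < len(lines) and lines[i].strip() and not lines[i].startswith("MOTIF"):
                fields = lines[i].split()
                if len(fields) != len(alphabet):
                    raise MemeFormatError(
                        f"{path.name}: matrix row has {len(fields)} fields, expected {len(alphabet)}")
                rows.append([float(f) for f in fields])
                i += 1
            if w_match and int(w_match.group(1)) != len(rows):
                raise MemeFormatError(
                    f"{path.name}: header w={w_match.group(1)} but {len(rows)} rows present")
            mat = np.array(rows)
            # reorder file alphabet -> alphabetical residue order
            perm = [alphabet.index(c) for c in AMINO_ACIDS]
            motifs.append((name, mat[:, perm]))
        else:
            i += 1

    if not motifs:
        raise MemeFormatError(f"{path.name}: no motifs found")
    if not 0 <= motif_index < len(motifs):
        raise IndexError(f"motif_index {motif_index} out of range; file has {len(motifs)} motif(s)")
    name, mat = motifs[motif_index]
    sums = mat.sum(axis=1)
    off = np.abs(sums - 1.0)
    if (off > 1e-3).any():
        raise MemeFormatError(
            f"{path.name}: motif {name} column sums deviate by up to {off.max():.4f} (> 1e-3)")
    if (off > 1e-6).any():
        logger.info("read_meme_pwm: renormalized %d columns of motif %s", int((off > 1e-6).sum()), name)
        mat = mat / sums[:, None]
    return PositionWeightMatrix(columns=mat, source_motif=f"{path.name}:{name}")


def sample_from_pwm(pwm: PositionWeightMatrix, n: int, seed: int) -> Repertoire:
    """Draw ``n`` sequences of the motif width, sampling position j's residue
    from PWM column j independently."""
    if n <= 0:
        raise ValueError("n must be positive")
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    cols = [rng.choice(letters, size=n, p=col / col.sum()) for col in pwm.columns]
    sequences = ["".join(row) for row in np.array(cols).T]
    return Repertoire(sequences, label="generated", source=f"pwm({pwm.source_motif})")


# ---------------------------------------------------------------------------
# Markov models
# ---------------------------------------------------------------------------


def _normalize_counts(counts: dict[str, np.ndarray], alpha: float) -> tuple[dict, set]:
    transition, absorbing = {}, set()
    for state, row in counts.items():
        row = row + alpha
        total = row.sum()
        if total == 0:
            transition[state] = row  # all-zero, flagged
            absorbing.add(state)
        else:
            transition[state] = row / total
    return transition, absorbing


def fit_first_order_markov(rep: Repertoire, alpha: float = 0.0) -> MarkovModel:
    """Estimate P(next residue | current residue) by transition counting.

    ``alpha`` adds Laplace pseudocounts (default none, so probabilities are
    exactly rational in the counts).
    """
    if not any(len(s) >= 2 for s in rep.sequences):
        raise ValueError("need at least one sequence of length >= 2 to count transitions")
    counts: dict[str, np.ndarray] = {c: np.zeros(20) for c in AMINO_ACIDS}
    starts: dict[str, float] = {}
    for s in rep.sequences:
        starts[s[0]] = starts.get(s[0], 0.0) + 1.0
        for a, b in zip(s, s[1:]):
            counts[a][_AA_INDEX[b]] += 1
    total_starts = sum(starts.values())
    start_distribution = {k: v / total_starts for k, v in starts.items()}
    transition, absorbing = _normalize_counts(counts, alpha)
    return MarkovModel(order=1, transition=transition,
                       start_distribution=start_distribution,
                       absorbing_states=absorbing)


def fit_second_order_markov(rep: Repertoire, alpha: float = 0.0) -> MarkovModel:
    """Estimate P(next residue | preceding pair) by trigram counting; the
    start distribution is the empirical first-pair frequency."""
    if not any(len(s) >= 3 for s in rep.sequences):
        raise ValueError("need at least one sequence of length >= 3 to count trigrams")
    counts: dict[str, np.ndarray] = {}
    starts: dict[str, float] = {}
    for s in rep.sequences:
        if len(s) < 2:
            continue
        pair = s[:2]
        starts[pair] = starts.get(pair, 0.0) + 1.0
        for j in range(len(s) - 2):
            state = s[j : j + 2]
            if state not in counts:
                counts[state] = np.zeros(20)
            counts[state][_AA_INDEX[s[j + 2]]] += 1
    total_starts = sum(starts.values())
    start_distribution = {k: v / total_starts for k, v in starts.items()}
    transition, absorbing = _normalize_counts(counts, alpha)
    return MarkovModel(order=2, transition=transition,
                       start_distribution=start_distribution,
                       absorbing_states=absorbing)


def sample_markov_sequences(model: MarkovModel, length: int, n: int, seed: int,
                            label: str = "generated", source: str = "",
                            uniform_start: bool = False) -> Repertoire:
    """Walk the chain to ``length`` residues, ``n`` times.

    The start state is drawn from the empirical start distribution (or
    uniformly over observed states with ``uniform_start``). Hitting a state
    with no outgoing probability restarts that sequence from a fresh start
    state; restarts are logged.
    """
    min_len = model.order
    if length < min_len:
        raise ValueError(f"length must be >= {min_len} for an order-{model.order} model")
    if n <= 0:
        raise ValueError("n must be positive")
    states = sorted(model.start_distribution)
    if not states:
        raise ValueError("model has no start states")
    if uniform_start:
        start_probs = np.full(len(states), 1.0 / len(states))
    else:
        start_probs = np.array([model.start_distribution[s] for s in states])
        start_probs = start_probs / start_probs.sum()
    rng = np.random.default_rng(seed)
    letters = np.array(list(AMINO_ACIDS))
    sequences = []
    n_restarts = 0
    while len(sequences) < n:
        seq = list(states[rng.choice(len(states), p=start_probs)])
        dead = False
        while len(seq) < length:
            state = "".join(seq[-model.order :])
            row = model.transition.get(state)
            if row is None or state in model.absorbing_states or row.sum() == 0:
                dead = True
                break
            seq.append(str(rng.choice(letters, p=row / row.sum())))
        if dead:
            n_restarts += 1
            continue
        sequences.append("".join(seq))
    if n_restarts:
        logger.info("markov sampling: %d dead-end restarts", n_restarts)
    return Repertoire(sequences, label=label, source=source or f"markov(order={model.order})")


def generate_markov(model: MarkovModel, length: int, n: int, seed: int,
                    uniform_start: bool = False) -> Repertoire:
    """Second-order Markov generation to a predefined sequence length."""
    if model.order != 2:
        raise ValueError("generate_markov expects a second-order model")
    if length < 2:
        raise ValueError("length must be >= 2")
    return sample_markov_sequences(model, length=length, n=n, seed=seed,
                                   uniform_start=uniform_start)
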