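"""Similarity metrics between generated, real-TCR and non-TCR repertoires.

The currency of most comparisons is the normalized amino-acid frequency
profile: a 20-vector of residue frequencies. On top of it sit the
frequency-threshold post-processing filter, overall and per-residue Pearson
correlation, the two-sample KS test, discriminator cross-validation
(confusion metrics), and t-SNE embedding distances (Euclidean, cosine,
centroid, 2-D KL, Earth Mover's).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import isnan

import numpy as np
from scipy import stats
from scipy.optimize import linprog
from scipy.spatial.distance import cdist

from .io_encoding import AMINO_ACIDS, EncodedBatch, Repertoire

logger = logging.getLogger("cdr3gen")

_AA_INDEX = {c: i for i, c in enumerate(AMINO_ACIDS)}

# Post-processing acceptance thresholds on the max per-residue frequency
# deviation, one preset per generator architecture.
FILTER_THRESHOLD_DENSE = 0.04
FILTER_THRESHOLD_LSTM = 0.14


@dataclass
class FrequencyProfile:
    """Normalized amino-acid frequency vector with its supporting count."""

    freq: np.ndarray
    n_residues: int = 0

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (20,):
            raise ValueError("frequency profile must have 20 entries")
        if (self.freq < 0).any():
            raise ValueError("frequencies must be nonnegative")
        if self.n_residues > 0 and abs(self.freq.sum() - 1.0) > 1e-9:
            raise ValueError(f"profile sums to {self.freq.sum()}, expected 1")

    def __getitem__(self, letter: str) -> float:
        return float(self.freq[_AA_INDEX[letter]])

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "FrequencyProfile":
        v = np.array([d.get(c, 0.0) for c in AMINO_ACIDS])
        return cls(freq=v / v.sum(), n_residues=0)


def amino_acid_frequencies(rep: Repertoire | list[str]) -> FrequencyProfile:
    """Pooled residue frequencies: occurrences of each letter over all
    sequences divided by the total residue count."""
    seqs = rep.sequences if isinstance(rep, Repertoire) else list(rep)
    if not seqs:
        raise ValueError("cannot compute frequencies of an empty repertoire")
    counts = np.zeros(20)
    for s in seqs:
        for c in s:
            counts[_AA_INDEX[c]] += 1
    total = counts.sum()
    return FrequencyProfile(freq=counts / total, n_residues=int(total))


def frequency_filter(candidates: Repertoire, reference: FrequencyProfile,
                     threshold: float) -> Repertoire:
    """Keep candidates whose own residue-frequency profile deviates from the
    reference by at most ``threshold`` in max-absolute per-letter terms.

    Input order is preserved; the acceptance rate is logged.
    """
    if threshold < 0:
        raise ValueError("threshold must be nonnegative")
    accepted = []
    for s in candidates.sequences:
        prof = amino_acid_frequencies([s])
        if np.max(np.abs(prof.freq - reference.freq)) <= threshold:
            accepted.append(s)
    rate = len(accepted) / len(candidates) if len(candidates) else 0.0
    logger.info("frequency_filter: accepted %d/%d (%.1f%%) at threshold %.3f",
                len(accepted), len(candidates), 100 * rate, threshold)
    return Repertoire(accepted, label=candidates.label,
                      source=f"{candidates.source}|filtered@{threshold}")


def pearson_overall(p: FrequencyProfile, q: FrequencyProfile) -> float:
    """Pearson correlation of two 20-residue frequency vectors; NaN when
    either vector has zero variance (correlation undefined)."""
    if np.ptp(p.freq) == 0 or np.ptp(q.freq) == 0:
        logger.warning("pearson_overall: zero-variance profile, correlation undefined")
        return float("nan")
    r, _ = stats.pearsonr(p.freq, q.freq)
    return float(r)


def pearson_per_amino_acid(real: Repertoire, generated: Repertoire,
                           n_batches: int = 50, batch_size: int = 100,
                           seed: int = 0) -> dict[str, float]:
    """Per-residue Pearson correlation across paired seeded subsamples.

    Each of ``n_batches`` rounds draws ``batch_size`` sequences (without
    replacement) from both repertoires; each residue's frequency per batch
    gives two paired series whose correlation is reported. Residues absent
    from every batch on either side, or with zero variance, are NaN.
    """
    if n_batches < 2:
        raise ValueError("need at least 2 batches for a correlation")
    if len(real) < batch_size or len(generated) < batch_size:
        raise ValueError("both repertoires must contain at least batch_size sequences")
    # one stream per side, both from the same seed: identical repertoires
    # under the same seed get identical index draws, giving correlation 1
    rng_r = np.random.default_rng(seed)
    rng_g = np.random.default_rng(seed)
    freq_r = np.empty((n_batches, 20))
    freq_g = np.empty((n_batches, 20))
    for b in range(n_batches):
        idx_r = rng_r.choice(len(real), size=batch_size, replace=False)
        idx_g = rng_g.choice(len(generated), size=batch_size, replace=False)
        freq_r[b] = amino_acid_frequencies([real.sequences[i] for i in idx_r]).freq
        freq_g[b] = amino_acid_frequencies([generated.sequences[i] for i in idx_g]).freq
    out: dict[str, float] = {}
    for k, letter in enumerate(AMINO_ACIDS):
        x, y = freq_r[:, k], freq_g[:, k]
        if x.sum() == 0 or y.sum() == 0 or np.std(x) == 0 or np.std(y) == 0:
            out[letter] = float("nan")
        else:
            out[letter] = float(stats.pearsonr(x, y)[0])
    return out


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: the maximum ECDF gap and its
    asymptotic p-value."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Discriminator cross-validation
# ---------------------------------------------------------------------------


@dataclass
class ConfusionSummary:
    """Confusion counts and derived metrics at a fixed score threshold.

    ``precision`` is NaN when no sequence is predicted positive.
    """

    tp: int
    tn: int
    fp: int
    fn: int
    threshold: float

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def precision(self) -> float:
        denom = self.tp + self.fp
        return self.tp / denom if denom else float("nan")

    @property
    def recall(self) -> float:
        denom = self.tp + self.fn
        return self.tp / denom if denom else float("nan")

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        if isnan(p) or isnan(r) or p + r == 0:
            return float("nan") if isnan(p) or isnan(r) else 0.0
        return 2 * p * r / (p + r)

    def as_dict(self) -> dict:
        return {"tp": self.tp, "tn": self.tn, "fp": self.fp, "fn": self.fn,
                "threshold": self.threshold, "accuracy": self.accuracy,
                "precision": self.precision, "recall": self.recall, "f1": self.f1}


def confusion_from_scores(labels: np.ndarray, scores: np.ndarray,
                          threshold: float = 0.5) -> ConfusionSummary:
    """Classify probability scores at ``threshold`` (label 1 = positive/real)
    and tally the confusion matrix."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    labels = np.asarray(labels).astype(bool)
    pred = np.asarray(scores, dtype=float) >= threshold
    return ConfusionSummary(
        tp=int(np.sum(pred & labels)), tn=int(np.sum(~pred & ~labels)),
        fp=int(np.sum(pred & ~labels)), fn=int(np.sum(~pred & labels)),
        threshold=threshold)


def cross_validate_discriminator(disc, real: Repertoire, fake: Repertoire,
                                 threshold: float = 0.5, seed: int = 0) -> ConfusionSummary:
    """Score a shuffled mix of real (positive) and fake (negative) sequences
    with a discriminator and summarize the confusion at ``threshold``.

    ``disc`` is either a trained discriminator exposing
    ``score_sequences(list[str]) -> probabilities`` or any callable with that
    signature. Default fixture sizes elsewhere give a 210-sequence mix.
    """
    if not len(real) or not len(fake):
        raise ValueError("both repertoires must be nonempty")
    scorer = disc.score_sequences if hasattr(disc, "score_sequences") else disc
    seqs = list(real.sequences) + list(fake.sequences)
    labels = np.array([1] * len(real) + [0] * len(fake))
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(seqs))
    seqs = [seqs[i] for i in perm]
    labels = labels[perm]
    scores = np.asarray(scorer(seqs), dtype=float).ravel()
    return confusion_from_scores(labels, scores, threshold)


# ---------------------------------------------------------------------------
# t-SNE embedding and point-cloud distances
# ---------------------------------------------------------------------------


@dataclass
class EmbeddingSet:
    """2-D t-SNE coordinates with one group label per point."""

    points: np.ndarray
    labels: list[str]
    seed: int = 0
    perplexity: float = 10.0

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("embedding must be n x 2")
        if len(self.labels) != self.points.shape[0]:
            raise ValueError("one label per point required")
        if not np.isfinite(self.points).all():
            raise ValueError("embedding coordinates must be finite")

    def group(self, label: str) -> np.ndarray:
        mask = np.array([l == label for l in self.labels])
        return self.points[mask]

    @property
    def group_names(self) -> list[str]:
        seen = []
        for l in self.labels:
            if l not in seen:
                seen.append(l)
        return seen


def tsne_embed(batches: dict[str, EncodedBatch | np.ndarray],
               perplexity: float = 10.0, seed: int = 0) -> EmbeddingSet:
    """Embed the scaled numeric sequence representations of several labeled
    groups into 2-D with t-SNE (PCA initialization, fixed random state)."""
    from sklearn.manifold import TSNE

    rows, labels = [], []
    for label, batch in batches.items():
        mat = batch.scaled if isinstance(batch, EncodedBatch) else np.asarray(batch, dtype=float)
        rows.append(mat)
        labels.extend([label] * mat.shape[0])
    X = np.vstack(rows)
    if X.shape[0] <= 3 * perplexity:
        raise ValueError(
            f"t-SNE needs more than 3*perplexity = {3 * perplexity:.0f} points, got {X.shape[0]}")
    emb = TSNE(n_components=2, perplexity=perplexity, init="pca",
               random_state=seed).fit_transform(X)
    return EmbeddingSet(points=emb, labels=labels, seed=seed, perplexity=perplexity)


def earth_movers_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Optimal-transport cost between two point sets with uniform weights and
    Euclidean ground distance, solved as a linear program on the transport
    polytope."""
    a, b = np.atleast_2d(a), np.atleast_2d(b)
    n, m = a.shape[0], b.shape[0]
    cost = cdist(a, b).ravel()
    # row-marginal and column-marginal equality constraints
    A_eq = np.zeros((n + m, n * m))
    for i in range(n):
        A_eq[i, i * m : (i + 1) * m] = 1.0
    for j in range(m):
        A_eq[n + j, j::m] = 1.0
    b_eq = np.concatenate([np.full(n, 1.0 / n), np.full(m, 1.0 / m)])
    res = linprog(cost, A_eq=A_eq, b_eq=b_eq, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def kl_divergence_2d(a: np.ndarray, b: np.ndarray, bins: int = 10,
                     epsilon: float = 1e-8) -> float:
    """KL between two point clouds' occupancy histograms on a shared
    ``bins`` x ``bins`` grid spanning the joint bounding box, with epsilon
    smoothing. Asymmetric in (a, b) like any KL."""
    from .gan_core import kl_divergence

    pts = np.vstack([a, b])
    lo, hi = pts.min(axis=0), pts.max(axis=0)
    span = np.where(hi - lo > 0, hi - lo, 1.0)
    edges = [np.linspace(lo[d], lo[d] + span[d], bins + 1) for d in range(2)]
    ha, _, _ = np.histogram2d(a[:, 0], a[:, 1], bins=edges)
    hb, _, _ = np.histogram2d(b[:, 0], b[:, 1], bins=edges)
    p = (ha / ha.sum()).ravel()
    q = (hb / hb.sum()).ravel()
    return kl_divergence(p, q, epsilon=epsilon)


@dataclass
class DistanceReport:
    """Distance/similarity metrics for each group pairing of an embedding."""

    pairings: dict[tuple[str, str], dict[str, float]] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {f"{a}-{b}": dict(m) for (a, b), m in self.pairings.items()}


def distance_suite(emb: EmbeddingSet,
                   pairings: list[tuple[str, str]] | None = None) -> DistanceReport:
    """Compute mean pairwise Euclidean distance, mean pairwise cosine
    similarity, centroid distance, 2-D histogram KL and Earth Mover's
    distance for each group pairing (default: all unordered pairs in label
    order, i.e. real-fake, real-generated, fake-generated)."""
    names = emb.group_names
    if pairings is None:
        pairings = [(a, b) for i, a in enumerate(names) for b in names[i + 1 :]]
    report = DistanceReport()
    for a_name, b_name in pairings:
        A, B = emb.group(a_name), emb.group(b_name)
        if A.size == 0 or B.size == 0:
            raise ValueError(f"group {a_name!r} or {b_name!r} missing from embedding")
        dists = cdist(A, B)
        norms_a = np.linalg.norm(A, axis=1)
        norms_b = np.linalg.norm(B, axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cos = (A @ B.T) / np.outer(norms_a, norms_b)
        finite_cos = cos[np.isfinite(cos)]  # points at the origin have no angle
        report.pairings[(a_name, b_name)] = {
            "mean_euclidean": float(dists.mean()),
            "mean_cosine_similarity": float(finite_cos.mean()) if finite_cos.size else float("nan"),
            "centroid_distance": float(np.linalg.norm(A.mean(axis=0) - B.mean(axis=0))),
            "kl_divergence_2d": kl_divergence_2d(A, B),
            "earth_movers": earth_movers_distance(A, B),
        }
    return report
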