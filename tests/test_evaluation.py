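"""Evaluation metrics against independent brute-force oracles."""

import numpy as np
import pytest

from cdr3gen import (
    AMINO_ACIDS,
    Repertoire,
    amino_acid_frequencies,
    confusion_from_scores,
    cross_validate_discriminator,
    distance_suite,
    earth_movers_distance,
    encode_sequences,
    frequency_filter,
    generate_non_tcr,
    ks_two_sample,
    pearson_overall,
    pearson_per_amino_acid,
    tsne_embed,
)
from cdr3gen.evaluation import EmbeddingSet, FrequencyProfile

from conftest import random_sequences

AA = AMINO_ACIDS


# -- independent oracles -----------------------------------------------------


def ecdf_ks_oracle(a, b):
    """Brute-force scan of |ECDF_a - ECDF_b| over every sample point."""
    a, b = np.sort(a), np.sort(b)
    best = 0.0
    for x in np.concatenate([a, b]):
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        best = max(best, abs(fa - fb))
    return best


def emd_assignment_oracle(A, B):
    """For equal-size uniform-weight sets, EMD is the optimal assignment
    cost divided by n (Birkhoff: the transport LP has a permutation vertex)."""
    from scipy.optimize import linear_sum_assignment
    from scipy.spatial.distance import cdist

    cost = cdist(A, B)
    r, c = linear_sum_assignment(cost)
    return cost[r, c].sum() / len(A)


def confusion_oracle(labels, scores, threshold):
    tp = tn = fp = fn = 0
    for y, s in zip(labels, scores):
        pred = s >= threshold
        if pred and y: tp += 1
        elif pred and not y: fp += 1
        elif not pred and y: fn += 1
        else: tn += 1
    return tp, tn, fp, fn


# -- frequency profiles ------------------------------------------------------


class TestFrequencies:
    def test_single_letter_repertoire(self):
        prof = amino_acid_frequencies(Repertoire(["AAAA"]))
        assert prof["A"] == 1.0 and prof.freq.sum() == 1.0

    def test_hand_counts(self):
        prof = amino_acid_frequencies(Repertoire(["AC", "CC"]))
        assert prof["A"] == 0.25 and prof["C"] == 0.75

    def test_normalization_over_random_repertoires(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            prof = amino_acid_frequencies(random_sequences(rng, 5))
            assert abs(prof.freq.sum() - 1.0) < 1e-9

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            amino_acid_frequencies([])


class TestFrequencyFilter:
    def test_identical_profile_accepted(self):
        rep = Repertoire(["ACAC"])
        ref = amino_acid_frequencies(rep)
        assert frequency_filter(rep, ref, 0.001).sequences == ["ACAC"]

    def test_hand_deviation(self):
        ref = FrequencyProfile.from_dict({"A": 0.5, "C": 0.5})
        out = frequency_filter(Repertoire(["AAAA"]), ref, 0.4)
        assert out.sequences == []  # deviation is 0.5 on both A and C

    def test_negative_threshold_rejected(self):
        ref = FrequencyProfile.from_dict({"A": 1.0})
        with pytest.raises(ValueError):
            frequency_filter(Repertoire(["A"]), ref, -0.1)

    @pytest.mark.parametrize("threshold", [0.04, 0.14])
    def test_matches_bruteforce_recomputation(self, threshold):
        rng = np.random.default_rng(1)
        candidates = Repertoire(random_sequences(rng, 1000))
        ref = amino_acid_frequencies(candidates)
        accepted = set(frequency_filter(candidates, ref, threshold).sequences)
        for s in candidates:
            counts = np.array([s.count(c) for c in AA], dtype=float)
            dev = np.max(np.abs(counts / counts.sum() - ref.freq))
            assert (dev <= threshold) == (s in accepted)


class TestPearson:
    def test_identity(self):
        p = FrequencyProfile.from_dict({"A": 0.5, "C": 0.3, "D": 0.2})
        assert pearson_overall(p, p) == pytest.approx(1.0)

    def test_affine_decreasing_is_anticorrelated(self):
        p = np.linspace(1, 2, 20)
        q = 3 - p
        prof_p = FrequencyProfile(p / p.sum(), n_residues=0)
        prof_q = FrequencyProfile(q / q.sum(), n_residues=0)
        assert pearson_overall(prof_p, prof_q) == pytest.approx(-1.0)

    def test_direct_formula_oracle(self):
        p = np.array([0.5, 0.3, 0.2] + [0.0] * 17)
        q = np.array([0.4, 0.4, 0.2] + [0.0] * 17)
        cov = np.mean((p - p.mean()) * (q - q.mean()))
        expected = cov / (p.std() * q.std())
        got = pearson_overall(FrequencyProfile(p, 0), FrequencyProfile(q, 0))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_reported_missing(self):
        p = FrequencyProfile(np.full(20, 0.05), 0)
        q = FrequencyProfile.from_dict({"A": 1.0})
        assert np.isnan(pearson_overall(p, q))


class TestPearsonPerAminoAcid:
    def test_identity_gives_unit_correlations(self):
        rep = generate_non_tcr(n=500, seed=0)
        result = pearson_per_amino_acid(rep, rep, n_batches=10, batch_size=100, seed=3)
        defined = [v for v in result.values() if not np.isnan(v)]
        assert defined and all(v == pytest.approx(1.0) for v in defined)

    def test_independent_repertoires_center_near_zero(self):
        a = generate_non_tcr(n=2000, seed=1)
        b = generate_non_tcr(n=2000, seed=2)
        result = pearson_per_amino_acid(a, b, n_batches=50, batch_size=100, seed=4)
        vals = [v for v in result.values() if not np.isnan(v)]
        assert abs(np.mean(vals)) < 0.15

    def test_single_batch_rejected(self):
        rep = generate_non_tcr(n=200, seed=5)
        with pytest.raises(ValueError):
            pearson_per_amino_acid(rep, rep, n_batches=1, batch_size=50, seed=0)


class TestKSTest:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_shifted_sample(self):
        d, _ = ks_two_sample([1, 2, 3], [2, 3, 4])
        assert d == pytest.approx(1 / 3)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_statistic_matches_ecdf_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            a = rng.normal(size=rng.integers(2, 50))
            b = rng.normal(loc=rng.uniform(-1, 1), size=rng.integers(2, 50))
            d, _ = ks_two_sample(a, b)
            assert d == pytest.approx(ecdf_ks_oracle(a, b), abs=1e-12)


class TestConfusion:
    def test_perfect_classifier(self):
        labels = np.array([1, 1, 0, 0])
        summary = confusion_from_scores(labels, labels.astype(float), 0.5)
        assert summary.tp + summary.tn == summary.total
        assert summary.accuracy == 1.0 and summary.f1 == 1.0

    def test_hand_built_confusion(self):
        s = confusion_from_scores([1, 1, 0, 0], [0.9, 0.2, 0.8, 0.1], 0.5)
        assert (s.tp, s.fn, s.fp, s.tn) == (1, 1, 1, 1)
        assert s.accuracy == s.precision == s.recall == s.f1 == 0.5

    def test_constant_zero_scores(self):
        s = confusion_from_scores([1, 0], [0.0, 0.0], 0.5)
        assert np.isnan(s.precision) and s.recall == 0.0

    def test_threshold_range_enforced(self):
        with pytest.raises(ValueError):
            confusion_from_scores([1], [0.5], 1.5)

    def test_identities_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = rng.integers(2, 40)
            labels = rng.integers(0, 2, n)
            scores = rng.uniform(0, 1, n)
            s = confusion_from_scores(labels, scores, 0.5)
            tp, tn, fp, fn = confusion_oracle(labels, scores, 0.5)
            assert (s.tp, s.tn, s.fp, s.fn) == (tp, tn, fp, fn)
            assert s.total == n
            assert s.accuracy == pytest.approx((tp + tn) / n)
            if tp + fp:
                assert s.precision == pytest.approx(tp / (tp + fp))
            if tp + fn:
                assert s.recall == pytest.approx(tp / (tp + fn))
            if tp + fp and tp + fn and s.precision + s.recall > 0:
                assert s.f1 == pytest.approx(
                    2 * s.precision * s.recall / (s.precision + s.recall))

    def test_cross_validation_with_oracle_scorer(self):
        real = Repertoire(["CAF"] * 105, label="real_tcr")
        fake = Repertoire(["WWW"] * 105, label="non_tcr")
        scorer = lambda seqs: np.array([1.0 if s == "CAF" else 0.0 for s in seqs])
        summary = cross_validate_discriminator(scorer, real, fake, seed=0)
        assert summary.total == 210  # mirrors the 210-sequence validation mix
        assert summary.accuracy == 1.0 and summary.f1 == 1.0


class TestEmbeddingAndDistances:
    def test_tsne_point_count_and_reproducibility(self):
        rng = np.random.default_rng(8)
        batches = {
            "real": encode_sequences(Repertoire(random_sequences(rng, 35)), 25),
            "fake": encode_sequences(Repertoire(random_sequences(rng, 35)), 25),
            "generated": encode_sequences(Repertoire(random_sequences(rng, 35)), 25),
        }
        emb1 = tsne_embed(batches, perplexity=10, seed=1)
        emb2 = tsne_embed(batches, perplexity=10, seed=1)
        assert emb1.points.shape == (105, 2)
        np.testing.assert_array_equal(emb1.points, emb2.points)

    def test_tsne_too_few_points(self):
        rng = np.random.default_rng(9)
        batches = {"real": encode_sequences(Repertoire(random_sequences(rng, 10)), 25)}
        with pytest.raises(ValueError, match="perplexity"):
            tsne_embed(batches, perplexity=10, seed=0)

    def test_separated_groups_get_positive_silhouette(self):
        from sklearn.metrics import silhouette_score

        rng = np.random.default_rng(10)
        a = ["C" * 10 + "A" * 10 + "F" * 5 for _ in range(35)]
        b = ["".join(rng.choice(list("WYHKR"), 25)) for _ in range(35)]
        batches = {"real": encode_sequences(Repertoire(a), 25),
                   "fake": encode_sequences(Repertoire(b), 25)}
        emb = tsne_embed(batches, perplexity=10, seed=2)
        labels = [0] * 35 + [1] * 35
        assert silhouette_score(emb.points, labels) > 0

    def test_identical_point_sets_give_zero(self):
        pts = np.random.default_rng(11).normal(size=(12, 2))
        emb = EmbeddingSet(points=np.vstack([pts, pts]),
                           labels=["a"] * 12 + ["b"] * 12)
        m = distance_suite(emb).pairings[("a", "b")]
        assert m["centroid_distance"] == pytest.approx(0.0, abs=1e-9)
        assert m["kl_divergence_2d"] == pytest.approx(0.0, abs=1e-5)
        assert m["earth_movers"] == pytest.approx(0.0, abs=1e-9)

    def test_singleton_geometry(self):
        emb = EmbeddingSet(points=np.array([[0.0, 0.0], [3.0, 4.0]]),
                           labels=["a", "b"])
        m = distance_suite(emb).pairings[("a", "b")]
        assert m["mean_euclidean"] == pytest.approx(5.0)
        assert m["centroid_distance"] == pytest.approx(5.0)
        assert m["earth_movers"] == pytest.approx(5.0, abs=1e-9)

    def test_emd_matches_assignment_oracle(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            A = rng.normal(size=(20, 2))
            B = rng.normal(loc=0.5, size=(20, 2))
            assert earth_movers_distance(A, B) == pytest.approx(
                emd_assignment_oracle(A, B), abs=1e-6)

    def test_metrics_symmetric_except_kl(self):
        rng = np.random.default_rng(13)
        pts = rng.normal(size=(20, 2))
        labels = ["a"] * 10 + ["b"] * 10
        emb = EmbeddingSet(points=pts, labels=labels)
        fwd = distance_suite(emb, pairings=[("a", "b")]).pairings[("a", "b")]
        rev = distance_suite(emb, pairings=[("b", "a")]).pairings[("b", "a")]
        for key in ("mean_euclidean", "mean_cosine_similarity",
                    "centroid_distance", "earth_movers"):
            assert fwd[key] == pytest.approx(rev[key], abs=1e-9)

    def test_emd_triangle_inequality(self):
        rng = np.random.default_rng(14)
        A, B, C = (rng.normal(loc=mu, size=(8, 2)) for mu in (0, 1, 2))
        ab = earth_movers_distance(A, B)
        bc = earth_movers_distance(B, C)
        ac = earth_movers_distance(A, C)
        assert ac <= ab + bc + 1e-9

    def test_missing_group_rejected(self):
        emb = EmbeddingSet(points=np.zeros((2, 2)), labels=["a", "a"])
        with pytest.raises(ValueError):
            distance_suite(emb, pairings=[("a", "b")])


def test_generated_real_distance_shrinks_with_matching_composition():
    """Moving the generator's composition toward the real profile must shrink
    the real-vs-generated embedding distances (3-point composition sweep)."""
    from cdr3gen import SyntheticConfig, generate_cdr3_like
    from cdr3gen.synthetic_data import DEFAULT_CDR3_COMPOSITION

    # far end of the sweep: mass piled on residues real CDR3 loops rarely use
    far = {c: 0.01 for c in AA}
    for c in "WHM":
        far[c] += (1 - 0.2) / 3
    total = sum(far.values())
    far = {c: v / total for c, v in far.items()}

    real = generate_cdr3_like(SyntheticConfig(n=100, seed=20))
    emds = []
    for mix in (0.0, 0.25, 1.0):
        comp = {c: (1 - mix) * far[c] + mix * DEFAULT_CDR3_COMPOSITION[c] for c in AA}
        total = sum(comp.values())
        comp = {c: v / total for c, v in comp.items()}
        gen = generate_cdr3_like(SyntheticConfig(n=100, seed=21, composition=comp))
        batches = {"real": encode_sequences(real, 25),
                   "generated": encode_sequences(gen, 25)}
        emb = tsne_embed(batches, perplexity=10, seed=3)
        emds.append(distance_suite(emb).pairings[("real", "generated")]["earth_movers"])
    assert emds[2] < emds[1] < emds[0]
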