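"""Homology module tests, pinned by an independent alignment oracle.

The oracle enumerates *every* global alignment of two short sequences,
scores them with needle-style affine gap costs (open + extend per gap run,
free end gaps) under BLOSUM62, and reports the identity percentages of all
maximum-score alignments.  The package's aligner must land on one of them.
"""

import itertools

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from subplastid.homology import (
    IdentityParams,
    homology_partition,
    homology_reduce,
    identity_matrix,
    mean_cross_identity,
    pairwise_identity,
)
from subplastid.seq_data import LabeledDataset, ProteinRecord

BLOSUM62 = substitution_matrices.load("BLOSUM62")


def enumerate_alignment_identities(a, b, gap_open=10.0, gap_extend=0.5):
    """Identity percents of all maximum-score global alignments (brute force)."""
    def walk(i, j, path):
        if i == len(a) and j == len(b):
            yield tuple(path)
            return
        if i < len(a) and j < len(b):
            yield from walk(i + 1, j + 1, path + ["M"])
        if i < len(a):
            yield from walk(i + 1, j, path + ["X"])  # gap in b
        if j < len(b):
            yield from walk(i, j + 1, path + ["Y"])  # gap in a

    def score_and_identity(path):
        score, identities = 0.0, 0
        i = j = 0
        runs = []  # (move, length, start_index)
        for move, group in itertools.groupby(path):
            runs.append((move, len(list(group))))
        pos = 0
        n_runs = len(runs)
        for r, (move, length) in enumerate(runs):
            if move == "M":
                for _ in range(length):
                    score += BLOSUM62[a[i], b[j]]
                    identities += a[i] == b[j]
                    i += 1
                    j += 1
            else:
                terminal = r == 0 or r == n_runs - 1
                if not terminal:
                    score -= gap_open + gap_extend * length
                if move == "X":
                    i += length
                else:
                    j += length
            pos += length
        return score, 100.0 * identities / len(path)

    best_score, best_identities = -np.inf, set()
    for path in walk(0, 0, []):
        score, identity = score_and_identity(path)
        if score > best_score + 1e-9:
            best_score, best_identities = score, {identity}
        elif abs(score - best_score) <= 1e-9:
            best_identities.add(identity)
    return best_identities


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACDE", "ACDE") == 100.0

    def test_needle_style_end_gap(self):
        # optimal alignment ACDE / ACD-: 3 identities over length 4
        assert pairwise_identity("ACDE", "ACD") == 75.0

    def test_disjoint_alphabets(self):
        assert pairwise_identity("AAAA", "CCCC") == 0.0

    def test_shorter_sequence_denominator(self):
        params = IdentityParams(denominator="shorter_sequence")
        assert pairwise_identity("ACDE", "ACD", params) == 100.0 * 3 / 3

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACDE")

    def test_agrees_with_exhaustive_alignment_oracle(self, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(25):
            a = "".join(rng.choice(letters, rng.integers(2, 6)))
            b = "".join(rng.choice(letters, rng.integers(2, 6)))
            allowed = enumerate_alignment_identities(a, b)
            got = pairwise_identity(a, b)
            assert any(abs(got - x) < 1e-9 for x in allowed), (a, b, got, allowed)

    def test_symmetry(self, rng):
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(100):
            a = "".join(rng.choice(letters, rng.integers(5, 30)))
            b = "".join(rng.choice(letters, rng.integers(5, 30)))
            assert pairwise_identity(a, b) == pairwise_identity(b, a)


def unlabeled(seqs):
    return LabeledDataset(
        [ProteinRecord(f"s{i+1}", s) for i, s in enumerate(seqs)]
    )


class TestHomologyReduce:
    def test_exact_duplicates_collapse(self):
        base = "ACDEFGHIKLMNPQRSTVWY"
        ds = unlabeled([base, base, "WYWYWYWYWYWYWYWYWYWY"])
        reduced = homology_reduce(ds, threshold=90)
        assert len(reduced) == 2

    def test_near_duplicate_removed_at_90(self):
        s1 = "ACDEFGHIKLMNPQRSTVWY"  # 20 residues
        s2 = s1[:10] + "W" + s1[11:]  # 1/20 substitution -> 95% identity
        s3 = "WYWYWYWYWYWYWYWYWYWY"
        reduced = homology_reduce(unlabeled([s1, s2, s3]), threshold=90)
        assert reduced.ids == ["s1", "s3"]

    def test_threshold_100_keeps_non_duplicates(self):
        ds = unlabeled(["ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLMNPQRSTVWW"])
        assert homology_reduce(ds, threshold=100).ids == ["s1", "s2"]

    def test_idempotence(self, rng):
        letters = np.array(list("ACDEFG"))
        seqs = ["".join(rng.choice(letters, 25)) for _ in range(12)]
        ds = unlabeled(seqs)
        once = homology_reduce(ds, threshold=60)
        twice = homology_reduce(once, threshold=60)
        assert once.ids == twice.ids

    def test_per_class_reduction_keeps_cross_class_twins(self):
        from subplastid.seq_data import ClassLabel

        seq = "ACDEFGHIKLMNPQRSTVWY"
        ds = LabeledDataset(
            [
                ProteinRecord("a", seq, ClassLabel("N_S")),
                ProteinRecord("b", seq, ClassLabel("P_S")),
            ]
        )
        reduced = homology_reduce(ds, threshold=90)
        assert set(reduced.ids) == {"a", "b"}


class TestHomologyPartition:
    def test_isolated_singleton_becomes_independent(self):
        core = "ACDEACDEACDEACDEACDEACDEACDE"
        cluster = [core[:i] + "G" + core[i + 1 :] for i in range(5)]
        outlier = "WYWYWYWYWYHHWYWYWYWYWYWYWYWY"
        result = homology_partition(
            unlabeled(cluster + [outlier]), threshold=40, independent_fraction=0.15
        )
        assert result.independent.ids == ["s6"]
        assert result.achieved_fraction == pytest.approx(1 / 6)

    def test_all_singletons_gives_three_of_twenty(self):
        letters = "ACDEFGHIKLMNPQRSTVWY"
        seqs = [aa * 30 for aa in letters]  # mutually 0% identical
        result = homology_partition(
            unlabeled(seqs), threshold=40, independent_fraction=0.15
        )
        assert len(result.independent) == 3

    def test_single_cluster_is_an_error(self):
        seqs = ["ACDEACDEACDE", "ACDEACDEACDW"]
        with pytest.raises(ValueError):
            homology_partition(unlabeled(seqs), threshold=0.0)

    def test_cross_set_identity_below_threshold(self, rng):
        """Soundness at small scale: exhaustive cross-set check."""
        letters = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for trial in range(5):
            seqs = []
            for _ in range(4):  # four families of mutated copies
                base = "".join(rng.choice(letters, 40))
                for _ in range(rng.integers(1, 4)):
                    mutated = list(base)
                    for pos in rng.choice(40, 5, replace=False):
                        mutated[pos] = rng.choice(letters)
                    seqs.append("".join(mutated))
            result = homology_partition(
                unlabeled(seqs), threshold=40, independent_fraction=0.15
            )
            for rec_a in result.train_test:
                for rec_b in result.independent:
                    assert pairwise_identity(rec_a.sequence, rec_b.sequence) < 40


class TestMeanCrossIdentity:
    def test_identical_singletons(self):
        a = unlabeled(["ACDEFGHIKLMN"])
        b = unlabeled(["ACDEFGHIKLMN"])
        assert mean_cross_identity(a, b) == {"all": 100.0}

    def test_fully_dissimilar(self):
        assert mean_cross_identity(
            unlabeled(["AAAAAAAAAAAA"]), unlabeled(["CCCCCCCCCCCC"])
        ) == {"all": 0.0}

    def test_two_by_two_mean(self):
        from subplastid.seq_data import ClassLabel

        def labeled(seqs, ids):
            return LabeledDataset(
                [ProteinRecord(i, s, ClassLabel("N_S")) for i, s in zip(ids, seqs)]
            )

        a = labeled(["ACDE" * 3, "ACDW" * 3], ["a1", "a2"])
        b = labeled(["ACDE" * 3, "AFDE" * 3], ["b1", "b2"])
        # pair identities: 100, 75, 75, 50
        assert mean_cross_identity(a, b)["N_S"] == pytest.approx(75.0)

    def test_class_missing_reported_as_none(self):
        from subplastid.seq_data import ClassLabel

        a = LabeledDataset([ProteinRecord("a", "ACDEFGHIKLMN", ClassLabel("N_S"))])
        b = LabeledDataset([ProteinRecord("b", "ACDEFGHIKLMN", ClassLabel("P_S"))])
        result = mean_cross_identity(a, b)
        assert result["N_S"] is None and result["P_S"] is None
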