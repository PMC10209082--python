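"""Sequence-identity computation, homology reduction and homology partitioning.

Near-duplicate sequences inflate cross-validation estimates, so training
sets are first *reduced* (no retained pair within a class above a high
identity threshold, 90% by default) and then *partitioned*: single-linkage
similarity clusters are assigned whole to either the train-test or the
independent set, so that no cross-set pair exceeds a low threshold (40% by
default).  Identity is computed from a Needleman–Wunsch global alignment
(BLOSUM62, gap open 10 / extend 0.5, free end gaps — the classic `needle`
convention) as 100 x identical columns / denominator, where the denominator
is the alignment length (needle-style) or the shorter sequence length
(CD-HIT-style).

Exact pairwise alignment replaces k-mer pre-filtering heuristics here: the
datasets this package targets are small enough for the all-pairs
computation, and the contract (no retained pair at or above the threshold)
is identical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .seq_data import LabeledDataset

__all__ = [
    "IdentityParams",
    "PartitionResult",
    "pairwise_identity",
    "identity_matrix",
    "homology_reduce",
    "homology_partition",
    "mean_cross_identity",
]


@dataclass(frozen=True)
class IdentityParams:
    """Alignment scoring and identity-denominator convention."""

    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5
    denominator: str = "alignment_length"  # or "shorter_sequence"

    def __post_init__(self):
        if self.gap_open < 0 or self.gap_extend < 0:
            raise ValueError("gap penalties must be >= 0")
        if self.denominator not in ("alignment_length", "shorter_sequence"):
            raise ValueError(f"unknown denominator {self.denominator!r}")


@dataclass
class PartitionResult:
    train_test: LabeledDataset
    independent: LabeledDataset
    clusters: dict[str, int]  # record id -> cluster id
    achieved_fraction: float


def _aligner(params: IdentityParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load(params.matrix)
    aligner.mode = "global"
    # needle semantics: a gap of length L costs open + L*extend
    aligner.open_gap_score = -(params.gap_open + params.gap_extend)
    aligner.extend_gap_score = -params.gap_extend
    # end gaps are free (needle endweight=false)
    aligner.open_end_insertion_score = 0.0
    aligner.extend_end_insertion_score = 0.0
    aligner.open_end_deletion_score = 0.0
    aligner.extend_end_deletion_score = 0.0
    return aligner


def pairwise_identity(
    a: str, b: str, params: IdentityParams = IdentityParams()
) -> float:
    """Percent identity of the global alignment of two sequences, in [0, 100].

    Symmetric by construction: the pair is put in canonical (sorted) order
    before aligning, so tie-breaking among co-optimal alignments cannot make
    identity(a, b) differ from identity(b, a).
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    if b < a:
        a, b = b, a
    alignment = _aligner(params).align(a, b)[0]
    counts = alignment.counts()
    if params.denominator == "alignment_length":
        denom = alignment.length
    else:
        denom = min(len(a), len(b))
    return 100.0 * counts.identities / denom


def identity_matrix(
    sequences: list[str], params: IdentityParams = IdentityParams()
) -> np.ndarray:
    """Symmetric all-pairs identity matrix (diagonal = 100)."""
    n = len(sequences)
    mat = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = pairwise_identity(
            sequences[i], sequences[j], params
        )
    return mat


def homology_reduce(
    dataset: LabeledDataset,
    threshold: float = 90.0,
    params: IdentityParams = IdentityParams(),
) -> LabeledDataset:
    """Greedy incremental clustering; returns one representative per cluster.

    Sequences are visited longest-first; each joins the first existing
    cluster whose representative it matches at >= threshold identity,
    otherwise it founds a new cluster.  When labels are present the
    reduction runs within each class separately (a near-identical pair in
    *different* classes is informative, not redundant).  Representatives
    are returned in the original dataset order.
    """
    if not 0 < threshold <= 100:
        raise ValueError("threshold must be in (0, 100]")

    def reduce_group(records) -> set[str]:
        order = sorted(records, key=lambda r: (-len(r.sequence), r.id))
        reps = []  # founding records
        for rec in order:
            if not any(
                pairwise_identity(rec.sequence, rep.sequence, params) >= threshold
                for rep in reps
            ):
                reps.append(rec)
        return {r.id for r in reps}

    if any(r.fine is not None for r in dataset):
        keep: set[str] = set()
        classes = sorted({r.fine for r in dataset if r.fine is not None})
        for cls in classes:
            keep |= reduce_group([r for r in dataset if r.fine == cls])
        keep |= {r.id for r in dataset if r.fine is None}
    else:
        keep = reduce_group(list(dataset))
    return dataset.subset(i for i in dataset.ids if i in keep)


def _single_linkage_clusters(identities: np.ndarray, threshold: float) -> list[int]:
    """Cluster ids under single linkage over edges with identity >= threshold."""
    n = identities.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in itertools.combinations(range(n), 2):
        if identities[i, j] >= threshold:
            ri, rj = find(i), find(j)
            if ri != rj:
                parent[max(ri, rj)] = min(ri, rj)
    roots = {}
    labels = []
    for i in range(n):
        r = find(i)
        labels.append(roots.setdefault(r, len(roots)))
    return labels


def homology_partition(
    dataset: LabeledDataset,
    threshold: float = 40.0,
    independent_fraction: float = 0.15,
    allow_moving: bool = False,
    params: IdentityParams = IdentityParams(),
) -> PartitionResult:
    """Split a dataset into train-test and independent sets along clusters.

    Single-linkage clusters over the >=threshold identity graph are assigned
    whole to one partition (largest first, greedily minimizing the gap to
    ``independent_fraction``), which guarantees every cross-set pair has
    identity strictly below the threshold.  ``allow_moving`` is accepted for
    interface compatibility but individual records are never relocated out
    of their cluster (the recommended, default behaviour).
    """
    if not 0 < independent_fraction < 1:
        raise ValueError("independent_fraction must be in (0, 1)")
    if allow_moving:
        raise NotImplementedError(
            "record relocation between clusters is not supported; "
            "use allow_moving=False"
        )
    n = len(dataset)
    if n < 2:
        raise ValueError("cannot partition fewer than 2 records")
    idmat = identity_matrix(dataset.sequences, params)
    labels = _single_linkage_clusters(idmat, threshold)
    clusters: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(idx)
    if len(clusters) < 2:
        raise ValueError(
            "all records fall into a single similarity cluster at "
            f"threshold {threshold}; both partitions cannot be non-empty"
        )

    # largest-first greedy: take a cluster into the independent set only if
    # that moves the achieved fraction closer to the target
    member_ids = {
        lab: sorted(dataset.records[i].id for i in idxs)
        for lab, idxs in clusters.items()
    }
    order = sorted(
        clusters, key=lambda lab: (-len(clusters[lab]), member_ids[lab][0])
    )
    indep_labels: set[int] = set()
    indep_size = 0
    for lab in order:
        size = len(clusters[lab])
        if abs((indep_size + size) / n - independent_fraction) < abs(
            indep_size / n - independent_fraction
        ):
            indep_labels.add(lab)
            indep_size += size
    # both partitions must be non-empty
    if not indep_labels:
        smallest = min(order, key=lambda lab: (len(clusters[lab]), member_ids[lab][0]))
        indep_labels.add(smallest)
        indep_size += len(clusters[smallest])
    if indep_size == n:
        raise ValueError("independent set would contain every record")

    indep_idx = sorted(i for lab in indep_labels for i in clusters[lab])
    train_idx = sorted(set(range(n)) - set(indep_idx))
    ids = dataset.ids
    return PartitionResult(
        train_test=dataset.subset(ids[i] for i in train_idx),
        independent=dataset.subset(ids[i] for i in indep_idx),
        clusters={ids[i]: labels[i] for i in range(n)},
        achieved_fraction=indep_size / n,
    )


def mean_cross_identity(
    a: LabeledDataset,
    b: LabeledDataset,
    params: IdentityParams = IdentityParams(),
) -> dict[str, float | None]:
    """Per-fine-class mean identity over all cross-set pairs.

    Classes absent from either set map to None (reported missing, never 0).
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both datasets must be non-empty")
    classes = sorted(
        {r.fine for r in a if r.fine is not None}
        | {r.fine for r in b if r.fine is not None}
    )
    if not classes:  # unlabeled data: one overall mean
        vals = [
            pairwise_identity(x.sequence, y.sequence, params)
            for x in a
            for y in b
        ]
        return {"all": float(np.mean(vals))}
    out: dict[str, float | None] = {}
    for cls in classes:
        seqs_a = [r.sequence for r in a if r.fine == cls]
        seqs_b = [r.sequence for r in b if r.fine == cls]
        if not seqs_a or not seqs_b:
            out[cls] = None
            continue
        vals = [
            pairwise_identity(x, y, params) for x in seqs_a for y in seqs_b
        ]
        out[cls] = float(np.mean(vals))
    return out
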