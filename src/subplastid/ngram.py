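"""Gapped n-gram features and QuiPT exact permutation-test selection.

Sequences are represented by the *presence or absence* of short amino-acid
motifs (n-grams).  An n-gram of length 1-3 may contain fixed-length gaps
between its specified residues; a gap position matches any residue.  The
gap convention is:

* length 1 — no gaps (20 patterns);
* length 2 — a single gap of 0 to 3 residues (4 x 400 = 1,600 patterns);
* length 3 — two gaps, each of 0 or 1 residues (4 x 8,000 = 32,000 patterns);

33,620 patterns in total.  Patterns render as the residues interleaved with
one underscore per gap residue, e.g. ``DP_G`` is D, P, one wildcard, G.

Feature selection uses QuiPT, the quick permutation test: for a binary
feature and binary target with fixed margins, the permutation distribution
of any contingency-table statistic depends only on the table overlap, which
is hypergeometric — so the exact permutation p-value is a hypergeometric
tail sum, no sampling involved.  The statistic is the mutual information of
the 2x2 table in bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import hypergeom

from .seq_data import AMINO_ACIDS, LabeledDataset

__all__ = [
    "NGramPattern",
    "FeatureMatrix",
    "enumerate_patterns",
    "extract_presence",
    "quipt_pvalue",
    "quipt_pvalues",
    "select_features",
]

_AA_SET = frozenset(AMINO_ACIDS)
#: gap lengths allowed for bigrams and (per slot) for trigrams
BIGRAM_GAPS = (0, 1, 2, 3)
TRIGRAM_GAPS = (0, 1)
_STAT_TOL = 1e-12  # "statistic >= observed" comparison tolerance


@dataclass(frozen=True)
class NGramPattern:
    """A gapped amino-acid motif: residues plus fixed gap lengths."""

    residues: tuple[str, ...]
    gaps: tuple[int, ...] = ()

    def __post_init__(self):
        k = len(self.residues)
        if not 1 <= k <= 3:
            raise ValueError("pattern length must be 1-3")
        if any(r not in _AA_SET for r in self.residues):
            raise ValueError(f"non-standard residue in pattern {self.residues}")
        if len(self.gaps) != k - 1:
            raise ValueError("need exactly len(residues)-1 gap lengths")
        if k == 2 and self.gaps[0] not in BIGRAM_GAPS:
            raise ValueError(f"bigram gap must be in {BIGRAM_GAPS}")
        if k == 3 and any(g not in TRIGRAM_GAPS for g in self.gaps):
            raise ValueError(f"trigram gaps must each be in {TRIGRAM_GAPS}")

    @property
    def span(self) -> int:
        """Number of sequence positions the pattern covers."""
        return len(self.residues) + sum(self.gaps)

    def __str__(self) -> str:
        out = [self.residues[0]]
        for gap, res in zip(self.gaps, self.residues[1:]):
            out.append("_" * gap)
            out.append(res)
        return "".join(out)

    @classmethod
    def from_string(cls, text: str) -> "NGramPattern":
        residues: list[str] = []
        gaps: list[int] = []
        gap = 0
        for ch in text:
            if ch == "_":
                gap += 1
            else:
                if residues:
                    gaps.append(gap)
                gap = 0
                residues.append(ch)
        if gap:
            raise ValueError(f"pattern {text!r} ends with a gap")
        return cls(tuple(residues), tuple(gaps))

    def matches(self, sequence: str) -> bool:
        """True iff the pattern occurs at at least one position."""
        span = self.span
        offsets = [0]
        for gap in self.gaps:
            offsets.append(offsets[-1] + 1 + gap)
        for start in range(len(sequence) - span + 1):
            if all(
                sequence[start + off] == res
                for off, res in zip(offsets, self.residues)
            ):
                return True
        return False

    def sort_key(self):
        return (len(self.residues), self.gaps, self.residues)


def enumerate_patterns() -> list[NGramPattern]:
    """All 33,620 patterns in canonical order (length, gaps, residues)."""
    patterns: list[NGramPattern] = []
    for aa in AMINO_ACIDS:
        patterns.append(NGramPattern((aa,)))
    for gap in BIGRAM_GAPS:
        for a in AMINO_ACIDS:
            for b in AMINO_ACIDS:
                patterns.append(NGramPattern((a, b), (gap,)))
    for g1 in TRIGRAM_GAPS:
        for g2 in TRIGRAM_GAPS:
            for a in AMINO_ACIDS:
                for b in AMINO_ACIDS:
                    for c in AMINO_ACIDS:
                        patterns.append(NGramPattern((a, b, c), (g1, g2)))
    return patterns


@dataclass
class FeatureMatrix:
    """Binary presence/absence matrix: rows = record ids, columns = patterns."""

    ids: list[str]
    patterns: list[str]  # canonical string form, in canonical column order
    X: sp.csr_matrix  # binary, shape (len(ids), len(patterns))

    def __post_init__(self):
        if self.X.shape != (len(self.ids), len(self.patterns)):
            raise ValueError("matrix shape does not match ids/patterns")

    @property
    def shape(self):
        return self.X.shape

    def column(self, pattern: str) -> np.ndarray:
        j = self.patterns.index(pattern)
        return np.asarray(self.X[:, j].todense()).ravel().astype(np.int8)

    def rows(self, row_index: Sequence[int]) -> "FeatureMatrix":
        return FeatureMatrix(
            [self.ids[i] for i in row_index], self.patterns, self.X[row_index]
        )

    def select_columns(self, col_index: Sequence[int]) -> "FeatureMatrix":
        return FeatureMatrix(
            self.ids, [self.patterns[j] for j in col_index], self.X[:, col_index]
        )


def _observed_patterns(sequence: str) -> set[str]:
    """All gapped n-grams occurring in a sequence (string form)."""
    found: set[str] = set()
    L = len(sequence)
    for i in range(L):
        a = sequence[i]
        found.add(a)
        for gap in BIGRAM_GAPS:
            j = i + 1 + gap
            if j < L:
                found.add(a + "_" * gap + sequence[j])
        for g1 in TRIGRAM_GAPS:
            j = i + 1 + g1
            if j >= L:
                continue
            for g2 in TRIGRAM_GAPS:
                k = j + 1 + g2
                if k < L:
                    found.add(
                        a + "_" * g1 + sequence[j] + "_" * g2 + sequence[k]
                    )
    return found


def extract_presence(
    dataset: Union[LabeledDataset, Iterable[tuple[str, str]]],
    patterns: Optional[Sequence[NGramPattern]] = None,
) -> FeatureMatrix:
    """Build the binary presence/absence matrix for a dataset.

    With ``patterns=None`` the columns are exactly the patterns observed in
    at least one sequence (all-zero columns carry no information and would
    receive p = 1 in selection anyway); with an explicit pattern list the
    columns are those patterns, in canonical order, including absent ones.
    """
    if isinstance(dataset, LabeledDataset):
        items = [(r.id, r.sequence) for r in dataset]
    else:
        items = list(dataset)
    per_seq = [_observed_patterns(seq) for _, seq in items]
    if patterns is None:
        observed = set().union(*per_seq) if per_seq else set()
        cols = sorted(observed, key=lambda s: NGramPattern.from_string(s).sort_key())
    else:
        cols = [str(p) for p in sorted(patterns, key=lambda p: p.sort_key())]
    col_index = {c: j for j, c in enumerate(cols)}
    rows_idx, cols_idx = [], []
    for i, found in enumerate(per_seq):
        hit = found if patterns is None else (found & col_index.keys())
        for c in hit:
            rows_idx.append(i)
            cols_idx.append(col_index[c])
    X = sp.csr_matrix(
        (np.ones(len(rows_idx), dtype=np.int8), (rows_idx, cols_idx)),
        shape=(len(items), len(cols)),
        dtype=np.int8,
    )
    return FeatureMatrix([rid for rid, _ in items], cols, X)


def _mi_bits(n: int, K: int, n1: int, m: np.ndarray) -> np.ndarray:
    """Mutual information (bits) of the 2x2 table with margins (K, n1) and
    overlap m, vectorized over m."""
    m = np.asarray(m, dtype=float)
    cells = np.stack([m, K - m, n1 - m, n - K - n1 + m])
    rows = np.array([K, K, n - K, n - K], dtype=float)[:, None]
    cols = np.array([n1, n - n1, n1, n - n1], dtype=float)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = cells / n * np.log2(cells * n / (rows * cols))
    terms = np.where(cells > 0, terms, 0.0)
    return np.maximum(terms.sum(axis=0), 0.0)


@lru_cache(maxsize=200_000)
def _pvalue_from_margins(n: int, K: int, n1: int, m: int) -> tuple[float, float]:
    """(statistic in bits, exact permutation p-value) from the table margins."""
    lo = max(0, K + n1 - n)
    hi = min(K, n1)
    ms = np.arange(lo, hi + 1)
    stats = _mi_bits(n, K, n1, ms)
    obs = _mi_bits(n, K, n1, np.array([m]))[0]
    pmf = hypergeom.pmf(ms, n, K, n1)
    p = float(pmf[stats >= obs - _STAT_TOL].sum())
    return float(obs), min(p, 1.0)


def quipt_pvalue(feature, target) -> tuple[float, float]:
    """Exact permutation test of association between two binary vectors.

    Returns (mutual information in bits, exact two-sided p-value).  The
    p-value is the probability, over all distinct permutations of the
    target, of a table statistic at least as large as the observed one;
    constant vectors give statistic 0 and p = 1.
    """
    f = np.asarray(feature, dtype=int)
    t = np.asarray(target, dtype=int)
    if f.shape != t.shape or f.ndim != 1:
        raise ValueError("feature and target must be equal-length 1-D vectors")
    n = f.size
    if n < 2:
        raise ValueError("need at least 2 observations")
    if not (set(np.unique(f)) <= {0, 1} and set(np.unique(t)) <= {0, 1}):
        raise ValueError("feature and target must be binary")
    return _pvalue_from_margins(n, int(f.sum()), int(t.sum()), int((f * t).sum()))


def quipt_pvalues(X: sp.spmatrix, target) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise QuiPT over a sparse binary matrix; returns (stats, ps)."""
    t = np.asarray(target, dtype=np.int8)
    n = X.shape[0]
    if t.size != n:
        raise ValueError("target length must equal number of rows")
    Xc = sp.csc_matrix(X)
    K = np.asarray(Xc.sum(axis=0)).ravel().astype(int)
    m = np.asarray(Xc[t == 1].sum(axis=0)).ravel().astype(int)
    n1 = int(t.sum())
    stats = np.empty(X.shape[1])
    ps = np.empty(X.shape[1])
    for j in range(X.shape[1]):
        stats[j], ps[j] = _pvalue_from_margins(n, K[j], n1, m[j])
    return stats, ps


def select_features(
    matrix: FeatureMatrix, target, alpha: float = 0.01
) -> tuple[FeatureMatrix, pd.DataFrame]:
    """Retain exactly the columns with exact p-value below ``alpha``.

    Returns the reduced matrix and a per-pattern result table (statistic in
    bits, p-value, selected flag).  An empty selection is returned as a
    zero-column matrix with a warning left to the caller's discretion.
    """
    stats, ps = quipt_pvalues(matrix.X, target)
    selected = ps < alpha
    result = pd.DataFrame(
        {
            "pattern": matrix.patterns,
            "statistic": stats,
            "p": ps,
            "selected": selected,
        }
    )
    return matrix.select_columns(np.flatnonzero(selected)), result
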