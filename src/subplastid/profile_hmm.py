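"""Profile hidden Markov models for thylakoid-lumen targeting signals.

A profile HMM summarises an alignment of Sec or Tat signal regions as a
chain of match states (one per well-occupied alignment column) with insert
and delete states, and scores a query by the log-odds (in bits) of its
N-terminal window under the profile versus an i.i.d. background.  Tat
signals carry the twin-arginine motif, so a Tat profile has two
high-arginine match columns that a Sec profile lacks — the score difference
is what the ensemble consumes.

The architecture is glocal: the profile must be traversed from begin to end
(no local entry/exit), while flanking insert states (I0 before the first
match column, Ik after the last) absorb the residues of the window that lie
outside the signal, so a signal at a variable N-terminal offset still
scores well.  Scoring uses the forward algorithm, summing over all paths;
Viterbi (best single path) is available for diagnostics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence, Union

import numpy as np

from .seq_data import AMINO_ACIDS

__all__ = [
    "ProfileHMM",
    "build_from_msa",
    "score_logodds",
    "viterbi_logodds",
    "read_msa_fasta",
    "write_msa_fasta",
]

_GAP_CHARS = frozenset("-.")
_NEG_INF = float("-inf")
_SCHEMA_VERSION = 1

Msa = Union[Sequence[str], Sequence[tuple[str, str]]]


def _rows(msa: Msa) -> list[str]:
    rows = [r[1] if isinstance(r, (tuple, list)) else r for r in msa]
    rows = [r.upper() for r in rows]
    if len(rows) < 2:
        raise ValueError("an MSA needs at least 2 rows")
    if len({len(r) for r in rows}) != 1:
        raise ValueError("all MSA rows must have equal aligned length")
    return rows


@dataclass
class ProfileHMM:
    """Match/insert/delete profile with explicit transition probabilities.

    States are labelled ``B``, ``M1..Mk``, ``I0..Ik``, ``D1..Dk``, ``E``;
    ``transitions`` maps (from, to) state labels to probabilities.  Insert
    emissions are tied to the background by construction but stored per
    state so hand-built toy models can deviate.
    """

    match_emissions: np.ndarray  # (k, 20)
    insert_emissions: np.ndarray  # (k+1, 20)
    background: np.ndarray  # (20,)
    transitions: dict[tuple[str, str], float]
    n_match: int

    def __post_init__(self):
        k = self.n_match
        if k < 1:
            raise ValueError("profile needs at least one match state")
        if self.match_emissions.shape != (k, 20):
            raise ValueError("match_emissions must be (n_match, 20)")
        if self.insert_emissions.shape != (k + 1, 20):
            raise ValueError("insert_emissions must be (n_match+1, 20)")
        for name, vecs in (
            ("match", self.match_emissions),
            ("insert", self.insert_emissions),
            ("background", self.background[None, :]),
        ):
            sums = vecs.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-9):
                raise ValueError(f"{name} emission vectors must sum to 1")
        outgoing: dict[str, float] = {}
        for (src, _), p in self.transitions.items():
            if p < 0:
                raise ValueError("negative transition probability")
            outgoing[src] = outgoing.get(src, 0.0) + p
        for src, total in outgoing.items():
            if abs(total - 1.0) > 1e-9:
                raise ValueError(
                    f"outgoing transitions of {src} sum to {total}, not 1"
                )

    # -- serialization ------------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {
                "schema_version": _SCHEMA_VERSION,
                "n_match": self.n_match,
                "alphabet": AMINO_ACIDS,
                "match_emissions": self.match_emissions.tolist(),
                "insert_emissions": self.insert_emissions.tolist(),
                "background": self.background.tolist(),
                "transitions": [
                    [src, dst, p] for (src, dst), p in sorted(self.transitions.items())
                ],
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ProfileHMM":
        data = json.loads(text)
        if data.get("schema_version") != _SCHEMA_VERSION:
            raise ValueError("unsupported profile schema version")
        return cls(
            match_emissions=np.array(data["match_emissions"]),
            insert_emissions=np.array(data["insert_emissions"]),
            background=np.array(data["background"]),
            transitions={(s, d): p for s, d, p in data["transitions"]},
            n_match=data["n_match"],
        )


def read_msa_fasta(path) -> list[tuple[str, str]]:
    """Read an aligned FASTA file (gap characters '-' and '.' allowed)."""
    rows: list[tuple[str, str]] = []
    header, chunks = None, []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    rows.append((header, "".join(chunks).upper()))
                header, chunks = line[1:].split()[0], []
            else:
                chunks.append(line)
        if header is not None:
            rows.append((header, "".join(chunks).upper()))
    _rows(rows)  # validates row count and equal lengths
    return rows


def write_msa_fasta(msa: Sequence[tuple[str, str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, row in msa:
            fh.write(f">{name}\n{row}\n")


def _allowed_transitions(k: int) -> list[tuple[str, str]]:
    out = [("B", "M1"), ("B", "D1"), ("B", "I0")]
    out += [("I0", "I0"), ("I0", "M1"), ("I0", "D1")]
    for j in range(1, k):
        out += [
            (f"M{j}", f"M{j+1}"),
            (f"M{j}", f"I{j}"),
            (f"M{j}", f"D{j+1}"),
            (f"I{j}", f"I{j}"),
            (f"I{j}", f"M{j+1}"),
            (f"I{j}", f"D{j+1}"),
            (f"D{j}", f"M{j+1}"),
            (f"D{j}", f"I{j}"),
            (f"D{j}", f"D{j+1}"),
        ]
    out += [
        (f"M{k}", f"I{k}"),
        (f"M{k}", "E"),
        (f"D{k}", f"I{k}"),
        (f"D{k}", "E"),
        (f"I{k}", f"I{k}"),
        (f"I{k}", "E"),
    ]
    return out


def build_from_msa(
    msa: Msa,
    gap_fraction_threshold: float = 0.5,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Cached front-end to :func:`_build_from_msa`.

    Building is deterministic, so identical inputs return the same profile
    object (treat profiles as immutable); this lets repeated CV folds share
    one compiled, score-cached profile per input alignment.
    """
    rows = tuple(_rows(msa))
    if background is None:
        return _build_cached(rows, gap_fraction_threshold, pseudocount)
    return _build_from_msa(rows, gap_fraction_threshold, pseudocount, background)


@lru_cache(maxsize=64)
def _build_cached(
    rows: tuple[str, ...], gap_fraction_threshold: float, pseudocount: float
) -> ProfileHMM:
    return _build_from_msa(rows, gap_fraction_threshold, pseudocount, None)


def _build_from_msa(
    msa: Msa,
    gap_fraction_threshold: float = 0.5,
    pseudocount: float = 1.0,
    background: np.ndarray | None = None,
) -> ProfileHMM:
    """Estimate a profile HMM from an aligned FASTA-style MSA.

    Columns whose gap fraction is below ``gap_fraction_threshold`` become
    match states.  Match emissions are (count + pseudocount) /
    (column residue count + 20 x pseudocount); transitions are estimated
    from the observed state path of every row with the same pseudocount
    spread over each state's allowed successors.  Insert emissions are tied
    to the background (uniform by default); rows are weighted equally.
    """
    rows = _rows(msa)
    n_cols = len(rows[0])
    gap_fraction = [
        sum(r[c] in _GAP_CHARS for r in rows) / len(rows) for c in range(n_cols)
    ]
    match_cols = [c for c in range(n_cols) if gap_fraction[c] < gap_fraction_threshold]
    k = len(match_cols)
    if k == 0:
        raise ValueError("no column qualifies as a match state")
    bg = (
        np.full(20, 1.0 / 20)
        if background is None
        else np.asarray(background, dtype=float)
    )
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    match_rank = {c: j + 1 for j, c in enumerate(match_cols)}

    emit_counts = np.zeros((k, 20))
    trans_counts: dict[tuple[str, str], float] = {}

    for row in rows:
        state = "B"
        insert_level = 0
        for c, ch in enumerate(row):
            if c in match_rank:
                j = match_rank[c]
                if ch in _GAP_CHARS:
                    nxt = f"D{j}"
                else:
                    nxt = f"M{j}"
                    if ch not in aa_index:
                        raise ValueError(f"non-standard residue {ch!r} in MSA")
                    emit_counts[j - 1, aa_index[ch]] += 1
                trans_counts[(state, nxt)] = trans_counts.get((state, nxt), 0) + 1
                state, insert_level = nxt, j
            elif ch not in _GAP_CHARS:
                nxt = f"I{insert_level}"
                trans_counts[(state, nxt)] = trans_counts.get((state, nxt), 0) + 1
                state = nxt
        trans_counts[(state, "E")] = trans_counts.get((state, "E"), 0) + 1

    col_totals = emit_counts.sum(axis=1, keepdims=True)
    match_emissions = (emit_counts + pseudocount) / (col_totals + 20 * pseudocount)

    allowed = _allowed_transitions(k)
    by_src: dict[str, list[tuple[str, str]]] = {}
    for src, dst in allowed:
        by_src.setdefault(src, []).append((src, dst))
    transitions: dict[tuple[str, str], float] = {}
    for src, pairs in by_src.items():
        counts = np.array([trans_counts.get(p, 0.0) for p in pairs]) + pseudocount
        probs = counts / counts.sum()
        for pair, p in zip(pairs, probs):
            transitions[pair] = float(p)

    return ProfileHMM(
        match_emissions=match_emissions,
        insert_emissions=np.tile(bg, (k + 1, 1)),
        background=bg,
        transitions=transitions,
        n_match=k,
    )


def _log2(x: float) -> float:
    return math.log2(x) if x > 0 else _NEG_INF


def _transition_arrays(hmm: ProfileHMM):
    """Compile the transition dict into per-column log2 arrays.

    Index ``j`` refers to match column j with ``M0 = B``; delete index 0 is
    unused.  Cached on the profile object (identity-keyed) since ensembles
    score many sequences against the same profile.
    """
    cached = getattr(hmm, "_compiled", None)
    if cached is not None:
        return cached
    k = hmm.n_match
    t = {pair: _log2(p) for pair, p in hmm.transitions.items()}
    g = lambda src, dst: t.get((src, dst), _NEG_INF)
    tMM = np.full(k + 1, _NEG_INF)  # M_j -> M_{j+1}, valid j = 0..k-1
    tMI = np.full(k + 1, _NEG_INF)  # M_j -> I_j
    tMD = np.full(k + 1, _NEG_INF)  # M_j -> D_{j+1}, valid j = 0..k-1
    tII = np.full(k + 1, _NEG_INF)  # I_j -> I_j
    tIM = np.full(k + 1, _NEG_INF)  # I_j -> M_{j+1}, valid j = 0..k-1
    tID = np.full(k + 1, _NEG_INF)  # I_j -> D_{j+1}, valid j = 0..k-1
    tDM = np.full(k + 1, _NEG_INF)  # D_j -> M_{j+1}, valid j = 1..k-1
    tDI = np.full(k + 1, _NEG_INF)  # D_j -> I_j, valid j = 1..k
    tDD = np.full(k + 1, _NEG_INF)  # D_j -> D_{j+1}, valid j = 1..k-1
    for j in range(k + 1):
        src = "B" if j == 0 else f"M{j}"
        tMI[j] = g(src, f"I{j}")
        tII[j] = g(f"I{j}", f"I{j}")
        if j < k:
            tMM[j] = g(src, f"M{j+1}")
            tMD[j] = g(src, f"D{j+1}")
            tIM[j] = g(f"I{j}", f"M{j+1}")
            tID[j] = g(f"I{j}", f"D{j+1}")
        if 1 <= j < k:
            tDM[j] = g(f"D{j}", f"M{j+1}")
            tDD[j] = g(f"D{j}", f"D{j+1}")
        if j >= 1:
            tDI[j] = g(f"D{j}", f"I{j}")
    ends = (g(f"M{k}", "E"), g(f"I{k}", "E"), g(f"D{k}", "E"))
    with np.errstate(divide="ignore"):
        eM = np.full((k + 1, 20), _NEG_INF)
        eM[1:] = np.log2(hmm.match_emissions)
        eI = np.log2(np.maximum(hmm.insert_emissions, 0.0))
    compiled = (tMM, tMI, tMD, tII, tIM, tID, tDM, tDI, tDD, ends, eM, eI)
    hmm._compiled = compiled
    return compiled


def _dp(hmm: ProfileHMM, sequence: str, viterbi: bool = False) -> float:
    """Forward (sum over paths) or Viterbi (best path) log2 probability of
    the full sequence being emitted begin-to-end."""
    k = hmm.n_match
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    try:
        x = [aa_index[ch] for ch in sequence]
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r}") from None
    if not x:
        raise ValueError("cannot score an empty sequence")
    (tMM, tMI, tMD, tII, tIM, tID, tDM, tDI, tDD, ends, eM, eI) = \
        _transition_arrays(hmm)
    comb = np.maximum if viterbi else np.logaddexp2

    # fM[j]/fI[j]: in state after emitting the residues seen so far, the
    # last one by M_j/I_j; fD[j]: in D_j (no emission).  fM[0] is B.
    fM = np.full(k + 1, _NEG_INF)
    fI = np.full(k + 1, _NEG_INF)
    fD = np.full(k + 1, _NEG_INF)
    fM[0] = 0.0
    for j in range(1, k + 1):  # delete chain reachable before any emission
        fD[j] = comb(
            comb(fM[j - 1] + tMD[j - 1], fI[j - 1] + tID[j - 1]),
            fD[j - 1] + tDD[j - 1],
        )
    with np.errstate(invalid="ignore"):
        for c in x:
            newM = np.full(k + 1, _NEG_INF)
            newM[1:] = eM[1:, c] + comb(
                comb(fM[:-1] + tMM[:-1], fI[:-1] + tIM[:-1]),
                fD[:-1] + tDM[:-1],
            )
            newI = eI[:, c] + comb(
                comb(fM + tMI, fI + tII), fD + tDI
            )
            newD = np.full(k + 1, _NEG_INF)
            for j in range(1, k + 1):
                newD[j] = comb(
                    comb(newM[j - 1] + tMD[j - 1], newI[j - 1] + tID[j - 1]),
                    newD[j - 1] + tDD[j - 1],
                )
            fM, fI, fD = newM, newI, newD
    tME, tIE, tDE = ends
    return float(comb(comb(fM[k] + tME, fI[k] + tIE), fD[k] + tDE))


def _null_log2(hmm: ProfileHMM, sequence: str) -> float:
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}
    return float(
        sum(math.log2(hmm.background[aa_index[ch]]) for ch in sequence)
    )


def score_logodds(hmm: ProfileHMM, sequence: str, window: int = 100) -> float:
    """Forward log-odds (bits) of the sequence's N-terminal window.

    log2 P(window | profile) - log2 P(window | background); finite for any
    non-empty standard-alphabet sequence.  ``window`` limits scoring to the
    first residues, where targeting signals reside; pass ``window=None`` (or
    a large value) to score the whole sequence.
    """
    if not sequence:
        raise ValueError("cannot score an empty sequence")
    seq = sequence if window is None else sequence[:window]
    cache = getattr(hmm, "_score_cache", None)
    if cache is None:
        cache = hmm._score_cache = {}
    if seq not in cache:
        cache[seq] = _dp(hmm, seq) - _null_log2(hmm, seq)
    return cache[seq]


def viterbi_logodds(hmm: ProfileHMM, sequence: str, window: int = 100) -> float:
    """Best-single-path log-odds (bits); never exceeds the forward score."""
    if not sequence:
        raise ValueError("cannot score an empty sequence")
    seq = sequence if window is None else sequence[:window]
    return _dp(hmm, seq, viterbi=True) - _null_log2(hmm, seq)
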