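"""Independent brute-force oracles shared by unit and acceptance tests.

Each oracle recomputes a quantity by literal enumeration, written without
reference to the package's own shortcut implementations.
"""

import itertools
import math

import numpy as np

from subplastid.seq_data import AMINO_ACIDS

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}


def brute_force_quipt(feature, target):
    """Exhaustive permutation p-value for the binary association test.

    Enumerates every distinct placement of the target's ones and recomputes
    a mutual-information statistic written independently of the package.
    """
    feature = list(feature)
    target = list(target)
    n = len(feature)

    def mutual_information(f, t):
        counts = {}
        for a, b in zip(f, t):
            counts[(a, b)] = counts.get((a, b), 0) + 1
        mi = 0.0
        for (a, b), c in counts.items():
            pa = sum(v for (x, _), v in counts.items() if x == a) / n
            pb = sum(v for (_, y), v in counts.items() if y == b) / n
            mi += (c / n) * math.log2((c / n) / (pa * pb))
        return mi

    observed = mutual_information(feature, target)
    ones = sum(target)
    hits = total = 0
    for positions in itertools.combinations(range(n), ones):
        perm = [1 if i in positions else 0 for i in range(n)]
        total += 1
        if mutual_information(feature, perm) >= observed - 1e-9:
            hits += 1
    return observed, hits / total


def enumerate_path_log2prob(hmm, seq):
    """Sum of P(path, seq) over all complete begin-to-end state paths."""
    total = 0.0

    def expand(state, pos, prob):
        nonlocal total
        if prob == 0.0:
            return
        if state == "E":
            if pos == len(seq):
                total += prob
            return
        for (src, dst), p in hmm.transitions.items():
            if src != state or p == 0.0:
                continue
            if dst == "E" or dst.startswith("D"):
                expand(dst, pos, prob * p)
            else:
                if pos >= len(seq):
                    continue
                j = int(dst[1:])
                if dst[0] == "M":
                    e = hmm.match_emissions[j - 1, AA_INDEX[seq[pos]]]
                else:
                    e = hmm.insert_emissions[j, AA_INDEX[seq[pos]]]
                expand(dst, pos + 1, prob * p * e)

    expand("B", 0, 1.0)
    return math.log2(total)


def null_log2(hmm, seq):
    return sum(math.log2(hmm.background[AA_INDEX[c]]) for c in seq)


def random_toy_hmm(rng, n_match):
    """A random fully-normalized toy profile with arbitrary emissions."""
    from subplastid.profile_hmm import ProfileHMM, _allowed_transitions

    match = rng.dirichlet(np.ones(20), size=n_match)
    background = rng.dirichlet(np.ones(20))
    inserts = np.tile(background, (n_match + 1, 1))
    by_src = {}
    for src, dst in _allowed_transitions(n_match):
        by_src.setdefault(src, []).append(dst)
    transitions = {}
    for src, dsts in by_src.items():
        probs = rng.dirichlet(np.ones(len(dsts)))
        for dst, p in zip(dsts, probs):
            transitions[(src, dst)] = float(p)
    return ProfileHMM(
        match_emissions=match,
        insert_emissions=inserts,
        background=background,
        transitions=transitions,
        n_match=n_match,
    )
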