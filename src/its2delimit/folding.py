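"""Secondary-structure prediction with a simplified nearest-neighbour model.

The folding objective is deliberately simple and fully documented rather
than a Turner-parameter reproduction: each canonical pair earns a reward
(GC=3, AU=2, GU=1), each stacked pair (both (i,j) and (i+1,j-1) paired)
earns a +1 bonus, hairpin loops must span at least ``min_loop`` unpaired
bases, and there are no dangles or multiloop terms. Higher scores are
better. Users wanting thermodynamic structures can supply Vienna/Mfold
output through :func:`its2delimit.seqio.read_vienna` instead.

``fold_mfe`` optimises this objective exactly by dynamic programming;
``brute_force_fold`` enumerates every nested canonical structure for
short sequences and serves as an independent oracle on the score.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from numba import njit

from .core import (
    AnnotatedSequence,
    SecondaryStructure,
    render_dotbracket,
)

NEG = -1e9

# Encoding: A=0, C=1, G=2, U=3, anything else (ambiguity) = 4, unpairable.
_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}


@dataclass(frozen=True)
class FoldParams:
    """Scoring parameters of the simplified folding model."""

    min_loop: int = 3
    gc_score: float = 3.0
    au_score: float = 2.0
    gu_score: float = 1.0
    stack_bonus: float = 1.0

    def pair_score_matrix(self) -> np.ndarray:
        ps = np.full((5, 5), NEG)
        a, c, g, u = 0, 1, 2, 3
        ps[g, c] = ps[c, g] = self.gc_score
        ps[a, u] = ps[u, a] = self.au_score
        ps[g, u] = ps[u, g] = self.gu_score
        return ps


DEFAULT_PARAMS = FoldParams()


def encode(residues: str) -> np.ndarray:
    return np.array([_CODE.get(ch, 4) for ch in residues], dtype=np.int8)


@njit(cache=True)
def _fill(codes, min_loop, ps, stack_bonus):  # pragma: no cover - numba
    n = codes.shape[0]
    W = np.zeros((n + 1, n + 1))
    V = np.full((n + 1, n + 1), NEG)
    for span in range(1, n + 1):
        for i in range(0, n - span + 1):
            j = i + span - 1  # inclusive interval [i, j]
            # V[i, j]: best score with (i, j) paired.
            if j - i - 1 >= min_loop and ps[codes[i], codes[j]] > NEG / 2:
                # W is stored as W[a, b] = best over inclusive [a, b-1]
                best_inner = W[i + 1, j]
                if V[i + 1, j - 1] > NEG / 2:
                    stacked = V[i + 1, j - 1] + stack_bonus
                    if stacked > best_inner:
                        best_inner = stacked
                V[i, j] = ps[codes[i], codes[j]] + best_inner
            # W[i, j+1]: best over inclusive [i, j].
            best = W[i + 1, j + 1]  # i unpaired
            for k in range(i + min_loop + 1, j + 1):
                if V[i, k] > NEG / 2:
                    cand = V[i, k] + W[k + 1, j + 1]
                    if cand > best:
                        best = cand
            W[i, j + 1] = best
    return W, V


def _traceback(codes, W, V, min_loop, stack_bonus, ps):
    """Deterministic traceback: prefer pairing i (to j first, then smaller
    k ascending) over leaving i unpaired; inside a pair prefer the stacked
    continuation."""
    n = codes.shape[0]
    pairs: set[tuple[int, int]] = set()
    stack = [("W", 0, n - 1)]  # inclusive intervals
    eps = 1e-9
    while stack:
        kind, i, j = stack.pop()
        if kind == "W":
            if i > j:
                continue
            target = W[i, j + 1]
            # candidate order: k = j, then ascending k, then i unpaired
            ks = [j] + list(range(i + min_loop + 1, j))
            chosen = False
            for k in ks:
                if V[i, k] > NEG / 2 and abs(V[i, k] + W[k + 1, j + 1] - target) < eps:
                    pairs.add((i, k))
                    stack.append(("V", i, k))
                    stack.append(("W", k + 1, j))
                    chosen = True
                    break
            if not chosen:
                stack.append(("W", i + 1, j))
        else:  # V: (i, j) is paired; decompose the interior
            target = V[i, j] - ps[codes[i], codes[j]]
            if (
                V[i + 1, j - 1] > NEG / 2
                and abs(V[i + 1, j - 1] + stack_bonus - target) < eps
            ):
                pairs.add((i + 1, j - 1))
                stack.append(("V", i + 1, j - 1))
            else:
                stack.append(("W", i + 1, j - 1))
    return pairs


def fold_mfe(
    seq: AnnotatedSequence, params: FoldParams = DEFAULT_PARAMS
) -> SecondaryStructure:
    """Fold one sequence to the optimum of the simplified objective.

    Deterministic: ties in the dynamic program are broken by preferring
    to pair the leftmost base, to its furthest partner first, and by
    preferring stacked continuations.
    """
    codes = encode(seq.residues)
    n = len(codes)
    ps = params.pair_score_matrix()
    if n < params.min_loop + 2:
        return SecondaryStructure(seq.id, "." * n, frozenset(), 0.0)
    W, V = _fill(codes, params.min_loop, ps, params.stack_bonus)
    score = float(W[0, n])
    pairs = _traceback(codes, W, V, params.min_loop, params.stack_bonus, ps)
    db = render_dotbracket(n, pairs)
    return SecondaryStructure(seq.id, db, frozenset(pairs), score)


def score_structure(
    residues: str, pairs: frozenset[tuple[int, int]], params: FoldParams = DEFAULT_PARAMS
) -> float:
    """Score an explicit structure under the folding objective."""
    codes = encode(residues)
    ps = params.pair_score_matrix()
    total = 0.0
    for i, j in pairs:
        s = ps[codes[i], codes[j]]
        if s < NEG / 2:
            raise ValueError(f"non-canonical pair at ({i}, {j})")
        total += s
        if (i + 1, j - 1) in pairs:
            total += params.stack_bonus
    return total


MAX_BRUTE_FORCE_LEN = 18


def enumerate_structures(
    residues: str, min_loop: int = 3
) -> list[frozenset[tuple[int, int]]]:
    """Exhaustively enumerate all nested canonical structures."""
    codes = encode(residues)
    ps = DEFAULT_PARAMS.pair_score_matrix()

    @lru_cache(maxsize=None)
    def rec(i: int, j: int):  # structures over [i, j) as frozensets
        if j - i <= min_loop:
            return [frozenset()]
        out = list(rec(i + 1, j))
        for k in range(i + min_loop + 1, j):
            if ps[codes[i], codes[k]] > NEG / 2:
                left = rec(i + 1, k)
                right = rec(k + 1, j)
                for s1 in left:
                    for s2 in right:
                        out.append(s1 | s2 | {(i, k)})
        return out

    return rec(0, len(codes))


def brute_force_fold(
    seq: AnnotatedSequence, params: FoldParams = DEFAULT_PARAMS
) -> SecondaryStructure:
    """Exhaustive-enumeration folding oracle for sequences of length <= 18.

    Independent of the dynamic program: scores every nested canonical
    structure and returns the best. Among co-optimal structures the
    lexicographically smallest dot-bracket is returned, which may differ
    from the DP traceback; the optimal *score* is always identical.
    """
    n = len(seq.residues)
    if n > MAX_BRUTE_FORCE_LEN:
        raise ValueError(
            f"brute_force_fold refuses length {n} > {MAX_BRUTE_FORCE_LEN}"
        )
    best_score = 0.0
    best: list[frozenset] = [frozenset()]
    for pairs in enumerate_structures(seq.residues, params.min_loop):
        sc = score_structure(seq.residues, pairs, params)
        if sc > best_score + 1e-12:
            best_score = sc
            best = [pairs]
        elif abs(sc - best_score) <= 1e-12:
            best.append(pairs)
    dbs = sorted(render_dotbracket(n, p) for p in best)
    chosen = dbs[0]
    return SecondaryStructure.from_dotbracket(seq.id, chosen, best_score)


def fold_all(
    seqs, params: FoldParams = DEFAULT_PARAMS
) -> list[SecondaryStructure]:
    return [fold_mfe(s, params) for s in seqs]
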