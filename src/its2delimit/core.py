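"""Shared domain types for the ITS2 delimitation pipeline.

Sequences are stored RNA-canonical (T -> U, upper case). IUPAC ambiguity
codes are retained but treated as unpairable in folding and as
non-comparable sites in distance and CBC computations. Coordinates are
0-based half-open internally; user-facing reports are 1-based inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

GAP_CHARS = "-."
CANONICAL_PAIRS = frozenset({"AU", "UA", "GC", "CG", "GU", "UG"})
IUPAC = set("ACGUNRYSWKMBDHV")
UNAMBIGUOUS = set("ACGU")


def canonicalize(residues: str) -> str:
    """Upper-case and map T to the RNA synonym U. Idempotent."""
    return residues.upper().replace("T", "U")


def is_canonical_pair(a: str, b: str) -> bool:
    return (a + b) in CANONICAL_PAIRS


@dataclass(frozen=True)
class AnnotatedSequence:
    """One ITS2 sequence with its identifier and optional annotations."""

    id: str
    residues: str
    species_hint: str | None = None
    is_outgroup: bool = False

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} has empty residues")
        canon = canonicalize(self.residues)
        bad = set(canon) - IUPAC - set(GAP_CHARS)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-IUPAC characters: {sorted(bad)}"
            )
        object.__setattr__(self, "residues", canon)

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> str:
        s = self.residues
        for g in GAP_CHARS:
            s = s.replace(g, "")
        return s


def check_unique_ids(seqs: Iterable[AnnotatedSequence]) -> None:
    seen = set()
    for s in seqs:
        if s.id in seen:
            raise ValueError(f"duplicate sequence id: {s.id!r}")
        seen.add(s.id)


@dataclass(frozen=True)
class Msa:
    """A multiple sequence alignment: equal-length gapped rows.

    Gap characters '-' and '.' are both accepted on input and normalised
    to '-'.
    """

    rows: tuple[AnnotatedSequence, ...]
    n_columns: int = field(init=False)

    def __init__(self, rows: Sequence[AnnotatedSequence]):
        rows = tuple(
            replace(r, residues=r.residues.replace(".", "-")) for r in rows
        )
        check_unique_ids(rows)
        if not rows:
            raise ValueError("alignment has no rows")
        ncol = len(rows[0].residues)
        for r in rows:
            if len(r.residues) != ncol:
                raise ValueError(
                    f"ragged alignment: row {r.id!r} has length "
                    f"{len(r.residues)}, expected {ncol}"
                )
        object.__setattr__(self, "rows", rows)
        object.__setattr__(self, "n_columns", ncol)

    def __len__(self) -> int:
        return len(self.rows)

    @property
    def labels(self) -> list[str]:
        return [r.id for r in self.rows]

    def row(self, label: str) -> AnnotatedSequence:
        for r in self.rows:
            if r.id == label:
                return r
        raise KeyError(label)


@dataclass(frozen=True)
class SecondaryStructure:
    """A nested RNA secondary structure in dot-bracket form.

    ``pairs`` holds 0-based (i, j) index pairs with i < j; ``score`` is the
    value of the folding objective (model units, higher is better).
    """

    seq_id: str
    dotbracket: str
    pairs: frozenset[tuple[int, int]]
    score: float = 0.0

    def __len__(self) -> int:
        return len(self.dotbracket)

    @staticmethod
    def from_dotbracket(
        seq_id: str, dotbracket: str, score: float = 0.0
    ) -> "SecondaryStructure":
        return SecondaryStructure(
            seq_id, dotbracket, frozenset(pair_table(dotbracket)), score
        )


def pair_table(dotbracket: str) -> set[tuple[int, int]]:
    """Decode a dot-bracket string into its set of (i, j) pairs.

    Raises ValueError with the offending index for unbalanced strings.
    """
    stack: list[int] = []
    pairs: set[tuple[int, int]] = set()
    for i, c in enumerate(dotbracket):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            pairs.add((stack.pop(), i))
        elif c != ".":
            raise ValueError(f"invalid dot-bracket character {c!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pairs


def render_dotbracket(n: int, pairs: Iterable[tuple[int, int]]) -> str:
    chars = ["."] * n
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


class DistanceMatrix:
    """A labelled, symmetric, zero-diagonal dissimilarity matrix."""

    __slots__ = ("labels", "values")

    def __init__(self, labels: Sequence[str], values, *, _validate: bool = True):
        self.labels = list(labels)
        self.values = np.asarray(values, dtype=float)
        if _validate:
            self.validate()

    def validate(self) -> None:
        n = len(self.labels)
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("distance matrix has non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")

    def __len__(self) -> int:
        return len(self.labels)

    def reorder(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Return a copy with rows/columns in the given label order."""
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(list(labels), self.values[np.ix_(idx, idx)],
                              _validate=False)

    def __getitem__(self, key: tuple[str, str]) -> float:
        a, b = key
        return float(self.values[self.labels.index(a), self.labels.index(b)])
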