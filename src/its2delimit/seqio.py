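"""Readers and writers for the plain-text formats the pipeline touches.

FASTA and aligned FASTA go through Biopython; Vienna dot-bracket triplets
and square PHYLIP distance matrices are simple enough to be handled here
directly. Every reader/writer pair is a lossless round trip at the
declared precision.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO

from .core import (
    AnnotatedSequence,
    DistanceMatrix,
    Msa,
    SecondaryStructure,
    check_unique_ids,
    pair_table,
)

PHYLIP_PRECISION = 6


def read_fasta(path, *, outgroup_id: str | None = None) -> list[AnnotatedSequence]:
    """Read a FASTA file into AnnotatedSequence records (order preserved).

    T/U are canonicalized to U. Duplicate ids and empty files are errors.
    ``outgroup_id`` flags the matching record as the outgroup.
    """
    records = [
        AnnotatedSequence(
            id=r.id,
            residues=str(r.seq),
            is_outgroup=(outgroup_id is not None and r.id == outgroup_id),
        )
        for r in SeqIO.parse(os.fspath(path), "fasta")
    ]
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    check_unique_ids(records)
    if outgroup_id is not None and not any(r.is_outgroup for r in records):
        raise ValueError(f"outgroup id {outgroup_id!r} not present in {path}")
    return records


def write_fasta(seqs: Iterable[AnnotatedSequence], path) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")


def read_alignment(path, *, outgroup_id: str | None = None) -> Msa:
    """Read an aligned FASTA file; rows must all have the same length."""
    return Msa(read_fasta(path, outgroup_id=outgroup_id))


def write_alignment(msa: Msa, path) -> None:
    write_fasta(msa.rows, path)


def read_vienna(path) -> list[SecondaryStructure]:
    """Read 3-line Vienna records: >id / sequence / dot-bracket.

    The structure line may carry a trailing score in parentheses, e.g.
    ``(((...))) (-3.20)``; it is parsed if present.
    """
    structures: list[SecondaryStructure] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if len(lines) % 3 != 0:
        raise ValueError(
            f"{path}: Vienna file must consist of header/sequence/structure "
            f"triplets (got {len(lines)} non-empty lines)"
        )
    for k in range(0, len(lines), 3):
        header, seqline, structline = lines[k : k + 3]
        if not header.startswith(">"):
            raise ValueError(f"{path}: expected '>' header, got {header!r}")
        seq_id = header[1:].split()[0]
        db = structline.split()[0]
        score = 0.0
        rest = structline[len(db):].strip()
        if rest.startswith("(") and rest.endswith(")"):
            try:
                score = float(rest[1:-1])
            except ValueError:
                pass
        seq = AnnotatedSequence(seq_id, seqline)
        if len(db) != len(seq.residues):
            raise ValueError(
                f"{path}: structure length {len(db)} != sequence length "
                f"{len(seq.residues)} for record {seq_id!r}"
            )
        pairs = pair_table(db)  # raises with position if unbalanced
        structures.append(
            SecondaryStructure(seq_id, db, frozenset(pairs), score)
        )
    return structures


def read_vienna_with_sequences(
    path,
) -> list[tuple[AnnotatedSequence, SecondaryStructure]]:
    """As read_vienna, but also return the sequences themselves."""
    out = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    structures = read_vienna(path)
    for k, st in enumerate(structures):
        seqline = lines[3 * k + 1]
        out.append((AnnotatedSequence(st.seq_id, seqline), st))
    return out


def write_vienna(
    items: Sequence[tuple[AnnotatedSequence, SecondaryStructure]], path
) -> None:
    with open(path, "w") as fh:
        for seq, st in items:
            fh.write(f">{seq.id}\n{seq.residues}\n{st.dotbracket} ({st.score:.2f})\n")


def read_phylip_matrix(path, *, asymmetry_tol: float = 1e-8) -> DistanceMatrix:
    """Read a square (or lower-triangular) PHYLIP distance matrix.

    Minor asymmetry (<= ``asymmetry_tol``) is repaired by averaging;
    larger asymmetry, negative entries, or a taxon-count mismatch raise.
    """
    with open(path) as fh:
        tokens_per_line = [ln.split() for ln in fh if ln.strip()]
    if not tokens_per_line:
        raise ValueError(f"{path}: empty distance matrix file")
    try:
        n = int(tokens_per_line[0][0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: first line must hold the taxon count")
    body = tokens_per_line[1:]
    # Rows may wrap; re-join tokens and split per taxon by counting.
    flat = [tok for row in body for tok in row]
    labels: list[str] = []
    values = np.zeros((n, n))
    pos = 0
    lower_triangular = None
    for i in range(n):
        if pos >= len(flat):
            raise ValueError(f"{path}: expected {n} rows, found {i}")
        labels.append(flat[pos])
        pos += 1
        if lower_triangular is None:
            # Peek: a full matrix row has n entries, a lower-tri row has i.
            remaining = len(flat) - pos
            lower_triangular = remaining < n * n - i  # heuristic on first row
            if i == 0:
                # First row: full has n numbers before next label token.
                k = 0
                while pos + k < len(flat):
                    try:
                        float(flat[pos + k])
                        k += 1
                    except ValueError:
                        break
                lower_triangular = k < n
        count = i if lower_triangular else n
        row_vals = flat[pos : pos + count]
        if len(row_vals) != count:
            raise ValueError(f"{path}: row {labels[-1]!r} is truncated")
        pos += count
        for j, tok in enumerate(row_vals):
            values[i, j] = float(tok)
    if pos != len(flat):
        raise ValueError(f"{path}: trailing data after {n} rows")
    if lower_triangular:
        values = values + values.T
    if np.any(values < 0):
        raise ValueError(f"{path}: negative distance entry")
    asym = np.max(np.abs(values - values.T))
    if asym > asymmetry_tol:
        raise ValueError(f"{path}: matrix asymmetry {asym:g} exceeds tolerance")
    values = 0.5 * (values + values.T)
    np.fill_diagonal(values, 0.0)
    return DistanceMatrix(labels, values)


def write_phylip_matrix(m: DistanceMatrix, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(m.labels)}\n")
        for label, row in zip(m.labels, m.values):
            cells = " ".join(f"{v:.{PHYLIP_PRECISION}f}" for v in row)
            fh.write(f"{label} {cells}\n")
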