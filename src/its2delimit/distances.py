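"""The two input tables of the method: AF (structure) and AB (sequence).

AF distances compare predicted dot-bracket structures directly, without
positional homology: either a global edit distance on the bracket strings
(handles unequal lengths; the default) or the symmetric base-pair set
difference (equal lengths only). AB distances are substitution-model
distances (JC69, K80, or F84) on homologous MSA columns with pairwise
deletion of gapped/ambiguous sites.

The F84 distance follows the DNADIST convention: pairwise maximum
likelihood under the F84 model with empirical base frequencies and a
fixed transition/transversion ratio (expected-count ratio, default 2.0).
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from scipy.optimize import minimize_scalar

from .core import DistanceMatrix, Msa, SecondaryStructure

# ---------------------------------------------------------------------------
# AF: structure distances
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EditCosts:
    match: float = 0.0
    substitution: float = 1.0
    indel: float = 1.0

    @property
    def is_unit(self) -> bool:
        return self.match == 0.0 and self.substitution == 1.0 and self.indel == 1.0


UNIT_COSTS = EditCosts()


def _edit_dp(a: str, b: str, costs: EditCosts) -> float:
    la, lb = len(a), len(b)
    prev = np.arange(lb + 1, dtype=float) * costs.indel
    for i in range(1, la + 1):
        cur = np.empty(lb + 1)
        cur[0] = i * costs.indel
        ai = a[i - 1]
        for j in range(1, lb + 1):
            diag = prev[j - 1] + (costs.match if ai == b[j - 1] else costs.substitution)
            cur[j] = min(diag, prev[j] + costs.indel, cur[j - 1] + costs.indel)
        prev = cur
    return float(prev[lb])


def structure_edit_distance(
    a: SecondaryStructure, b: SecondaryStructure, costs: EditCosts = UNIT_COSTS
) -> float:
    """Global alignment distance between two dot-bracket strings.

    Unit costs (the default) make this the Levenshtein distance, computed
    with edlib; arbitrary costs fall back to an explicit dynamic program.
    Symmetric, zero iff the strings are equal (for positive costs).
    """
    for s in (a, b):
        if set(s.dotbracket) - set("()."):
            raise ValueError(f"invalid dot-bracket for {s.seq_id!r}")
    if costs.is_unit:
        return float(edlib.align(a.dotbracket, b.dotbracket, task="distance")["editDistance"])
    return _edit_dp(a.dotbracket, b.dotbracket, costs)


def base_pair_distance(a: SecondaryStructure, b: SecondaryStructure) -> int:
    """Size of the symmetric difference of the two base-pair sets."""
    if len(a) != len(b):
        raise ValueError(
            "base_pair_distance requires equal lengths "
            f"({len(a)} vs {len(b)}); use structure_edit_distance instead"
        )
    return len(a.pairs ^ b.pairs)


def af_matrix(
    structures: list[SecondaryStructure], metric: str = "edit",
    costs: EditCosts = UNIT_COSTS,
) -> DistanceMatrix:
    """All pairwise structure distances under the chosen metric."""
    labels = [s.seq_id for s in structures]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate structure ids")
    if len(structures) < 2:
        raise ValueError("need at least two structures")
    n = len(structures)
    values = np.zeros((n, n))
    fn = {
        "edit": lambda x, y: structure_edit_distance(x, y, costs),
        "bp": base_pair_distance,
    }[metric]
    for i in range(n):
        for j in range(i + 1, n):
            values[i, j] = values[j, i] = fn(structures[i], structures[j])
    return DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# AB: substitution-model distances
# ---------------------------------------------------------------------------

_NUC_INDEX = {"A": 0, "C": 1, "G": 2, "U": 3}
_PURINE = (0, 2)  # A, G
_TRANSITIONS = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->U


class SaturationError(ValueError):
    pass


def encode_row(residues: str) -> np.ndarray:
    """Integer-code an aligned row; gaps/ambiguities become -1."""
    return np.array([_NUC_INDEX.get(ch, -1) for ch in residues], dtype=np.int8)


def _comparable(x: np.ndarray, y: np.ndarray):
    mask = (x >= 0) & (y >= 0)
    if not mask.any():
        raise ValueError("zero comparable sites between rows")
    return x[mask], y[mask]


def _jc69(p: float, pair: str) -> float:
    arg = 1.0 - 4.0 * p / 3.0
    if arg <= 0:
        raise SaturationError(f"JC69 saturation (p={p:.4f}) for pair {pair}")
    return -0.75 * np.log(arg)


def _k80(P: float, Q: float, pair: str) -> float:
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0 or a2 <= 0:
        raise SaturationError(f"K80 saturation (P={P:.4f}, Q={Q:.4f}) for pair {pair}")
    return -0.5 * np.log(a1) - 0.25 * np.log(a2)


def f84_rate_components(freqs: np.ndarray, ts_tv_ratio: float):
    """Solve the F84 two-process rates from the expected ts/tv count ratio.

    F84 is a superposition of a 'general' replacement process (rate g,
    target drawn from the stationary frequencies) and a 'within-group'
    process (rate w, target drawn from the purine or pyrimidine group).
    Returns (g, w) scaled so the total substitution rate is 1.
    """
    pa, pc, pg, pu = freqs
    pr, py = pa + pg, pc + pu
    # expected transversions per unit g: 2 * pr * py
    tv = 2.0 * pr * py
    # expected transitions: 2 papg (g + w/pr) + 2 pcpu (g + w/py)
    ts_g = 2.0 * pa * pg + 2.0 * pc * pu
    ts_w = 2.0 * pa * pg / pr + 2.0 * pc * pu / py if pr > 0 and py > 0 else 0.0
    # ratio = (ts_g * g + ts_w * w) / (tv * g); set g = 1, solve for w
    if ts_w <= 0:
        raise ValueError("degenerate base frequencies for F84")
    w = (ts_tv_ratio * tv - ts_g) / ts_w
    if w < 0:
        raise ValueError(
            f"ts/tv ratio {ts_tv_ratio} is below the attainable minimum "
            f"{ts_g / tv:.4f} for these base frequencies"
        )
    g = 1.0
    # total substitution rate for scaling to expected subs/site
    mu = g * sum(
        freqs[i] * (1.0 - freqs[i]) for i in range(4)
    ) + w * (pa * (1 - pa / pr) + pg * (1 - pg / pr) + pc * (1 - pc / py) + pu * (1 - pu / py))
    return g / mu, w / mu


def f84_transition_probabilities(
    t: float, freqs: np.ndarray, g: float, w: float
) -> np.ndarray:
    """Closed-form F84 transition probability matrix P_ij(t)."""
    pa, pc, pg, pu = freqs
    pr, py = pa + pg, pc + pu
    group_freq = np.array([pr, py, pr, py])
    e1 = np.exp(-g * t)  # no general event
    e2 = np.exp(-(g + w) * t)  # no event at all
    P = np.empty((4, 4))
    for i in range(4):
        for j in range(4):
            same_group = group_freq[i] == group_freq[j] and (
                (i in _PURINE) == (j in _PURINE)
            )
            val = (1.0 - e1) * freqs[j]
            if (i in _PURINE) == (j in _PURINE):
                val += (e1 - e2) * freqs[j] / group_freq[j]
            if i == j:
                val += e2
            P[i, j] = val
    return P


def _f84_ml_distance(
    counts: np.ndarray, freqs: np.ndarray, ts_tv_ratio: float, pair: str
) -> float:
    """Maximise the pairwise F84 likelihood over the branch length."""
    g, w = f84_rate_components(freqs, ts_tv_ratio)
    n_diff = counts.sum() - np.trace(counts)
    if n_diff == 0:
        return 0.0

    def neg_loglik(t):
        P = f84_transition_probabilities(t, freqs, g, w)
        with np.errstate(divide="ignore"):
            lp = np.log(np.maximum(freqs[:, None] * P, 1e-300))
        return -(counts * lp).sum()

    res = minimize_scalar(
        neg_loglik, bounds=(1e-8, 50.0), method="bounded",
        options={"xatol": 1e-10},
    )
    if not res.success:
        raise SaturationError(f"F84 optimisation failed for pair {pair}")
    if res.x > 49.0:
        raise SaturationError(f"F84 saturation for pair {pair}")
    return float(res.x)


def pairwise_seq_distance(
    row_a: str,
    row_b: str,
    model: str = "f84",
    *,
    ts_tv_ratio: float = 2.0,
    freqs: np.ndarray | None = None,
    pair_label: str = "?",
) -> float:
    """Model distance between two aligned rows with pairwise deletion.

    Sites with a gap or ambiguity code in either row are excluded. For
    F84, ``freqs`` are the stationary base frequencies (usually empirical
    frequencies of the whole alignment); if omitted they are estimated
    from the two rows.
    """
    if len(row_a) != len(row_b):
        raise ValueError("aligned rows differ in length")
    x, y = _comparable(encode_row(row_a), encode_row(row_b))
    n = len(x)
    diff = x != y
    p = diff.mean()
    model = model.lower()
    if model == "jc69":
        return float(_jc69(p, pair_label))
    ts = np.fromiter(
        ((int(a), int(b)) in _TRANSITIONS for a, b in zip(x[diff], y[diff])),
        dtype=bool, count=int(diff.sum()),
    )
    P = ts.sum() / n
    Q = p - P
    if model == "k80":
        return float(_k80(P, Q, pair_label))
    if model == "f84":
        counts = np.zeros((4, 4))
        np.add.at(counts, (x, y), 1.0)
        counts = 0.5 * (counts + counts.T)  # symmetrise pair pattern counts
        if freqs is None:
            freqs = counts.sum(axis=0) + counts.sum(axis=1)
            freqs = freqs / freqs.sum()
        if np.any(freqs <= 0):
            raise ValueError("F84 requires all four bases present")
        return _f84_ml_distance(counts, np.asarray(freqs, float), ts_tv_ratio, pair_label)
    raise ValueError(f"unknown model {model!r}")


def empirical_frequencies(msa: Msa) -> np.ndarray:
    counts = np.zeros(4)
    for r in msa.rows:
        enc = encode_row(r.residues)
        for k in range(4):
            counts[k] += int((enc == k).sum())
    if np.any(counts == 0):
        # add-one smoothing keeps F84 defined on degenerate toy alignments
        counts += 1.0
    return counts / counts.sum()


def ab_matrix(
    msa: Msa,
    model: str = "f84",
    *,
    ts_tv_ratio: float = 2.0,
    cap: float | None = None,
) -> DistanceMatrix:
    """All pairwise model distances over an MSA.

    Saturated pairs raise a SaturationError listing the offenders, unless
    ``cap`` is given, in which case their distance is truncated at that
    value instead.
    """
    labels = msa.labels
    n = len(labels)
    values = np.zeros((n, n))
    freqs = empirical_frequencies(msa) if model.lower() == "f84" else None
    saturated: list[str] = []
    for i in range(n):
        for j in range(i + 1, n):
            pair = f"{labels[i]}/{labels[j]}"
            try:
                d = pairwise_seq_distance(
                    msa.rows[i].residues,
                    msa.rows[j].residues,
                    model,
                    ts_tv_ratio=ts_tv_ratio,
                    freqs=freqs,
                    pair_label=pair,
                )
            except SaturationError:
                if cap is None:
                    saturated.append(pair)
                    continue
                d = cap
            if cap is not None:
                d = min(d, cap)
            values[i, j] = values[j, i] = d
    if saturated:
        raise SaturationError(
            "saturated pairs (pass a cap to truncate): " + ", ".join(saturated)
        )
    return DistanceMatrix(labels, values)
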