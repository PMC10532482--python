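"""Synthetic ITS2-like families with known truth, for end-to-end testing.

The generator emulates what the pipeline needs from real ITS2 data: a
conserved multi-helix scaffold (stems designed GC-rich so the folding
objective recovers them), species-structured sequence variation, and
compensatory base changes planted between species and never within.
Within-species variation touches unpaired scaffold sites only, so
within-species CBC counts are exactly zero by construction; planted
CBCs replace a scaffold pair with a doubly-changed canonical pair on
one species' stem lineage. It does not emulate indel evolution or
thermodynamic energy landscapes.

Also provides the ultrametric-tree simulators (Yule species tree over
Kingman within-species coalescents) used to exercise the GMYC model
with planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .core import AnnotatedSequence, Msa, SecondaryStructure, render_dotbracket

BASES = np.array(list("ACGU"))
# full compensatory replacement: both sides change, pairing stays canonical
CBC_SWAP = {"GC": "UA", "CG": "AU", "AU": "CG", "UA": "GC", "GU": "UA", "UG": "AU"}
HEMI_SWAP = {"GC": "GU", "CG": "UG", "AU": "GU", "UA": "UG", "GU": "GC", "UG": "CG"}


# ---------------------------------------------------------------------------
# scaffold
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Helix:
    open_pos: int  # 5' index of the outermost pair
    close_pos: int  # 3' index of the outermost pair
    stem_len: int

    def pairs(self) -> list[tuple[int, int]]:
        return [(self.open_pos + k, self.close_pos - k) for k in range(self.stem_len)]


@dataclass(frozen=True)
class Scaffold:
    """Helix layout of an ITS2-like family."""

    length: int
    helices: tuple[Helix, ...]

    def pairs(self) -> list[tuple[int, int]]:
        return [p for h in self.helices for p in h.pairs()]

    def dotbracket(self) -> str:
        return render_dotbracket(self.length, self.pairs())

    def paired_positions(self) -> set[int]:
        return {i for p in self.pairs() for i in p}


def default_scaffold(
    n_helices: int = 5, length: int = 260, stem_len: int = 8, loop_len: int = 5
) -> Scaffold:
    """Evenly spaced helices separated by unpaired linkers."""
    block = 2 * stem_len + loop_len
    if n_helices * block > length:
        raise ValueError("scaffold too small for the requested helices")
    gap = (length - n_helices * block) // (n_helices + 1)
    helices = []
    pos = gap
    for _ in range(n_helices):
        helices.append(Helix(pos, pos + block - 1, stem_len))
        pos += block + gap
    return Scaffold(length, tuple(helices))


def _root_sequence(scaffold: Scaffold, rng: np.random.Generator) -> np.ndarray:
    """Design a root sequence: GC-rich stems, A/C loops and linkers.

    A and C cannot pair with each other, so unpaired regions stay
    unpaired under the folding objective while stems fold stably."""
    seq = rng.choice(np.array(list("AC")), size=scaffold.length, p=[0.65, 0.35])
    pair_types = np.array(["GC", "CG", "AU", "UA"])
    for i, j in scaffold.pairs():
        pt = rng.choice(pair_types, p=[0.45, 0.35, 0.1, 0.1])
        seq[i], seq[j] = pt[0], pt[1]
    return seq


def _substitute_unpaired(
    seq: np.ndarray, rate: float, unpaired: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """JC-style substitutions restricted to unpaired scaffold sites."""
    seq = seq.copy()
    hits = unpaired[rng.random(len(unpaired)) < rate]
    for pos in hits:
        alternatives = [b for b in "ACGU" if b != seq[pos]]
        seq[pos] = alternatives[rng.integers(0, 3)]
    return seq


def _substitute_pairs(
    seq: np.ndarray,
    rate: float,
    pairs: list[tuple[int, int]],
    rng: np.random.Generator,
    reserved: set[tuple[int, int]] = frozenset(),
) -> np.ndarray:
    """Stem evolution between species: canonical pairing is conserved,
    so a hit is either a compensatory double change (a CBC) or a
    single-side change to another canonical pair (a hemi-CBC), half
    each. Reserved positions (used for explicit planting) are skipped."""
    seq = seq.copy()
    for i, j in pairs:
        if (i, j) in reserved:
            continue
        r = rng.random()
        if r < rate:
            old = seq[i] + seq[j]
            new = CBC_SWAP[old] if r < rate / 2 else HEMI_SWAP[old]
            seq[i], seq[j] = new[0], new[1]
    return seq


# ---------------------------------------------------------------------------
# ultrametric tree simulators (used by the GMYC tests as planted truth)
# ---------------------------------------------------------------------------


def simulate_coalescent_tree(
    labels: list[str], rng: np.random.Generator, ne: float = 1.0
) -> tuple[dendropy.Tree, float]:
    """Single-population Kingman coalescent; returns (tree, root age)."""
    n = len(labels)
    if n < 2:
        raise ValueError("need at least two tips")
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for l in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(l))
        node.age_ = 0.0
        nodes.append(node)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 * ne / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        parent = dendropy.Node()
        parent.age_ = t
        for child in (nodes[i], nodes[j]):
            parent.add_child(child)
            child.edge.length = t - child.age_
        nodes = [nd for m, nd in enumerate(nodes) if m not in (i, j)] + [parent]
    tree.seed_node = nodes[0]
    tree.is_rooted = True
    return tree, t


def simulate_species_tree_ages(
    n_species: int, depth: float, rng: np.random.Generator, min_frac: float = 0.4
) -> list[float]:
    """Ascending species-tree join ages; the root is at ``depth``."""
    if n_species < 2:
        return []
    inner = sorted(rng.uniform(min_frac * depth, depth, size=n_species - 2))
    return inner + [depth]


def simulate_species_coalescent_tree(
    n_species: int,
    tips_per_species: int,
    rng: np.random.Generator,
    species_depth: float = 10.0,
    ne: float = 0.1,
) -> tuple[dendropy.Tree, list[list[str]]]:
    """Yule-like species tree over within-species Kingman subtrees.

    Species divergences fall in [0.4, 1] x ``species_depth``; within a
    species, lineages coalesce at scale ``ne``. Returns the glued
    ultrametric tree and the true partition of tip labels."""
    partition = []
    subtrees = []
    for s in range(n_species):
        labels = [f"sp{s+1}_t{k+1}" for k in range(tips_per_species)]
        partition.append(labels)
        if tips_per_species == 1:
            sub, h = None, 0.0
        else:
            sub, h = simulate_coalescent_tree(labels, rng, ne=ne)
        subtrees.append((labels, sub, h))

    all_labels = [l for labels, _, _ in subtrees for l in labels]
    taxa = dendropy.TaxonNamespace(all_labels)
    tree = dendropy.Tree(taxon_namespace=taxa)

    def clone_into(sub_labels, sub, h):
        if sub is None:
            node = dendropy.Node(taxon=taxa.get_taxon(sub_labels[0]))
            node.age_ = 0.0
            return node
        mapping = {}
        for nd in sub.postorder_node_iter():
            new = dendropy.Node(
                taxon=taxa.get_taxon(nd.taxon.label) if nd.is_leaf() else None
            )
            new.age_ = nd.age_
            for c in nd.child_nodes():
                new.add_child(mapping[c])
                mapping[c].edge.length = new.age_ - mapping[c].age_
            mapping[nd] = new
        return mapping[sub.seed_node]

    roots = [clone_into(labels, sub, h) for labels, sub, h in subtrees]
    ages = simulate_species_tree_ages(n_species, species_depth, rng)
    max_sub_age = max(r.age_ for r in roots)
    if ages and ages[0] <= max_sub_age:
        raise ValueError("species depth too shallow for the coalescent scale")
    while len(roots) > 1:
        age = ages.pop(0)
        i, j = sorted(rng.choice(len(roots), size=2, replace=False))
        parent = dendropy.Node()
        parent.age_ = age
        for child in (roots[i], roots[j]):
            parent.add_child(child)
            child.edge.length = age - child.age_
        roots = [r for m, r in enumerate(roots) if m not in (i, j)] + [parent]
    tree.seed_node = roots[0]
    tree.is_rooted = True
    return tree, partition


# ---------------------------------------------------------------------------
# sequence families
# ---------------------------------------------------------------------------


@dataclass
class SyntheticFamily:
    """A generated family with its full ground truth."""

    sequences: list[AnnotatedSequence]
    true_partition: list[list[str]]
    true_structures: list[SecondaryStructure]
    planted_cbcs: list[dict]
    params: dict = field(default_factory=dict)

    @property
    def species_of(self) -> dict[str, str]:
        out = {}
        for k, block in enumerate(self.true_partition):
            for label in block:
                out[label] = f"species{k+1}"
        return out

    def msa(self, include_outgroup: bool = True) -> Msa:
        rows = [
            s for s in self.sequences
            if include_outgroup or not s.is_outgroup
        ]
        return Msa(rows)

    def ingroup(self) -> list[AnnotatedSequence]:
        return [s for s in self.sequences if not s.is_outgroup]

    @property
    def outgroup_id(self) -> str | None:
        for s in self.sequences:
            if s.is_outgroup:
                return s.id
        return None


def _evolve_species_members(
    species_seq: np.ndarray,
    labels: list[str],
    unpaired: np.ndarray,
    within_div: float,
    rng: np.random.Generator,
) -> dict[str, np.ndarray]:
    """Within-species variation along a Kingman genealogy, unpaired
    sites only (paired columns are identical within a species)."""
    if len(labels) == 1:
        return {labels[0]: species_seq.copy()}
    tree, height = simulate_coalescent_tree(labels, rng, ne=1.0)
    out = {}

    def descend(node, seq):
        for child in node.child_nodes():
            frac = (child.edge.length or 0.0) / max(height, 1e-12)
            child_seq = _substitute_unpaired(seq, within_div * frac, unpaired, rng)
            if child.is_leaf():
                out[child.taxon.label] = child_seq
            else:
                descend(child, child_seq)

    descend(tree.seed_node, species_seq)
    return out


def generate_family(
    n_species: int = 5,
    seqs_per_species: int = 8,
    scaffold: Scaffold | None = None,
    within_div: float = 0.01,
    between_div: float = 0.10,
    n_planted_cbcs: int = 2,
    seed: int = 0,
    species_sizes: list[int] | None = None,
) -> SyntheticFamily:
    """Generate one ITS2-like family; deterministic per seed.

    Species stems diverge from a shared root sequence at unpaired sites
    (rate ``between_div`` per site) and carry ``n_planted_cbcs``
    compensatory double substitutions each, at species-unique scaffold
    pair positions, so every species pair is separated by at least
    2 * ``n_planted_cbcs`` CBCs while within-species CBCs are zero."""
    if not (0.0 <= within_div <= 0.2 and 0.0 <= between_div <= 0.2):
        raise ValueError("divergence rates must lie in [0, 0.2]")
    if n_species < 1 or seqs_per_species < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    if scaffold is None:
        scaffold = default_scaffold(5)
    sizes = species_sizes or [seqs_per_species] * n_species
    if len(sizes) != n_species:
        raise ValueError("species_sizes length must equal n_species")

    scaffold_pairs = scaffold.pairs()
    if n_species * n_planted_cbcs > len(scaffold_pairs):
        raise ValueError("scaffold too small for the requested planted CBCs")
    unpaired = np.array(
        sorted(set(range(scaffold.length)) - scaffold.paired_positions())
    )
    root = _root_sequence(scaffold, rng)
    db = scaffold.dotbracket()

    # species-unique pair positions for planting, kept clear of the
    # random stem evolution so planted counts are guaranteed minima
    order = rng.permutation(len(scaffold_pairs))
    reserved = {
        scaffold_pairs[k] for k in order[: n_species * n_planted_cbcs]
    }
    planted: list[dict] = []
    sequences: list[AnnotatedSequence] = []
    structures: list[SecondaryStructure] = []
    partition: list[list[str]] = []
    pair_cursor = 0
    for s in range(n_species):
        name = f"species{s+1}"
        stem = _substitute_unpaired(root, between_div, unpaired, rng)
        stem = _substitute_pairs(stem, between_div, scaffold_pairs, rng, reserved)
        for _ in range(n_planted_cbcs):
            i, j = scaffold_pairs[order[pair_cursor]]
            pair_cursor += 1
            old = stem[i] + stem[j]
            new = CBC_SWAP[old]
            stem[i], stem[j] = new[0], new[1]
            planted.append(
                {"species": name, "columns": (i, j), "from": old, "to": new}
            )
        labels = [f"{name}_{k+1:02d}" for k in range(sizes[s])]
        partition.append(labels)
        members = _evolve_species_members(stem, labels, unpaired, within_div, rng)
        for label in labels:
            seq_str = "".join(members[label])
            sequences.append(AnnotatedSequence(label, seq_str, species_hint=name))
            structures.append(SecondaryStructure.from_dotbracket(label, db))

    return SyntheticFamily(
        sequences=sequences,
        true_partition=partition,
        true_structures=structures,
        planted_cbcs=planted,
        params={
            "n_species": n_species,
            "species_sizes": sizes,
            "within_div": within_div,
            "between_div": between_div,
            "n_planted_cbcs": n_planted_cbcs,
            "seed": seed,
            "scaffold": {
                "length": scaffold.length,
                "helices": [
                    (h.open_pos, h.close_pos, h.stem_len) for h in scaffold.helices
                ],
            },
        },
    )


TULASNELLA_SEED = 42
CLADE_A_SIZES = [30, 24, 22]
CLADE_B_SIZES = [20, 18, 16, 12]


def _clade_scaffold(length: int, shared: list[Helix], extra: list[Helix]) -> Scaffold:
    return Scaffold(length, tuple(shared + extra))


def default_tulasnella_like(seed: int = TULASNELLA_SEED) -> SyntheticFamily:
    """The built-in study family: 142 ingroup sequences, 7 species in two
    clades with 4- vs 6-helix scaffolds, plus one outgroup.

    Clade B shares clade A's four helices and adds two more in regions
    that are unpaired linkers in clade A, so consensus structures type
    the clades as 4-domain vs 6-domain while CBCs planted in the shared
    helices separate every species pair, across clades included."""
    rng = np.random.default_rng(seed)
    length = 260
    stem_len, loop_len = 8, 5
    block = 2 * stem_len + loop_len  # 21
    # four shared helices and two clade-B-only helices interleaved
    starts_shared = [10, 60, 110, 160]
    starts_extra = [205, 232]
    shared = [Helix(p, p + block - 1, stem_len) for p in starts_shared]
    extra = [Helix(p, p + block - 1, stem_len) for p in starts_extra]
    scaffold_a = _clade_scaffold(length, shared, [])
    scaffold_b = _clade_scaffold(length, shared, extra)

    root = _root_sequence(scaffold_b, rng)  # stems designed for all six
    # clade A: melt the two extra helices into unpairable linker
    root_a = root.copy()
    for h in extra:
        for i, j in h.pairs():
            root_a[i] = "A" if rng.random() < 0.6 else "C"
            root_a[j] = "A" if rng.random() < 0.6 else "C"
    root_b = root

    shared_pairs = [p for h in shared for p in h.pairs()]
    order = rng.permutation(len(shared_pairs))
    reserved = {shared_pairs[k] for k in order[: 7 * 2]}

    # species-specific helix-length variation on two designated helices:
    # ITS2 helices vary in length between species, and this is what lets
    # the alignment-free table resolve more than the two clades. Each
    # species extends helices II and IV outward by its own (e2, e4)
    # base pairs; sequences within a species share the extension.
    extensions = [(0, 1), (2, 0), (1, 3), (3, 2), (0, 0), (2, 3), (1, 0)]
    var_helices = (shared[1], shared[3])
    pair_types = np.array(["GC", "CG", "UA", "AU"])
    clade_defs = [
        ("A", scaffold_a, root_a, CLADE_A_SIZES),
        ("B", scaffold_b, root_b, CLADE_B_SIZES),
    ]
    sequences, structures, partition, planted = [], [], [], []
    pair_cursor = 0
    sp_index = 0
    for clade_name, scaffold, clade_root, sizes in clade_defs:
        unpaired = np.array(
            sorted(set(range(length)) - scaffold.paired_positions())
        )
        clade_pairs = scaffold.pairs()
        clade_stem = _substitute_unpaired(clade_root, 0.15, unpaired, rng)
        clade_stem = _substitute_pairs(clade_stem, 0.15, clade_pairs, rng, reserved)
        db = scaffold.dotbracket()
        for size in sizes:
            sp_index += 1
            name = f"T{clade_name}{sp_index}"
            stem = _substitute_unpaired(clade_stem, 0.10, unpaired, rng)
            stem = _substitute_pairs(stem, 0.10, clade_pairs, rng, reserved)
            for _ in range(2):
                i, j = shared_pairs[order[pair_cursor]]
                pair_cursor += 1
                old = stem[i] + stem[j]
                new = CBC_SWAP[old]
                stem[i], stem[j] = new[0], new[1]
                planted.append(
                    {"species": name, "columns": (i, j), "from": old, "to": new}
                )
            # species-specific helix extensions
            extra_pairs: list[tuple[int, int]] = []
            for helix, ext in zip(var_helices, extensions[sp_index - 1]):
                for k in range(1, ext + 1):
                    i, j = helix.open_pos - k, helix.close_pos + k
                    pt = pair_types[rng.integers(0, 4)]
                    stem[i], stem[j] = pt[0], pt[1]
                    extra_pairs.append((i, j))
            sp_db = render_dotbracket(
                length, scaffold.pairs() + extra_pairs
            )
            sp_unpaired = np.array(
                sorted(set(unpaired) - {i for p in extra_pairs for i in p})
            )
            labels = [f"{name}_{k+1:02d}" for k in range(size)]
            partition.append(labels)
            members = _evolve_species_members(stem, labels, sp_unpaired, 0.01, rng)
            for label in labels:
                sequences.append(
                    AnnotatedSequence(label, "".join(members[label]),
                                      species_hint=name)
                )
                structures.append(SecondaryStructure.from_dotbracket(label, sp_db))

    # synthetic outgroup: heavily diverged from the root (still alignable,
    # like a distant fungal ITS2), no constraint to the scaffold pairing
    out_seq = root.copy()
    hit = rng.random(length) < 0.35
    for pos in np.nonzero(hit)[0]:
        alternatives = [b for b in "ACGU" if b != out_seq[pos]]
        out_seq[pos] = alternatives[rng.integers(0, 3)]
    sequences.append(
        AnnotatedSequence("OUTGROUP_1", "".join(out_seq), is_outgroup=True)
    )
    structures.append(
        SecondaryStructure.from_dotbracket("OUTGROUP_1", "." * length)
    )

    return SyntheticFamily(
        sequences=sequences,
        true_partition=partition,
        true_structures=structures,
        planted_cbcs=planted,
        params={"preset": "tulasnella-like", "seed": seed, "length": length},
    )
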