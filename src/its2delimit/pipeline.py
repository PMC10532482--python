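"""End-to-end orchestration: sequences -> AF/AB matrices -> compromise ->
trees -> GMYC delimitation -> CBC corroboration -> report.

Every stage is deterministic given the seed in the configuration. The
report is a plain serializable structure mirroring the result surfaces
of the method: the three matrices, the DISTATIS weights, three Newick
trees, one GMYC result per tree, the CBC table, and a consensus
structure with domain typing per delimited cluster.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .cbc import (
    cbc_matrix,
    consensus_structure,
    delimit_by_cbc,
    project_structures,
)
from .core import AnnotatedSequence, DistanceMatrix, Msa, SecondaryStructure
from .distances import ab_matrix, af_matrix
from .distatis import compute_compromise
from .folding import FoldParams, fold_mfe
from .gmyc import GmycResult, gmyc_multiple, gmyc_single
from .seqio import (
    read_alignment,
    read_fasta,
    read_vienna,
    write_phylip_matrix,
    write_vienna,
)
from .trees import (
    bootstrap_support,
    make_ultrametric,
    neighbor_joining,
    prune_taxa,
    to_newick,
)


@dataclass
class PipelineConfig:
    """Everything one run needs. Paths may be replaced by in-memory
    objects (a list of AnnotatedSequence, an Msa, structures)."""

    sequences: object = None  # path or list[AnnotatedSequence]
    alignment: object = None  # path or Msa
    structures: object = None  # path, list[SecondaryStructure], or None->fold
    outgroup: str | None = None
    # folding
    min_loop: int = 3
    # AB
    ab_model: str = "f84"
    ts_tv_ratio: float = 2.0
    saturation_cap: float | None = None
    # AF
    af_metric: str = "edit"
    # distatis; raw (Gower) centering by default: squaring lets the
    # deepest, highest-variance distances dominate the compromise rows
    square_first: bool = False
    n_factors_kept: int = 2
    # compromise tree
    minkowski_p: float = 2.0
    n_boot: int = 1000
    seed: int = 42
    # gmyc; the delimitation table counts groups with more than two
    # sequences, hence the reporting threshold of 3
    gmyc_mode: str = "multiple"
    df: int = 3
    min_cluster_size: int = 3
    ultrametric_interval: tuple[float, float] = (0.0, 10.0)
    # cbc
    cbc_scope: str = "intersection"
    consensus_threshold: float = 0.5
    # output
    outdir: str | None = None

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(PipelineConfig)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "ultrametric_interval" in raw:
            raw["ultrametric_interval"] = tuple(raw["ultrametric_interval"])
        return PipelineConfig(**raw)


@dataclass
class PipelineReport:
    """Machine-readable outcome of one pipeline run."""

    labels: list[str]
    ab: DistanceMatrix
    af: DistanceMatrix
    compromise: DistanceMatrix
    alpha: dict[str, float]
    rv: float
    newick: dict[str, str]
    gmyc: dict[str, GmycResult]
    bootstrap_min: float
    bootstrap_max: float
    cbc: dict
    consensus: list[dict]
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "labels": self.labels,
            "alpha": self.alpha,
            "rv_ab_af": self.rv,
            "matrices": {
                "ab": self.ab.values.tolist(),
                "af": self.af.values.tolist(),
                "compromise": self.compromise.values.tolist(),
            },
            "trees": self.newick,
            "gmyc": {k: v.to_dict() for k, v in self.gmyc.items()},
            "bootstrap": {"min": self.bootstrap_min, "max": self.bootstrap_max},
            "cbc": self.cbc,
            "consensus": self.consensus,
            "metadata": self.metadata,
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _load_sequences(cfg: PipelineConfig) -> list[AnnotatedSequence]:
    if cfg.sequences is None:
        raise ValueError("pipeline config has no sequences")
    if isinstance(cfg.sequences, (str, Path)):
        return read_fasta(cfg.sequences, outgroup_id=cfg.outgroup)
    return list(cfg.sequences)


def _load_alignment(cfg: PipelineConfig) -> Msa:
    if cfg.alignment is None:
        raise ValueError("pipeline config has no alignment")
    if isinstance(cfg.alignment, (str, Path)):
        return read_alignment(cfg.alignment)
    return cfg.alignment


def _load_structures(
    cfg: PipelineConfig, seqs: list[AnnotatedSequence]
) -> list[SecondaryStructure]:
    if cfg.structures is None:
        params = FoldParams(min_loop=cfg.min_loop)
        return [fold_mfe(s, params) for s in seqs]
    if isinstance(cfg.structures, (str, Path)):
        return read_vienna(cfg.structures)
    return list(cfg.structures)


def _log(stage: str, **info) -> None:
    parts = " ".join(f"{k}={v}" for k, v in info.items())
    print(f"[its2delimit] stage={stage} {parts}")


def run_pipeline(cfg: PipelineConfig) -> PipelineReport:
    t0 = time.time()
    seqs = _load_sequences(cfg)
    msa = _load_alignment(cfg)
    if set(msa.labels) != {s.id for s in seqs}:
        raise ValueError("alignment and sequence labels differ")
    _log("load", n_sequences=len(seqs), n_columns=msa.n_columns)

    structures = _load_structures(cfg, seqs)
    _log("fold", n_structures=len(structures))

    af = af_matrix(structures, metric=cfg.af_metric)
    _log("af_matrix", n=len(af), mean=f"{af.values.mean():.4f}")
    ab = ab_matrix(
        msa, cfg.ab_model, ts_tv_ratio=cfg.ts_tv_ratio, cap=cfg.saturation_cap
    )
    _log("ab_matrix", n=len(ab), mean=f"{ab.values.mean():.4f}")

    comp = compute_compromise(
        [ab, af],
        table_names=["AB", "AF"],
        square_first=cfg.square_first,
        n_factors_kept=cfg.n_factors_kept,
    )
    _log(
        "distatis",
        alpha_ab=f"{comp.alpha[0]:.4f}",
        alpha_af=f"{comp.alpha[1]:.4f}",
        rv=f"{comp.rv_matrix[0, 1]:.4f}",
    )

    ab_tree = neighbor_joining(ab)
    af_tree = neighbor_joining(af)
    # The compromise dendrogram is rooted by construction, so the
    # outgroup is not needed there; its large, high-variance distances
    # would otherwise dominate every taxon's distance profile and mask
    # the fine within/between-species contrast.
    comp_d = comp.compromise_distance
    if cfg.outgroup is not None:
        ingroup = [l for l in comp_d.labels if l != cfg.outgroup]
        comp_d = comp_d.reorder(ingroup)
    comp_tree = bootstrap_support(
        comp_d.values,
        comp_d.labels,
        n_boot=cfg.n_boot,
        seed=cfg.seed,
        minkowski_p=cfg.minkowski_p,
    )
    supports = [
        n.support for n in comp_tree.preorder_node_iter()
        if getattr(n, "support", None) is not None
    ]
    _log("trees", nboot=cfg.n_boot, support_min=min(supports),
         support_max=max(supports))

    interval = cfg.ultrametric_interval
    ultra = {
        "ab_nj": make_ultrametric(ab_tree, interval, outgroup=cfg.outgroup),
        "af_nj": make_ultrametric(af_tree, interval, outgroup=cfg.outgroup),
        "compromise": make_ultrametric(comp_tree, interval),
    }
    newick = {
        "ab_nj": to_newick(ab_tree),
        "af_nj": to_newick(af_tree),
        "compromise": to_newick(comp_tree),
    }

    gmyc_fn = gmyc_multiple if cfg.gmyc_mode == "multiple" else gmyc_single
    gmyc_results: dict[str, GmycResult] = {}
    for name, tree in ultra.items():
        t = tree
        if cfg.outgroup is not None:
            t = prune_taxa(tree, [cfg.outgroup])
        t.resolve_polytomies()
        res = gmyc_fn(
            t, df=cfg.df, min_cluster_size=cfg.min_cluster_size
        )
        gmyc_results[name] = res
        _log(
            "gmyc", tree=name, mode=cfg.gmyc_mode,
            clusters=res.n_ml_clusters, p=f"{res.p_value:.4g}",
        )

    # CBC analysis on the ingroup
    ingroup_ids = [s.id for s in seqs if not s.is_outgroup]
    msa_in = Msa([msa.row(i) for i in ingroup_ids])
    structs_in = [s for s in structures if s.seq_id in set(ingroup_ids)]
    sa = project_structures(msa_in, structs_in)
    table = cbc_matrix(sa, pair_scope=cfg.cbc_scope)
    cbc_report = delimit_by_cbc(table)
    cbc_report["cbc_counts"] = table.cbc_counts.tolist()
    cbc_report["hcbc_counts"] = table.hcbc_counts.tolist()
    _log("cbc", n_groups=len(table.partition),
         total_cbc_pairs=int((table.cbc_counts > 0).sum() // 2))

    # consensus structure per delimited cluster on the compromise tree
    consensus_out = []
    comp_clusters = gmyc_results["compromise"].clusters
    row_index = {l: k for k, l in enumerate(msa_in.labels)}
    for cluster in comp_clusters:
        members = [l for l in cluster if l in row_index]
        if len(members) < cfg.min_cluster_size:
            continue
        sub_msa = Msa([msa_in.row(l) for l in members])
        sub_structs = [structs_in[row_index[l]] for l in members]
        sub_sa = project_structures(sub_msa, sub_structs)
        cons = consensus_structure(sub_sa, threshold=cfg.consensus_threshold)
        consensus_out.append(
            {
                "members": sorted(members),
                "dotbracket": cons.dotbracket,
                "n_domains": cons.n_domains,
                "n_subdomains": cons.n_subdomains,
                "type_label": cons.type_label,
            }
        )
    _log("consensus", n_groups=len(consensus_out))

    report = PipelineReport(
        labels=list(msa.labels),
        ab=ab,
        af=af,
        compromise=comp.compromise_distance,
        alpha={"AB": float(comp.alpha[0]), "AF": float(comp.alpha[1])},
        rv=float(comp.rv_matrix[0, 1]),
        newick=newick,
        gmyc=gmyc_results,
        bootstrap_min=float(min(supports)),
        bootstrap_max=float(max(supports)),
        cbc=cbc_report,
        consensus=consensus_out,
        metadata={
            "version": __version__,
            "seed": cfg.seed,
            "elapsed_s": round(time.time() - t0, 2),
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        },
    )
    if cfg.outdir is not None:
        _write_outputs(report, seqs, structures, cfg)
    return report


def _write_outputs(report, seqs, structures, cfg) -> None:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_phylip_matrix(report.ab, outdir / "ab.phylip")
    write_phylip_matrix(report.af, outdir / "af.phylip")
    write_phylip_matrix(report.compromise, outdir / "compromise.phylip")
    by_id = {s.id: s for s in seqs}
    write_vienna(
        [(by_id[st.seq_id], st) for st in structures], outdir / "structures.vienna"
    )
    for name, nwk in report.newick.items():
        (outdir / f"{name}.nwk").write_text(nwk + "\n")
    (outdir / "report.json").write_text(report.to_json(indent=2))
    rows = compare_trees(report)
    with open(outdir / "gmyc_summary.tsv", "w") as fh:
        fh.write("tree\tlr_p_value\tn_ml_clusters\n")
        for r in rows:
            fh.write(f"{r['tree']}\t{r['lr_p_value']:.6g}\t{r['n_ml_clusters']}\n")


def compare_trees(report: PipelineReport) -> list[dict]:
    """One row per tree: the LR p-value and ML cluster count surface."""
    rows = []
    for name in ("ab_nj", "af_nj", "compromise"):
        if name not in report.gmyc:
            continue
        res = report.gmyc[name]
        rows.append(
            {
                "tree": name,
                "lr_p_value": res.p_value,
                "n_ml_clusters": res.n_ml_clusters,
            }
        )
    return rows
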