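"""Run the full delimitation workflow on the built-in study family.

The family emulates the shape of a difficult fungal ITS2 data set: 142
sequences from 7 species in two clades (each clade with its own helix
scaffold), plus one outgroup. The pipeline folds or accepts structures,
builds the AB/AF/compromise matrices, three trees, runs GMYC on each,
and corroborates the partition with CBC counts.
"""

from its2delimit import PipelineConfig, compare_trees, run_pipeline
from its2delimit.synthetic import default_tulasnella_like

family = default_tulasnella_like()
config = PipelineConfig(
    sequences=family.sequences,
    alignment=family.msa(),
    structures=family.true_structures,  # or None to fold internally
    outgroup=family.outgroup_id,
    seed=42,
    n_boot=200,
)
report = run_pipeline(config)

print()
print(f"{'tree':<12} {'LR p-value':>12} {'ML clusters':>12}")
for row in compare_trees(report):
    print(f"{row['tree']:<12} {row['lr_p_value']:>12.3g} "
          f"{row['n_ml_clusters']:>12}")
print()
print(f"true species: {len(family.true_partition)}")
print(f"CBC-zero groups (ingroup): {len(report.cbc['partition'])}")
print(f"bootstrap support range: {report.bootstrap_min:.0f}% .. "
      f"{report.bootstrap_max:.0f}%")
print()
print("A significant LR p-value (< 0.05) means the mixed speciation/")
print("coalescent model beats a single-process explanation of the tree.")
print("The compromise tree should recover the 7 planted species; the")
print("structure-only (AF) tree resolves fewer groups on its own.")
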