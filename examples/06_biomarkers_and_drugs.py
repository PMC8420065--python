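"""Biomarker evaluation, over-representation and drug-target mapping.

The prognostic module's diagnostic value is scored on an independent
tumor/normal validation matrix (ROC AUC of the mean member-gene z-score,
plus per-gene AUCs and rank-sum statistics), its mRNAs are tested for
over-representation in synthetic gene sets, and down-regulating
drug-lncRNA associations are restricted to the hypo-network lncRNAs.
"""

from emtrn import StudyConfig, gene_set_ora, simulate_study
from emtrn.downstream import build_drug_network, expression_group_stats, module_auc_report
from emtrn.pipeline import run_in_memory

cfg = StudyConfig(seed=1)
study = simulate_study(cfg, seed=1)
res = run_in_memory(study, cfg)

module = study.ground_truth["modules"][0]
genes = module["lncrnas"] + module["mrnas"]
auc, per_gene = module_auc_report(study.validation_expr, study.validation_labels, genes)
print(f"module-level validation AUC: {auc:.4f}")
print(f"per-gene AUCs: min {per_gene['auc'].min():.3f}, "
      f"median {per_gene['auc'].median():.3f}")

stats = expression_group_stats(study.validation_expr, study.validation_labels, genes)
n_up = (stats["direction"] == "up_in_tumor").sum()
print(f"{n_up}/{len(genes)} module genes are up in tumor on the validation matrix")

# over-representation of the module mRNAs against synthetic gene sets
universe = set(study.genes["gene_id"])
collection = {
    "module_mrnas_plus_noise": set(module["mrnas"]) | set(list(universe)[:10]),
    "random_background": set(list(universe)[50:90]),
}
ora = gene_set_ora(set(module["mrnas"]), collection, universe, p_cut=0.01)
for _, row in ora.iterrows():
    print(f"gene set {row['set_name']}: overlap {row['overlap']}, "
          f"p = {row['p']:.2e} {'(significant)' if row['significant'] else ''}")

edges, _g = build_drug_network(study.drugs, res.networks["hypo"])
hits = {tuple(h) for h in study.ground_truth["drug_hits"]}
got = set(zip(edges["drug"], edges["lncrna"]))
print(f"drug network: {len(edges)} down-regulating drug->lncRNA edges; "
      f"planted hits recovered {len(got & hits)}/{len(hits)}")
# Each retained drug is one that suppresses a lncRNA which the study says is
# activated by enhancer hypomethylation - the drug-repurposing hypothesis.
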