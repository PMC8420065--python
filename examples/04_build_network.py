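"""Assemble the enhancer-methylation-mediated regulatory network (EMTRN).

lncRNA-mRNA pairs sharing >= 2 miRNAs (hypergeometric FDR <= 0.05) are
intersected with the DMER-linked gene sets, screened for co-expression
(PCC > 0.5, p <= 0.05), and split into hyper-/hypomethylation subnetworks
by the direction of each gene's associated DMERs.
"""

from emtrn import StudyConfig, simulate_study
from emtrn.cerna import network_node_table
from emtrn.pipeline import run_in_memory

cfg = StudyConfig(seed=1)
study = simulate_study(cfg, seed=1)
res = run_in_memory(study, cfg)

print(f"ceRNA pairs after hypergeometric FDR + DMER intersection: {len(res.cerna_pairs)}")
print(f"EMTRN edges after co-expression screen (PCC > 0.5):       {len(res.emtrn_edges)}")
for key in ("full", "hyper", "hypo"):
    g = res.networks[key]
    print(f"  {key:5s} network: {g.number_of_nodes():3d} nodes, "
          f"{g.number_of_edges():3d} edges")

nodes = network_node_table(res.networks["hypo"])
hubs = nodes.loc[nodes["hub"]]
print(f"hub nodes (top 15% of degree in the hypo network): "
      f"{', '.join(hubs['node'])}")

planted = {
    (l, m)
    for mod in study.ground_truth["modules"]
    for l in mod["lncrnas"]
    for m in mod["mrnas"]
}
got = set(zip(res.emtrn_edges["lncrna"], res.emtrn_edges["mrna"]))
print(f"planted module edges surviving all screens: {len(got & planted)}/{len(planted)}")
# The hypo network is the substrate for module mining: a biclique there is a
# set of lncRNAs and mRNAs that are pairwise co-expressed, share miRNAs and
# are all tied to hypomethylated enhancers.
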