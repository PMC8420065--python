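"""Generate the default synthetic study and inspect its planted truth.

The generator emulates an HM450K tumor/normal methylome study with matched
tumor expression, miRNA interaction tables, survival follow-up and a drug
association table, and writes down exactly what it planted.
"""

from emtrn import StudyConfig, simulate_study, write_study

cfg = StudyConfig(seed=1)
study = simulate_study(cfg, seed=1)

print(f"beta matrix:        {study.beta.values.shape[0]} probes x "
      f"{study.beta.values.shape[1]} samples "
      f"({(study.beta.groups == 'tumor').sum()} tumor / "
      f"{(study.beta.groups == 'normal').sum()} normal)")
print(f"missing beta cells: {study.beta.values.isna().to_numpy().mean():.1%}")
print(f"expression:         {len(study.lnc_expr)} lncRNAs + {len(study.mrna_expr)} "
      f"mRNAs x {study.lnc_expr.shape[1]} tumor samples")
print(f"interactions:       {len(study.lnc_mirna)} lncRNA-miRNA, "
      f"{len(study.mirna_mrna)} miRNA-mRNA edges")

gt = study.ground_truth
print(f"\nplanted truth: {len(gt['hypo_region_ids'])} hypomethylated and "
      f"{len(gt['hyper_region_ids'])} hypermethylated enhancer regions "
      f"(beta shift {gt['delta_methylation']}),")
print(f"  {len(gt['planted_links'])} region->gene links, "
      f"{len(gt['modules'])} co-expression bicliques, prognostic module "
      f"{gt['prognostic_module']} (hazard coefficient {gt['hazard_coef']}),")
print(f"  {len(gt['drug_hits'])} drug hits on module lncRNAs.")

write_study(study, "scratch/example_study")
print("\nstudy files + ground_truth.json written to scratch/example_study/")
# Every downstream stage reads these files; the ids above are what the
# pipeline is expected to rediscover without seeing the ground truth.
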