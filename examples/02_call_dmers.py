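"""Probe QC, imputation, enhancer-region construction and DMER calling.

Probes missing in more than 30% of samples are dropped, the rest are
k-nearest-neighbour imputed, +/-500 bp windows around enhancer CpGs are
merged into regions, and region-level beta values are tested tumor vs
normal with an empirical-Bayes moderated t (BH-corrected).
"""

from emtrn import (
    StudyConfig,
    build_enhancer_regions,
    call_dmers,
    filter_probes_by_missingness,
    fit_group_difference,
    knn_impute,
    simulate_study,
    summarize_region_methylation,
)

cfg = StudyConfig(seed=1)
study = simulate_study(cfg, seed=1)

filtered, removed = filter_probes_by_missingness(study.beta, cfg.max_missing_fraction)
print(f"missingness filter: {len(removed)} of {len(study.beta.values)} probes removed")

complete = knn_impute(filtered, cfg.knn_k)
manifest = study.manifest.loc[study.manifest["probe_id"].isin(complete.values.index)]
regions = build_enhancer_regions(manifest, cfg.window_half_width)
lengths = [r.end - r.start for r in regions]
frac_1kb = sum(1 for L in lengths if L == 1000) / len(regions)
print(f"enhancer regions:   {len(regions)} merged regions, "
      f"{frac_1kb:.1%} exactly 1000 bp (single-probe class)")

region_meth = summarize_region_methylation(complete, regions)
dmers = call_dmers(fit_group_difference(region_meth), cfg.dmer_lfc, cfg.dmer_adj_p)
counts = dmers["direction"].value_counts()
print(f"DMERs:              {counts.get('hypo', 0)} hypo- and "
      f"{counts.get('hyper', 0)} hypermethylated of {len(dmers)} regions tested")

truth = set(study.ground_truth["hypo_region_ids"]) | set(
    study.ground_truth["decoy_region_ids"]
)
called = set(dmers.index[dmers["direction"] == "hypo"])
print(f"planted hypo recovery: {len(called & truth)}/{len(truth)} recalled, "
      f"{len(called & truth)}/{len(called)} of calls are planted")
# A hypomethylated DMER is a candidate activated enhancer; the next stage
# links each one to genes within 1 Mbp whose expression it anticorrelates with.
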