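"""Synthetic in-silico study generator with planted, machine-readable truth.

The generator emulates the shapes of an HM450K tumor/normal methylome study
with matched tumor expression: beta values are drawn on the logit scale and
inverse-logit mapped (bimodal, in-range); planted differential enhancer
probes receive a raw-scale group mean shift of +/-delta clipped to
[0.01, 0.99]; planted target genes' log expression is linearly coupled to
their region's per-sample beta; planted biclique modules share a per-module
latent factor (giving pairwise co-expression of about 0.7 at the default
loading) and a disjoint block of shared miRNAs on an Erdos-Renyi background;
survival times are exponential with hazard proportional to
exp(coef * module factor) under independent exponential censoring.

Every external data dependency of the protocol is thereby replaced by a
generator whose planted truth (region ids, links, module memberships,
prognostic module, drug hits) is exported alongside the data, so recovery
can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationParams, StudyConfig
from .errors import IntegrityError, ParameterError
from .methylome import (
    MethylationMatrix,
    build_enhancer_regions,
    filter_probes_by_missingness,
)


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# stand-alone stochastic primitives
# ---------------------------------------------------------------------------

def simulate_survival_times(
    linear_predictor: pd.Series,
    baseline_hazard: float,
    censor_rate: float,
    seed,
) -> pd.DataFrame:
    """Exponential survival with proportional hazards and independent censoring.

    Event time ~ Exp(baseline_hazard * exp(linear_predictor)); censoring time
    ~ Exp(censor_rate) (censor_rate = 0 disables censoring); the observed
    time is the minimum with the event flag set accordingly.
    """
    if baseline_hazard <= 0:
        raise ParameterError(f"baseline_hazard must be > 0, got {baseline_hazard}")
    if censor_rate < 0:
        raise ParameterError(f"censor_rate must be >= 0, got {censor_rate}")
    rng = _as_rng(seed)
    lp = np.asarray(linear_predictor, dtype=float)
    rates = baseline_hazard * np.exp(lp)
    event_t = rng.exponential(1.0 / rates)
    if censor_rate > 0:
        censor_t = rng.exponential(1.0 / censor_rate, size=lp.size)
    else:
        censor_t = np.full(lp.size, np.inf)
    time = np.minimum(event_t, censor_t)
    event = event_t <= censor_t
    index = (
        linear_predictor.index
        if isinstance(linear_predictor, pd.Series)
        else pd.RangeIndex(lp.size)
    )
    return pd.DataFrame(
        {"sample_id": index, "time": np.maximum(time, 1e-12), "event": event}
    ).reset_index(drop=True)


def inject_missingness(values: pd.DataFrame, fraction: float, seed) -> pd.DataFrame:
    """Mask exactly floor(fraction * n_cells) cells uniformly at random."""
    if not 0.0 <= fraction < 1.0:
        raise ParameterError(f"fraction must be in [0, 1), got {fraction}")
    rng = _as_rng(seed)
    out = values.to_numpy(dtype=float, copy=True)
    n_mask = int(np.floor(fraction * out.size))
    if n_mask:
        flat = rng.choice(out.size, size=n_mask, replace=False)
        out.flat[flat] = np.nan
    return pd.DataFrame(out, index=values.index, columns=values.columns)


# ---------------------------------------------------------------------------
# the full study
# ---------------------------------------------------------------------------

@dataclass
class SyntheticStudy:
    manifest: pd.DataFrame          # probe_id, chrom, pos (0-based), is_enhancer
    genes: pd.DataFrame             # gene_id, gene_type, chrom, strand, tss (0-based)
    beta: MethylationMatrix         # probes x (tumor + normal), NaN = missing
    lnc_expr: pd.DataFrame          # lncRNA x tumor samples, FPKM-like
    mrna_expr: pd.DataFrame         # mRNA x tumor samples, FPKM-like
    validation_expr: pd.DataFrame   # all genes x validation samples
    validation_labels: pd.Series
    lnc_mirna: pd.DataFrame         # columns lncrna, mirna
    mirna_mrna: pd.DataFrame        # columns mirna, mrna
    survival: pd.DataFrame          # sample_id, time, event (tumor samples)
    drugs: pd.DataFrame             # drug, lncrna, direction
    ground_truth: dict

    def check_ground_truth_ids(self) -> None:
        """Every planted id must exist in the corresponding generated table."""
        gt = self.ground_truth
        gene_ids = set(self.genes["gene_id"])
        for link in gt["planted_links"] + gt["decoy_links"]:
            if link["gene_id"] not in gene_ids:
                raise IntegrityError(f"planted gene {link['gene_id']} not generated")
        for mod in gt["modules"]:
            for gid in mod["lncrnas"] + mod["mrnas"]:
                if gid not in gene_ids:
                    raise IntegrityError(f"module gene {gid} not generated")
        for g in gt["promoter_regulated_genes"]:
            if g not in gene_ids:
                raise IntegrityError(f"promoter-regulated gene {g} not generated")
        drugs = set(self.drugs["drug"])
        for drug, lnc in gt["drug_hits"]:
            if drug not in drugs or lnc not in gene_ids:
                raise IntegrityError(f"drug hit ({drug}, {lnc}) not generated")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_study(config: StudyConfig, seed: int) -> SyntheticStudy:
    """Generate a complete synthetic study; deterministic given ``seed``."""
    p: SimulationParams = config.sim
    p.validate()
    rng = np.random.default_rng(seed)

    chroms = [f"chr{i + 1}" for i in range(p.n_chrom)]
    tumor_ids = [f"T{i + 1:03d}" for i in range(p.n_tumor)]
    normal_ids = [f"N{i + 1:03d}" for i in range(p.n_normal)]
    samples = tumor_ids + normal_ids
    groups = pd.Series(
        ["tumor"] * p.n_tumor + ["normal"] * p.n_normal, index=samples, name="group"
    )

    # ---- gene models ----------------------------------------------------
    n_genes = p.n_lncrna + p.n_mrna
    lnc_ids = [f"LNC_{i + 1:04d}" for i in range(p.n_lncrna)]
    mrna_ids = [f"MRNA_{i + 1:04d}" for i in range(p.n_mrna)]
    gene_rows = []
    li = mi = 0
    for g in range(n_genes):
        # every third gene is a lncRNA so both types sit on every chromosome
        if g % 3 == 0 and li < p.n_lncrna:
            gid, gtype = lnc_ids[li], "lncRNA"
            li += 1
        else:
            gid, gtype = mrna_ids[mi], "mRNA"
            mi += 1
        chrom = chroms[g % p.n_chrom]
        slot = g // p.n_chrom
        tss = 15_000 + slot * p.gene_spacing + int(rng.integers(-2000, 2001))
        strand = "+" if rng.random() < 0.5 else "-"
        gene_rows.append((gid, gtype, chrom, strand, tss))
    genes = pd.DataFrame(gene_rows, columns=["gene_id", "gene_type", "chrom", "strand", "tss"])
    gene_pos = genes.set_index("gene_id")

    # ---- planted entities ----------------------------------------------
    module_lncs: list[list[str]] = []
    module_mrnas: list[list[str]] = []
    lnc_pool = list(rng.permutation(lnc_ids))
    mrna_pool = list(rng.permutation(mrna_ids))
    for n_l, n_m in p.module_shapes:
        module_lncs.append(sorted(lnc_pool[:n_l]))
        del lnc_pool[:n_l]
        module_mrnas.append(sorted(mrna_pool[:n_m]))
        del mrna_pool[:n_m]
    extra_lnc = lnc_pool[: p.n_extra_links // 2]
    extra_mrna = mrna_pool[: p.n_extra_links - p.n_extra_links // 2]
    planted_link_genes = (
        [g for mod in module_lncs for g in mod]
        + [g for mod in module_mrnas for g in mod]
        + extra_lnc
        + extra_mrna
    )
    decoy_genes = mrna_pool[p.n_extra_links : p.n_extra_links + p.n_decoy_links]
    taken = set(planted_link_genes) | set(decoy_genes)
    dpmg_pool = [g for g in lnc_pool + mrna_pool if g not in taken]
    promoter_regulated = sorted(dpmg_pool[: p.n_promoter_regulated])

    # ---- enhancer probe layout -----------------------------------------
    n_slots = p.enhancer_probes_per_chrom
    slot_taken: dict[tuple[str, int], str] = {}

    def claim_slot_near(chrom: str, target_pos: int, owner: str) -> int:
        slot = int(round((target_pos - 1000) / p.probe_spacing))
        slot = min(max(slot, 0), n_slots - 1)
        for offset in range(n_slots):
            for cand in (slot - offset, slot + offset):
                if 0 <= cand < n_slots and (chrom, cand) not in slot_taken:
                    slot_taken[(chrom, cand)] = owner
                    return cand
        raise ParameterError("no free enhancer probe slot left")

    planted_probe_of: dict[str, str] = {}     # gene -> probe id (hypo, coupled)
    probe_kind: dict[str, str] = {}
    hyper_positions: dict[str, tuple[str, int]] = {}
    for gid in planted_link_genes + decoy_genes:
        tss = int(gene_pos.loc[gid, "tss"])
        chrom = gene_pos.loc[gid, "chrom"]
        offset = int(rng.integers(-200_000, 200_001))
        slot = claim_slot_near(chrom, tss + offset, gid)
        pid = f"{chrom}_e{slot:04d}"
        planted_probe_of[gid] = pid
        probe_kind[pid] = "hypo"
    # planted hyper regions live in a reserved segment > 1 Mbp past the gene
    # territory so no planted gene can acquire a discordant (mixed) direction
    hyper_probes = []
    for h in range(p.n_planted_hyper):
        chrom = chroms[h % p.n_chrom]
        tail = int(genes.loc[genes["chrom"] == chrom, "tss"].max())
        pos = tail + 1_010_000 + (h // p.n_chrom) * 3 * p.probe_spacing
        pid = f"{chrom}_h{h:02d}"
        hyper_probes.append(pid)
        probe_kind[pid] = "hyper"
        hyper_positions[pid] = (chrom, pos)

    probe_rows = []
    for chrom in chroms:
        for slot in range(n_slots):
            pid = f"{chrom}_e{slot:04d}"
            base = 1000 + slot * p.probe_spacing
            if pid in probe_kind:      # planted probes stay isolated: no jitter
                pos = base
            else:
                pos = base + int(rng.integers(-p.probe_jitter, p.probe_jitter + 1))
            probe_rows.append((pid, chrom, max(pos, config.window_half_width), True))
    for pid, (chrom, pos) in hyper_positions.items():
        probe_rows.append((pid, chrom, pos, True))
    # promoter probes, strand-aware, inside [TSS-2kb, TSS) / [TSS, TSS+2kb)
    for gid, row in gene_pos.iterrows():
        for j in range(p.promoter_probes_per_gene):
            off = 500 + 1000 * j
            pos = row["tss"] - off if row["strand"] == "+" else row["tss"] + off
            probe_rows.append((f"{gid}_pr{j}", row["chrom"], int(pos), False))
    manifest = pd.DataFrame(probe_rows, columns=["probe_id", "chrom", "pos", "is_enhancer"])

    # ---- methylation matrix --------------------------------------------
    n_samp = len(samples)
    is_tumor = np.array([g == "tumor" for g in groups])
    enh_mask = manifest["is_enhancer"].to_numpy()
    betas = np.empty((len(manifest), n_samp))
    probe_signal: dict[str, np.ndarray] = {}   # planted probes, pre-noise signal

    # per-module latent factors; a module gene's enhancer region co-varies
    # with its module's factor (coordinated demethylation of the module's
    # enhancers), so planted links and planted co-expression reinforce
    factors = rng.normal(0.0, 1.0, size=(len(p.module_shapes), n_samp))
    module_of_gene: dict[str, int] = {}
    for m, (lncs_m, mrnas_m) in enumerate(zip(module_lncs, module_mrnas)):
        for gid in lncs_m + mrnas_m:
            module_of_gene[gid] = m
    gene_of_probe = {pid: gid for gid, pid in planted_probe_of.items()}

    mu_background = rng.normal(0.0, 1.5, size=len(manifest))
    sq_share = np.sqrt(p.region_factor_share)
    for i, (pid, is_enh) in enumerate(zip(manifest["probe_id"], enh_mask)):
        kind = probe_kind.get(pid)
        if is_enh and kind is not None:
            lo, hi = (0.55, 0.85) if kind == "hypo" else (0.15, 0.45)
            base = rng.uniform(lo, hi)
            shift = (-1.0 if kind == "hypo" else 1.0) * p.delta_methylation
            u_s = rng.normal(0.0, 1.0, size=n_samp)
            mod = module_of_gene.get(gene_of_probe.get(pid))
            if mod is not None:
                w_s = sq_share * factors[mod] + np.sqrt(1.0 - p.region_factor_share) * u_s
            else:
                w_s = u_s
            signal = base + np.where(is_tumor, shift, 0.0) + p.region_beta_sd * w_s
            eps = rng.normal(0.0, p.probe_noise_sd, size=n_samp)
            betas[i] = np.clip(signal + eps, 0.01, 0.99)
            probe_signal[pid] = np.clip(signal, 0.01, 0.99)
        elif is_enh:
            betas[i] = _sigmoid(mu_background[i] + rng.normal(0.0, 0.5, size=n_samp))
    # promoter probes share a per-gene, per-sample deviation
    prom_signal: dict[str, np.ndarray] = {}
    dpmg_sign = {g: (-1.0 if rng.random() < 0.7 else 1.0) for g in promoter_regulated}
    for gid in gene_pos.index:
        base = rng.uniform(0.2, 0.8)
        shift = dpmg_sign.get(gid, 0.0) * p.promoter_delta
        r_s = rng.normal(0.0, p.promoter_beta_sd, size=n_samp)
        signal = base + np.where(is_tumor, shift, 0.0) + r_s
        prom_signal[gid] = np.clip(signal, 0.01, 0.99)
    for i, (pid, is_enh) in enumerate(zip(manifest["probe_id"], enh_mask)):
        if is_enh:
            continue
        gid = pid.rsplit("_pr", 1)[0]
        eps = rng.normal(0.0, p.probe_noise_sd, size=n_samp)
        betas[i] = np.clip(prom_signal[gid] + eps, 0.01, 0.99)

    beta_frame = pd.DataFrame(
        betas, index=pd.Index(manifest["probe_id"], name="probe_id"), columns=samples
    )
    beta_frame = inject_missingness(beta_frame, p.missing_fraction, rng)
    # push a background minority of enhancer probes over the 30% filter
    background_enh = [
        pid for pid in manifest.loc[enh_mask, "probe_id"] if pid not in probe_kind
    ]
    n_high = int(np.floor(p.high_missing_fraction * len(background_enh)))
    high_missing = list(rng.choice(background_enh, size=n_high, replace=False))
    for pid in high_missing:
        cols = rng.choice(n_samp, size=int(p.high_missing_cell_fraction * n_samp), replace=False)
        beta_frame.loc[pid, beta_frame.columns[cols]] = np.nan
    beta = MethylationMatrix(beta_frame, groups)

    # ---- ground-truth region ids (same QC + merge the pipeline applies) --
    kept, _removed = filter_probes_by_missingness(beta, config.max_missing_fraction)
    kept_manifest = manifest.loc[manifest["probe_id"].isin(kept.values.index)]
    regions = build_enhancer_regions(kept_manifest, config.window_half_width)
    region_of_probe = {pid: r.region_id for r in regions for pid in r.probes}

    def region_of(gene: str) -> str:
        return region_of_probe[planted_probe_of[gene]]

    # ---- tumor expression ----------------------------------------------
    baseline = pd.Series(rng.normal(3.0, 1.0, size=n_genes), index=genes["gene_id"].to_numpy())
    tumor_idx = np.arange(p.n_tumor)          # tumor samples come first
    log_expr = np.empty((n_genes, p.n_tumor))
    for i, gid in enumerate(genes["gene_id"]):
        noise_sd = p.background_expr_noise_sd
        x = np.zeros(p.n_tumor)
        if gid in planted_probe_of:
            beta_t = probe_signal[planted_probe_of[gid]][tumor_idx]
            slope = p.coupling_slope if gid not in decoy_genes else -p.coupling_slope
            x = x + slope * beta_t
            noise_sd = p.planted_expr_noise_sd
        if gid in module_of_gene:
            # loading signed like the (negative) methylation coupling, so the
            # factor's contributions to expression and to region beta agree
            x = x - p.module_loading * factors[module_of_gene[gid], tumor_idx]
        if gid in dpmg_sign:
            x = x + p.promoter_coupling_slope * prom_signal[gid][tumor_idx]
            noise_sd = p.planted_expr_noise_sd
        log_expr[i] = baseline[gid] + x + rng.normal(0.0, noise_sd, size=p.n_tumor)
    expr = pd.DataFrame(
        np.exp(log_expr), index=pd.Index(genes["gene_id"], name="gene_id"), columns=tumor_ids
    )
    lnc_expr = expr.loc[[g for g in genes["gene_id"] if g.startswith("LNC_")]]
    mrna_expr = expr.loc[[g for g in genes["gene_id"] if g.startswith("MRNA_")]]

    # ---- validation expression -----------------------------------------
    v_tumor = [f"VT{i + 1:03d}" for i in range(p.n_validation_tumor)]
    v_normal = [f"VN{i + 1:03d}" for i in range(p.n_validation_normal)]
    v_samples = v_tumor + v_normal
    v_is_tumor = np.array([s.startswith("VT") for s in v_samples])
    v_log = np.empty((n_genes, len(v_samples)))
    for i, gid in enumerate(genes["gene_id"]):
        effect = p.validation_effect if gid in module_of_gene else 0.0
        v_log[i] = (
            baseline[gid]
            + np.where(v_is_tumor, effect, 0.0)
            + rng.normal(0.0, p.validation_noise_sd, size=len(v_samples))
        )
    validation_expr = pd.DataFrame(
        np.exp(v_log), index=pd.Index(genes["gene_id"], name="gene_id"), columns=v_samples
    )
    validation_labels = pd.Series(
        np.where(v_is_tumor, "tumor", "normal"), index=v_samples, name="group"
    )

    # ---- miRNA interaction tables --------------------------------------
    mirna_ids = [f"MIR_{i + 1:04d}" for i in range(p.n_mirna)]
    mir_pool = list(rng.permutation(mirna_ids))
    module_mirnas = []
    for _ in p.module_shapes:
        module_mirnas.append(sorted(mir_pool[: p.mirnas_per_module]))
        del mir_pool[: p.mirnas_per_module]
    lnc_mir_rows = []
    mir_mrna_rows = []
    for m, (lncs_m, mrnas_m) in enumerate(zip(module_lncs, module_mrnas)):
        for l in lncs_m:
            for mir in module_mirnas[m]:
                lnc_mir_rows.append((l, mir))
        for g in mrnas_m:
            for mir in module_mirnas[m]:
                mir_mrna_rows.append((mir, g))
    bg_l = rng.random((p.n_lncrna, p.n_mirna)) < p.background_mirna_edge_prob
    bg_m = rng.random((p.n_mirna, p.n_mrna)) < p.background_mirna_edge_prob
    for i, l in enumerate(lnc_ids):
        for j in np.flatnonzero(bg_l[i]):
            lnc_mir_rows.append((l, mirna_ids[j]))
    for j, mir in enumerate(mirna_ids):
        for g in np.flatnonzero(bg_m[j]):
            mir_mrna_rows.append((mir, mrna_ids[g]))
    lnc_mirna = pd.DataFrame(lnc_mir_rows, columns=["lncrna", "mirna"]).drop_duplicates().reset_index(drop=True)
    mirna_mrna = pd.DataFrame(mir_mrna_rows, columns=["mirna", "mrna"]).drop_duplicates().reset_index(drop=True)

    # ---- survival --------------------------------------------------------
    lp = pd.Series(p.hazard_coef * factors[0, tumor_idx], index=tumor_ids)
    survival = simulate_survival_times(lp, p.baseline_hazard, p.censor_rate, rng)

    # ---- drugs -----------------------------------------------------------
    drug_ids = [f"DRUG_{i + 1:02d}" for i in range(p.n_drugs)]
    drug_rows = []
    drug_hits = []
    all_module_lncs = [g for mod in module_lncs for g in mod]
    for i, lnc in enumerate(all_module_lncs):
        drug = drug_ids[i % p.n_drugs]
        drug_rows.append((drug, lnc, "down"))
        drug_hits.append([drug, lnc])
    non_network = [g for g in lnc_ids if g not in set(all_module_lncs)]
    for i in range(p.n_decoy_drug_rows):
        drug = drug_ids[(i + 3) % p.n_drugs]
        if i % 2 == 0 and all_module_lncs:
            drug_rows.append((drug, all_module_lncs[i % len(all_module_lncs)], "up"))
        else:
            drug_rows.append((drug, non_network[i % len(non_network)], "down"))
    drugs = pd.DataFrame(drug_rows, columns=["drug", "lncrna", "direction"]).drop_duplicates().reset_index(drop=True)

    # ---- ground truth ----------------------------------------------------
    gt_modules = [
        {"module_id": f"GT_M{m + 1}", "lncrnas": module_lncs[m], "mrnas": module_mrnas[m]}
        for m in range(len(p.module_shapes))
    ]
    ground_truth = {
        "delta_methylation": p.delta_methylation,
        "hazard_coef": p.hazard_coef,
        "hypo_region_ids": sorted({region_of(g) for g in planted_link_genes}),
        "decoy_region_ids": sorted({region_of(g) for g in decoy_genes}),
        "hyper_region_ids": sorted({region_of_probe[pid] for pid in hyper_probes}),
        "planted_links": [
            {"region_id": region_of(g), "gene_id": g} for g in sorted(planted_link_genes)
        ],
        "decoy_links": [
            {"region_id": region_of(g), "gene_id": g} for g in sorted(decoy_genes)
        ],
        "modules": gt_modules,
        "prognostic_module": "GT_M1",
        "promoter_regulated_genes": promoter_regulated,
        "drug_hits": sorted(drug_hits),
    }

    study = SyntheticStudy(
        manifest=manifest,
        genes=genes,
        beta=beta,
        lnc_expr=lnc_expr,
        mrna_expr=mrna_expr,
        validation_expr=validation_expr,
        validation_labels=validation_labels,
        lnc_mirna=lnc_mirna,
        mirna_mrna=mirna_mrna,
        survival=survival,
        drugs=drugs,
        ground_truth=ground_truth,
    )
    study.check_ground_truth_ids()
    return study


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write every file the pipeline reads, plus ground_truth.json."""
    from . import io

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_probe_manifest(study.manifest, outdir / "probes.tsv")
    io.write_gene_models(study.genes, outdir / "genes.tsv")
    io.write_matrix(study.beta.values, outdir / "beta.tsv")
    io.write_sample_groups(study.beta.groups, outdir / "sample_groups.tsv")
    io.write_matrix(study.lnc_expr, outdir / "expr_lncrna.tsv")
    io.write_matrix(study.mrna_expr, outdir / "expr_mrna.tsv")
    io.write_matrix(study.validation_expr, outdir / "expr_validation.tsv")
    io.write_sample_groups(study.validation_labels, outdir / "validation_groups.tsv")
    io.write_edge_list(study.lnc_mirna, outdir / "lnc_mirna.tsv")
    io.write_edge_list(study.mirna_mrna, outdir / "mirna_mrna.tsv")
    io.write_survival(study.survival, outdir / "survival.tsv")
    io.write_edge_list(study.drugs, outdir / "drugs.tsv")
    with open(outdir / "ground_truth.json", "w", encoding="utf-8") as fh:
        json.dump(study.ground_truth, fh, indent=1, sort_keys=True)
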