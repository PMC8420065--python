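"""Study configuration: screening thresholds and synthetic-study parameters.

Defaults mirror the published analysis protocol the pipeline reimplements:
probes missing in more than 30% of samples are dropped, k = 10 nearest
neighbours impute the rest, enhancer windows are +/-500 bp around each CpG,
promoters are the 2 kb upstream of the TSS, enhancer--gene pairing is capped
at 1 Mbp, and the screening cuts (|log2FC| >= 0.01 with BH-adjusted p <= 0.05
for enhancer regions, |delta-median| >= 0.1 for promoter genes, negative
methylation--expression correlation at p <= 0.05, shared-miRNA hypergeometric
FDR <= 0.05 with >= 2 shared miRNAs, co-expression PCC > 0.5 at p <= 0.05,
bicliques with both sides >= 2, log-rank p <= 0.05, over-representation
p <= 0.01) follow the same protocol.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class SimulationParams:
    """Parameters of the synthetic study generator.

    The defaults define a desk-scale study: 60 tumor and 30 normal
    methylomes over ~2,000 enhancer probes, 300 genes (100 lncRNA,
    200 mRNA), 100 miRNAs, 20 planted hypomethylated-enhancer target
    links, 3 planted co-expression bicliques and 1 prognostic module.
    """

    n_chrom: int = 4
    enhancer_probes_per_chrom: int = 500
    probe_spacing: int = 3000          # bp between successive enhancer probe slots
    probe_jitter: int = 1200           # uniform jitter so some windows overlap and merge
    n_lncrna: int = 100
    n_mrna: int = 200
    n_mirna: int = 100
    promoter_probes_per_gene: int = 2
    gene_spacing: int = 20000          # bp between successive TSSs
    n_tumor: int = 60
    n_normal: int = 30
    n_validation_tumor: int = 40
    n_validation_normal: int = 20

    # methylation model
    missing_fraction: float = 0.05     # uniform per-cell missingness
    high_missing_fraction: float = 0.02  # fraction of background probes pushed over the 30% filter
    high_missing_cell_fraction: float = 0.45
    delta_methylation: float = 0.25    # planted tumor-vs-normal beta shift
    region_beta_sd: float = 0.15       # per-sample biological variation shared within a region
    probe_noise_sd: float = 0.05       # residual probe-level noise on the beta scale

    # planted differential enhancer regions and target links
    n_planted_hyper: int = 5
    n_decoy_links: int = 3             # positive-coupling decoy region->gene pairs
    n_extra_links: int = 4             # planted links outside any biclique module
    module_shapes: tuple = ((3, 4), (2, 3), (2, 2))  # (n lncRNA, n mRNA) per planted biclique

    # expression model (log scale; matrices are exported as FPKM-like exp values)
    coupling_slope: float = -0.8       # log-expression units per unit of region beta
    module_loading: float = 0.19      # latent-factor loading magnitude of module genes
    region_factor_share: float = 0.5   # share of module-region beta variance from the factor
    planted_expr_noise_sd: float = 0.14
    background_expr_noise_sd: float = 0.5
    validation_effect: float = 0.8     # tumor-vs-normal log shift of planted module genes
    validation_noise_sd: float = 0.3

    # promoter-regulated (DPMG) genes
    n_promoter_regulated: int = 10
    promoter_delta: float = 0.2
    promoter_coupling_slope: float = -1.5
    promoter_beta_sd: float = 0.1

    # miRNA interaction tables
    mirnas_per_module: int = 6
    background_mirna_edge_prob: float = 0.03

    # survival model
    baseline_hazard: float = 0.1
    hazard_coef: float = 0.8           # log-hazard per unit of the prognostic module factor
    censor_rate: float = 0.01

    # drug table
    n_drugs: int = 8
    n_decoy_drug_rows: int = 6

    def validate(self) -> None:
        if self.n_tumor < 4 or self.n_normal < 4:
            raise ParameterError(
                "need at least 4 tumor and 4 normal samples for stable "
                f"variance estimates (got {self.n_tumor}/{self.n_normal})"
            )
        if not 0.0 <= self.missing_fraction < 1.0:
            raise ParameterError("missing_fraction must be in [0, 1)")
        if self.baseline_hazard <= 0 or self.censor_rate < 0:
            raise ParameterError("hazard rates must be positive")


@dataclass
class StudyConfig:
    """All thresholds of the inference chain plus the simulation block."""

    max_missing_fraction: float = 0.30
    knn_k: int = 10
    window_half_width: int = 500
    promoter_length: int = 2000
    max_enhancer_gene_distance: int = 1_000_000
    dmer_lfc: float = 0.01
    dmer_adj_p: float = 0.05
    dpmg_delta: float = 0.10
    dpmg_adj_p: float = 0.05
    link_p: float = 0.05
    cerna_min_shared: int = 2
    cerna_fdr: float = 0.05
    coexpr_pcc: float = 0.5
    coexpr_p: float = 0.05
    biclique_min_lncrna: int = 2
    biclique_min_mrna: int = 2
    survival_p: float = 0.05
    ora_p: float = 0.01
    hub_fraction: float = 0.15
    mirna_universe: str = "union"      # or "intersection"
    standardize_cox: bool = False
    seed: int = 0
    sim: SimulationParams = field(default_factory=SimulationParams)

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ParameterError("seed must be an integer")
        if self.mirna_universe not in ("union", "intersection"):
            raise ParameterError("mirna_universe must be 'union' or 'intersection'")
        self.sim.validate()


def _asdict(cfg: StudyConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["sim"]["module_shapes"] = [list(s) for s in cfg.sim.module_shapes]
    return d


def load_config(path: str | Path) -> StudyConfig:
    """Load a StudyConfig from YAML; missing keys fall back to defaults."""
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    sim_raw = raw.pop("sim", {}) or {}
    if "module_shapes" in sim_raw:
        sim_raw["module_shapes"] = tuple(tuple(s) for s in sim_raw["module_shapes"])
    known_sim = {f.name for f in dataclasses.fields(SimulationParams)}
    known_cfg = {f.name for f in dataclasses.fields(StudyConfig)}
    bad = (set(sim_raw) - known_sim) | (set(raw) - known_cfg)
    if bad:
        raise ParameterError(f"unknown config keys: {sorted(bad)}")
    cfg = StudyConfig(sim=SimulationParams(**sim_raw), **raw)
    cfg.validate()
    return cfg


def save_config(cfg: StudyConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(_asdict(cfg), fh, sort_keys=False)
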