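"""Methylome processing: probe QC, imputation, enhancer-region construction,
region/promoter summarization, and moderated differential testing.

The differential test follows the empirical-Bayes moderated t approach of
limma/Smyth (2004): per-feature pooled residual variances are shrunk toward a
common prior estimated by moment-matching a scaled-F distribution to the
observed variances, and the group-difference coefficient on the beta scale is
tested on the augmented degrees of freedom. On beta-value input the fitted
group contrast (mean tumor beta minus mean normal beta) plays the role of the
"log2 fold change" reported by the linear-model convention, and the +/-0.01
effect cut applies to it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import IntegrityError, InvariantError, ParameterError

TUMOR = "tumor"
NORMAL = "normal"


@dataclass
class MethylationMatrix:
    """Beta values (features x samples) with group labels.

    Missing cells are NaN in ``values``. ``groups`` maps every sample id to
    'tumor' or 'normal'.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = self.groups.reindex(self.values.columns)
        if self.groups.isna().any():
            missing = list(self.values.columns[self.groups.isna()])
            raise IntegrityError(f"samples without group label: {missing[:5]}")
        observed = self.values.to_numpy(dtype=float)
        with np.errstate(invalid="ignore"):
            bad = np.nansum((observed < 0) | (observed > 1))
        if bad:
            raise InvariantError(f"{int(bad)} beta values outside [0, 1]")

    @property
    def feature_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def tumor_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == TUMOR])

    def normal_samples(self) -> list[str]:
        return list(self.groups.index[self.groups == NORMAL])


@dataclass
class EnhancerRegion:
    """A merged enhancer interval in 0-based half-open coordinates."""

    region_id: str
    chrom: str
    start: int
    end: int
    probes: list[str] = field(default_factory=list)

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


# ---------------------------------------------------------------------------
# probe QC and imputation
# ---------------------------------------------------------------------------

def filter_probes_by_missingness(
    matrix: MethylationMatrix, max_fraction: float = 0.30
) -> tuple[MethylationMatrix, pd.Index]:
    """Drop features missing in strictly more than ``max_fraction`` of samples.

    Returns the filtered matrix and the index of removed feature ids.
    """
    if matrix.values.shape[1] == 0:
        raise ParameterError("matrix has no samples")
    frac = matrix.values.isna().mean(axis=1)
    removed = matrix.values.index[frac > max_fraction]
    if len(removed) == len(matrix.values):
        warnings.warn("all features removed by the missingness filter")
    kept = MethylationMatrix(matrix.values.drop(index=removed), matrix.groups)
    return kept, removed


def knn_impute(matrix: MethylationMatrix, k: int = 10) -> MethylationMatrix:
    """Impute missing betas from the k nearest probes (rows).

    Distance between two probes is the Euclidean distance over columns
    observed in both, rescaled by sqrt(n_columns / n_shared) so sparsity does
    not shrink distances. The imputed cell is the unweighted mean of the k
    nearest probes' observed values in that sample, clipped to [0, 1]. A
    probe sharing no observed column with any donor falls back to its own
    observed mean, with a warning.
    """
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    X = matrix.values.to_numpy(dtype=float, copy=True)
    n_feat, n_samp = X.shape
    obs = ~np.isnan(X)
    if not obs.any(axis=1).all():
        bad = matrix.values.index[~obs.any(axis=1)]
        raise ParameterError(f"features with no observed value: {list(bad[:5])}")
    if obs.all():
        return MethylationMatrix(matrix.values.copy(), matrix.groups)

    Z = np.where(obs, X, 0.0)
    shared = obs.astype(float) @ obs.T.astype(float)          # shared observed columns
    sq = Z**2
    # sum over shared columns of (x_i - x_j)^2
    cross = Z @ Z.T
    si = sq @ obs.T.astype(float)
    d2 = si + si.T - 2.0 * cross
    with np.errstate(divide="ignore", invalid="ignore"):
        d2 = d2 * (n_samp / shared)
    np.fill_diagonal(d2, np.inf)
    d2[shared == 0] = np.inf
    d2 = np.maximum(d2, 0.0)

    row_mean = np.nansum(X, axis=1) / obs.sum(axis=1)
    out = X.copy()
    for i in range(n_feat):
        miss_cols = np.flatnonzero(~obs[i])
        if miss_cols.size == 0:
            continue
        order = np.argsort(d2[i], kind="stable")
        finite = order[np.isfinite(d2[i][order])]
        for j in miss_cols:
            donors = finite[obs[finite, j]][:k]
            if donors.size == 0:
                warnings.warn(
                    f"no kNN donor for feature {matrix.values.index[i]!r} in "
                    f"sample {matrix.values.columns[j]!r}; using the probe mean"
                )
                out[i, j] = row_mean[i]
            else:
                out[i, j] = X[donors, j].mean()
    out = np.clip(out, 0.0, 1.0)
    return MethylationMatrix(
        pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns),
        matrix.groups,
    )


# ---------------------------------------------------------------------------
# enhancer regions and promoter mapping
# ---------------------------------------------------------------------------

def build_enhancer_regions(
    manifest: pd.DataFrame, half_width: int = 500
) -> list[EnhancerRegion]:
    """Merge +/-half_width windows around enhancer probes into regions.

    Windows are [pos - half_width, pos + half_width) in 0-based half-open
    coordinates; windows on the same chromosome merge transitively when their
    intersection is non-empty. Touching (bookended) windows stay separate,
    which preserves the dominant single-probe region length of exactly
    2*half_width. Region ids are assigned in (chrom, start) order.
    """
    enh = manifest.loc[manifest["is_enhancer"]]
    intervals = []
    for pid, chrom, pos in zip(enh["probe_id"], enh["chrom"], enh["pos"]):
        start = pos - half_width
        if start < 0:
            warnings.warn(f"probe {pid!r} window clipped at chromosome start")
            start = 0
        intervals.append((chrom, start, pos + half_width, pid))
    intervals.sort(key=lambda t: (t[0], t[1], t[2], t[3]))

    merged: list[EnhancerRegion] = []
    current: EnhancerRegion | None = None
    for chrom, start, end, pid in intervals:
        if current is not None and chrom == current.chrom and start < current.end:
            current.end = max(current.end, end)
            current.probes.append(pid)
        else:
            current = EnhancerRegion("", chrom, start, end, [pid])
            merged.append(current)
    for i, region in enumerate(merged, start=1):
        region.region_id = f"ENH_{i:06d}"
    return merged


def summarize_region_methylation(
    matrix: MethylationMatrix, regions: list[EnhancerRegion]
) -> MethylationMatrix:
    """Region beta per sample = arithmetic mean of member probe betas."""
    if matrix.values.isna().any().any():
        raise ParameterError("matrix must be complete (impute first)")
    index = matrix.values.index
    rows = []
    ids = []
    for region in regions:
        if not region.probes:
            continue
        missing = [p for p in region.probes if p not in index]
        if missing:
            raise IntegrityError(
                f"region {region.region_id} references unknown probes {missing[:3]}"
            )
        rows.append(matrix.values.loc[region.probes].mean(axis=0))
        ids.append(region.region_id)
    frame = pd.DataFrame(rows, index=pd.Index(ids, name="region_id"))
    return MethylationMatrix(frame, matrix.groups)


def map_promoter_probes(
    manifest: pd.DataFrame, genes: pd.DataFrame, upstream: int = 2000
) -> dict[str, list[str]]:
    """Assign non-enhancer probes to strand-aware promoters.

    The promoter is the ``upstream`` bp ending at the TSS: [tss-upstream, tss)
    for + strand genes, [tss, tss+upstream) for - strand (0-based half-open).
    Enhancer-flagged probes are excluded, and probes inside the promoters of
    two or more genes are discarded entirely.
    """
    probes = manifest.loc[~manifest["is_enhancer"]]
    hits: dict[str, list[str]] = {}
    probe_genes: dict[str, list[str]] = {}
    for chrom, sub in probes.groupby("chrom", sort=False):
        gsub = genes.loc[genes["chrom"] == chrom]
        if gsub.empty:
            continue
        pos = sub["pos"].to_numpy()
        pids = sub["probe_id"].to_numpy()
        for gid, strand, tss in zip(gsub["gene_id"], gsub["strand"], gsub["tss"]):
            if strand == "+":
                lo, hi = tss - upstream, tss
            else:
                lo, hi = tss, tss + upstream
            inside = (pos >= lo) & (pos < hi)
            for pid in pids[inside]:
                probe_genes.setdefault(pid, []).append(gid)
    for pid, gids in probe_genes.items():
        if len(gids) == 1:
            hits.setdefault(gids[0], []).append(pid)
    return {g: sorted(ps) for g, ps in hits.items()}


def summarize_promoter_methylation(
    matrix: MethylationMatrix, mapping: dict[str, list[str]]
) -> MethylationMatrix:
    """Gene promoter beta per sample = mean of its mapped probes."""
    rows = []
    ids = []
    index = matrix.values.index
    for gene in sorted(mapping):
        probes = [p for p in mapping[gene] if p in index]
        if not probes:
            continue
        rows.append(matrix.values.loc[probes].mean(axis=0))
        ids.append(gene)
    frame = pd.DataFrame(rows, index=pd.Index(ids, name="gene_id"))
    return MethylationMatrix(frame, matrix.groups)


# ---------------------------------------------------------------------------
# moderated differential testing
# ---------------------------------------------------------------------------

def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration, Smyth 2004)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return x


def estimate_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Moment-match a scaled-F prior (d0, s0^2) to sample variances.

    Uses the closed forms on log variances: with z = log(s2),
    e = z - digamma(df/2) + log(df/2) is an unbiased estimate of log(sigma^2)
    up to the prior spread; the excess variance of e over trigamma(df/2)
    determines d0 via the inverse trigamma.
    """
    s2 = np.asarray(s2, dtype=float)
    s2 = s2[np.isfinite(s2) & (s2 > 0)]
    if s2.size < 2:
        return np.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2)
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    evar = np.var(e, ddof=1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        # no excess spread: point-mass prior at the mean sample variance
        return np.inf, float(np.mean(s2))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = float(np.exp(np.mean(e) + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_2


def fit_group_difference(
    matrix: MethylationMatrix, prior_df: float | None = None
) -> pd.DataFrame:
    """Moderated two-group differential test on a complete feature matrix.

    Per feature, the coefficient is mean(tumor) - mean(normal); the pooled
    residual variance is shrunk toward the moment-matched prior and the
    moderated t is referred to a t distribution on d0 + d degrees of freedom.
    P-values are BH-adjusted across all features. ``prior_df`` overrides the
    estimated d0 (0 recovers the ordinary pooled two-sample t; numpy.inf
    fixes the variance at the prior).

    Returns a DataFrame indexed by feature id with columns mean_tumor,
    mean_normal, delta_median, log2fc, t, p, adj_p, zero_variance.
    """
    tumor = matrix.tumor_samples()
    normal = matrix.normal_samples()
    n1, n2 = len(tumor), len(normal)
    if n1 < 2 or n2 < 2:
        raise ParameterError(f"need >= 2 samples per group, got {n1}/{n2}")
    if matrix.values.isna().any().any():
        raise ParameterError("matrix must be complete (impute first)")

    T = matrix.values[tumor].to_numpy(dtype=float)
    N = matrix.values[normal].to_numpy(dtype=float)
    mean_t = T.mean(axis=1)
    mean_n = N.mean(axis=1)
    coef = mean_t - mean_n
    delta_median = np.median(T, axis=1) - np.median(N, axis=1)

    df = n1 + n2 - 2
    ss = ((T - mean_t[:, None]) ** 2).sum(axis=1) + ((N - mean_n[:, None]) ** 2).sum(axis=1)
    s2 = ss / df
    zero_var = s2 <= 1e-24  # tolerate rounding residue of constant rows

    if prior_df is None:
        d0, s0_2 = estimate_variance_prior(s2[~zero_var], df)
    else:
        d0 = float(prior_df)
        _, s0_2 = estimate_variance_prior(s2[~zero_var], df)

    # total df capped at the summed residual df over features (the posterior
    # cannot be more informative than the whole experiment)
    df_cap = df * max(int((~zero_var).sum()), 1)
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_2)
        df_total = df_cap
    elif d0 == 0:
        s2_post = s2.copy()
        df_total = df
    else:
        s2_post = (d0 * s0_2 + df * s2) / (d0 + df)
        df_total = min(d0 + df, df_cap)

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = coef / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df_total)

    # features with no residual variance in either group have no defined t;
    # they are reported with p = 1 and flagged rather than dropped
    undefined = ~np.isfinite(tstat) | zero_var
    tstat = np.where(undefined, np.nan, tstat)
    p = np.where(undefined, 1.0, p)
    p = np.clip(p, 0.0, 1.0)
    adj_p = multipletests(p, method="fdr_bh")[1]

    return pd.DataFrame(
        {
            "mean_tumor": mean_t,
            "mean_normal": mean_n,
            "delta_median": delta_median,
            "log2fc": coef,
            "t": tstat,
            "p": p,
            "adj_p": adj_p,
            "zero_variance": zero_var,
        },
        index=matrix.values.index,
    )


def call_dmers(
    results: pd.DataFrame, lfc: float = 0.01, adj_p: float = 0.05
) -> pd.DataFrame:
    """Label enhancer regions hyper/hypo/ns by effect size and adjusted p."""
    out = results.copy()
    sig = out["adj_p"] <= adj_p
    direction = np.where(
        sig & (out["log2fc"] >= lfc), "hyper",
        np.where(sig & (out["log2fc"] <= -lfc), "hypo", "ns"),
    )
    out["direction"] = direction
    return out


def call_dpmgs(
    results: pd.DataFrame, delta: float = 0.10, adj_p: float = 0.05
) -> pd.DataFrame:
    """Label promoter genes by |delta-median| >= delta and adjusted p."""
    out = results.copy()
    sig = (out["adj_p"] <= adj_p) & (out["delta_median"].abs() >= delta)
    out["direction"] = np.where(
        sig & (out["delta_median"] > 0), "hyper",
        np.where(sig & (out["delta_median"] < 0), "hypo", "ns"),
    )
    return out
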