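"""Bulk and single-cell differential expression.

Bulk: pOverA low-coverage filtering, median-of-ratios size factors, a
per-gene negative-binomial Wald test per timepoint contrast, k = 2 k-means
gene clustering of DE-gene profiles with centroid-correlation top-gene
selection, and a two-way (treatment x time) ANOVA of per-replicate cluster
means.

Single cell: per-cell-type rank-sum DE between conditions with BH adjustment
and a strict |log2FC| > 1 volcano rule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .stats_enrich import benjamini_hochberg


@dataclass
class BulkDEParams:
    """Bulk DE thresholds: pOverA count/sample minima, BH alpha, |log2FC|."""

    pover_a_count: int = 10
    pover_a_samples: int = 3
    alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    dispersion_floor: float = 1e-8
    pseudocount: float = 0.5
    # empirical-Bayes moderation of the per-gene MoM dispersion toward the
    # dataset median (prior df); 0 disables moderation
    dispersion_prior_df: float = 20.0

    def __post_init__(self) -> None:
        if min(self.pover_a_count, self.pover_a_samples) <= 0:
            raise ValueError("pOverA thresholds must be > 0")
        if self.alpha <= 0 or self.min_abs_log2fc <= 0:
            raise ValueError("alpha and min_abs_log2fc must be > 0")


# ---------------------------------------------------------------------------
# filtering and normalization
# ---------------------------------------------------------------------------


def pover_a_filter(counts: pd.DataFrame, params: BulkDEParams | None = None) -> pd.DataFrame:
    """Retain genes with count >= A in at least P samples.

    Genes with zero counts across all samples are removed first; the pOverA
    rule (count >= ``pover_a_count`` in >= ``pover_a_samples`` samples) is
    then applied.
    """
    params = params or BulkDEParams()
    nonzero = counts.sum(axis=1) > 0
    counts = counts.loc[nonzero]
    keep = (counts >= params.pover_a_count).sum(axis=1) >= params.pover_a_samples
    return counts.loc[keep]


def median_of_ratios_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors over a geometric-mean pseudo-reference.

    Only genes with nonzero counts in every sample contribute; each sample's
    factor is the median of its count / geometric-mean ratios.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    mat = counts.to_numpy(float)
    all_nonzero = np.all(mat > 0, axis=1)
    if not np.any(all_nonzero):
        raise ValueError(
            "no gene has nonzero counts in every sample; consider a "
            "pseudo-reference fallback on a less sparse table"
        )
    ref = np.exp(np.log(mat[all_nonzero]).mean(axis=1))
    ratios = mat[all_nonzero] / ref[:, None]
    factors = np.median(ratios, axis=0)
    return pd.Series(factors, index=counts.columns, name="size_factor")


# ---------------------------------------------------------------------------
# negative-binomial Wald test
# ---------------------------------------------------------------------------


def nb_wald_test(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    contrast: tuple[list, list],
    params: BulkDEParams | None = None,
) -> pd.DataFrame:
    """Per-gene NB Wald test between two sample groups.

    Counts are normalized by the size factors; each gene's NB dispersion is a
    pooled (across the two groups) method-of-moments estimate floored at
    ``dispersion_floor`` and moderated toward the dataset-median dispersion
    with ``dispersion_prior_df`` prior degrees of freedom (trend-free
    empirical-Bayes sharing across genes — a per-gene 4-df estimate cannot
    simultaneously control FDR and retain power at triplicate sample sizes).
    The log2 fold change is the log2 ratio of normalized group means
    (pseudocount ``pseudocount``); the Wald statistic — the log-scale mean
    difference over its delta-method standard error — is referred to a t
    distribution with (n1 + n2 - 2) + prior df, reflecting the information in
    the moderated dispersion. BH adjustment is across genes; ``call`` is
    +1/-1/0 per the strict |log2FC| > threshold rule.
    """
    params = params or BulkDEParams()
    cols_a, cols_b = contrast
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("need >= 2 replicates per group")
    sf_a = size_factors[cols_a].to_numpy()
    sf_b = size_factors[cols_b].to_numpy()
    ya = counts[cols_a].to_numpy(float) / sf_a  # normalized counts
    yb = counts[cols_b].to_numpy(float) / sf_b
    na, nb = ya.shape[1], yb.shape[1]

    ma, mb = ya.mean(axis=1), yb.mean(axis=1)
    grand = (ya.sum(axis=1) + yb.sum(axis=1)) / (na + nb)
    # pooled within-group variance of normalized counts (na + nb - 2 df)
    ss = ((ya - ma[:, None]) ** 2).sum(axis=1) + ((yb - mb[:, None]) ** 2).sum(axis=1)
    pooled_var = ss / (na + nb - 2)
    # normalized counts are modelled as NB on the common scale,
    # Var(y) = mu + alpha mu^2 (size factors are ~1 after median-of-ratios,
    # and this keeps the test a function of the normalized counts alone)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_hat = (pooled_var - grand) / grand**2
    alpha_hat = np.where(np.isfinite(alpha_hat), alpha_hat, 0.0)
    alpha_hat = np.maximum(alpha_hat, params.dispersion_floor)
    resid_df = na + nb - 2
    d0 = params.dispersion_prior_df
    if d0 > 0 and len(alpha_hat) > 1:
        alpha_prior = float(np.median(alpha_hat))
        alpha_hat = (d0 * alpha_prior + resid_df * alpha_hat) / (d0 + resid_df)
        alpha_hat = np.maximum(alpha_hat, params.dispersion_floor)

    pc = params.pseudocount
    log2fc = np.log2((ma + pc) / (mb + pc))
    all_zero_flag = (ma == 0) | (mb == 0)

    def group_var(mu, n):
        # delta-method variance of the group log-mean
        var_mean = (mu + alpha_hat * mu**2) / n
        return var_mean / (mu + pc) ** 2

    se = np.sqrt(group_var(ma, na) + group_var(mb, nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        wald = (np.log(ma + pc) - np.log(mb + pc)) / se
    wald = np.where(np.isfinite(wald), wald, 0.0)
    p = 2.0 * stats.t.sf(np.abs(wald), df=resid_df + d0)
    q = benjamini_hochberg(p)
    call = np.zeros(len(counts), int)
    sig = q < params.alpha
    call[sig & (log2fc > params.min_abs_log2fc)] = 1
    call[sig & (log2fc < -params.min_abs_log2fc)] = -1
    return pd.DataFrame(
        {
            "baseMean": grand,
            "log2FC": log2fc,
            "dispersion": alpha_hat,
            "stat": wald,
            "p": p,
            "q": q,
            "call": call,
            "zero_group": all_zero_flag,
        },
        index=counts.index,
    )


# ---------------------------------------------------------------------------
# gene clustering of DE genes
# ---------------------------------------------------------------------------


def vst_like_transform(counts: pd.DataFrame, size_factors: pd.Series) -> pd.DataFrame:
    """Variance-stabilizing transform: log2(normalized count + 1)."""
    return np.log2(counts / size_factors + 1.0)


@dataclass
class GeneClusterResult:
    labels: pd.Series  # gene -> cluster (1 = up-regulated-first ordering)
    centroids: pd.DataFrame  # cluster x samples, on the row-centered scale
    centroid_corr: pd.Series  # gene -> Pearson rho with its cluster centroid
    top_genes: dict[int, list]  # cluster -> top-N genes at rho > threshold
    inertia: float


def kmeans_gene_clusters(
    profiles: pd.DataFrame,
    condition_of_sample: dict[str, str] | pd.Series,
    treated_label: str = "uvb",
    k: int = 2,
    seed: int = 0,
    top_n: int = 100,
    min_centroid_corr: float = 0.85,
) -> GeneClusterResult:
    """k-means (k = 2) clustering of row-centered DE-gene profiles.

    Rows (genes) are centered by subtracting their mean; Lloyd k-means runs
    with 25 restarts and tolerance 1e-6 at a fixed seed. Clusters are
    relabeled so cluster 1 has the larger mean treated-minus-control
    difference ("up-regulated" first). Per gene, the Pearson correlation with
    its cluster centroid is reported, and up to ``top_n`` genes per cluster
    with rho > ``min_centroid_corr`` are selected.
    """
    if len(profiles) < k:
        raise ValueError("need at least k genes")
    centered = profiles.sub(profiles.mean(axis=1), axis=0)
    if np.allclose(centered.to_numpy().std(axis=0).sum(), 0):
        raise ValueError("all row-centered profiles identical; clustering is degenerate")
    km = KMeans(n_clusters=k, n_init=25, tol=1e-6, random_state=seed, algorithm="lloyd")
    raw_labels = km.fit_predict(centered.to_numpy())

    cond = pd.Series(condition_of_sample)[profiles.columns]
    trt = centered.loc[:, cond == treated_label].mean(axis=1)
    ctl = centered.loc[:, cond != treated_label].mean(axis=1)
    diff = trt - ctl
    order = np.argsort(
        [-diff[raw_labels == c].mean() for c in range(k)], kind="stable"
    )  # descending treated-control difference
    relabel = {int(old): i + 1 for i, old in enumerate(order)}
    labels = pd.Series([relabel[int(c)] for c in raw_labels], index=profiles.index, name="cluster")

    centroids = centered.groupby(labels).mean()
    cvals = centered.to_numpy()
    cents = centroids.loc[labels].to_numpy()
    num = ((cvals - cvals.mean(1, keepdims=True)) * (cents - cents.mean(1, keepdims=True))).sum(1)
    den = np.sqrt(
        ((cvals - cvals.mean(1, keepdims=True)) ** 2).sum(1)
        * ((cents - cents.mean(1, keepdims=True)) ** 2).sum(1)
    )
    with np.errstate(invalid="ignore"):
        rho = np.where(den > 0, num / den, 0.0)
    centroid_corr = pd.Series(np.clip(rho, -1, 1), index=profiles.index, name="centroid_rho")

    top_genes = {}
    for c in centroids.index:
        members = centroid_corr[labels == c]
        eligible = members[members > min_centroid_corr].sort_values(ascending=False)
        top_genes[int(c)] = eligible.head(top_n).index.tolist()
    return GeneClusterResult(
        labels=labels,
        centroids=centroids,
        centroid_corr=centroid_corr,
        top_genes=top_genes,
        inertia=float(km.inertia_),
    )


def cluster_mean_anova(long_table: pd.DataFrame) -> pd.DataFrame:
    """Two-way ANOVA (treatment x time, Type-II SS) of per-replicate cluster
    means.

    ``long_table`` needs columns ``value``, ``treatment``, ``time``. Type-II
    sums of squares keep the decomposition order-invariant under the mild
    imbalance of a missing replicate. All-equal values report F = 0, p = 1.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for colname in ("value", "treatment", "time"):
        if colname not in long_table:
            raise ValueError(f"long_table must contain a {colname!r} column")
    if long_table.groupby(["treatment", "time"], observed=True).size().min() < 1:
        raise ValueError("every treatment x time cell needs at least one replicate")
    if np.ptp(long_table["value"].to_numpy()) == 0:
        idx = ["C(treatment)", "C(time)", "C(treatment):C(time)", "Residual"]
        return pd.DataFrame(
            {"sum_sq": 0.0, "df": np.nan, "F": [0.0, 0.0, 0.0, np.nan], "PR(>F)": [1.0, 1.0, 1.0, np.nan]},
            index=idx,
        )
    model = smf.ols("value ~ C(treatment) * C(time)", data=long_table).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return table


# ---------------------------------------------------------------------------
# single-cell condition DE
# ---------------------------------------------------------------------------


def volcano_call(q, log2fc, alpha: float = 0.05, min_abs_log2fc: float = 1.0) -> np.ndarray:
    """+1 / -1 / 0 volcano calls with strict inequalities at both thresholds."""
    q = np.asarray(q, float)
    log2fc = np.asarray(log2fc, float)
    call = np.zeros(q.shape, int)
    call[(q < alpha) & (log2fc > min_abs_log2fc)] = 1
    call[(q < alpha) & (log2fc < -min_abs_log2fc)] = -1
    return call


def sc_condition_de(
    adata: ad.AnnData,
    groupby: str = "cell_type",
    condition_key: str = "condition",
    treated: str = "uvb",
    control: str = "control",
    alpha: float = 0.05,
    min_abs_log2fc: float = 1.0,
    min_cells: int = 20,
) -> pd.DataFrame:
    """Treated-vs-control rank-sum DE within each cell type.

    Per gene: rank-sum p on log-normalized values, BH q across genes within
    the cell type, log2 ratio of normalized group means (pseudocount 1).
    ``call`` is +1 for q < alpha and log2FC > threshold, -1 for q < alpha and
    log2FC < -threshold (strict inequalities), else 0. Cell types with fewer
    than ``min_cells`` cells in either condition are skipped with a warning.
    """
    X = adata.X
    X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    norm = np.expm1(X)
    frames = []
    for ct, sub in adata.obs.groupby(groupby, observed=True):
        mask = adata.obs[groupby] == ct
        cond = adata.obs.loc[mask, condition_key]
        it = (cond == treated).to_numpy()
        ic = (cond == control).to_numpy()
        if it.sum() < min_cells or ic.sum() < min_cells:
            warnings.warn(f"group {ct!r} has < {min_cells} cells in a condition; skipped")
            continue
        Xg = X[np.asarray(mask)]
        ng = norm[np.asarray(mask)]
        res = stats.mannwhitneyu(Xg[it], Xg[ic], axis=0, alternative="two-sided", method="asymptotic")
        m_t = ng[it].mean(axis=0)
        m_c = ng[ic].mean(axis=0)
        log2fc = np.log2((m_t + 1.0) / (m_c + 1.0))
        q = benjamini_hochberg(res.pvalue)
        call = volcano_call(q, log2fc, alpha, min_abs_log2fc)
        frames.append(
            pd.DataFrame(
                {
                    "group": ct,
                    "gene": adata.var_names,
                    "p": res.pvalue,
                    "q": q,
                    "log2FC": log2fc,
                    "call": call,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=["group", "gene", "p", "q", "log2FC", "call"])
    return pd.concat(frames, ignore_index=True)
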