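"""Marker-signature assignment of coelomocyte cell types to cell clusters.

Cluster labels are an input (from any upstream clustering); each cluster is
scored by one-vs-rest rank-sum marker tests and mapped to one of the four
coelomocyte types — phagocytes, vibratile cells, red spherule cells (RSC) and
colorless spherule cells (CSC) — through a marker dictionary. RSC are defined
by Pks1; phagocytes by any of the SpTrf family, TLR family, SpC3 or Sp-B7L3;
vibratile cells by dynein heavy chain genes; CSC by a combined signature of
bactericidal permeability-increasing protein, lysozyme and strongylocin
together with non-significant Pks1/phagocyte markers. Rules are evaluated in
the fixed precedence RSC -> phagocyte -> vibratile -> CSC, since Pks1 is the
only definitive single marker and CSC are partly defined by exclusion.
"""

from __future__ import annotations

import fnmatch
import warnings
from dataclasses import dataclass, field

import anndata as ad
import numpy as np
import pandas as pd
from scipy import stats

from .stats_enrich import benjamini_hochberg, paired_t


@dataclass
class MarkerCallParams:
    """Marker-significance thresholds: BH-adjusted p and log2 fold-change
    (one-vs-rest, up-regulated side)."""

    alpha: float = 0.05
    min_log2fc: float = 0.5

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.min_log2fc <= 0:
            raise ValueError("thresholds must be > 0")


@dataclass
class MarkerRule:
    """One cell-type signature.

    ``required`` is a list of gene groups (patterns resolved by fnmatch
    against the matrix's gene identifiers). With ``mode="any"`` the rule fires
    if at least one group contains a significant marker; with ``mode="all"``
    every group must. Genes matched by ``excluded`` groups must all be
    non-significant for the rule to fire.
    """

    cell_type: str
    required: list[list[str]]
    mode: str = "any"
    excluded: list[list[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in ("any", "all"):
            raise ValueError("mode must be 'any' or 'all'")
        if not self.required or any(not g for g in self.required):
            raise ValueError("required groups must be non-empty")


PHAGOCYTE_GROUPS = [["SpTrf*"], ["Tlr*"], ["SpC3"], ["Sp-B7L3"]]


def default_marker_dictionary() -> list[MarkerRule]:
    """Default coelomocyte marker dictionary, in precedence order."""
    return [
        MarkerRule("red_spherule", required=[["Pks1"]]),
        MarkerRule("phagocyte", required=PHAGOCYTE_GROUPS, mode="any"),
        MarkerRule("vibratile", required=[["Dyhc*"]], mode="any"),
        MarkerRule(
            "colorless_spherule",
            required=[["Bpi*"], ["Lyz*"], ["StrCn*"]],
            mode="all",
            excluded=[["Pks1"]] + PHAGOCYTE_GROUPS,
        ),
    ]


def _resolve_group(patterns: list[str], gene_names) -> list[str]:
    hits: list[str] = []
    for pat in patterns:
        hits.extend(g for g in gene_names if fnmatch.fnmatchcase(g, pat))
    return hits


def rank_cluster_markers(
    adata: ad.AnnData,
    cluster_key: str = "cluster",
    params: MarkerCallParams | None = None,
    min_cells: int = 3,
) -> pd.DataFrame:
    """One-vs-rest marker statistics per cluster on log-normalized values.

    For every cluster x gene: a Wilcoxon rank-sum statistic of the cluster's
    cells against all other cells, the log2 fold-change of normalized means
    (pseudocount 1), BH-adjusted p within the cluster, and a significance flag
    (q < alpha and log2FC > min_log2fc). Clusters with fewer than ``min_cells``
    cells are excluded with a warning. ``adata.X`` must hold log1p-normalized
    values.
    """
    params = params or MarkerCallParams()
    clusters = pd.Categorical(adata.obs[cluster_key])
    if len(clusters.categories) < 2:
        raise ValueError("need at least two clusters for one-vs-rest testing")
    X = adata.X
    X = np.asarray(X.todense()) if hasattr(X, "todense") else np.asarray(X)
    norm = np.expm1(X)  # back to the normalized (pre-log) scale for means
    frames = []
    for cl in clusters.categories:
        mask = np.asarray(clusters == cl)
        if mask.sum() < min_cells:
            warnings.warn(f"cluster {cl!r} has < {min_cells} cells; excluded from marker ranking")
            continue
        res = stats.mannwhitneyu(
            X[mask], X[~mask], axis=0, alternative="two-sided", method="asymptotic"
        )
        m_in = norm[mask].mean(axis=0)
        m_out = norm[~mask].mean(axis=0)
        log2fc = np.log2((m_in + 1.0) / (m_out + 1.0))
        q = benjamini_hochberg(res.pvalue)
        frames.append(
            pd.DataFrame(
                {
                    "cluster": cl,
                    "gene": adata.var_names,
                    "statistic": res.statistic,
                    "p": res.pvalue,
                    "q": q,
                    "log2fc": log2fc,
                    "significant": (q < params.alpha) & (log2fc > params.min_log2fc),
                }
            )
        )
    if not frames:
        raise ValueError("no cluster had enough cells for marker ranking")
    return pd.concat(frames, ignore_index=True)


def assign_cell_types(
    marker_table: pd.DataFrame,
    dictionary: list[MarkerRule] | None = None,
) -> dict[str, str]:
    """Map each cluster to a coelomocyte type via the marker dictionary.

    Rules are evaluated in the dictionary's order; the first rule that fires
    wins. Clusters matching no rule are ``"unassigned"``. Raises if any
    dictionary group resolves to no gene in the marker table.
    """
    dictionary = dictionary if dictionary is not None else default_marker_dictionary()
    gene_names = marker_table["gene"].unique().tolist()
    missing = []
    for rule in dictionary:
        for group in rule.required + rule.excluded:
            if not _resolve_group(group, gene_names):
                missing.append((rule.cell_type, tuple(group)))
    if missing:
        raise ValueError(f"marker dictionary groups absent from the data: {missing}")

    assignment: dict[str, str] = {}
    for cl, sub in marker_table.groupby("cluster", observed=True):
        sig = set(sub.loc[sub["significant"], "gene"])
        assigned = "unassigned"
        for rule in dictionary:
            fires = [bool(set(_resolve_group(g, gene_names)) & sig) for g in rule.required]
            ok = any(fires) if rule.mode == "any" else all(fires)
            if ok and rule.excluded:
                ok = not any(set(_resolve_group(g, gene_names)) & sig for g in rule.excluded)
            if ok:
                assigned = rule.cell_type
                break
        assignment[str(cl)] = assigned
    return assignment


def cell_type_fractions(cell_table: pd.DataFrame, type_key: str = "cell_type") -> pd.DataFrame:
    """Per-sample cell-type fractions (samples x types, rows sum to 1).

    Every type present anywhere — including ``unassigned`` — appears as a
    column in every sample, with fraction 0 where absent.
    """
    counts = (
        cell_table.groupby(["sample", type_key], observed=True).size().unstack(fill_value=0)
    )
    return counts.div(counts.sum(axis=1), axis=0)


def compare_fractions(
    fractions: pd.DataFrame, condition_of_sample: dict[str, str] | pd.Series
) -> pd.DataFrame:
    """Two-sided paired t-test of each cell type's fraction across conditions.

    Samples are paired by their order within each condition (replicate 1 with
    replicate 1, etc.); both conditions must have equal sample counts. The
    report lists, per type, mean paired difference, t, two-sided p and a
    degenerate-variance flag (p = 1 when all paired differences are zero).
    """
    cond = pd.Series(condition_of_sample)
    levels = sorted(cond.unique())
    if len(levels) != 2:
        raise ValueError("exactly two conditions are required")
    a_samples = sorted(cond.index[cond == levels[0]])
    b_samples = sorted(cond.index[cond == levels[1]])
    if len(a_samples) != len(b_samples):
        raise ValueError("paired comparison needs equal sample counts per condition")
    rows = []
    for ct in fractions.columns:
        a = fractions.loc[a_samples, ct].to_numpy()
        b = fractions.loc[b_samples, ct].to_numpy()
        res = paired_t(b, a, direction="two-sided")  # condition-2 minus condition-1
        rows.append(
            {
                "cell_type": ct,
                "mean_diff": res["mean_diff"],
                "t": res["t"],
                "p": res["p"],
                "degenerate": res["degenerate"],
            }
        )
    return pd.DataFrame(rows)
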