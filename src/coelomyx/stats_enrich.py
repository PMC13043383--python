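"""Shared statistical primitives and gene-set over-representation.

Benjamini-Hochberg adjustment, the Wilcoxon rank-sum test, paired t-tests,
one-way ANOVA with Tukey HSD, and a GMT-driven hypergeometric
over-representation analysis with a STRING-like enrichment-strength score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Order-preserving, capped at 1. NaN entries are propagated as NaN and
    excluded from the number of tests m.
    """
    p = np.asarray(pvalues, float)
    out = np.full(p.shape, np.nan)
    valid = ~np.isnan(p)
    pv = p[valid]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    res = np.empty(m)
    res[order] = np.minimum(adj, 1.0)
    out[valid] = res
    return out


# ---------------------------------------------------------------------------
# gene sets / ORA
# ---------------------------------------------------------------------------


@dataclass
class GeneSetCollection:
    """Named gene sets harmonized against a background universe.

    Sets are intersected with the universe; sets that become empty are dropped
    with a warning.
    """

    sets: dict[str, set] = field(default_factory=dict)
    universe: set = field(default_factory=set)

    def __post_init__(self) -> None:
        self.universe = set(self.universe)
        harmonized = {}
        for name, genes in self.sets.items():
            kept = set(genes) & self.universe
            if not kept:
                warnings.warn(f"gene set {name!r} is empty after harmonization; dropped")
                continue
            harmonized[name] = kept
        self.sets = harmonized

    @classmethod
    def from_gmt(cls, path, universe=None) -> "GeneSetCollection":
        """Read tab-separated GMT (name, description, genes...)."""
        sets: dict[str, set] = {}
        genes_seen: set = set()
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                sets[parts[0]] = set(g for g in parts[2:] if g)
                genes_seen |= sets[parts[0]]
        return cls(sets=sets, universe=set(universe) if universe is not None else genes_seen)


def hypergeometric_ora(query, collection: GeneSetCollection) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each set.

    The enrichment strength is log10((overlap/query)/(set/universe)), a
    fold-enrichment on the log scale. BH adjustment is across sets.
    """
    query = set(query)
    if not query <= collection.universe:
        raise ValueError("query genes must be a subset of the universe")
    if not query:
        return pd.DataFrame(
            columns=["set", "overlap", "set_size", "query_size", "universe_size", "p", "q", "strength"]
        )
    M, N = len(collection.universe), len(query)
    rows = []
    for name, genes in collection.sets.items():
        k = len(genes & query)
        n = len(genes)
        p = float(stats.hypergeom.sf(k - 1, M, n, N)) if k > 0 else 1.0
        strength = np.log10((k / N) / (n / M)) if k > 0 else -np.inf
        rows.append(
            {
                "set": name,
                "overlap": k,
                "set_size": n,
                "query_size": N,
                "universe_size": M,
                "p": min(p, 1.0),
                "strength": strength,
            }
        )
    table = pd.DataFrame(rows)
    table["q"] = benjamini_hochberg(table["p"])
    return table[["set", "overlap", "set_size", "query_size", "universe_size", "p", "q", "strength"]]


# ---------------------------------------------------------------------------
# two-sample and paired tests
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided") -> dict:
    """Wilcoxon rank-sum (Mann-Whitney U) with midranks for ties.

    Exact p for combined n <= 20 without ties; normal approximation with tie
    correction otherwise. Identical pooled values give p = 1.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each group needs at least one observation")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return {"statistic": float(x.size * y.size / 2.0), "p": 1.0, "method": "degenerate"}
    has_ties = np.unique(pooled).size < pooled.size
    if pooled.size <= 20 and not has_ties:
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="exact")
        method = "exact"
    else:
        res = stats.mannwhitneyu(x, y, alternative=alternative, method="asymptotic")
        method = "asymptotic"
    return {"statistic": float(res.statistic), "p": float(res.pvalue), "method": method}


def paired_t(pairs_a, pairs_b, direction: str = "two-sided") -> dict:
    """Paired t-test on differences a - b.

    ``direction`` is ``"greater"``/``"less"`` for the one-tailed variants or
    ``"two-sided"``. Zero-variance differences are flagged degenerate with
    p = 1 when all differences are zero, otherwise p = 0 or 1 by direction.
    """
    a = np.asarray(pairs_a, float)
    b = np.asarray(pairs_b, float)
    if a.shape != b.shape or a.size < 2:
        raise ValueError("need >= 2 matched pairs")
    d = a - b
    if np.ptp(d) == 0:
        if d[0] == 0:
            return {"t": 0.0, "p": 1.0, "mean_diff": 0.0, "degenerate": True}
        sign = np.sign(d[0])
        if direction == "two-sided":
            p = 0.0
        elif direction == "greater":
            p = 0.0 if sign > 0 else 1.0
        else:
            p = 0.0 if sign < 0 else 1.0
        return {"t": float(sign * np.inf), "p": p, "mean_diff": float(d.mean()), "degenerate": True}
    res = stats.ttest_rel(a, b, alternative=direction)
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "mean_diff": float(d.mean()),
        "degenerate": False,
    }


def paired_t_one_tailed(pairs_a, pairs_b, direction: str = "greater") -> dict:
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    return paired_t(pairs_a, pairs_b, direction=direction)


def oneway_anova_tukey(groups: dict) -> dict:
    """One-way ANOVA with post-hoc Tukey HSD over all group pairs.

    ``groups`` maps group name -> 1d sample. All-identical data reports F = 0,
    p = 1 with all pairwise Tukey p = 1.
    """
    names = list(groups)
    arrays = [np.asarray(groups[n], float) for n in names]
    if len(arrays) < 2:
        raise ValueError("need at least two groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two observations")
    pooled = np.concatenate(arrays)
    pairs = [(names[i], names[j]) for i in range(len(names)) for j in range(i + 1, len(names))]
    if np.ptp(pooled) == 0:
        tukey_p = pd.Series({p: 1.0 for p in pairs})
        return {"F": 0.0, "p": 1.0, "tukey": tukey_p}
    F, p = stats.f_oneway(*arrays)
    if not np.isfinite(F):
        F, p = 0.0, 1.0
    hsd = stats.tukey_hsd(*arrays)
    tukey_p = pd.Series(
        {pair: float(hsd.pvalue[names.index(pair[0]), names.index(pair[1])]) for pair in pairs}
    )
    return {"F": float(F), "p": float(p), "tukey": tukey_p}
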