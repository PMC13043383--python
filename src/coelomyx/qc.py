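"""Single-cell quality control and normalization.

Cells are filtered on total UMI counts by a median +/- n*MAD rule, genes by a
minimum detected-cell count, and the surviving matrix is depth-normalized to
the median cell total and log1p-transformed (raw counts are kept in
``layers["counts"]``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scanpy as sc


@dataclass
class QCParams:
    """QC thresholds. ``n_mads``: half-width of the total-count acceptance
    window in median absolute deviations; ``min_cells_per_gene``: minimum
    number of cells a gene must be detected in."""

    n_mads: float = 5.0
    min_cells_per_gene: int = 50
    pseudocount: float = 1.0

    def __post_init__(self) -> None:
        if self.n_mads <= 0:
            raise ValueError("n_mads must be > 0")
        if self.min_cells_per_gene < 0:
            raise ValueError("min_cells_per_gene must be >= 0")


def _totals(adata: ad.AnnData) -> np.ndarray:
    X = adata.X
    return np.asarray(X.sum(axis=1)).ravel() if hasattr(X, "tocsr") else X.sum(axis=1)


def filter_cells_mad(
    adata: ad.AnnData, params: QCParams | None = None
) -> tuple[ad.AnnData, pd.DataFrame]:
    """Remove cells whose total counts fall beyond ``n_mads`` absolute
    deviations of the median total.

    The MAD is the unscaled median of absolute deviations from the median of
    raw totals; removal is two-sided and strict (totals exactly at a bound are
    kept). If the MAD is zero but totals differ, the mean absolute deviation
    is used instead (with a warning); identical totals remove nothing.

    Returns the filtered view (copied) and a report listing removed cell IDs,
    their totals and the acceptance bounds.
    """
    params = params or QCParams()
    if adata.n_obs < 3:
        raise ValueError("need at least 3 cells for MAD-based filtering")
    totals = _totals(adata)
    med = np.median(totals)
    mad = np.median(np.abs(totals - med))
    if mad == 0 and np.ptp(totals) > 0:
        mad = np.mean(np.abs(totals - med))
        warnings.warn(
            "MAD of totals is zero with non-identical totals; "
            "falling back to the mean absolute deviation"
        )
    lo, hi = med - params.n_mads * mad, med + params.n_mads * mad
    keep = (totals >= lo) & (totals <= hi)
    report = pd.DataFrame(
        {
            "cell_id": adata.obs_names[~keep],
            "total_counts": totals[~keep],
            "lower_bound": lo,
            "upper_bound": hi,
        }
    )
    return adata[keep].copy(), report


def filter_genes_min_cells(adata: ad.AnnData, params: QCParams | None = None) -> ad.AnnData:
    """Drop genes detected (count > 0) in fewer than ``min_cells_per_gene``
    cells; the order of surviving genes is preserved."""
    params = params or QCParams()
    out = adata.copy()
    sc.pp.filter_genes(out, min_cells=params.min_cells_per_gene)
    if out.n_vars == 0:
        raise ValueError(
            "no genes survive the min-cells filter; lower min_cells_per_gene"
        )
    return out


def normalize_log(adata: ad.AnnData) -> ad.AnnData:
    """Scale each cell to the median pre-normalization total, then log1p.

    Raw counts are retained in ``layers["counts"]``; the normalized (pre-log)
    matrix is in ``layers["normalized"]`` and ``X`` holds log1p values.
    """
    totals = _totals(adata)
    if np.any(totals <= 0):
        raise ValueError("zero-total cell encountered; run cell QC first")
    out = adata.copy()
    out.layers["counts"] = out.X.copy()
    sc.pp.normalize_total(out, target_sum=None)  # scanpy's None target = median total
    out.layers["normalized"] = out.X.copy()
    sc.pp.log1p(out)
    return out
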