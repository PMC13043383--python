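"""Synthetic data generation for the coelomocyte UVB-response pipeline.

Everything downstream of sequencing is testable without the deposited data:
this module emits UMI count matrices with the statistical structure the
analysis assumes (Poisson thinning of correlated latent expression with
cell-specific depths), bulk negative-binomial count tables, and small image /
dose-response fixtures for the functional assays.

Measurement model for single cells: a cell i of type t under condition c
carries a latent relative-expression vector z_i with E z_ij = mu_j and
Cov(z_ij, z_ik) = sigma_jk; observed counts are X_ij ~ Poisson(s_i * z_ij)
where s_i is the cell's sequencing depth. Latent marginals are gamma, coupled
through a Gaussian copula whose correlation is taken as the "true" rho for
recovery tests.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field, asdict

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

CELL_TYPES = ("phagocyte", "vibratile", "red_spherule", "colorless_spherule")

#: control-condition cell-type proportions used as generator defaults
DEFAULT_PROPORTIONS = {
    "phagocyte": 0.79,
    "vibratile": 0.07,
    "red_spherule": 0.06,
    "colorless_spherule": 0.08,
}

#: marker genes planted per cell type (elevated by ``marker_fold`` in that type)
DEFAULT_MARKERS = {
    "red_spherule": ["Pks1"],
    "phagocyte": ["SpTrf-E1", "SpTrf-A6", "Tlr1", "Tlr4", "SpC3", "Sp-B7L3"],
    "vibratile": ["Dyhc1", "Dyhc2", "Sp-P2rx4", "FoxJ1"],
    "colorless_spherule": ["Bpi", "Lyz1", "StrCn1"],
}


class CovarianceRepairError(ValueError):
    """Latent covariance could not be made positive semi-definite."""


# ---------------------------------------------------------------------------
# designs and latent model
# ---------------------------------------------------------------------------


@dataclass
class DCPair:
    """A planted differential-co-expression gene pair (phagocyte-specific)."""

    gene_j: str
    gene_k: str
    rho_control: float
    rho_treated: float


@dataclass
class LatentModel:
    """Latent expression model: gene means, dispersions and copula correlation.

    ``sigma_jj`` is parameterized through a per-gene coefficient of variation
    so that condition- or type-specific mean shifts preserve relative
    dispersion: sigma_jj = (cv_j * mu_j)**2.
    """

    gene_names: list[str]
    mu: np.ndarray  # (G,) relative expression, > 0
    cv: np.ndarray  # (G,) latent coefficient of variation, >= 0
    corr: np.ndarray  # (G, G) latent (copula) correlation
    markers: dict[str, list[str]] = field(default_factory=dict)
    marker_fold: float = 8.0
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> log2 shift (treated)
    dc_pairs: list[DCPair] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, float)
        self.cv = np.asarray(self.cv, float)
        self.corr = np.asarray(self.corr, float)
        if np.any(self.mu <= 0):
            raise ValueError("all latent gene means must be > 0")
        if np.any(self.cv < 0):
            raise ValueError("latent CVs must be >= 0")
        if self.corr.shape != (len(self.gene_names),) * 2:
            raise ValueError("correlation matrix shape does not match gene count")
        if np.any(np.abs(self.corr) > 1 + 1e-12):
            raise ValueError("latent correlations must lie in [-1, 1]")

    @property
    def sigma(self) -> np.ndarray:
        """Implied latent covariance matrix sigma_jk = cv_j mu_j cv_k mu_k rho_jk."""
        sd = self.cv * self.mu
        return np.outer(sd, sd) * self.corr

    def index_of(self, gene: str) -> int:
        return self.gene_names.index(gene)


@dataclass
class CohortDesign:
    """Two-condition single-cell cohort layout (control vs UVB-treated)."""

    n_cells_per_sample: int = 1000
    n_samples_per_condition: int = 3
    proportions: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    depth_mean: float = 5000.0
    depth_cv: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells_per_sample <= 0:
            raise ValueError("n_cells_per_sample must be > 0")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-8:
            raise ValueError(f"cell-type proportions must sum to 1 (got {total})")


@dataclass
class BulkDesign:
    """Bulk RNA-seq layout: conditions x timepoints x replicates NB counts."""

    n_genes: int = 2000
    conditions: tuple[str, str] = ("control", "uvb")
    timepoints: tuple = (0, 1, 3, 6, 24)
    n_replicates: int = 3
    mean_log: float = np.log(100.0)
    mean_sdlog: float = 1.0
    dispersion: float = 0.05
    de_fraction: float = 0.1
    de_log2fc: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")


def nearest_psd_correlation(corr: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Repair a symmetric matrix to the nearest PSD correlation by eigenvalue
    clipping at 0 (applied once), restoring a unit diagonal afterwards.

    Raises :class:`CovarianceRepairError` naming the worst offending pairs if
    the result is still indefinite.
    """
    corr = (corr + corr.T) / 2.0
    vals, vecs = np.linalg.eigh(corr)
    if vals.min() >= -tol:
        return corr
    vals = np.clip(vals, 0.0, None)
    repaired = (vecs * vals) @ vecs.T
    d = np.sqrt(np.clip(np.diag(repaired), tol, None))
    repaired = repaired / np.outer(d, d)
    np.fill_diagonal(repaired, 1.0)
    check = np.linalg.eigvalsh((repaired + repaired.T) / 2.0)
    if check.min() < -1e-8 or not np.all(np.isfinite(repaired)):
        off = np.abs(corr - np.eye(len(corr)))
        jj, kk = np.unravel_index(np.argsort(off, axis=None)[::-1][:3], off.shape)
        pairs = [(int(j), int(k)) for j, k in zip(jj, kk)]
        raise CovarianceRepairError(
            f"correlation matrix not PSD after repair; offending pairs (by |rho|): {pairs}"
        )
    return repaired


def default_latent_model(
    n_genes: int = 200,
    seed: int = 0,
    marker_fold: float = 8.0,
    n_de_genes: int = 20,
    de_log2fc: float = 2.0,
    n_dc_pairs: int = 5,
    dc_rho_control: float = 0.0,
    dc_rho_treated: float = 0.6,
    base_cv: float = 0.45,
) -> LatentModel:
    """Construct the default cohort latent model with planted structure.

    Marker genes for the four coelomocyte types, condition-DE genes and
    phagocyte-specific differential co-expression pairs are planted on top of
    independent background genes; relative gene means are log-normal and
    normalized to sum to 1.
    """
    rng = np.random.default_rng(seed)
    markers = {t: list(g) for t, g in DEFAULT_MARKERS.items()}
    marker_names = [g for gl in markers.values() for g in gl]
    dc_names = [f"Dc{i}{s}" for i in range(n_dc_pairs) for s in ("a", "b")]
    de_names = [f"De{i}" for i in range(n_de_genes)]
    n_bg = n_genes - len(marker_names) - len(dc_names) - len(de_names)
    if n_bg < 0:
        raise ValueError("n_genes too small for the planted structure")
    gene_names = marker_names + de_names + dc_names + [f"Bg{i}" for i in range(n_bg)]

    mu = rng.lognormal(mean=0.0, sigma=1.0, size=len(gene_names))
    mu /= mu.sum()
    cv = np.full(len(gene_names), base_cv)
    corr = np.eye(len(gene_names))
    de_genes = {g: de_log2fc for g in de_names}
    dc_pairs = [
        DCPair(f"Dc{i}a", f"Dc{i}b", dc_rho_control, dc_rho_treated)
        for i in range(n_dc_pairs)
    ]
    return LatentModel(
        gene_names=gene_names,
        mu=mu,
        cv=cv,
        corr=corr,
        markers=markers,
        marker_fold=marker_fold,
        de_genes=de_genes,
        dc_pairs=dc_pairs,
    )


# ---------------------------------------------------------------------------
# latent draws
# ---------------------------------------------------------------------------


def _gamma_copula_draw(
    rng: np.random.Generator, n: int, mu: np.ndarray, cv: np.ndarray, corr: np.ndarray
) -> np.ndarray:
    """Draw n latent vectors with gamma marginals (mean mu, CV cv) coupled by a
    Gaussian copula with the given correlation. Genes with cv = 0 are constant."""
    G = len(mu)
    corr = nearest_psd_correlation(corr)
    vals, vecs = np.linalg.eigh(corr)
    root = vecs * np.sqrt(np.clip(vals, 0.0, None))
    y = rng.standard_normal((n, G)) @ root.T
    u = stats.norm.cdf(y)
    # avoid exactly 0/1 quantiles
    u = np.clip(u, 1e-12, 1 - 1e-12)
    z = np.empty((n, G))
    pos = cv > 0
    if np.any(pos):
        shape = 1.0 / cv[pos] ** 2
        scale = mu[pos] * cv[pos] ** 2
        z[:, pos] = stats.gamma.ppf(u[:, pos], shape[None, :], scale=scale[None, :])
    z[:, ~pos] = mu[~pos]
    return z


def draw_depths(rng: np.random.Generator, n: int, mean: float, cv: float) -> np.ndarray:
    """Log-normal sequencing depths rescaled so the distribution mean equals
    ``mean`` (CV on the natural scale is ``cv``)."""
    if cv <= 0:
        return np.full(n, float(mean))
    sdlog = np.sqrt(np.log1p(cv**2))
    mulog = np.log(mean) - sdlog**2 / 2.0
    return rng.lognormal(mulog, sdlog, size=n)


def _group_params(model: LatentModel, cell_type: str, condition: str):
    """Mean vector and copula correlation for one (cell type, condition) group."""
    mu = model.mu.copy()
    for g in model.markers.get(cell_type, []):
        mu[model.index_of(g)] *= model.marker_fold
    if condition != "control":
        for g, shift in model.de_genes.items():
            mu[model.index_of(g)] *= 2.0**shift
    corr = model.corr.copy()
    for pair in model.dc_pairs:
        j, k = model.index_of(pair.gene_j), model.index_of(pair.gene_k)
        if cell_type == "phagocyte":
            rho = pair.rho_treated if condition != "control" else pair.rho_control
        else:
            rho = pair.rho_control
        corr[j, k] = corr[k, j] = rho
    return mu, corr


def simulate_single_cell_cohort(
    design: CohortDesign, model: LatentModel
) -> tuple[ad.AnnData, pd.DataFrame, dict]:
    """Simulate a two-condition single-cell cohort.

    Returns ``(adata, cell_table, truth)`` where ``adata`` holds sparse UMI
    counts (cells x genes) with per-cell sample/condition/cluster labels,
    ``cell_table`` mirrors ``adata.obs`` and ``truth`` records the planted
    markers, DE genes, DC pairs and the latent depths. Regeneration with the
    same design seed is bit-identical.
    """
    rng = np.random.default_rng(design.seed)
    types = list(design.proportions)
    probs = np.array([design.proportions[t] for t in types])
    conditions = ["control", "uvb"]
    samples = [
        (c, f"{c}_{i + 1}")
        for c in conditions
        for i in range(design.n_samples_per_condition)
    ]

    rows_X, rows_obs = [], []
    for condition, sample in samples:
        n = design.n_cells_per_sample
        type_idx = rng.choice(len(types), size=n, p=probs)
        depths = draw_depths(rng, n, design.depth_mean, design.depth_cv)
        X = np.zeros((n, len(model.gene_names)))
        for ti, t in enumerate(types):
            sel = np.flatnonzero(type_idx == ti)
            if sel.size == 0:
                continue
            mu, corr = _group_params(model, t, condition)
            z = _gamma_copula_draw(rng, sel.size, mu, model.cv, corr)
            X[sel] = rng.poisson(depths[sel, None] * z)
        rows_X.append(X)
        rows_obs.append(
            pd.DataFrame(
                {
                    "cell_id": [f"{sample}_c{i}" for i in range(n)],
                    "sample": sample,
                    "condition": condition,
                    "cluster": [f"cl{ti}" for ti in type_idx],
                    "cell_type_true": [types[ti] for ti in type_idx],
                    "depth_true": depths,
                }
            )
        )

    obs = pd.concat(rows_obs, ignore_index=True).set_index("cell_id")
    X = sp.csr_matrix(np.vstack(rows_X).astype(np.int64))
    adata = ad.AnnData(
        X=X, obs=obs, var=pd.DataFrame(index=pd.Index(model.gene_names, name="gene"))
    )
    adata.uns["simdata"] = {
        "seed": int(design.seed),
        "n_cells_per_sample": int(design.n_cells_per_sample),
        "proportions": dict(design.proportions),
        "depth_mean": float(design.depth_mean),
        "depth_cv": float(design.depth_cv),
    }
    truth = {
        "markers": {t: list(g) for t, g in model.markers.items()},
        "marker_fold": model.marker_fold,
        "de_genes": dict(model.de_genes),
        "dc_pairs": [asdict(p) for p in model.dc_pairs],
        "cluster_to_type": {f"cl{i}": t for i, t in enumerate(types)},
    }
    return adata, obs.reset_index(), truth


# ---------------------------------------------------------------------------
# bulk counts
# ---------------------------------------------------------------------------


def simulate_bulk_experiment(design: BulkDesign) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate an NB bulk count table over conditions x timepoints x replicates.

    Planted DE genes receive a ``de_log2fc`` mean shift in the non-control
    condition at every timepoint. Returns ``(counts, truth)`` with genes as
    rows; truth lists per-gene DE status and the planted log2 fold change.
    """
    rng = np.random.default_rng(design.seed)
    genes = [f"g{i}" for i in range(design.n_genes)]
    base_mean = rng.lognormal(design.mean_log, design.mean_sdlog, size=design.n_genes)
    n_de = int(round(design.de_fraction * design.n_genes))
    de_idx = rng.choice(design.n_genes, size=n_de, replace=False)
    is_de = np.zeros(design.n_genes, bool)
    is_de[de_idx] = True

    cols, data = [], []
    for cond in design.conditions:
        mu = base_mean.copy()
        if cond != design.conditions[0]:
            mu[is_de] *= 2.0**design.de_log2fc
        for tp in design.timepoints:
            for r in range(design.n_replicates):
                cols.append(f"{cond}_T{tp}_R{r + 1}")
                if design.dispersion == 0:
                    counts = rng.poisson(mu)
                else:
                    lam = rng.gamma(1.0 / design.dispersion, mu * design.dispersion)
                    counts = rng.poisson(lam)
                data.append(counts)
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    truth = pd.DataFrame(
        {
            "gene": genes,
            "base_mean": base_mean,
            "is_de": is_de,
            "log2fc": np.where(is_de, design.de_log2fc, 0.0),
        }
    ).set_index("gene")
    return counts, truth


# ---------------------------------------------------------------------------
# assay fixtures
# ---------------------------------------------------------------------------

#: UVB doses (mJ/cm^2) used for the dose-response viability layout
DEFAULT_DOSES = (0.0, 1000.0, 2000.0, 4000.0, 6000.0, 9999.0)


def _dose_response_fixture(params: dict, rng: np.random.Generator):
    ld50 = float(params.get("ld50", 1000.0))
    hill = float(params.get("hill", 2.0))
    top = float(params.get("top", 100.0))
    noise_cv = float(params.get("noise_cv", 0.0))
    replicates = int(params.get("replicates", 3))
    doses = np.asarray(params.get("doses", DEFAULT_DOSES), float)
    rows = []
    for d in doses:
        v = top / (1.0 + (d / ld50) ** hill) if d > 0 else top
        for r in range(replicates):
            obs = v * (1.0 + noise_cv * rng.standard_normal()) if noise_cv > 0 else v
            rows.append({"dose": d, "replicate": r + 1, "viability": max(obs, 0.0)})
    table = pd.DataFrame(rows)
    truth = {"ld50": ld50, "hill": hill, "top": top}
    return {"table": table, "truth": truth}


def _comet_fixture(params: dict, rng: np.random.Generator):
    head_sum = int(params.get("head_sum", 900))
    tail_sum = int(params.get("tail_sum", 100))
    shape = tuple(params.get("shape", (64, 128)))
    img = np.zeros(shape, np.uint32)
    head = np.zeros(shape, bool)
    tail = np.zeros(shape, bool)
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    head[(yy - shape[0] // 2) ** 2 + (xx - shape[0] // 2) ** 2 <= (shape[0] // 4) ** 2] = True
    tail[
        (abs(yy - shape[0] // 2) <= shape[0] // 6)
        & (xx > shape[0] // 2 + shape[0] // 4)
        & (xx < shape[1] - 4)
    ] = True
    for mask, total in ((head, head_sum), (tail, tail_sum)):
        idx = np.flatnonzero(mask.ravel())
        base, extra = divmod(total, idx.size)
        vals = np.full(idx.size, base, np.uint32)
        vals[:extra] += 1  # distribute the remainder; sums are exact
        img.ravel()[idx] = vals
    pct = 100.0 * tail_sum / (head_sum + tail_sum)
    return {
        "image": img,
        "head_mask": head,
        "tail_mask": tail,
        "truth": {"head_sum": head_sum, "tail_sum": tail_sum, "tail_percent": pct},
    }


def _puncta_fixture(params: dict, rng: np.random.Generator):
    n_nuclei = int(params.get("n_nuclei", 12))
    n_puncta = int(params.get("n_puncta", 40))
    shape = tuple(params.get("shape", (256, 256)))
    nucleus_radius = int(params.get("nucleus_radius", 6))
    punctum_side = int(params.get("punctum_side", 2))
    puncta_value = int(params.get("puncta_value", 200))

    nuclei_img = rng.integers(0, 8, size=shape).astype(np.uint8)
    signal_img = rng.integers(0, 4, size=shape).astype(np.uint8)
    yy, xx = np.mgrid[: shape[0], : shape[1]]

    # nuclei: well-separated disks (rejection sampling, seeded)
    centers: list[tuple[int, int]] = []
    margin = nucleus_radius + 2
    while len(centers) < n_nuclei:
        cy = int(rng.integers(margin, shape[0] - margin))
        cx = int(rng.integers(margin, shape[1] - margin))
        if all((cy - y) ** 2 + (cx - x) ** 2 > (4 * nucleus_radius) ** 2 for y, x in centers):
            centers.append((cy, cx))
    for cy, cx in centers:
        nuclei_img[(yy - cy) ** 2 + (xx - cx) ** 2 <= nucleus_radius**2] = 220

    # puncta: non-overlapping small squares of constant intensity
    placed: list[tuple[int, int]] = []
    while len(placed) < n_puncta:
        py = int(rng.integers(1, shape[0] - punctum_side - 1))
        px = int(rng.integers(1, shape[1] - punctum_side - 1))
        if all(abs(py - y) > 2 * punctum_side or abs(px - x) > 2 * punctum_side for y, x in placed):
            placed.append((py, px))
            signal_img[py : py + punctum_side, px : px + punctum_side] = puncta_value
    area = punctum_side**2
    truth = {
        "n_nuclei": n_nuclei,
        "n_puncta": n_puncta,
        "punctum_area": area,
        "puncta_value": puncta_value,
        "integrated_density": n_puncta * area * puncta_value,
        "density_per_nucleus": n_puncta * area * puncta_value / n_nuclei,
    }
    return {"signal": signal_img, "nuclei": nuclei_img, "truth": truth}


ASSAY_KINDS = ("dose_response", "comet_masks", "puncta_image")


def simulate_assay_fixtures(kind: str, params: dict | None = None, seed: int = 0, outdir=None):
    """Generate a functional-assay fixture with a known ground truth.

    ``kind`` is one of ``dose_response`` (3-parameter logistic viability
    table), ``comet_masks`` (intensity image with head/tail label masks of
    exactly known integrated intensity) or ``puncta_image`` (two-channel
    autophagy image with known puncta and nuclei counts). If ``outdir`` is
    given, CSV/PNG files plus a YAML truth sidecar are written there.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "dose_response":
        out = _dose_response_fixture(params, rng)
    elif kind == "comet_masks":
        out = _comet_fixture(params, rng)
    elif kind == "puncta_image":
        out = _puncta_fixture(params, rng)
    else:
        raise ValueError(f"unknown fixture kind {kind!r}; expected one of {ASSAY_KINDS}")
    out["truth"]["seed"] = int(seed)
    if outdir is not None:
        _write_fixture(kind, out, outdir)
    return out


def _write_fixture(kind: str, out: dict, outdir) -> None:
    import os

    import imageio.v3 as iio
    import yaml

    os.makedirs(outdir, exist_ok=True)
    if kind == "dose_response":
        out["table"].to_csv(os.path.join(outdir, "dose_response.csv"), index=False)
    elif kind == "comet_masks":
        iio.imwrite(os.path.join(outdir, "comet_image.png"), out["image"].astype(np.uint16))
        iio.imwrite(
            os.path.join(outdir, "comet_head_mask.png"),
            (out["head_mask"] * 255).astype(np.uint8),
        )
        iio.imwrite(
            os.path.join(outdir, "comet_tail_mask.png"),
            (out["tail_mask"] * 255).astype(np.uint8),
        )
    elif kind == "puncta_image":
        iio.imwrite(os.path.join(outdir, "puncta_signal.png"), out["signal"])
        iio.imwrite(os.path.join(outdir, "puncta_nuclei.png"), out["nuclei"])
    with open(os.path.join(outdir, f"{kind}_truth.yaml"), "w") as fh:
        yaml.safe_dump(out["truth"], fh)


# ---------------------------------------------------------------------------
# on-disk interchange (MTX triplet + TSV sidecars + YAML params)
# ---------------------------------------------------------------------------


def write_cohort(adata: ad.AnnData, outdir) -> None:
    """Write a cohort as MatrixMarket triplet + genes.tsv/cells.tsv + YAML sidecar."""
    import os

    import yaml
    from scipy.io import mmwrite

    os.makedirs(outdir, exist_ok=True)
    mmwrite(os.path.join(outdir, "matrix.mtx"), sp.coo_matrix(adata.X))
    pd.Series(adata.var_names, name="gene").to_csv(
        os.path.join(outdir, "genes.tsv"), sep="\t", index=False
    )
    adata.obs.reset_index().to_csv(os.path.join(outdir, "cells.tsv"), sep="\t", index=False)
    params = adata.uns.get("simdata", {})
    with open(os.path.join(outdir, "params.yaml"), "w") as fh:
        yaml.safe_dump(params, fh)


def read_cohort(indir) -> ad.AnnData:
    import os

    from scipy.io import mmread

    X = sp.csr_matrix(mmread(os.path.join(indir, "matrix.mtx")))
    genes = pd.read_csv(os.path.join(indir, "genes.tsv"), sep="\t")["gene"].astype(str)
    obs = pd.read_csv(os.path.join(indir, "cells.tsv"), sep="\t").set_index("cell_id")
    return ad.AnnData(X=X, obs=obs, var=pd.DataFrame(index=pd.Index(genes, name="gene")))
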