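"""Quantification of the functional readouts.

Three-parameter logistic dose-response (LD50) fitting, comet-assay tail-DNA
percent, fluorescence image thresholding (Otsu / triangle) with
nuclei-normalized integrated puncta density, and western-blot densitometry
normalization against a beta-actin loading control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

NO_KILL = float("inf")


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------


@dataclass
class DoseResponseFit:
    """Three-parameter logistic fit V(d) = V_max / (1 + (d / LD50)^h)."""

    ld50: float
    hill: float
    top: float
    residual_ss: float
    converged: bool
    no_kill: bool = False


def logistic3(dose, ld50, hill, top):
    dose = np.asarray(dose, float)
    with np.errstate(divide="ignore"):
        ratio = np.where(dose > 0, dose / ld50, 0.0)
        return top / (1.0 + ratio**hill)


def fit_ld50_3param(table: pd.DataFrame) -> DoseResponseFit:
    """Least-squares fit of the three-parameter logistic to a dose-viability
    table (columns ``dose`` and ``viability``; the zero dose anchors the top
    asymptote).

    Multi-start over log-spaced LD50 initials crossed with Hill slopes
    {0.5, 1, 2, 4}; the best converged fit is returned. A table whose
    viability does not decrease with dose gets the no-kill sentinel
    (LD50 = +inf).
    """
    if table["dose"].nunique() < 4 or 0 not in table["dose"].values:
        raise ValueError("need >= 4 dose levels including dose 0")
    dose = table["dose"].to_numpy(float)
    viab = table["viability"].to_numpy(float)

    means = table.groupby("dose")["viability"].mean().sort_index()
    if means.diff().dropna().min() >= 0:  # viability never drops with dose
        return DoseResponseFit(NO_KILL, np.nan, float(means.iloc[0]), 0.0, True, no_kill=True)

    top0 = float(means.loc[0])
    pos = dose[dose > 0]
    ld50_grid = np.geomspace(pos.min(), pos.max(), 6)
    best = None
    for ld0 in ld50_grid:
        for h0 in (0.5, 1.0, 2.0, 4.0):
            try:
                res = optimize.least_squares(
                    lambda th: logistic3(dose, np.exp(th[0]), th[1], th[2]) - viab,
                    x0=[np.log(ld0), h0, top0],
                    bounds=([np.log(pos.min() / 100), 0.05, 0.0], [np.log(pos.max() * 100), 20.0, np.inf]),
                )
            except Exception:
                continue
            ss = float(2 * res.cost)
            if best is None or ss < best[0]:
                best = (ss, res)
    if best is None:
        return DoseResponseFit(np.nan, np.nan, np.nan, np.nan, False)
    ss, res = best
    return DoseResponseFit(
        ld50=float(np.exp(res.x[0])),
        hill=float(res.x[1]),
        top=float(res.x[2]),
        residual_ss=ss,
        converged=bool(res.success),
    )


# ---------------------------------------------------------------------------
# comet assay
# ---------------------------------------------------------------------------


@dataclass
class CometRecord:
    head_intensity: float
    tail_intensity: float
    tail_percent: float
    valid: bool = True


def comet_tail_percent(image, head_mask, tail_mask) -> CometRecord:
    """Tail DNA percent: 100 * tail / (head + tail) integrated intensity.

    Masks must be disjoint; zero total intensity is flagged undefined.
    """
    image = np.asarray(image, float)
    head_mask = np.asarray(head_mask, bool)
    tail_mask = np.asarray(tail_mask, bool)
    if np.any(head_mask & tail_mask):
        raise ValueError("head and tail masks overlap")
    head = float(image[head_mask].sum())
    tail = float(image[tail_mask].sum())
    total = head + tail
    if total == 0:
        return CometRecord(head, tail, np.nan, valid=False)
    return CometRecord(head, tail, 100.0 * tail / total)


def comet_slide_mean(records: list[CometRecord], min_cells: int = 50) -> float:
    """Per-slide mean tail percent over scored cells (>= ``min_cells``)."""
    valid = [r.tail_percent for r in records if r.valid]
    if len(valid) < min_cells:
        raise ValueError(f"need >= {min_cells} scored cells per slide, got {len(valid)}")
    return float(np.mean(valid))


# ---------------------------------------------------------------------------
# image thresholding
# ---------------------------------------------------------------------------


def _histogram(image: np.ndarray, nbins: int = 256):
    image = np.asarray(image)
    if np.issubdtype(image.dtype, np.integer) and image.max() <= 255 and image.min() >= 0:
        counts = np.bincount(image.ravel().astype(np.int64), minlength=256)
        centers = np.arange(256, dtype=float)
        return counts.astype(float), centers
    lo, hi = float(image.min()), float(image.max())
    counts, edges = np.histogram(image.ravel(), bins=nbins, range=(lo, hi))
    centers = (edges[:-1] + edges[1:]) / 2.0
    return counts.astype(float), centers


def otsu_threshold(image) -> float:
    """Otsu's threshold: the histogram level maximizing between-class
    variance (the lowest level on ties). Foreground is > threshold."""
    image = np.asarray(image)
    if np.ptp(image) == 0:
        raise ValueError("cannot threshold a constant image")
    counts, centers = _histogram(image)
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    m = np.cumsum(counts * centers)
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m / w0
        mu1 = (m[-1] - m) / w1
        between = w0 * w1 * (mu0 - mu1) ** 2
    between = np.nan_to_num(between[:-1], nan=-1.0)  # a cut after the last bin is void
    return float(centers[int(np.argmax(between))])  # argmax takes the lowest tie


def triangle_threshold(image) -> float:
    """Triangle threshold: the level of maximum perpendicular distance from
    the line joining the histogram peak to the far end of the occupied range."""
    image = np.asarray(image)
    if np.ptp(image) == 0:
        raise ValueError("cannot threshold a constant image")
    counts, centers = _histogram(image)
    occupied = np.flatnonzero(counts)
    peak = int(np.argmax(counts))
    lo, hi = occupied[0], occupied[-1]
    # work on the longer flank of the peak
    if hi - peak >= peak - lo:
        span = np.arange(peak, hi + 1)
    else:
        span = np.arange(lo, peak + 1)[::-1]
    x = span.astype(float)
    y = counts[span]
    x0, y0 = x[0], y[0]
    x1, y1 = x[-1], y[-1]
    norm = np.hypot(x1 - x0, y1 - y0)
    dist = np.abs((y1 - y0) * x - (x1 - x0) * y + x1 * y0 - y1 * x0) / norm
    return float(centers[span[int(np.argmax(dist))]])


def image_threshold(image, method: str = "otsu") -> float:
    if method == "otsu":
        return otsu_threshold(image)
    if method == "triangle":
        return triangle_threshold(image)
    raise ValueError("method must be 'otsu' or 'triangle'")


# ---------------------------------------------------------------------------
# autophagy puncta quantification
# ---------------------------------------------------------------------------


def count_nuclei(nuclei_image, min_peak_distance: int = 5) -> int:
    """Count nuclei by Otsu thresholding, connected components, and
    distance-transform peak splitting of merged blobs (each component counts
    max(1, number of distance peaks))."""
    from skimage.feature import peak_local_max

    img = np.asarray(nuclei_image)
    if np.ptp(img) == 0:
        return 0  # featureless channel: nothing to count
    mask = img > otsu_threshold(img)
    labels, n_comp = ndimage.label(mask)
    if n_comp == 0:
        return 0
    total = 0
    dist = ndimage.distance_transform_edt(mask)
    for comp in range(1, n_comp + 1):
        comp_mask = labels == comp
        peaks = peak_local_max(
            np.where(comp_mask, dist, 0.0), min_distance=min_peak_distance, exclude_border=False
        )
        total += max(1, len(peaks))
    return total


def puncta_density_normalized(signal_image, nuclei_image) -> dict:
    """Triangle-thresholded integrated signal density per detected nucleus.

    The signal channel is thresholded with the triangle method, pixel
    intensities are integrated over the foreground, and the result is divided
    by the nuclei count from the Hoechst channel. Zero detected nuclei flags
    the value undefined.
    """
    signal = np.asarray(signal_image, float)
    if np.ptp(signal) == 0:
        density = 0.0
        thr = 0.0
    else:
        thr = triangle_threshold(signal_image)
        density = float(signal[signal > thr].sum())
    n_nuclei = count_nuclei(nuclei_image)
    if n_nuclei == 0:
        return {"integrated_density": density, "n_nuclei": 0, "density_per_nucleus": np.nan,
                "threshold": thr, "valid": False}
    return {
        "integrated_density": density,
        "n_nuclei": n_nuclei,
        "density_per_nucleus": density / n_nuclei,
        "threshold": thr,
        "valid": True,
    }


# ---------------------------------------------------------------------------
# densitometry
# ---------------------------------------------------------------------------


@dataclass
class DensitometryRecord:
    lane: str
    raw: float
    background: float
    control: float
    control_background: float
    normalized: float


def densitometry_normalize(
    lanes: dict[str, float],
    background: float,
    controls: dict[str, float],
    control_background: float | None = None,
) -> pd.DataFrame:
    """Background-corrected lane densities normalized to the matched
    beta-actin loading-control band.

    normalized = (lane - background) / (control - control_background). The
    control must exceed its background (otherwise the blot is invalid).
    """
    if control_background is None:
        control_background = background
    rows = []
    for lane, raw in lanes.items():
        if lane not in controls:
            raise ValueError(f"no loading control for lane {lane!r}")
        ctrl = controls[lane]
        denom = ctrl - control_background
        if denom <= 0:
            raise ValueError(f"control <= background for lane {lane!r}: invalid blot")
        rows.append(
            DensitometryRecord(
                lane=lane,
                raw=float(raw),
                background=float(background),
                control=float(ctrl),
                control_background=float(control_background),
                normalized=(raw - background) / denom,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
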