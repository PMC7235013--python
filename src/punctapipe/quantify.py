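"""Per-synapse intensity extraction and photoconversion metrics.

Records live in a pandas DataFrame with one row per ROI.  Raw columns
``G0, G1, R0, R1`` hold the maximum voxel value of the ROI in the raw
median-filtered volume of each channel/timepoint (deconvolved data are
never quantified).  Normalized columns ``g0, g1, r0, r1`` divide green
values by the population mean of G0 and red values by the population mean
of R0, computed over kept (non-autofluorescent, valid) records.  The
photoconversion metric is

    pc = ΔR / (g0 + g1),  ΔR = r1 - r0,

chosen because dividing the red change by total green removes the
correlation with synapse size that raw ΔR carries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .detect import SpotROI
from .preprocess import ProcessedPair
from .volume import ImageVolume

RAW_COLUMNS = ("G0", "G1", "R0", "R1")


@dataclass
class RejectionReport:
    """Outcome of the baseline-red autofluorescence filter."""

    threshold: float
    n_detected: int
    n_rejected: int
    rejected_ids: list[int] = field(default_factory=list)

    @property
    def fraction_rejected(self) -> float:
        return self.n_rejected / self.n_detected if self.n_detected else 0.0


def _medfilt_voxels(vol: ImageVolume | ProcessedPair) -> np.ndarray:
    """Accept a ProcessedPair (uses its raw median-filtered member) or a
    plain volume; the deconvolved member is never reachable from here."""
    if isinstance(vol, ProcessedPair):
        return np.asarray(vol.raw_medfilt.voxels)
    return np.asarray(vol.voxels)


def roi_max_intensity(roi: SpotROI, vol: ImageVolume | ProcessedPair) -> float:
    """Maximum voxel value over the ROI's member voxels."""
    data = _medfilt_voxels(vol)
    v = roi.voxels
    inside = np.all((v >= 0) & (v < np.asarray(data.shape)), axis=1)
    if not inside.any():
        return float("nan")
    v = v[inside]
    return float(data[v[:, 0], v[:, 1], v[:, 2]].max())


def reject_autofluorescent(
    rois: list[SpotROI],
    r0: ImageVolume | ProcessedPair,
    k: float = 3.0,
) -> tuple[list[SpotROI], RejectionReport]:
    """Flag spots with elevated baseline red as autofluorescent clutter.

    The threshold is dynamic, computed from the histogram of per-spot R0
    maxima: median + k * 1.4826 * MAD (the MAD is scaled to a robust sigma,
    so k plays the usual "k-sigma" role and stays robust against the heavy
    right tail the clutter itself creates).  When the MAD is zero the
    threshold falls back to Otsu's split of the spot histogram.

    Returns the kept spots and a report; rejected ids are listed in the
    report so callers can flag rather than delete the records.
    """
    if not rois:
        return [], RejectionReport(threshold=float("nan"), n_detected=0, n_rejected=0)
    r0_max = np.array([roi_max_intensity(roi, r0) for roi in rois])
    finite = np.isfinite(r0_max)
    med = float(np.median(r0_max[finite]))
    mad = float(np.median(np.abs(r0_max[finite] - med)))
    if mad > 0:
        threshold = med + k * 1.4826 * mad
    else:
        from skimage.filters import threshold_otsu

        vals = r0_max[finite]
        threshold = float(threshold_otsu(vals)) if np.unique(vals).size > 1 \
            else float("inf")
    rejected = [roi.id for roi, v in zip(rois, r0_max)
                if np.isfinite(v) and v > threshold]
    kept = [roi for roi in rois if roi.id not in set(rejected)]
    report = RejectionReport(threshold=threshold, n_detected=len(rois),
                             n_rejected=len(rejected), rejected_ids=rejected)
    if not kept:
        import warnings

        warnings.warn("all spots rejected by the baseline-red filter")
    return kept, report


def extract_intensities(
    rois: list[SpotROI],
    volumes: dict[str, ImageVolume | ProcessedPair],
    autofluorescent_ids: set[int] | None = None,
) -> pd.DataFrame:
    """Build the per-synapse record table from raw median-filtered volumes.

    ``volumes`` maps channel/timepoint keys ("G0", "G1", "R0", "R1", or
    further timepoints like "G2"/"R2") to volumes.  The intensity statistic
    is the ROI maximum; the ROI mean is stored alongside for diagnostics
    but never enters the metrics.  ROIs that fall outside a volume are
    flagged ``invalid`` rather than dropped.
    """
    autofluorescent_ids = autofluorescent_ids or set()
    rows = []
    for roi in rois:
        row: dict = {
            "roi_id": roi.id,
            "z_um": roi.centroid_um[0],
            "y_um": roi.centroid_um[1],
            "x_um": roi.centroid_um[2],
            "volume_voxels": roi.volume_voxels,
            "autofluorescent": roi.id in autofluorescent_ids,
            "invalid": False,
        }
        for key, vol in volumes.items():
            data = _medfilt_voxels(vol)
            v = roi.voxels
            inside = np.all((v >= 0) & (v < np.asarray(data.shape)), axis=1)
            if not inside.all():
                row["invalid"] = True
            if inside.any():
                vals = data[v[inside, 0], v[inside, 1], v[inside, 2]]
                row[key] = float(vals.max())
                row[f"mean_{key}"] = float(vals.mean())
            else:
                row[key] = np.nan
                row[f"mean_{key}"] = np.nan
                row["invalid"] = True
        rows.append(row)
    return pd.DataFrame(rows)


def _kept_mask(records: pd.DataFrame) -> pd.Series:
    mask = pd.Series(True, index=records.index)
    if "autofluorescent" in records:
        mask &= ~records["autofluorescent"]
    if "invalid" in records:
        mask &= ~records["invalid"]
    return mask


def normalize_population(records: pd.DataFrame) -> pd.DataFrame:
    """Add g0, g1, r0, r1: green scaled by mean(G0), red by mean(R0).

    Population means run over kept records only (autofluorescent or invalid
    rows are excluded from the means but still normalized).  By
    construction the mean of g0 and of r0 over kept records is exactly 1.
    """
    kept = _kept_mask(records)
    if not kept.any():
        raise ValueError("no kept records to normalize against")
    g_mean = records.loc[kept, "G0"].mean()
    r_mean = records.loc[kept, "R0"].mean()
    if not (g_mean > 0 and r_mean > 0):
        raise ValueError("population mean of G0/R0 is zero; cannot normalize")
    out = records.copy()
    for col in records.columns:
        if col.startswith("G") and col[1:].isdigit():
            out[col.lower()] = records[col] / g_mean
        if col.startswith("R") and col[1:].isdigit():
            out[col.lower()] = records[col] / r_mean
    return out


def photoconversion_metrics(records: pd.DataFrame) -> pd.DataFrame:
    """Add ΔR, R1/G1 and pc = ΔR/(g0+g1) columns with explicit validity flags.

    Degenerate denominators flag the metric (``pc_valid`` / ``ratio_valid``
    False) instead of propagating NaNs silently.
    """
    for col in ("g0", "g1", "r0", "r1"):
        if col not in records:
            raise ValueError("records must be normalized first (missing g0..r1)")
    out = records.copy()
    out["dR"] = out["r1"] - out["r0"]
    denom = out["g0"] + out["g1"]
    out["pc_valid"] = denom > 0
    out["pc"] = np.where(out["pc_valid"], out["dR"] / denom.replace(0, np.nan), np.nan)
    out["ratio_valid"] = out["g1"] > 0
    out["r1_over_g1"] = np.where(out["ratio_valid"],
                                 out["r1"] / out["g1"].replace(0, np.nan), np.nan)
    return out


def size_bias_diagnostics(records: pd.DataFrame) -> pd.DataFrame:
    """Spearman rank correlation of each metric against the size proxy g0.

    Baseline green (g0) proxies postsynaptic size.  On data where true
    conversion is size-independent, ΔR correlates with size while
    pc = ΔR/(g0+g1) does not — the reason pc is the metric of choice.
    Constant metric values yield an undefined rho (NaN, flagged).
    """
    kept = records[_kept_mask(records)]
    if len(kept) < 10:
        raise ValueError("need at least 10 kept records")
    rows = []
    for metric in ("dR", "pc", "r1_over_g1"):
        x = kept["g0"].to_numpy()
        y = kept[metric].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        if np.unique(y[ok]).size < 2 or np.unique(x[ok]).size < 2:
            rows.append({"metric": metric, "rho": np.nan, "p_value": np.nan,
                         "defined": False, "n": int(ok.sum())})
            continue
        rho, p = stats.spearmanr(x[ok], y[ok])
        rows.append({"metric": metric, "rho": float(rho), "p_value": float(p),
                     "defined": True, "n": int(ok.sum())})
    return pd.DataFrame(rows)


# ----------------------------------------------------------- 2D time traces

@dataclass
class FluorescenceTrace:
    """ΔF/F (and optional R/G0) time course of one circular ROI."""

    dff: np.ndarray
    f: np.ndarray
    f0: float
    center_yx: tuple[int, int]
    r_over_g0: np.ndarray | None = None
    flagged: bool = False


def _circle_mask(shape, center_yx, diameter_px) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    r = diameter_px / 2.0
    return (yy - center_yx[0]) ** 2 + (xx - center_yx[1]) ** 2 <= r ** 2


def dff_trace(
    movie: np.ndarray,
    baseline_window: tuple[int, int],
    roi_center_yx: tuple[int, int] | None = None,
    roi_diameter_px: int = 10,
    background_rois: list[tuple[int, int]] | None = None,
    red_movie: np.ndarray | None = None,
) -> FluorescenceTrace:
    """ΔF/F trace of a circular ROI in a 2D time-lapse movie.

    The ROI is a circle of ``roi_diameter_px`` centered on the brightest
    pixel of the mean image (re-centered onto the local maximum when a
    starting center is supplied).  Mean background over the given circular
    background ROIs is subtracted frame-by-frame before computing
    F0 (mean over ``baseline_window`` frames, e.g. the 300 ms before
    stimulus onset) and ΔF/F = (F - F0)/F0.  A non-positive F0 flags the
    trace instead of producing infinities.
    """
    movie = np.asarray(movie, float)
    if movie.ndim != 3:
        raise ValueError("movie must be (t, y, x)")
    t0, t1 = baseline_window
    if not (0 <= t0 < t1 <= movie.shape[0]):
        raise ValueError("baseline window must lie inside the trace")
    mean_img = movie.mean(axis=0)
    if roi_center_yx is None:
        center = np.unravel_index(np.argmax(mean_img), mean_img.shape)
    else:
        # re-center on the brightest pixel within the starting circle
        m = _circle_mask(mean_img.shape, roi_center_yx, roi_diameter_px)
        masked = np.where(m, mean_img, -np.inf)
        center = np.unravel_index(np.argmax(masked), mean_img.shape)
    mask = _circle_mask(mean_img.shape, center, roi_diameter_px)

    def roi_trace(mov, msk):
        return mov[:, msk].mean(axis=1)

    f = roi_trace(movie, mask)
    if background_rois:
        bg = np.mean(
            [roi_trace(movie, _circle_mask(mean_img.shape, c, roi_diameter_px))
             for c in background_rois], axis=0)
        f = f - bg
    f0 = float(f[t0:t1].mean())
    flagged = not f0 > 0
    dff = (f - f0) / f0 if not flagged else np.full_like(f, np.nan)
    r_over_g0 = None
    if red_movie is not None:
        r = roi_trace(np.asarray(red_movie, float), mask)
        if background_rois:
            r = r - np.mean(
                [roi_trace(np.asarray(red_movie, float),
                           _circle_mask(mean_img.shape, c, roi_diameter_px))
                 for c in background_rois], axis=0)
        r_over_g0 = r / f0 if not flagged else np.full_like(r, np.nan)
    return FluorescenceTrace(dff=dff, f=f, f0=f0, center_yx=tuple(int(c) for c in center),
                             r_over_g0=r_over_g0, flagged=flagged)
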