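"""Downstream analyses of per-synapse photoconversion records.

Covers the biology-facing summaries: which synapses were active (3-sigma
rule on the photoconversion metric), how conversion falls off with distance
from the soma (20 µm concentric Sholl rings + exponential fit, distance
constant λ), how the converted signal turns over in time (exponential decay
fit, time constant τ), and how strongly a synaptically targeted label is
enriched in spines/boutons relative to shafts once normalized by a
cytosolic filler.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import spearmanr


def _col_or(records: pd.DataFrame, name: str, default) -> pd.Series:
    if name in records:
        return records[name]
    return pd.Series(default, index=records.index)


# ------------------------------------------------------------- active rule

def classify_active(
    records: pd.DataFrame,
    sigma_mult: float = 3.0,
    robust: bool = False,
    metric: str = "pc",
) -> tuple[pd.DataFrame, float]:
    """Flag synapses whose metric exceeds mean + sigma_mult * sigma.

    The population statistics run over kept records with a valid metric.
    ``robust=True`` swaps in median + sigma_mult * 1.4826 * MAD.  A zero
    spread (all-equal values) is an error — no meaningful threshold exists.
    """
    kept = records[~_col_or(records, "autofluorescent", False)]
    vals = kept.loc[_col_or(kept, "pc_valid", True), metric].dropna().to_numpy()
    if vals.size < 20:
        raise ValueError("need >= 20 records for a stable sigma")
    if robust:
        center = float(np.median(vals))
        spread = 1.4826 * float(np.median(np.abs(vals - center)))
    else:
        center = float(np.mean(vals))
        spread = float(np.std(vals, ddof=1))
    if spread == 0:
        raise ValueError("zero spread in the metric; threshold undefined")
    threshold = center + sigma_mult * spread
    out = records.copy()
    out["active"] = ((out[metric] > threshold) & _col_or(out, "pc_valid", True)
                     & ~_col_or(out, "autofluorescent", False))
    return out, threshold


# ------------------------------------------------------------- Sholl rings

def ring_analysis(
    records: pd.DataFrame,
    ring_width_um: float = 20.0,
    metric: str = "pc",
    max_distance_um: float | None = None,
) -> pd.DataFrame:
    """Bin synapses into concentric rings around the soma; median + IQR per ring.

    Rings are contiguous [0, w), [w, 2w), ... by Euclidean distance; each
    synapse lands in exactly one ring.  Empty rings are reported with n=0
    so ring indices stay aligned with distance.
    """
    if ring_width_um <= 0:
        raise ValueError("ring_width_um must be > 0")
    if "distance_um" not in records:
        raise ValueError("records need a distance_um column")
    kept = records[~_col_or(records, "autofluorescent", False)].copy()
    kept = kept[np.isfinite(kept[metric])]
    d = kept["distance_um"].to_numpy()
    if np.any(d < 0):
        raise ValueError("negative distance")
    top = max_distance_um if max_distance_um is not None else (d.max() if d.size else 0)
    n_rings = max(1, int(np.ceil(top / ring_width_um + 1e-9)))
    rows = []
    for i in range(n_rings):
        inner, outer = i * ring_width_um, (i + 1) * ring_width_um
        sel = kept[(d >= inner) & (d < outer)][metric].to_numpy()
        rows.append({
            "ring": i, "inner_um": inner, "outer_um": outer,
            "center_um": (inner + outer) / 2.0, "n": int(sel.size),
            "median": float(np.median(sel)) if sel.size else np.nan,
            "q25": float(np.percentile(sel, 25)) if sel.size else np.nan,
            "q75": float(np.percentile(sel, 75)) if sel.size else np.nan,
            "iqr": float(np.percentile(sel, 75) - np.percentile(sel, 25))
            if sel.size else np.nan,
        })
    return pd.DataFrame(rows)


# -------------------------------------------------------------------- fits

@dataclass
class FitResult:
    """Nonlinear least-squares fit of an exponential model."""

    model: str
    params: dict[str, float]
    stderr: dict[str, float]
    r_squared: float
    n_points: int
    converged: bool
    selected_model: str | None = None
    note: str = ""


def _multistart_fit(func, x, y, p0_list, sigma=None, bounds=(-np.inf, np.inf)):
    best = None
    for p0 in p0_list:
        try:
            popt, pcov = curve_fit(func, x, y, p0=p0, sigma=sigma,
                                   absolute_sigma=False, bounds=bounds,
                                   maxfev=20000, xtol=1e-10, ftol=1e-10)
        except (RuntimeError, ValueError):
            continue
        resid = y - func(x, *popt)
        if sigma is not None:
            cost = float(np.sum((resid / sigma) ** 2))
        else:
            cost = float(np.sum(resid ** 2))
        if best is None or cost < best[2]:
            best = (popt, pcov, cost)
    return best


def _log_linear_seed(x, y) -> tuple[float, float]:
    """Initial (A, scale) from a log-linear regression on positive values."""
    pos = y > 0
    if pos.sum() >= 2 and np.ptp(x[pos]) > 0:
        slope, intercept = np.polyfit(x[pos], np.log(y[pos]), 1)
        if slope < 0:
            return float(np.exp(intercept)), float(-1.0 / slope)
    return float(max(y.max(), 1e-6)), float(max(np.ptp(x), 1.0))


def fit_exponential_curve(x: np.ndarray, y: np.ndarray,
                          weights: np.ndarray | None = None) -> FitResult:
    """Fit A·exp(-x/λ) to raw (x, y) points, optionally count-weighted.

    This is the bare decay fit used both on per-ring medians and directly
    on per-spine amplitude tables.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need matched x/y with >= 3 points")
    sigma = 1.0 / np.sqrt(np.asarray(weights, float)) if weights is not None else None

    def model(d, a, lam):
        return a * np.exp(-d / lam)

    a0, l0 = _log_linear_seed(x, y)
    best = _multistart_fit(model, x, y, [(a0, l0), (a0, l0 / 2), (a0, l0 * 2)],
                           sigma=sigma, bounds=([0, 1e-6], [np.inf, np.inf]))
    if best is None:
        return FitResult("A*exp(-x/lambda)", {}, {}, -np.inf, int(x.size), False,
                         note="optimization failed")
    popt, pcov, _ = best
    resid = y - model(x, *popt)
    sst = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid ** 2)) / sst if sst > 0 else -np.inf
    err = np.sqrt(np.abs(np.diag(pcov)))
    converged = bool(np.isfinite(popt).all() and popt[1] > 0)
    return FitResult(
        model="A*exp(-x/lambda)",
        params={"A": float(popt[0]), "lambda_um": float(popt[1])},
        stderr={"A": float(err[0]), "lambda_um": float(err[1])},
        r_squared=r2, n_points=int(x.size), converged=converged,
    )


def fit_exponential_distance(rings: pd.DataFrame, metric_col: str = "median"
                             ) -> FitResult:
    """Weighted fit of A·exp(-d/λ) to per-ring medians at ring centers.

    Weights are the per-ring synapse counts.  Requires >= 4 non-empty
    rings.  Monotonically non-decreasing medians cannot carry a decay
    constant; the result is flagged non-converged.
    """
    filled = rings[rings["n"] > 0]
    if len(filled) < 4:
        raise ValueError("need >= 4 non-empty rings")
    x = filled["center_um"].to_numpy(float)
    y = filled[metric_col].to_numpy(float)
    w = filled["n"].to_numpy(float)
    fit = fit_exponential_curve(x, y, weights=w)
    if bool(np.all(np.diff(y) >= 0)):
        fit.converged = False
        fit.note = "non-decreasing data; lambda unreliable"
    return fit


def fit_exponential_decay(
    timepoints_min: np.ndarray,
    values: np.ndarray,
) -> FitResult:
    """Fit A·exp(-t/τ) + C to a photoconversion time course.

    ``values`` is either one population trace (n_timepoints,) or a
    per-synapse matrix (n_synapses, n_timepoints), which is averaged.
    A constant model is fitted alongside; ``selected_model`` reports which
    wins by small-sample AIC — outside-region control traces should select
    "constant".
    """
    t = np.asarray(timepoints_min, float)
    v = np.asarray(values, float)
    if v.ndim == 2:
        v = np.nanmean(v, axis=0)
    if t.size != v.size:
        raise ValueError("timepoints and values differ in length")
    if t.size < 4:
        raise ValueError("need >= 4 timepoints (3-parameter model)")

    def model(tt, a, tau, c):
        return a * np.exp(-tt / tau) + c

    span = v.max() - v.min()
    tau0 = max(np.ptp(t) / 3.0, 1e-3)
    starts = [(span, tau0, v.min()), (span, tau0 / 2, v.min()),
              (span, tau0 * 2, v.min())]
    best = _multistart_fit(model, t, v, starts,
                           bounds=([-np.inf, 1e-6, -np.inf], [np.inf, np.inf, np.inf]))
    n = t.size
    sse_const = float(np.sum((v - v.mean()) ** 2))
    # floor at the float64 noise of the data scale: exact fits tie and the
    # AIC penalty then favors the simpler model
    sse_floor = n * (float(np.abs(v).max()) + 1e-12) ** 2 * 1e-20

    def aic(sse, k):
        sse = max(sse, sse_floor)
        return n * np.log(sse / n) + 2 * k

    if best is None:
        return FitResult("A*exp(-t/tau)+C", {}, {}, -np.inf, n, False,
                         selected_model="constant", note="optimization failed")
    popt, pcov, _ = best
    resid = v - model(t, *popt)
    sse = float(np.sum(resid ** 2))
    sst = sse_const
    r2 = 1.0 - sse / sst if sst > 0 else -np.inf
    err = np.sqrt(np.abs(np.diag(pcov)))
    selected = "exponential" if aic(sse, 3) < aic(sse_const, 1) else "constant"
    converged = np.isfinite(popt).all() and popt[1] > 0 and selected == "exponential"
    return FitResult(
        model="A*exp(-t/tau)+C",
        params={"A": float(popt[0]), "tau_min": float(popt[1]), "C": float(popt[2])},
        stderr={"A": float(err[0]), "tau_min": float(err[1]), "C": float(err[2])},
        r_squared=r2, n_points=n, converged=bool(converged),
        selected_model=selected,
    )


# -------------------------------------------------------------- enrichment

@dataclass
class EnrichmentResult:
    """Filler-normalized compartment enrichment of a targeted label."""

    ratios: np.ndarray
    median: float
    flagged: np.ndarray  # pairs with zero shaft intensity


def enrichment_ratio(
    target_compartment: np.ndarray,
    target_shaft: np.ndarray,
    filler_compartment: np.ndarray,
    filler_shaft: np.ndarray,
) -> EnrichmentResult:
    """Per-structure enrichment = (target_comp/target_shaft)/(filler_comp/filler_shaft).

    The cytosolic filler ratio normalizes out the volume difference between
    a bouton/spine and its shaft, so a ratio of 1 means no specific
    enrichment; with filler == target the ratio is identically 1.  Pairs
    with a zero shaft intensity are flagged and excluded from the median.
    """
    tc, ts = np.asarray(target_compartment, float), np.asarray(target_shaft, float)
    fc, fs = np.asarray(filler_compartment, float), np.asarray(filler_shaft, float)
    if not (tc.shape == ts.shape == fc.shape == fs.shape):
        raise ValueError("all four arrays must be paired (same shape)")
    flagged = (ts == 0) | (fs == 0) | (fc == 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = (tc / ts) / (fc / fs)
    ratios = np.where(flagged, np.nan, ratios)
    valid = ratios[~flagged]
    if valid.size == 0:
        raise ValueError("no valid pairs (all shaft intensities zero)")
    return EnrichmentResult(ratios=ratios, median=float(np.median(valid)),
                            flagged=flagged)


def rings_monotone_decreasing(rings: pd.DataFrame) -> bool:
    """Noise-tolerant monotonicity check: Spearman rho(ring index, median) < 0."""
    filled = rings[rings["n"] > 0]
    rho, _ = spearmanr(filled["ring"], filled["median"])
    return bool(rho < 0)
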