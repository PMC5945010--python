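"""Pairing park greenness cycles with a gridded NDVI-like product.

Cells of a monthly (lat, lon) NDVI grid are selected within a fixed radius
of each park centre — by default a Euclidean 0.5 degrees in lat/lon space,
boundary inclusive (a 0.5-degree box is available as an alternative, since
"within 0.5 degrees" is ambiguous) — and averaged per month. The monthly
means are paired with the parks' monthly mean greenness and the pooled
park-month pairs are correlated (Pearson with a percentile-bootstrap CI by
resampling pairs; Spearman as a point estimate). Per-park correlations are
deliberately not emitted: with only 12 points each they are unstable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .phenostats import BootstrapConfig, child_rng

__all__ = [
    "CorrelationResult",
    "load_ndvi_grid",
    "select_park_cells",
    "monthly_ndvi",
    "pair_series",
    "correlate",
]

logger = logging.getLogger(__name__)

NDVI_COLUMNS = ["lat", "lon", "month", "ndvi"]

#: Absolute slack for the inclusive radius test, absorbing float noise in
#: lattice coordinates built by repeated addition.
_BOUNDARY_TOL = 1e-9


@dataclass(frozen=True)
class CorrelationResult:
    """Pooled paired-series correlation estimates."""

    pearson_r: float
    pearson_ci_low: float
    pearson_ci_high: float
    spearman_rho: float
    n_pairs: int


def load_ndvi_grid(path: str | Path) -> pd.DataFrame:
    """Read an NDVI grid CSV (``lat,lon,month,ndvi``) with validation."""
    df = pd.read_csv(path)
    missing = [c for c in NDVI_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"NDVI grid missing columns {missing}")
    if not df["month"].between(1, 12).all():
        raise ValueError("NDVI grid months must lie in 1..12")
    if not df["ndvi"].between(-1.0, 1.0).all():
        raise ValueError("NDVI values must lie in [-1, 1]")
    return df[NDVI_COLUMNS].copy()


def select_park_cells(
    cells: pd.DataFrame,
    center: tuple[float, float],
    radius_deg: float = 0.5,
    method: str = "radius",
    park: str | None = None,
) -> pd.DataFrame:
    """Cells within ``radius_deg`` of a park centre (boundary inclusive).

    ``method="radius"`` keeps cells with Euclidean degree distance
    ``sqrt(dlat^2 + dlon^2) <= radius_deg``; ``method="box"`` keeps cells
    with ``max(|dlat|, |dlon|) <= radius_deg``.

    Raises
    ------
    ValueError
        If the selection is empty (the error names the park when given).
    """
    if radius_deg <= 0:
        raise ValueError("radius_deg must be > 0")
    lat0, lon0 = center
    dlat = cells["lat"].to_numpy() - lat0
    dlon = cells["lon"].to_numpy() - lon0
    if method == "radius":
        mask = np.hypot(dlat, dlon) <= radius_deg + _BOUNDARY_TOL
    elif method == "box":
        mask = np.maximum(np.abs(dlat), np.abs(dlon)) <= radius_deg + _BOUNDARY_TOL
    else:
        raise ValueError(f"unknown selection method {method!r}")
    selected = cells.loc[mask]
    if selected.empty:
        name = park or f"centre {center}"
        raise ValueError(f"no NDVI cells within {radius_deg} deg of {name}")
    return selected


def monthly_ndvi(cells: pd.DataFrame) -> pd.Series:
    """Arithmetic mean NDVI per month over a cell selection.

    Months with no cells are absent from the result.
    """
    if cells.empty:
        raise ValueError("empty cell selection")
    return cells.groupby("month")["ndvi"].mean()


def pair_series(
    greenness_monthly: pd.DataFrame,
    ndvi_monthly: dict[str, pd.Series],
) -> pd.DataFrame:
    """Join monthly greenness means with monthly NDVI means per park.

    ``greenness_monthly`` is the output of
    :func:`ambientgreen.phenostats.monthly_stats` (columns ``park, period,
    mean``); ``ndvi_monthly`` maps park name to a month-indexed NDVI Series.
    (park, month) entries missing either series are skipped — no imputation.
    """
    rows = []
    for _, row in greenness_monthly.iterrows():
        park = row["park"]
        month = int(row["period"])
        series = ndvi_monthly.get(park)
        if series is None or month not in series.index:
            continue
        rows.append(
            {
                "park": park,
                "month": month,
                "greenness_mean": float(row["mean"]),
                "ndvi_mean": float(series.loc[month]),
            }
        )
    return pd.DataFrame(rows, columns=["park", "month", "greenness_mean", "ndvi_mean"])


def correlate(
    pairs: pd.DataFrame,
    cfg: BootstrapConfig = BootstrapConfig(),
) -> CorrelationResult:
    """Pearson and Spearman correlation of the pooled park-month pairs.

    The Pearson CI is a percentile bootstrap over resampled *pairs* (rows
    drawn with replacement at the original count); replicates whose
    resample is degenerate (zero variance in either series) are redrawn
    implicitly by being skipped. Spearman is reported as a point estimate
    only.
    """
    if len(pairs) < 3:
        raise ValueError("correlation requires at least 3 pairs")
    x = pairs["greenness_mean"].to_numpy(dtype=float)
    y = pairs["ndvi_mean"].to_numpy(dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate series: zero variance")
    pearson = float(stats.pearsonr(x, y).statistic)
    spearman = float(stats.spearmanr(x, y).statistic)
    rng = child_rng(cfg, "pooled", "pearson")
    n = x.size
    reps = np.empty(cfg.n_reps)
    reps.fill(np.nan)
    idx = rng.integers(0, n, size=(cfg.n_reps, n))
    xs = x[idx]
    ys = y[idx]
    xc = xs - xs.mean(axis=1, keepdims=True)
    yc = ys - ys.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum(axis=1) * (yc**2).sum(axis=1))
    ok = denom > 0
    reps[ok] = (xc * yc).sum(axis=1)[ok] / denom[ok]
    finite = reps[np.isfinite(reps)]
    lo, hi = np.quantile(finite, [cfg.alpha / 2.0, 1.0 - cfg.alpha / 2.0])
    return CorrelationResult(
        pearson_r=pearson,
        pearson_ci_low=float(lo),
        pearson_ci_high=float(hi),
        spearman_rho=spearman,
        n_pairs=int(n),
    )
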