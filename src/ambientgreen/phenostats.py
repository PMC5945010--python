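"""Monthly and seasonal aggregation with percentile-bootstrap intervals.

Observations (one greenness value per image, labelled with park and month)
are pooled by (park, calendar month) across years, or by (park, season) for
the JJA (June-August, summer) and DJF (December-February, winter) pools.
Each pool is summarised by its mean, a percentile bootstrap confidence
interval of the mean (statistic recomputed on resamples drawn with
replacement at the original sample size; default 10 000 resamples, 95%
interval), the sample size, and the coefficient of variation (sample SD /
mean). The summer-winter contrast bootstraps the difference of means with
independent resampling of the two pools.

Randomness discipline: one root seed; each (park, period) pool derives its
own child seed from a stable hash of the labels, so results do not depend
on iteration order. No multiple-testing correction is applied across parks.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "bootstrap_ci",
    "monthly_stats",
    "seasonal_stats",
    "season_contrast",
    "SEASONS",
    "child_rng",
]

#: Season label -> calendar months.
SEASONS: dict[str, tuple[int, ...]] = {"JJA": (6, 7, 8), "DJF": (12, 1, 2)}

_REDUCERS: dict[str, Callable[[np.ndarray, int], np.ndarray]] = {
    "mean": lambda a, axis: a.mean(axis=axis),
    "median": lambda a, axis: np.median(a, axis=axis),
}


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings: 10 000 resamples and a 95% interval by default."""

    n_reps: int = 10_000
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class BootstrapResult:
    estimate: float
    ci_low: float
    ci_high: float
    degenerate: bool = False


def child_rng(cfg: BootstrapConfig, *labels: object) -> np.random.Generator:
    """Generator for one labelled pool, derived from the root seed.

    The child entropy mixes the root seed with a CRC-32 of the label tuple,
    so every (park, period) pool gets an independent, order-independent
    stream.
    """
    key = zlib.crc32("\x1f".join(str(x) for x in labels).encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, key]))


def _resample_stat(
    values: np.ndarray,
    reducer: Callable[[np.ndarray, int], np.ndarray],
    n_reps: int,
    rng: np.random.Generator,
) -> np.ndarray:
    n = values.size
    # chunk the (n_reps, n) index matrix to bound memory at ~32 MB
    chunk = max(1, min(n_reps, int(4e6 / max(n, 1)) + 1))
    out = np.empty(n_reps)
    done = 0
    while done < n_reps:
        k = min(chunk, n_reps - done)
        idx = rng.integers(0, n, size=(k, n))
        out[done : done + k] = reducer(values[idx], 1)
        done += k
    return out


def bootstrap_ci(
    values: Sequence[float],
    statistic: str | Callable[[np.ndarray], float] = "mean",
    cfg: BootstrapConfig = BootstrapConfig(),
    rng: np.random.Generator | None = None,
) -> BootstrapResult:
    """Percentile-bootstrap confidence interval of a statistic.

    The estimate is the statistic on the original sample; the interval is
    the (alpha/2, 1 - alpha/2) quantile pair of the statistic over
    ``cfg.n_reps`` resamples of size n drawn with replacement. A sample of
    size 1 yields a degenerate interval equal to the single value, flagged
    via ``BootstrapResult.degenerate``.
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size == 0:
        raise ValueError("bootstrap_ci requires a non-empty sample")
    if callable(statistic):
        reducer = lambda a, axis: np.apply_along_axis(statistic, axis, a)  # noqa: E731
        estimate = float(statistic(arr))
    else:
        try:
            reducer = _REDUCERS[statistic]
        except KeyError:
            raise ValueError(f"unknown statistic {statistic!r}") from None
        estimate = float(reducer(arr[None, :], 1)[0])
    if arr.size == 1:
        return BootstrapResult(estimate, estimate, estimate, degenerate=True)
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    stats = _resample_stat(arr, reducer, cfg.n_reps, rng)
    lo, hi = np.quantile(stats, [cfg.alpha / 2.0, 1.0 - cfg.alpha / 2.0])
    return BootstrapResult(estimate, float(lo), float(hi))


def _cv(values: np.ndarray) -> float:
    if values.size < 2:
        return 0.0
    mean = values.mean()
    if mean == 0:
        return 0.0
    return float(abs(values.std(ddof=1) / mean))


def _pool_stat(
    park: str,
    period: object,
    values: np.ndarray,
    cfg: BootstrapConfig,
) -> dict:
    res = bootstrap_ci(values, "mean", cfg, rng=child_rng(cfg, park, period))
    return {
        "park": park,
        "period": period,
        "mean": res.estimate,
        "ci_low": res.ci_low,
        "ci_high": res.ci_high,
        "n": int(values.size),
        "cv": _cv(values),
    }


def monthly_stats(obs: pd.DataFrame, cfg: BootstrapConfig = BootstrapConfig()) -> pd.DataFrame:
    """Per-(park, month) mean greenness with bootstrap CI, n and CV.

    ``obs`` must have columns ``park``, ``month`` (1-12) and ``greenness``;
    months are pooled across years. Months with no observations are simply
    absent from the output (never emitted as zero).
    """
    _require_columns(obs, ("park", "month", "greenness"))
    rows = [
        _pool_stat(park, int(month), grp["greenness"].to_numpy(), cfg)
        for (park, month), grp in obs.groupby(["park", "month"], sort=True)
    ]
    return pd.DataFrame(rows, columns=["park", "period", "mean", "ci_low", "ci_high", "n", "cv"])


def seasonal_stats(obs: pd.DataFrame, cfg: BootstrapConfig = BootstrapConfig()) -> pd.DataFrame:
    """JJA and DJF pooled statistics per park (same columns as monthly).

    A park-season with no observations is absent from the output.
    """
    _require_columns(obs, ("park", "month", "greenness"))
    rows = []
    for park, grp in obs.groupby("park", sort=True):
        for season, months in SEASONS.items():
            values = grp.loc[grp["month"].isin(months), "greenness"].to_numpy()
            if values.size == 0:
                continue
            rows.append(_pool_stat(str(park), season, values, cfg))
    return pd.DataFrame(rows, columns=["park", "period", "mean", "ci_low", "ci_high", "n", "cv"])


def season_contrast(obs: pd.DataFrame, cfg: BootstrapConfig = BootstrapConfig()) -> pd.DataFrame:
    """Summer-minus-winter mean contrast per park, with a bootstrap CI.

    Each bootstrap replicate resamples the JJA and DJF pools independently
    and takes the difference of their means; significance at the 95% level
    means the percentile interval of the difference excludes zero. For
    reference against the visual reading of CI bars, ``ci_overlap`` reports
    whether the two seasons' own intervals overlap. Parks missing either
    season pool are absent from the output.
    """
    _require_columns(obs, ("park", "month", "greenness"))
    seasonal = seasonal_stats(obs, cfg)
    rows = []
    for park, grp in obs.groupby("park", sort=True):
        summer = grp.loc[grp["month"].isin(SEASONS["JJA"]), "greenness"].to_numpy()
        winter = grp.loc[grp["month"].isin(SEASONS["DJF"]), "greenness"].to_numpy()
        if summer.size == 0 or winter.size == 0:
            continue
        rng = child_rng(cfg, park, "JJA-DJF")
        diff = float(summer.mean() - winter.mean())
        reps_s = _resample_stat(summer, _REDUCERS["mean"], cfg.n_reps, rng)
        reps_w = _resample_stat(winter, _REDUCERS["mean"], cfg.n_reps, rng)
        lo, hi = np.quantile(reps_s - reps_w, [cfg.alpha / 2.0, 1.0 - cfg.alpha / 2.0])
        srow = seasonal[(seasonal["park"] == park) & (seasonal["period"] == "JJA")].iloc[0]
        wrow = seasonal[(seasonal["park"] == park) & (seasonal["period"] == "DJF")].iloc[0]
        overlap = bool(
            srow["ci_low"] <= wrow["ci_high"] and wrow["ci_low"] <= srow["ci_high"]
        )
        rows.append(
            {
                "park": str(park),
                "diff_mean": diff,
                "diff_ci_low": float(lo),
                "diff_ci_high": float(hi),
                "significant_95": bool(lo > 0.0 or hi < 0.0),
                "ci_overlap": overlap,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["park", "diff_mean", "diff_ci_low", "diff_ci_high",
                 "significant_95", "ci_overlap"],
    )


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...]) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"observations missing columns {missing}")
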