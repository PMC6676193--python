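"""Per-subject probe x parameter Spearman correlation matrices.

Correlations are computed over the sampling days shared between the
methylation and parameter series (seven in-mission days by default), with
average (fractional) ranks for ties and pairwise-complete observations.
The resulting matrix is column-standardized (mean 0, sd 1 per parameter)
before biclustering.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from methylink.errors import ConfigurationError
from methylink.synthetic import DEFAULT_SHARED_DAYS

log = logging.getLogger(__name__)


def _rank_zscore(values: np.ndarray) -> np.ndarray:
    """Row-wise average ranks, centered and scaled; zero-variance rows -> NaN."""
    ranks = sps.rankdata(values, axis=1)
    ranks -= ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((ranks ** 2).sum(axis=1, keepdims=True))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = ranks / norm
    out[np.squeeze(norm, axis=1) < 1e-12] = np.nan
    return out


def spearman_matrix(
    beta: pd.DataFrame,
    params: pd.DataFrame,
    shared_days=None,
    min_points: int = 5,
) -> pd.DataFrame:
    """Spearman rank correlation of every probe with every parameter.

    Parameters
    ----------
    beta, params
        Probes x days and parameters x days matrices with a common day-label
        vocabulary (``day+2`` etc.).
    shared_days
        Day labels to correlate over; defaults to the seven in-mission days
        shared between blood and parameter sampling.
    min_points
        Cells with fewer pairwise-complete observations become NaN.

    Zero-variance series yield NaN (not 0), logged per probe/parameter.
    """
    if shared_days is None:
        shared_days = [f"day{d:+d}" for d in DEFAULT_SHARED_DAYS]
    shared_days = [d for d in shared_days]
    missing = [d for d in shared_days if d not in beta.columns or d not in params.columns]
    if missing:
        raise ConfigurationError(f"shared days absent from inputs: {missing}")

    b = beta[shared_days].to_numpy(dtype=float)
    p = params[shared_days].to_numpy(dtype=float)

    if not (np.isnan(b).any() or np.isnan(p).any()):
        zb = _rank_zscore(b)
        zp = _rank_zscore(p)
        n_const = int(np.isnan(zb[:, 0]).sum() + np.isnan(zp[:, 0]).sum())
        if n_const:
            log.info("spearman_matrix: %d zero-variance series set to NaN", n_const)
        rho = zb @ zp.T
        rho = np.clip(rho, -1.0, 1.0, out=rho)
        # rows/cols that were constant propagate NaN through the product
        return pd.DataFrame(rho, index=beta.index, columns=params.index)

    # slow path: pairwise-complete per cell
    rho = np.full((b.shape[0], p.shape[0]), np.nan)
    for j in range(p.shape[0]):
        pj = p[j]
        ok_p = np.isfinite(pj)
        for i in range(b.shape[0]):
            ok = ok_p & np.isfinite(b[i])
            if ok.sum() < min_points:
                continue
            x, y = b[i, ok], pj[ok]
            if np.ptp(x) < 1e-15 or np.ptp(y) < 1e-15:
                continue
            rho[i, j] = sps.spearmanr(x, y).statistic
    return pd.DataFrame(rho, index=beta.index, columns=params.index)


def standardize(X: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Column-wise centering and scaling to unit sd.

    Missing cells are imputed to the column mean (0 after centering);
    degenerate (constant or all-missing) columns become all-zero and are
    logged. Matches the conventional column-default scaling of statistical
    environments (sd with the n-1 denominator).
    """
    if X.shape[0] < 2:
        raise ConfigurationError("standardize requires at least two rows")
    mean = X.mean(axis=0, skipna=True)
    sd = X.std(axis=0, ddof=ddof, skipna=True)
    degenerate = ~(sd > 1e-12) | mean.isna()
    if degenerate.any():
        log.info("standardize: %d degenerate column(s) set to zero", int(degenerate.sum()))
    safe_sd = sd.where(~degenerate, 1.0)
    out = (X - mean) / safe_sd
    out = out.fillna(0.0)
    out.loc[:, degenerate] = 0.0
    return out


def align_days(
    series_days: list[str], target_days: list[str], tolerance: int = 5
) -> dict[str, str | None]:
    """Nearest-day alignment for parameters sampled off the shared grid.

    Maps each target day label to the closest available series day within
    ``tolerance`` days (ties resolved toward the earlier day), or None.
    Day labels follow the ``day%+d`` convention.
    """
    def num(label: str) -> int:
        return int(label.removeprefix("day"))

    available = sorted(series_days, key=num)
    mapping: dict[str, str | None] = {}
    for t in target_days:
        best, best_d = None, tolerance + 1
        for s in available:
            d = abs(num(s) - num(t))
            if d < best_d:
                best, best_d = s, d
        mapping[t] = best if best_d <= tolerance else None
    return mapping
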