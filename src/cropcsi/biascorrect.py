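"""Non-parametric quantile mapping of re-forecast variables.

Forecast monthly precipitation, monthly mean temperature and daily maximum
temperature are mapped onto the observed climatology by an empirical
quantile-quantile transfer: paired quantiles at evenly spaced probabilities
on each side, piecewise-linear interpolation between them, constant-offset
extrapolation beyond the outermost pair. Members are pooled when fitting;
the map is fitted per variable, start month, calendar month and grid cell so
lead-dependent bias is removed. Corrected precipitation is floored at zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import DataError, InsufficientDataError


@dataclass
class QuantileMap:
    """Fitted empirical transfer function between two samples."""

    source_q: np.ndarray   # forecast-side quantiles, strictly increasing
    target_q: np.ndarray   # observation-side quantiles (paired)
    floor_zero: bool = False

    def __post_init__(self) -> None:
        if self.source_q.size != self.target_q.size or self.source_q.size < 2:
            raise DataError("quantile vectors must be paired with length >= 2")
        if np.any(np.diff(self.source_q) <= 0):
            raise DataError("source quantiles must be strictly increasing")


def fit_qmap(model_values: np.ndarray, obs_values: np.ndarray,
             n_quantiles: int = 21, floor_zero: bool = False) -> QuantileMap:
    """Fit the empirical quantile transfer from pooled samples.

    If either sample is smaller than ``n_quantiles`` the quantile count is
    reduced (with a warning) so every knot is supported by data. Tied source
    quantiles are merged, averaging their targets, to keep the transfer
    strictly monotone.
    """
    mv = np.asarray(model_values, dtype=float).ravel()
    ov = np.asarray(obs_values, dtype=float).ravel()
    if mv.size < 20 or ov.size < 20:
        raise InsufficientDataError("quantile mapping needs >= 20 samples per side")
    if not (np.all(np.isfinite(mv)) and np.all(np.isfinite(ov))):
        raise DataError("non-finite values in quantile-map fit")
    nq = int(n_quantiles)
    if min(mv.size, ov.size) < nq:
        nq = int(min(mv.size, ov.size))
        warnings.warn(f"sample smaller than requested quantile count; using {nq}")
    probs = np.linspace(0.0, 1.0, nq)
    sq = np.quantile(mv, probs)
    tq = np.quantile(ov, probs)
    uniq, inverse = np.unique(sq, return_inverse=True)
    if uniq.size < sq.size:
        merged_t = np.array([tq[inverse == u].mean() for u in range(uniq.size)])
        sq, tq = uniq, merged_t
    if sq.size < 2:
        raise DataError("degenerate (constant) forecast sample; cannot map quantiles")
    return QuantileMap(source_q=sq, target_q=tq, floor_zero=floor_zero)


def apply_qmap(qmap: QuantileMap, values: np.ndarray) -> np.ndarray:
    """Apply the transfer: linear inside the training range, constant offset
    beyond it; precipitation-style maps are floored at zero."""
    v = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(v)):
        raise DataError("non-finite values passed to quantile mapping")
    out = np.interp(v, qmap.source_q, qmap.target_q)
    low = v < qmap.source_q[0]
    high = v > qmap.source_q[-1]
    out = np.where(low, v + (qmap.target_q[0] - qmap.source_q[0]), out)
    out = np.where(high, v + (qmap.target_q[-1] - qmap.source_q[-1]), out)
    if qmap.floor_zero:
        out = np.clip(out, 0.0, None)
    return out


def correct_field(model_field: np.ndarray, obs_field: np.ndarray,
                  n_quantiles: int = 21, floor_zero: bool = False) -> np.ndarray:
    """Quantile-map a member field cell by cell (members pooled).

    ``model_field`` has shape (members, years, ..., nlat, nlon) and
    ``obs_field`` (years, ..., nlat, nlon); all leading axes of each cell's
    sample (members, years and any day axis) are pooled when fitting that
    cell's map.
    """
    mf = np.asarray(model_field, dtype=float)
    of = np.asarray(obs_field, dtype=float)
    nlat, nlon = mf.shape[-2:]
    out = np.empty_like(mf)
    for i in range(nlat):
        for j in range(nlon):
            qm = fit_qmap(mf[..., i, j], of[..., i, j],
                          n_quantiles=n_quantiles, floor_zero=floor_zero)
            out[..., i, j] = apply_qmap(qm, mf[..., i, j])
    return out
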