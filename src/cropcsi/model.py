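"""Country-level Combined Stress Index calibration.

The CSI estimates standardised yield anomalies as a bilinear combination of
the de-trended drought and heat predictors,

    Y_std* = a * SPEI*_opt + b * HDD_std*_JJA + eps = CSI + eps,

with (a, b) fitted by ridge regression (intercept-free on centred anomalies,
so the covariance between the two stressors is accounted for). Predictive
performance is the leave-one-out cross-validated

    Q^2 = 1 - sum_t (yhat_t^(-t) - y_t)^2 / sum_t (y_t - y_mean)^2,

where yhat_t^(-t) is predicted from a model calibrated without year t. The
SPEI aggregation window (timescale 1-3 months, ending June-August) is chosen
per country by maximising Q^2 over the nine candidates. The ridge penalty is
selected from a grid by inner leave-one-out within each training fold, so the
penalty choice never sees the held-out year.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, Optional, Sequence, Tuple

import numpy as np

from .errors import DegenerateSeriesError, InsufficientDataError, ModelFailureError

DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(np.logspace(-3, 2, 6))


def ridge_fit(spei: np.ndarray, hdd: np.ndarray, y: np.ndarray,
              ridge_lambda: float) -> Tuple[float, float]:
    """Intercept-free two-predictor ridge solution.

    Minimises sum (y - a*spei - b*hdd)^2 + lambda (a^2 + b^2). At lambda = 0
    this is the OLS normal-equation solution; a singular design then raises.
    """
    x = np.column_stack([np.asarray(spei, float), np.asarray(hdd, float)])
    y = np.asarray(y, float)
    a = x.T @ x + ridge_lambda * np.eye(2)
    if ridge_lambda == 0 and np.linalg.matrix_rank(a) < 2:
        raise DegenerateSeriesError("singular design with lambda = 0")
    coef = np.linalg.solve(a, x.T @ y)
    return float(coef[0]), float(coef[1])


def q_squared(y: np.ndarray, y_pred: np.ndarray) -> float:
    """Cross-validated coefficient of prediction (1 = perfect, <= 0 = no skill)."""
    y = np.asarray(y, float)
    y_pred = np.asarray(y_pred, float)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0:
        raise DegenerateSeriesError("constant series: Q^2 undefined")
    return 1.0 - float(np.sum((y_pred - y) ** 2)) / sst


def _loo_press(x: np.ndarray, y: np.ndarray, lam: float) -> float:
    """Exact ridge leave-one-out PRESS via the hat-matrix shortcut."""
    a_inv = np.linalg.inv(x.T @ x + lam * np.eye(x.shape[1]))
    h = x @ a_inv @ x.T
    resid = y - h @ y
    denom = 1.0 - np.diag(h)
    denom = np.where(np.abs(denom) < 1e-12, 1e-12, denom)
    return float(np.mean((resid / denom) ** 2))


def select_lambda(x: np.ndarray, y: np.ndarray,
                  lambda_grid: Sequence[float]) -> float:
    """Smallest grid value attaining the minimal LOO PRESS."""
    press = [_loo_press(x, y, lam) for lam in lambda_grid]
    return float(lambda_grid[int(np.argmin(press))])


@dataclass
class Q2Result:
    """LOO predictive performance of one candidate model."""

    q2: float
    n_years: int
    loo_pred: np.ndarray = field(repr=False)
    significant: Optional[bool] = None
    p_value: Optional[float] = None


def loo_q2(y: np.ndarray, spei: np.ndarray, hdd: np.ndarray,
           lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
           min_years: int = 20) -> Q2Result:
    """Leave-one-out Q^2 with nested ridge-penalty selection.

    For every held-out year the penalty is re-selected by inner LOO on the
    remaining years and the model refitted, so Q^2 is a genuine out-of-sample
    measure.
    """
    y = np.asarray(y, float)
    x = np.column_stack([np.asarray(spei, float), np.asarray(hdd, float)])
    n = y.size
    if n < min_years:
        raise InsufficientDataError(f"LOO Q^2 needs >= {min_years} years; got {n}")
    pred = np.empty(n)
    for t in range(n):
        keep = np.ones(n, bool)
        keep[t] = False
        lam = select_lambda(x[keep], y[keep], lambda_grid)
        a, b = ridge_fit(x[keep, 0], x[keep, 1], y[keep], lam)
        pred[t] = a * x[t, 0] + b * x[t, 1]
    return Q2Result(q2=q_squared(y, pred), n_years=n, loo_pred=pred)


def _loo_operator(x: np.ndarray, lam: float) -> np.ndarray:
    """Matrix L with (L y)_t = ridge LOO prediction of year t at fixed lambda.

    Linear in y, which lets the permutation null be evaluated as one matrix
    product over all permuted series.
    """
    n = x.shape[0]
    op = np.zeros((n, n))
    for t in range(n):
        keep = np.ones(n, bool)
        keep[t] = False
        xtr = x[keep]
        a_inv = np.linalg.inv(xtr.T @ xtr + lam * np.eye(x.shape[1]))
        op[t, keep] = x[t] @ a_inv @ xtr.T
    return op


@dataclass
class CSIModel:
    """Fitted per-country CSI model (coefficients, chosen SPEI window, skill)."""

    country: str
    a: float
    b: float
    ridge_lambda: float
    opt_choice: Tuple[int, int]   # (timescale k, ending month)
    q2: float
    fit_period: Tuple[int, int]
    significant: Optional[bool] = None
    p_value: Optional[float] = None

    def to_dict(self) -> dict:
        d = asdict(self)
        d["opt_choice"] = list(self.opt_choice)
        d["fit_period"] = list(self.fit_period)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CSIModel":
        d = dict(d)
        d["opt_choice"] = tuple(d["opt_choice"])
        d["fit_period"] = tuple(d["fit_period"])
        return cls(**d)


def predict_csi(model: CSIModel, spei: np.ndarray, hdd: np.ndarray) -> np.ndarray:
    """CSI = a * SPEI* + b * HDD_std* (the noise term is not part of CSI)."""
    return model.a * np.asarray(spei, float) + model.b * np.asarray(hdd, float)


def significance_test(y: np.ndarray, spei: np.ndarray, hdd: np.ndarray,
                      observed_q2: float, ridge_lambda: float,
                      n_perm: int = 500, alpha: float = 0.05,
                      rng: Optional[np.random.Generator] = None
                      ) -> Tuple[bool, float]:
    """Permutation test of the LOO Q^2.

    Re-evaluates the LOO Q^2 on ``n_perm`` year-permuted yield series (penalty
    held at the value selected on the observed data, which makes the LOO
    predictions linear in y) and flags significance when the observed Q^2
    exceeds the (1 - alpha) quantile of the null. A Q^2 at or below zero is
    never significant.
    """
    if n_perm < 100:
        import warnings

        warnings.warn("fewer than 100 permutations: significance is unstable")
    if observed_q2 <= 0:
        return False, 1.0
    rng = np.random.default_rng() if rng is None else rng
    y = np.asarray(y, float)
    x = np.column_stack([np.asarray(spei, float), np.asarray(hdd, float)])
    op = _loo_operator(x, ridge_lambda)
    n = y.size
    perms = np.stack([rng.permutation(y) for _ in range(n_perm)], axis=1)  # (n, B)
    preds = op @ perms
    sst = np.sum((perms - perms.mean(axis=0)) ** 2, axis=0)
    null_q2 = 1.0 - np.sum((preds - perms) ** 2, axis=0) / sst
    p = float((np.sum(null_q2 >= observed_q2) + 1) / (n_perm + 1))
    threshold = float(np.quantile(null_q2, 1.0 - alpha))
    return bool(observed_q2 > threshold), p


def optimise_spei_choice(country: str, years: np.ndarray, y_std: np.ndarray,
                         spei_candidates: Dict[Tuple[int, int], np.ndarray],
                         hdd_std: np.ndarray,
                         lambda_grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
                         min_years: int = 20) -> Tuple[CSIModel, Q2Result]:
    """Select the SPEI aggregation window maximising leave-one-out Q^2.

    Candidates are scanned in lexicographic (timescale, ending month) order
    and ties broken in favour of the earlier candidate, so the result is
    deterministic. The winning window is refitted on all years with the
    penalty selected by full-sample LOO.
    """
    years = np.asarray(years)
    best: Optional[Tuple[Tuple[int, int], Q2Result]] = None
    for key in sorted(spei_candidates):
        spei = np.asarray(spei_candidates[key], float)
        if np.std(spei) == 0:
            continue
        try:
            res = loo_q2(y_std, spei, hdd_std, lambda_grid, min_years=min_years)
        except DegenerateSeriesError:
            continue
        if best is None or res.q2 > best[1].q2:
            best = (key, res)
    if best is None:
        raise ModelFailureError(
            f"country {country!r}: every SPEI candidate is degenerate"
        )
    key, res = best
    spei = np.asarray(spei_candidates[key], float)
    x = np.column_stack([spei, np.asarray(hdd_std, float)])
    lam = select_lambda(x, y_std, lambda_grid)
    a, b = ridge_fit(spei, hdd_std, y_std, lam)
    model = CSIModel(
        country=country,
        a=a,
        b=b,
        ridge_lambda=lam,
        opt_choice=key,
        q2=res.q2,
        fit_period=(int(years.min()), int(years.max())),
    )
    return model, res
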