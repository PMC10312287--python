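"""FC, partial correlation, input-variance estimates, and communication change.

The decomposition rests on three observable quantities per edge:

* the Pearson correlation of the two nodes' BOLD series (FC);
* the shared input variance — the total variance (trace of the covariance
  matrix) of the BOLD signals of neighbors common to both nodes;
* the two unshared input variances — the total variance of each exclusive
  neighbor set's signals after residualizing them against the shared set.

A baseline (resting-state) regression

    FC = beta0 * shared + beta1 * unshared_1 + beta2 * unshared_2 + const

supplies coefficients used to predict the FC change a task-induced change in
input variances would produce on its own,

    predicted dFC = beta0 * d_shared + beta1 * d_unshared_1 + beta2 * d_unshared_2,

and communication change is the residual part of the observed FC change:

    dComm = dFC - predicted dFC.

A positive dComm indicates FC change beyond what shared/unshared input
fluctuation explains, i.e. a candidate change in local coupling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "InputVarianceTriple",
    "BaselineModel",
    "EdgeChangeRecord",
    "pearson_fc",
    "partial_correlation",
    "residualize",
    "shared_input_variance",
    "unshared_input_variance",
    "fit_baseline_model",
    "predict_delta_fc",
    "communication_change",
]


@dataclass(frozen=True)
class InputVarianceTriple:
    """Shared and unshared input-variance estimates for one edge/session."""

    shared: float
    unshared_1: float
    unshared_2: float

    def __post_init__(self) -> None:
        if self.shared < -1e-12 or self.unshared_1 < -1e-12 or self.unshared_2 < -1e-12:
            raise ValueError("input variances must be nonnegative")

    def __sub__(self, other: "InputVarianceTriple") -> tuple[float, float, float]:
        return (
            self.shared - other.shared,
            self.unshared_1 - other.unshared_1,
            self.unshared_2 - other.unshared_2,
        )

    def as_array(self) -> np.ndarray:
        return np.array([self.shared, self.unshared_1, self.unshared_2])


@dataclass(frozen=True)
class BaselineModel:
    """Per-edge OLS fit of FC on the input-variance triple across sessions."""

    beta0: float  # shared-variance coefficient
    beta1: float  # unshared-variance coefficient, node 1 side
    beta2: float  # unshared-variance coefficient, node 2 side
    intercept: float
    adj_r2: float
    defined: bool = True

    def betas(self) -> np.ndarray:
        return np.array([self.beta0, self.beta1, self.beta2])


@dataclass(frozen=True)
class EdgeChangeRecord:
    """Observed and decomposed FC change for one edge in one condition/session."""

    edge: tuple[int, int]
    condition: str
    session: int
    delta_fc: float
    delta_shared: float
    delta_unshared_1: float
    delta_unshared_2: float
    predicted_delta_fc: float
    delta_comm: float


def pearson_fc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be one-dimensional with equal length")
    if len(x) < 3:
        raise ValueError("series must have length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    sx = np.sqrt(xc @ xc)
    sy = np.sqrt(yc @ yc)
    if sx == 0 or sy == 0:
        raise ValueError("correlation undefined for zero-variance series")
    return float(np.clip((xc @ yc) / (sx * sy), -1.0, 1.0))


def residualize(
    signals: np.ndarray,
    covariates: Sequence[np.ndarray] | np.ndarray,
    allow_rank_deficient: bool = False,
) -> np.ndarray:
    """Least-squares residuals of each signal on the covariates plus intercept.

    ``signals`` is (T,) or (T, n); covariates a sequence of (T,) series.
    Rank-deficient covariate matrices raise by default; with
    ``allow_rank_deficient`` the minimum-norm solution is used.
    """
    y = np.asarray(signals, dtype=float)
    squeeze = y.ndim == 1
    if squeeze:
        y = y[:, None]
    covs = np.column_stack(covariates) if len(covariates) else np.empty((y.shape[0], 0))
    if covs.shape[0] != y.shape[0]:
        raise ValueError("signal/covariate length mismatch")
    design = np.column_stack([np.ones(y.shape[0]), covs])
    if y.shape[0] <= design.shape[1]:
        raise ValueError(
            f"need more than {design.shape[1]} time points to residualize "
            f"against {covs.shape[1]} covariates"
        )
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1] and not allow_rank_deficient:
        raise np.linalg.LinAlgError(
            "rank-deficient covariate matrix; pass allow_rank_deficient=True "
            "to use the minimum-norm solution"
        )
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    return resid[:, 0] if squeeze else resid


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: Sequence[np.ndarray],
    allow_rank_deficient: bool = False,
) -> float:
    """Correlation between x and y after removing the covariates' contribution.

    Computed as the Pearson correlation of the least-squares residuals of x
    and y on the covariates (with intercept); equals the precision-matrix
    partial correlation -Omega_xy / sqrt(Omega_xx * Omega_yy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(covariates) >= len(x) - 2:
        raise ValueError("too many covariates for the series length")
    rx = residualize(x, covariates, allow_rank_deficient)
    ry = residualize(y, covariates, allow_rank_deficient)
    for resid, orig in ((rx, x), (ry, y)):
        if resid.std() <= 1e-10 * max(orig.std(), 1e-300):
            raise ValueError(
                "residual has (numerically) zero variance: a covariate "
                "explains one of the series exactly"
            )
    return pearson_fc(rx, ry)


def shared_input_variance(signals: Sequence[np.ndarray]) -> float:
    """Total variance (trace of the covariance matrix) of a set of signals.

    Sample variances use denominator T-1.  An empty set contributes zero.
    """
    if len(signals) == 0:
        return 0.0
    arr = np.column_stack(signals)
    if arr.shape[0] < 2:
        raise ValueError("signals must have length >= 2")
    return float(arr.var(axis=0, ddof=1).sum())


def unshared_input_variance(
    signals_excl: Sequence[np.ndarray],
    signals_shared: Sequence[np.ndarray],
    allow_rank_deficient: bool = False,
) -> float:
    """Total variance of exclusive-neighbor signals after removing shared ones.

    Each signal in ``signals_excl`` is residualized (least squares, with
    intercept) against all signals in ``signals_shared``; the result is the
    trace of the residual covariance matrix.  With no shared signals this is
    the plain total variance of the exclusive set.
    """
    if len(signals_excl) == 0:
        return 0.0
    if len(signals_shared) == 0:
        return shared_input_variance(signals_excl)
    resid = residualize(
        np.column_stack(signals_excl), signals_shared, allow_rank_deficient
    )
    return float(resid.var(axis=0, ddof=1).sum())


def fit_baseline_model(
    fc_by_session: np.ndarray,
    triples_by_session: Sequence[InputVarianceTriple],
) -> BaselineModel:
    """OLS fit of FC on (shared, unshared_1, unshared_2) across baseline sessions.

    Requires at least 5 sessions.  Degenerate designs (a constant regressor,
    collinearity) yield a model flagged ``defined=False`` whose coefficients
    must not be used for prediction.
    """
    fc = np.asarray(fc_by_session, dtype=float)
    X = np.array([t.as_array() for t in triples_by_session])
    if fc.ndim != 1 or len(fc) != X.shape[0]:
        raise ValueError("one FC value per session is required")
    n = len(fc)
    if n < 5:
        raise ValueError("baseline regression requires at least 5 sessions")
    design = np.column_stack([np.ones(n), X])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        return BaselineModel(np.nan, np.nan, np.nan, np.nan, np.nan, defined=False)
    coef, *_ = np.linalg.lstsq(design, fc, rcond=None)
    resid = fc - design @ coef
    ss_res = resid @ resid
    ss_tot = ((fc - fc.mean()) ** 2).sum()
    if ss_tot == 0:
        adj_r2 = -np.inf if ss_res > 0 else 0.0
    else:
        p = 3
        adj_r2 = 1.0 - (ss_res / (n - p - 1)) / (ss_tot / (n - 1))
    return BaselineModel(
        beta0=float(coef[1]),
        beta1=float(coef[2]),
        beta2=float(coef[3]),
        intercept=float(coef[0]),
        adj_r2=float(adj_r2),
    )


def predict_delta_fc(model: BaselineModel, delta: tuple[float, float, float]) -> float:
    """FC change attributable to the input-variance change alone.

    The intercept drops out of the differenced model, so the prediction is
    the pure linear form in the variance deltas.
    """
    if not model.defined:
        raise ValueError("baseline model is undefined for this edge")
    return float(model.betas() @ np.asarray(delta, dtype=float))


def communication_change(
    delta_fc: float, model: BaselineModel, delta: tuple[float, float, float]
) -> float:
    """Observed FC change minus the input-variance-predicted change."""
    return float(delta_fc) - predict_delta_fc(model, delta)
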