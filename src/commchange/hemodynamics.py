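"""Balloon–Windkessel transform from neural activity to BOLD signal.

State equations (per node, neural drive ``x(t)``):

    ds/dt     = x - kappa*s - gamma*(f - 1)
    df/dt     = s
    tau_h dv/dt = f - v**(1/alpha)
    tau_h dq/dt = f*(1 - (1-rho)**(1/f))/rho - v**(1/alpha) * q/v

    BOLD = V0 * (k1*(1 - q) + k2*(1 - q/v) + k3*(1 - v))

``f`` is normalized blood inflow, ``v`` normalized blood volume, ``q``
normalized deoxyhemoglobin content and ``rho`` the resting oxygen extraction
fraction.  At rest (zero drive) ``f = v = q = 1`` and the BOLD output is
identically zero.

Neural input is mean-centered by default before driving the vasodilatory
signal: the Wilson–Cowan activity fluctuates around a sigmoid fixed point
near 0.5-0.8, and the balloon model's drive is a perturbation around rest —
without centering, the constant baseline would saturate the flow response.

The positive states f, v, q are integrated in log space (the update steps
their logarithms), which keeps them strictly positive for any finite drive
— strong negative noise excursions would otherwise let an explicit Euler
step push the inflow through zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["HemodynamicParams", "bold_transform"]

_RHO = 0.34


@dataclass(frozen=True)
class HemodynamicParams:
    """Balloon–Windkessel parameters (standard values, units of seconds)."""

    kappa: float = 0.65  # vasodilatory signal decay rate, 1/s
    gamma: float = 0.41  # flow-dependent feedback rate, 1/s
    tau_h: float = 0.98  # hemodynamic transit time, s
    alpha: float = 0.32  # vessel stiffness exponent
    rho: float = _RHO  # resting oxygen extraction fraction
    v0: float = 0.02  # resting blood volume fraction
    k1: float = 7.0 * _RHO
    k2: float = 2.0
    k3: float = 2.0 * _RHO - 0.2

    def __post_init__(self) -> None:
        for name in ("kappa", "gamma", "tau_h", "v0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.rho < 1:
            raise ValueError("rho must lie in (0, 1)")


def bold_transform(
    neural: np.ndarray,
    dt: float,
    params: HemodynamicParams | None = None,
    center: bool = True,
) -> np.ndarray:
    """Transform a neural activity series into a BOLD series.

    Parameters
    ----------
    neural
        Neural drive, time on the last axis; leading axes are independent
        batch dimensions (runs, signals).
    dt
        Sampling interval of ``neural`` in seconds.
    params
        Balloon–Windkessel parameters; standard defaults if omitted.
    center
        Subtract the temporal mean before integration (default).  With
        centering any constant input maps to the resting state and a zero
        BOLD output.

    Returns
    -------
    BOLD series with the same shape as ``neural``.
    """
    if params is None:
        params = HemodynamicParams()
    if dt <= 0:
        raise ValueError("dt must be positive")
    x = np.asarray(neural, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("neural input must be finite")
    if x.shape[-1] < 1:
        raise ValueError("neural input must be non-empty")
    if center:
        x = x - x.mean(axis=-1, keepdims=True)

    # Sub-step so the effective Euler step is <= 0.01 * tau_h for stability.
    n_sub = max(1, int(np.ceil(dt / (0.01 * params.tau_h))))
    h = dt / n_sub

    batch_shape = x.shape[:-1]
    n_t = x.shape[-1]
    s = np.zeros(batch_shape)
    # f, v, q integrated via their logarithms: positivity is structural.
    lf = np.zeros(batch_shape)
    lv = np.zeros(batch_shape)
    lq = np.zeros(batch_shape)

    inv_alpha = 1.0 / params.alpha
    one_minus_rho = 1.0 - params.rho
    out = np.empty_like(x)
    for t in range(n_t):
        drive = x[..., t]  # zero-order hold across sub-steps
        for _ in range(n_sub):
            # Inflow floored at 1% of resting flow in the derivatives: the
            # 1/f terms are stiff as f -> 0, and physiological inflow never
            # actually vanishes.  Active only during extreme excursions.
            f = np.maximum(np.exp(lf), 0.01)
            v = np.exp(lv)
            q = np.exp(lq)
            fv = v ** inv_alpha  # outflow
            extraction = (1.0 - one_minus_rho ** (1.0 / f)) / params.rho
            s = s + h * (drive - params.kappa * s - params.gamma * (f - 1.0))
            lf = np.maximum(lf + h * s / f, np.log(0.005))
            lv = lv + h * (f - fv) / (params.tau_h * v)
            lq = lq + h * (f * extraction / q - fv / v) / params.tau_h
        v = np.exp(lv)
        q = np.exp(lq)
        if not (
            np.all(np.isfinite(v)) and np.all(np.isfinite(q)) and np.all(np.isfinite(s))
        ):
            raise FloatingPointError(
                f"hemodynamic state diverged at sample {t}"
            )
        out[..., t] = params.v0 * (
            params.k1 * (1.0 - q) + params.k2 * (1.0 - q / v) + params.k3 * (1.0 - v)
        )
    return out
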