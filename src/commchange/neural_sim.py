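"""Stochastic two-node Wilson–Cowan dynamics with shared and unshared inputs.

The model describes the excitatory activity ``x_i(t)`` of two coupled neural
populations:

    tau * dx1/dt = -x1 + f(w11*x1 + w12*x2 + s + I1)
    tau * dx2/dt = -x2 + f(w21*x1 + w22*x2 + s + I2)

where ``f(x) = 1/(1 + exp(-k*x))`` is a sigmoid activation, ``s(t)`` is a
zero-mean Gaussian signal common to both nodes (variance ``v_sh``) and
``I1(t), I2(t)`` are independent zero-mean Gaussian signals idiosyncratic to
each node (variance ``v_un``).  The off-diagonal couplings ``w12, w21`` set
the strength of direct inter-regional interaction; the shared input inflates
the inter-node correlation without any direct interaction, and the
idiosyncratic inputs attenuate it.

Integration is explicit Euler with one Gaussian draw per step: ``s_t`` is
drawn as N(0, v_sh) and enters the drift directly, so the realized signal
variance equals the configured variance independently of the step size
(the inputs are treated as signals with a stated variance, not as scaled
white-noise increments).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SimulationConfig",
    "NeuralTrajectory",
    "sigmoid",
    "simulate_neural",
    "simulate_neural_batch",
]


def _default_coupling() -> np.ndarray:
    return np.array([[2.0, 1.0], [1.0, 2.0]])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one two-node simulation scenario.

    Defaults are the baseline scenario: recurrent self-coupling 2, symmetric
    inter-node coupling 1, shared-input variance 0.25, unshared-input
    variance 0.35, sigmoid gain 0.5.
    """

    tau: float = 1.0  # population time constant, model time units
    coupling: np.ndarray = field(default_factory=_default_coupling)  # W, 2x2
    k: float = 0.5  # sigmoid gain
    v_sh: float = 0.25  # shared-input variance
    v_un: float = 0.35  # unshared-input variance (both nodes)
    dt: float = 0.05  # Euler step, model time units
    n_bold_steps: int = 2000  # emitted samples after burn-in
    burn_in: int = 200  # discarded initial steps
    x0: tuple[float, float] = (0.5, 0.5)  # initial state (zero-input fixed point)
    seed: int = 0

    def __post_init__(self) -> None:
        W = np.asarray(self.coupling, dtype=float)
        if W.shape != (2, 2):
            raise ValueError(f"coupling must be 2x2, got shape {W.shape}")
        object.__setattr__(self, "coupling", W)
        if not (self.tau > 0 and self.dt > 0 and self.k > 0):
            raise ValueError("tau, dt and k must be positive")
        if self.v_sh < 0 or self.v_un < 0:
            raise ValueError("input variances must be nonnegative")
        if self.n_bold_steps < 2:
            raise ValueError("n_bold_steps must be at least 2")
        if self.burn_in < 0:
            raise ValueError("burn_in must be nonnegative")

    def with_coupling_offdiag(self, w: float) -> "SimulationConfig":
        """Return a copy with both off-diagonal couplings set to ``w``."""
        W = self.coupling.copy()
        W[0, 1] = W[1, 0] = w
        return replace(self, coupling=W)


@dataclass(frozen=True)
class NeuralTrajectory:
    """Emitted neural series and the input realizations that produced them."""

    x1: np.ndarray
    x2: np.ndarray
    s: np.ndarray
    i1: np.ndarray
    i2: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        n = len(self.x1)
        for name in ("x2", "s", "i1", "i2"):
            if len(getattr(self, name)) != n:
                raise ValueError("trajectory series must have equal length")


def sigmoid(x, k: float):
    """Sigmoid activation ``f(x) = 1/(1 + exp(-k*x))``.

    Strictly increasing with limits 0 and 1; ``f(0) = 0.5`` for any gain.
    """
    if k <= 0:
        raise ValueError("gain k must be positive")
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("sigmoid input must be finite")
    out = 1.0 / (1.0 + np.exp(-k * x))
    return out if out.ndim else float(out)


def _run_seeds(seed: int, n_runs: int) -> list[np.random.SeedSequence]:
    """Deterministic per-run sub-seeds derived from the scenario seed."""
    return [np.random.SeedSequence(entropy=seed, spawn_key=(r,)) for r in range(n_runs)]


def simulate_neural_batch(config: SimulationConfig, n_runs: int) -> NeuralTrajectory:
    """Integrate ``n_runs`` independent realizations of the scenario.

    Returns a :class:`NeuralTrajectory` whose series have shape
    ``(n_runs, n_bold_steps)``.  Run ``r`` is reproducible in isolation:
    it depends only on ``config.seed`` and ``r``.
    """
    n_total = config.burn_in + config.n_bold_steps
    sd_sh = np.sqrt(config.v_sh)
    sd_un = np.sqrt(config.v_un)

    # Per-run input draws from per-run sub-generators (run r reproducible alone).
    s = np.empty((n_runs, n_total))
    i1 = np.empty((n_runs, n_total))
    i2 = np.empty((n_runs, n_total))
    for r, ss in enumerate(_run_seeds(config.seed, n_runs)):
        rng = np.random.default_rng(ss)
        s[r] = rng.standard_normal(n_total) * sd_sh
        i1[r] = rng.standard_normal(n_total) * sd_un
        i2[r] = rng.standard_normal(n_total) * sd_un

    W = config.coupling
    a = config.dt / config.tau
    k = config.k
    x1 = np.full(n_runs, float(config.x0[0]))
    x2 = np.full(n_runs, float(config.x0[1]))
    x1_out = np.empty((n_runs, n_total))
    x2_out = np.empty((n_runs, n_total))
    for t in range(n_total):
        u1 = W[0, 0] * x1 + W[0, 1] * x2 + s[:, t] + i1[:, t]
        u2 = W[1, 0] * x1 + W[1, 1] * x2 + s[:, t] + i2[:, t]
        x1 = x1 + a * (-x1 + 1.0 / (1.0 + np.exp(-k * u1)))
        x2 = x2 + a * (-x2 + 1.0 / (1.0 + np.exp(-k * u2)))
        if not (np.all(np.isfinite(x1)) and np.all(np.isfinite(x2))):
            raise FloatingPointError(f"neural integration diverged at step {t}")
        x1_out[:, t] = x1
        x2_out[:, t] = x2

    b = config.burn_in
    return NeuralTrajectory(
        x1=x1_out[:, b:],
        x2=x2_out[:, b:],
        s=s[:, b:],
        i1=i1[:, b:],
        i2=i2[:, b:],
        dt=config.dt,
    )


def simulate_neural(config: SimulationConfig) -> NeuralTrajectory:
    """Integrate a single realization of the scenario (run index 0)."""
    batch = simulate_neural_batch(config, n_runs=1)
    return NeuralTrajectory(
        x1=batch.x1[0], x2=batch.x2[0], s=batch.s[0],
        i1=batch.i1[0], i2=batch.i2[0], dt=batch.dt,
    )
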