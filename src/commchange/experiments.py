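"""Simulation protocol and the task-vs-rest analysis pipeline.

Two entry surfaces:

* the two-node protocol — run a baseline scenario many times, fit the
  FC-on-input-variance regression across runs, then sweep one parameter at a
  time (shared variance, unshared variance, inter-node coupling) and measure
  how FC, communication change and partial correlation respond;

* the parcellated pipeline — given labeled rest/task session matrices,
  build the 5%-sparsity graph from average rest FC, fit per-edge baseline
  models across rest sessions, and score every task session's FC change,
  predicted change, communication change, per-edge prediction accuracy and
  ICC(1,k) task discrimination.

In the two-node scenario the input-signal roles are explicit: the shared
input ``s`` plays the shared-neighbor set and each idiosyncratic input plays
one exclusive-neighbor set, all BOLD-transformed with the same hemodynamic
model as the nodes.  The baseline regression is estimated from run-to-run
stochastic variation in the realized input variances across fixed-parameter
runs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .connectivity_metrics import (
    BaselineModel,
    InputVarianceTriple,
    communication_change,
    fit_baseline_model,
    pearson_fc,
    predict_delta_fc,
    residualize,
    shared_input_variance,
    unshared_input_variance,
)
from .graph_neighbors import neighbor_sets, threshold_graph
from .hemodynamics import HemodynamicParams, bold_transform
from .icc_stats import icc1k_long
from .neural_sim import SimulationConfig, simulate_neural_batch
from .synthetic_cohort import SessionMatrix

__all__ = [
    "ScenarioRuns",
    "BaselineResult",
    "SweepResult",
    "SensitivityRatios",
    "PipelineResult",
    "run_scenario",
    "run_baseline",
    "run_sweep",
    "sensitivity_ratios",
    "task_rest_pipeline",
    "SWEEP_GRIDS",
]

# Printed sweep ranges, 5 evenly spaced points each, centered on baseline.
SWEEP_GRIDS = {
    "v_sh": np.linspace(0.15, 0.35, 5),
    "v_un": np.linspace(0.25, 0.45, 5),
    "w_offdiag": np.linspace(0.4, 1.6, 5),
}


@dataclass(frozen=True)
class ScenarioRuns:
    """Per-run measurements from repeated simulation of one scenario."""

    fc: np.ndarray  # (n_runs,) node-pair BOLD correlation
    pcorr: np.ndarray  # (n_runs,) partial correlation given input BOLD
    shared: np.ndarray  # (n_runs,) realized shared input variance
    unshared_1: np.ndarray
    unshared_2: np.ndarray

    @property
    def n_runs(self) -> int:
        return len(self.fc)

    def triples(self) -> list[InputVarianceTriple]:
        return [
            InputVarianceTriple(s, u1, u2)
            for s, u1, u2 in zip(self.shared, self.unshared_1, self.unshared_2)
        ]

    def mean_triple(self) -> InputVarianceTriple:
        return InputVarianceTriple(
            float(self.shared.mean()),
            float(self.unshared_1.mean()),
            float(self.unshared_2.mean()),
        )


@dataclass(frozen=True)
class BaselineResult:
    config: SimulationConfig
    runs: ScenarioRuns
    model: BaselineModel

    @property
    def mean_fc(self) -> float:
        return float(self.runs.fc.mean())

    @property
    def mean_triple(self) -> InputVarianceTriple:
        return self.runs.mean_triple()


@dataclass(frozen=True)
class SweepResult:
    """Per-grid-value summaries and slopes for one swept parameter."""

    param: str
    grid: np.ndarray
    mean_fc: np.ndarray
    sd_fc: np.ndarray
    mean_comm: np.ndarray
    sd_comm: np.ndarray
    mean_pcorr: np.ndarray
    sd_pcorr: np.ndarray
    slope_fc: float
    slope_comm: float
    slope_pcorr: float
    fc_runs: np.ndarray  # (n_grid, n_runs), for bootstrap
    comm_runs: np.ndarray  # (n_grid, n_runs)


@dataclass(frozen=True)
class SensitivityRatios:
    """|slope(FC)| / |slope(comm)| for the two variance sweeps."""

    ratio_shared: float
    ratio_unshared: float
    dampening_shared: bool  # ratio > 1: communication is less input-sensitive
    dampening_unshared: bool
    ci_shared: tuple[float, float]
    ci_unshared: tuple[float, float]


def _slope(grid: np.ndarray, values: np.ndarray) -> float:
    if len(np.unique(grid)) < 2:
        raise ValueError("slope undefined for a single-point grid")
    return float(np.polyfit(grid, values, 1)[0])


def run_scenario(
    config: SimulationConfig,
    n_runs: int,
    hemo: HemodynamicParams | None = None,
    seconds_per_unit: float = 1.0,
) -> ScenarioRuns:
    """Simulate ``n_runs`` realizations and measure FC, partial correlation
    and the realized input-variance triple on BOLD-transformed signals."""
    traj = simulate_neural_batch(config, n_runs)
    dt_s = config.dt * seconds_per_unit
    stacked = np.stack([traj.x1, traj.x2, traj.s, traj.i1, traj.i2])
    bold = bold_transform(stacked, dt=dt_s, params=hemo)
    b_x1, b_x2, b_s, b_i1, b_i2 = bold

    fc = np.empty(n_runs)
    pcorr = np.empty(n_runs)
    shared = np.empty(n_runs)
    un1 = np.empty(n_runs)
    un2 = np.empty(n_runs)
    for r in range(n_runs):
        fc[r] = pearson_fc(b_x1[r], b_x2[r])
        covs = [b_s[r], b_i1[r], b_i2[r]]
        rx = residualize(b_x1[r], covs)
        ry = residualize(b_x2[r], covs)
        pcorr[r] = pearson_fc(rx, ry)
        shared[r] = shared_input_variance([b_s[r]])
        un1[r] = unshared_input_variance([b_i1[r]], [b_s[r]])
        un2[r] = unshared_input_variance([b_i2[r]], [b_s[r]])
    return ScenarioRuns(fc=fc, pcorr=pcorr, shared=shared, unshared_1=un1, unshared_2=un2)


def run_baseline(
    config: SimulationConfig,
    n_runs: int = 500,
    hemo: HemodynamicParams | None = None,
    seconds_per_unit: float = 1.0,
) -> BaselineResult:
    """Fixed-parameter baseline runs plus the FC-on-variances regression.

    The regression across runs exploits the run-to-run stochastic variation
    of the realized input variances, mimicking session-to-session variation
    of resting-state data.
    """
    if n_runs < 10:
        raise ValueError("baseline requires at least 10 runs")
    runs = run_scenario(config, n_runs, hemo, seconds_per_unit)
    model = fit_baseline_model(runs.fc, runs.triples())
    return BaselineResult(config=config, runs=runs, model=model)


def _scenario_config(base: SimulationConfig, param: str, value: float, seed: int) -> SimulationConfig:
    if param == "v_sh":
        return replace(base, v_sh=value, seed=seed)
    if param == "v_un":
        return replace(base, v_un=value, seed=seed)
    if param == "w_offdiag":
        return replace(base.with_coupling_offdiag(value), seed=seed)
    raise ValueError(f"unknown sweep parameter {param!r}")


def run_sweep(
    param: str,
    grid: Sequence[float],
    n_runs: int,
    baseline: BaselineResult,
    hemo: HemodynamicParams | None = None,
    seconds_per_unit: float = 1.0,
    common_random_numbers: bool = False,
) -> SweepResult:
    """Sweep one parameter, measuring FC/communication/partial correlation.

    Communication change per run compares that run's FC and realized
    variances against the baseline means, using the baseline regression
    coefficients.

    By default each grid point draws its runs independently from its own
    deterministic seed, matching the plain repeated-runs protocol.  With
    ``common_random_numbers=True`` every grid point instead reuses the
    baseline's per-run draws (run r sees the same input realization at
    every parameter value, scaled to that value's variance): a Monte-Carlo
    variance-reduction device for the individual slope estimates that
    leaves each point's marginal distribution unchanged.  Note it is a poor
    choice for the FC/communication slope *ratio*: with run noise removed,
    the communication slope is dominated by the baseline-regression
    estimation error and can land arbitrarily close to zero.
    """
    grid = np.asarray(sorted(grid), dtype=float)
    base = baseline.config
    if not baseline.model.defined:
        raise ValueError("baseline model is undefined; cannot compute communication")
    offsets = {"v_sh": 1, "v_un": 2, "w_offdiag": 3}
    if param not in offsets:
        raise ValueError(f"unknown sweep parameter {param!r}; expected one of {sorted(offsets)}")
    param_offset = offsets[param]
    mean_fc, sd_fc = np.empty(len(grid)), np.empty(len(grid))
    mean_comm, sd_comm = np.empty(len(grid)), np.empty(len(grid))
    mean_pc, sd_pc = np.empty(len(grid)), np.empty(len(grid))
    fc_runs = np.empty((len(grid), n_runs))
    comm_runs = np.empty((len(grid), n_runs))
    base_triple = baseline.mean_triple
    for gi, value in enumerate(grid):
        if common_random_numbers:
            seed = base.seed
        else:
            seed = base.seed + 10_000 * param_offset + 100 * (gi + 1)
        cfg = _scenario_config(base, param, float(value), seed)
        runs = run_scenario(cfg, n_runs, hemo, seconds_per_unit)
        comm = np.array(
            [
                communication_change(
                    fc_r - baseline.mean_fc, baseline.model, triple_r - base_triple
                )
                for fc_r, triple_r in zip(runs.fc, runs.triples())
            ]
        )
        fc_runs[gi] = runs.fc
        comm_runs[gi] = comm
        mean_fc[gi], sd_fc[gi] = runs.fc.mean(), runs.fc.std(ddof=1)
        mean_comm[gi], sd_comm[gi] = comm.mean(), comm.std(ddof=1)
        mean_pc[gi], sd_pc[gi] = runs.pcorr.mean(), runs.pcorr.std(ddof=1)
    return SweepResult(
        param=param,
        grid=grid,
        mean_fc=mean_fc,
        sd_fc=sd_fc,
        mean_comm=mean_comm,
        sd_comm=sd_comm,
        mean_pcorr=mean_pc,
        sd_pcorr=sd_pc,
        slope_fc=_slope(grid, mean_fc),
        slope_comm=_slope(grid, mean_comm),
        slope_pcorr=_slope(grid, mean_pc),
        fc_runs=fc_runs,
        comm_runs=comm_runs,
    )


def _bootstrap_ratio(
    sweep: SweepResult, n_boot: int, rng: np.random.Generator
) -> np.ndarray:
    n_grid, n_runs = sweep.fc_runs.shape
    ratios = np.empty(n_boot)
    for b in range(n_boot):
        # paired resampling: the same run indices at every grid value, so a
        # common-random-numbers sweep keeps its run-level pairing
        idx = rng.integers(0, n_runs, size=n_runs)
        mfc = sweep.fc_runs[:, idx].mean(axis=1)
        mcm = sweep.comm_runs[:, idx].mean(axis=1)
        s_fc = _slope(sweep.grid, mfc)
        s_cm = _slope(sweep.grid, mcm)
        ratios[b] = np.abs(s_fc) / np.abs(s_cm) if s_cm != 0 else np.inf
    return ratios


def sensitivity_ratios(
    sweep_shared: SweepResult,
    sweep_unshared: SweepResult,
    n_boot: int = 200,
    seed: int = 0,
) -> SensitivityRatios:
    """How much more sensitive FC is than communication to input variance.

    Ratio |slope(FC)| / |slope(comm)| per variance sweep; a ratio above 1
    means the input effect is dampened in communication change.  Bootstrap
    CIs (95%, resampling runs within each grid value) quantify stability;
    a near-zero communication slope makes the ratio unstable, which the CI
    width reveals.
    """
    rng = np.random.default_rng(seed)
    r_sh = abs(sweep_shared.slope_fc) / abs(sweep_shared.slope_comm)
    r_un = abs(sweep_unshared.slope_fc) / abs(sweep_unshared.slope_comm)
    boot_sh = _bootstrap_ratio(sweep_shared, n_boot, rng)
    boot_un = _bootstrap_ratio(sweep_unshared, n_boot, rng)
    ci = lambda b: tuple(np.percentile(b, [2.5, 97.5]).tolist())
    return SensitivityRatios(
        ratio_shared=float(r_sh),
        ratio_unshared=float(r_un),
        dampening_shared=r_sh > 1,
        dampening_unshared=r_un > 1,
        ci_shared=ci(boot_sh),
        ci_unshared=ci(boot_un),
    )


# ---------------------------------------------------------------------------
# Parcellated task-vs-rest pipeline
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PipelineResult:
    """Edge-level outputs of the task-vs-rest analysis."""

    records: pd.DataFrame  # one row per edge x condition x session
    prediction_corr: pd.DataFrame  # per-edge corr(actual dFC, predicted dFC)
    icc: pd.DataFrame  # per-edge ICC(1,k) of dFC and dComm across conditions
    baseline_models: dict[tuple[int, int], BaselineModel]
    adjacency: np.ndarray
    n_edges_skipped: int


def _edge_session_measure(
    data: np.ndarray, i: int, j: int, hood, allow_rank_deficient: bool = False
) -> tuple[float, InputVarianceTriple]:
    """FC and input-variance triple of edge (i, j) in one session matrix."""
    fc = pearson_fc(data[:, i], data[:, j])
    sh_signals = [data[:, n] for n in sorted(hood.n_shared)]
    n1_signals = [data[:, n] for n in sorted(hood.n_only_i)]
    n2_signals = [data[:, n] for n in sorted(hood.n_only_j)]
    triple = InputVarianceTriple(
        shared=shared_input_variance(sh_signals),
        unshared_1=unshared_input_variance(n1_signals, sh_signals, allow_rank_deficient),
        unshared_2=unshared_input_variance(n2_signals, sh_signals, allow_rank_deficient),
    )
    return fc, triple


def task_rest_pipeline(
    sessions: Sequence[SessionMatrix],
    sparsity: float = 0.05,
    rest_condition: str = "rest",
    icc_floor_negative: bool = True,
    allow_rank_deficient: bool = True,
) -> PipelineResult:
    """Full communication-change analysis of a labeled multi-session cohort.

    The graph and neighbor sets come from the average rest-session FC at the
    given sparsity; per-edge baseline regressions are fitted across rest
    sessions; every session (task and rest alike, so rest can serve as a
    condition in the ICC) is scored against the rest means.  Edges whose
    baseline regression is degenerate are skipped and counted.
    """
    rest = [s for s in sessions if s.condition == rest_condition]
    tasks = [s for s in sessions if s.condition != rest_condition]
    if len(rest) < 5:
        raise ValueError("need at least 5 rest sessions for the baseline model")
    if not tasks:
        raise ValueError("need at least one non-rest condition")

    # Graph from average rest FC.
    rest_fc_mats = [np.corrcoef(s.data.T) for s in rest]
    adjacency = threshold_graph(np.mean(rest_fc_mats, axis=0), sparsity)
    edges = [tuple(e) for e in np.argwhere(np.triu(adjacency, k=1))]

    rows = []
    models: dict[tuple[int, int], BaselineModel] = {}
    n_skipped = 0
    for (i, j) in edges:
        hood = neighbor_sets(adjacency, i, j)
        rest_fc = np.empty(len(rest))
        rest_triples = []
        for r, sess in enumerate(rest):
            fc, triple = _edge_session_measure(
                sess.data, i, j, hood, allow_rank_deficient
            )
            rest_fc[r] = fc
            rest_triples.append(triple)
        model = fit_baseline_model(rest_fc, rest_triples)
        if not model.defined:
            n_skipped += 1
            continue
        models[(i, j)] = model
        rest_mean_fc = rest_fc.mean()
        rest_mean_triple = InputVarianceTriple(
            *np.mean([t.as_array() for t in rest_triples], axis=0)
        )
        for sess in itertools.chain(rest, tasks):
            fc, triple = _edge_session_measure(
                sess.data, i, j, hood, allow_rank_deficient
            )
            d_fc = fc - rest_mean_fc
            d_triple = triple - rest_mean_triple
            pred = predict_delta_fc(model, d_triple)
            rows.append(
                {
                    "edge_i": i,
                    "edge_j": j,
                    "condition": sess.condition,
                    "session": sess.session,
                    "delta_fc": d_fc,
                    "d_shared": d_triple[0],
                    "d_unshared1": d_triple[1],
                    "d_unshared2": d_triple[2],
                    "predicted_delta_fc": pred,
                    "delta_comm": d_fc - pred,
                }
            )

    records = pd.DataFrame(rows)

    # Per-edge accuracy: corr(actual, predicted) over task sessions only.
    pred_rows = []
    task_records = records[records["condition"] != rest_condition]
    for (i, j), grp in task_records.groupby(["edge_i", "edge_j"]):
        if grp["predicted_delta_fc"].std(ddof=1) == 0 or grp["delta_fc"].std(ddof=1) == 0:
            r = np.nan
        else:
            r = pearson_fc(grp["delta_fc"].to_numpy(), grp["predicted_delta_fc"].to_numpy())
        pred_rows.append({"edge_i": i, "edge_j": j, "prediction_corr": r})
    prediction_corr = pd.DataFrame(pred_rows)

    # Per-edge ICC(1,k) across conditions (rest included as a condition).
    icc_rows = []
    for (i, j), grp in records.groupby(["edge_i", "edge_j"]):
        row = {"edge_i": i, "edge_j": j}
        for measure in ("delta_fc", "delta_comm"):
            res = icc1k_long(
                grp,
                group_col="condition",
                rater_col="session",
                value_col=measure,
                floor_negative=icc_floor_negative,
            )
            key = "fc" if measure == "delta_fc" else "comm"
            row[f"icc_{key}"] = res.icc
            row[f"icc_{key}_p"] = res.p_value
        icc_rows.append(row)
    icc = pd.DataFrame(icc_rows)

    return PipelineResult(
        records=records,
        prediction_corr=prediction_corr,
        icc=icc,
        baseline_models=models,
        adjacency=adjacency,
        n_edges_skipped=n_skipped,
    )
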