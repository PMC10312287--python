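"""Synthetic multi-session rest/task cohort with known ground truth.

Generates parcellated BOLD-like session matrices from a linear latent-factor
model with community structure:

    y = (I - C)^{-1} (L * driver + noise),  then AR(1) temporal smoothing,

where each parcel loads on its community's shared latent driver with a
parcel-specific loading ``L`` (heterogeneous, so within-community FC varies
and thresholded graphs have ragged, realistic neighborhoods), receives
independent idiosyncratic noise, and is influenced by its peers through a
sparse coupling matrix ``C``.  Baseline coupling is directional: a fixed set
of source -> receiver pairs (``C[receiver, source] = w``), mimicking
afferent projections; each receiver thereby gains an idiosyncratic neighbor
(its source) in thresholded graphs.  Because the baseline C is
feed-forward, a condition perturbation that couples two non-source parcels
changes only those two parcels' series — the perturbation is provably
confined to the pair, which makes coupling-recovery scoring exact.  This
realizes exactly the three factors the communication-change
decomposition targets — local coupling (``C``), shared input (community
drivers) and unshared input (idiosyncratic noise) — at a scale where the
whole task-vs-rest pipeline runs in seconds and expected correlations are
analytically checkable (two uncoupled parcels with unit loading on one
driver of variance v over unit noise correlate at v/(v+1)).

Session-to-session variability is injected by jittering driver and noise
amplitudes per session, mimicking slow state fluctuations across scanning
days; the baseline regression of FC on input variances feeds on exactly
this variation.

Per-condition perturbations change one mechanism at a time:

* ``coupling``      — add an offset to C on listed edges;
* ``shared_amp``    — scale the driver amplitude of listed communities;
* ``unshared_amp``  — scale the idiosyncratic noise of listed parcels.

A ground-truth ledger records every applied perturbation so recovery can be
scored edge by edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import lfilter

__all__ = [
    "Perturbation",
    "CohortConfig",
    "CohortStructure",
    "SessionMatrix",
    "base_structure",
    "generate_cohort",
]


@dataclass(frozen=True)
class Perturbation:
    """One per-condition change of a single generative mechanism.

    ``kind`` is 'coupling' (targets: edge tuples, effect added to C),
    'shared_amp' (targets: community labels, driver std scaled by effect) or
    'unshared_amp' (targets: parcel indices, noise std scaled by effect).
    """

    condition: str
    kind: str
    targets: tuple
    effect: float

    def __post_init__(self) -> None:
        if self.kind not in ("coupling", "shared_amp", "unshared_amp"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")
        if self.kind != "coupling" and self.effect < 0:
            raise ValueError("amplitude scale factors must be nonnegative")


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for one synthetic cohort.

    Defaults mimic the shape of a deep precision-fMRI dataset at desk scale:
    50 parcels in 4 communities, 10 sessions in each of 4 conditions
    (rest plus three tasks), 800 time points per session.
    """

    n_parcels: int = 50
    n_communities: int = 4
    n_sessions: int = 10  # per condition
    n_timepoints: int = 800
    conditions: tuple[str, ...] = ("rest", "task_a", "task_b", "task_c")
    driver_var: float = 1.0  # shared latent driver variance per community
    idio_var: float = 1.0  # idiosyncratic noise variance per parcel
    loading_range: tuple[float, float] = (0.5, 1.5)  # per-parcel driver loading
    n_coupled_pairs: int = 25  # source -> receiver pairs (random matching)
    coupling_weight: float = 0.7  # C[receiver, source] for each pair
    ar_coef: float = 0.3  # first-order autoregressive smoothing
    session_var_jitter: float = 0.2  # session-to-session input-amplitude spread
    perturbations: tuple[Perturbation, ...] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.driver_var < 0 or self.idio_var < 0:
            raise ValueError("variances must be nonnegative")
        if not 0 <= self.ar_coef < 1:
            raise ValueError("ar_coef must lie in [0, 1)")
        if self.n_parcels < self.n_communities:
            raise ValueError("need at least one parcel per community")
        if not 0 < self.loading_range[0] <= self.loading_range[1]:
            raise ValueError("loading_range must be positive and ordered")
        if "rest" not in self.conditions:
            raise ValueError("a 'rest' condition is required")
        for p in self.perturbations:
            if p.condition not in self.conditions:
                raise ValueError(
                    f"perturbation targets unknown condition {p.condition!r}"
                )


@dataclass(frozen=True)
class CohortStructure:
    """The fixed (condition-independent) anatomy of a cohort.

    Drawn deterministically from ``config.seed``; shared by all sessions and
    conditions so that only the configured perturbations differ between
    rest and task.
    """

    community: np.ndarray  # (n_parcels,) community label per parcel
    loading: np.ndarray  # (n_parcels,) driver loading per parcel
    coupling: np.ndarray  # (n_parcels, n_parcels), C[i, j]: influence of j on i
    coupled_pairs: tuple[tuple[int, int], ...]  # (source, receiver) pairs

    @property
    def sources(self) -> frozenset[int]:
        return frozenset(s for s, _ in self.coupled_pairs)

    @property
    def receivers(self) -> frozenset[int]:
        return frozenset(r for _, r in self.coupled_pairs)


@dataclass(frozen=True)
class SessionMatrix:
    """One session's time-by-parcel data with its labels."""

    data: np.ndarray  # (n_timepoints, n_parcels)
    session: int
    condition: str
    parcel_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.data.ndim != 2:
            raise ValueError("session data must be 2-dimensional")
        if np.any(np.isnan(self.data)):
            raise ValueError("session data contains NaN")
        if self.data.shape[0] < 100:
            raise ValueError("sessions require at least 100 time points")


def base_structure(config: CohortConfig) -> CohortStructure:
    """Draw the cohort's fixed community/loading/coupling structure."""
    p = config.n_parcels
    community = np.empty(p, dtype=int)
    for c, parcels in enumerate(np.array_split(np.arange(p), config.n_communities)):
        community[parcels] = c
    rng = np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(999,))
    )
    lo, hi = config.loading_range
    loading = rng.uniform(lo, hi, size=p)
    # Source -> receiver pairs form a random matching: each parcel plays at
    # most one role in one pair, so baseline coupling is feed-forward
    # (nilpotent C) and no parcel becomes a coupling hub.
    perm = rng.permutation(p)
    n_pairs = min(config.n_coupled_pairs, p // 2)
    pairs = tuple(
        sorted((int(perm[2 * m]), int(perm[2 * m + 1])) for m in range(n_pairs))
    )
    C = np.zeros((p, p))
    for (src, rcv) in pairs:
        C[rcv, src] = config.coupling_weight
    return CohortStructure(
        community=community, loading=loading, coupling=C, coupled_pairs=pairs
    )


def expected_correlation(
    config: CohortConfig,
    structure: CohortStructure | None = None,
    condition: str = "rest",
) -> np.ndarray:
    """Model-implied parcel correlation matrix for one condition.

    Exact under the linear generator (the AR(1) smoothing applies the same
    filter to every parcel, leaving zero-lag correlations unchanged, and
    session amplitude jitter averages out):

        Sigma_base = v * (l l^T ∘ same-community) + diag(idio),
        Sigma_y    = (I-C)^{-1} Sigma_base (I-C)^{-T}.
    """
    if structure is None:
        structure = base_structure(config)
    C, driver_std, noise_std = _condition_params(config, structure, condition)
    same = structure.community[:, None] == structure.community[None, :]
    comm_var = (driver_std**2)[structure.community]
    sigma_base = (
        np.outer(structure.loading, structure.loading)
        * same
        * np.sqrt(np.outer(comm_var, comm_var))
    )
    sigma_base[np.diag_indices_from(sigma_base)] += noise_std**2
    mix = np.linalg.inv(np.eye(config.n_parcels) - C)
    sigma = mix @ sigma_base @ mix.T
    d = np.sqrt(np.diag(sigma))
    return sigma / np.outer(d, d)


def strong_community_edges(
    config: CohortConfig,
    structure: CohortStructure | None = None,
    sparsity: float = 0.05,
    n_edges: int = 4,
) -> tuple[tuple[int, int], ...]:
    """Within-community edges of the expected rest graph with full neighborhoods.

    Ranks edges of the model-implied rest correlation graph (thresholded at
    ``sparsity``) by expected FC and returns the strongest within-community
    edges whose shared and both exclusive neighbor sets are nonempty — the
    natural targets for coupling perturbations whose recovery is scored,
    since their baseline regression is well defined.  Two exclusions keep a
    coupling perturbation on the chosen edges strictly confined to their own
    node pairs: at most one edge per community (a perturbed endpoint sits in
    the shared neighborhood of other same-community edges), and no endpoint
    may be a source of the feed-forward baseline coupling (perturbing a
    source's series would propagate into its receiver's series and bias
    neighboring edges' variance estimates).
    """
    from .graph_neighbors import neighbor_sets, threshold_graph

    if structure is None:
        structure = base_structure(config)
    corr = expected_correlation(config, structure)
    adj = threshold_graph(corr, sparsity)
    sources = structure.sources
    candidates = [
        (corr[i, j], (int(i), int(j)))
        for i, j in np.argwhere(np.triu(adj, k=1))
        if structure.community[i] == structure.community[j]
        and int(i) not in sources
        and int(j) not in sources
    ]
    chosen: list[tuple[int, int]] = []
    used_communities: set[int] = set()
    for _, (i, j) in sorted(candidates, reverse=True):
        c = int(structure.community[i])
        if c in used_communities:
            continue
        hood = neighbor_sets(adj, i, j)
        if hood.n_shared and hood.n_only_i and hood.n_only_j:
            chosen.append((i, j))
            used_communities.add(c)
        if len(chosen) == n_edges:
            break
    return tuple(chosen)


def _condition_params(
    config: CohortConfig, structure: CohortStructure, condition: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(C, driver_std per community, noise_std per parcel) for a condition."""
    C = structure.coupling.copy()
    driver_std = np.full(config.n_communities, np.sqrt(config.driver_var))
    noise_std = np.full(config.n_parcels, np.sqrt(config.idio_var))
    for p in config.perturbations:
        if p.condition != condition:
            continue
        if p.kind == "coupling":
            for (i, j) in p.targets:
                C[i, j] += p.effect
                C[j, i] += p.effect
        elif p.kind == "shared_amp":
            for c in p.targets:
                driver_std[c] *= p.effect
        else:  # unshared_amp
            for i in p.targets:
                noise_std[i] *= p.effect
    return C, driver_std, noise_std


def generate_cohort(
    config: CohortConfig,
) -> tuple[list[SessionMatrix], list[dict]]:
    """Generate all sessions of the cohort plus the ground-truth ledger.

    Returns ``(sessions, ledger)`` where the ledger lists, for every
    perturbation, the affected edges/communities/parcels with kind and
    signed direction.  Fully reproducible from ``config.seed``; session s of
    condition c depends only on (seed, condition index, s).
    """
    structure = base_structure(config)
    parcel_names = tuple(f"p{i:03d}" for i in range(config.n_parcels))
    sessions: list[SessionMatrix] = []
    ledger: list[dict] = [
        {
            "condition": p.condition,
            "kind": p.kind,
            "targets": list(p.targets),
            "effect": p.effect,
            "sign": int(
                np.sign(p.effect if p.kind == "coupling" else p.effect - 1.0)
            ),
        }
        for p in config.perturbations
    ]

    eye = np.eye(config.n_parcels)
    for ci, condition in enumerate(config.conditions):
        C, driver_std, noise_std = _condition_params(config, structure, condition)
        radius = np.max(np.abs(np.linalg.eigvals(C)))
        if radius >= 1:
            raise ValueError(
                f"coupling spectral radius {radius:.3f} >= 1 in condition "
                f"{condition!r}: generative model unstable"
            )
        mix = np.linalg.inv(eye - C)
        for s in range(config.n_sessions):
            ss = np.random.SeedSequence(entropy=config.seed, spawn_key=(ci, s))
            rng = np.random.default_rng(ss)
            # Slow day-to-day fluctuation of input amplitudes; the baseline
            # FC-on-variance regression is identified by this variation.
            d_jit = np.abs(
                1.0
                + config.session_var_jitter * rng.standard_normal(config.n_communities)
            )
            n_jit = np.abs(
                1.0 + config.session_var_jitter * rng.standard_normal(config.n_parcels)
            )
            drivers = rng.standard_normal(
                (config.n_timepoints, config.n_communities)
            ) * (driver_std * d_jit)
            noise = rng.standard_normal(
                (config.n_timepoints, config.n_parcels)
            ) * (noise_std * n_jit)
            base = structure.loading * drivers[:, structure.community] + noise
            y = base @ mix.T
            if config.ar_coef > 0:
                y = lfilter([1.0], [1.0, -config.ar_coef], y, axis=0)
            sessions.append(
                SessionMatrix(
                    data=y, session=s, condition=condition,
                    parcel_labels=parcel_names,
                )
            )
    return sessions, ledger
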