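"""Synthetic survival cohorts with overlapping gene groups.

Environments and genes are multivariate normal with AR(1) correlations
(0.3 and 0.5 by default), survival times are exponential with rate
``10 * exp(linear predictor)``, and censoring times are uniform on ``(0, b)``
with ``b`` calibrated by Monte-Carlo bisection to hit a target censoring
rate. All randomness flows from one master seed through named substreams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coxcore import SurvivalDataset
from .pathways import PathwayCollection, build_expansion, chain_layout, collapse_latent

__all__ = [
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_OVERLAPS",
    "SimConfig",
    "TrueParameters",
    "default_pathways",
    "true_parameters",
    "calibrate_censoring_bound",
    "simulate_dataset",
]

#: chain-overlap group layout used by the simulation design: 25 groups,
#: consecutive pairs share the stated number of genes (500 unique genes,
#: 632 latent columns in total)
DEFAULT_GROUP_SIZES: tuple[int, ...] = (
    3, 3, 3, 6, 6, 6, 9, 9, 9, 15, 15, 15, 24, 24, 24,
    36, 36, 36, 45, 45, 45, 60, 60, 60, 38,
)
DEFAULT_OVERLAPS: tuple[int, ...] = (
    1, 1, 0, 2, 2, 0, 3, 3, 0, 5, 5, 0, 8, 8, 0, 12, 12, 0, 15, 15, 0, 20, 20, 0,
)


@dataclass(frozen=True)
class SimConfig:
    """Design constants of the simulation study."""

    n_train: int = 300
    n_test: int = 100
    q: int = 5
    alpha: tuple[float, ...] = (1.5, 2.25, 3.0, -1.5, 0.0)
    ar_env: float = 0.3
    ar_gene: float = 0.5
    group_sizes: tuple[int, ...] = DEFAULT_GROUP_SIZES
    group_overlaps: tuple[int, ...] = DEFAULT_OVERLAPS
    #: group id -> constant latent effect shared by its member genes
    effective_groups: tuple[tuple[str, float], ...] = (
        ("1", 3.0), ("7", 3.0), ("13", 2.0), ("19", -2.0),
    )
    #: (environment name, gene name, effect, group the pair belongs to)
    interaction_effects: tuple[tuple[str, str, float, str], ...] = (
        ("E1", "G22", 1.5, "7"),
        ("E1", "G24", 1.5, "7"),
        ("E2", "G26", 2.0, "7"),
        ("E2", "G78", -1.0, "13"),
        ("E3", "G83", -1.5, "13"),
        ("E3", "G88", -2.0, "13"),
    )
    baseline_rate: float = 10.0
    censor_target: float = 0.30

    @property
    def env_names(self) -> tuple[str, ...]:
        return tuple(f"E{j}" for j in range(1, self.q + 1))


@dataclass(frozen=True)
class TrueParameters:
    """Full true coefficient vector over (environments, genes, interactions)."""

    feature_names: tuple[str, ...]
    theta: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray
    eta: np.ndarray

    @property
    def support(self) -> tuple[str, ...]:
        return tuple(
            n for n, v in zip(self.feature_names, self.theta) if v != 0.0
        )

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.theta))

    @property
    def size(self) -> int:
        return self.theta.shape[0]


def default_pathways(config: SimConfig = SimConfig()) -> PathwayCollection:
    """The simulation's chain-overlap group structure."""
    return chain_layout(config.group_sizes, config.group_overlaps)


def true_parameters(config: SimConfig = SimConfig()) -> TrueParameters:
    """Assemble the true coefficient vector of the simulation design.

    Gene effects collapse the per-group constant latent effects through the
    expansion map; interaction effects sit on the six named pairs. A named
    interaction gene outside its stated group raises (layout corruption
    guard).
    """
    pathways = default_pathways(config)
    expansion = build_expansion(pathways)
    slices = expansion.group_column_slices()
    gamma = np.zeros(expansion.d)
    for gid, effect in config.effective_groups:
        gamma[slices[gid]] = effect
    beta = collapse_latent(gamma, expansion)

    env_names = config.env_names
    gene_names = pathways.genes
    for env, gene, _eff, gid in config.interaction_effects:
        members = pathways.members[pathways.group_names.index(gid)]
        if gene not in members:
            raise ValueError(
                f"interaction gene {gene!r} is not in its stated group {gid!r}"
            )
        if env not in env_names:
            raise ValueError(f"unknown environment {env!r}")
    alpha = np.asarray(config.alpha, float)
    if alpha.shape[0] != config.q:
        raise ValueError("alpha length must equal q")

    eta = np.zeros(config.q * len(gene_names))
    gene_pos = {g: i for i, g in enumerate(gene_names)}
    env_pos = {e: i for i, e in enumerate(env_names)}
    for env, gene, eff, _gid in config.interaction_effects:
        eta[env_pos[env] * len(gene_names) + gene_pos[gene]] = eff

    names = (
        env_names
        + gene_names
        + tuple(f"{e}:{g}" for e in env_names for g in gene_names)
    )
    theta = np.concatenate([alpha, beta, eta])
    return TrueParameters(
        feature_names=names, theta=theta, alpha=alpha, beta=beta, eta=eta
    )


def _ar1_normal(rng: np.random.Generator, n: int, p: int, rho: float) -> np.ndarray:
    """Standard-normal matrix with AR(1) column correlation ``rho^|j-k|``."""
    z = rng.standard_normal((n, p))
    x = np.empty_like(z)
    x[:, 0] = z[:, 0]
    scale = np.sqrt(1.0 - rho * rho)
    for j in range(1, p):
        x[:, j] = rho * x[:, j - 1] + scale * z[:, j]
    return x


def _linear_predictor(
    E: np.ndarray, X: np.ndarray, config: SimConfig, truth: TrueParameters
) -> np.ndarray:
    lp = E @ truth.alpha + X @ truth.beta
    env_pos = {e: i for i, e in enumerate(config.env_names)}
    gene_pos = {g: i for i, g in enumerate(default_pathways(config).genes)}
    for env, gene, eff, _gid in config.interaction_effects:
        lp = lp + eff * E[:, env_pos[env]] * X[:, gene_pos[gene]]
    return lp


def _draw_event_times(
    rng: np.random.Generator, lp: np.ndarray, rate: float
) -> np.ndarray:
    """Exponential survival times with rate ``rate * exp(lp)``, computed in
    log space; values below 1e-300 are floored."""
    log_u = np.log(rng.exponential(scale=1.0, size=lp.shape[0]))
    log_t = log_u - np.log(rate) - lp
    log_t = np.clip(log_t, np.log(1e-300), None)
    return np.exp(log_t)


_CENSOR_CACHE: dict[tuple, float] = {}


def _config_key(config: SimConfig) -> tuple:
    return (
        config.q, config.alpha, config.ar_env, config.ar_gene,
        config.group_sizes, config.group_overlaps, config.effective_groups,
        config.interaction_effects, config.baseline_rate,
    )


def calibrate_censoring_bound(
    config: SimConfig,
    target: float | None = None,
    mc_draws: int = 100_000,
    calib_seed: int = 2_024,
    tol: float = 0.005,
) -> float:
    """Upper bound ``b`` of the Uniform(0, b) censoring distribution such
    that the censoring probability ``P(C < T)`` is within ``tol`` of the
    target, by Monte-Carlo bisection. Cached per (design, target)."""
    if target is None:
        target = config.censor_target
    if not (0.0 < target < 1.0):
        raise ValueError("target censoring rate must be in (0, 1)")
    key = (_config_key(config), round(target, 6), mc_draws, calib_seed)
    if key in _CENSOR_CACHE:
        return _CENSOR_CACHE[key]

    truth = true_parameters(config)
    rng = np.random.default_rng(np.random.SeedSequence(calib_seed))
    p = len(truth.beta)
    times = np.empty(mc_draws)
    chunk = 20_000
    for start in range(0, mc_draws, chunk):
        m = min(chunk, mc_draws - start)
        E = _ar1_normal(rng, m, config.q, config.ar_env)
        X = _ar1_normal(rng, m, p, config.ar_gene)
        lp = _linear_predictor(E, X, config, truth)
        times[start : start + m] = _draw_event_times(rng, lp, config.baseline_rate)

    def censor_rate(b: float) -> float:
        # P(C < T) with C ~ U(0, b) equals E[min(T, b)] / b
        return float(np.minimum(times, b).mean() / b)

    lo = hi = float(np.quantile(times, 1.0 - target))
    lo = max(lo, 1e-250)
    hi = max(hi, 1e-250)
    for _ in range(200):
        if censor_rate(lo) > target:
            break
        lo /= 8.0
    for _ in range(200):
        if censor_rate(hi) < target:
            break
        hi *= 8.0
    b = lo
    for _ in range(60):
        b = float(np.sqrt(lo * hi))  # bisect on the log scale
        r = censor_rate(b)
        if abs(r - target) <= tol:
            break
        if r > target:
            lo = b
        else:
            hi = b
    _CENSOR_CACHE[key] = b
    return b


def _draw_cohort(
    config: SimConfig,
    truth: TrueParameters,
    pathways: PathwayCollection,
    n: int,
    bound: float,
    seeds,
) -> SurvivalDataset:
    rng_cov, rng_surv, rng_cens = (np.random.default_rng(s) for s in seeds)
    p = pathways.p
    E = _ar1_normal(rng_cov, n, config.q, config.ar_env)
    X = _ar1_normal(rng_cov, n, p, config.ar_gene)
    lp = _linear_predictor(E, X, config, truth)
    T = _draw_event_times(rng_surv, lp, config.baseline_rate)
    C = rng_cens.uniform(0.0, bound, size=n)
    C = np.clip(C, 1e-300, None)
    t = np.minimum(T, C)
    delta = (T <= C).astype(int)
    return SurvivalDataset(
        time=t,
        event=delta,
        E=E,
        X=X,
        env_names=config.env_names,
        gene_names=pathways.genes,
    )


def simulate_dataset(
    config: SimConfig = SimConfig(),
    seed: int = 0,
    censor_bound: float | None = None,
) -> tuple[SurvivalDataset, SurvivalDataset, TrueParameters]:
    """Draw one training and one (independent) test cohort plus the true
    parameters. The censoring bound is calibrated once per design and reused
    for both cohorts; same seed gives bitwise-identical datasets."""
    truth = true_parameters(config)
    pathways = default_pathways(config)
    if censor_bound is None:
        censor_bound = calibrate_censoring_bound(config)
    ss = np.random.SeedSequence(seed).spawn(6)
    train = _draw_cohort(
        config, truth, pathways, config.n_train, censor_bound, ss[:3]
    )
    test = _draw_cohort(
        config, truth, pathways, config.n_test, censor_bound, ss[3:]
    )
    return train, test, truth
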