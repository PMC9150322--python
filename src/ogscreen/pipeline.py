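"""Four-step overlapping-group screening of gene-environment interactions.

Step 1 selects candidate pathways by an overlapping-group-lasso Cox fit on
the latent-effect expansion. Step 2 scores each candidate pathway's
interaction block with the variance-component test. Step 3 calibrates a
selection cutoff by permuting covariate rows: each replicate permutes E and X
jointly (outcomes fixed), refits the null model, recomputes all group
p-values and records their minimum; the cutoff is the median of those minima.
Step 4 fits the final penalized Cox model on the environments, the selected
genes and the selected interaction columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .coxcore import (
    FinalModel,
    SurvivalDataset,
    fit_null_cox,
    fit_overlap_group_cox,
    fit_penalized_cox,
)
from .pathways import PathwayCollection, build_expansion
from .skat import skat_group_pvalue

__all__ = [
    "OgsConfig",
    "OgsSelection",
    "permutation_threshold",
    "select_interaction_groups",
    "run_ogs",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OgsConfig:
    """Tuning knobs for the four-step pipeline."""

    penalty: str = "lasso"
    permutations: int = 30  # I
    folds: int = 10
    n_lambdas_group: int = 100
    lambda_min_ratio_group: float = 1e-3
    group_cv_rule: str = "1se"
    n_lambdas_final: int = 100
    lambda_min_ratio_final: float = 1e-2
    unpenalized_env: bool = False


@dataclass
class OgsSelection:
    """Record of the screening decisions."""

    m_main: tuple[str, ...]
    group_pvalues: dict[str, float]
    tau: tuple[float, ...]
    c_int: float
    m_int: tuple[str, ...]
    selected_genes: tuple[str, ...]
    selected_interactions: tuple[tuple[str, str], ...]
    permutations: int
    early_stop: bool = False
    extras: dict = field(default_factory=dict)

    @property
    def A(self) -> int:
        return len(self.m_main)


def _group_pvalues(
    data: SurvivalDataset,
    null,
    pathways: PathwayCollection,
    group_ids,
) -> dict[str, float]:
    out = {}
    for gid in group_ids:
        genes = pathways.members[pathways.group_names.index(gid)]
        out[gid] = skat_group_pvalue(data, null, genes, group_id=gid).p
    return out


def permutation_threshold(
    data: SurvivalDataset,
    pathways: PathwayCollection,
    m_main,
    permutations: int = 30,
    rng_seed: int = 0,
    max_retries: int = 5,
) -> tuple[tuple[float, ...], float]:
    """Permutation-calibrated cutoff for the group p-values.

    Each replicate draws one permutation ``pi`` shared by the environment and
    expression rows (outcomes stay in place), refits the null Cox model on
    the permuted environments, recomputes the p-value of every candidate
    group and keeps the minimum; the cutoff is the median of the
    ``permutations`` minima. Deterministic given ``rng_seed``.
    """
    if len(m_main) < 1:
        raise ValueError("need at least one candidate group")
    if permutations < 1:
        raise ValueError("need at least one permutation replicate")
    rng = np.random.default_rng(rng_seed)
    taus: list[float] = []
    for r in range(permutations):
        for attempt in range(max_retries + 1):
            pi = rng.permutation(data.n)
            permuted = SurvivalDataset(
                time=data.time,
                event=data.event,
                E=data.E[pi],
                X=data.X[pi],
                env_names=data.env_names,
                gene_names=data.gene_names,
            )
            try:
                null_perm = fit_null_cox(permuted)
                pvals = _group_pvalues(permuted, null_perm, pathways, m_main)
                break
            except (RuntimeError, np.linalg.LinAlgError) as exc:
                logger.warning(
                    "permutation replicate %d attempt %d failed: %s",
                    r, attempt, exc,
                )
                if attempt == max_retries:
                    raise
        taus.append(min(pvals.values()))
    c_int = float(np.median(taus))
    return tuple(taus), c_int


def select_interaction_groups(group_pvalues: dict[str, float], c_int: float):
    """Groups whose p-value is strictly below the cutoff."""
    for gid, p in group_pvalues.items():
        if not (0.0 <= p <= 1.0):
            raise ValueError(f"p-value for group {gid!r} outside [0, 1]")
    return tuple(gid for gid, p in group_pvalues.items() if p < c_int)


def run_ogs(
    data: SurvivalDataset,
    pathways: PathwayCollection,
    config: OgsConfig = OgsConfig(),
    rng_seed: int = 0,
) -> tuple[OgsSelection, FinalModel]:
    """Run the full four-step pipeline and return the selection record plus
    the fitted final model. Deterministic given ``rng_seed``."""
    expansion = build_expansion(pathways)
    step1 = fit_overlap_group_cox(
        data,
        expansion,
        folds=config.folds,
        rng_seed=rng_seed,
        n_lambdas=config.n_lambdas_group,
        lambda_min_ratio=config.lambda_min_ratio_group,
        cv_rule=config.group_cv_rule,
    )
    m_main = step1.selected
    if len(m_main) == 0:
        logger.warning("no pathway selected; falling back to environment-only model")
        model = fit_penalized_cox(
            data.time,
            data.event,
            data.E,
            data.env_names,
            penalty=config.penalty,
            folds=config.folds,
            rng_seed=rng_seed + 1,
            n_lambdas=config.n_lambdas_final,
            lambda_min_ratio=config.lambda_min_ratio_final,
            unpenalized=data.env_names if config.unpenalized_env else (),
        )
        selection = OgsSelection(
            m_main=(),
            group_pvalues={},
            tau=(),
            c_int=float("nan"),
            m_int=(),
            selected_genes=(),
            selected_interactions=(),
            permutations=config.permutations,
            early_stop=True,
            extras={"step1_lambda": step1.lam},
        )
        return selection, model

    null = fit_null_cox(data)
    pvals = _group_pvalues(data, null, pathways, m_main)
    tau, c_int = permutation_threshold(
        data,
        pathways,
        m_main,
        permutations=config.permutations,
        rng_seed=rng_seed + 10_000,
    )
    m_int = select_interaction_groups(pvals, c_int)

    selected_genes = pathways.genes_of(m_main)
    int_genes = pathways.genes_of(m_int) if m_int else ()
    if int_genes:
        U, u_names = data.interactions(int_genes)
        selected_interactions = tuple(
            (env, g) for env in data.env_names for g in int_genes
        )
    else:
        U = np.empty((data.n, 0))
        u_names = ()
        selected_interactions = ()

    gene_idx = [data.gene_names.index(g) for g in selected_genes]
    Z = np.hstack([data.E, data.X[:, gene_idx], U])
    names = tuple(data.env_names) + tuple(selected_genes) + tuple(u_names)
    model = fit_penalized_cox(
        data.time,
        data.event,
        Z,
        names,
        penalty=config.penalty,
        folds=config.folds,
        rng_seed=rng_seed + 1,
        n_lambdas=config.n_lambdas_final,
        lambda_min_ratio=config.lambda_min_ratio_final,
        unpenalized=data.env_names if config.unpenalized_env else (),
    )
    selection = OgsSelection(
        m_main=m_main,
        group_pvalues=pvals,
        tau=tau,
        c_int=c_int,
        m_int=m_int,
        selected_genes=selected_genes,
        selected_interactions=selected_interactions,
        permutations=config.permutations,
        extras={"step1_lambda": step1.lam},
    )
    return selection, model
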