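"""Cox partial-likelihood machinery.

Provides the null-model fit (coefficients, Breslow baseline increments,
martingale residuals and the covariance kernel ``V = diag(c) - P P'``),
penalized Cox regression with ridge or lasso penalties selected by
cross-validated partial-likelihood deviance, and an overlapping-group-lasso
Cox fit on the latent-effect expanded design.

Ties are handled with the Breslow approximation throughout, matching the
Breslow baseline-hazard matrices the downstream variance-component test
requires. Penalized fits standardize design columns internally and report
coefficients on the original scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

from .pathways import ExpansionMap

__all__ = [
    "SurvivalDataset",
    "NullCoxFit",
    "FinalModel",
    "GroupLassoResult",
    "fit_null_cox",
    "fit_penalized_cox",
    "fit_overlap_group_cox",
    "cox_loglik",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class SurvivalDataset:
    """Right-censored survival outcomes with environment and expression blocks.

    ``time`` holds observed times (event or censoring), ``event`` the event
    indicator (1 = event observed). ``E`` is samples x environments, ``X``
    samples x genes. Interaction columns are materialized on demand in
    environment-major order (e1*g1, ..., e1*gk, e2*g1, ...).
    """

    time: np.ndarray
    event: np.ndarray
    E: np.ndarray
    X: np.ndarray
    env_names: tuple[str, ...]
    gene_names: tuple[str, ...]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event)
        self.E = np.atleast_2d(np.asarray(self.E, dtype=float))
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        n = self.time.shape[0]
        if self.event.shape[0] != n or self.E.shape[0] != n or self.X.shape[0] != n:
            raise ValueError("inconsistent sample counts across blocks")
        if np.any(self.time <= 0):
            raise ValueError("observed times must be strictly positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        self.event = self.event.astype(int)
        if len(self.env_names) != self.E.shape[1]:
            raise ValueError("env_names length mismatch")
        if len(self.gene_names) != self.X.shape[1]:
            raise ValueError("gene_names length mismatch")
        self.env_names = tuple(self.env_names)
        self.gene_names = tuple(self.gene_names)

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def q(self) -> int:
        return self.E.shape[1]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def interactions(
        self, genes: Sequence[str] | None = None
    ) -> tuple[np.ndarray, tuple[str, ...]]:
        """Environment-major interaction columns for the given genes
        (all genes by default). Returns the matrix and its column names
        ``"env:gene"``."""
        if genes is None:
            genes = self.gene_names
        idx = [self.gene_names.index(g) for g in genes]
        if len(idx) == 0:
            raise ValueError("no genes requested")
        Xg = self.X[:, idx]
        blocks = [self.E[:, [j]] * Xg for j in range(self.q)]
        names = tuple(f"{env}:{g}" for env in self.env_names for g in genes)
        return np.hstack(blocks), names

    def subset(self, rows: np.ndarray) -> "SurvivalDataset":
        return SurvivalDataset(
            time=self.time[rows],
            event=self.event[rows],
            E=self.E[rows],
            X=self.X[rows],
            env_names=self.env_names,
            gene_names=self.gene_names,
        )


@dataclass
class NullCoxFit:
    """Null Cox model on the environment block only, with the Breslow
    baseline quantities needed by the variance-component test."""

    alpha: np.ndarray
    eta: np.ndarray  # linear predictor E @ alpha
    event_times: np.ndarray  # ordered distinct failure times
    baseline_increments: np.ndarray  # Breslow jumps dLambda0 at event_times
    P: np.ndarray  # n x nu, p_ij = at-risk * exp(eta_i) * dLambda0_j
    c: np.ndarray  # cumulative hazard per subject (row sums of P)
    m: np.ndarray  # martingale residuals, delta - c
    V: np.ndarray  # diag(c) - P P'
    E: np.ndarray  # design used (for projection in the covariance)
    loglik: float
    n_iter: int


@dataclass
class FinalModel:
    """Penalized Cox model over named features; the prognostic index of a
    covariate row is its linear predictor."""

    feature_names: tuple[str, ...]
    coef: np.ndarray
    penalty: str
    lam: float
    cv_deviance: float = np.nan
    dropped_constant: tuple[str, ...] = field(default_factory=tuple)

    def predict(self, Z: np.ndarray) -> np.ndarray:
        """Prognostic index for each row of ``Z`` (columns ordered as
        ``feature_names``)."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if Z.shape[1] != len(self.feature_names):
            raise ValueError("design width does not match fitted features")
        return Z @ self.coef

    @property
    def selected(self) -> tuple[str, ...]:
        return tuple(n for n, b in zip(self.feature_names, self.coef) if b != 0.0)


@dataclass
class GroupLassoResult:
    """Outcome of the overlapping-group-lasso Cox fit: the selected groups
    plus path diagnostics."""

    selected: tuple[str, ...]
    lam: float
    gamma: np.ndarray
    alpha: np.ndarray
    lambdas: np.ndarray
    cv_deviance: np.ndarray


# ---------------------------------------------------------------------------
# Breslow partial-likelihood primitives (vectorized over tied-time blocks)
# ---------------------------------------------------------------------------


def _sorted_views(time, event, eta):
    order = np.argsort(time, kind="stable")
    return order, time[order], event[order].astype(np.int64), eta[order]


def _block_structure(t_sorted: np.ndarray):
    """Start index of each tied-time block plus the block id per subject."""
    starts = np.flatnonzero(np.r_[True, t_sorted[1:] != t_sorted[:-1]])
    counts = np.diff(np.r_[starts, t_sorted.shape[0]])
    block_of = np.repeat(np.arange(starts.shape[0]), counts)
    return starts, block_of


def _breslow_pass(time, event, eta):
    """One pass over the risk sets.

    Returns (in input order unless noted) the log partial likelihood, the
    cumulative hazards ``c``, the diagonal of ``P P'``, distinct event times
    and Breslow increments, and the sorted bookkeeping needed by callers that
    want risk-set means.
    """
    n = time.shape[0]
    order, t, d, eta_s = _sorted_views(time, event, eta)
    shift = float(np.max(eta_s))
    w = np.exp(eta_s - shift)
    s0 = np.cumsum(w[::-1])[::-1]
    starts, block_of = _block_structure(t)
    s0b = s0[starts]
    dcount = np.add.reduceat(d, starts)
    has_event = dcount > 0
    inc_s = np.zeros_like(s0b)
    np.divide(dcount, s0b, out=inc_s, where=has_event & (s0b > 0))  # shifted scale
    cum1 = np.cumsum(inc_s)[block_of]
    cum2 = np.cumsum(inc_s * inc_s)[block_of]
    c_sorted = w * cum1
    ppdiag_sorted = w * w * cum2
    # shift cancels in the partial likelihood (sum of d equals event count)
    ll = float((eta_s - shift)[d > 0].sum() - (dcount[has_event] * np.log(s0b[has_event])).sum())
    c = np.empty(n)
    ppdiag = np.empty(n)
    c[order] = c_sorted
    ppdiag[order] = ppdiag_sorted
    event_times = t[starts][has_event]
    increments = inc_s[has_event] * np.exp(-shift)
    return ll, c, ppdiag, event_times, increments, (order, t, d, w, s0, starts, dcount)


def cox_loglik(time: np.ndarray, event: np.ndarray, eta: np.ndarray) -> float:
    """Breslow-approximation Cox partial log-likelihood at linear predictor
    ``eta``; stable under large ``eta``."""
    return _breslow_pass(time, event, eta)[0]


def _baseline_matrix(time, eta, event_times, increments):
    """Dense ``n x nu`` matrix, ``p_ij = 1{t_i >= t_(j)} exp(eta_i) dLam_j``."""
    at_risk = time[:, None] >= event_times[None, :]
    return at_risk * np.exp(eta)[:, None] * increments[None, :]


def _score_info(time, event, Z, eta):
    """Log-likelihood, score ``Z'm`` and observed information ``Z'VZ``.

    Uses the identities score = Z'(delta - c) and information =
    Z'diag(c)Z - sum_j d_j zbar_j zbar_j' with zbar_j the risk-set mean.
    """
    ll, c, _, _, _, (order, t, d, w, s0, starts, dcount) = _breslow_pass(
        time, event, eta
    )
    m = event - c
    grad = Z.T @ m
    Zs = Z[order]
    s1 = np.cumsum((w[:, None] * Zs)[::-1], axis=0)[::-1]
    has_event = dcount > 0
    zbar = s1[starts][has_event] / s0[starts][has_event][:, None]
    dj = dcount[has_event].astype(float)
    info = Zs.T @ (c[order][:, None] * Zs) - zbar.T @ (dj[:, None] * zbar)
    return ll, grad, info


def _newton_cox(
    time: np.ndarray,
    event: np.ndarray,
    Z: np.ndarray,
    ridge: float = 0.0,
    beta0: np.ndarray | None = None,
    max_iter: int = 100,
    tol: float = 1e-9,
) -> tuple[np.ndarray, float, int, bool]:
    """Newton-Raphson maximizer of the Breslow partial likelihood, optionally
    with a ridge penalty ``n*ridge/2 * ||beta||^2`` subtracted. Returns
    (beta, loglik, n_iter, converged); loglik excludes the penalty."""
    n, p = Z.shape
    beta = np.zeros(p) if beta0 is None else np.asarray(beta0, float).copy()
    ll, grad, info = _score_info(time, event, Z, Z @ beta)
    it = 0
    converged = False
    eye = np.eye(p)
    for it in range(1, max_iter + 1):
        g = grad - ridge * n * beta
        H = info + ridge * n * eye
        try:
            step = np.linalg.solve(H, g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        obj_old = ll - 0.5 * ridge * n * float(beta @ beta)
        frac = 1.0
        for _ in range(35):
            beta_new = beta + frac * step
            ll_new, grad_new, info_new = _score_info(
                time, event, Z, Z @ beta_new
            )
            obj_new = ll_new - 0.5 * ridge * n * float(beta_new @ beta_new)
            if np.isfinite(obj_new) and obj_new >= obj_old - 1e-12:
                break
            frac *= 0.5
        beta, ll, grad, info = beta_new, ll_new, grad_new, info_new
        if np.max(np.abs(frac * step)) < tol or abs(obj_new - obj_old) < tol * (
            abs(obj_old) + 1.0
        ):
            converged = True
            break
    return beta, ll, it, converged


# ---------------------------------------------------------------------------
# public fits
# ---------------------------------------------------------------------------


def fit_null_cox(data: SurvivalDataset, max_iter: int = 100) -> NullCoxFit:
    """Fit the Cox model on the environment block only and assemble the
    Breslow baseline-hazard matrices.

    Returns the coefficient vector, martingale residuals ``m = delta - c``,
    the ``n x nu`` at-risk/hazard matrix ``P`` and the covariance kernel
    ``V = diag(c) - P P'``.
    """
    if data.event.sum() < 1:
        raise ValueError("null Cox fit requires at least one event")
    if np.linalg.matrix_rank(data.E) < data.q:
        raise ValueError("environment design is rank-deficient")
    alpha, ll, it, converged = _newton_cox(
        data.time, data.event, data.E, max_iter=max_iter
    )
    if not converged:
        raise RuntimeError(f"null Cox fit did not converge in {it} iterations")
    eta = data.E @ alpha
    _, c, _, event_times, increments, _ = _breslow_pass(data.time, data.event, eta)
    P = _baseline_matrix(data.time, eta, event_times, increments)
    m = data.event - c
    V = np.diag(c) - P @ P.T
    return NullCoxFit(
        alpha=alpha,
        eta=eta,
        event_times=event_times,
        baseline_increments=increments,
        P=P,
        c=c,
        m=m,
        V=V,
        E=data.E,
        loglik=ll,
        n_iter=it,
    )


def _event_stratified_folds(event, folds, rng_seed):
    folds = max(2, min(folds, int(event.sum())))
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=rng_seed)
    return list(skf.split(np.zeros(event.shape[0]), event))


def _drop_constant_columns(Z, names):
    sd = Z.std(axis=0)
    keep = sd > 0
    dropped = tuple(n for n, k in zip(names, keep) if not k)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} constant design column(s): "
            + ", ".join(dropped[:5])
        )
    return Z[:, keep], tuple(n for n, k in zip(names, keep) if k), dropped


def fit_penalized_cox(
    time: np.ndarray,
    event: np.ndarray,
    Z: np.ndarray,
    feature_names: Sequence[str],
    penalty: str = "lasso",
    folds: int = 10,
    rng_seed: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-2,
    unpenalized: Sequence[str] = (),
) -> FinalModel:
    """Penalized Cox regression with the penalty level chosen by k-fold
    cross-validated partial-likelihood deviance (Verweij-van Houwelingen),
    minimum-deviance rule, folds stratified by event status.

    Lasso fits use the coordinate-descent elastic-net path; ridge fits use a
    Newton solver on a log-spaced grid. Coefficients come back on the
    original covariate scale; deterministic given ``rng_seed``.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    Z = np.atleast_2d(np.asarray(Z, float))
    if event.sum() < 2:
        raise ValueError("need at least two events")
    if Z.shape[1] < 1:
        raise ValueError("design must have at least one column")
    Z, names, dropped = _drop_constant_columns(Z, tuple(feature_names))
    if Z.shape[1] == 0:
        raise ValueError("all design columns are constant")
    if penalty not in ("ridge", "lasso"):
        raise ValueError("penalty must be 'ridge' or 'lasso'")

    fold_idx = _event_stratified_folds(event, folds, rng_seed)
    if penalty == "lasso":
        coef, lam, cvdev = _lasso_cv(
            time, event, Z, names, fold_idx, n_lambdas, lambda_min_ratio,
            unpenalized,
        )
    else:
        coef, lam, cvdev = _ridge_cv(
            time, event, Z, fold_idx, n_lambdas, lambda_min_ratio
        )
    return FinalModel(
        feature_names=names,
        coef=coef,
        penalty=penalty,
        lam=lam,
        cv_deviance=cvdev,
        dropped_constant=dropped,
    )


def _lasso_cv(time, event, Z, names, fold_idx, n_lambdas, lambda_min_ratio,
              unpenalized):
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    pf = np.ones(Z.shape[1])
    for nm in unpenalized:
        if nm in names:
            pf[names.index(nm)] = 0.0
    base = CoxnetSurvivalAnalysis(
        n_alphas=n_lambdas,
        alpha_min_ratio=lambda_min_ratio,
        l1_ratio=1.0,
        penalty_factor=pf,
        normalize=True,
    )
    base.fit(Z, y)
    alphas = np.asarray(base.alphas_)
    cvl = np.zeros(len(alphas))
    for tr, _te in fold_idx:
        fold_model = CoxnetSurvivalAnalysis(
            alphas=alphas, l1_ratio=1.0, penalty_factor=pf, normalize=True
        )
        try:
            fold_model.fit(Z[tr], y[tr])
        except (ValueError, ArithmeticError):
            continue
        fitted = np.asarray(fold_model.alphas_)
        coefs = fold_model.coef_
        for ai, a in enumerate(alphas):
            # nearest fitted alpha: Coxnet may truncate the requested path
            j = int(np.argmin(np.abs(np.log(fitted) - np.log(a))))
            beta = coefs[:, j]
            eta_all = Z @ beta
            cvl[ai] += cox_loglik(time, event, eta_all) - cox_loglik(
                time[tr], event[tr], eta_all[tr]
            )
    dev = -2.0 * cvl
    best = int(np.argmin(dev))
    return base.coef_[:, best], float(alphas[best]), float(dev[best])


def _ridge_cv(time, event, Z, fold_idx, n_lambdas, lambda_min_ratio):
    mu, sd = Z.mean(axis=0), Z.std(axis=0)
    Zs = (Z - mu) / sd
    n = Z.shape[0]
    # grid anchored at the scale of the null-model score
    g0 = np.abs(Zs.T @ (event - event.mean())) / n
    lam_max = max(float(g0.max()), 1e-3) * 10.0
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)
    cvl = np.zeros(len(lambdas))
    for tr, _te in fold_idx:
        beta_warm = None
        for li, lam in enumerate(lambdas):
            beta, _, _, _ = _newton_cox(
                time[tr], event[tr], Zs[tr], ridge=lam, beta0=beta_warm,
                max_iter=50, tol=1e-8,
            )
            beta_warm = beta
            eta_all = Zs @ beta
            cvl[li] += cox_loglik(time, event, eta_all) - cox_loglik(
                time[tr], event[tr], eta_all[tr]
            )
    dev = -2.0 * cvl
    best = int(np.argmin(dev))
    beta_s, _, _, _ = _newton_cox(
        time, event, Zs, ridge=float(lambdas[best]), max_iter=100
    )
    return beta_s / sd, float(lambdas[best]), float(dev[best])


# ---------------------------------------------------------------------------
# overlapping-group-lasso Cox (latent-effect expansion)
# ---------------------------------------------------------------------------


def _irls_weights(time, event, eta):
    """IRLS weights (diagonal of the Breslow information approximation,
    ``w_i = c_i - sum_j p_ij^2``) and working response."""
    _, c, ppdiag, _, _, _ = _breslow_pass(time, event, eta)
    w = np.clip(c - ppdiag, 1e-10, None)
    z = eta + (event - c) / w
    return w, z


def _group_lasso_fit(
    time,
    event,
    Zu,
    Xt,
    slices,
    kappas,
    spec_bounds,
    lam,
    alpha,
    gamma,
    active,
    max_outer: int = 15,
    tol: float = 1e-4,
):
    """One penalized fit at level ``lam``: unpenalized block ``Zu`` plus a
    group-lasso penalty ``lam * kappa_g * ||gamma_g||`` per latent column
    block of ``Xt``, solved by IRLS with blockwise proximal (majorized)
    updates over an active set with a full KKT check on exit.

    ``alpha``, ``gamma`` and ``active`` are updated in place (warm starts).
    """
    n = time.shape[0]
    G = len(slices)
    eta = Zu @ alpha + Xt @ gamma
    for _kkt_round in range(6):
        for _outer in range(max_outer):
            w, z = _irls_weights(time, event, eta)
            wmax = float(w.max())
            resid = w * (z - eta)
            eta_old = eta.copy()
            for _sweep in range(4):
                delta_max = 0.0
                A = Zu.T @ (w[:, None] * Zu)
                b = Zu.T @ resid + A @ alpha
                alpha_new = np.linalg.solve(A, b)
                da = Zu @ (alpha_new - alpha)
                eta += da
                resid -= w * da
                delta_max = max(delta_max, float(np.max(np.abs(alpha_new - alpha))))
                alpha = alpha_new
                for gi in range(G):
                    if not active[gi]:
                        continue
                    sl = slices[gi]
                    Xg = Xt[:, sl]
                    t_g = wmax * spec_bounds[gi] / n
                    u = gamma[sl] + (Xg.T @ resid) / (n * t_g)
                    unorm = math.sqrt(float(u @ u))
                    thresh = lam * kappas[gi] / t_g
                    if unorm <= thresh:
                        if gamma[sl].any():
                            diff = -gamma[sl]
                            de = Xg @ diff
                            eta += de
                            resid -= w * de
                            delta_max = max(delta_max, float(np.max(np.abs(diff))))
                            gamma[sl] = 0.0
                        continue
                    gnew = (1.0 - thresh / unorm) * u
                    diff = gnew - gamma[sl]
                    dmax = float(np.max(np.abs(diff)))
                    if dmax > 0:
                        de = Xg @ diff
                        eta += de
                        resid -= w * de
                        delta_max = max(delta_max, dmax)
                        gamma[sl] = gnew
                if delta_max < tol:
                    break
            if float(np.max(np.abs(eta - eta_old))) < tol:
                break
        # KKT check over all groups at the current quadratic approximation
        w, z = _irls_weights(time, event, eta)
        resid = w * (z - eta)
        full_grad = Xt.T @ resid / n
        grad_sq = np.add.reduceat(full_grad * full_grad, [sl.start for sl in slices])
        gnorms = np.sqrt(grad_sq)
        violations = (~active) & (gnorms > lam * kappas * (1.0 + 1e-6))
        if not violations.any():
            break
        active |= violations
    return alpha, gamma, eta


def _spectral_bounds(Xt, slices):
    return np.array(
        [np.linalg.norm(Xt[:, sl], 2) ** 2 for sl in slices]
    )


def fit_overlap_group_cox(
    data: SurvivalDataset,
    expansion: ExpansionMap,
    folds: int = 10,
    rng_seed: int = 0,
    n_lambdas: int = 100,
    lambda_min_ratio: float = 1e-3,
    cv_rule: str = "1se",
) -> GroupLassoResult:
    """Overlapping-group-penalized Cox fit on the latent-effect expanded
    design; environments enter unpenalized.

    Each pathway's latent block carries a group-lasso penalty weighted by
    ``sqrt(block size)``. The penalty level is chosen on a log-spaced path by
    k-fold cross-validated partial-likelihood deviance; the selected group set
    contains every pathway whose latent block is nonzero at that level. An
    empty selection is a valid outcome.
    """
    missing = set(expansion.pathways.genes) - set(data.gene_names)
    if missing:
        raise ValueError(
            f"expansion references genes absent from data: {sorted(missing)[:5]}"
        )
    gene_pos = {g: i for i, g in enumerate(data.gene_names)}
    E_sd = np.where(data.E.std(axis=0) > 0, data.E.std(axis=0), 1.0)
    Zu = (data.E - data.E.mean(axis=0)) / E_sd
    group_names = expansion.pathways.group_names

    # standardized latent design (duplicated gene columns), stacked group-wise
    blocks = []
    slices: list[slice] = []
    start = 0
    for members in expansion.pathways.members:
        cols = data.X[:, [gene_pos[g] for g in members]]
        mu, sd = cols.mean(axis=0), cols.std(axis=0)
        sd = np.where(sd > 0, sd, 1.0)
        blocks.append((cols - mu) / sd)
        slices.append(slice(start, start + cols.shape[1]))
        start += cols.shape[1]
    Xt = np.ascontiguousarray(np.hstack(blocks))
    d = Xt.shape[1]
    kappas = np.sqrt(np.array([sl.stop - sl.start for sl in slices], dtype=float))

    # lambda path anchored at the null-model score
    null = fit_null_cox(
        SurvivalDataset(
            time=data.time, event=data.event, E=Zu, X=data.X[:, :1],
            env_names=data.env_names, gene_names=data.gene_names[:1],
        )
    )
    n = data.n
    g0 = Xt.T @ null.m / n
    grad_norms = np.sqrt(
        np.add.reduceat(g0 * g0, [sl.start for sl in slices])
    )
    lam_max = float((grad_norms / kappas).max()) * 1.001
    lambdas = np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambdas)

    q = Zu.shape[1]

    def _path_fit(rows):
        t_, e_ = data.time[rows], data.event[rows]
        Zu_r = np.ascontiguousarray(Zu[rows])
        Xt_r = np.ascontiguousarray(Xt[rows])
        spec = _spectral_bounds(Xt_r, slices)
        alpha = np.zeros(q)
        gamma = np.zeros(d)
        active = np.zeros(len(slices), dtype=bool)
        out = []
        for lam in lambdas:
            alpha, gamma, _ = _group_lasso_fit(
                t_, e_, Zu_r, Xt_r, slices, kappas, spec, lam, alpha, gamma,
                active,
            )
            out.append((alpha.copy(), gamma.copy()))
        return out

    if cv_rule not in ("min", "1se"):
        raise ValueError("cv_rule must be 'min' or '1se'")
    fold_idx = _event_stratified_folds(data.event, folds, rng_seed)
    fold_dev = np.zeros((len(fold_idx), len(lambdas)))
    for fi, (tr, _te) in enumerate(fold_idx):
        for li, (alpha, gamma) in enumerate(_path_fit(tr)):
            eta_all = Zu @ alpha + Xt @ gamma
            fold_dev[fi, li] = -2.0 * (
                cox_loglik(data.time, data.event, eta_all)
                - cox_loglik(data.time[tr], data.event[tr], eta_all[tr])
            )
    dev = fold_dev.sum(axis=0)
    best = int(np.argmin(dev))
    if cv_rule == "1se":
        # largest lambda whose deviance is within one standard error of the
        # minimum (SE across folds of the per-fold deviance sums)
        se = float(fold_dev[:, best].std(ddof=1) * np.sqrt(len(fold_idx)))
        within = np.flatnonzero(dev <= dev[best] + se)
        best = int(within[0])  # lambdas are decreasing along the path

    full_path = _path_fit(np.arange(n))
    alpha_best, gamma_best = full_path[best]
    selected = tuple(
        name for name, sl in zip(group_names, slices)
        if gamma_best[sl].any()
    )
    return GroupLassoResult(
        selected=selected,
        lam=float(lambdas[best]),
        gamma=gamma_best,
        alpha=alpha_best,
        lambdas=lambdas,
        cv_deviance=dev,
    )
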