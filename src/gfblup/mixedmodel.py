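"""GBLUP / GFBLUP mixed models with reliability-weighted residuals.

The model is ``y = 1 mu + sum_k g_k + e`` with ``g_k ~ N(0, G_k sigma_k^2)``
and ``e ~ N(0, D sigma_e^2)``, where D is diagonal with entries
``(1 - r^2)/r^2`` for a record of reliability r^2 (D = I for unweighted
residuals).  GBLUP has one genomic component (G over all markers); GFBLUP
has two (feature matrix G_f and remainder matrix G_R).

Variance components are estimated by average-information REML with an
EM-REML fallback whenever an AI step leaves the parameter space or fails to
improve the restricted likelihood.  BLUPs and validation predictions follow
the standard conditional-mean algebra:

``g_hat_k = sigma_k^2 G_k V^{-1} (y - 1 mu_hat)``,

evaluated on the training block of each relationship matrix, with
``mu_hat`` the generalized least squares mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .grm import RelationshipMatrix

_LOG2PI = np.log(2.0 * np.pi)


def reliability_weights(reliability: np.ndarray) -> np.ndarray:
    """Diagonal of D: (1 - r^2)/r^2 per record."""
    r2 = np.asarray(reliability, dtype=float)
    if np.any(r2 <= 0) or np.any(r2 > 1):
        raise ValueError("reliabilities must lie in (0, 1]")
    return (1.0 - r2) / r2


@dataclass
class VarianceComponents:
    """REML estimates for one model fit.

    ``variances`` holds the genetic components first and the residual last;
    ``names`` labels them in the same order.
    """

    variances: np.ndarray
    names: list
    se: np.ndarray
    loglik: float
    converged: bool
    n_iter: int

    @property
    def residual(self) -> float:
        return float(self.variances[-1])

    @property
    def genetic(self) -> np.ndarray:
        return self.variances[:-1]

    def __getitem__(self, name: str) -> float:
        return float(self.variances[self.names.index(name)])


@dataclass
class ModelFit:
    """Converged model with BLUPs for the training individuals."""

    vc: VarianceComponents
    mu: float
    blups: dict                  # component name -> array over training ids
    gebv: np.ndarray             # total genomic value, training ids
    training_ids: np.ndarray
    y: np.ndarray = field(repr=False, default=None)
    d: np.ndarray = field(repr=False, default=None)


@dataclass
class PartitionSummary:
    """Variance-partition ratios of a GFBLUP (or GBLUP) fit."""

    h2_feature: float            # H^2_f = s2_f / (s2_f + s2_R)
    snp_f: float                 # m_f / (m_f + m_R)
    h2: float                    # genomic heritability


def _as_matrices(grms) -> list:
    out = []
    for g in grms:
        out.append(g.values if isinstance(g, RelationshipMatrix) else np.asarray(g, dtype=float))
    return out


def _d_vector(d, n) -> np.ndarray:
    if d is None:
        return np.ones(n)
    d = np.asarray(d, dtype=float)
    if d.ndim == 2:
        d = np.diag(d)
    if d.shape != (n,):
        raise ValueError("D must be a length-n diagonal")
    if np.any(d <= 0):
        raise ValueError("D must be positive")
    return d


def _build_v(variances, gmats, d):
    n = d.size
    v = np.zeros((n, n))
    for s2, g in zip(variances[:-1], gmats):
        v += s2 * g
    v[np.diag_indices_from(v)] += variances[-1] * d
    return v


def _reml_pieces(variances, y, gmats, d, names):
    """Cholesky-based REML quantities for an intercept-only model."""
    n = y.size
    v = _build_v(variances, gmats, d)
    try:
        c, low = linalg.cho_factor(v, lower=True, check_finite=False)
    except linalg.LinAlgError as err:
        raise ValueError(
            "V is not positive definite for components "
            + ", ".join(f"{k}={s:.3g}" for k, s in zip(names, variances))
        ) from err
    logdet_v = 2.0 * np.log(np.diag(c)).sum()
    vi = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
    vi_x = vi.sum(axis=1)                     # V^-1 1
    xt_vi_x = vi_x.sum()
    p = vi - np.outer(vi_x, vi_x) / xt_vi_x   # REML projection
    py = p @ y
    ll = -0.5 * ((n - 1) * _LOG2PI + logdet_v + np.log(xt_vi_x) + y @ py)
    return ll, p, py, vi, vi_x, xt_vi_x


def restricted_loglik(variances, y, grms, d=None) -> float:
    """Restricted log-likelihood of ``y = 1 mu + sum_k g_k + e``.

    ``variances`` lists the genetic components (one per matrix in ``grms``)
    followed by the residual; ``d`` is the residual diagonal (default I).
    Includes the -(n-1)/2 log(2 pi) constant.
    """
    y = np.asarray(y, dtype=float)
    gmats = _as_matrices(grms)
    variances = np.asarray(variances, dtype=float)
    if variances.size != len(gmats) + 1:
        raise ValueError("need one variance per GRM plus a residual variance")
    d = _d_vector(d, y.size)
    names = [f"g{k}" for k in range(len(gmats))] + ["e"]
    ll, *_ = _reml_pieces(variances, y, gmats, d, names)
    return float(ll)


def reml_fit(y, grms, d=None, init=None, tol: float = 1e-6, max_iter: int = 100,
             names=None, verbose: bool = False) -> VarianceComponents:
    """Average-information REML with EM fallback.

    Parameters
    ----------
    y
        Phenotype vector (one record per individual; intercept-only fixed
        effects, the DRP convention).
    grms
        Sequence of relationship matrices (``RelationshipMatrix`` or dense
        arrays); may be empty for a residual-only model.
    d
        Residual diagonal weights (default identity).
    init
        Starting variances (genetic..., residual); default splits Var(y)
        equally across components.
    tol
        Convergence threshold on the change in restricted log-likelihood.

    Accepted updates never decrease the likelihood: an AI step is halved
    toward the current point while it fails, and replaced by an EM step if
    needed.  Variances are clamped to ``1e-8 Var(y)``.
    """
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 phenotyped individuals")
    gmats = _as_matrices(grms)
    for g in gmats:
        if g.shape != (n, n):
            raise ValueError("GRM dimension does not match phenotype length")
    d = _d_vector(d, n)
    k = len(gmats)
    if names is None:
        names = [f"g{j}" for j in range(k)] + ["e"]
    var_y = float(np.var(y, ddof=1))
    floor = 1e-8 * var_y
    theta = (
        np.full(k + 1, var_y / (k + 1))
        if init is None
        else np.maximum(np.asarray(init, dtype=float), floor)
    )

    def derivs(j, p_or_none, vec):
        # A_j @ vec where A_j = dV/dtheta_j
        return gmats[j] @ vec if j < k else d * vec

    ll, p, py, *_ = _reml_pieces(theta, y, gmats, d, names)
    converged = False
    ai = np.eye(k + 1)
    it = 0
    for it in range(1, max_iter + 1):
        # score and AI matrix at the current point
        a_py = [derivs(j, None, py) for j in range(k + 1)]
        score = np.empty(k + 1)
        for j in range(k + 1):
            tr_pa = float(np.sum(p * gmats[j])) if j < k else float(np.sum(np.diag(p) * d))
            score[j] = -0.5 * (tr_pa - py @ a_py[j])
        b = np.column_stack(a_py)
        pb = p @ b
        ai = 0.5 * (b.T @ pb)

        accepted = False
        try:
            delta = np.linalg.solve(ai, score)
        except np.linalg.LinAlgError:
            delta = None
        if delta is not None:
            step = 1.0
            for _ in range(12):  # step-halving keeps the likelihood monotone
                cand = np.maximum(theta + step * delta, floor)
                try:
                    ll_new, p_new, py_new, *_ = _reml_pieces(cand, y, gmats, d, names)
                except ValueError:
                    step *= 0.5
                    continue
                if ll_new >= ll - 1e-10:
                    accepted = True
                    break
                step *= 0.5
        if not accepted:
            # EM-REML update (monotone but slow)
            cand = np.empty(k + 1)
            for j in range(k + 1):
                tr_pa = float(np.sum(p * gmats[j])) if j < k else float(np.sum(np.diag(p) * d))
                cand[j] = theta[j] + theta[j] ** 2 * ((py @ a_py[j]) - tr_pa) / n
            cand = np.maximum(cand, floor)
            ll_new, p_new, py_new, *_ = _reml_pieces(cand, y, gmats, d, names)

        delta_ll = ll_new - ll
        theta, ll, p, py = cand, ll_new, p_new, py_new
        if verbose:
            print(f"iter {it}: ll={ll:.6f} theta={theta}")
        if abs(delta_ll) < tol:
            converged = True
            break

    try:
        se = np.sqrt(np.diag(np.linalg.inv(ai)))
    except np.linalg.LinAlgError:
        se = np.full(k + 1, np.nan)
    return VarianceComponents(
        variances=theta,
        names=list(names),
        se=se,
        loglik=float(ll),
        converged=converged,
        n_iter=it,
    )


def blup_solve(vc: VarianceComponents, y, grms, d=None, training_ids=None) -> ModelFit:
    """Solve component BLUPs ``g_hat_k = s2_k G_k V^{-1}(y - 1 mu_hat)``."""
    y = np.asarray(y, dtype=float)
    gmats = _as_matrices(grms)
    d = _d_vector(d, y.size)
    names = vc.names
    _, p, py, vi, vi_x, xt_vi_x = _reml_pieces(vc.variances, y, gmats, d, names)
    mu = float((vi_x @ y) / xt_vi_x)
    resid = vi @ (y - mu)        # V^-1 (y - 1 mu)
    blups = {}
    for name, s2, g in zip(names[:-1], vc.variances[:-1], gmats):
        blups[name] = s2 * (g @ resid)
    gebv = (
        np.sum(list(blups.values()), axis=0) if blups else np.zeros_like(y)
    )
    ids = np.asarray(training_ids, dtype=object) if training_ids is not None else np.arange(y.size)
    return ModelFit(vc=vc, mu=mu, blups=blups, gebv=gebv, training_ids=ids, y=y, d=d)


def predict_gebv(fit: ModelFit, grms_full, training_ids, target_ids) -> dict:
    """Predict component genetic values and GEBV for target individuals.

    ``grms_full`` are relationship matrices spanning training and target
    individuals.  The conditional-mean formula
    ``g_hat_k(target) = s2_k G_k[target, training] V_train^{-1} (y - 1 mu)``
    is used; it coincides with solving the joint mixed-model equations with
    the targets' records set missing.

    Returns ``{"gebv": array, component name: array, ...}`` over targets.
    """
    training_ids = np.asarray(training_ids, dtype=object)
    target_ids = np.asarray(target_ids, dtype=object)
    mats = []
    for g in grms_full:
        if not isinstance(g, RelationshipMatrix):
            raise TypeError("predict_gebv needs RelationshipMatrix inputs (for id lookup)")
        known = set(g.ids)
        missing = [i for i in target_ids if i not in known]
        if missing:
            raise KeyError(f"target individuals absent from GRM: {missing[:5]}")
        lookup = {i: j for j, i in enumerate(g.ids)}
        tr = np.array([lookup[i] for i in training_ids])
        tg = np.array([lookup[i] for i in target_ids])
        mats.append((g.values[np.ix_(tr, tr)], g.values[np.ix_(tg, tr)]))

    y, d, vc = fit.y, fit.d, fit.vc
    v = np.zeros((y.size, y.size))
    for s2, (gtt, _) in zip(vc.variances[:-1], mats):
        v += s2 * gtt
    v[np.diag_indices_from(v)] += vc.residual * d
    c, low = linalg.cho_factor(v, lower=True, check_finite=False)
    resid = linalg.cho_solve((c, low), y - fit.mu, check_finite=False)

    out = {}
    total = np.zeros(target_ids.size)
    for name, s2, (_, gxt) in zip(vc.names[:-1], vc.variances[:-1], mats):
        pred = s2 * (gxt @ resid)
        out[name] = pred
        total += pred
    out["gebv"] = total
    return out


def summarize_partition(vc: VarianceComponents, m_f: int, m_r: int) -> PartitionSummary:
    """H^2_f, SNP_f and genomic heritability from a fit's components."""
    if m_f + m_r <= 0:
        raise ValueError("m_f + m_R must be positive")
    genetic = vc.genetic
    s2_e = vc.residual
    s2_g = float(genetic.sum())
    h2 = s2_g / (s2_g + s2_e) if (s2_g + s2_e) > 0 else np.nan
    if genetic.size == 2:
        s2_f, s2_r = float(genetic[0]), float(genetic[1])
        h2f = s2_f / (s2_f + s2_r) if (s2_f + s2_r) > 0 else np.nan
    else:
        h2f = np.nan
    return PartitionSummary(h2_feature=h2f, snp_f=m_f / (m_f + m_r), h2=h2)
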