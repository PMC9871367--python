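"""Batch-screened component-wise gradient boosting.

The algorithm fits a sparse linear model on a genotype dosage matrix by
component-wise boosting: in each iteration the variant most correlated with
the current negative gradient is selected, a univariate linear base-learner
(intercept + variant + mandatory covariates) is fitted to the gradient, and
the predictor is updated by a fraction ``nu`` of that fit.

Scanning all p variants every iteration is wasteful at biobank scale, so an
outer loop first screens a *batch*: the ``p_batch`` variants with the highest
absolute Pearson correlation to the current negative gradient.  Boosting then
iterates inside the batch until either

* the largest absolute in-batch correlation falls below ``c_stop`` — the
  largest absolute *out-of-batch* correlation recorded when the batch was
  built (a variant outside the batch may now fit better), or
* ``m_batch`` updates have been made in the batch.

A held-out validation set is scored as the fit proceeds: the outer loop stops
once the batch-end validation loss has not improved for ``b_stop``
consecutive batches (or after ``b_max`` batches), and the returned model is
the snapshot from the iteration with minimal validation loss — the validation
set chooses the number of boosting iterations.

If all variants were mutually independent the batch construction would select
the same variant in every iteration as the non-batched algorithm; the
non-batched classic is provided as :func:`fit_l2boost_reference` and serves
as a testing oracle.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .genotype_io import GenotypeMatrix, PhenotypeTable, VariantInfo
from .losses import LossSpec, get_loss
from .prs import PRSModel

logger = logging.getLogger(__name__)

#: sentinel for "the batch holds every variant; nothing was excluded"
NO_OUTER = -np.inf


@dataclass(frozen=True)
class Hyperparameters:
    """Tuning parameters of the batch-screened boosting fit.

    Defaults follow the recommended large-scale settings: learning rate
    nu=0.1, batch size p_batch=1000 with m_batch equal to the batch size,
    an effectively unbounded batch budget b_max=20000, and outer early
    stopping after b_stop=2 batches without validation improvement.
    """

    p_batch: int = 1000
    nu: float = 0.1
    m_batch: int | None = None  # None -> p_batch
    b_max: int = 20000
    b_stop: int = 2
    loss: str = "l2"
    m_total: int | None = None  # optional hard cap on total iterations

    def __post_init__(self):
        if self.m_total is not None and self.m_total < 1:
            raise ValueError("m_total must be >= 1")
        if self.p_batch < 1:
            raise ValueError("p_batch must be >= 1")
        if not (0.0 < self.nu <= 1.0):
            raise ValueError("nu must be in (0, 1]")
        if self.m_batch is not None and self.m_batch < 1:
            raise ValueError("m_batch must be >= 1")
        if self.b_max < 1 or self.b_stop < 1:
            raise ValueError("b_max and b_stop must be >= 1")
        get_loss(self.loss)

    @property
    def effective_m_batch(self) -> int:
        return self.p_batch if self.m_batch is None else self.m_batch


@dataclass
class Batch:
    """Index set of screened variants plus the frozen outer-correlation bound.

    ``c_stop`` is computed once at batch creation (the largest absolute
    correlation among *excluded* variants) and never refreshed mid-batch.
    ``u_norm`` is the centered-gradient norm at creation: the inner stopping
    rule compares screening statistics on the covariance scale
    (``correlation x gradient norm``), under which the frozen out-of-batch
    bound stays exact for orthogonal variants; at batch creation the two
    scales coincide.
    """

    indices: np.ndarray
    c_stop: float
    u_norm: float = 1.0


@dataclass
class FitPath:
    """Per-iteration and per-batch fitting history."""

    iterations: list = field(default_factory=list)   # (m, variant_index, coef_increment)
    batches: list = field(default_factory=list)      # dict per batch

    def selected_sequence(self) -> list[int]:
        return [j for (_, j, _) in self.iterations]

    def record_iteration(self, m: int, j: int, increment: float) -> None:
        self.iterations.append((m, int(j), float(increment)))

    def record_batch(self, k: int, batch_size: int, n_inner: int,
                     val_loss: float, n_selected: int) -> None:
        self.batches.append({
            "k": k, "batch_size": batch_size, "n_inner": n_inner,
            "val_loss": val_loss, "n_selected": n_selected,
        })
        logger.info("batch\t%d\t%d\t%.6g\t%d", k, n_inner, val_loss, n_selected)


@dataclass
class BoostState:
    """Evolving fit: coefficients, cached predictions and negative gradient.

    ``prediction`` is on the response scale for l2 loss and the
    linear-predictor scale for log loss; it always equals
    ``beta0 + X @ beta + C @ gamma``.  ``y`` is kept so single steps can
    refresh the negative gradient.
    """

    beta0: float
    beta: dict            # variant column index -> coefficient
    gamma: np.ndarray     # covariate coefficients, length q
    prediction: np.ndarray
    u: np.ndarray
    y: np.ndarray | None = None
    m: int = 0
    k: int = 0
    steps_in_batch: int = 0
    path: FitPath = field(default_factory=FitPath)


# ---------------------------------------------------------------------------
# correlation screening
# ---------------------------------------------------------------------------

def _as_matrix(G) -> np.ndarray:
    if isinstance(G, GenotypeMatrix):
        if G.missing_mask.any():
            raise ValueError("genotypes contain missing values; impute first")
        return G.dosages
    return np.asarray(G, dtype=float)


def _column_norms(X: np.ndarray) -> np.ndarray:
    """Euclidean norms of the mean-centered columns (0 for constant columns)."""
    n = X.shape[0]
    sq = np.einsum("ij,ij->j", X, X)
    return np.sqrt(np.maximum(sq - n * X.mean(axis=0) ** 2, 0.0))


def _correlations(X: np.ndarray, col_norms: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Pearson correlation of every column of X with u; 0 where undefined.

    Relies on u being centered before the product: for centered u,
    sum(x_j * u_c) equals the centered cross-product, so X need not be
    centered column-wise (one matmul, no copy of X).
    """
    uc = u - u.mean()
    u_norm = float(np.sqrt(uc @ uc))
    if u_norm == 0.0:
        return np.zeros(X.shape[1])
    raw = X.T @ uc
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = raw / (col_norms * u_norm)
    corr[col_norms == 0.0] = 0.0
    return corr


def compute_correlations(G, u, subset=None) -> np.ndarray:
    """Pearson correlation of each (subset) variant column with the vector u.

    Zero-variance columns and a zero-variance u yield correlation 0, never
    NaN, so monomorphic variants can never win a screening round.
    """
    X = _as_matrix(G)
    u = np.asarray(u, dtype=float)
    if X.shape[0] != u.shape[0]:
        raise ValueError("u length does not match sample count")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples to compute correlations")
    if subset is not None:
        X = X[:, np.asarray(subset, dtype=int)]
    return _correlations(X, _column_norms(X), u)


def screen_batch(G, u, p_batch: int) -> Batch:
    """Select the p_batch variants with largest |correlation| to u.

    Ties break toward the lowest variant index.  ``c_stop`` is the largest
    absolute correlation among the excluded variants; if no variant is
    excluded it is the ``-inf`` sentinel (the inner stopping rule can then
    never fire on correlations, reproducing non-batched boosting).
    """
    X = _as_matrix(G)
    p = X.shape[1]
    if not (1 <= p_batch <= p):
        raise ValueError(f"p_batch must be in [1, {p}], got {p_batch}")
    abs_corr = np.abs(compute_correlations(X, u))
    if not abs_corr.any():
        logger.warning("all screening correlations are zero; taking the first "
                       "%d variants", p_batch)
    order = np.argsort(-abs_corr, kind="stable")  # ties -> lowest index first
    chosen = np.sort(order[:p_batch])
    c_stop = float(abs_corr[order[p_batch:]].max()) if p_batch < p else NO_OUTER
    uc = np.asarray(u, dtype=float)
    uc = uc - uc.mean()
    return Batch(indices=chosen, c_stop=c_stop,
                 u_norm=float(np.sqrt(uc @ uc)))


# ---------------------------------------------------------------------------
# base-learner
# ---------------------------------------------------------------------------

def fit_base_learner(x_j, C, u) -> tuple[float, float, np.ndarray]:
    """OLS fit of u on (1, x_j, covariates); returns (intercept, slope, gamma).

    The covariates are mandatory: they appear in every base-learner design and
    never compete with the variants for selection.
    """
    x = np.asarray(x_j, dtype=float)
    u = np.asarray(u, dtype=float)
    C = np.asarray(C, dtype=float) if C is not None else np.empty((x.size, 0))
    if C.size == 0:
        C = C.reshape(x.size, 0)
    n, q = C.shape
    design = np.column_stack([np.ones(n), x, C])
    gram = design.T @ design
    try:
        coefs = np.linalg.solve(gram, design.T @ u)
    except np.linalg.LinAlgError:
        coefs = None
    if coefs is None or not np.isfinite(coefs).all():
        _raise_collinear(design)
    return float(coefs[0]), float(coefs[1]), coefs[2:]


def _raise_collinear(design: np.ndarray):
    """Identify which design column is in the span of the others."""
    full_rank = np.linalg.matrix_rank(design)
    names = ["intercept", "variant"] + [f"covariate_{i}" for i in
                                        range(design.shape[1] - 2)]
    for col in range(design.shape[1]):
        reduced = np.delete(design, col, axis=1)
        if np.linalg.matrix_rank(reduced) == full_rank:
            raise np.linalg.LinAlgError(
                f"rank-deficient base-learner design: column {names[col]!r} "
                "is collinear with the others"
            )
    raise np.linalg.LinAlgError("rank-deficient base-learner design")


# ---------------------------------------------------------------------------
# boosting steps
# ---------------------------------------------------------------------------

class _Workspace:
    """Cached column statistics so each step costs one batch-sized matvec."""

    def __init__(self, X: np.ndarray, y: np.ndarray, C: np.ndarray,
                 loss: LossSpec):
        self.X = X
        self.y = y
        self.C = C
        self.loss = loss
        self.col_norms = _column_norms(X)

    def batch_correlations(self, batch: Batch, u: np.ndarray) -> np.ndarray:
        idx = batch.indices
        return _correlations(self.X[:, idx], self.col_norms[idx], u)


def boosting_step(state: BoostState, batch: Batch, G, C, nu: float,
                  loss: LossSpec | str) -> BoostState:
    """One boosting update restricted to the given batch (in place).

    Selects the in-batch variant with the largest absolute correlation to the
    current negative gradient (ties toward the lowest variant index), fits
    the base-learner, and moves all coefficients a fraction nu toward it.
    """
    if state.y is None:
        raise ValueError("BoostState.y is unset; cannot refresh the gradient")
    loss = get_loss(loss) if isinstance(loss, str) else loss
    X = _as_matrix(G)
    C = np.asarray(C, dtype=float) if C is not None else np.empty((X.shape[0], 0))
    ws = _Workspace(X, state.y, C, loss)
    _step(state, batch, ws, nu)
    state.u = loss.negative_gradient(state.y, state.prediction)
    return state


def _step(state: BoostState, batch: Batch, ws: _Workspace, nu: float) -> int:
    """Select, fit and apply one update; returns the selected column index.

    Does not refresh ``state.u`` — the caller does, since the training y
    lives with the caller.
    """
    corr = ws.batch_correlations(batch, state.u)
    local = int(np.argmax(np.abs(corr)))  # batch.indices sorted -> lowest index wins ties
    j = int(batch.indices[local])
    b0, slope, gamma_inc = fit_base_learner(ws.X[:, j], ws.C, state.u)
    state.beta0 += nu * b0
    state.beta[j] = state.beta.get(j, 0.0) + nu * slope
    if gamma_inc.size:
        state.gamma = state.gamma + nu * gamma_inc
    delta = nu * (b0 + slope * ws.X[:, j])
    if gamma_inc.size:
        delta = delta + nu * (ws.C @ gamma_inc)
    state.prediction = state.prediction + delta
    state.m += 1
    state.steps_in_batch += 1
    state.path.record_iteration(state.m, j, nu * slope)
    return j


def check_inner_stop(state: BoostState, batch: Batch, G,
                     m_batch: int | None = None) -> bool:
    """True when boosting should leave the current batch.

    Fires when the frozen out-of-batch bound c_stop strictly exceeds the
    largest absolute in-batch correlation to the current negative gradient —
    a variant outside the batch may now fit better — or when m_batch updates
    have been spent inside the batch.  Both sides are compared on the
    covariance scale (correlation times the centered-gradient norm at the
    respective evaluation time), so the comparison reproduces the classic
    selection order exactly when variants are orthogonal.
    """
    if m_batch is not None and state.steps_in_batch >= m_batch:
        return True
    if batch.c_stop == NO_OUTER:
        return False
    uc = state.u - state.u.mean()
    u_norm = float(np.sqrt(uc @ uc))
    in_batch = np.abs(compute_correlations(G, state.u, subset=batch.indices))
    return batch.c_stop * batch.u_norm > float(in_batch.max()) * u_norm


# ---------------------------------------------------------------------------
# full fits
# ---------------------------------------------------------------------------

def _unpack(G, P, default_prefix="v"):
    """Accept (GenotypeMatrix, PhenotypeTable) or plain arrays."""
    X = _as_matrix(G)
    if isinstance(G, GenotypeMatrix):
        variants = G.variants
    else:
        width = max(4, len(str(X.shape[1])))
        variants = [VariantInfo(f"{default_prefix}{j + 1:0{width}d}", "0", j + 1,
                                "A", "B") for j in range(X.shape[1])]
    if isinstance(P, PhenotypeTable):
        y, C, cov_names = P.y, P.covariates, list(P.covariate_names)
    else:
        y = np.asarray(P, dtype=float)
        C, cov_names = np.empty((X.shape[0], 0)), []
    if y.shape[0] != X.shape[0]:
        raise ValueError("phenotype length does not match sample count")
    return X, y, C, cov_names, variants


def _snapshot(state: BoostState):
    return (state.beta0, dict(state.beta), state.gamma.copy(), state.m, state.k)


def fit_snpboost(G_train, P_train, G_val, P_val,
                 hp: Hyperparameters | None = None) -> tuple[PRSModel, FitPath]:
    """Fit a sparse PRS by batch-screened component-wise boosting.

    Training data drive the gradient fits; validation data select the number
    of boosting iterations and control early stopping.  The returned model is
    the snapshot from the iteration with minimal validation loss, not the
    final state; the outer loop stops once the batch-end validation loss has
    not improved for ``b_stop`` consecutive batches.

    Parameters
    ----------
    G_train, G_val
        :class:`GenotypeMatrix` (fully imputed) or plain (n, p) arrays with
        identical column order.
    P_train, P_val
        :class:`PhenotypeTable` (same covariate columns in both) or plain
        response vectors.
    hp
        :class:`Hyperparameters`; defaults to the recommended settings.
    """
    hp = hp or Hyperparameters()
    loss = get_loss(hp.loss)
    X, y, C, cov_names, variants = _unpack(G_train, P_train)
    X_val, y_val, C_val, cov_names_val, _ = _unpack(G_val, P_val)
    if y_val.size == 0:
        raise ValueError(
            "validation set is empty: early stopping needs validation samples; "
            "to fit without one, set b_max=1 and use m_batch as a fixed "
            "iteration budget"
        )
    if cov_names != cov_names_val:
        raise ValueError("train and validation covariate columns differ")
    if X.shape[1] != X_val.shape[1]:
        raise ValueError("train and validation variant counts differ")
    if loss.name == "log" and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("log loss requires a {0,1}-coded phenotype")

    n, p = X.shape
    q = C.shape[1]
    p_batch = min(hp.p_batch, p)
    m_batch = hp.effective_m_batch

    ws = _Workspace(X, y, C, loss)
    col_means = X.mean(axis=0)
    sq_norms = ws.col_norms ** 2
    # a zero-variance column can never be selected (correlation 0), but guard
    # the division anyway
    sq_norms[sq_norms == 0.0] = np.inf
    state = BoostState(
        beta0=0.0, beta={}, gamma=np.zeros(q),
        prediction=np.zeros(n), u=loss.negative_gradient(y, np.zeros(n)),
        y=y,
    )
    pred_val = np.zeros(X_val.shape[0])

    # best_iter_loss drives model selection (validation chooses the number of
    # boosting iterations); batch-end losses drive the outer stall rule
    best_iter_loss = np.inf
    best = _snapshot(state)
    best_val = np.inf
    stall = 0

    for k in range(1, hp.b_max + 1):
        state.k = k
        batch = screen_batch(X, state.u, p_batch)
        state.steps_in_batch = 0
        m_before = state.m
        # one slice per batch; screening statistics computed once per step
        # serve both the next selection and the frozen-c_stop check.  The
        # normalized covariance |x_j' u_c| / ||x_j,c|| orders identically to
        # the correlation (common factor 1/||u_c||) and is what the frozen
        # bound is compared against.
        Xb = X[:, batch.indices]
        norms_b = ws.col_norms[batch.indices].copy()
        norms_b[norms_b == 0.0] = np.inf  # zero-variance: statistic 0
        cov_bound = batch.c_stop * batch.u_norm

        def screen_stats(u):
            uc = u - u.mean()
            return np.abs(Xb.T @ uc) / norms_b

        stat = screen_stats(state.u)
        hit_m_total = False
        while True:
            local = int(np.argmax(stat))
            j = int(batch.indices[local])
            if q:
                b0, slope, gamma_inc = fit_base_learner(X[:, j], C, state.u)
            else:  # closed-form simple regression on the gradient
                u_mean = state.u.mean()
                slope = float((X[:, j] @ state.u - n * col_means[j] * u_mean)
                              / sq_norms[j])
                b0 = u_mean - slope * col_means[j]
            state.beta0 += hp.nu * b0
            state.beta[j] = state.beta.get(j, 0.0) + hp.nu * slope
            delta = hp.nu * (b0 + slope * X[:, j])
            if q:
                state.gamma = state.gamma + hp.nu * gamma_inc
                delta = delta + hp.nu * (C @ gamma_inc)
            state.prediction = state.prediction + delta
            state.m += 1
            state.steps_in_batch += 1
            state.path.record_iteration(state.m, j, hp.nu * slope)
            state.u = loss.negative_gradient(y, state.prediction)
            # validation prediction tracks the fit so the returned model can
            # be the iteration with minimal validation loss
            delta_val = hp.nu * (b0 + slope * X_val[:, j])
            if q:
                delta_val = delta_val + hp.nu * (C_val @ gamma_inc)
            pred_val = pred_val + delta_val
            val_loss = loss.evaluate(y_val, pred_val)
            if val_loss < best_iter_loss:
                best_iter_loss = val_loss
                best = _snapshot(state)
            if hp.m_total is not None and state.m >= hp.m_total:
                hit_m_total = True
                break
            if state.steps_in_batch >= m_batch:
                break
            stat = screen_stats(state.u)
            if cov_bound > float(stat.max()):
                break
        state.path.record_batch(k, len(batch.indices), state.m - m_before,
                                val_loss, len(state.beta))
        if val_loss < best_val:
            best_val = val_loss
            stall = 0
        else:
            stall += 1
            if stall >= hp.b_stop:
                break
        if hit_m_total:
            break

    beta0, beta, gamma, m_best, k_best = best
    model = PRSModel(
        intercept=beta0,
        coefficients={variants[j].variant_id: b for j, b in sorted(beta.items())
                      if b != 0.0},
        variant_info={variants[j].variant_id: variants[j]
                      for j in sorted(beta) if beta[j] != 0.0},
        covariate_coefficients=dict(zip(cov_names, gamma)),
        loss=loss.name,
        hyperparameters=hp,
        n_iterations=m_best,
        n_batches=k_best,
    )
    return model, state.path


def fit_l2boost_reference(G_train, y_train, m_stop: int, nu: float = 0.1
                          ) -> tuple[PRSModel, FitPath]:
    """Classic non-batched component-wise L2-boosting (testing oracle).

    Every iteration scans all p variants for the one most correlated with the
    current residuals, fits a simple linear regression of the residuals on it
    and applies the nu-damped update.  With p < n and m_stop large this
    converges to the ordinary least-squares solution.  Deterministic; ties
    break toward the lowest variant index.
    """
    X, y, _, _, variants = _unpack(G_train, y_train)
    n, p = X.shape
    if n < 2:
        raise ValueError("need at least 2 samples")
    path = FitPath()
    beta0 = 0.0
    beta = np.zeros(p)
    resid = y.astype(float).copy()

    xbar = X.mean(axis=0)
    xc = X - xbar
    xc_norm = np.sqrt(np.einsum("ij,ij->j", xc, xc))
    xc_sq = xc_norm ** 2

    for m in range(1, m_stop + 1):
        rc = resid - resid.mean()
        r_norm = np.sqrt(rc @ rc)
        if r_norm == 0.0:
            break
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = (xc.T @ rc) / (xc_norm * r_norm)
        corr[xc_norm == 0.0] = 0.0
        j = int(np.argmax(np.abs(corr)))
        slope = float((xc[:, j] @ resid) / xc_sq[j])
        intercept = float(resid.mean() - slope * xbar[j])
        beta0 += nu * intercept
        beta[j] += nu * slope
        resid -= nu * (intercept + slope * X[:, j])
        path.record_iteration(m, j, nu * slope)

    model = PRSModel(
        intercept=beta0,
        coefficients={variants[j].variant_id: float(beta[j])
                      for j in np.flatnonzero(beta)},
        variant_info={variants[j].variant_id: variants[j]
                      for j in np.flatnonzero(beta)},
        covariate_coefficients={},
        loss="l2",
        hyperparameters=Hyperparameters(p_batch=p, m_batch=max(m_stop, 1),
                                        b_max=1, nu=nu),
        n_iterations=len(path.iterations),
        n_batches=1,
    )
    return model, path
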