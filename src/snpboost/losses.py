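"""Loss functions and their negative gradients.

The boosting engine is loss-agnostic: it only sees a :class:`LossSpec`
exposing a mean loss and the negative gradient of that loss with respect to
the current prediction.  For squared error the negative gradient is the
residual vector; for the log loss (binary traits, modelled on the logit
scale) it is ``y - sigmoid(eta)``.

Mean (not sum) conventions are used throughout so that validation losses are
comparable across sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import expit

_PROB_EPS = 1e-12


def l2_loss(y, yhat) -> float:
    """Mean squared error (1/n) * sum (yhat_i - y_i)^2."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    return float(np.mean((yhat - y) ** 2))


def logistic_link(eta) -> np.ndarray:
    """sigma(eta) = exp(eta) / (1 + exp(eta)), overflow-safe, clipped away
    from exactly 0 and 1 (only at the floating-point boundary, so the logit
    identity survives for |eta| up to ~30; the loss applies its own, coarser
    clip)."""
    p = expit(np.asarray(eta, dtype=float))
    return np.clip(p, np.finfo(float).tiny, np.nextafter(1.0, 0.0))


def log_loss(y, p_hat) -> float:
    """Mean binomial deviance -(1/n) sum [y ln p + (1-y) ln(1-p)]."""
    y = np.asarray(y, dtype=float)
    p = np.clip(np.asarray(p_hat, dtype=float), _PROB_EPS, 1.0 - _PROB_EPS)
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("binary phenotype must be coded {0, 1}")
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


@dataclass(frozen=True)
class LossSpec:
    """Contract between a loss and the boosting engine.

    ``evaluate(y, prediction)`` is the mean loss; ``prediction`` is on the
    response scale for l2 and on the linear-predictor scale for log loss.
    ``negative_gradient(y, prediction)`` is the steepest-descent direction
    the base-learners are fitted to.
    """

    name: str
    evaluate: Callable[[np.ndarray, np.ndarray], float]
    negative_gradient: Callable[[np.ndarray, np.ndarray], np.ndarray]
    validation_metric_name: str


def _l2_negative_gradient(y, yhat):
    return np.asarray(y, dtype=float) - np.asarray(yhat, dtype=float)


def _log_negative_gradient(y, eta):
    return np.asarray(y, dtype=float) - expit(np.asarray(eta, dtype=float))


def _log_evaluate(y, eta):
    return log_loss(y, logistic_link(eta))


L2 = LossSpec("l2", l2_loss, _l2_negative_gradient, "mean squared error")
LOG = LossSpec("log", _log_evaluate, _log_negative_gradient, "mean log loss")

_LOSSES = {"l2": L2, "log": LOG}


def get_loss(name: str) -> LossSpec:
    try:
        return _LOSSES[name]
    except KeyError:
        raise ValueError(f"unknown loss {name!r}; available: {sorted(_LOSSES)}") from None


def negative_gradient(loss: LossSpec | str, y, prediction) -> np.ndarray:
    """Negative gradient of the mean loss w.r.t. the prediction vector."""
    if isinstance(loss, str):
        loss = get_loss(loss)
    return loss.negative_gradient(y, prediction)
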