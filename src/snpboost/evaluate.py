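"""Evaluation metrics for fitted polygenic scores.

Prediction accuracy: MSEP (mean squared error of prediction on a held-out
set), its square root RMSEP, and R^2 defined as the *squared Pearson
correlation* between predicted and observed phenotype (affine-invariant, the
convention used when benchmarking PRS).  Binary traits are scored by mean
log loss and AUC (Mann-Whitney formulation, ties counted 1/2).

Selection accuracy against simulated ground truth: true-positive rate and
precision of the selected variant set, and the mean squared error of the
coefficient estimates averaged over all p variants (absent coefficients
count as zero).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .losses import log_loss
from .prs import PRSModel
from .simulate import SimTruth


@dataclass
class MetricsReport:
    msep: float | None = None
    rmsep: float | None = None
    r2: float | None = None
    auc: float | None = None
    log_loss: float | None = None
    n_selected_variants: int | None = None
    coef_mse: float | None = None
    tp_rate: float | None = None
    precision: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items() if v is not None}


def squared_correlation(y, yhat) -> float:
    """R^2 as the squared Pearson correlation; 0 (with a warning) when either
    vector is constant."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if np.ptp(yhat) == 0.0 or np.ptp(y) == 0.0:
        warnings.warn("constant predictions or outcomes: correlation undefined, "
                      "reporting R^2 = 0")
        return 0.0
    r = np.corrcoef(y, yhat)[0, 1]
    return float(r * r)


def auc_mann_whitney(y, scores) -> float:
    """AUC via the rank-sum (Mann-Whitney U) identity; ties contribute 1/2."""
    y = np.asarray(y, dtype=float)
    s = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both cases and controls")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def prediction_metrics(y, yhat, binary: bool = False) -> MetricsReport:
    """Held-out prediction accuracy.

    Continuous: MSEP, RMSEP and squared-correlation R^2.  Binary: ``yhat``
    are probabilities; reports AUC and mean log loss.
    """
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if binary:
        return MetricsReport(auc=auc_mann_whitney(y, yhat),
                             log_loss=log_loss(y, yhat))
    msep = float(np.mean((yhat - y) ** 2))
    return MetricsReport(msep=msep, rmsep=float(np.sqrt(msep)),
                         r2=squared_correlation(y, yhat))


def selection_metrics(model: PRSModel, truth: SimTruth) -> MetricsReport:
    """Variant-selection accuracy against simulated ground truth.

    TP rate = |selected ∩ causal| / |causal|; precision = |selected ∩ causal|
    / |selected| (0, with a warning, when nothing was selected); coef_mse is
    the mean over all p variants of (beta_hat - beta_true)^2 with absent
    entries treated as 0.
    """
    id_to_idx = {vid: j for j, vid in enumerate(truth.variant_ids)}
    unknown = [v for v in model.coefficients if v not in id_to_idx]
    if unknown:
        raise ValueError(f"model variants not in truth panel: {unknown[:5]}")
    selected = {id_to_idx[v] for v in model.coefficients}
    causal = set(int(i) for i in truth.causal_indices)
    hits = len(selected & causal)

    tp_rate = hits / len(causal) if causal else 0.0
    if selected:
        precision = hits / len(selected)
    else:
        warnings.warn("no variants selected; precision reported as 0")
        precision = 0.0

    beta_hat = np.zeros(truth.p)
    for vid, b in model.coefficients.items():
        beta_hat[id_to_idx[vid]] = b
    coef_mse = float(np.mean((beta_hat - truth.full_beta()) ** 2))

    return MetricsReport(n_selected_variants=len(selected), coef_mse=coef_mse,
                         tp_rate=tp_rate, precision=precision)


def bootstrap_ci(metric_fn, y, yhat, n_boot: int = 1000, seed: int = 0,
                 alpha: float = 0.05) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for a sample-wise metric."""
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    rng = np.random.default_rng(seed)
    stats = []
    n = y.shape[0]
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        stats.append(metric_fn(y[idx], yhat[idx]))
    lo, hi = np.quantile(stats, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def write_metrics(report: MetricsReport, path) -> None:
    """Emit metrics as a one-row tab-delimited table plus key=value pairs."""
    items = report.to_dict()
    with open(path, "w") as fh:
        fh.write("\t".join(items) + "\n")
        fh.write("\t".join(f"{v:.6g}" if isinstance(v, float) else str(v)
                           for v in items.values()) + "\n")
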