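"""Fitted polygenic risk scores as portable objects.

A fitted PRS is just an intercept, a sparse map of variant effects (each
carrying its effect and other allele) and optional covariate coefficients —
shareable exactly like GWAS summary statistics.  This module scores
genotype data with such a model, round-trips it through a tab-delimited
score file, and fits the standard downstream regressions that quantify what
the score adds over covariates:

* ``M_PRS``   — outcome on the PRS alone,
* ``M_f``     — outcome on the PRS plus covariates (age, sex, PCs, ...),
* ``M_c``     — outcome on covariates only (the baseline).

The fourth variant of the design — including the covariates in the boosting
fit itself (``M_PRS,c``) — is not fitted here: that is simply the boosting
fit with a covariate matrix supplied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

from .genotype_io import GenotypeMatrix, VariantInfo
from .losses import logistic_link

DOWNSTREAM_KINDS = ("M_PRS", "M_f", "M_c")


@dataclass
class PRSModel:
    """Sparse linear scoring model: intercept + sum of dosage-weighted effects."""

    intercept: float
    coefficients: dict            # variant_id -> beta (no exact zeros)
    variant_info: dict            # variant_id -> VariantInfo
    covariate_coefficients: dict  # covariate name -> coefficient
    loss: str = "l2"
    hyperparameters: object = None
    n_iterations: int = 0
    n_batches: int = 0

    def __post_init__(self):
        zeros = [v for v, b in self.coefficients.items() if b == 0.0]
        for v in zeros:
            del self.coefficients[v]
            self.variant_info.pop(v, None)
        missing = set(self.coefficients) - set(self.variant_info)
        if missing:
            raise ValueError(f"no allele metadata for variants {sorted(missing)[:5]}")

    @property
    def n_variants(self) -> int:
        return len(self.coefficients)


def predict(model: PRSModel, G: GenotypeMatrix, C=None,
            covariate_names: list[str] | None = None,
            return_probabilities: bool = False) -> np.ndarray:
    """Score genotypes with a fitted PRS.

    Every model variant must be present in ``G``.  If the target data lists
    the model's other allele as its effect allele, the dosage is flipped to
    ``2 - x`` before scoring; any other allele mismatch is an error (no
    strand-flip inference).  For a log-loss model,
    ``return_probabilities=True`` maps the linear score through the logistic
    function.
    """
    col_of = {v.variant_id: j for j, v in enumerate(G.variants)}
    missing = [vid for vid in model.coefficients if vid not in col_of]
    if missing:
        raise ValueError(f"variants absent from genotype data: {missing[:10]}"
                         f"{'...' if len(missing) > 10 else ''}")
    if G.missing_mask.any():
        raise ValueError("genotypes contain missing values; impute first")

    score = np.full(G.n_samples, model.intercept, dtype=float)
    for vid, beta in model.coefficients.items():
        j = col_of[vid]
        target, ours = G.variants[j], model.variant_info[vid]
        x = G.dosages[:, j]
        if (target.effect_allele == ours.effect_allele
                and target.other_allele == ours.other_allele):
            pass
        elif (target.effect_allele == ours.other_allele
                and target.other_allele == ours.effect_allele):
            x = 2.0 - x
        else:
            raise ValueError(
                f"allele mismatch at {vid}: model {ours.effect_allele}/"
                f"{ours.other_allele} vs data {target.effect_allele}/"
                f"{target.other_allele}"
            )
        score += beta * x

    if model.covariate_coefficients:
        if C is None:
            raise ValueError("model includes covariates; supply a covariate matrix")
        C = np.asarray(C, dtype=float)
        names = covariate_names or list(model.covariate_coefficients)
        gamma = np.array([model.covariate_coefficients[name] for name in names])
        if C.shape[1] != gamma.size:
            raise ValueError("covariate matrix width does not match model")
        score += C @ gamma

    if return_probabilities:
        if model.loss != "log":
            raise ValueError("probabilities are only defined for log-loss models")
        return logistic_link(score)
    return score


# ---------------------------------------------------------------------------
# score-file serialization
# ---------------------------------------------------------------------------

_G17 = "{:.17g}".format  # round-trips float64 exactly


def export_prs(model: PRSModel, path) -> None:
    """Write the model as a tab-delimited score file.

    Comment lines (``#key=value``) carry the intercept, loss and covariate
    coefficients; the body has one row per variant: variant_id, chromosome,
    position, effect_allele, other_allele, beta.
    """
    with open(path, "w") as fh:
        fh.write(f"#loss={model.loss}\n")
        fh.write(f"#intercept={_G17(model.intercept)}\n")
        fh.write(f"#n_iterations={model.n_iterations}\n")
        fh.write(f"#n_batches={model.n_batches}\n")
        for name, g in model.covariate_coefficients.items():
            fh.write(f"#covariate={name}\t{_G17(g)}\n")
        fh.write("variant_id\tchromosome\tposition\teffect_allele"
                 "\tother_allele\tbeta\n")
        for vid, beta in model.coefficients.items():
            v = model.variant_info[vid]
            fh.write(f"{vid}\t{v.chromosome}\t{v.position}\t{v.effect_allele}"
                     f"\t{v.other_allele}\t{_G17(beta)}\n")


def import_prs(path) -> PRSModel:
    """Read a score file written by :func:`export_prs`."""
    meta = {"loss": "l2", "intercept": 0.0, "n_iterations": 0, "n_batches": 0}
    covariates: dict[str, float] = {}
    coefficients: dict[str, float] = {}
    variant_info: dict[str, VariantInfo] = {}
    header_seen = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("=")
                if key == "covariate":
                    name, _, g = value.partition("\t")
                    covariates[name] = float(g)
                elif key in ("intercept",):
                    meta[key] = float(value)
                elif key in ("n_iterations", "n_batches"):
                    meta[key] = int(value)
                elif key == "loss":
                    meta[key] = value
                else:
                    raise ValueError(f"{path}:{lineno}: unknown header key {key!r}")
                continue
            if not header_seen:
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 columns, "
                                 f"got {len(parts)}")
            vid, chrom, pos, ea, oa, beta = parts
            try:
                coefficients[vid] = float(beta)
                variant_info[vid] = VariantInfo(vid, chrom, int(pos), ea, oa)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from None
    return PRSModel(
        intercept=meta["intercept"], coefficients=coefficients,
        variant_info=variant_info, covariate_coefficients=covariates,
        loss=meta["loss"], n_iterations=meta["n_iterations"],
        n_batches=meta["n_batches"],
    )


# ---------------------------------------------------------------------------
# downstream evaluation models
# ---------------------------------------------------------------------------

@dataclass
class DownstreamModel:
    """Linear or logistic regression of the outcome on PRS and/or covariates."""

    kind: str
    gamma0: float
    gamma_prs: float | None = None
    gamma_covariates: dict = field(default_factory=dict)
    binary: bool = False

    def predict(self, prs_values=None, C=None) -> np.ndarray:
        terms = [self.gamma0]
        if self.gamma_prs is not None:
            if prs_values is None:
                raise ValueError(f"{self.kind} needs PRS values")
            terms.append(self.gamma_prs * np.asarray(prs_values, dtype=float))
        if self.gamma_covariates:
            if C is None:
                raise ValueError(f"{self.kind} needs covariates")
            C = np.asarray(C, dtype=float)
            g = np.array(list(self.gamma_covariates.values()))
            terms.append(C @ g)
        eta = sum(terms)
        eta = np.asarray(eta, dtype=float)
        return logistic_link(eta) if self.binary else eta


def fit_downstream(prs_values, C, y, kind: str,
                   covariate_names: list[str] | None = None,
                   binary: bool = False) -> DownstreamModel:
    """Fit one of the standard evaluation regressions by maximum likelihood.

    ``M_PRS`` regresses the outcome on the score alone, ``M_f`` on the score
    plus covariates, ``M_c`` on covariates only.  Continuous outcomes use
    ordinary least squares, binary outcomes logistic regression.  Typically
    fitted on the combined training + validation samples and evaluated on the
    held-out test set.
    """
    if kind not in DOWNSTREAM_KINDS:
        raise ValueError(f"kind must be one of {DOWNSTREAM_KINDS}, got {kind!r}")
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    C = np.asarray(C, dtype=float) if C is not None else np.empty((n, 0))
    if C.size == 0:
        C = C.reshape(n, 0)
    cov_names = covariate_names or [f"cov{i + 1}" for i in range(C.shape[1])]

    cols, names = [np.ones(n)], ["const"]
    if kind in ("M_PRS", "M_f"):
        prs = np.asarray(prs_values, dtype=float)
        if np.ptp(prs) == 0.0:
            raise ValueError("PRS column is constant; cannot fit a PRS model")
        cols.append(prs)
        names.append("PRS")
    if kind in ("M_f", "M_c"):
        for i in range(C.shape[1]):
            cols.append(C[:, i])
            names.append(cov_names[i])
    design = np.column_stack(cols)

    if binary:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.Logit(y, design).fit(disp=0)
    else:
        res = sm.OLS(y, design).fit()

    params = dict(zip(names, res.params))
    return DownstreamModel(
        kind=kind,
        gamma0=float(params["const"]),
        gamma_prs=float(params["PRS"]) if "PRS" in params else None,
        gamma_covariates={name: float(params[name]) for name in names
                          if name not in ("const", "PRS")},
        binary=binary,
    )


def adjust_ldl_statin(y_measured, on_statin, factor: float = 0.684) -> np.ndarray:
    """Multiply measured LDL-cholesterol by ``factor`` for statin users.

    Statins lower measured LDL; the conventional correction factor 0.684 is
    applied multiplicatively to flagged individuals, others are unchanged.
    Whether the factor should multiply or divide the measured value is
    genuinely ambiguous in the PRS literature; the multiplicative form is
    implemented (see the methods note).
    """
    y = np.asarray(y_measured, dtype=float)
    flag = np.asarray(on_statin, dtype=bool)
    if y.shape != flag.shape:
        raise ValueError("length mismatch between measurements and statin flags")
    return np.where(flag, y * factor, y)
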