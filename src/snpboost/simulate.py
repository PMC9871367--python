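"""Synthetic genotype and phenotype generation.

The generator emulates the statistical structure of a biobank-style PRS
experiment without any external data: hard-call dosages in {0, 1, 2} drawn
at per-variant allele frequencies (optionally with block-correlated variants
standing in for linkage disequilibrium), continuous phenotypes from a sparse
linear model with Gaussian noise calibrated to a target heritability h2, and
binary phenotypes from the logistic analogue at a target prevalence.

Defaults mirror the common experimental design: common variants
(MAF >= 1%), a 50/20/30 train/validation/test split, and sparsity given as
the fraction of causal variants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit
from scipy.stats import norm

from .genotype_io import GenotypeMatrix, PhenotypeTable, VariantInfo


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one synthetic dataset.

    ``h2`` is the fraction of phenotypic variance explained by the genetic
    component; ``s`` the fraction of variants that are causal.  With
    ``ld_block_size > 1`` variants within a block share a latent Gaussian
    factor with pairwise correlation ``ld_rho``.
    """

    n: int
    p: int
    maf_range: tuple[float, float] = (0.01, 0.5)
    h2: float = 0.5
    s: float = 0.01
    seed: int = 0
    ld_block_size: int = 1
    ld_rho: float = 0.0
    split: tuple[float, float, float] = (0.5, 0.2, 0.3)

    def __post_init__(self):
        low, high = self.maf_range
        if not (0.0 < low <= high <= 0.5):
            raise ValueError(f"maf_range must satisfy 0 < low <= high <= 0.5, "
                             f"got {self.maf_range}")
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError("h2 must be in [0, 1]")
        if not (0.0 < self.s <= 1.0):
            raise ValueError("s must be in (0, 1]")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ValueError("ld_rho must be in [0, 1)")
        if any(f <= 0 for f in self.split) or abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must be positive and sum to 1")
        if self.h2 > 0 and round(self.s * self.p) < 1:
            raise ValueError(
                f"s*p = {self.s * self.p:.3g} rounds to zero causal variants; "
                "increase s or p"
            )

    @property
    def n_causal(self) -> int:
        return int(round(self.s * self.p))


@dataclass
class SimTruth:
    """Generative ground truth for scoring variant selection and coefficients."""

    causal_indices: np.ndarray
    true_beta: np.ndarray              # effects of the causal variants, in order
    genetic_component: np.ndarray
    realized_h2: float
    variant_ids: list[str] = field(default_factory=list)
    p: int = 0

    def full_beta(self) -> np.ndarray:
        """Length-p effect vector with zeros at non-causal positions."""
        beta = np.zeros(self.p)
        beta[self.causal_indices] = self.true_beta
        return beta


def _rng(cfg: SimConfig, stream: int) -> np.random.Generator:
    # independent streams per stage so genotypes are identical across
    # phenotype redraws with the same seed
    return np.random.default_rng(np.random.SeedSequence([cfg.seed, stream]))


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw an n x p hard-call dosage matrix.

    Per variant a MAF is drawn uniformly from ``maf_range`` and dosages are
    Binomial(2, maf) across samples.  With ``ld_block_size > 1`` each allele
    copy is generated from a block-shared latent Gaussian (pairwise
    correlation ``ld_rho``) thresholded at the Hardy-Weinberg quantile, so
    marginals stay Binomial while within-block dosages are positively
    correlated.
    """
    rng = _rng(cfg, 0)
    n, p = cfg.n, cfg.p
    mafs = rng.uniform(*cfg.maf_range, size=p)

    if cfg.ld_block_size == 1 or cfg.ld_rho == 0.0:
        dosages = rng.binomial(2, mafs, size=(n, p)).astype(float)
    else:
        dosages = np.empty((n, p))
        thresholds = norm.ppf(mafs)
        rho = cfg.ld_rho
        for start in range(0, p, cfg.ld_block_size):
            stop = min(start + cfg.ld_block_size, p)
            width = stop - start
            block = np.zeros((n, width))
            for _copy in range(2):  # two allele draws per genotype (HWE)
                shared = rng.standard_normal((n, 1))
                noise = rng.standard_normal((n, width))
                latent = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise
                block += latent < thresholds[start:stop]
            dosages[:, start:stop] = block

    variants = [
        VariantInfo(f"snp{j + 1:06d}", "1", j + 1, "A", "B") for j in range(p)
    ]
    sample_ids = [f"sim_{i + 1}" for i in range(n)]
    return GenotypeMatrix(dosages, np.zeros((n, p), dtype=bool), variants,
                          sample_ids)


def _draw_effects(G: GenotypeMatrix, cfg: SimConfig, rng: np.random.Generator):
    causal = np.sort(rng.choice(cfg.p, size=cfg.n_causal, replace=False))
    beta = rng.standard_normal(cfg.n_causal)
    g = G.dosages[:, causal] @ beta
    return causal, beta, g


def simulate_phenotype(G: GenotypeMatrix, cfg: SimConfig
                       ) -> tuple[PhenotypeTable, SimTruth]:
    """Continuous phenotype from a sparse linear model with Gaussian noise.

    ``round(s*p)`` causal variants get standard-Gaussian effects; the noise
    variance is solved from the *realized* sample variance of the genetic
    component g so that var(g)/var(y) matches h2 tightly even at small n:
    ``var(eps) = var(g) * (1 - h2) / h2``.  ``h2 = 1`` yields the noiseless
    phenotype y = g; ``h2 = 0`` yields pure standard-normal noise (warned).
    """
    rng = _rng(cfg, 1)
    if cfg.h2 == 0.0:
        warnings.warn("h2 = 0: phenotype is pure noise, truth has no signal")
        y = rng.standard_normal(cfg.n)
        truth = SimTruth(np.array([], dtype=int), np.array([]),
                         np.zeros(cfg.n), 0.0, G.variant_ids(), cfg.p)
        return PhenotypeTable(list(G.sample_ids), y), truth

    causal, beta, g = _draw_effects(G, cfg, rng)
    var_g = float(np.var(g))
    if var_g == 0.0:
        raise ValueError("genetic component has zero variance; causal variants "
                         "are monomorphic in this sample")
    if cfg.h2 == 1.0:
        y = g.copy()
    else:
        sigma = np.sqrt(var_g * (1.0 - cfg.h2) / cfg.h2)
        y = g + rng.normal(0.0, sigma, size=cfg.n)
    realized = var_g / float(np.var(y))
    truth = SimTruth(causal, beta, g, realized, G.variant_ids(), cfg.p)
    return PhenotypeTable(list(G.sample_ids), y), truth


def simulate_binary_phenotype(G: GenotypeMatrix, cfg: SimConfig,
                              prevalence: float
                              ) -> tuple[PhenotypeTable, SimTruth]:
    """Binary phenotype from a logistic model at a target prevalence.

    The genetic component is rescaled so its share of the liability variance
    (logistic residual variance pi^2/3) equals ``h2``; the intercept alpha is
    then solved by root-finding so that ``mean(sigmoid(alpha + g))`` equals
    the target prevalence, and cases are Bernoulli draws.
    """
    if not (0.0 < prevalence < 1.0):
        raise ValueError("prevalence must be in (0, 1)")
    rng = _rng(cfg, 2)
    if cfg.h2 == 0.0:
        g = np.zeros(cfg.n)
        causal, beta = np.array([], dtype=int), np.array([])
    else:
        causal, beta, g = _draw_effects(G, cfg, rng)
        var_g = float(np.var(g))
        if var_g == 0.0:
            raise ValueError("genetic component has zero variance")
        target_var = cfg.h2 * (np.pi ** 2 / 3.0) / (1.0 - cfg.h2) \
            if cfg.h2 < 1.0 else None
        if target_var is None:
            raise ValueError("liability h2 = 1 is not representable in a "
                             "logistic model")
        scale = np.sqrt(target_var / var_g)
        beta = beta * scale
        g = (g - g.mean()) * scale

    def mean_prob(alpha):
        return float(np.mean(expit(alpha + g))) - prevalence

    lo, hi = -50.0, 50.0
    if mean_prob(lo) > 0 or mean_prob(hi) < 0:
        raise ValueError(f"prevalence {prevalence} unattainable for this "
                         "genetic component")
    alpha = brentq(mean_prob, lo, hi, xtol=1e-10)
    probs = expit(alpha + g)
    y = rng.binomial(1, probs).astype(float)
    realized = float(np.var(g) / (np.var(g) + np.pi ** 2 / 3.0))
    truth = SimTruth(causal, beta, g, realized, G.variant_ids(), cfg.p)
    return PhenotypeTable(list(G.sample_ids), y), truth


def split_samples(n: int, fractions=(0.5, 0.2, 0.3), seed: int = 0
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Random disjoint train/validation/test partition of range(n)."""
    fractions = tuple(fractions)
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_test = n - n_train - n_val
    if min(n_train, n_val, n_test) < 1:
        raise ValueError(f"n = {n} too small for nonempty splits {fractions}")
    perm = np.random.default_rng(seed).permutation(n)
    return (np.sort(perm[:n_train]),
            np.sort(perm[n_train:n_train + n_val]),
            np.sort(perm[n_train + n_val:]))


def write_truth(truth: SimTruth, path) -> None:
    """Tab-delimited ground-truth effect table (variant_id, true_beta)."""
    with open(path, "w") as fh:
        fh.write("variant_id\ttrue_beta\n")
        for idx, beta in zip(truth.causal_indices, truth.true_beta):
            fh.write(f"{truth.variant_ids[idx]}\t{beta:.17g}\n")
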