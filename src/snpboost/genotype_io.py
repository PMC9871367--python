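"""Genotype and phenotype I/O: PLINK 1 binary triples, filtering, imputation.

Dosages count copies of the *effect allele*, which is taken to be PLINK's A1
(the first allele column of the .bim file), matching PLINK scoring
conventions so exported score files are directly usable.  Minor allele
frequency is folded to <= 0.5 for filtering, but dosages are never flipped:
fitted coefficients carry their sign relative to the stored effect allele.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PLINK_MAGIC = bytes([0x6C, 0x1B])
SNP_MAJOR_MODE = 0x01

# 2-bit PLINK codes (per sample, LSB first within each byte), SNP-major:
#   00 -> homozygous A1 (2 effect-allele copies)
#   01 -> missing
#   10 -> heterozygous   (1 copy)
#   11 -> homozygous A2  (0 copies)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class PlinkFormatError(ValueError):
    """Raised when a .bed file does not carry the expected magic/mode bytes."""


class PlinkCorruptionError(ValueError):
    """Raised when a .bed payload size is inconsistent with .bim/.fam."""


@dataclass(frozen=True)
class VariantInfo:
    """Identity of one genotyped variant (one column of the dosage matrix)."""

    variant_id: str
    chromosome: str
    position: int  # 1-based bp
    effect_allele: str
    other_allele: str

    def __post_init__(self):
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if self.effect_allele == self.other_allele:
            raise ValueError(
                f"{self.variant_id}: effect and other allele are identical "
                f"({self.effect_allele})"
            )


@dataclass
class GenotypeMatrix:
    """n x p matrix of effect-allele dosages in [0, 2] with variant metadata.

    ``dosages[i, j]`` is the dosage of sample ``sample_ids[i]`` at variant
    ``variants[j]``; missing entries are flagged in ``missing_mask`` and hold
    NaN until imputed.
    """

    dosages: np.ndarray
    missing_mask: np.ndarray
    variants: list[VariantInfo]
    sample_ids: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        n, p = self.dosages.shape
        if self.missing_mask.shape != (n, p):
            raise ValueError("missing_mask shape does not match dosages")
        if len(self.variants) != p:
            raise ValueError(f"{len(self.variants)} variant records for {p} columns")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample ids for {n} rows")
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            dupes = pd.Series(ids)[pd.Series(ids).duplicated()].unique()
            raise ValueError(f"duplicate variant ids: {list(dupes)[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        observed = self.dosages[~self.missing_mask]
        if observed.size and (np.nanmin(observed) < 0 or np.nanmax(observed) > 2):
            raise ValueError("non-missing dosages must lie in [0, 2]")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]


@dataclass
class PhenotypeTable:
    """Phenotype vector plus optional covariate matrix, keyed by sample id."""

    sample_ids: list[str]
    y: np.ndarray
    covariates: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.sample_ids)
        if self.y.shape != (n,):
            raise ValueError(f"y has shape {self.y.shape}, expected ({n},)")
        if np.isnan(self.y).any():
            raise ValueError("phenotype contains missing values")
        self.covariates = np.asarray(self.covariates, dtype=float)
        if self.covariates.size == 0:
            self.covariates = np.empty((n, 0))
        if self.covariates.shape[0] != n:
            raise ValueError("covariate rows do not match sample count")
        if not np.isfinite(self.covariates).all():
            raise ValueError("covariates contain non-finite values")
        if len(self.covariate_names) != self.covariates.shape[1]:
            raise ValueError("covariate_names length does not match covariate columns")

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[1]


# ---------------------------------------------------------------------------
# PLINK 1 binary codec
# ---------------------------------------------------------------------------

def read_bim(bim_path) -> list[VariantInfo]:
    try:
        bim = pd.read_csv(
            bim_path, sep=r"\s+", header=None,
            names=["chrom", "variant_id", "cm", "pos", "a1", "a2"],
            dtype={"chrom": str, "variant_id": str, "a1": str, "a2": str},
        )
    except pd.errors.EmptyDataError:
        return []
    return [
        VariantInfo(r.variant_id, r.chrom, int(r.pos), r.a1, r.a2)
        for r in bim.itertuples()
    ]


def read_fam(fam_path) -> list[str]:
    try:
        fam = pd.read_csv(
            fam_path, sep=r"\s+", header=None,
            names=["fid", "iid", "father", "mother", "sex", "pheno"],
            dtype={"fid": str, "iid": str},
        )
    except pd.errors.EmptyDataError:
        return []
    return [f"{r.fid}_{r.iid}" for r in fam.itertuples()]


def read_plink(bed_path, bim_path, fam_path) -> GenotypeMatrix:
    """Read a PLINK 1 .bed/.bim/.fam triple into a :class:`GenotypeMatrix`.

    Only the SNP-major layout (mode byte ``0x01``) is supported.  Decoding is
    variant-major: each variant occupies ``ceil(n/4)`` bytes, four samples per
    byte, two bits per sample starting at the least significant bits.
    """
    variants = read_bim(bim_path)
    sample_ids = read_fam(fam_path)
    n, p = len(sample_ids), len(variants)

    with open(bed_path, "rb") as fh:
        header = fh.read(3)
        payload = fh.read()
    if len(header) < 3 or header[:2] != PLINK_MAGIC:
        raise PlinkFormatError(
            f"{bed_path}: bad magic bytes {header[:2]!r}, expected 6c 1b"
        )
    if header[2] != SNP_MAJOR_MODE:
        raise PlinkFormatError(
            f"{bed_path}: mode byte {header[2]:#04x}, only SNP-major (0x01) supported"
        )
    bytes_per_variant = (n + 3) // 4
    expected = bytes_per_variant * p
    if len(payload) != expected:
        raise PlinkCorruptionError(
            f"{bed_path}: payload is {len(payload)} bytes, expected {expected} "
            f"for {n} samples x {p} variants"
        )

    raw = np.frombuffer(payload, dtype=np.uint8).reshape(p, bytes_per_variant)
    # unpack 4 samples/byte, LSB pair first
    codes = np.empty((p, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (raw >> (2 * k)) & 0b11
    codes = codes[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T.copy()  # n x p
    missing = np.isnan(dosages)
    return GenotypeMatrix(dosages, missing, variants, sample_ids)


def write_plink(G: GenotypeMatrix, prefix) -> None:
    """Write a GenotypeMatrix as a PLINK 1 triple ``prefix.{bed,bim,fam}``.

    Non-integer dosages are refused: the 2-bit format encodes hard calls only.
    """
    prefix = str(prefix)
    obs = G.dosages[~G.missing_mask]
    if obs.size and not np.allclose(obs, np.round(obs)):
        raise ValueError("PLINK 1 .bed stores hard calls; dosages must be integers")

    n, p = G.dosages.shape
    code = np.full((p, n), 0b01, dtype=np.uint8)  # missing
    d = G.dosages.T
    with np.errstate(invalid="ignore"):
        code[d == 2] = 0b00
        code[d == 1] = 0b10
        code[d == 0] = 0b11
    bytes_per_variant = (n + 3) // 4
    padded = np.full((p, bytes_per_variant * 4), 0b00, dtype=np.uint8)
    padded[:, :n] = code
    out = np.zeros((p, bytes_per_variant), dtype=np.uint8)
    for k in range(4):
        out |= padded[:, k::4] << (2 * k)

    with open(prefix + ".bed", "wb") as fh:
        fh.write(PLINK_MAGIC + bytes([SNP_MAJOR_MODE]))
        fh.write(out.tobytes())
    with open(prefix + ".bim", "w") as fh:
        for v in G.variants:
            fh.write(f"{v.chromosome}\t{v.variant_id}\t0\t{v.position}"
                     f"\t{v.effect_allele}\t{v.other_allele}\n")
    with open(prefix + ".fam", "w") as fh:
        for sid in G.sample_ids:
            fid, _, iid = sid.partition("_")
            fh.write(f"{fid or sid}\t{iid or sid}\t0\t0\t0\t-9\n")


# ---------------------------------------------------------------------------
# Phenotype / covariate tables
# ---------------------------------------------------------------------------

def read_phenotypes(path, phenotype: str, covariates: list[str] | None = None,
                    binary: bool = False) -> PhenotypeTable:
    """Read a whitespace-delimited table with header and FID/IID key columns.

    Binary phenotypes are expected as {0,1}; the PLINK-style {1,2} coding is
    auto-detected, shifted down by one, and logged.
    """
    df = pd.read_csv(path, sep=r"\s+", dtype={"FID": str, "IID": str})
    for col in ("FID", "IID"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required key column {col}")
    if phenotype not in df.columns:
        raise ValueError(f"{path}: no phenotype column {phenotype!r}")
    df = df.dropna(subset=[phenotype])
    y = df[phenotype].to_numpy(dtype=float)
    if binary:
        values = set(np.unique(y))
        if values <= {1.0, 2.0}:
            logger.warning("phenotype %s uses PLINK {1,2} coding; shifting to {0,1}",
                           phenotype)
            y = y - 1.0
        elif not values <= {0.0, 1.0}:
            raise ValueError(f"binary phenotype {phenotype} has values outside "
                             "{0,1} and {1,2}")
    covariates = covariates or []
    missing_cov = [c for c in covariates if c not in df.columns]
    if missing_cov:
        raise ValueError(f"{path}: missing covariate columns {missing_cov}")
    C = df[covariates].to_numpy(dtype=float) if covariates else np.empty((len(df), 0))
    sample_ids = [f"{f}_{i}" for f, i in zip(df["FID"], df["IID"])]
    return PhenotypeTable(sample_ids, y, C, list(covariates))


# ---------------------------------------------------------------------------
# Filtering, imputation, alignment
# ---------------------------------------------------------------------------

def variant_qc_stats(G: GenotypeMatrix) -> pd.DataFrame:
    """Per-variant call rate and folded minor-allele frequency.

    MAF is computed on non-missing dosages as the effect-allele frequency
    folded to <= 0.5.  Variants with zero non-missing entries get call rate 0
    and MAF NaN.
    """
    n = G.n_samples
    n_obs = (~G.missing_mask).sum(axis=0)
    call_rate = n_obs / n if n else np.zeros(G.n_variants)
    with np.errstate(invalid="ignore"):
        mean_dosage = np.nansum(np.where(G.missing_mask, 0.0, G.dosages), axis=0) / n_obs
    freq = mean_dosage / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    return pd.DataFrame({
        "variant_id": G.variant_ids(),
        "call_rate": call_rate,
        "maf": maf,
    })


def filter_variants(G: GenotypeMatrix, maf_min: float = 0.0,
                    call_rate_min: float = 0.0) -> GenotypeMatrix:
    """Keep variants with folded MAF >= maf_min and call rate >= call_rate_min.

    Order is preserved; a variant with no observed genotypes has call rate 0
    and is dropped by any positive threshold (never an error).
    """
    if not (0.0 <= maf_min <= 0.5):
        raise ValueError(f"maf_min must be in [0, 0.5], got {maf_min}")
    if not (0.0 <= call_rate_min <= 1.0):
        raise ValueError(f"call_rate_min must be in [0, 1], got {call_rate_min}")
    stats = variant_qc_stats(G)
    keep = (stats["call_rate"].to_numpy() >= call_rate_min) & \
           (np.nan_to_num(stats["maf"].to_numpy(), nan=-1.0) >= maf_min)
    idx = np.flatnonzero(keep)
    return GenotypeMatrix(
        G.dosages[:, idx].copy(),
        G.missing_mask[:, idx].copy(),
        [G.variants[j] for j in idx],
        list(G.sample_ids),
    )


def impute_missing(G: GenotypeMatrix, strategy: str = "mean") -> GenotypeMatrix:
    """Fill missing dosages.

    ``mean``      — per-variant mean of the observed dosages (every variant
                    must have at least one observed genotype);
    ``reference`` — zero copies of the effect allele.
    """
    if strategy not in ("mean", "reference"):
        raise ValueError(f"unknown imputation strategy {strategy!r}")
    dosages = G.dosages.copy()
    if strategy == "mean":
        n_obs = (~G.missing_mask).sum(axis=0)
        all_missing = np.flatnonzero(n_obs == 0)
        if all_missing.size:
            bad = G.variants[all_missing[0]].variant_id
            raise ValueError(
                f"cannot mean-impute variant {bad!r}: no observed genotypes"
            )
        with np.errstate(invalid="ignore"):
            col_mean = np.nansum(np.where(G.missing_mask, 0.0, dosages), axis=0) / n_obs
        fill = np.broadcast_to(col_mean, dosages.shape)
    else:
        fill = np.zeros_like(dosages)
    dosages[G.missing_mask] = fill[G.missing_mask]
    return GenotypeMatrix(
        dosages, np.zeros_like(G.missing_mask), list(G.variants), list(G.sample_ids)
    )


def align_samples(G: GenotypeMatrix, P: PhenotypeTable
                  ) -> tuple[GenotypeMatrix, PhenotypeTable]:
    """Restrict genotypes and phenotypes to their common samples, in G's order."""
    pheno_index = {sid: i for i, sid in enumerate(P.sample_ids)}
    g_keep = [i for i, sid in enumerate(G.sample_ids) if sid in pheno_index]
    if not g_keep:
        raise ValueError("no samples shared between genotype and phenotype data")
    dropped_g = G.n_samples - len(g_keep)
    dropped_p = len(P.sample_ids) - len(g_keep)
    if dropped_g or dropped_p:
        logger.info("align_samples: dropped %d genotype-only and %d phenotype-only "
                    "samples", dropped_g, dropped_p)
    ids = [G.sample_ids[i] for i in g_keep]
    p_keep = [pheno_index[sid] for sid in ids]
    G2 = GenotypeMatrix(G.dosages[g_keep], G.missing_mask[g_keep],
                        list(G.variants), ids)
    P2 = PhenotypeTable(ids, P.y[p_keep], P.covariates[p_keep],
                        list(P.covariate_names))
    return G2, P2


def subset_samples(G: GenotypeMatrix, idx) -> GenotypeMatrix:
    """Row-subset a GenotypeMatrix by integer index array."""
    idx = np.asarray(idx, dtype=int)
    return GenotypeMatrix(G.dosages[idx], G.missing_mask[idx], list(G.variants),
                          [G.sample_ids[i] for i in idx])


def subset_phenotypes(P: PhenotypeTable, idx) -> PhenotypeTable:
    idx = np.asarray(idx, dtype=int)
    return PhenotypeTable([P.sample_ids[i] for i in idx], P.y[idx],
                          P.covariates[idx], list(P.covariate_names))
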