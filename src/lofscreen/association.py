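"""Genotype-phenotype association on de-regressed breeding values.

Two routes per site: a one-way fixed-effect linear model (GLM) treating the
genotype as an unordered factor, and a kinship mixed model (MLM)

    y = X beta + u + e,   cov(u) = sigma_g^2 K,   cov(e) = sigma_e^2 I,

with K the identity-by-state kinship built from chip genotypes. Variance
components are estimated by REML through a single spectral decomposition of
K and a 1-D search over the variance ratio delta = sigma_e^2 / sigma_g^2
(the EMMA device), after which the genotype effect is tested with an F test
under the fitted covariance. With K = I and sigma_g -> 0 the MLM collapses
to the GLM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize
from scipy import stats as sps

from .popgen_stats import hwe_test
from .variants import MISSING, GenotypeMatrix

GENOTYPE_LABELS = {0: "hom_ref", 1: "het", 2: "hom_alt"}


@dataclass
class KinshipMatrix:
    """Symmetric IBS similarity matrix over ordered samples, values in [0,1]."""

    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.samples), len(self.samples)):
            raise ValueError("kinship shape does not match sample count")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("kinship matrix must be symmetric")
        self.values = v

    def subset(self, keep: list[str]) -> "KinshipMatrix":
        idx = [self.samples.index(s) for s in keep]
        return KinshipMatrix(keep, self.values[np.ix_(idx, idx)])


@dataclass
class AssociationResult:
    site_id: str
    method: str  # "GLM" | "MLM"
    p_nominal: float | None
    p_bonferroni: float | None = None
    r2: float | None = None
    genotype_means: dict[str, tuple[float, float]] = field(default_factory=dict)
    n_per_genotype: dict[str, int] = field(default_factory=dict)
    testable: bool = True
    h2: float | None = None  # MLM only: sigma_g^2 / (sigma_g^2 + sigma_e^2)


@dataclass
class ChipQCReport:
    n_snps_in: int
    n_maf_fail: int
    n_snp_callrate_fail: int
    n_hwe_fail: int
    n_snps_out: int
    n_animals_in: int
    n_animal_callrate_fail: int
    n_animals_out: int


def chip_qc_filter(
    chip: GenotypeMatrix,
    maf_min: float = 0.05,
    call_rate_min: float = 0.90,
    hwe_p_min: float = 1e-5,
) -> tuple[GenotypeMatrix, ChipQCReport]:
    """Standard chip QC: drop SNPs with MAF <= maf_min, call rate <=
    call_rate_min or HWE P < hwe_p_min, then drop animals with call rate <=
    call_rate_min over the surviving SNPs."""
    calls = chip.calls
    n_samples, n_snps = calls.shape
    called = calls != MISSING
    keep = np.ones(n_snps, dtype=bool)
    n_maf = n_cr = n_hwe = 0
    for j in range(n_snps):
        col = calls[called[:, j], j]
        if len(col) == 0 or len(col) / n_samples <= call_rate_min:
            keep[j] = False
            n_cr += 1
            continue
        n_aa = int((col == 0).sum())
        n_ab = int((col == 1).sum())
        n_bb = int((col == 2).sum())
        q = (2 * n_bb + n_ab) / (2 * len(col))
        if min(q, 1 - q) <= maf_min:
            keep[j] = False
            n_maf += 1
            continue
        _, _, p_hwe = hwe_test(n_aa, n_ab, n_bb)
        if p_hwe is not None and p_hwe < hwe_p_min:
            keep[j] = False
            n_hwe += 1
    snp_idx = [int(j) for j in np.flatnonzero(keep)]
    if not snp_idx:
        raise ValueError("chip QC removed every SNP")
    filtered = chip.subset_sites(snp_idx)
    animal_cr = (filtered.calls != MISSING).mean(axis=1)
    keep_animals = [s for s, cr in zip(filtered.samples, animal_cr) if cr > call_rate_min]
    n_animal_fail = n_samples - len(keep_animals)
    if n_animal_fail:
        filtered = filtered.subset_samples(keep_animals)
    report = ChipQCReport(
        n_snps_in=n_snps,
        n_maf_fail=n_maf,
        n_snp_callrate_fail=n_cr,
        n_hwe_fail=n_hwe,
        n_snps_out=len(snp_idx),
        n_animals_in=n_samples,
        n_animal_callrate_fail=n_animal_fail,
        n_animals_out=len(keep_animals) if n_animal_fail else n_samples,
    )
    return filtered, report


def ibs_kinship(chip: GenotypeMatrix) -> KinshipMatrix:
    """Identity-by-state kinship: mean shared-allele fraction over SNPs.

    For a pair of genotypes with dosage difference d in {0,1,2} alleles, the
    per-SNP contribution is 1 - d/2; averaging over SNPs non-missing in both
    samples gives k_ij in [0,1]. Self-similarity is 1. A pair with no shared
    non-missing SNP is flagged NaN.
    """
    if chip.n_samples < 2 or chip.n_sites < 1:
        raise ValueError("need >=2 samples and >=1 SNP")
    dos = chip.calls.astype(float)
    dos[chip.calls == MISSING] = np.nan
    n = chip.n_samples
    k = np.ones((n, n))
    for i in range(n):
        diff = np.abs(dos[i] - dos[i + 1 :])  # (n-i-1, n_snps)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pairs
            sim = 1.0 - np.nanmean(diff, axis=1) / 2.0
        k[i, i + 1 :] = sim
        k[i + 1 :, i] = sim
    return KinshipMatrix(list(chip.samples), k)


def _genotype_series(dosage: np.ndarray) -> pd.Series:
    return pd.Series(dosage).map(GENOTYPE_LABELS)


def _means_and_counts(y: np.ndarray, g: np.ndarray):
    means: dict[str, tuple[float, float]] = {}
    counts: dict[str, int] = {}
    for level in sorted(set(g)):
        label = GENOTYPE_LABELS[int(level)]
        yv = y[g == level]
        se = float(yv.std(ddof=1) / np.sqrt(len(yv))) if len(yv) > 1 else float("nan")
        means[label] = (float(yv.mean()), se)
        counts[label] = int(len(yv))
    return means, counts


def glm_assoc(dosage: np.ndarray, phenotype: np.ndarray, site_id: str = "") -> AssociationResult:
    """One-way fixed-effect linear model with genotype as categorical factor.

    Complete-case on genotype and phenotype; the P-value is from the overall
    F test of the genotype factor and r2 is model SS / total SS.
    """
    dosage = np.asarray(dosage, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    ok = ~(np.isnan(dosage) | np.isnan(phenotype))
    g, y = dosage[ok].astype(int), phenotype[ok]
    levels = np.unique(g)
    means, counts = _means_and_counts(y, g)
    if len(levels) < 2:
        return AssociationResult(
            site_id=site_id, method="GLM", p_nominal=None, testable=False,
            genotype_means=means, n_per_genotype=counts,
        )
    X = sm.add_constant(pd.get_dummies(_genotype_series(g), drop_first=True).astype(float))
    fit = sm.OLS(y, X).fit()
    return AssociationResult(
        site_id=site_id,
        method="GLM",
        p_nominal=float(fit.f_pvalue),
        r2=float(fit.rsquared),
        genotype_means=means,
        n_per_genotype=counts,
    )


def _reml_neg_loglik(log_delta: float, s: np.ndarray, ystar: np.ndarray, xstar: np.ndarray) -> float:
    delta = np.exp(log_delta)
    w = 1.0 / (s + delta)
    xtwx = xstar.T @ (w[:, None] * xstar)
    xtwy = xstar.T @ (w * ystar)
    beta = np.linalg.solve(xtwx, xtwy)
    r = ystar - xstar @ beta
    rss = float(np.sum(w * r * r))
    n, p = xstar.shape
    nu = n - p
    sign, logdet_xtwx = np.linalg.slogdet(xtwx)
    _, logdet_xtx = np.linalg.slogdet(xstar.T @ xstar)
    sigma_g2 = rss / nu
    ll = -0.5 * (
        nu * np.log(2 * np.pi * sigma_g2)
        + nu
        + np.sum(np.log(s + delta))
        + logdet_xtwx
        - logdet_xtx
    )
    return -ll


def mlm_assoc(
    dosage: np.ndarray,
    phenotype: np.ndarray,
    kinship: KinshipMatrix,
    samples: list[str] | None = None,
    site_id: str = "",
) -> AssociationResult:
    """Kinship mixed-model association at one site.

    REML over the variance ratio via spectral decomposition of K; genotype
    significance from an F test comparing the genotype factor against the
    intercept-only model under the fitted covariance. ``samples`` orders the
    dosage/phenotype vectors for alignment with the kinship matrix; by
    default the kinship sample order is assumed.
    """
    dosage = np.asarray(dosage, dtype=float)
    phenotype = np.asarray(phenotype, dtype=float)
    if samples is None:
        samples = kinship.samples
    if len(samples) != len(dosage) or len(samples) != len(phenotype):
        raise ValueError("dosage/phenotype/sample lengths disagree")
    missing_k = set(samples) - set(kinship.samples)
    if missing_k:
        raise ValueError(f"kinship does not cover samples: {sorted(missing_k)[:5]}")
    ok = ~(np.isnan(dosage) | np.isnan(phenotype))
    kept = [s for s, o in zip(samples, ok) if o]
    g, y = dosage[ok].astype(int), phenotype[ok]
    k = kinship.subset(kept).values
    if np.isnan(k).any():
        raise ValueError("kinship contains missing pairs for phenotyped samples")
    means, counts = _means_and_counts(y, g)
    if len(np.unique(g)) < 2:
        return AssociationResult(
            site_id=site_id, method="MLM", p_nominal=None, testable=False,
            genotype_means=means, n_per_genotype=counts,
        )

    eigvals, u = np.linalg.eigh(k)
    if eigvals.min() < -1e-8:
        # bending: minimal diagonal inflation to restore PSD
        warnings.warn(f"kinship not PSD (min eigenvalue {eigvals.min():.3g}); bending applied")
        eigvals = eigvals - eigvals.min()
    s = np.clip(eigvals, 0.0, None)

    dummies = pd.get_dummies(_genotype_series(g), drop_first=True).astype(float).to_numpy()
    X = np.column_stack([np.ones(len(y)), dummies])
    ystar = u.T @ y
    xstar = u.T @ X

    res = optimize.minimize_scalar(
        _reml_neg_loglik,
        bounds=(np.log(1e-5), np.log(1e5)),
        args=(s, ystar, xstar),
        method="bounded",
        options={"xatol": 1e-6},
    )
    delta = float(np.exp(res.x))
    w = 1.0 / (s + delta)

    def wrss(xs: np.ndarray) -> float:
        beta = np.linalg.solve(xs.T @ (w[:, None] * xs), xs.T @ (w * ystar))
        r = ystar - xs @ beta
        return float(np.sum(w * r * r))

    rss_full = wrss(xstar)
    rss_null = wrss(xstar[:, :1])
    n, p = xstar.shape
    q = p - 1
    f_stat = ((rss_null - rss_full) / q) / (rss_full / (n - p))
    p_val = float(sps.f.sf(f_stat, q, n - p))
    r2 = float(1.0 - rss_full / rss_null)
    return AssociationResult(
        site_id=site_id,
        method="MLM",
        p_nominal=p_val,
        r2=r2,
        genotype_means=means,
        n_per_genotype=counts,
        h2=1.0 / (1.0 + delta),
    )


def bonferroni_adjust(p_nominal: float, m: int) -> float:
    """Bonferroni-corrected P: min(1, m * p), m = number of tests."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not (0.0 <= p_nominal <= 1.0):
        raise ValueError(f"p outside [0,1]: {p_nominal}")
    return min(1.0, m * p_nominal)


def write_kinship(kinship: KinshipMatrix, path) -> None:
    pd.DataFrame(kinship.values, index=kinship.samples, columns=kinship.samples).to_csv(
        path, sep="\t"
    )


def read_kinship(path) -> KinshipMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return KinshipMatrix([str(s) for s in df.index], df.to_numpy(dtype=float))
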