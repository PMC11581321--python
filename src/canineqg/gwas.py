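"""Univariate linear-mixed-model association with Wald tests.

Per-SNP model: y = W alpha + x beta + u + eps with u ~ N(0, sigma_g2 K) for
the centered GRM K and eps ~ N(0, sigma_e2 I). The kinship is
eigendecomposed once; each SNP's variance ratio is either re-optimized by
REML (``per_snp``, the exact treatment) or reused from the covariate-only
null model (``null_once``, faster, p-values differ slightly). The reported
statistic is the Wald chi-square (beta_hat / se)^2 on 1 df.

Also provides the genomic inflation factor (median association chi-square
over the null median 0.4549), Bonferroni / suggestive thresholds, and
QQ-plot tables.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
from scipy.stats import chi2

from .errors import ConfigError, IntegrityError, NumericalError
from .formats import GenotypeMatrix
from .qc import impute_mean
from .relmat import RelationshipMatrix, build_G_centered
from .varcomp import ModelSpec, design_matrix

__all__ = [
    "GwasModelSpec",
    "GwasTable",
    "run_lmm_gwas",
    "genomic_inflation",
    "thresholds",
    "qq_table",
]

#: median of the 1-df chi-square distribution
CHI2_1_MEDIAN = float(chi2.ppf(0.5, df=1))

_LOG_GAMMA_BOUNDS = (-10.0, 10.0)


@dataclass(frozen=True)
class GwasModelSpec:
    """Covariates and variance-ratio handling for the association scan."""

    fixed_factors: tuple[str, ...] = ("sex", "measurement_date")
    covariates: tuple[str, ...] = ("age",)
    lambda_mode: str = "per_snp"  # or "null_once"
    alpha: float = 0.05
    lenient_neglog10: float = 4.0

    def validate(self) -> None:
        if self.lambda_mode not in {"per_snp", "null_once"}:
            raise ConfigError(f"unknown lambda_mode {self.lambda_mode!r}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must lie in (0, 1)")


@dataclass
class GwasTable:
    snps: pd.DataFrame  # per-SNP rows
    lambda_gc: float
    n_snps: int
    bonferroni_p: float
    suggestive_p: float
    lenient_neglog10: float
    skipped: list[tuple[str, str]] = field(default_factory=list)

    def significant(self, p_threshold: Optional[float] = None) -> pd.DataFrame:
        thr = self.bonferroni_p if p_threshold is None else p_threshold
        return self.snps.loc[self.snps["p_wald"] <= thr]


def _reml_gamma(
    s: np.ndarray, yt: np.ndarray, Xt: np.ndarray
) -> tuple[float, float]:
    """Maximize the restricted likelihood over gamma = sigma_g2 / sigma_e2.

    Returns (gamma, sigma_e2_hat). Inputs are already rotated by the
    kinship eigenvectors; s holds the eigenvalues.
    """
    n, p = Xt.shape

    def neg_ll(lg: float) -> float:
        w = np.exp(lg) * s + 1.0
        Wi = 1.0 / w
        XtWX = Xt.T @ (Xt * Wi[:, None])
        XtWy = Xt.T @ (yt * Wi)
        try:
            c = scipy.linalg.cho_factor(XtWX)
        except scipy.linalg.LinAlgError:
            return np.inf
        beta = scipy.linalg.cho_solve(c, XtWy)
        r = yt - Xt @ beta
        sigma_e2 = float(r @ (r * Wi)) / (n - p)
        if sigma_e2 <= 0:
            return np.inf
        return 0.5 * (
            (n - p) * np.log(sigma_e2)
            + np.sum(np.log(w))
            + 2.0 * np.sum(np.log(np.diag(c[0])))
        )

    lo, hi = _LOG_GAMMA_BOUNDS
    grid = np.linspace(lo, hi, 21)
    vals = [neg_ll(g) for g in grid]
    k = int(np.argmin(vals))
    res = scipy.optimize.minimize_scalar(
        neg_ll,
        bounds=(grid[max(k - 1, 0)], grid[min(k + 1, len(grid) - 1)]),
        method="bounded",
        options={"xatol": 1e-8},
    )
    gamma = float(np.exp(res.x))
    w = gamma * s + 1.0
    Wi = 1.0 / w
    XtWX = Xt.T @ (Xt * Wi[:, None])
    beta = np.linalg.solve(XtWX, Xt.T @ (yt * Wi))
    r = yt - Xt @ beta
    sigma_e2 = float(r @ (r * Wi)) / (n - p)
    return gamma, sigma_e2


def _gls_wald(
    s: np.ndarray, yt: np.ndarray, Xt: np.ndarray, gamma: float
) -> tuple[float, float, float]:
    """GLS effect, SE, and Wald p for the last column of Xt."""
    n, p = Xt.shape
    w = gamma * s + 1.0
    Wi = 1.0 / w
    XtWX = Xt.T @ (Xt * Wi[:, None])
    XtWy = Xt.T @ (yt * Wi)
    try:
        XtWX_inv = scipy.linalg.inv(XtWX)
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError("singular design in GLS") from exc
    beta = XtWX_inv @ XtWy
    r = yt - Xt @ beta
    sigma_e2 = float(r @ (r * Wi)) / (n - p)
    se = float(np.sqrt(sigma_e2 * XtWX_inv[-1, -1]))
    b = float(beta[-1])
    stat = (b / se) ** 2
    return b, se, float(chi2.sf(stat, df=1))


def run_lmm_gwas(
    phenotypes: pd.DataFrame,
    trait: str,
    genotypes: GenotypeMatrix,
    kinship: Optional[RelationshipMatrix] = None,
    spec: GwasModelSpec = GwasModelSpec(),
) -> GwasTable:
    """Per-SNP mixed-model association scan.

    Animals are the intersection of phenotyped, genotyped, and kinship ids.
    MAF is taken pre-imputation; missing dosages are mean-imputed for the
    regression. Monomorphic SNPs are skipped with a logged reason.
    """
    spec.validate()
    model = ModelSpec(
        trait=trait, fixed_factors=spec.fixed_factors, covariates=spec.covariates
    )
    maf_pre = genotypes.maf()
    gm = impute_mean(genotypes)
    skipped: list[tuple[str, str]] = []
    poly = gm.dosage.std(axis=0) > 0.0
    if not poly.all():
        skipped += [(gm.snp_ids[j], "monomorphic") for j in np.flatnonzero(~poly)]
        maf_pre = maf_pre[poly]
        gm = gm.subset(snps=poly)
    if kinship is None:
        kinship = build_G_centered(gm)
    ph = phenotypes.copy()
    ph["animal_id"] = ph["animal_id"].astype(str)
    ph = ph.loc[~ph[trait].isna()]
    phen_ids = set(ph["animal_id"])
    kin_ids = set(kinship.ids)
    ids = [a for a in gm.animal_ids if a in phen_ids and a in kin_ids]
    if not ids:
        raise IntegrityError("no animals shared by phenotypes, genotypes, kinship")
    gm = gm.subset(animals=ids)
    K = kinship.submatrix(ids).values
    ph = ph.set_index("animal_id").loc[ids].reset_index()

    y = ph[trait].to_numpy(dtype=float)
    W, _ = design_matrix(ph, model)
    s, U = scipy.linalg.eigh(K)
    if s[0] < -1e-6 * max(abs(s[-1]), 1.0):
        raise NumericalError(
            f"kinship matrix is not PSD (smallest eigenvalue {s[0]:.3e})"
        )
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    Wt = U.T @ W
    Xt_all = U.T @ gm.dosage  # rotate all SNP columns once

    gamma_null, _ = _reml_gamma(s, yt, Wt)

    rows = []
    m = gm.n_snps
    for j in range(m):
        x = gm.dosage[:, j]
        if x.std() == 0.0:  # can still occur after restricting animals
            skipped.append((gm.snp_ids[j], "monomorphic"))
            continue
        Xt = np.column_stack([Wt, Xt_all[:, j]])
        if spec.lambda_mode == "per_snp":
            gamma, _ = _reml_gamma(s, yt, Xt)
        else:
            gamma = gamma_null
        beta, se, p = _gls_wald(s, yt, Xt, gamma)
        rows.append(
            (
                gm.snp_ids[j], str(gm.chromosome[j]), int(gm.position_bp[j]),
                str(gm.allele_minor[j]), str(gm.allele_major[j]),
                float(maf_pre[j]), beta, se, p,
            )
        )
    snps = pd.DataFrame(
        rows,
        columns=[
            "snp_id", "chromosome", "position_bp", "allele_minor",
            "allele_major", "maf", "beta", "se_beta", "p_wald",
        ],
    )
    n_tested = len(snps)
    if n_tested == 0:
        raise ConfigError("no polymorphic SNPs to test")
    bonf, sugg = thresholds(spec.alpha, n_tested)
    return GwasTable(
        snps=snps,
        lambda_gc=genomic_inflation(snps["p_wald"].to_numpy()),
        n_snps=n_tested,
        bonferroni_p=bonf,
        suggestive_p=sugg,
        lenient_neglog10=spec.lenient_neglog10,
        skipped=skipped,
    )


def genomic_inflation(p_values: Sequence[float]) -> float:
    """Genomic inflation factor lambda_gc.

    Back-converts p-values to 1-df chi-square statistics and divides their
    median by the null median (~0.4549); ~1 indicates well-controlled
    stratification.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ConfigError("genomic inflation undefined for empty input")
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ConfigError("p-values must lie in (0, 1]")
    stats = chi2.isf(p, df=1)
    return float(np.median(stats) / CHI2_1_MEDIAN)


def thresholds(alpha: float, n_snps: int) -> tuple[float, float]:
    """Genome-wide (Bonferroni alpha/N) and suggestive (1/N) p thresholds."""
    if n_snps < 1:
        raise ConfigError("n_snps must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ConfigError("alpha must lie in (0, 1)")
    return alpha / n_snps, min(1.0 / n_snps, 1.0)


def qq_table(p_values: Sequence[float]) -> pd.DataFrame:
    """Expected vs observed -log10 p for a QQ plot.

    Observed p-values are sorted ascending; expected quantiles are
    (i - 0.5)/n for ranks i = 1..n.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ConfigError("qq_table requires at least one p-value")
    if np.any((p <= 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ConfigError("p-values must lie in (0, 1]")
    obs = np.sort(p)
    n = p.size
    exp = (np.arange(1, n + 1) - 0.5) / n
    return pd.DataFrame(
        {
            "expected_neglog10": -np.log10(exp),
            "observed_neglog10": -np.log10(obs),
        }
    )
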