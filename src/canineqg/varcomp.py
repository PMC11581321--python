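"""Single-trait animal-model REML and heritability.

The model is y = Xb + u + e with u ~ N(0, sigma_a2 K) for a relationship
matrix K (pedigree A, genomic G, or the single-step H) restricted to the
phenotyped animals, and e ~ N(0, sigma_e2 I). Because there is a single
random effect, the restricted likelihood can be profiled down to one
dimension: after rotating by the eigenvectors of K the covariance is
diagonal in the variance ratio gamma = sigma_a2 / sigma_e2, and gamma is
optimized by a guarded one-dimensional search. This is exact for this model
class and globally reliable, unlike general-purpose AI-REML iterations.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize

from .errors import ConfigError, IdentifiabilityError, NumericalError
from .relmat import RelationshipMatrix

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "adjust_phenotypes",
    "reml_fit",
    "heritability",
    "heritability_binary",
]

_LOG_GAMMA_BOUNDS = (-12.0, 12.0)
_BOUNDARY_TOL = 1e-6


@dataclass(frozen=True)
class ModelSpec:
    """Trait and fixed-effect structure of the animal model."""

    trait: str = "trait"
    fixed_factors: tuple[str, ...] = ("sex", "measurement_date")
    covariates: tuple[str, ...] = ("age",)


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    h2: float
    se_h2: float
    loglik: float
    n_iterations: int
    converged: bool
    boundary: bool = False

    @property
    def sigma_p2(self) -> float:
        return self.sigma_a2 + self.sigma_e2

    @property
    def lambda_ratio(self) -> float:
        """Mixed-model-equation shrinkage ratio sigma_e2 / sigma_a2."""
        if self.sigma_a2 <= 0:
            raise NumericalError("lambda ratio undefined at sigma_a2 = 0")
        return self.sigma_e2 / self.sigma_a2


def design_matrix(
    phenotypes: pd.DataFrame, model: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Intercept + reference-coded factor dummies + covariates.

    Raises :class:`NumericalError` naming the collinear columns if the
    design is rank-deficient.
    """
    cols: list[np.ndarray] = [np.ones(len(phenotypes))]
    names = ["intercept"]
    for f in model.fixed_factors:
        if f not in phenotypes.columns:
            raise ConfigError(f"fixed factor {f!r} not in phenotype table")
        dummies = pd.get_dummies(phenotypes[f].astype(str), prefix=f, drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(dtype=float))
            names.append(c)
    for c in model.covariates:
        if c not in phenotypes.columns:
            raise ConfigError(f"covariate {c!r} not in phenotype table")
        cols.append(phenotypes[c].to_numpy(dtype=float))
        names.append(c)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, _, piv = scipy.linalg.qr(X, mode="economic", pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise NumericalError(f"rank-deficient fixed-effect design; collinear: {bad}")
    return X, names


def adjust_phenotypes(phenotypes: pd.DataFrame, model: ModelSpec) -> pd.Series:
    """Adjusted phenotypes y_c = y - X (X'X)^-1 X'y (OLS residuals).

    Residuals are orthogonal to the fixed-effect design columns; downstream
    BLUP models then fit only an overall mean.
    """
    y = phenotypes[model.trait].to_numpy(dtype=float)
    keep = ~np.isnan(y)
    sub = phenotypes.loc[keep]
    X, _ = design_matrix(sub, model)
    beta, *_ = np.linalg.lstsq(X, y[keep], rcond=None)
    resid = y[keep] - X @ beta
    return pd.Series(resid, index=sub["animal_id"].astype(str), name=f"{model.trait}_adj")


def _restricted_loglik(
    log_gamma: float, s: np.ndarray, yt: np.ndarray, Xt: np.ndarray
) -> tuple[float, float]:
    """Profiled restricted log-likelihood at gamma = exp(log_gamma).

    Returns (loglik, sigma_e2_hat); constants independent of gamma omitted.
    """
    gamma = np.exp(log_gamma)
    w = gamma * s + 1.0  # Var(y~_i) / sigma_e2
    n, p = Xt.shape
    Wi = 1.0 / w
    XtWX = Xt.T @ (Xt * Wi[:, None])
    XtWy = Xt.T @ (yt * Wi)
    try:
        c = scipy.linalg.cho_factor(XtWX)
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError("singular weighted design in REML") from exc
    beta = scipy.linalg.cho_solve(c, XtWy)
    r = yt - Xt @ beta
    rss = float(r @ (r * Wi))
    sigma_e2 = rss / (n - p)
    logdet_XtWX = 2.0 * np.sum(np.log(np.diag(c[0])))
    ll = -0.5 * (
        (n - p) * np.log(sigma_e2)
        + np.sum(np.log(w))
        + logdet_XtWX
        + (n - p)
    )
    return ll, sigma_e2


def reml_fit(
    phenotypes: pd.DataFrame,
    model: ModelSpec,
    relmat: RelationshipMatrix,
) -> VarianceComponents:
    """REML variance components for one trait against any relationship matrix.

    The matrix is restricted to phenotyped animals and eigendecomposed once;
    the variance ratio is profiled out and optimized on the log scale
    (coarse grid + bounded Brent refinement). The standard error of h2 comes
    from the curvature of the profiled restricted log-likelihood; solutions
    at the h2 in {0, 1} boundary are flagged and report NaN SE.
    """
    y_all = phenotypes[model.trait].to_numpy(dtype=float)
    keep = ~np.isnan(y_all)
    sub = phenotypes.loc[keep]
    ids = sub["animal_id"].astype(str).tolist()
    K = relmat.submatrix(ids).values
    X, _ = design_matrix(sub, model)
    y = y_all[keep]
    n, p = X.shape
    if n < p + 2:
        raise ConfigError(f"need at least {p + 2} phenotyped animals, have {n}")
    s, U = scipy.linalg.eigh(K)
    if s[0] < -1e-6 * max(s[-1], 1.0):
        raise NumericalError(
            f"relationship matrix is not PSD (smallest eigenvalue {s[0]:.3e})"
        )
    s = np.clip(s, 0.0, None)
    if s[-1] - s[0] < 1e-8:
        raise IdentifiabilityError(
            "relationship matrix is (a multiple of) the identity on the "
            "phenotyped animals; additive and residual variances are confounded"
        )
    yt = U.T @ y
    Xt = U.T @ X

    evals = 0

    def neg_ll(lg: float) -> float:
        nonlocal evals
        evals += 1
        return -_restricted_loglik(lg, s, yt, Xt)[0]

    lo, hi = _LOG_GAMMA_BOUNDS
    grid = np.linspace(lo, hi, 49)
    vals = np.array([neg_ll(g) for g in grid])
    k = int(np.argmin(vals))
    a = grid[max(k - 1, 0)]
    b = grid[min(k + 1, len(grid) - 1)]
    res = scipy.optimize.minimize_scalar(
        neg_ll, bounds=(a, b), method="bounded",
        options={"xatol": 1e-10},
    )
    log_gamma = float(res.x)
    ll, sigma_e2 = _restricted_loglik(log_gamma, s, yt, Xt)
    gamma = np.exp(log_gamma)
    sigma_a2 = gamma * sigma_e2
    h2 = sigma_a2 / (sigma_a2 + sigma_e2)
    boundary = bool(
        h2 < _BOUNDARY_TOL
        or h2 > 1.0 - _BOUNDARY_TOL
        or log_gamma <= lo + 1e-3  # optimizer pinned at a search bound
        or log_gamma >= hi - 1e-3
    )

    se_h2 = float("nan")
    if not boundary:
        # curvature of the profiled restricted log-likelihood in h2
        def ll_of_h2(h: float) -> float:
            return _restricted_loglik(np.log(h / (1.0 - h)), s, yt, Xt)[0]

        eps = min(1e-4, h2 / 2, (1.0 - h2) / 2)
        d2 = (ll_of_h2(h2 + eps) - 2.0 * ll + ll_of_h2(h2 - eps)) / eps**2
        if d2 < 0:
            se_h2 = float(np.sqrt(-1.0 / d2))

    return VarianceComponents(
        sigma_a2=float(sigma_a2),
        sigma_e2=float(sigma_e2),
        h2=float(h2),
        se_h2=se_h2,
        loglik=float(ll),
        n_iterations=evals,
        converged=bool(res.success),
        boundary=boundary,
    )


def heritability(sigma_a2: float, sigma_p2: float) -> float:
    """Narrow-sense heritability h2 = sigma_a2 / sigma_p2."""
    if sigma_p2 <= 0:
        raise ConfigError("phenotypic variance must be positive")
    if not (0.0 <= sigma_a2 <= sigma_p2):
        raise ConfigError("additive variance must lie in [0, sigma_p2]")
    return sigma_a2 / sigma_p2


def heritability_binary(sigma_a2: float, incidence: float) -> float:
    """Observed-scale heritability of a 0/1 trait.

    h2 = sigma_a2 / (phi (1 - phi)) with phi the incidence; the denominator
    is the phenotypic variance of a Bernoulli trait. The ratio can exceed 1
    when the additive variance was estimated on another scale — it is
    returned as computed, with a warning.
    """
    if not (0.0 < incidence < 1.0):
        raise ConfigError("incidence must lie strictly between 0 and 1")
    if sigma_a2 < 0:
        raise ConfigError("additive variance must be non-negative")
    h2 = sigma_a2 / (incidence * (1.0 - incidence))
    if h2 > 1.0:
        warnings.warn(
            f"observed-scale heritability {h2:.3g} exceeds 1; the additive "
            "variance is inconsistent with a Bernoulli phenotypic variance",
            stacklevel=2,
        )
    return h2
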