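"""(G)EBV prediction by mixed-model equations and cross-validated accuracy.

Four configurations are supported:

* PBLUP    — pedigree A over all animals;
* PBLUP_G  — pedigree A22 restricted to genotyped animals (phenotypes of
             genotyped animals only);
* GBLUP    — VanRaden G over genotyped animals;
* SSGBLUP  — single-step H^-1 over all animals.

All solve the same model y_c = 1 mu + Z u + e on fixed-effect-adjusted
phenotypes, with shrinkage ratio lambda* = sigma_e2 / sigma_a2 and the
method's relationship inverse in Henderson's mixed-model equations.
Validation animals are masked from the data vector, never from the
relationship structure, so their EBVs flow purely through relationships.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.linalg

from .errors import ConfigError, NumericalError
from .relmat import RelationshipMatrix
from .varcomp import VarianceComponents

__all__ = [
    "PredictionMethod",
    "EbvResult",
    "CvResult",
    "predict_ebv",
    "crossvalidate",
    "bias_slope",
]

#: relative MME residual tolerance asserted on every solve
_MME_RTOL = 1e-8


class PredictionMethod(str, Enum):
    PBLUP_G = "pblup-g"
    PBLUP = "pblup"
    GBLUP = "gblup"
    SSGBLUP = "ssgblup"


@dataclass
class EbvResult:
    method: PredictionMethod
    ebv: pd.Series  # animal_id -> EBV (trait units)
    mu: float
    lambda_ratio: float
    mme_residual: float


@dataclass
class CvResult:
    method: PredictionMethod
    fold_accuracies: list[float]
    mean_accuracy: float
    empirical_se: float
    bias_slope: float
    seed: int


def _kinv_for_method(
    method: PredictionMethod,
    A_inv: Optional[RelationshipMatrix] = None,
    A22: Optional[RelationshipMatrix] = None,
    G: Optional[RelationshipMatrix] = None,
    H_inv: Optional[RelationshipMatrix] = None,
) -> tuple[np.ndarray, list[str]]:
    """Relationship inverse and animal scope for the requested method."""
    method = PredictionMethod(method)
    if method is PredictionMethod.PBLUP:
        if A_inv is None:
            raise ConfigError("PBLUP requires A_inv")
        return A_inv.values, A_inv.ids
    if method is PredictionMethod.SSGBLUP:
        if H_inv is None:
            raise ConfigError("ssGBLUP requires H_inv")
        return H_inv.values, H_inv.ids
    if method is PredictionMethod.PBLUP_G:
        if A22 is None:
            raise ConfigError("PBLUP-G requires A22")
        src = A22
    else:  # GBLUP
        if G is None:
            raise ConfigError("GBLUP requires G (no genotypes available?)")
        src = G
    n = len(src.ids)
    M = src.values + 1e-8 * np.eye(n)  # numerical ridge before inversion
    try:
        Minv = scipy.linalg.inv(M)
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError(f"{src.kind} is singular and cannot be inverted") from exc
    return Minv, src.ids


def predict_ebv(
    y_c: pd.Series,
    method: PredictionMethod,
    varcomp: VarianceComponents,
    *,
    A_inv: Optional[RelationshipMatrix] = None,
    A22: Optional[RelationshipMatrix] = None,
    G: Optional[RelationshipMatrix] = None,
    H_inv: Optional[RelationshipMatrix] = None,
    mask_ids: Sequence[str] = (),
) -> EbvResult:
    """Solve the mixed-model equations for y_c = 1 mu + Z u + e.

    ``y_c`` are adjusted phenotypes indexed by animal id; ``mask_ids``
    (validation animals) keep their slot in the relationship structure but
    contribute no data. EBVs are returned for every animal in the method's
    relationship scope, phenotyped or not.
    """
    if varcomp.sigma_a2 <= 0 or varcomp.sigma_e2 <= 0:
        raise ConfigError("both variance components must be positive for BLUP")
    Kinv, ids = _kinv_for_method(method, A_inv=A_inv, A22=A22, G=G, H_inv=H_inv)
    lam = varcomp.lambda_ratio
    mask = {str(a) for a in mask_ids}
    y_c = y_c.dropna()
    obs_ids = [a for a in ids if a in y_c.index and a not in mask]
    if not obs_ids:
        raise ConfigError("no phenotyped animals left after masking")
    n_all = len(ids)
    pos = {a: i for i, a in enumerate(ids)}
    obs_idx = np.array([pos[a] for a in obs_ids], dtype=np.int64)
    y = y_c.loc[obs_ids].to_numpy(dtype=float)

    # Henderson's MME for a single overall mean:
    # [ n_obs   z'      ] [mu]   [ sum y ]
    # [ z   ZtZ + lam*Kinv ] [u ] = [ Z'y   ]
    lhs = np.zeros((n_all + 1, n_all + 1))
    rhs = np.zeros(n_all + 1)
    lhs[0, 0] = len(obs_ids)
    z = np.zeros(n_all)
    z[obs_idx] = 1.0
    lhs[0, 1:] = z
    lhs[1:, 0] = z
    lhs[1:, 1:] = lam * Kinv
    lhs[1 + obs_idx, 1 + obs_idx] += 1.0
    rhs[0] = y.sum()
    rhs[1 + obs_idx] = y
    try:
        sol = scipy.linalg.solve(lhs, rhs, assume_a="sym")
    except scipy.linalg.LinAlgError as exc:
        raise NumericalError("singular mixed-model equations") from exc
    resid = np.linalg.norm(lhs @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
    if resid > _MME_RTOL:
        raise NumericalError(f"MME solution residual {resid:.2e} exceeds {_MME_RTOL}")
    return EbvResult(
        method=PredictionMethod(method),
        ebv=pd.Series(sol[1:], index=ids, name="ebv"),
        mu=float(sol[0]),
        lambda_ratio=lam,
        mme_residual=float(resid),
    )


def bias_slope(y_c: Sequence[float], ebv: Sequence[float]) -> float:
    """Regression slope of phenotype on (G)EBV: cov(y_c, ebv) / var(ebv).

    1 means unbiased prediction; <1 (>1) indicates over- (under-) dispersed
    EBVs, i.e. over- or underestimation of differences between animals.
    """
    y = np.asarray(y_c, dtype=float)
    g = np.asarray(ebv, dtype=float)
    if len(y) != len(g) or len(y) < 3:
        raise ConfigError("bias slope needs >= 3 paired observations")
    vg = g.var(ddof=1)
    if vg <= 0:
        raise NumericalError("zero-variance EBVs; bias slope undefined")
    return float(np.cov(y, g, ddof=1)[0, 1] / vg)


def crossvalidate(
    y_c: pd.Series,
    method: PredictionMethod,
    varcomp: VarianceComponents,
    *,
    A_inv: Optional[RelationshipMatrix] = None,
    A22: Optional[RelationshipMatrix] = None,
    G: Optional[RelationshipMatrix] = None,
    H_inv: Optional[RelationshipMatrix] = None,
    n_folds: int = 5,
    n_repeats: int = 1,
    seed: int = 0,
    subset_ids: Optional[Sequence[str]] = None,
    h2: Optional[float] = None,
    pool_folds: bool = False,
) -> CvResult:
    """Seeded k-fold cross-validated prediction accuracy and bias.

    Animals in scope (phenotyped animals in the method's relationship
    structure, optionally restricted to ``subset_ids`` for cross-method
    comparisons) are partitioned into ``n_folds`` equal groups; each fold in
    turn is masked and predicted. Fold accuracy is Pearson's r between
    adjusted phenotype and EBV over the fold's animals divided by sqrt(h2);
    the empirical SE is sd(fold accuracies)/sqrt(n_folds); the bias slope is
    pooled over all validation predictions. ``n_repeats`` > 1 repeats the
    partition with fresh seeds and pools the fold accuracies.
    """
    _, ids = _kinv_for_method(method, A_inv=A_inv, A22=A22, G=G, H_inv=H_inv)
    y_c = y_c.dropna()
    scope = [a for a in ids if a in y_c.index]
    if subset_ids is not None:
        wanted = {str(a) for a in subset_ids}
        scope = [a for a in scope if a in wanted]
    if len(scope) < n_folds:
        raise ConfigError(
            f"{len(scope)} phenotyped animals in scope; need >= {n_folds}"
        )
    if h2 is None:
        h2 = varcomp.h2
    if not (0.0 < h2 <= 1.0):
        raise ConfigError("accuracy denominator requires h2 in (0, 1]")
    kwargs = dict(A_inv=A_inv, A22=A22, G=G, H_inv=H_inv)
    accs: list[float] = []
    pooled_y: list[np.ndarray] = []
    pooled_g: list[np.ndarray] = []
    for rep in range(n_repeats):
        rng = np.random.default_rng([int(seed), rep])
        perm = rng.permutation(len(scope))
        folds = np.array_split(perm, n_folds)
        rep_y, rep_g = [], []
        for fold in folds:
            fold_ids = [scope[i] for i in fold]
            if len(fold_ids) < 3:
                raise ConfigError(f"fold with {len(fold_ids)} animals; need >= 3")
            result = predict_ebv(
                y_c, method, varcomp, mask_ids=fold_ids, **kwargs
            )
            yv = y_c.loc[fold_ids].to_numpy(dtype=float)
            gv = result.ebv.loc[fold_ids].to_numpy(dtype=float)
            pooled_y.append(yv)
            pooled_g.append(gv)
            rep_y.append(yv)
            rep_g.append(gv)
            if not pool_folds:
                r = np.corrcoef(yv, gv)[0, 1]
                accs.append(float(r / np.sqrt(h2)))
        if pool_folds:
            r = np.corrcoef(np.concatenate(rep_y), np.concatenate(rep_g))[0, 1]
            accs.append(float(r / np.sqrt(h2)))
    slope = bias_slope(np.concatenate(pooled_y), np.concatenate(pooled_g))
    accs_arr = np.asarray(accs)
    se = float(accs_arr.std(ddof=1) / np.sqrt(len(accs_arr))) if len(accs_arr) > 1 else 0.0
    return CvResult(
        method=PredictionMethod(method),
        fold_accuracies=[float(a) for a in accs],
        mean_accuracy=float(accs_arr.mean()),
        empirical_se=se,
        bias_slope=slope,
        seed=seed,
    )
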